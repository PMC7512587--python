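# Methods

This note records the model, the defaults and why they were chosen, the
numerical decisions, what the synthetic generator does and does not
emulate, and known limitations. It documents design reasoning only;
every empirical number it mentions is computed by the test suite or the
acceptance script, not asserted here.

## Problem and data model

A *mutation record* is a single-residue substitution in a named protein
together with the experimental temperature (°C) and pH at which the
stability change was measured, and a ΔΔG (kcal/mol) and/or a binary
label. The mutation key includes temperature and pH: the same
substitution measured under different conditions is treated as a distinct
experiment, because condition dependence is part of what the method
predicts. The label convention is configurable; the default calls
ΔΔG > 0 stabilizing ("positive") and puts the ΔΔG = 0 boundary in the
destabilizing class, since published thermodynamic databases disagree on
sign conventions and a fixed, documented rule matters more than the
choice itself.

Class balancing keeps every stabilizing record and subsamples
destabilizing ones to `round(ratio · n_pos)` without replacement. With
868 positives and ratio 2 this requests 1736 negatives; the emulated
study reports 1737 for the same design, a one-record discrepancy we do
not reproduce silently (the rounding rule is the contract).
De-duplication against a reference set removes records with an identical
mutation key and records whose substitution (conditions ignored) appears
in the reference with the opposite label; the second rule is
deliberately condition-free, since an opposite label for the same
substitution at any condition makes the pair unusable for a direction
classifier's independent test set.

## Feature encoding

Attributes are read from AAindex1 flat files (one value per standard
residue). Entries with any missing value are dropped rather than imputed
— a mutation row must have no missing attribute values, and imputation
would manufacture physicochemical scales. Remaining attributes pass a
greedy Pearson filter in file order: an entry is kept iff |r| < 0.8
against every previously kept entry. Absolute correlation is used
because an anticorrelated scale carries the same information; file-order
greediness makes the retained set deterministic. Zero-variance entries
are dropped (r is undefined).

For m retained attributes the encodings are: 2m V features (odd index =
wild-type value, even = mutant), m M features (mutant − wild
difference), and their 3m-feature union; basis features are the two
residue symbols (kept categorical — an instance-based classifier handles
symbols natively and one-hot would distort the transformation model),
position, temperature and pH (numeric). By construction
M(k) = V(2k) − V(2k−1) exactly.

## mRMR and the ensemble ranking

Mutual information uses the plug-in estimator over discretized columns,
in bits. Numeric columns are discretized by the mean ± σ three-state
rule (below μ−σ / within / above μ+σ), the scheme of the original mRMR
literature; equal-frequency binning is available. Symbolic columns pass
through unchanged. The σ = 0 degenerate case maps everything to the
middle state.

The set-level quantities follow the quotient form: mean relevance D,
mean pairwise redundancy R with the i = j self-information terms
included in the double sum, and score D/R. The greedy ranking uses the
standard incremental form — first pick argmax I(i;c), then argmax of
I(i;c) over the mean MI against already-selected features. A zero mean
redundancy yields a +∞ sentinel ordered by relevance; all ties break by
(higher relevance, then lexicographic name), which makes rankings
deterministic and invariant to column order (property-tested). InfoGain
(relevance only) and chi-squared rankers are provided as baselines.

Regular-mRMR draws N resampled datasets, ranks each with mRMR truncated
to the top `per_set_top`, converts ranks to weights `k = n − pos + 1`
inside a window n (0 outside), and averages the weights into the
significance score S_j. Defaults N = 5, per_set_top = 50, n = 30 are the
emulated study's stated settings; truncate-at-50-then-weight-at-30 is
the reading most consistent with its description. The default resample
composition is "balanced": all positives plus an equal number of
negatives drawn without replacement, which keeps every scarce positive
while varying the negatives — the sampling noise the ensemble is meant
to average over. A "uniform" composition (size-`sample_size` simple
random sample) is available. The summation index in the significance
average runs over the N feature sets; S_j ties break by mean per-set
rank, then name.

## K* classifier

K* is lazy: fitting stores the instances and per-symbolic-attribute
symbol frequencies. Per attribute, the probability of transforming the
query value into a stored value is

* symbolic: P(a→b) = s·freq(b) for b ≠ a, (1−s) + s·freq(a) for b = a;
* numeric: weight exp(−|Δ|/x0) — the discrete exponential kernel over
  the stored values, a deliberate simplification of the original
  continuous-integral formulation that preserves its behaviour and is
  exactly testable.

The free scale per (query, attribute) is chosen by the blend b: the
effective count n_eff = (Σw)²/Σw² is driven to
n_lo + (b/100)(N − n_lo), with n_lo the s→0 / x0→0 limit (count of
matching or minimum-distance instances). x0 is solved by bisection on
log x0 with geometric bracket widening, vectorized across queries, to a
relative tolerance of 1e−6·N; non-convergence raises with the bracket.
s is solved on [0, 1] and clamped when the target is unreachable — at
b = 100 with non-uniform symbol frequencies the most uniform reachable
weighting is s = 1, which leaves residual frequency weighting; the exact
class-prior limit therefore holds attribute-wise for numeric features.
b = 0 and b = 100 short-circuit to their analytic limits
(minimum-distance indicator / uniform weights) rather than approaching
them numerically. The blend default is 20, the convention of the toolkit
that popularized K*; one global blend covers all attributes.

Per-instance probabilities are products over attributes, accumulated in
log space with per-row shifts to avoid underflow; class probabilities
are normalized sums over each class's instances. If the total mass is
exactly zero (possible at b = 0 when a query symbol matches no stored
instance) the classifier falls back to the training class priors. Exact
probability ties predict the destabilizing class — the majority class
under the 1:2 design — and the tie class is configurable. Models persist
to a single JSON archive (config, schema, instances, labels) and reload
bit-for-bit.

## Evaluation and wrapper selection

Sn, Sp, ACC and MCC come from pooled (micro-averaged) k-fold confusion
counts: with ~10% test folds and MCC's instability on small counts,
pooling is the stabler estimator. Folds are stratified by default and
seeded; a training fold containing a single class triggers a warning but
is still evaluated. Zero-denominator conventions: Sn/Sp are NaN
(undefined), MCC is 0 when any denominator factor vanishes.

The hill climb is a single greedy pass over the significance-ordered
candidates, starting from the basis-feature model; each candidate is
evaluated once on basis ∪ accepted ∪ {candidate} with the same seed
(hence identical folds — a paired comparison) and accepted iff the MCC
strictly improves. A second predicate (`mcc_then_sn`) also accepts equal
MCC with strictly higher sensitivity, because a strict-only rule cannot
represent selection traces in which a feature is retained at unchanged
MCC. A caveat worth stating plainly: with a noisy CV estimate, *any*
strict-improvement rule accepts the running maxima of the noise
sequence, so on data with no signal at all the procedure still accepts a
few (≈ ln of the list length) chance features, independent of sample
size. This is a property of wrapper selection by noisy score, not an
implementation artifact; an acceptance margin or repeated-CV averaging
would reduce it but is not part of the procedure specified here.

## Synthetic generator

The generator emulates the structure of a thermodynamic-database-derived
pool: ~30% stabilizing fraction (868/2864 in the emulated pool),
temperatures uniform on 5–65 °C, pH on 2.7–9.2, positions on 1–300,
random distinct residue pairs, and an attribute table of standard-normal
20-vectors (544 entries by default, matching the emulated attribute
count). Labels follow a logistic model on the planted attributes'
mutant-minus-wild differences; the intercept is calibrated by root
finding so the marginal stabilizing fraction equals `positive_fraction`
for any effect size (without calibration a strong effect inflates the
positive rate through the logistic's nonlinearity). An optional
independent label flip adds noise. ΔΔG magnitudes are |N(1, 0.5)|
kcal/mol with the sign implied by the label — only the sign is
meaningful. Routing the effect through attribute differences makes the
M feature the most direct signal carrier while the corresponding V pair
carries it jointly.

What the generator does *not* emulate: real protein sequences or
structures, correlated attributes (entries are independent draws, except
explicitly injected affine duplicates for filter tests), protein-level
clustering of mutations, condition–effect interactions, or the marginal
distributions of real thermodynamic databases beyond class balance and
condition ranges. Tests passing on this generator therefore demonstrate
that the pipeline recovers planted structure and honours its contracts —
not that any particular accuracy carries over to curated experimental
data.

## Problem sizes used in the checks

The end-to-end checks run at desk scale by design: parameter recovery
uses 500 records, 10 attributes (30 candidate features), effect size 5,
no label noise, 10 seeds for the ranking stage and 2 seeds for the
hill-climb stage; the no-signal (null) check uses 150 records, 10
attributes, 5-fold CV, 10 seeds. Unit oracles (exhaustive mutual
information, stepwise greedy recomputation, all-pairs correlation) run
on vectors of ≤ 40 samples and ≤ 6 features.

## Known limitations

* Exact feature identities from the emulated study (specific V/M indices)
  depend on its unstated attribute-database version and are out of scope;
  only the count identities (m → 2m/m/3m) are reproducible.
* The K* numeric model is the discrete-kernel approximation described
  above, not the original closed-form integral.
* Hill climbing is single-pass and deterministic; no restarts, no nested
  CV for the blend parameter.
* The chance-acceptance behaviour of strict-improvement wrapper selection
  under a pure-noise null, discussed above.
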