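"""Synthetic attribute tables and mutation datasets with plantable signal.

The generator emulates the structure of a ProTherm-derived training pool:
single-site substitutions with experimental temperature (5–65 °C) and pH
(2.7–9.2), a roughly 30 % stabilizing fraction (868 of 2864 in the
emulated pool), and an AAindex-style table of amino-acid attributes.

The label model is logistic on the planted difference features: for the
first ``n_informative`` attributes a, the generative log-odds of a
stabilizing label are

    logit p = b + effect_size · Σ_a (a(mut) − a(wild))

with the intercept b calibrated so the marginal stabilizing fraction
equals ``positive_fraction`` whatever the effect size, followed by an
optional independent label flip with probability ``label_noise``.  Routing the effect through attribute *differences* means
both the V (wild/mutant value) and M (difference) encodings carry the
signal, with the M feature carrying it most directly.  ΔΔG magnitudes are
cosmetic — |Normal(1, 0.5)| kcal/mol with the sign implied by the label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy.optimize import brentq

from .attributes import AAINDEX_ORDER, AttributeEntry, AttributeTable
from .dataset import NEGATIVE, POSITIVE, MutationDataset, MutationRecord
from .errors import KStableError


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic study.

    Defaults mirror the emulated study conditions: 2864 records with a
    868/2864 stabilizing fraction, temperatures uniform on 5–65 °C, pH on
    2.7–9.2, one informative attribute with a strong effect and no label
    noise.  ``n_attributes`` defaults to the 544 attributes of the emulated
    attribute database.
    """

    n_attributes: int = 544
    n_informative: int = 1
    n_records: int = 2864
    positive_fraction: float = 868 / 2864
    effect_size: float = 5.0
    temp_range: tuple[float, float] = (5.0, 65.0)
    ph_range: tuple[float, float] = (2.7, 9.2)
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_informative <= self.n_attributes):
            raise KStableError("n_informative must be in [0, n_attributes]")
        if not (0.0 < self.positive_fraction < 1.0):
            raise KStableError("positive_fraction must be in (0, 1)")
        if not (0.0 <= self.label_noise < 0.5):
            raise KStableError("label_noise must be in [0, 0.5)")
        for lo, hi in (self.temp_range, self.ph_range):
            if not lo < hi:
                raise KStableError("ranges must be non-empty intervals")


def make_attribute_table(
    spec: GeneratorSpec, duplicate_pairs: int = 0
) -> AttributeTable:
    """Draw ``n_attributes`` complete attributes, 20 standard-normal values each.

    ``duplicate_pairs`` appends that many affine copies (2·v + 1) of the
    first entries, giving |r| = 1 pairs for correlation-filter tests.
    """
    rng = np.random.default_rng(spec.seed)
    entries = []
    for i in range(spec.n_attributes):
        values = dict(zip(AAINDEX_ORDER, rng.standard_normal(20).tolist()))
        tag = "informative" if i < spec.n_informative else "background"
        entries.append(
            AttributeEntry(f"SYN{i + 1:04d}", f"synthetic {tag} attribute {i + 1}", values)
        )
    for j in range(duplicate_pairs):
        src = entries[j]
        values = {aa: 2.0 * src.values[aa] + 1.0 for aa in AAINDEX_ORDER}
        entries.append(
            AttributeEntry(f"DUP{j + 1:04d}",
                           f"affine duplicate of {src.accession}", values)
        )
    return AttributeTable(entries)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def make_mutation_dataset(spec: GeneratorSpec, table: AttributeTable) -> MutationDataset:
    """Generate a labelled dataset whose labels follow the logistic model."""
    rng = np.random.default_rng(spec.seed + 1)
    aa = np.array(list(AAINDEX_ORDER))
    n = spec.n_records
    wild_i = rng.integers(0, 20, size=n)
    shift = rng.integers(1, 20, size=n)
    mut_i = (wild_i + shift) % 20  # guaranteed ≠ wild
    positions = rng.integers(1, 301, size=n)
    temps = rng.uniform(*spec.temp_range, size=n)
    phs = rng.uniform(*spec.ph_range, size=n)
    protein_ids = np.array([f"P{j:04d}" for j in rng.integers(0, 40, size=n)])

    informative = [table[i] for i in range(spec.n_informative)]
    diff_sum = np.zeros(n)
    for entry in informative:
        vec = entry.vector()
        diff_sum += vec[mut_i] - vec[wild_i]
    z = spec.effect_size * diff_sum
    # Calibrate the intercept so the marginal stabilizing fraction equals
    # positive_fraction whatever the planted effect size.
    base = brentq(
        lambda b: float(np.mean(_sigmoid(b + z))) - spec.positive_fraction,
        -50.0, 50.0,
    )
    p_pos = _sigmoid(base + z)
    labels = np.where(rng.random(n) < p_pos, POSITIVE, NEGATIVE)
    if spec.label_noise > 0:
        flip = rng.random(n) < spec.label_noise
        labels = np.where(
            flip, np.where(labels == POSITIVE, NEGATIVE, POSITIVE), labels
        )
    magnitudes = np.abs(rng.normal(1.0, 0.5, size=n))
    ddg = np.where(labels == POSITIVE, magnitudes, -magnitudes)

    records = [
        MutationRecord(
            protein_id=str(protein_ids[i]),
            position=int(positions[i]),
            wild_aa=str(aa[wild_i[i]]),
            mut_aa=str(aa[mut_i[i]]),
            temperature=float(temps[i]),
            pH=float(phs[i]),
            ddg=float(ddg[i]),
            label=str(labels[i]),
        )
        for i in range(n)
    ]
    return MutationDataset(records, name=f"synthetic_seed{spec.seed}")


def informative_feature_names(spec: GeneratorSpec) -> dict[str, list[str]]:
    """Feature names that carry planted signal under the standard schemas.

    Assumes the attribute table is used unfiltered (the synthetic entries
    are independent draws, so the correlation filter keeps them all, in
    order).
    """
    m_names = [f"M{k}" for k in range(1, spec.n_informative + 1)]
    v_names = []
    for k in range(1, spec.n_informative + 1):
        v_names += [f"V{2 * k - 1}", f"V{2 * k}"]
    return {"M": m_names, "V": v_names}
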