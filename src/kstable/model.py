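"""High-level modelling interface: build, fit, summarize, predict.

:class:`KStableModel` bundles the whole workflow behind a single object:
attribute preparation (drop incomplete, Pearson de-correlation), feature
encoding, regular-mRMR significance ranking, hill-climbing wrapper
selection under cross-validated MCC, and a final K* classifier trained on
all records with the basis plus accepted features.  ``fit()`` returns a
:class:`KStableResults` carrying the selected features, the hill-climb
trace, pooled cross-validation metrics, and a ``summary()`` table;
``predict`` classifies new mutations.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .attributes import (
    FEATURE_SET_ALL,
    AttributeTable,
    FeatureMatrix,
    build_schema,
    concat_schemas,
    drop_incomplete,
    encode,
    encode_unlabelled,
    parse_aaindex1,
    pearson_filter,
)
from .dataset import MutationDataset, read_mutation_table
from .errors import KStableError
from .evaluation import (
    PREDICATE_MCC_STRICT,
    HillClimbTrace,
    Metrics,
    cross_validate,
)
from .evaluation import hill_climb as _hill_climb
from .kstar import KStarClassifier, KStarConfig
from .mrmr import DiscretizationScheme
from .regular_mrmr import ResamplePlan, SignificanceRanking, regular_mrmr_rank


class KStableModel:
    """Thermostability-change classifier specification bound to data.

    Parameters
    ----------
    dataset:
        Labelled mutation dataset (the training pool).
    attribute_table:
        Raw amino-acid attribute table; incomplete entries are dropped and
        attributes greedily de-correlated at ``corr_threshold`` before
        encoding.
    feature_set:
        Candidate encoding family: ``"2mrmr"`` (V features), ``"diff"``
        (M features) or ``"all"`` (both; default).
    plan, kstar_config, scheme:
        Resampling plan for regular-mRMR, K* hyperparameters, and the
        discretization scheme for mutual information.
    n_candidates:
        How many top-significance features enter the hill climb
        (default: the plan's weight window).
    k_folds, predicate, seed:
        Cross-validation folds, hill-climb acceptance predicate, and the
        seed governing resampling and fold assignment.
    """

    def __init__(
        self,
        dataset: MutationDataset,
        attribute_table: AttributeTable,
        feature_set: str = FEATURE_SET_ALL,
        corr_threshold: float = 0.8,
        plan: ResamplePlan | None = None,
        kstar_config: KStarConfig | None = None,
        scheme: DiscretizationScheme | None = None,
        n_candidates: int | None = None,
        k_folds: int = 10,
        predicate: str = PREDICATE_MCC_STRICT,
        seed: int = 0,
    ):
        if not dataset.has_labels:
            raise KStableError("KStableModel requires a fully labelled dataset")
        self.dataset = dataset
        self.raw_table = attribute_table
        self.table = pearson_filter(drop_incomplete(attribute_table), corr_threshold)
        if len(self.table) == 0:
            raise KStableError("no usable attributes after filtering")
        self.feature_set = feature_set
        self.plan = plan or ResamplePlan(seed=seed)
        self.kstar_config = kstar_config or KStarConfig()
        self.scheme = scheme or DiscretizationScheme()
        self.k_folds = k_folds
        self.predicate = predicate
        self.seed = seed
        self.basis_schema = build_schema(self.table, "basis")
        self.mrmr_schema = build_schema(self.table, feature_set)
        self.full_schema = concat_schemas(self.basis_schema, self.mrmr_schema)
        self.n_candidates = n_candidates or self.plan.n

    @classmethod
    def from_files(cls, mutation_table, aaindex_file, dialect: str = "csv", **kwargs):
        """Build a model straight from a mutation CSV/TSV and an AAindex1 file."""
        dataset = read_mutation_table(mutation_table, dialect=dialect)
        table = parse_aaindex1(aaindex_file)
        return cls(dataset, table, **kwargs)

    def fit(self) -> "KStableResults":
        """Run selection and training; returns the results object."""
        ranking = regular_mrmr_rank(
            self.dataset, self.table, self.mrmr_schema, self.plan, self.scheme
        )
        candidates = ranking.truncate(self.n_candidates)
        matrix = encode(self.dataset, self.table, self.full_schema)
        trace = _hill_climb(
            matrix,
            self.basis_schema.names,
            candidates,
            config=self.kstar_config,
            predicate=self.predicate,
            k=self.k_folds,
            seed=self.seed,
        )
        final_features = tuple(self.basis_schema.names) + trace.selected
        classifier = KStarClassifier(self.kstar_config).fit(matrix.select(final_features))
        return KStableResults(self, ranking, trace, final_features, classifier)


@dataclass
class KStableResults:
    """Fitted state: selection outcome, diagnostics, trained classifier."""

    model: KStableModel
    significance: SignificanceRanking
    trace: HillClimbTrace
    features: tuple[str, ...]
    classifier: KStarClassifier

    @property
    def selected(self) -> tuple[str, ...]:
        """Features accepted by the hill climb (excluding the basis set)."""
        return self.trace.selected

    @property
    def basis_metrics(self) -> Metrics:
        return self.trace.basis_metrics

    @property
    def cv_metrics(self) -> Metrics:
        """Pooled cross-validation metrics of the final feature combination."""
        return self.trace.final_metrics

    def predict(self, dataset) -> pd.DataFrame:
        """Classify mutations; returns probabilities and predicted labels."""
        frame = encode_unlabelled(dataset, self.model.table,
                                  self.classifier._schema)
        probs = self.classifier.predict_proba(frame)
        labels = self.classifier.predict(frame)
        out = probs.copy()
        out["prediction"] = labels
        return out

    def summary(self) -> str:
        """Plain-text report in the style of a model-results summary table."""
        m = self.model
        buf = io.StringIO()
        w = buf.write
        w("K* thermostability-change model\n")
        w("=" * 64 + "\n")
        w(f"Records:              {len(m.dataset)} "
          f"({m.dataset.n_positive} stabilizing / "
          f"{m.dataset.n_negative} destabilizing)\n")
        w(f"Attributes:           {len(m.raw_table)} raw -> "
          f"{len(m.table)} after completeness + |r|<{0.8:g} filter\n")
        w(f"Candidate encoding:   {m.feature_set} "
          f"({len(m.mrmr_schema)} features)\n")
        w(f"Resampling plan:      N={m.plan.N}, top {m.plan.per_set_top} per set, "
          f"weight window n={m.plan.n}, composition={m.plan.composition}\n")
        w(f"Classifier:           K* (blend={m.kstar_config.blend:g}), "
          f"{m.k_folds}-fold CV, seed={m.seed}\n")
        w("-" * 64 + "\n")
        w("Hill-climbing trace (pooled CV metrics)\n")
        w(f"{'feature combination':<34}{'Sn':>7}{'Sp':>7}{'ACC':>7}{'MCC':>7}\n")
        bm = self.basis_metrics
        w(f"{'Basis':<34}{bm.sn:>7.3f}{bm.sp:>7.3f}{bm.acc:>7.3f}{bm.mcc:>7.3f}\n")
        kept: list[str] = []
        for step in self.trace.steps:
            if not step.accepted:
                continue
            kept.append(step.feature)
            combo = "Basis + " + " + ".join(kept)
            sm = step.metrics
            w(f"{combo:<34}{sm.sn:>7.3f}{sm.sp:>7.3f}{sm.acc:>7.3f}{sm.mcc:>7.3f}\n")
        w("-" * 64 + "\n")
        w(f"Selected features:    {', '.join(self.selected) or '(none)'}\n")
        fm = self.cv_metrics
        w(f"Final CV metrics:     Sn={fm.sn:.3f}  Sp={fm.sp:.3f}  "
          f"ACC={fm.acc:.3f}  MCC={fm.mcc:.3f}\n")
        return buf.getvalue()
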