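"""Confusion metrics, seeded cross-validation, and hill-climbing selection.

Cross-validation pools the per-fold confusion counts before computing
metrics (micro-averaging), which keeps MCC stable when folds are small.
The hill climb is a single greedy pass over a priority-ordered candidate
list: starting from the basis-feature model, each candidate feature is
added once and kept only if it improves the cross-validated MCC (strict
improvement by default; a variant also accepts equal MCC with higher
sensitivity).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .attributes import FeatureMatrix
from .dataset import NEGATIVE, POSITIVE, kfold_indices
from .errors import KStableError
from .kstar import KStarClassifier, KStarConfig

PREDICATE_MCC_STRICT = "mcc_strict"
PREDICATE_MCC_THEN_SN = "mcc_then_sn"


@dataclass(frozen=True)
class ConfusionCounts:
    """2×2 confusion counts with positive = stabilizing."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise KStableError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


@dataclass(frozen=True)
class Metrics:
    """Sensitivity, specificity, accuracy, Matthews correlation.

    Sn or Sp with a zero denominator is reported as NaN (undefined);
    MCC with any zero denominator factor is 0 by convention.
    """

    sn: float
    sp: float
    acc: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {"Sn": self.sn, "Sp": self.sp, "ACC": self.acc, "MCC": self.mcc}

    def __str__(self) -> str:
        return (f"Sn={self.sn:.3f} Sp={self.sp:.3f} "
                f"ACC={self.acc:.3f} MCC={self.mcc:.3f}")


def confusion(predictions: Sequence, truths: Sequence) -> ConfusionCounts:
    """Cross-tabulate predicted vs true labels (positive = stabilizing)."""
    predictions = list(predictions)
    truths = list(truths)
    if len(predictions) != len(truths):
        raise KStableError(
            f"length mismatch: {len(predictions)} predictions vs {len(truths)} truths")
    tp = fp = fn = tn = 0
    for p, t in zip(predictions, truths):
        if t == POSITIVE:
            if p == POSITIVE:
                tp += 1
            else:
                fn += 1
        elif t == NEGATIVE:
            if p == POSITIVE:
                fp += 1
            else:
                tn += 1
        else:
            raise KStableError(f"unknown truth label {t!r}")
    return ConfusionCounts(tp, fp, fn, tn)


def metrics(c: ConfusionCounts) -> Metrics:
    """Compute Sn/Sp/ACC/MCC from confusion counts."""
    sn = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else math.nan
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else math.nan
    total = c.total
    acc = (c.tp + c.tn) / total if total > 0 else math.nan
    denom = (
        (c.tp + c.fn) * (c.tn + c.fp) * (c.tp + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return Metrics(sn, sp, acc, mcc)


@dataclass(frozen=True)
class CrossValidationResult:
    counts: ConfusionCounts  # pooled across folds
    metrics: Metrics
    k: int
    seed: int


def cross_validate(
    matrix: FeatureMatrix,
    feature_names: Iterable[str] | None = None,
    config: KStarConfig | None = None,
    k: int = 10,
    seed: int = 0,
    stratified: bool = True,
) -> CrossValidationResult:
    """Seeded k-fold CV of K* on a feature subset, pooling confusion counts."""
    if k < 2:
        raise KStableError(f"k must be ≥ 2, got {k}")
    sub = matrix if feature_names is None else matrix.select(feature_names)
    folds = kfold_indices(
        len(sub), k, seed=seed, labels=sub.target if stratified else None
    )
    n = len(sub)
    counts = ConfusionCounts()
    for fold in folds:
        test_mask = np.zeros(n, dtype=bool)
        test_mask[fold] = True
        train = sub.take(np.flatnonzero(~test_mask))
        test = sub.take(np.flatnonzero(test_mask))
        if len(set(train.target.tolist())) < 2:
            warnings.warn(
                "training fold contains a single class; fold still evaluated",
                stacklevel=2,
            )
        clf = KStarClassifier(config).fit(train)
        preds = clf.predict(test.frame)
        counts = counts + confusion(preds, test.target)
    if counts.total != n:
        raise KStableError("cross-validation folds did not cover every record once")
    return CrossValidationResult(counts, metrics(counts), k, seed)


def _accepts(candidate: Metrics, incumbent: Metrics, predicate: str) -> bool:
    if predicate == PREDICATE_MCC_STRICT:
        return candidate.mcc > incumbent.mcc
    if predicate == PREDICATE_MCC_THEN_SN:
        if candidate.mcc > incumbent.mcc:
            return True
        sn_c = -math.inf if math.isnan(candidate.sn) else candidate.sn
        sn_i = -math.inf if math.isnan(incumbent.sn) else incumbent.sn
        return candidate.mcc == incumbent.mcc and sn_c > sn_i
    raise KStableError(f"unknown acceptance predicate {predicate!r}")


@dataclass(frozen=True)
class HillClimbStep:
    feature: str
    metrics: Metrics
    accepted: bool


@dataclass
class HillClimbTrace:
    """Full record of one hill-climbing run."""

    basis_features: tuple[str, ...]
    basis_metrics: Metrics
    steps: tuple[HillClimbStep, ...]
    selected: tuple[str, ...]
    final_metrics: Metrics

    def to_tsv(self, target) -> None:
        rows = [
            {
                "feature_combination": " + ".join(["Basis"]),
                "Sn": self.basis_metrics.sn, "Sp": self.basis_metrics.sp,
                "ACC": self.basis_metrics.acc, "MCC": self.basis_metrics.mcc,
                "accepted": True,
            }
        ]
        kept: list[str] = []
        for s in self.steps:
            combo = " + ".join(["Basis"] + kept + [s.feature])
            rows.append(
                {"feature_combination": combo, "Sn": s.metrics.sn,
                 "Sp": s.metrics.sp, "ACC": s.metrics.acc, "MCC": s.metrics.mcc,
                 "accepted": s.accepted}
            )
            if s.accepted:
                kept.append(s.feature)
        pd.DataFrame(rows).to_csv(target, sep="\t", index=False)


def hill_climb(
    matrix: FeatureMatrix,
    basis_features: Iterable[str],
    priority_list,
    config: KStarConfig | None = None,
    predicate: str = PREDICATE_MCC_STRICT,
    k: int = 10,
    seed: int = 0,
) -> HillClimbTrace:
    """Greedy single-pass wrapper selection over a priority-ordered list.

    ``priority_list`` may be a SignificanceRanking, a RankedFeatureList, or
    a plain sequence of feature names; each feature is evaluated exactly
    once, in order, on top of basis ∪ already-accepted features.
    """
    basis = tuple(basis_features)
    names = getattr(priority_list, "names", None)
    candidates = tuple(names if names is not None else priority_list)
    if not candidates:
        raise KStableError("hill_climb requires a non-empty priority list")
    incumbent = cross_validate(matrix, basis, config, k=k, seed=seed).metrics
    basis_metrics = incumbent
    selected: list[str] = []
    steps: list[HillClimbStep] = []
    for feature in candidates:
        if feature in basis or feature in selected:
            # Re-adding an existing column cannot change the model.
            steps.append(HillClimbStep(feature, incumbent, False))
            continue
        subset = basis + tuple(selected) + (feature,)
        m = cross_validate(matrix, subset, config, k=k, seed=seed).metrics
        accepted = _accepts(m, incumbent, predicate)
        steps.append(HillClimbStep(feature, m, accepted))
        if accepted:
            selected.append(feature)
            incumbent = m
    return HillClimbTrace(basis, basis_metrics, tuple(steps),
                          tuple(selected), incumbent)
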