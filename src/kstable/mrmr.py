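"""Minimum-redundancy–maximum-relevance feature ranking.

Relevance and redundancy are plug-in mutual-information estimates (bits)
over discretized feature columns.  The set-level quantities are

    D = (1/|S|)   Σ_{i∈S}   I(i; c)        (mean relevance)
    R = (1/|S|²)  Σ_{i,j∈S} I(i; j)        (mean pairwise redundancy,
                                            diagonal included)
    mRMR = D / R                           (quotient combination)

Ranking uses the standard greedy incremental form of the quotient
criterion: the first feature maximizes I(i;c); each later pick maximizes
I(i;c) divided by its mean MI against the already-selected set.  Ties are
broken by higher relevance, then lexicographic feature name, so rankings
are deterministic and invariant to column order.

InfoGain (relevance-only) and chi-squared rankers are provided as
baselines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import mutual_info_score

from .attributes import FeatureMatrix
from .errors import KStableError

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class DiscretizationScheme:
    """How numeric columns are turned into states before MI estimation.

    ``mean_sigma_3state`` (default) maps v < μ−σ → 0, μ−σ ≤ v ≤ μ+σ → 1,
    v > μ+σ → 2, with μ and σ from the column itself.  ``equal_frequency``
    uses quantile bins.  Categorical columns always pass through unchanged.
    """

    method: str = "mean_sigma_3state"
    bins: int = 3

    def __post_init__(self) -> None:
        if self.method not in ("mean_sigma_3state", "equal_frequency"):
            raise KStableError(f"unknown discretization method {self.method!r}")
        if self.bins < 2:
            raise KStableError(f"bins must be ≥ 2, got {self.bins}")


def discretize(values, scheme: DiscretizationScheme | None = None) -> np.ndarray:
    """Discretize a single column; symbolic input is returned unchanged."""
    scheme = scheme or DiscretizationScheme()
    arr = np.asarray(values)
    if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
        return arr.copy()
    arr = arr.astype(float)
    if scheme.method == "mean_sigma_3state":
        mu = arr.mean()
        sigma = arr.std()
        return np.where(arr < mu - sigma, 0, np.where(arr > mu + sigma, 2, 1))
    codes = pd.qcut(arr, q=scheme.bins, labels=False, duplicates="drop")
    return np.nan_to_num(np.asarray(codes, dtype=float), nan=0.0).astype(int)


def mutual_information(x, y) -> float:
    """Plug-in mutual information between two state vectors, in bits."""
    x = np.asarray(x, dtype=object)
    y = np.asarray(y, dtype=object)
    if len(x) != len(y):
        raise KStableError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) == 0:
        raise KStableError("mutual_information of empty vectors")
    return max(0.0, float(mutual_info_score(x, y)) / _LN2)


def entropy_bits(x) -> float:
    """Plug-in Shannon entropy of a state vector, in bits."""
    _, counts = np.unique(np.asarray(x, dtype=object), return_counts=True)
    return float(stats.entropy(counts, base=2))


def relevance(features: Sequence, target) -> float:
    """Mean I(i;c) over a feature set (Eq. D)."""
    features = list(features)
    if not features:
        raise KStableError("relevance of an empty feature set")
    return float(np.mean([mutual_information(f, target) for f in features]))


def redundancy(features: Sequence) -> float:
    """(1/|S|²) Σ over all ordered pairs (i,j), diagonal included (Eq. R)."""
    features = list(features)
    if not features:
        raise KStableError("redundancy of an empty feature set")
    s = len(features)
    total = 0.0
    for i in range(s):
        for j in range(s):
            total += mutual_information(features[i], features[j])
    return total / (s * s)


def mrmr_score(D: float, R: float) -> float:
    """Quotient combination D / R; R = 0 maps to a +inf sentinel."""
    if R == 0.0:
        return math.inf
    return D / R


@dataclass(frozen=True)
class RankedFeature:
    name: str
    relevance: float  # I(i;c), bits
    redundancy: float  # mean MI against features selected before it, bits
    score: float


@dataclass
class RankedFeatureList:
    """Ordered ranking with per-feature relevance/redundancy/score."""

    entries: tuple[RankedFeature, ...]

    def __post_init__(self) -> None:
        self.entries = tuple(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, i):
        return self.entries[i]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries)

    def position(self, name: str) -> int | None:
        """1-based rank of a feature, or None if absent."""
        for i, e in enumerate(self.entries, start=1):
            if e.name == name:
                return i
        return None

    def truncate(self, n: int) -> "RankedFeatureList":
        return RankedFeatureList(self.entries[:n])

    def to_tsv(self, target) -> None:
        df = pd.DataFrame(
            {
                "rank": np.arange(1, len(self.entries) + 1),
                "feature": [e.name for e in self.entries],
                "relevance_bits": [e.relevance for e in self.entries],
                "redundancy_bits": [e.redundancy for e in self.entries],
                "score": [e.score for e in self.entries],
            }
        )
        df.to_csv(target, sep="\t", index=False)


def _discretized_columns(matrix: FeatureMatrix, scheme: DiscretizationScheme):
    cols = {}
    for name in matrix.feature_names:
        cols[name] = np.asarray(discretize(matrix.frame[name].to_numpy(), scheme),
                                dtype=object)
    return cols


def _check_n(n: int, n_features: int) -> None:
    if n <= 0:
        raise KStableError(f"n must be positive, got {n}")
    if n > n_features:
        raise KStableError(f"n={n} exceeds number of candidate features {n_features}")


def mrmr_rank(
    matrix: FeatureMatrix, n: int, scheme: DiscretizationScheme | None = None
) -> RankedFeatureList:
    """Greedy incremental quotient-mRMR ranking of the top ``n`` features."""
    scheme = scheme or DiscretizationScheme()
    _check_n(n, len(matrix.feature_names))
    cols = _discretized_columns(matrix, scheme)
    target = matrix.target
    rel = {name: mutual_information(col, target) for name, col in cols.items()}

    remaining = set(matrix.feature_names)
    red_sum = {name: 0.0 for name in remaining}  # Σ MI(i, j∈selected)
    entries: list[RankedFeature] = []
    for step in range(n):
        best_name, best_key = None, None
        for name in remaining:
            if step == 0:
                mean_red = 0.0
            else:
                mean_red = red_sum[name] / step
            score = mrmr_score(rel[name], mean_red)
            key = (score, rel[name], _NegStr(name))
            if best_key is None or key > best_key:
                best_name, best_key = name, key
        mean_red = 0.0 if step == 0 else red_sum[best_name] / step
        entries.append(
            RankedFeature(best_name, rel[best_name], mean_red,
                          mrmr_score(rel[best_name], mean_red))
        )
        remaining.discard(best_name)
        chosen_col = cols[best_name]
        for name in remaining:
            red_sum[name] += mutual_information(cols[name], chosen_col)
    return RankedFeatureList(tuple(entries))


class _NegStr(str):
    """Reverses string comparison so lexicographically smaller names win a max()."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


def infogain_rank(
    matrix: FeatureMatrix, n: int, scheme: DiscretizationScheme | None = None
) -> RankedFeatureList:
    """Relevance-only ranking by I(i;c)."""
    scheme = scheme or DiscretizationScheme()
    _check_n(n, len(matrix.feature_names))
    cols = _discretized_columns(matrix, scheme)
    rel = {name: mutual_information(col, matrix.target) for name, col in cols.items()}
    order = sorted(rel, key=lambda nm: (-rel[nm], nm))[:n]
    return RankedFeatureList(
        tuple(RankedFeature(nm, rel[nm], 0.0, rel[nm]) for nm in order)
    )


def chi2_statistic(x, y) -> float:
    """Pearson chi-squared statistic of the x × y contingency table."""
    table = pd.crosstab(pd.Series(np.asarray(x, dtype=object)),
                        pd.Series(np.asarray(y, dtype=object))).to_numpy()
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 0.0
    return float(stats.chi2_contingency(table, correction=False)[0])


def chisquared_rank(
    matrix: FeatureMatrix, n: int, scheme: DiscretizationScheme | None = None
) -> RankedFeatureList:
    """Ranking by the chi-squared statistic of (discretized feature × label)."""
    scheme = scheme or DiscretizationScheme()
    _check_n(n, len(matrix.feature_names))
    cols = _discretized_columns(matrix, scheme)
    rel = {name: mutual_information(col, matrix.target) for name, col in cols.items()}
    chi = {name: chi2_statistic(col, matrix.target) for name, col in cols.items()}
    order = sorted(chi, key=lambda nm: (-chi[nm], nm))[:n]
    return RankedFeatureList(
        tuple(RankedFeature(nm, rel[nm], 0.0, chi[nm]) for nm in order)
    )
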