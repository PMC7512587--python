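"""Regular-mRMR: ensemble feature selection by rank aggregation.

Plain mRMR ranks features on one (sub)sampled training set; when the
training set is itself a class-balanced subsample of a larger pool, the
ranking inherits that sampling noise.  Regular-mRMR stabilizes it:

1. draw N resampled datasets PT_1..PT_N from the full pool,
2. run mRMR on each, keeping the ``per_set_top`` highest-scoring features,
3. convert each feature's rank ``pos`` in each PT set into a weight
   ``k = n − pos + 1`` inside a window of size ``n`` (0 outside it),
4. average the weights over the N sets into a significance score
   ``S_j = (1/N) Σ_i k_{i,j}`` and rank features by S_j.

With the defaults (N = 5, top 50 kept per set, window n = 30) a feature
ranked first in every set scores S = 30; one absent from every top window
scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .attributes import AttributeTable, FeatureMatrix, FeatureSchema, encode
from .dataset import NEGATIVE, POSITIVE, MutationDataset
from .errors import DatasetError, KStableError
from .mrmr import DiscretizationScheme, RankedFeatureList, mrmr_rank

COMPOSITION_BALANCED = "balanced"
COMPOSITION_UNIFORM = "uniform"


@dataclass(frozen=True)
class ResamplePlan:
    """How the PT resamples are drawn and aggregated.

    ``balanced`` composition takes every positive record plus an equal
    number of negatives sampled without replacement (per set); ``uniform``
    draws ``sample_size`` records uniformly without replacement regardless
    of class.  ``sample_size`` defaults to 2 × n_positive when needed.
    """

    N: int = 5
    per_set_top: int = 50
    n: int = 30
    composition: str = COMPOSITION_BALANCED
    sample_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise KStableError(f"N must be ≥ 1, got {self.N}")
        if self.n > self.per_set_top:
            raise KStableError(
                f"weight window n={self.n} exceeds per_set_top={self.per_set_top}")
        if self.composition not in (COMPOSITION_BALANCED, COMPOSITION_UNIFORM):
            raise KStableError(f"unknown composition {self.composition!r}")


def build_pt_sets(dataset: MutationDataset, plan: ResamplePlan) -> list[MutationDataset]:
    """Draw the N resampled PT datasets under the plan's seed."""
    if not dataset.has_labels:
        raise DatasetError("build_pt_sets requires labels on every record")
    rng = np.random.default_rng(plan.seed)
    sets: list[MutationDataset] = []
    pos_idx = [i for i, r in enumerate(dataset) if r.label == POSITIVE]
    neg_idx = [i for i, r in enumerate(dataset) if r.label == NEGATIVE]
    for i in range(plan.N):
        if plan.composition == COMPOSITION_BALANCED:
            if len(neg_idx) < len(pos_idx):
                raise DatasetError(
                    f"balanced resample needs {len(pos_idx)} negatives, "
                    f"have {len(neg_idx)}")
            chosen = rng.choice(len(neg_idx), size=len(pos_idx), replace=False)
            keep = set(pos_idx) | {neg_idx[j] for j in chosen.tolist()}
        else:
            size = plan.sample_size or min(len(dataset), 2 * len(pos_idx))
            if size > len(dataset):
                raise DatasetError(
                    f"uniform resample of {size} exceeds dataset size {len(dataset)}")
            keep = set(rng.choice(len(dataset), size=size, replace=False).tolist())
        records = [r for j, r in enumerate(dataset) if j in keep]
        sets.append(MutationDataset(records, name=f"{dataset.name}_PT{i + 1}"))
    return sets


def rank_weight(pos: int, n: int) -> int:
    """Rank-derived weight k = n − pos + 1 inside the window, 0 outside."""
    if pos < 1:
        raise KStableError(f"rank position must be ≥ 1, got {pos}")
    if pos > n:
        return 0
    return n - pos + 1


@dataclass(frozen=True)
class SignificanceEntry:
    name: str
    score: float  # S_j, the mean rank weight
    per_set_ranks: tuple[int, ...]  # 1-based rank in each PT set, 0 = absent


@dataclass
class SignificanceRanking:
    """Features ordered by significance score S_j (descending)."""

    entries: tuple[SignificanceEntry, ...]
    n: int  # the weight window used

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

    def truncate(self, n: int) -> "SignificanceRanking":
        return SignificanceRanking(self.entries[:n], self.n)

    def to_tsv(self, target) -> None:
        n_sets = len(self.entries[0].per_set_ranks) if self.entries else 0
        df = pd.DataFrame(
            {
                "feature": [e.name for e in self.entries],
                "significance": [e.score for e in self.entries],
                **{
                    f"rank_in_PT{i + 1}": [e.per_set_ranks[i] for e in self.entries]
                    for i in range(n_sets)
                },
            }
        )
        df.to_csv(target, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, source, n: int = 30) -> "SignificanceRanking":
        df = pd.read_csv(source, sep="\t")
        rank_cols = [c for c in df.columns if c.startswith("rank_in_PT")]
        entries = tuple(
            SignificanceEntry(
                str(row["feature"]), float(row["significance"]),
                tuple(int(row[c]) for c in rank_cols))
            for _, row in df.iterrows()
        )
        return cls(entries, n)


def significance(
    per_set_rankings: Sequence[RankedFeatureList], plan: ResamplePlan
) -> SignificanceRanking:
    """Aggregate per-set mRMR rankings into significance scores.

    Rankings are truncated to ``plan.per_set_top`` before weighting; the
    weight window is ``plan.n``.  Output is sorted by S_j descending, ties
    by mean per-set rank (absent counted as per_set_top + 1), then name.
    """
    rankings = list(per_set_rankings)
    if not rankings:
        raise KStableError("significance requires at least one ranking")
    rankings = [r.truncate(plan.per_set_top) for r in rankings]
    names: list[str] = []
    seen: set[str] = set()
    for r in rankings:
        for nm in r.names:
            if nm not in seen:
                seen.add(nm)
                names.append(nm)
    N = len(rankings)
    absent_rank = plan.per_set_top + 1
    entries = []
    for nm in names:
        ranks = tuple(r.position(nm) or 0 for r in rankings)
        s = sum(rank_weight(p, plan.n) for p in ranks if p > 0) / N
        mean_rank = float(np.mean([p if p > 0 else absent_rank for p in ranks]))
        entries.append((nm, s, mean_rank, ranks))
    entries.sort(key=lambda t: (-t[1], t[2], t[0]))
    return SignificanceRanking(
        tuple(SignificanceEntry(nm, s, ranks) for nm, s, _, ranks in entries),
        n=plan.n,
    )


def regular_mrmr_rank(
    dataset: MutationDataset,
    table: AttributeTable,
    schema: FeatureSchema,
    plan: ResamplePlan | None = None,
    scheme: DiscretizationScheme | None = None,
) -> SignificanceRanking:
    """Full regular-mRMR pipeline: resample → per-set mRMR → aggregate."""
    plan = plan or ResamplePlan()
    scheme = scheme or DiscretizationScheme()
    pt_sets = build_pt_sets(dataset, plan)
    rankings = []
    for pt in pt_sets:
        matrix = encode(pt, table, schema)
        top = min(plan.per_set_top, len(schema))
        rankings.append(mrmr_rank(matrix, top, scheme))
    return significance(rankings, plan)
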