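"""Mutation datasets: reading, labelling, balancing, de-duplication, folds.

A :class:`MutationRecord` is one single-site substitution together with the
experimental conditions (temperature, pH) under which the stability change
was measured, and either a free-energy difference ΔΔG (kcal/mol), a binary
stability label, or both.  A :class:`MutationDataset` is an ordered,
key-unique collection of records.  The mutation key includes temperature and
pH: the same substitution measured under different conditions is a distinct
experiment.
"""

from __future__ import annotations

import dataclasses
import io
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .errors import DatasetError, MutationTableError

#: The 20 standard amino-acid one-letter codes.
AA_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY")

POSITIVE = "positive"
NEGATIVE = "negative"
LABELS = (POSITIVE, NEGATIVE)

#: Default ΔΔG sign convention: ΔΔG > 0 means stabilizing.
DDG_GT0_STABILIZING = "positive_is_stabilizing_ddG_gt0"
DDG_LT0_STABILIZING = "positive_is_stabilizing_ddG_lt0"

#: Column order of the on-disk mutation table.
TABLE_COLUMNS = (
    "protein_id",
    "position",
    "wild_aa",
    "mut_aa",
    "temperature_C",
    "pH",
    "ddG",
    "label",
)
_REQUIRED_COLUMNS = TABLE_COLUMNS[:6]


@dataclass(frozen=True)
class MutationRecord:
    """One single-site mutation with its experimental context.

    Invariants are enforced at construction: the wild-type and mutant
    residues must be distinct standard amino acids, pH must lie in [0, 14],
    and at least one of ``ddg`` or ``label`` must be present.
    """

    protein_id: str
    position: int
    wild_aa: str
    mut_aa: str
    temperature: float
    pH: float
    ddg: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise DatasetError("protein_id must be non-empty")
        if not (isinstance(self.position, (int, np.integer)) and self.position >= 1):
            raise DatasetError(f"position must be a positive integer, got {self.position!r}")
        for role, aa in (("wild_aa", self.wild_aa), ("mut_aa", self.mut_aa)):
            if aa not in AA_LETTERS:
                raise DatasetError(f"{role} {aa!r} is not a standard amino-acid letter")
        if self.wild_aa == self.mut_aa:
            raise DatasetError(
                f"wild_aa and mut_aa are both {self.wild_aa!r}: not a mutation"
            )
        if not (0.0 <= self.pH <= 14.0):
            raise DatasetError(f"pH {self.pH!r} outside [0, 14]")
        if self.temperature < -273.15:
            raise DatasetError(f"temperature {self.temperature!r} below absolute zero")
        if self.ddg is not None and not math.isfinite(self.ddg):
            raise DatasetError(f"ddG must be finite, got {self.ddg!r}")
        if self.label is not None and self.label not in LABELS:
            raise DatasetError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.ddg is None and self.label is None:
            raise DatasetError("record needs at least one of ddG or label")

    @property
    def key(self) -> tuple:
        """Full mutation key: substitution plus experimental conditions."""
        return (
            self.protein_id,
            int(self.position),
            self.wild_aa,
            self.mut_aa,
            float(self.temperature),
            float(self.pH),
        )

    @property
    def site_key(self) -> tuple:
        """Condition-free key: the substitution itself."""
        return (self.protein_id, int(self.position), self.wild_aa, self.mut_aa)


class MutationDataset:
    """Ordered collection of :class:`MutationRecord` with unique keys."""

    def __init__(self, records: Iterable[MutationRecord], name: str = "dataset"):
        self.records: tuple[MutationRecord, ...] = tuple(records)
        self.name = name
        seen: set[tuple] = set()
        for r in self.records:
            if r.key in seen:
                raise DatasetError(f"duplicate mutation key {r.key} in dataset {name!r}")
            seen.add(r.key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MutationRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> MutationRecord:
        return self.records[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, MutationDataset) and self.records == other.records

    @property
    def labels(self) -> tuple[str | None, ...]:
        return tuple(r.label for r in self.records)

    @property
    def has_labels(self) -> bool:
        return all(r.label is not None for r in self.records)

    @property
    def n_positive(self) -> int:
        return sum(r.label == POSITIVE for r in self.records)

    @property
    def n_negative(self) -> int:
        return sum(r.label == NEGATIVE for r in self.records)

    def positives(self) -> "MutationDataset":
        return MutationDataset(
            (r for r in self.records if r.label == POSITIVE), f"{self.name}_pos"
        )

    def negatives(self) -> "MutationDataset":
        return MutationDataset(
            (r for r in self.records if r.label == NEGATIVE), f"{self.name}_neg"
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "protein_id": r.protein_id,
                "position": int(r.position),
                "wild_aa": r.wild_aa,
                "mut_aa": r.mut_aa,
                "temperature_C": float(r.temperature),
                "pH": float(r.pH),
                "ddG": np.nan if r.ddg is None else float(r.ddg),
                "label": r.label,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))

    def to_csv(self, path_or_buf, dialect: str = "csv") -> None:
        sep = "," if dialect == "csv" else "\t"
        self.to_dataframe().to_csv(path_or_buf, sep=sep, index=False)


def read_mutation_table(source, dialect: str = "csv", name: str | None = None) -> MutationDataset:
    """Read a CSV/TSV mutation table into a :class:`MutationDataset`.

    The header must name ``protein_id, position, wild_aa, mut_aa,
    temperature_C, pH`` and may add ``ddG`` and/or ``label``.  Rows that
    violate record invariants are collected and reported together with
    their 1-based line numbers (header = line 1).
    """
    if dialect not in ("csv", "tsv"):
        raise MutationTableError(f"unknown dialect {dialect!r}")
    sep = "," if dialect == "csv" else "\t"
    try:
        df = pd.read_csv(source, sep=sep, dtype={"protein_id": str, "label": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise MutationTableError(f"cannot parse mutation table: {exc}") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MutationTableError(f"malformed header: missing columns {missing}")

    records: list[MutationRecord] = []
    row_errors: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        try:
            ddg = row.get("ddG", np.nan)
            ddg = None if pd.isna(ddg) else float(ddg)
            label = row.get("label", None)
            label = None if pd.isna(label) else str(label).strip().lower()
            records.append(
                MutationRecord(
                    protein_id=str(row["protein_id"]),
                    position=int(row["position"]),
                    wild_aa=str(row["wild_aa"]),
                    mut_aa=str(row["mut_aa"]),
                    temperature=float(row["temperature_C"]),
                    pH=float(row["pH"]),
                    ddg=ddg,
                    label=label,
                )
            )
        except (DatasetError, ValueError, TypeError) as exc:
            row_errors.append((line, str(exc)))
    if row_errors:
        raise MutationTableError("invalid rows in mutation table", row_errors)
    if name is None:
        name = getattr(source, "name", None) or "dataset"
    return MutationDataset(records, name=str(name))


def label_from_ddg(
    record: MutationRecord, convention: str = DDG_GT0_STABILIZING
) -> MutationRecord:
    """Return a copy of ``record`` with the label set from the sign of ΔΔG.

    Under the default convention ΔΔG > 0 is stabilizing (positive) and
    ΔΔG ≤ 0 destabilizing; the boundary ΔΔG = 0 is destabilizing.  The
    alternate convention flips the sign.
    """
    if record.ddg is None:
        raise DatasetError("cannot label from ddG: ddG is absent")
    if convention == DDG_GT0_STABILIZING:
        label = POSITIVE if record.ddg > 0 else NEGATIVE
    elif convention == DDG_LT0_STABILIZING:
        label = POSITIVE if record.ddg < 0 else NEGATIVE
    else:
        raise DatasetError(f"unknown ΔΔG sign convention {convention!r}")
    return dataclasses.replace(record, label=label)


def label_dataset_from_ddg(
    dataset: MutationDataset, convention: str = DDG_GT0_STABILIZING
) -> MutationDataset:
    """Apply :func:`label_from_ddg` to every record."""
    return MutationDataset(
        (label_from_ddg(r, convention) for r in dataset), name=dataset.name
    )


def balance_dataset(dataset: MutationDataset, ratio: float, seed: int) -> MutationDataset:
    """Class-ratio balancing: keep all positives, subsample the negatives.

    Keeps every positive record and exactly ``round(ratio * n_positive)``
    negatives sampled uniformly without replacement under ``seed``.  Record
    order of the input is preserved.
    """
    if not dataset.has_labels:
        raise DatasetError("balance_dataset requires labels on every record")
    if ratio <= 0:
        raise DatasetError(f"ratio must be positive, got {ratio!r}")
    n_pos = dataset.n_positive
    n_neg = dataset.n_negative
    want = round(ratio * n_pos)
    if n_neg < want:
        raise DatasetError(
            f"too few negatives: need {want}, have {n_neg} (deficit {want - n_neg})"
        )
    neg_idx = [i for i, r in enumerate(dataset) if r.label == NEGATIVE]
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(len(neg_idx), size=want, replace=False).tolist())
    keep = {neg_idx[j] for j in chosen}
    records = [
        r for i, r in enumerate(dataset) if r.label == POSITIVE or i in keep
    ]
    return MutationDataset(records, name=f"{dataset.name}_balanced")


def deduplicate_against(
    candidate: MutationDataset, reference: MutationDataset
) -> MutationDataset:
    """Remove redundant and conflicting records from ``candidate``.

    Redundant: same full mutation key occurs in ``reference``.  Conflicting:
    the same substitution (protein, position, wild, mutant — conditions
    ignored) occurs in ``reference`` with the opposite label.
    """
    if not (candidate.has_labels and reference.has_labels):
        raise DatasetError("deduplicate_against requires labels on both datasets")
    ref_keys = {r.key for r in reference}
    ref_site_labels: dict[tuple, set[str]] = {}
    for r in reference:
        ref_site_labels.setdefault(r.site_key, set()).add(r.label)

    kept = []
    for r in candidate:
        if r.key in ref_keys:
            continue
        other = ref_site_labels.get(r.site_key, set())
        opposite = NEGATIVE if r.label == POSITIVE else POSITIVE
        if opposite in other:
            continue
        kept.append(r)
    return MutationDataset(kept, name=f"{candidate.name}_dedup")


def kfold_split(
    dataset: MutationDataset, k: int, seed: int = 0, stratified: bool = True
) -> list[MutationDataset]:
    """Partition the dataset into ``k`` seeded, (optionally stratified) folds."""
    if k < 2:
        raise DatasetError(f"k must be ≥ 2, got {k}")
    if k > len(dataset):
        raise DatasetError(f"k={k} exceeds dataset size {len(dataset)}")
    idx_folds = kfold_indices(len(dataset), k, seed=seed,
                              labels=dataset.labels if stratified else None)
    return [
        MutationDataset((dataset[i] for i in fold), name=f"{dataset.name}_fold{j}")
        for j, fold in enumerate(idx_folds)
    ]


def kfold_indices(
    n: int, k: int, seed: int = 0, labels: Sequence | None = None
) -> list[np.ndarray]:
    """Index-level fold assignment shared by dataset- and matrix-level CV."""
    if labels is not None:
        if any(l is None for l in labels):
            raise DatasetError("stratified folds require labels on every record")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        y = np.asarray(labels, dtype=object)
        return [test for _, test in splitter.split(np.zeros(n), y)]
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(n))]
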