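"""Amino-acid attribute tables and physicochemical feature encoding.

Attributes come from AAindex1-style flat files: one numeric value per
standard residue per attribute (hydrophobicity scales, volumes, transfer
energies, ...).  After dropping incomplete entries and greedily removing
highly correlated ones, each retained attribute k yields

* two **V features** — ``V(2k-1)`` = attribute value of the wild-type
  residue, ``V(2k)`` = value of the mutant residue ("2-mRMR" encoding);
* one **M feature** — ``M(k)`` = mutant minus wild-type value
  ("diff-mRMR" encoding).

The odd-index = wild-type convention is fixed so that feature names are
stable identifiers across encodings.  Basis features (wild/mutant residue
symbols, position, temperature, pH) are carried alongside: residues stay
categorical symbols, the rest numeric.
"""

from __future__ import annotations

import io
import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .dataset import MutationDataset
from .errors import AAindexFormatError, DatasetError, EncodingError

#: Residue order of AAindex1 value rows (A R N D C Q E G H I / L K M F P S T W Y V).
AAINDEX_ORDER = "ARNDCQEGHILKMFPSTWYV"

FEATURE_SET_BASIS = "basis"
FEATURE_SET_2MRMR = "2mrmr"
FEATURE_SET_DIFF = "diff"
FEATURE_SET_ALL = "all"
FEATURE_SETS = (FEATURE_SET_BASIS, FEATURE_SET_2MRMR, FEATURE_SET_DIFF, FEATURE_SET_ALL)

KIND_BASIS_SYMBOLIC = "basis_symbolic"
KIND_BASIS_NUMERIC = "basis_numeric"
KIND_V = "V"
KIND_M = "M"

BASIS_FEATURES = ("wild_aa", "mut_aa", "position", "temperature", "pH")
_BASIS_KINDS = {
    "wild_aa": KIND_BASIS_SYMBOLIC,
    "mut_aa": KIND_BASIS_SYMBOLIC,
    "position": KIND_BASIS_NUMERIC,
    "temperature": KIND_BASIS_NUMERIC,
    "pH": KIND_BASIS_NUMERIC,
}


@dataclass(frozen=True)
class AttributeEntry:
    """One named amino-acid attribute: accession, description, 20 values.

    ``values`` maps residue letters to floats; a missing (``NA``) value is
    stored as ``None``.
    """

    accession: str
    description: str
    values: Mapping[str, float | None]

    @property
    def complete(self) -> bool:
        return all(self.values.get(aa) is not None for aa in AAINDEX_ORDER)

    def vector(self) -> np.ndarray:
        """Values in AAindex residue order; requires completeness."""
        if not self.complete:
            raise EncodingError(f"attribute {self.accession} has missing values")
        return np.array([self.values[aa] for aa in AAINDEX_ORDER], dtype=float)


class AttributeTable:
    """Ordered collection of attributes with unique accessions."""

    def __init__(self, entries: Iterable[AttributeEntry]):
        self.entries: tuple[AttributeEntry, ...] = tuple(entries)
        seen: set[str] = set()
        for e in self.entries:
            if e.accession in seen:
                raise AAindexFormatError(f"duplicate accession {e.accession!r}")
            seen.add(e.accession)
        self._by_accession = {e.accession: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[AttributeEntry]:
        return iter(self.entries)

    def __getitem__(self, key: int | str) -> AttributeEntry:
        if isinstance(key, str):
            try:
                return self._by_accession[key]
            except KeyError:
                raise KeyError(f"no attribute with accession {key!r}") from None
        return self.entries[key]

    def __contains__(self, accession: str) -> bool:
        return accession in self._by_accession

    @property
    def accessions(self) -> tuple[str, ...]:
        return tuple(e.accession for e in self.entries)

    @property
    def complete(self) -> bool:
        return all(e.complete for e in self.entries)


def _coerce_stream(source):
    if hasattr(source, "read"):
        return source, False
    return open(os.fspath(source), "r", encoding="utf-8"), True


def parse_aaindex1(source) -> AttributeTable:
    """Parse an AAindex1 flat file (path or text stream).

    Recognized record lines: ``H`` accession, ``D`` description, ``I``
    value-header followed by two rows of 10 whitespace-separated values in
    the standard residue order, ``//`` entry terminator.  Other record
    types (R, A, T, J, C, ...) are ignored.  ``NA`` values are parsed as
    missing.
    """
    stream, close = _coerce_stream(source)
    entries: list[AttributeEntry] = []
    acc: str | None = None
    desc_parts: list[str] = []
    value_rows: list[list[float | None]] = []
    rows_expected = 0
    try:
        for raw in stream:
            line = raw.rstrip("\n")
            if rows_expected > 0:
                tokens = line.split()
                if len(tokens) != 10:
                    raise AAindexFormatError(
                        f"attribute {acc or '<unnamed>'}: value row has "
                        f"{len(tokens)} tokens, expected 10"
                    )
                row: list[float | None] = []
                for tok in tokens:
                    if tok.upper() == "NA":
                        row.append(None)
                    else:
                        try:
                            row.append(float(tok))
                        except ValueError:
                            raise AAindexFormatError(
                                f"attribute {acc}: bad value token {tok!r}"
                            ) from None
                value_rows.append(row)
                rows_expected -= 1
                continue
            if line.startswith("H "):
                acc = line[2:].strip()
            elif line.startswith("D "):
                desc_parts.append(line[2:].strip())
            elif line.startswith("I "):
                value_rows = []
                rows_expected = 2
            elif line.startswith("//"):
                if acc is not None:
                    if len(value_rows) != 2:
                        raise AAindexFormatError(
                            f"attribute {acc}: missing value rows"
                        )
                    flat = value_rows[0] + value_rows[1]
                    values = dict(zip(AAINDEX_ORDER, flat))
                    entries.append(
                        AttributeEntry(acc, " ".join(desc_parts), values)
                    )
                acc = None
                desc_parts = []
                value_rows = []
        if rows_expected > 0:
            raise AAindexFormatError(f"attribute {acc}: truncated value rows")
    finally:
        if close:
            stream.close()
    return AttributeTable(entries)


def write_aaindex1(table: AttributeTable, target) -> None:
    """Write an :class:`AttributeTable` back to AAindex1 flat-file format."""
    stream, close = (target, False) if hasattr(target, "write") else (
        open(os.fspath(target), "w", encoding="utf-8"), True)
    try:
        for e in table:
            stream.write(f"H {e.accession}\n")
            stream.write(f"D {e.description}\n")
            stream.write("I    A/L     R/K     N/M     D/F     C/P     "
                         "Q/S     E/T     G/W     H/Y     I/V\n")
            vals = [e.values.get(aa) for aa in AAINDEX_ORDER]
            for half in (vals[:10], vals[10:]):
                stream.write("  " + " ".join(
                    "NA" if v is None else f"{v:.6g}" for v in half) + "\n")
            stream.write("//\n")
    finally:
        if close:
            stream.close()


def drop_incomplete(table: AttributeTable) -> AttributeTable:
    """Remove entries with any missing value, preserving order."""
    return AttributeTable(e for e in table if e.complete)


def pearson_filter(
    table: AttributeTable, threshold: float = 0.8, absolute: bool = True
) -> AttributeTable:
    """Greedy de-correlation scan in table order.

    An entry is retained iff its Pearson correlation against every
    previously retained entry stays below ``threshold`` (absolute value by
    default).  Zero-variance entries are dropped outright (r undefined).
    """
    if not table.complete:
        raise EncodingError("pearson_filter requires a complete attribute table")
    kept: list[AttributeEntry] = []
    kept_vectors: list[np.ndarray] = []
    for e in table:
        v = e.vector()
        if np.std(v) == 0.0:
            continue
        ok = True
        for w in kept_vectors:
            r = float(np.corrcoef(v, w)[0, 1])
            if (abs(r) if absolute else r) >= threshold:
                ok = False
                break
        if ok:
            kept.append(e)
            kept_vectors.append(v)
    return AttributeTable(kept)


@dataclass(frozen=True)
class FeatureDescriptor:
    """What one feature column is: its kind and, for V/M, its source attribute."""

    kind: str
    attribute_index: int | None = None  # 1-based, in post-filter table order
    accession: str | None = None
    role: str | None = None  # "wild" | "mutant" for V features


@dataclass
class FeatureSchema:
    """Ordered feature names plus a descriptor for each."""

    names: tuple[str, ...]
    descriptors: dict[str, FeatureDescriptor]
    feature_set: str = "custom"

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        missing = [n for n in self.names if n not in self.descriptors]
        if missing:
            raise EncodingError(f"schema names without descriptors: {missing}")

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.descriptors

    @property
    def symbolic_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.names
                     if self.descriptors[n].kind == KIND_BASIS_SYMBOLIC)

    @property
    def numeric_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.names
                     if self.descriptors[n].kind != KIND_BASIS_SYMBOLIC)

    def subset(self, names: Iterable[str]) -> "FeatureSchema":
        names = tuple(names)
        unknown = [n for n in names if n not in self.descriptors]
        if unknown:
            raise EncodingError(f"unknown feature names: {unknown}")
        return FeatureSchema(names, {n: self.descriptors[n] for n in names},
                             feature_set="subset")

    def to_json(self) -> str:
        payload = {
            "feature_set": self.feature_set,
            "features": [
                {"name": n, **{k: v for k, v in vars(self.descriptors[n]).items()
                               if v is not None}}
                for n in self.names
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FeatureSchema":
        payload = json.loads(text)
        names = []
        descriptors = {}
        for item in payload["features"]:
            name = item.pop("name")
            names.append(name)
            descriptors[name] = FeatureDescriptor(**item)
        return cls(tuple(names), descriptors, payload.get("feature_set", "custom"))


def concat_schemas(*schemas: FeatureSchema) -> FeatureSchema:
    names: list[str] = []
    descriptors: dict[str, FeatureDescriptor] = {}
    for s in schemas:
        for n in s.names:
            if n in descriptors:
                raise EncodingError(f"duplicate feature name {n!r} across schemas")
            names.append(n)
            descriptors[n] = s.descriptors[n]
    return FeatureSchema(tuple(names), descriptors,
                         feature_set="+".join(s.feature_set for s in schemas))


def build_schema(table: AttributeTable, feature_set: str) -> FeatureSchema:
    """Construct the feature schema for one encoding family.

    For m retained attributes: ``2mrmr`` yields 2m V features (V1..V2m,
    odd = wild-type), ``diff`` yields m M features, ``all`` yields 3m
    (all V then all M), and ``basis`` yields the 5 mutation descriptors.
    """
    if feature_set not in FEATURE_SETS:
        raise EncodingError(f"unknown feature set {feature_set!r}")
    if feature_set == FEATURE_SET_BASIS:
        descriptors = {n: FeatureDescriptor(kind=_BASIS_KINDS[n]) for n in BASIS_FEATURES}
        return FeatureSchema(BASIS_FEATURES, descriptors, feature_set)

    if not table.complete:
        raise EncodingError("feature schemas require a complete attribute table")
    v_names: list[str] = []
    m_names: list[str] = []
    descriptors = {}
    for k, entry in enumerate(table, start=1):
        wild_name, mut_name = f"V{2 * k - 1}", f"V{2 * k}"
        v_names += [wild_name, mut_name]
        descriptors[wild_name] = FeatureDescriptor(
            KIND_V, attribute_index=k, accession=entry.accession, role="wild")
        descriptors[mut_name] = FeatureDescriptor(
            KIND_V, attribute_index=k, accession=entry.accession, role="mutant")
        m_name = f"M{k}"
        m_names.append(m_name)
        descriptors[m_name] = FeatureDescriptor(
            KIND_M, attribute_index=k, accession=entry.accession)
    if feature_set == FEATURE_SET_2MRMR:
        names = tuple(v_names)
    elif feature_set == FEATURE_SET_DIFF:
        names = tuple(m_names)
    else:
        names = tuple(v_names + m_names)
    descriptors = {n: descriptors[n] for n in names}
    return FeatureSchema(names, descriptors, feature_set)


@dataclass
class FeatureMatrix:
    """Encoded features for a dataset: a DataFrame plus schema and target.

    Symbolic columns hold residue letters (object dtype); everything else
    is float.  ``target`` is the per-row stability label vector.
    """

    frame: pd.DataFrame
    target: np.ndarray
    schema: FeatureSchema

    def __post_init__(self) -> None:
        self.target = np.asarray(self.target, dtype=object)
        if list(self.frame.columns) != list(self.schema.names):
            raise EncodingError("frame columns do not match schema names")
        if len(self.frame) != len(self.target):
            raise EncodingError("target length does not match row count")
        if self.frame.isna().any().any():
            raise EncodingError("feature matrix contains missing cells")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return self.schema.names

    def select(self, names: Iterable[str]) -> "FeatureMatrix":
        """Column subset (keeps all rows)."""
        sub = self.schema.subset(names)
        return FeatureMatrix(self.frame[list(sub.names)].copy(), self.target, sub)

    def take(self, indices) -> "FeatureMatrix":
        """Row subset by positional indices."""
        idx = np.asarray(indices, dtype=int)
        return FeatureMatrix(
            self.frame.iloc[idx].reset_index(drop=True), self.target[idx], self.schema
        )

    def to_csv(self, path, schema_path=None) -> None:
        df = self.frame.copy()
        df["__label__"] = self.target
        df.to_csv(path, index=False)
        if schema_path is not None:
            with open(schema_path, "w", encoding="utf-8") as fh:
                fh.write(self.schema.to_json())

    @classmethod
    def read_csv(cls, path, schema_path) -> "FeatureMatrix":
        with open(schema_path, "r", encoding="utf-8") as fh:
            schema = FeatureSchema.from_json(fh.read())
        df = pd.read_csv(path)
        target = df.pop("__label__").to_numpy(dtype=object)
        for n in schema.symbolic_names:
            df[n] = df[n].astype(object)
        return cls(df[list(schema.names)], target, schema)


def encode(
    dataset: MutationDataset, table: AttributeTable, schema: FeatureSchema
) -> FeatureMatrix:
    """Encode a labelled dataset under a schema.

    V(2k−1) = attribute_k(wild), V(2k) = attribute_k(mutant),
    M(k) = attribute_k(mutant) − attribute_k(wild); basis columns are copied
    from the record.
    """
    if not dataset.has_labels:
        raise DatasetError("encode requires labels on every record")
    return _encode_frame(dataset, table, schema,
                         target=np.array(dataset.labels, dtype=object))


def encode_unlabelled(
    dataset_records, table: AttributeTable, schema: FeatureSchema
) -> pd.DataFrame:
    """Encode records without requiring labels (prediction-time path)."""
    ds = dataset_records
    frame = _encode_frame(ds, table, schema, target=None)
    return frame


def _attribute_value(entry: AttributeEntry, aa: str) -> float:
    v = entry.values.get(aa)
    if v is None:
        raise EncodingError(
            f"attribute {entry.accession} has no value for residue {aa!r}")
    return float(v)


def _encode_frame(dataset, table, schema, target):
    columns: dict[str, list] = {n: [] for n in schema.names}
    for rec in dataset:
        for name in schema.names:
            d = schema.descriptors[name]
            if d.kind == KIND_BASIS_SYMBOLIC:
                columns[name].append(rec.wild_aa if name == "wild_aa" else rec.mut_aa)
            elif d.kind == KIND_BASIS_NUMERIC:
                val = {"position": float(rec.position),
                       "temperature": float(rec.temperature),
                       "pH": float(rec.pH)}[name]
                columns[name].append(val)
            else:
                if d.accession is not None and d.accession in table:
                    entry = table[d.accession]
                elif d.attribute_index is not None and d.attribute_index <= len(table):
                    entry = table[d.attribute_index - 1]
                else:
                    raise EncodingError(f"feature {name}: source attribute not in table")
                if d.kind == KIND_V:
                    aa = rec.wild_aa if d.role == "wild" else rec.mut_aa
                    columns[name].append(_attribute_value(entry, aa))
                else:  # M
                    columns[name].append(
                        _attribute_value(entry, rec.mut_aa)
                        - _attribute_value(entry, rec.wild_aa)
                    )
    frame = pd.DataFrame(columns, columns=list(schema.names))
    for n in schema.symbolic_names:
        frame[n] = frame[n].astype(object)
    if target is None:
        return frame
    return FeatureMatrix(frame, target, schema)
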