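import io

import numpy as np
import pandas as pd
import pytest

from kstable.attributes import (
    AAINDEX_ORDER,
    AttributeEntry,
    AttributeTable,
    FeatureDescriptor,
    FeatureMatrix,
    FeatureSchema,
    parse_aaindex1,
)
from kstable.dataset import MutationDataset, MutationRecord

# A two-entry AAindex1 fixture: the Kyte-Doolittle-style hydropathy values
# used for hand-computed encodings, and an entry with one NA value.
AAINDEX_FIXTURE = """\
H TEST0001
D synthetic hydropathy-like scale
R none
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   1.8    -4.5    -3.5    -3.5     2.5    -3.5    -3.5    -0.4    -3.2     4.5
   3.8    -3.9     1.9     2.8    -1.6    -0.8    -0.7    -0.9    -1.3     4.2
//
H TEST0002
D entry with a missing value
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.1     0.2      NA     0.4     0.5     0.6     0.7     0.8     0.9     1.0
   1.1     1.2     1.3     1.4     1.5     1.6     1.7     1.8     1.9     2.0
//
"""


@pytest.fixture
def aaindex_table() -> AttributeTable:
    return parse_aaindex1(io.StringIO(AAINDEX_FIXTURE))


@pytest.fixture
def hydro_entry(aaindex_table) -> AttributeEntry:
    return aaindex_table["TEST0001"]


def make_record(i=0, **kw) -> MutationRecord:
    base = dict(
        protein_id=f"P{i:03d}", position=10 + i, wild_aa="A", mut_aa="G",
        temperature=25.0, pH=7.0, ddg=1.0, label="positive",
    )
    base.update(kw)
    return MutationRecord(**base)


@pytest.fixture
def small_dataset() -> MutationDataset:
    """3 stabilizing + 5 destabilizing records with distinct keys."""
    records = [make_record(i, ddg=1.0 + i, label="positive") for i in range(3)]
    records += [
        make_record(10 + i, wild_aa="L", mut_aa="K", ddg=-1.0 - i, label="negative")
        for i in range(5)
    ]
    return MutationDataset(records, name="small")


def numeric_matrix(columns: dict, labels) -> FeatureMatrix:
    """FeatureMatrix with numeric-only columns (no symbolic attributes)."""
    names = tuple(columns)
    schema = FeatureSchema(
        names, {n: FeatureDescriptor(kind="basis_numeric") for n in names}
    )
    frame = pd.DataFrame({n: np.asarray(v, dtype=float) for n, v in columns.items()})
    return FeatureMatrix(frame, np.asarray(labels, dtype=object), schema)


def mixed_matrix(numeric: dict, symbolic: dict, labels) -> FeatureMatrix:
    names = tuple(numeric) + tuple(symbolic)
    desc = {n: FeatureDescriptor(kind="basis_numeric") for n in numeric}
    desc |= {n: FeatureDescriptor(kind="basis_symbolic") for n in symbolic}
    frame = pd.DataFrame(
        {**{n: np.asarray(v, dtype=float) for n, v in numeric.items()},
         **{n: np.asarray(v, dtype=object) for n, v in symbolic.items()}}
    )
    return FeatureMatrix(frame, np.asarray(labels, dtype=object),
                         FeatureSchema(names, desc))
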