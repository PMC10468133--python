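"""Shared fixture builders for the test suite."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cofrac.proteome import ProteinGroupTable


def make_table(rows, fractions, replicates) -> ProteinGroupTable:
    """Build a ProteinGroupTable from (protein_id, peptides, {(f, r): value})."""
    ids = [r[0] for r in rows]
    meta = pd.DataFrame({
        "gene": [f"G_{pid}" for pid in ids],
        "unique_peptides": [r[1] for r in rows],
        "is_decoy": [pid.startswith("REV_") for pid in ids],
        "is_contaminant": [pid.startswith("CON__") for pid in ids],
    }, index=pd.Index(ids, name="protein_id"))
    cols = pd.MultiIndex.from_product([fractions, replicates],
                                      names=["fraction", "replicate"])
    lfq = pd.DataFrame(0.0, index=meta.index, columns=cols)
    for pid, _, cells in rows:
        for (f, r), v in cells.items():
            lfq.loc[pid, (f, r)] = v
    return ProteinGroupTable(meta=meta, lfq=lfq)


def hand_filter_fixture():
    """20 hand-labeled rows over fractions 23–27 × 3 replicates.

    Returns (table, expected survivor ids, expected per-rule removal counts).
    Attribution follows cascade order: peptide rule, then co-occurrence,
    then decoy, then contaminant.
    """
    F = list(range(23, 28))
    R = [1, 2, 3]
    all3 = lambda f, v=100.0: {(f, r): v for r in R}
    rows = [
        ("P01", 5, all3(24)),                                   # keep
        ("P02", 3, all3(23)),                                   # keep (boundary)
        ("P03", 2, {(f, r): 50.0 for f in F for r in R}),       # peptides
        ("P04", 0, all3(25)),                                   # peptides
        ("P05", 5, {(24, 1): 9.0, (24, 2): 9.0, (25, 3): 9.0}),  # co-occurrence
        ("P06", 5, {}),                                         # co-occurrence
        ("P07", 4, all3(26)),                                   # keep
        ("REV_P08", 5, all3(24)),                               # decoy
        ("REV_P09", 1, all3(24)),                               # peptides (order)
        ("CON__P10", 5, all3(25)),                              # contaminant
        ("CON__P11", 5, {(24, 1): 7.0, (24, 2): 7.0}),          # co-occurrence
        ("P12", 3, {**all3(23), (26, 2): 5.0}),                 # keep
        ("P13", 10, all3(27)),                                  # keep
        ("P14", 3, {(24, 1): 4.0, (25, 2): 4.0, (26, 3): 4.0}),  # co-occurrence
        ("P15", 2, all3(24)),                                   # peptides
        ("P16", 6, {**all3(23), (25, 1): 2.0, (25, 2): 2.0}),   # keep
        ("P17", 3, {(f, r): 1.0 for f in F for r in R}),        # keep
        ("REV_P18", 4, {(23, 1): 3.0, (23, 3): 3.0}),           # co-occurrence
        ("P19", 3, all3(27, v=1e-6)),                           # keep (tiny > 0)
        ("P20", 4, {**all3(27), (23, 1): 8.0}),                 # keep
    ]
    table = make_table(rows, F, R)
    survivors = {"P01", "P02", "P07", "P12", "P13", "P16", "P17", "P19", "P20"}
    counts = {"peptides": 4, "cooccurrence": 5, "decoy": 1, "contaminant": 1}
    return table, survivors, counts


@pytest.fixture
def filter_fixture():
    return hand_filter_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
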