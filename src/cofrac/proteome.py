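"""Protein-group quantification tables and the identification filter cascade.

Label-free quantification (LFQ) intensities are reported per protein group,
per 1-ml fraction, per replicate run, in a MaxQuant-style tab-separated table.
The cascade keeps proteins with at least three unique peptides that were
detected in the same fraction in every replicate, then removes decoy-search
hits and annotated contaminants.  Surviving profiles are averaged across
replicates (zero = not detected, included in the mean), max-normalized per
protein, and compared against a reference lipoprotein proteome list.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

log = logging.getLogger(__name__)

__all__ = [
    "TableDialect",
    "ProteinGroupTable",
    "ProteinProfileMatrix",
    "FilterReport",
    "OverlapReport",
    "read_protein_groups",
    "read_reference_list",
    "filter_protein_groups",
    "average_lfq",
    "normalize_profiles",
    "total_abundance",
    "reference_overlap",
]


@dataclass(frozen=True)
class TableDialect:
    """Column conventions of the quantification table (MaxQuant defaults)."""

    protein_col: str = "Protein IDs"
    gene_col: str = "Gene names"
    peptides_col: str = "Unique peptides"
    lfq_pattern: str = r"LFQ intensity F(\d+) R(\d+)"
    reverse_col: str = "Reverse"
    contaminant_col: str = "Potential contaminant"
    flag_value: str = "+"
    decoy_prefix: str = "REV_"
    contaminant_prefix: str = "CON__"


DEFAULT_DIALECT = TableDialect()


@dataclass
class ProteinGroupTable:
    """Protein groups with per-(fraction, replicate) LFQ intensities.

    ``meta`` is indexed by accession with columns ``gene``, ``unique_peptides``,
    ``is_decoy``, ``is_contaminant``; ``lfq`` shares the index and has a
    (fraction, replicate) MultiIndex on columns.  Zero intensity means the
    protein was not detected in that fraction/run.
    """

    meta: pd.DataFrame
    lfq: pd.DataFrame
    filter_report: "FilterReport | None" = None

    def __post_init__(self):
        if not self.meta.index.equals(self.lfq.index):
            raise InputError("meta and lfq indices differ")
        if self.meta.index.has_duplicates:
            dup = self.meta.index[self.meta.index.duplicated()][0]
            raise InputError(f"duplicate protein id: {dup}")
        if (self.meta["unique_peptides"] < 0).any():
            raise InputError("unique_peptides must be >= 0")
        if (self.lfq.to_numpy() < 0).any():
            raise InputError("intensities must be >= 0")
        self.lfq = self.lfq.sort_index(axis=1)

    def __len__(self) -> int:
        return len(self.meta)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.meta.index)

    @property
    def fractions(self) -> list[int]:
        return sorted({f for f, _ in self.lfq.columns})

    @property
    def replicates(self) -> list[int]:
        return sorted({r for _, r in self.lfq.columns})

    def to_tsv(self, path: str | Path, dialect: TableDialect = DEFAULT_DIALECT) -> None:
        out = pd.DataFrame(index=self.meta.index)
        out[dialect.protein_col] = self.meta.index
        out[dialect.gene_col] = self.meta["gene"]
        out[dialect.peptides_col] = self.meta["unique_peptides"]
        for (f, r) in self.lfq.columns:
            out[f"LFQ intensity F{f} R{r}"] = self.lfq[(f, r)]
        out[dialect.reverse_col] = np.where(self.meta["is_decoy"], dialect.flag_value, "")
        out[dialect.contaminant_col] = np.where(
            self.meta["is_contaminant"], dialect.flag_value, "")
        out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_protein_groups(path: str | Path,
                        dialect: TableDialect = DEFAULT_DIALECT) -> ProteinGroupTable:
    """Parse a MaxQuant-dialect protein-group TSV."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"protein-group table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={dialect.reverse_col: str,
                                            dialect.contaminant_col: str})
    for col in (dialect.protein_col, dialect.peptides_col):
        if col not in df.columns:
            raise InputError(f"missing column {col!r} in {path}")
    pat = re.compile(dialect.lfq_pattern)
    lfq_cols = {}
    for col in df.columns:
        m = pat.fullmatch(col)
        if m:
            lfq_cols[(int(m.group(1)), int(m.group(2)))] = col
    if not lfq_cols:
        raise InputError(f"no LFQ intensity columns matched in {path}")
    ids = df[dialect.protein_col].astype(str)
    rev = df.get(dialect.reverse_col, pd.Series("", index=df.index)).fillna("")
    con = df.get(dialect.contaminant_col, pd.Series("", index=df.index)).fillna("")
    meta = pd.DataFrame({
        "gene": df.get(dialect.gene_col, pd.Series("", index=df.index)).fillna(""),
        "unique_peptides": df[dialect.peptides_col].astype(int),
        "is_decoy": (rev == dialect.flag_value).to_numpy()
        | ids.str.startswith(dialect.decoy_prefix).to_numpy(),
        "is_contaminant": (con == dialect.flag_value).to_numpy()
        | ids.str.startswith(dialect.contaminant_prefix).to_numpy(),
    })
    meta.index = pd.Index(ids, name="protein_id")
    lfq = pd.DataFrame(
        {key: df[col].astype(float).fillna(0.0).to_numpy() for key, col in lfq_cols.items()},
        index=meta.index,
    )
    lfq.columns = pd.MultiIndex.from_tuples(lfq.columns, names=["fraction", "replicate"])
    return ProteinGroupTable(meta=meta, lfq=lfq)


def read_reference_list(path: str | Path) -> set[str]:
    """One accession per line; ``#`` starts a comment."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"reference list not found: {path}")
    out = set()
    for line in path.read_text().splitlines():
        acc = line.split("#", 1)[0].strip()
        if acc:
            out.add(acc)
    return out


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping for the identification cascade (counts are disjoint,
    attributed in cascade order)."""

    n_input: int
    n_fail_peptides: int
    n_fail_cooccurrence: int
    n_decoy: int
    n_contaminant: int
    n_output: int

    @property
    def removed(self) -> int:
        return (self.n_fail_peptides + self.n_fail_cooccurrence
                + self.n_decoy + self.n_contaminant)


def filter_protein_groups(table: ProteinGroupTable, *,
                          min_unique_peptides: int = 3,
                          require_cooccurrence: bool = True,
                          n_replicates: int | None = None,
                          fraction_range: tuple[int, int] = (23, 50)
                          ) -> ProteinGroupTable:
    """Apply the identification cascade; the report is on ``filter_report``.

    Order: (i) unique-peptide minimum, (ii) co-occurrence — at least one
    fraction in ``fraction_range`` where the protein is detected in every
    replicate — then decoy removal, then contaminant removal.
    """
    if len(table) == 0:
        log.warning("empty protein-group table passed to filter")
        return replace(table, filter_report=FilterReport(0, 0, 0, 0, 0, 0))
    lo, hi = fraction_range
    have = set(table.fractions)
    wanted = set(range(lo, hi + 1))
    if not wanted <= have:
        missing = sorted(wanted - have)
        raise InputError(f"fraction range {fraction_range} not in table; "
                         f"unknown fractions {missing}")
    reps = table.replicates if n_replicates is None else list(range(1, n_replicates + 1))
    pep_ok = table.meta["unique_peptides"] >= min_unique_peptides
    if require_cooccurrence:
        cols = [(f, r) for f in sorted(wanted) for r in reps]
        detected = table.lfq[cols].to_numpy() > 0
        # (proteins, fractions, replicates): a fraction counts when every
        # replicate detected the protein there
        cube = detected.reshape(len(table), len(wanted), len(reps))
        cooc_ok = pd.Series(cube.all(axis=2).any(axis=1), index=table.meta.index)
    else:
        cooc_ok = pd.Series(True, index=table.meta.index)
    n_fail_pep = int((~pep_ok).sum())
    n_fail_cooc = int((pep_ok & ~cooc_ok).sum())
    stage1 = pep_ok & cooc_ok
    decoy = stage1 & table.meta["is_decoy"]
    stage2 = stage1 & ~table.meta["is_decoy"]
    contam = stage2 & table.meta["is_contaminant"]
    keep = stage2 & ~table.meta["is_contaminant"]
    report = FilterReport(
        n_input=len(table),
        n_fail_peptides=n_fail_pep,
        n_fail_cooccurrence=n_fail_cooc,
        n_decoy=int(decoy.sum()),
        n_contaminant=int(contam.sum()),
        n_output=int(keep.sum()),
    )
    log.info("filter cascade: %d -> %d (peptides %d, co-occurrence %d, "
             "decoy %d, contaminant %d)", report.n_input, report.n_output,
             report.n_fail_peptides, report.n_fail_cooccurrence,
             report.n_decoy, report.n_contaminant)
    return ProteinGroupTable(meta=table.meta[keep].copy(),
                             lfq=table.lfq[keep].copy(),
                             filter_report=report)


@dataclass
class ProteinProfileMatrix:
    """Proteins × fractions intensity matrix (averaged over replicates).

    When ``normalized``, every row is scaled so its maximum equals 1.
    """

    values: pd.DataFrame  # index: accession; columns: fraction ids (int)
    normalized: bool = False

    def __post_init__(self):
        self.values = self.values.sort_index(axis=1)
        if self.normalized:
            arr = self.values.to_numpy()
            if arr.size and (arr.min() < 0 or arr.max() > 1 + 1e-12):
                raise InputError("normalized matrix entries must lie in [0, 1]")

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def fractions(self) -> list[int]:
        return [int(c) for c in self.values.columns]

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", float_format="%.17g")


def average_lfq(table: ProteinGroupTable) -> ProteinProfileMatrix:
    """Arithmetic mean intensity over replicates per fraction.

    Zeros (non-detections) are included in the mean: co-absence across
    fractions is itself co-elution evidence downstream.
    """
    mean = table.lfq.T.groupby(level="fraction").mean().T
    mean.columns = [int(c) for c in mean.columns]
    return ProteinProfileMatrix(values=mean, normalized=False)


def normalize_profiles(matrix: ProteinProfileMatrix) -> ProteinProfileMatrix:
    """Scale each protein's profile by the fraction of maximal intensity."""
    row_max = matrix.values.max(axis=1)
    zero = row_max[row_max <= 0]
    if len(zero):
        raise InputError(f"all-zero profile for protein(s): {list(zero.index)}")
    return ProteinProfileMatrix(values=matrix.values.div(row_max, axis=0),
                                normalized=True)


def total_abundance(matrix: ProteinProfileMatrix) -> pd.DataFrame:
    """Summed averaged intensity per protein with descending rank.

    Ties rank stably by accession.  Refuses normalized input: sums of
    max-scaled rows are unitless and not comparable across proteins.
    """
    if matrix.normalized:
        raise InputError("total abundance requires the unnormalized matrix")
    total = matrix.values.sum(axis=1)
    order = sorted(total.index, key=lambda p: (-total[p], p))
    rank = pd.Series({p: i + 1 for i, p in enumerate(order)}, name="rank")
    return pd.DataFrame({"total": total, "rank": rank})


@dataclass(frozen=True)
class OverlapReport:
    """Set and abundance overlap between the study and a reference proteome."""

    n_shared: int
    n_unique_study: int
    n_unique_reference: int
    shared_abundance_pct: float
    unique_abundance_pct: float


def _strip_isoform(acc: str) -> str:
    return acc.split("-", 1)[0]


def reference_overlap(matrix: ProteinProfileMatrix, reference_ids: Iterable[str],
                      *, strip_isoforms: bool = True) -> OverlapReport:
    """Compare detected accessions (and their abundance share) to a reference."""
    if matrix.normalized:
        raise InputError("reference overlap needs the unnormalized matrix")
    study = list(matrix.proteins)
    if not study or not reference_ids:
        raise InputError("study and reference sets must be non-empty")
    key = _strip_isoform if strip_isoforms else (lambda a: a)
    ref = {key(a) for a in reference_ids}
    shared = [p for p in study if key(p) in ref]
    unique = [p for p in study if key(p) not in ref]
    totals = matrix.values.sum(axis=1)
    grand = float(totals.sum())
    shared_pct = 100.0 * float(totals.loc[shared].sum()) / grand if grand else 0.0
    return OverlapReport(
        n_shared=len(shared),
        n_unique_study=len(unique),
        n_unique_reference=len(ref - {key(p) for p in study}),
        shared_abundance_pct=shared_pct,
        unique_abundance_pct=100.0 - shared_pct,
    )
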