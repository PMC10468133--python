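"""Offline GO-BP over-representation and functional-enrichment matrix calls.

Enrichment is a one-sided hypergeometric test of each biological-process term
against a user-supplied protein→term annotation table, Bonferroni-corrected
over the tested terms (default significance: corrected p < 0.01).  The
protein × significant-term relation is rendered as a ±1 binary matrix, rows
and columns are hierarchically clustered independently (Jaccard distance on
the +1 indicators, average linkage), each dendrogram is cut into g groups
(default 10), and any of the g×g blocks whose +1 correspondence exceeds 50%
is called a functional cluster.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom

from .errors import InputError

log = logging.getLogger(__name__)

__all__ = [
    "AnnotationTable",
    "EnrichmentResult",
    "EnrichmentMatrix",
    "ClusterCall",
    "read_annotation",
    "read_gaf",
    "enrich_terms",
    "build_binary_matrix",
    "cocluster",
    "detect_functional_clusters",
]


@dataclass(frozen=True)
class AnnotationTable:
    """Unique (protein, term) annotation pairs with term names."""

    df: pd.DataFrame  # columns: protein, term_id, term_name

    def __post_init__(self):
        required = {"protein", "term_id", "term_name"}
        if not required <= set(self.df.columns):
            raise InputError(f"annotation table needs columns {sorted(required)}")
        if self.df.duplicated(subset=["protein", "term_id"]).any():
            raise InputError("duplicate (protein, term) annotation pairs")

    @property
    def proteins(self) -> set[str]:
        return set(self.df["protein"])

    @property
    def terms(self) -> list[str]:
        return sorted(set(self.df["term_id"]))

    def term_members(self) -> dict[str, set[str]]:
        return {t: set(g["protein"])
                for t, g in self.df.groupby("term_id", sort=True)}

    def term_names(self) -> dict[str, str]:
        return dict(zip(self.df["term_id"], self.df["term_name"]))

    def to_tsv(self, path: str | Path) -> None:
        self.df.sort_values(["protein", "term_id"]).to_csv(
            path, sep="\t", index=False)


def read_annotation(path: str | Path) -> AnnotationTable:
    """Read ``protein<TAB>term_id[<TAB>term_name]``."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"annotation table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "term_name" not in df.columns:
        df["term_name"] = df["term_id"]
    return AnnotationTable(df=df[["protein", "term_id", "term_name"]])


def read_gaf(path: str | Path, aspect: str = "P") -> AnnotationTable:
    """Read a GAF 2.2 file, keeping one aspect (default biological process)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"GAF file not found: {path}")
    rows = []
    for line in path.read_text().splitlines():
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 9:
            continue
        if cols[8] != aspect:
            continue
        rows.append({"protein": cols[1], "term_id": cols[4],
                     "term_name": cols[4]})
    df = pd.DataFrame(rows, columns=["protein", "term_id", "term_name"])
    return AnnotationTable(df=df.drop_duplicates(subset=["protein", "term_id"]))


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric over-representation of one term.

    k of n study proteins carry the term; K of N background proteins do.
    """

    term_id: str
    term_name: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    p_bonferroni: float

    @property
    def significant(self) -> bool:  # at the alpha used during testing
        return bool(self._significant)

    _significant: bool = False


def enrich_terms(study_proteins: Iterable[str], annotation: AnnotationTable,
                 background: Iterable[str] | None = None, alpha: float = 0.01,
                 min_count: int = 2, ease: bool = False
                 ) -> list[EnrichmentResult]:
    """One-sided hypergeometric enrichment with Bonferroni correction.

    Terms with fewer than ``min_count`` study proteins are not tested (and do
    not count toward the correction).  ``ease=True`` applies the DAVID-style
    EASE penalty (one study success removed before the tail sum).
    """
    study = set(study_proteins)
    bg = annotation.proteins if background is None else set(background)
    missing = sorted(study - bg)
    if missing:
        raise InputError(f"study proteins absent from background: {missing}")
    n, N = len(study), len(bg)
    members = annotation.term_members()
    names = annotation.term_names()
    tested = []
    for term, prots in members.items():
        K = len(prots & bg)
        k = len(prots & study)
        if k < min_count or K == 0:
            continue
        shift = 2 if ease else 1
        p = float(hypergeom.sf(k - shift, N, K, n))
        tested.append((term, k, K, min(p, 1.0)))
    m = len(tested)
    out = []
    for term, k, K, p in tested:
        p_b = min(1.0, p * m)
        out.append(EnrichmentResult(
            term_id=term, term_name=names.get(term, term), k=k, K=K, n=n, N=N,
            p_value=p, p_bonferroni=p_b, _significant=p_b < alpha))
    out.sort(key=lambda r: (r.p_value, r.term_id))
    log.info("enrichment: %d terms tested, %d significant at Bonferroni < %g",
             m, sum(r.significant for r in out), alpha)
    return out


@dataclass
class EnrichmentMatrix:
    """±1 protein × term relation with optional co-clustering structure."""

    values: pd.DataFrame  # entries in {+1, −1}
    row_order: list[str] | None = None  # dendrogram leaf order
    col_order: list[str] | None = None
    row_groups: pd.Series | None = None  # protein → group label (1..g)
    col_groups: pd.Series | None = None
    n_groups: int | None = None

    def __post_init__(self):
        arr = self.values.to_numpy()
        if arr.size and not np.isin(arr, (-1, 1)).all():
            raise InputError("matrix entries must be +1 or -1")

    @property
    def clustered(self) -> bool:
        return self.row_groups is not None and self.col_groups is not None

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t")


def build_binary_matrix(significant, annotation: AnnotationTable,
                        study_proteins: Iterable[str]) -> EnrichmentMatrix:
    """+1 iff the protein is annotated to the (significant) term, else −1.

    ``significant`` may be :class:`EnrichmentResult` objects or plain term
    ids.  Study proteins annotated to none of the terms are dropped (logged).
    """
    terms = [r.term_id if isinstance(r, EnrichmentResult) else str(r)
             for r in significant]
    if not terms:
        raise InputError("no significant terms to build the matrix from")
    terms = sorted(dict.fromkeys(terms))
    proteins = sorted(set(study_proteins))
    members = annotation.term_members()
    mat = np.full((len(proteins), len(terms)), -1, dtype=np.int8)
    for j, t in enumerate(terms):
        prots = members.get(t, set())
        for i, p in enumerate(proteins):
            if p in prots:
                mat[i, j] = 1
    values = pd.DataFrame(mat, index=proteins, columns=terms)
    empty = values.index[(values == -1).all(axis=1)]
    if len(empty):
        log.info("dropping %d proteins with no significant term", len(empty))
        values = values.drop(index=empty)
    return EnrichmentMatrix(values=values)


def _cluster_axis(indicator: np.ndarray, labels: Sequence[str], n_groups: int,
                  method: str, metric: str):
    if len(labels) == 1:
        return list(labels), pd.Series([1], index=list(labels))
    dist = pdist(indicator.astype(bool), metric=metric)
    Z = linkage(dist, method=method)
    order = [labels[i] for i in leaves_list(Z)]
    flat = fcluster(Z, t=n_groups, criterion="maxclust")
    return order, pd.Series(flat, index=list(labels))


def cocluster(matrix: EnrichmentMatrix, n_groups: int = 10,
              method: str = "average", metric: str = "jaccard"
              ) -> EnrichmentMatrix:
    """Independent hierarchical clustering of rows and columns.

    Jaccard distance on the +1 indicator vectors groups proteins (terms) by
    shared term (protein) membership; each dendrogram is cut into exactly
    ``n_groups`` with scipy's maxclust criterion.  Deterministic.
    """
    values = matrix.values
    if len(values.index) < n_groups or len(values.columns) < n_groups:
        raise InputError(
            f"matrix {values.shape} smaller than n_groups={n_groups}")
    ind = (values.to_numpy() == 1)
    row_order, row_groups = _cluster_axis(ind, list(values.index),
                                          n_groups, method, metric)
    col_order, col_groups = _cluster_axis(ind.T, list(values.columns),
                                          n_groups, method, metric)
    return EnrichmentMatrix(values=values, row_order=row_order,
                            col_order=col_order, row_groups=row_groups,
                            col_groups=col_groups, n_groups=n_groups)


@dataclass(frozen=True)
class ClusterCall:
    """One g×g block whose +1 correspondence exceeded the cutoff."""

    row_group: int
    col_group: int
    correspondence: float
    n_proteins: int
    n_terms: int


def detect_functional_clusters(matrix: EnrichmentMatrix,
                               min_correspondence: float = 0.5
                               ) -> list[ClusterCall]:
    """Call blocks with strictly more than ``min_correspondence`` +1 entries.

    Correspondence is the fraction of +1 entries in the protein-group ×
    term-group block; exactly 50% is NOT a call.
    """
    if not matrix.clustered:
        raise InputError("matrix has no block grid; run cocluster first")
    values = matrix.values
    calls = []
    for rg in sorted(matrix.row_groups.unique()):
        rows = matrix.row_groups.index[matrix.row_groups == rg]
        for cg in sorted(matrix.col_groups.unique()):
            cols = matrix.col_groups.index[matrix.col_groups == cg]
            block = values.loc[rows, cols].to_numpy()
            corr = float((block == 1).mean())
            if corr > min_correspondence:
                calls.append(ClusterCall(row_group=int(rg), col_group=int(cg),
                                         correspondence=corr,
                                         n_proteins=len(rows),
                                         n_terms=len(cols)))
    return calls
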