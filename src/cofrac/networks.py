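"""Co-elution network inference over normalized protein profiles.

Three complementary scorings of every unordered protein pair:

* global Pearson correlation across the whole fraction window;
* local Spearman rank correlation inside a sliding ±2-fraction window
  (one network per complete window, collapsible to a global union network);
* a reference-trained classifier in the spirit of PrInCE — per-pair profile
  features (Pearson r, Euclidean distance, co-apex offset) fed to a Gaussian
  naive-Bayes model trained on known-complex co-member pairs against seeded
  random non-member pairs.

Edges require a score strictly above the threshold (default 0.85 for all
methods, a deliberately conservative uniform cut).
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.naive_bayes import GaussianNB

from .errors import InputError
from .proteome import ProteinProfileMatrix

log = logging.getLogger(__name__)

__all__ = [
    "CoelutionNetwork",
    "ReferenceComplexSet",
    "pcc_network",
    "local_spearman_networks",
    "collapse_local_networks",
    "prince_scores",
    "read_reference_complexes",
]

Pair = tuple[str, str]


def _pair(a: str, b: str) -> Pair:
    return (a, b) if a < b else (b, a)


@dataclass
class CoelutionNetwork:
    """Scored undirected co-elution graph for one method.

    ``edges`` maps sorted accession pairs to scores; every stored edge scored
    strictly above ``threshold``.  ``edge_windows`` records, for collapsed
    local networks, which window ids supported each edge.
    """

    nodes: tuple[str, ...]
    edges: dict[Pair, float]
    method: str
    threshold: float
    window_id: int | None = None
    n_pairs_evaluated: int = 0
    n_pairs_skipped: int = 0
    edge_windows: dict[Pair, tuple[int, ...]] | None = None

    def __post_init__(self):
        self.nodes = tuple(self.nodes)
        node_set = set(self.nodes)
        for (a, b), score in self.edges.items():
            if a == b:
                raise InputError(f"self-edge on {a}")
            if a > b:
                raise InputError(f"edge ({a}, {b}) not in canonical order")
            if a not in node_set or b not in node_set:
                raise InputError(f"edge endpoint outside node universe: ({a}, {b})")
            if not score > self.threshold:
                raise InputError(
                    f"edge ({a}, {b}) score {score} not above threshold {self.threshold}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, a: str, b: str) -> bool:
        return _pair(a, b) in self.edges

    def score(self, a: str, b: str) -> float:
        return self.edges[_pair(a, b)]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"protein_a": a, "protein_b": b, "score": s, "method": self.method,
             "window": "" if self.window_id is None else self.window_id}
            for (a, b), s in sorted(self.edges.items())
        ]
        return pd.DataFrame(
            rows, columns=["protein_a", "protein_b", "score", "method", "window"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | Path, nodes: Sequence[str], threshold: float
                 ) -> "CoelutionNetwork":
        df = pd.read_csv(path, sep="\t", dtype={"window": str})
        edges = {
            _pair(str(r.protein_a), str(r.protein_b)): float(r.score)
            for r in df.itertuples()
        }
        method = str(df["method"].iloc[0]) if len(df) else "unknown"
        return cls(nodes=tuple(nodes), edges=edges, method=method,
                   threshold=threshold)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), s in self.edges.items():
            g.add_edge(a, b, score=s)
        return g


def _matrix_array(matrix: ProteinProfileMatrix, require_normalized: bool = True
                  ) -> tuple[list[str], np.ndarray]:
    if require_normalized and not matrix.normalized:
        raise InputError("network inference expects the max-normalized matrix")
    return list(matrix.proteins), matrix.values.to_numpy(dtype=float)


def pcc_network(matrix: ProteinProfileMatrix, threshold: float = 0.85
                ) -> CoelutionNetwork:
    """Pearson correlation network over the full fraction window.

    All n(n−1)/2 pairs are evaluated; pairs involving a flat (zero-variance)
    profile have undefined correlation and are skipped (counted, logged).
    """
    proteins, arr = _matrix_array(matrix)
    n = len(proteins)
    if n < 2:
        raise InputError("need at least two proteins")
    if arr.shape[1] < 3:
        raise InputError("need at least three fractions")
    sd = arr.std(axis=1)
    flat = sd == 0
    n_flat = int(flat.sum())
    if n_flat:
        log.info("pcc: %d zero-variance profiles skipped", n_flat)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(arr)
    iu, ju = np.triu_indices(n, k=1)
    valid = ~(flat[iu] | flat[ju])
    hit = valid & (corr[iu, ju] > threshold)
    edges = {_pair(proteins[i], proteins[j]): float(corr[i, j])
             for i, j in zip(iu[hit], ju[hit])}
    skipped = int((~valid).sum())
    return CoelutionNetwork(nodes=tuple(proteins), edges=edges, method="pcc",
                            threshold=threshold,
                            n_pairs_evaluated=n * (n - 1) // 2,
                            n_pairs_skipped=skipped)


def local_spearman_networks(matrix: ProteinProfileMatrix, half_window: int = 2,
                            threshold: float = 0.85
                            ) -> list[CoelutionNetwork]:
    """One Spearman network per complete sliding window of 2·hw+1 fractions.

    A window centered on fraction c spans [c−hw, c+hw]; with F fractions there
    are F − 2·hw complete windows.  Ties get average ranks; profiles constant
    within a window are skipped there.
    """
    if half_window < 1:
        raise InputError("half_window must be >= 1")
    proteins, arr = _matrix_array(matrix)
    fractions = matrix.fractions
    width = 2 * half_window + 1
    if arr.shape[1] < width:
        raise InputError(
            f"need at least {width} fractions, have {arr.shape[1]}")
    n = len(proteins)
    iu, ju = np.triu_indices(n, k=1)
    out = []
    for start in range(arr.shape[1] - width + 1):
        center = fractions[start + half_window]
        sub = arr[:, start:start + width]
        flat = np.ptp(sub, axis=1) == 0
        ranks = rankdata(sub, axis=1)  # average ranks for ties
        with np.errstate(invalid="ignore"):
            rho = np.corrcoef(ranks)
        valid = ~(flat[iu] | flat[ju])
        hit = valid & (rho[iu, ju] > threshold)
        edges = {_pair(proteins[i], proteins[j]): float(rho[i, j])
                 for i, j in zip(iu[hit], ju[hit])}
        skipped = int((~valid).sum())
        out.append(CoelutionNetwork(
            nodes=tuple(proteins), edges=edges, method="local_spearman",
            threshold=threshold, window_id=center,
            n_pairs_evaluated=n * (n - 1) // 2, n_pairs_skipped=skipped))
    return out


def collapse_local_networks(locals_: Sequence[CoelutionNetwork]
                            ) -> CoelutionNetwork:
    """Union of the per-window networks; edge score = max over windows.

    Window provenance for each edge is kept in ``edge_windows``.
    """
    if not locals_:
        raise InputError("no local networks to collapse")
    methods = {net.method for net in locals_}
    if len(methods) != 1:
        raise InputError(f"cannot collapse mixed methods: {sorted(methods)}")
    universes = {net.nodes for net in locals_}
    if len(universes) != 1:
        raise InputError("local networks disagree on the node universe")
    edges: dict[Pair, float] = {}
    provenance: dict[Pair, list[int]] = {}
    for net in locals_:
        for pair, score in net.edges.items():
            if pair not in edges or score > edges[pair]:
                edges[pair] = score
            provenance.setdefault(pair, []).append(
                net.window_id if net.window_id is not None else -1)
    first = locals_[0]
    return CoelutionNetwork(
        nodes=first.nodes, edges=edges, method=first.method,
        threshold=first.threshold,
        n_pairs_evaluated=first.n_pairs_evaluated,
        edge_windows={p: tuple(sorted(w)) for p, w in provenance.items()})


@dataclass(frozen=True)
class ReferenceComplexSet:
    """CORUM-style reference: complex id → member accessions (each ≥ 2)."""

    complexes: dict[str, frozenset[str]]

    def __post_init__(self):
        object.__setattr__(self, "complexes",
                           {k: frozenset(v) for k, v in self.complexes.items()})
        for cid, members in self.complexes.items():
            if len(members) < 2:
                raise InputError(f"complex {cid} has fewer than 2 members")

    def co_member_pairs(self, universe: Iterable[str] | None = None
                        ) -> set[Pair]:
        uni = None if universe is None else set(universe)
        pairs: set[Pair] = set()
        for members in self.complexes.values():
            present = members if uni is None else members & uni
            pairs.update(_pair(a, b)
                         for a, b in itertools.combinations(sorted(present), 2))
        return pairs

    def to_tsv(self, path: str | Path) -> None:
        rows = [{"complex_id": cid, "members": ";".join(sorted(members))}
                for cid, members in sorted(self.complexes.items())]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_reference_complexes(path: str | Path) -> ReferenceComplexSet:
    """Read a ``complex_id<TAB>member;member;...`` table."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"reference complex table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"complex_id", "members"} <= set(df.columns):
        raise InputError(f"expected columns complex_id, members in {path}")
    return ReferenceComplexSet(complexes={
        str(r.complex_id): frozenset(str(r.members).split(";"))
        for r in df.itertuples()
    })


def _pair_features(arr: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray,
                   corr: np.ndarray, apex: np.ndarray) -> np.ndarray:
    r = corr[idx_a, idx_b]
    r = np.nan_to_num(r, nan=0.0)
    dist = np.linalg.norm(arr[idx_a] - arr[idx_b], axis=1)
    offset = np.abs(apex[idx_a] - apex[idx_b]).astype(float)
    return np.column_stack([r, dist, offset])


def prince_scores(matrix: ProteinProfileMatrix, reference: ReferenceComplexSet,
                  threshold: float = 0.85, seed: int = 17,
                  negative_ratio: int = 10) -> CoelutionNetwork:
    """Reference-trained co-elution classifier (simplified PrInCE).

    Positives are co-member pairs of the reference complexes present in the
    matrix; negatives are ``negative_ratio`` times as many seeded random
    non-co-member pairs.  A Gaussian naive-Bayes model over three profile
    features scores every pair; the edge score is the posterior probability
    of interaction.  Deterministic given ``seed``.
    """
    proteins, arr = _matrix_array(matrix)
    n = len(proteins)
    if n < 2:
        raise InputError("need at least two proteins")
    index = {p: i for i, p in enumerate(proteins)}
    pos_pairs = {p for p in reference.co_member_pairs(proteins)
                 if p[0] in index and p[1] in index}
    if not pos_pairs:
        raise InputError("no usable reference co-member pairs in the matrix")
    all_pairs = [_pair(a, b) for a, b in itertools.combinations(proteins, 2)]
    co_member_any = reference.co_member_pairs()  # excl. from negatives
    candidates = [p for p in all_pairs if p not in co_member_any]
    rng = np.random.default_rng(seed)
    n_neg = min(negative_ratio * len(pos_pairs), len(candidates))
    neg_idx = rng.choice(len(candidates), size=n_neg, replace=False)
    neg_pairs = [candidates[i] for i in sorted(neg_idx)]

    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(arr)
    apex = arr.argmax(axis=1)

    def feats(pairs):
        ia = np.fromiter((index[a] for a, _ in pairs), dtype=int, count=len(pairs))
        ib = np.fromiter((index[b] for _, b in pairs), dtype=int, count=len(pairs))
        return _pair_features(arr, ia, ib, corr, apex)

    pos_sorted = sorted(pos_pairs)
    X = np.vstack([feats(pos_sorted), feats(neg_pairs)])
    y = np.concatenate([np.ones(len(pos_sorted)), np.zeros(len(neg_pairs))])
    clf = GaussianNB()
    clf.fit(X, y)
    scores = clf.predict_proba(feats(all_pairs))[:, 1]
    edges = {
        _pair(a, b): float(s)
        for (a, b), s in zip(all_pairs, scores) if s > threshold
    }
    return CoelutionNetwork(nodes=tuple(proteins), edges=edges, method="prince",
                            threshold=threshold,
                            n_pairs_evaluated=n * (n - 1) // 2)
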