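"""Consensus networks, inter-method agreement, and maximal-clique subspecies.

The most robust co-elution relationships are the edges found by every
scoring method.  Agreement between two methods is quantified with a 2×2
Fisher's exact test over the shared pair universe, and fully interconnected
subgraphs (maximal cliques) of the consensus network are the candidate
lipoprotein particle subspecies.

The two-sided Fisher p-value is computed by exact integer hypergeometric
enumeration: within a margin family all table probabilities share the
denominator C(N, c1), so "probability ≤ observed" is an exact integer
comparison of numerators — no floating-point tie ambiguity.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .networks import CoelutionNetwork, Pair, _pair

log = logging.getLogger(__name__)

__all__ = [
    "AgreementResult",
    "CliqueSet",
    "CliqueSummary",
    "fisher_exact_two_sided",
    "intersect_networks",
    "method_agreement",
    "maximal_cliques",
    "summarize_cliques",
]


def intersect_networks(nets: Sequence[CoelutionNetwork]) -> CoelutionNetwork:
    """Edge-set intersection of ≥2 networks on a shared node universe.

    The consensus edge score is the minimum method score (conservative).
    Venn region counts over the union of edges are attached as ``venn``
    (keys are '+'-joined method-label combinations).
    """
    if len(nets) < 2:
        raise InputError("need at least two networks to intersect")
    universes = {net.nodes for net in nets}
    if len(universes) != 1:
        raise InputError("networks disagree on the node universe")
    if not nets[0].nodes:
        raise InputError("empty node universe")
    labels = [net.method for net in nets]
    if len(set(labels)) != len(labels):
        labels = [f"{net.method}#{i}" for i, net in enumerate(nets)]
    membership: dict[Pair, list[str]] = {}
    for label, net in zip(labels, nets):
        for pair in net.edges:
            membership.setdefault(pair, []).append(label)
    venn: dict[str, int] = {}
    for pair, found_in in membership.items():
        key = "+".join(found_in)
        venn[key] = venn.get(key, 0) + 1
    common = [pair for pair, found_in in membership.items()
              if len(found_in) == len(nets)]
    threshold = min(net.threshold for net in nets)
    edges = {pair: min(net.edges[pair] for net in nets) for pair in common}
    out = CoelutionNetwork(
        nodes=nets[0].nodes, edges=edges, method="consensus",
        threshold=threshold, n_pairs_evaluated=nets[0].n_pairs_evaluated)
    out.venn = venn  # region counts, union of edge sets
    return out


def fisher_exact_two_sided(a: int, b: int, c: int, d: int
                           ) -> tuple[float, float]:
    """Two-sided Fisher's exact p and sample odds ratio for [[a, b], [c, d]].

    p sums hypergeometric probabilities of all tables with the same margins
    whose probability does not exceed the observed one (integer-exact
    comparison).  The odds ratio is the sample a·d/(b·c) with a Haldane +0.5
    on every cell when any cell is zero (logged).
    """
    if min(a, b, c, d) < 0:
        raise InputError("table cells must be nonnegative")
    n_tot = a + b + c + d
    if n_tot == 0:
        raise InputError("empty table")
    r1, c1 = a + b, a + c
    r2 = c + d
    lo_a, hi_a = max(0, c1 - r2), min(r1, c1)
    weights = [math.comb(r1, x) * math.comb(r2, c1 - x)
               for x in range(lo_a, hi_a + 1)]
    obs = weights[a - lo_a]
    numer = sum(w for w in weights if w <= obs)
    p = numer / math.comb(n_tot, c1)
    if min(a, b, c, d) == 0:
        log.debug("zero cell: Haldane-corrected odds ratio")
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(p), float(odds)


@dataclass(frozen=True)
class AgreementResult:
    """2×2 agreement between two methods over the shared pair universe."""

    method_a: str
    method_b: str
    table: np.ndarray  # [[both, a_only], [b_only, neither]]
    odds_ratio: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.odds_ratio > 1.0 and self.p_value < 0.05


def method_agreement(net_a: CoelutionNetwork, net_b: CoelutionNetwork
                     ) -> AgreementResult:
    """Fisher's exact association between two edge sets.

    Every unordered pair of the shared node universe is classified into the
    2×2 table (in both / a only / b only / neither).
    """
    shared = sorted(set(net_a.nodes) & set(net_b.nodes))
    if len(shared) < 2:
        raise InputError("shared node universe has fewer than 2 nodes")
    universe_pairs = len(shared) * (len(shared) - 1) // 2
    shared_set = set(shared)
    ea = {p for p in net_a.edges if p[0] in shared_set and p[1] in shared_set}
    eb = {p for p in net_b.edges if p[0] in shared_set and p[1] in shared_set}
    both = len(ea & eb)
    a_only = len(ea - eb)
    b_only = len(eb - ea)
    neither = universe_pairs - both - a_only - b_only
    p, odds = fisher_exact_two_sided(both, a_only, b_only, neither)
    return AgreementResult(
        method_a=net_a.method, method_b=net_b.method,
        table=np.array([[both, a_only], [b_only, neither]], dtype=int),
        odds_ratio=odds, p_value=p)


def _bron_kerbosch(adj: dict[str, set[str]]) -> list[frozenset[str]]:
    """Maximal cliques via Bron–Kerbosch with pivoting."""
    cliques: list[frozenset[str]] = []

    def expand(r: set[str], p: set[str], x: set[str]) -> None:
        if not p and not x:
            cliques.append(frozenset(r))
            return
        pivot = max(p | x, key=lambda u: len(p & adj[u]))
        for v in list(p - adj[pivot]):
            expand(r | {v}, p & adj[v], x & adj[v])
            p.remove(v)
            x.add(v)

    expand(set(), set(adj), set())
    return cliques


@dataclass(frozen=True)
class CliqueSet:
    """Maximal cliques of a network, canonically ordered.

    Order: descending size, then lexicographic on the sorted member tuple —
    byte-stable for regression output.
    """

    cliques: tuple[tuple[str, ...], ...]
    source: str
    min_size: int

    def __len__(self) -> int:
        return len(self.cliques)

    def as_sets(self) -> list[frozenset[str]]:
        return [frozenset(c) for c in self.cliques]

    def to_tsv(self, path: str | Path) -> None:
        rows = [{"clique_id": f"clique_{i + 1:04d}", "size": len(c),
                 "members": ";".join(c)} for i, c in enumerate(self.cliques)]
        pd.DataFrame(rows, columns=["clique_id", "size", "members"]).to_csv(
            path, sep="\t", index=False)


def maximal_cliques(net: CoelutionNetwork, min_size: int = 2) -> CliqueSet:
    """Enumerate every maximal clique of size ≥ ``min_size``."""
    adj: dict[str, set[str]] = {node: set() for node in net.nodes}
    for (a, b) in net.edges:
        adj[a].add(b)
        adj[b].add(a)
    found = [c for c in _bron_kerbosch(adj) if len(c) >= min_size]
    ordered = sorted((tuple(sorted(c)) for c in found),
                     key=lambda c: (-len(c), c))
    return CliqueSet(cliques=tuple(ordered), source=net.method,
                     min_size=min_size)


@dataclass(frozen=True)
class CliqueSummary:
    """Size histogram and per-clique provenance report."""

    size_histogram: dict[int, int]
    table: pd.DataFrame

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def summarize_cliques(cliques: CliqueSet,
                      reference_ids: Iterable[str] | None = None
                      ) -> CliqueSummary:
    """Histogram clique sizes and flag members known from the reference."""
    ref = set(reference_ids) if reference_ids is not None else None
    hist: dict[int, int] = {}
    rows = []
    for i, members in enumerate(cliques.cliques):
        hist[len(members)] = hist.get(len(members), 0) + 1
        row = {"clique_id": f"clique_{i + 1:04d}", "size": len(members),
               "members": ";".join(members)}
        if ref is not None:
            known = [m for m in members if m in ref]
            row["n_reference_known"] = len(known)
            row["n_study_unique"] = len(members) - len(known)
        rows.append(row)
    cols = ["clique_id", "size", "members"] + (
        ["n_reference_known", "n_study_unique"] if ref is not None else [])
    return CliqueSummary(size_histogram=hist,
                         table=pd.DataFrame(rows, columns=cols))
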