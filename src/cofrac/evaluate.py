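"""Closed-loop recovery metrics against planted ground truth."""
from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .cliques import CliqueSet
from .enrichment import ClusterCall, EnrichmentMatrix
from .peaks import PeakModel


def component_recovery(model: PeakModel, true_means: Sequence[float],
                       tolerance_ml: float = 0.25) -> bool:
    """True when every planted mean has a fitted component within tolerance."""
    fitted = [c.mean for c in model.components]
    return all(min(abs(f - mu) for f in fitted) <= tolerance_ml
               for mu in true_means)


def complex_recovery(cliques: CliqueSet,
                     complexes: Mapping[str, Iterable[str]],
                     min_member_fraction: float = 0.8
                     ) -> tuple[int, int, dict[str, float]]:
    """How many planted complexes surface as a clique.

    A complex counts as recovered when some maximal clique contains at least
    ``min_member_fraction`` of its members.  Returns (recovered, total,
    best member fraction per complex).
    """
    sets = cliques.as_sets()
    detail: dict[str, float] = {}
    recovered = 0
    for cid, members in complexes.items():
        ms = set(members)
        best = max((len(ms & c) / len(ms) for c in sets), default=0.0)
        detail[cid] = best
        if best >= min_member_fraction:
            recovered += 1
    return recovered, len(complexes), detail


def module_recovery(calls: Sequence[ClusterCall], matrix: EnrichmentMatrix,
                    modules: Mapping[str, Iterable[str]],
                    module_terms: Mapping[str, Iterable[str]]
                    ) -> tuple[int, int]:
    """How many planted annotation modules were called as a block.

    A module is recovered when some called block pairs a protein group whose
    majority belongs to the module with a term group whose majority are the
    module's terms.
    """
    recovered = 0
    for name, prots in modules.items():
        prot_set, term_set = set(prots), set(module_terms[name])
        hit = False
        for call in calls:
            rows = matrix.row_groups.index[matrix.row_groups == call.row_group]
            cols = matrix.col_groups.index[matrix.col_groups == call.col_group]
            if (len(set(rows) & prot_set) > len(rows) / 2
                    and len(set(cols) & term_set) > len(cols) / 2):
                hit = True
                break
        recovered += hit
    return recovered, len(modules)
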