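"""Hypergeometric enrichment, binary matrix, co-clustering, block calls."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cofrac.enrichment import (AnnotationTable, build_binary_matrix, cocluster,
                               detect_functional_clusters, enrich_terms,
                               read_annotation)
from cofrac.errors import InputError
from cofrac.evaluate import module_recovery
from cofrac.simulate import generate_annotation


def annotation_from_pairs(pairs):
    return AnnotationTable(df=pd.DataFrame(
        [{"protein": p, "term_id": t, "term_name": t} for p, t in pairs]))


class TestEnrichTerms:
    def test_closed_form_tail(self):
        # all 3 study proteins carry T, 3 of 100 background do:
        # p = C(3,3)*C(97,0)/C(100,3)
        background = [f"B{i}" for i in range(100)]
        study = background[:3]
        pairs = [(p, "T") for p in study]
        pairs += [(p, "U") for p in background]  # covers the background
        ann = annotation_from_pairs(pairs)
        res = {r.term_id: r for r in
               enrich_terms(study, ann, background=background)}
        assert res["T"].p_value == pytest.approx(1 / math.comb(100, 3),
                                                 rel=1e-12)

    def test_universal_term_not_significant(self):
        background = [f"B{i}" for i in range(50)]
        pairs = [(p, "ALL") for p in background]
        ann = annotation_from_pairs(pairs)
        res = enrich_terms(background[:10], ann, background=background)
        assert res[0].p_value == pytest.approx(1.0)
        assert not res[0].significant

    def test_matches_enumeration_oracle(self, rng):
        # exhaustive tail sums for N <= 40 random configurations
        for _ in range(50):
            N = int(rng.integers(8, 41))
            n = int(rng.integers(2, N))
            K = int(rng.integers(2, N))
            background = [f"B{i}" for i in range(N)]
            study = list(rng.choice(background, size=n, replace=False))
            holders = list(rng.choice(background, size=K, replace=False))
            k = len(set(study) & set(holders))
            if k < 2:
                continue
            pairs = [(p, "T") for p in holders]
            pairs += [(p, "BG") for p in background]
            ann = annotation_from_pairs(pairs)
            res = {r.term_id: r for r in
                   enrich_terms(study, ann, background=background)}
            oracle = sum(math.comb(K, x) * math.comb(N - K, n - x)
                         for x in range(k, min(K, n) + 1)) / math.comb(N, n)
            assert res["T"].p_value == pytest.approx(oracle, abs=1e-10)

    def test_bonferroni_properties(self, rng):
        prots = [f"B{i}" for i in range(30)]
        pairs = [(p, f"T{j}") for j, chunk in
                 enumerate(np.array_split(np.array(prots), 5))
                 for p in chunk]
        pairs += [(p, "BG") for p in prots]
        ann = annotation_from_pairs(pairs)
        res = enrich_terms(prots[:12], ann, background=prots)
        for r in res:
            assert r.p_bonferroni >= r.p_value
            assert r.p_bonferroni <= 1.0
        # significant-set size is non-increasing as alpha shrinks
        n_sig = [sum(r.p_bonferroni < alpha for r in res)
                 for alpha in (0.2, 0.05, 0.01, 0.001)]
        assert n_sig == sorted(n_sig, reverse=True)

    def test_ease_penalty_is_conservative(self):
        background = [f"B{i}" for i in range(60)]
        study = background[:10]
        pairs = [(p, "T") for p in background[:12]]
        pairs += [(p, "BG") for p in background]
        ann = annotation_from_pairs(pairs)
        plain = enrich_terms(study, ann, background=background)
        eased = enrich_terms(study, ann, background=background, ease=True)
        p0 = {r.term_id: r.p_value for r in plain}
        p1 = {r.term_id: r.p_value for r in eased}
        assert p1["T"] >= p0["T"]

    def test_study_outside_background_rejected(self):
        ann = annotation_from_pairs([("A", "T"), ("B", "T")])
        with pytest.raises(InputError, match="ZZ"):
            enrich_terms(["A", "ZZ"], ann, background=["A", "B"])


class TestBinaryMatrix:
    def test_forced_column(self):
        ann = annotation_from_pairs([("A", "T")])
        m = build_binary_matrix(["T"], ann, ["A", "B"])
        assert m.values.loc["A", "T"] == 1
        assert "B" not in m.values.index  # no significant term -> dropped

    def test_all_annotated(self):
        pairs = [(p, t) for p in "AB" for t in ("T1", "T2")]
        m = build_binary_matrix(["T1", "T2"], annotation_from_pairs(pairs),
                                ["A", "B"])
        assert (m.values.to_numpy() == 1).all()

    def test_matches_membership_oracle(self, rng):
        prots = [f"P{i}" for i in range(12)]
        terms = [f"T{j}" for j in range(6)]
        pairs = [(p, t) for p in prots for t in terms if rng.random() < 0.4]
        ann = annotation_from_pairs(pairs + [(prots[0], "EXTRA")])
        m = build_binary_matrix(terms, ann, prots)
        members = set(pairs)
        for p in m.values.index:
            for t in terms:
                assert m.values.loc[p, t] == (1 if (p, t) in members else -1)


class TestCocluster:
    def test_perfect_blocks_recovered(self):
        ann, truth = generate_annotation(
            [f"P{i:03d}" for i in range(60)], n_modules=10,
            terms_per_module=5, flip_noise=0.0, seed=1)
        m = build_binary_matrix(ann.terms, ann, sorted(ann.proteins))
        out = cocluster(m, n_groups=10)
        # every planted module becomes one homogeneous row group
        for prots in truth.modules.values():
            groups = set(out.row_groups[list(prots)])
            assert len(groups) == 1
        calls = detect_functional_clusters(out)
        rec, total = module_recovery(calls, out, truth.modules,
                                     truth.module_terms)
        assert rec == total == 10

    def test_permutation_invariance(self, rng):
        ann, _ = generate_annotation([f"P{i:03d}" for i in range(40)],
                                     n_modules=5, terms_per_module=4,
                                     flip_noise=0.1, seed=3)
        m = build_binary_matrix(ann.terms, ann, sorted(ann.proteins))
        perm_rows = list(rng.permutation(m.values.index))
        perm_cols = list(rng.permutation(m.values.columns))
        m_perm = type(m)(values=m.values.loc[perm_rows, perm_cols])
        a = cocluster(m, n_groups=5)
        b = cocluster(m_perm, n_groups=5)
        # identical partitions up to group relabeling
        mapping = {}
        for p in a.row_groups.index:
            ga, gb = a.row_groups[p], b.row_groups[p]
            assert mapping.setdefault(ga, gb) == gb

    def test_singleton_cut(self):
        ann, _ = generate_annotation([f"P{i}" for i in range(8)], n_modules=4,
                                     terms_per_module=3, seed=0)
        m = build_binary_matrix(ann.terms, ann, sorted(ann.proteins))
        out = cocluster(m, n_groups=len(m.values.index))
        assert out.row_groups.nunique() == len(m.values.index)

    def test_too_small_matrix_rejected(self):
        ann = annotation_from_pairs([("A", "T"), ("B", "T")])
        m = build_binary_matrix(["T"], ann, ["A", "B"])
        with pytest.raises(InputError):
            cocluster(m, n_groups=10)


class TestDetect:
    def _matrix(self, block):
        values = pd.DataFrame(block, index=[f"P{i}" for i in range(len(block))],
                              columns=[f"T{j}" for j in range(len(block[0]))])
        m = build_binary_matrix(
            list(values.columns),
            annotation_from_pairs([(p, t) for p in values.index
                                   for t in values.columns
                                   if values.loc[p, t] == 1]),
            list(values.index))
        m.row_groups = pd.Series(1, index=values.index)
        m.col_groups = pd.Series(1, index=values.columns)
        m.n_groups = 1
        return m

    def test_full_block_called(self):
        calls = detect_functional_clusters(self._matrix([[1, 1], [1, 1]]))
        assert len(calls) == 1
        assert calls[0].correspondence == pytest.approx(1.0)

    def test_exact_half_not_called(self):
        calls = detect_functional_clusters(self._matrix([[1, -1], [-1, 1]]))
        assert calls == []

    def test_unclustered_matrix_rejected(self):
        ann = annotation_from_pairs([("A", "T")])
        m = build_binary_matrix(["T"], ann, ["A"])
        with pytest.raises(InputError):
            detect_functional_clusters(m)


def test_annotation_roundtrip(tmp_path, rng):
    ann, _ = generate_annotation([f"P{i}" for i in range(20)], n_modules=4,
                                 terms_per_module=3, flip_noise=0.1, seed=5)
    path = tmp_path / "ann.tsv"
    ann.to_tsv(path)
    back = read_annotation(path)
    a = set(map(tuple, ann.df[["protein", "term_id"]].to_numpy()))
    b = set(map(tuple, back.df[["protein", "term_id"]].to_numpy()))
    assert a == b
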