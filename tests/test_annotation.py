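"""Interval overlap, Venn partition, QTL-class and gene-set enrichment."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from longcnv.annotation import (
    Feature,
    QTL_CLASSES,
    geneset_enrichment,
    overlap,
    qtl_class_enrichment,
    venn_partition,
)


def _gene(chrom, start, end, name):
    return Feature(chrom, start, end, name, kind="gene")


def _qtl(chrom, start, end, name, cls):
    return Feature(chrom, start, end, name, kind="qtl", trait_class=cls)


class TestOverlap:
    def test_shared_bases_reported(self):
        hits = overlap([("1", 100, 200)], [_gene("1", 150, 300, "g")])
        assert [f.name for f in hits[0]] == ["g"]

    def test_half_open_adjacency_no_overlap(self):
        hits = overlap([("1", 100, 200)], [_gene("1", 200, 300, "g")])
        assert hits[0] == []

    def test_chromosome_mismatch_empty(self):
        hits = overlap([("2", 100, 200)], [_gene("1", 100, 200, "g")])
        assert hits[0] == []

    def test_min_overlap_bp(self):
        hits = overlap([("1", 100, 200)], [_gene("1", 190, 300, "g")], min_overlap_bp=20)
        assert hits[0] == []

    def test_matches_brute_force_on_random_intervals(self):
        rng = np.random.default_rng(0)
        chroms = ["1", "2", "3"]
        queries = []
        feats = []
        for i in range(1000):
            c = chroms[int(rng.integers(3))]
            s = int(rng.integers(0, 1_000_000))
            queries.append((c, s, s + int(rng.integers(1, 50_000))))
        for i in range(300):
            c = chroms[int(rng.integers(3))]
            s = int(rng.integers(0, 1_000_000))
            feats.append(_gene(c, s, s + int(rng.integers(1, 80_000)), f"g{i}"))
        got = overlap(queries, feats)
        for (c, qs, qe), hits in zip(queries, got):
            brute = sorted(
                (f.name for f in feats
                 if f.chromosome == c and min(qe, f.end_bp) - max(qs, f.start_bp) >= 1)
            )
            assert sorted(f.name for f in hits) == brute

    def test_symmetric_pairs(self):
        rng = np.random.default_rng(1)
        a = [("1", int(s), int(s) + 10_000) for s in rng.integers(0, 200_000, 40)]
        b = [_gene("1", int(s), int(s) + 15_000, f"g{i}")
             for i, s in enumerate(rng.integers(0, 200_000, 40))]
        forward = {(i, f.name) for i, fs in enumerate(overlap(a, b)) for f in fs}
        a_feats = [_gene(c, s, e, f"q{i}") for i, (c, s, e) in enumerate(a)]
        b_queries = [(f.chromosome, f.start_bp, f.end_bp) for f in b]
        backward = {(int(f.name[1:]), b[j].name)
                    for j, fs in enumerate(overlap(b_queries, a_feats)) for f in fs}
        assert forward == backward


class TestVennPartition:
    def test_disjoint_singletons(self):
        sets = {k: {k} for k in "ABCD"}
        regions = venn_partition(sets)
        for k in "ABCD":
            assert regions[frozenset([k])] == 1
        assert sum(regions.values()) == 4

    def test_identical_sets_only_full_intersection(self):
        sets = {k: {"x", "y"} for k in "ABCD"}
        regions = venn_partition(sets)
        assert regions[frozenset("ABCD")] == 2
        assert sum(regions.values()) == 2

    def test_matches_bitmask_enumeration(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(20)]
        sets = {k: {g for g in genes if rng.random() < 0.4} for k in "ABCD"}
        regions = venn_partition(sets)
        union = set().union(*sets.values())
        assert sum(regions.values()) == len(union)
        for r in range(1, 5):
            for combo in combinations("ABCD", r):
                members = set(union)
                for k in "ABCD":
                    members &= sets[k] if k in combo else union - sets[k]
                assert regions[frozenset(combo)] == len(members)


class TestQtlEnrichment:
    def _qtls(self):
        return [
            _qtl("1", 0, 100_000, "q1", "Health"),
            _qtl("1", 0, 100_000, "q2", "Health"),
            _qtl("1", 200_000, 300_000, "q3", "Milk"),
        ]

    def test_identical_proportions_p_one(self):
        iv = [("1", 0, 50_000), ("1", 400_000, 450_000)]
        out = qtl_class_enrichment(iv, iv, self._qtls())
        assert out["Health"]["p_value"] == pytest.approx(1.0)

    def test_multiple_qtls_count_once(self):
        iv = [("1", 0, 50_000)]
        out = qtl_class_enrichment(iv, [("1", 400_000, 410_000)], self._qtls())
        assert out["Health"]["de_novo_count"] == 1  # two Health QTLs, one CNV

    def test_extreme_separation_significant(self):
        dn = [("1", 0, 50_000) for _ in range(10)]
        const = [("1", 400_000, 410_000) for _ in range(10)]
        out = qtl_class_enrichment(dn, const, self._qtls())
        assert out["Health"]["p_value"] < 1e-6

    def test_matches_exhaustive_enumeration(self):
        dn = [("1", 0, 50_000)] * 4 + [("1", 400_000, 410_000)] * 8
        const = [("1", 0, 50_000)] * 3 + [("1", 400_000, 410_000)] * 6
        out = qtl_class_enrichment(dn, const, self._qtls())
        n, k = 12, 4
        p0 = 3 / 9
        probs = stats.binom.pmf(np.arange(n + 1), n, p0)
        expected = probs[probs <= probs[k] * (1 + 1e-12)].sum()
        assert out["Health"]["p_value"] == pytest.approx(expected)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            qtl_class_enrichment([], [("1", 0, 1)], self._qtls())

    def test_all_six_classes_reported(self):
        iv = [("1", 0, 50_000)]
        out = qtl_class_enrichment(iv, iv, self._qtls())
        assert set(out) == set(QTL_CLASSES)


class TestGenesetEnrichment:
    def test_reference_scale_expected_and_ratio(self):
        # category of 127 reference genes, 2 hits among 9 analyzed genes in a
        # universe of 19,639: E ~ 0.058, R ~ 34.4
        analyzed = [f"a{i}" for i in range(7)] + ["hit1", "hit2"]
        category = {f"c{i}" for i in range(125)} | {"hit1", "hit2"}
        res = geneset_enrichment(analyzed, {"unfolded protein binding": category}, 19_639)[0]
        assert res.C == 127 and res.O == 2
        assert res.E == pytest.approx(0.0582, abs=0.0005)
        assert res.R == pytest.approx(34.38, abs=0.15)
        assert res.raw_p == pytest.approx(0.0014, abs=2e-4)

    def test_zero_overlap_conventions(self):
        res = geneset_enrichment(["a"], {"cat": {"x", "y"}}, 100)[0]
        assert res.O == 0 and res.R == 0.0 and res.raw_p == 1.0

    def test_matches_combinatorial_enumeration(self):
        # universe of 10, category of 3, draw 4, observe >= 2
        universe = [f"g{i}" for i in range(10)]
        category = set(universe[:3])
        draw = universe[1:5]  # contains g1, g2 from the category
        res = geneset_enrichment(draw, {"cat": category}, 10)[0]
        count = 0
        total = 0
        for combo in combinations(universe, 4):
            total += 1
            if len(category & set(combo)) >= 2:
                count += 1
        assert res.raw_p == pytest.approx(count / total)

    def test_bh_adjustment_hand_computed(self):
        # five random categories; the reported adj_p must equal a hand-rolled
        # Benjamini-Hochberg (sorted raw*m/rank with a running minimum from
        # the bottom) applied to the reported raw_p values
        rng = np.random.default_rng(5)
        universe = [f"g{i}" for i in range(60)]
        cats = {f"cat{j}": {g for g in universe if rng.random() < 0.25} for j in range(5)}
        res = geneset_enrichment(universe[:10], cats, 60)
        raws = np.array([r.raw_p for r in res])
        m = len(raws)
        order = np.argsort(raws, kind="stable")
        hand = np.empty(m)
        running = 1.0
        for rank_from_top in range(m - 1, -1, -1):
            i = order[rank_from_top]
            running = min(running, raws[i] * m / (rank_from_top + 1))
            hand[i] = running
        for r, h in zip(res, hand):
            assert r.adj_p == pytest.approx(h)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(3)
        universe = [f"g{i}" for i in range(50)]
        cats = {f"cat{j}": {g for g in universe if rng.random() < 0.2} for j in range(6)}
        res = geneset_enrichment(universe[:8], cats, 50)
        for r in res:
            assert r.adj_p >= r.raw_p - 1e-12

    def test_hypergeometric_matches_enumeration_small_universes(self):
        for N, C, k in [(8, 3, 4), (12, 5, 6), (15, 6, 5)]:
            universe = [f"g{i}" for i in range(N)]
            category = set(universe[:C])
            draw = universe[C - 2 : C - 2 + k]  # two members from the category
            O = len(category & set(draw))
            res = geneset_enrichment(draw, {"cat": category}, N)[0]
            count = sum(
                1 for combo in combinations(universe, k)
                if len(category & set(combo)) >= O
            )
            from math import comb
            assert res.raw_p == pytest.approx(count / comb(N, k))
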