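"""DEG filtering, Venn partition, GSEA running sum, ORA, marker sets."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import zfbattery as z
from zfbattery.enrichment import GeneSet, _es_from_positions, gsea_es
from zfbattery.errors import ValidationError


def toy_table():
    return pd.DataFrame({
        "gene": list("abcdef"),
        "log2FoldChange": [0.5, 0.19, -0.5, 0.25, 0.2, 0.5],
        "pvalue": [0.01, 0.001, 0.04, 0.06, 0.01, 0.05],
    })


class TestFilterDegs:
    def test_strict_thresholds(self):
        # p<0.05 AND |lfc|>0.2, both strict: only a and c survive
        assert z.filter_degs(toy_table()) == ["a", "c"]

    def test_empty_table(self):
        assert z.filter_degs(pd.DataFrame(columns=["gene", "log2FoldChange",
                                                   "pvalue"])) == []

    def test_monotone_in_lfc_threshold(self):
        tab = toy_table()
        prev = set(z.filter_degs(tab, lfc_min=0.0))
        for lfc in (0.1, 0.2, 0.3, 0.6):
            cur = set(z.filter_degs(tab, lfc_min=lfc))
            assert cur <= prev
            prev = cur


class TestVenn:
    def test_disjoint(self):
        counts = z.venn_overlap([["a", "b"], ["c", "d", "e"], ["f", "g", "h", "i"]])
        assert (counts["100"], counts["010"], counts["001"]) == (2, 3, 4)
        assert sum(v for k, v in counts.items() if k.count("1") > 1) == 0

    def test_identical(self):
        counts = z.venn_overlap([list("abcde")] * 3)
        assert counts["111"] == 5 and sum(counts.values()) == 5

    def test_hand_partition(self):
        counts = z.venn_overlap([{"a", "b", "c"}, {"b", "c", "d"}, {"c", "e"}])
        assert counts == {"100": 1, "010": 1, "001": 1, "110": 1,
                          "101": 0, "011": 0, "111": 1}

    def test_wrong_arity(self):
        with pytest.raises(ValidationError):
            z.venn_overlap([["a"], ["b"]])


class TestRankGenes:
    def test_descending_with_lexicographic_ties(self):
        tab = pd.DataFrame({"gene": ["b", "a", "c"],
                            "log2FoldChange": [1.0, 1.0, -2.0],
                            "pvalue": [0.01, 0.01, 0.001]})
        ranked = z.rank_genes(tab)
        assert list(ranked.gene) == ["a", "b", "c"]
        assert (np.diff(ranked.score) <= 1e-12).all()

    def test_duplicate_gene_rejected(self):
        tab = pd.DataFrame({"gene": ["a", "a"], "log2FoldChange": [1, 2],
                            "pvalue": [0.1, 0.1]})
        with pytest.raises(ValidationError):
            z.rank_genes(tab)

    def test_missing_scores_excluded(self):
        tab = pd.DataFrame({"gene": ["a", "b"], "log2FoldChange": [1.0, np.nan],
                            "pvalue": [0.1, 0.1]})
        assert list(z.rank_genes(tab).gene) == ["a"]


def equal_score_ranking(genes):
    return pd.DataFrame({"gene": list(genes), "score": [1.0] * len(genes)})


class TestGseaES:
    def test_singleton_top_gene_is_one(self):
        rk = pd.DataFrame({"gene": list("abcd"), "score": [4.0, 3.0, 2.0, 1.0]})
        es, running, leading = gsea_es(rk, GeneSet("s", "", ("a",)))
        assert es == pytest.approx(1.0)
        assert leading == ["a"]

    def test_bottom_singleton_equal_scores(self):
        es, running, leading = gsea_es(equal_score_ranking("abcd"),
                                       GeneSet("s", "", ("d",)))
        assert np.allclose(running, [-1 / 3, -2 / 3, -1.0, 0.0])
        assert es == pytest.approx(-1.0)
        assert leading == ["d"]

    def test_hand_walk_top_two_of_ten(self):
        rk = pd.DataFrame({"gene": [f"g{i}" for i in range(10)],
                           "score": np.arange(10, 0, -1.0)})
        es, running, leading = gsea_es(rk, GeneSet("s", "", ("g0", "g1")))
        assert running[0] == pytest.approx(10 / 19)
        assert running[1] == pytest.approx(1.0)
        assert es == pytest.approx(1.0)
        assert leading == ["g0", "g1"]

    def test_errors(self):
        rk = equal_score_ranking("abcd")
        with pytest.raises(ValidationError):
            gsea_es(rk, GeneSet("s", "", ("x", "y")))
        with pytest.raises(ValidationError):
            gsea_es(rk, GeneSet("s", "", tuple("abcd")))

    def test_running_sum_ends_at_zero_unweighted(self, rng):
        rk = pd.DataFrame({"gene": [f"g{i}" for i in range(30)],
                           "score": np.sort(rng.normal(size=30))[::-1]})
        members = tuple(rng.choice(rk.gene, 6, replace=False))
        _, running, _ = gsea_es(rk, GeneSet("s", "", members), weight=0.0)
        assert running[-1] == pytest.approx(0.0, abs=1e-12)

    def test_reversal_negates_es_unweighted(self, rng):
        rk = pd.DataFrame({"gene": [f"g{i}" for i in range(25)],
                           "score": np.sort(rng.normal(size=25))[::-1]})
        members = tuple(rng.choice(rk.gene, 5, replace=False))
        es_fwd, _, _ = gsea_es(rk, GeneSet("s", "", members), weight=0.0)
        rev = rk.iloc[::-1].reset_index(drop=True)
        es_rev, _, _ = gsea_es(rev, GeneSet("s", "", members), weight=0.0)
        assert es_rev == pytest.approx(-es_fwd, abs=1e-9)

    def test_es_bounded(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 60))
            m = int(rng.integers(1, n))
            rk = pd.DataFrame({"gene": [f"g{i:03d}" for i in range(n)],
                               "score": np.sort(rng.normal(size=n))[::-1]})
            members = tuple(rng.choice(rk.gene, m, replace=False))
            if m == n:
                continue
            es, _, _ = gsea_es(rk, GeneSet("s", "", members))
            assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12

    def test_fast_position_form_agrees_with_full_walk(self, rng):
        """The O(m) hit-position evaluation used for permutation nulls
        matches the explicit running-sum walk; on exact |max|=|min| ties
        (sign ambiguous by float noise) magnitudes must still agree."""
        for _ in range(300):
            n = int(rng.integers(10, 80))
            m = int(rng.integers(1, min(10, n - 1) + 1))
            scores = np.sort(rng.normal(size=n))[::-1]
            rk = pd.DataFrame({"gene": [f"g{i:03d}" for i in range(n)],
                               "score": scores})
            pos = np.sort(rng.choice(n, m, replace=False))
            es_full, _, _ = gsea_es(rk, GeneSet("s", "", tuple(rk.gene[pos])))
            w = np.abs(scores[pos])
            w = w / w.sum()
            es_fast = _es_from_positions(pos, w, n)
            assert abs(es_fast) == pytest.approx(abs(es_full), abs=1e-10)
            if es_fast != pytest.approx(es_full, abs=1e-10):
                # sign flip is only tolerated on an exact |max| = |min| tie
                assert es_fast == pytest.approx(-es_full, abs=1e-10)


class TestGseaSignificance:
    def test_deterministic(self):
        tab = z.simulate_deg_table(300, seed=1)
        rk = z.rank_genes(tab)
        sets = [GeneSet("s", "", tuple(tab.gene[:20]))]
        a = z.gsea_significance(rk, sets, n_perm=100, seed=3)
        b = z.gsea_significance(rk, sets, n_perm=100, seed=3)
        assert a[0].es == b[0].es and a[0].p_value == b[0].p_value
        assert a[0].nes == b[0].nes

    def test_nes_sign_matches_es(self, rng):
        tab = z.simulate_deg_table(400, seed=2)
        rk = z.rank_genes(tab)
        sets = [GeneSet(f"s{i}", "", tuple(rng.choice(tab.gene, 15, replace=False)))
                for i in range(10)]
        for r in z.gsea_significance(rk, sets, n_perm=200, seed=4):
            assert np.sign(r.nes) == np.sign(r.es)
            assert 0 < r.p_value <= 1
            assert r.q_value >= r.p_value - 1e-12

    def test_low_n_perm_warns(self):
        tab = z.simulate_deg_table(100, seed=5)
        rk = z.rank_genes(tab)
        with pytest.warns(UserWarning):
            z.gsea_significance(rk, [GeneSet("s", "", tuple(tab.gene[:5]))],
                                n_perm=10, seed=1)


class TestMarkerSets:
    def test_planted_recovery(self):
        genes = [f"g{i:05d}" for i in range(300)]
        mk = {"A": genes[:25], "B": genes[25:50]}
        counts, labels = z.simulate_cluster_matrix(
            300, {c: (60, mk[c], 8.0) for c in mk}, seed=9)
        sets = {s.name: set(s.members) for s in z.build_marker_sets(counts, labels)}
        for c in mk:
            assert len(sets[c] & set(mk[c])) / 25 >= 0.9

    def test_null_sets_near_empty(self):
        counts, labels = z.simulate_cluster_matrix(
            300, {"A": (50, [], 1.0), "B": (50, [], 1.0)}, seed=10)
        for s in z.build_marker_sets(counts, labels):
            assert len(s) <= 3

    def test_truncation_at_k(self):
        genes = [f"g{i:05d}" for i in range(100)]
        counts, labels = z.simulate_cluster_matrix(
            100, {"A": (40, genes[:30], 6.0), "B": (40, [], 1.0)}, seed=11)
        for s in z.build_marker_sets(counts, labels, k=3):
            assert len(s) <= 3

    def test_tiny_cluster_skipped(self):
        counts, labels = z.simulate_cluster_matrix(
            50, {"A": (1, [], 1.0), "B": (30, [], 1.0)}, seed=12)
        names = [s.name for s in z.build_marker_sets(counts, labels)]
        assert "A" not in names


def brute_force_hypergeom_tail(universe_n, set_n, query_n, observed):
    """Exhaustive P(X >= observed) by enumerating combinations."""
    total = math.comb(universe_n, query_n)
    favorable = sum(
        math.comb(set_n, k) * math.comb(universe_n - set_n, query_n - k)
        for k in range(observed, min(set_n, query_n) + 1))
    return favorable / total


class TestORA:
    def test_exact_hand_example(self):
        uni = [f"u{i}" for i in range(10)]
        out = z.ora(uni[:4], [GeneSet("S", "", tuple(uni[:5]))], uni)
        assert out.p_value[0] == pytest.approx(5 / 210)

    def test_zero_overlap_p_one(self):
        uni = [f"u{i}" for i in range(10)]
        out = z.ora(uni[8:10], [GeneSet("S", "", tuple(uni[:3]))], uni)
        assert out.overlap[0] == 0 and out.p_value[0] == pytest.approx(1.0)

    def test_query_equals_universe_saturates(self):
        uni = [f"u{i}" for i in range(8)]
        out = z.ora(uni, [GeneSet("S", "", tuple(uni[:4]))], uni)
        assert out.overlap[0] == 4 and out.p_value[0] == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            z.ora([], [GeneSet("S", "", ("a",))], [])

    def test_matches_exhaustive_enumeration(self):
        uni = [f"u{i}" for i in range(12)]
        for set_n, query_n in itertools.product((2, 5, 8), (1, 4, 7)):
            gs = GeneSet("S", "", tuple(uni[:set_n]))
            for overlap in range(0, min(set_n, query_n) + 1):
                query = uni[:overlap] + uni[set_n:set_n + (query_n - overlap)]
                out = z.ora(query, [gs], uni)
                assert out.overlap[0] == overlap
                assert out.p_value[0] == pytest.approx(
                    brute_force_hypergeom_tail(12, set_n, query_n, overlap))


def brute_force_bh(pvals):
    m = len(pvals)
    order = np.argsort(pvals, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, pvals[idx] * m / rank)
        q[idx] = prev
    return q


def test_bh_adjustment_matches_brute_force(rng):
    for _ in range(30):
        p = rng.uniform(0, 1, int(rng.integers(1, 40)))
        assert np.allclose(sps.false_discovery_control(p), brute_force_bh(p))
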