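"""Minimal GSEA: ranking, running-sum ES, permutation stats, overlap, ORA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from daposcope import enrichment as en
from daposcope.core import ExpressionMatrix, GeneSetCollection


def bruteforce_es(scores: pd.Series, members: set, weight: float = 1.0):
    """Independent running-sum enumeration (plain python loop)."""
    total_hit = sum(abs(scores[g]) ** weight for g in scores.index
                    if g in members)
    n_miss = len(scores) - len(members & set(scores.index))
    running, best = 0.0, 0.0
    for g in scores.index:
        if g in members:
            running += (abs(scores[g]) ** weight) / total_hit
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


@pytest.fixture
def toy_matrix(rng):
    values = pd.DataFrame(rng.normal(10, 2, size=(20, 12)),
                          index=[f"g{i:02d}" for i in range(20)],
                          columns=[f"s{i}" for i in range(12)])
    stages = pd.Series(["normal"] * 6 + ["SII"] * 6, index=values.columns)
    return ExpressionMatrix(values, stages)


class TestRankGenes:
    def test_equal_group_means_near_zero(self):
        values = pd.DataFrame(np.tile([[5.0, 5, 5, 5, 5, 5]], (4, 1)),
                              index=list("abcd"),
                              columns=[f"s{i}" for i in range(6)])
        em = ExpressionMatrix(values, pd.Series(
            ["normal"] * 3 + ["SII"] * 3, index=values.columns))
        scores = en.rank_genes(em, em.samples_of("SII"),
                               em.samples_of("normal"))
        np.testing.assert_allclose(scores, 0.0)

    def test_closed_form_single_gene(self):
        # (mu1 - mu2) / (sd1 + sd2) when the 0.2|mu| floor does not bind
        a, b = np.array([10.0, 30.0, 20.0]), np.array([1.0, 3.0, 2.0])
        values = pd.DataFrame([np.r_[a, b]], index=["g"],
                              columns=[f"s{i}" for i in range(6)])
        em = ExpressionMatrix(values, pd.Series(
            ["SII"] * 3 + ["normal"] * 3, index=values.columns))
        score = en.rank_genes(em, em.samples_of("SII"),
                              em.samples_of("normal"))["g"]
        sd_a = max(a.std(ddof=1), 0.2 * a.mean())
        sd_b = max(b.std(ddof=1), 0.2 * b.mean())
        assert score == pytest.approx((a.mean() - b.mean()) / (sd_a + sd_b))

    def test_ties_broken_lexicographically(self, toy_matrix):
        em = ExpressionMatrix(
            pd.DataFrame(np.ones((5, 12)), index=list("edcba"),
                         columns=toy_matrix.samples),
            toy_matrix.stages)
        ranked = en.rank_genes(em, em.samples_of("SII"),
                               em.samples_of("normal"))
        assert list(ranked.index) == sorted(ranked.index)


class TestEnrichmentScore:
    def test_all_members_first_gives_one(self):
        scores = pd.Series([3.0, 2.0, 1.0, -1.0, -2.0],
                           index=list("abcde"))
        es, leading = en.enrichment_score(scores, ["a", "b"])
        assert es == pytest.approx(1.0)
        assert leading == ["a", "b"]

    def test_whole_universe_convention_zero(self):
        scores = pd.Series([2.0, 1.0], index=list("ab"))
        es, leading = en.enrichment_score(scores, ["a", "b"])
        assert es == 0.0 and leading == []

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            en.enrichment_score(pd.Series([1.0], index=["a"]), ["zzz"])

    def test_bruteforce_enumeration_small_universe(self, rng):
        scores = pd.Series(
            np.sort(rng.normal(size=10))[::-1],
            index=[f"g{i}" for i in range(10)])
        for members in itertools.combinations(scores.index, 3):
            es, _ = en.enrichment_score(scores, list(members))
            assert es == pytest.approx(
                bruteforce_es(scores, set(members)), abs=1e-12)

    def test_scaling_invariance(self, rng):
        """Positive rescaling of scores (a monotone map) leaves ES fixed."""
        scores = pd.Series(rng.normal(size=15),
                           index=[f"g{i}" for i in range(15)])
        scores = scores.sort_values(ascending=False)
        es1, _ = en.enrichment_score(scores, ["g1", "g4", "g9"])
        es2, _ = en.enrichment_score(scores * 7.5, ["g1", "g4", "g9"])
        assert es1 == pytest.approx(es2)

    def test_reversal_negates_es(self, rng):
        scores = pd.Series(rng.normal(size=12),
                           index=[f"g{i}" for i in range(12)])
        scores = scores.sort_values(ascending=False)
        rev = scores.iloc[::-1]
        members = ["g2", "g5", "g7"]
        es_f, _ = en.enrichment_score(scores, members)
        es_r, _ = en.enrichment_score(rev, members)
        assert es_f == pytest.approx(-es_r)

    def test_leading_edge_subset_of_members(self, rng):
        scores = pd.Series(rng.normal(size=30),
                           index=[f"g{i:02d}" for i in range(30)])
        scores = scores.sort_values(ascending=False)
        members = [f"g{i:02d}" for i in (3, 7, 11, 20, 25)]
        es, leading = en.enrichment_score(scores, members)
        assert set(leading) <= set(members)
        assert abs(es) <= 1.0


class TestNesFdr:
    @pytest.fixture
    def null_setup(self, rng):
        ranked = pd.Series(np.sort(rng.normal(size=60))[::-1],
                           index=[f"g{i:02d}" for i in range(60)])
        genes = list(ranked.index)
        sets = {}
        for i in range(8):
            idx = rng.choice(60, size=10, replace=False)
            sets[f"S{i}"] = [genes[j] for j in idx]
        return ranked, GeneSetCollection(sets)

    def test_fixed_seed_reproducible(self, null_setup):
        ranked, coll = null_setup
        a = en.nes_fdr(ranked, coll, n_perm=100, seed=5)
        b = en.nes_fdr(ranked, coll, n_perm=100, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_null_nes_magnitude_near_one(self, null_setup):
        """Random sets on a random ranking: mean |NES| close to 1 by
        construction of the normalization."""
        ranked, coll = null_setup
        res = en.nes_fdr(ranked, coll, n_perm=300, seed=1)
        assert res["nes"].abs().mean() == pytest.approx(1.0, abs=0.35)

    def test_q_at_least_p_under_pooled_null(self, null_setup):
        ranked, coll = null_setup
        res = en.nes_fdr(ranked, coll, n_perm=300, seed=2)
        assert (res["fdr_q"] >= res["pvalue"] - 0.05).all()
        assert res["fdr_q"].between(0, 1).all()

    def test_sign_consistency(self, null_setup):
        ranked, coll = null_setup
        res = en.nes_fdr(ranked, coll, n_perm=100, seed=3)
        assert (np.sign(res["nes"]) == np.sign(res["es"])).all()

    def test_phenotype_mode_runs(self, toy_matrix, rng):
        genes = list(toy_matrix.genes)
        coll = GeneSetCollection({"S0": genes[:5], "S1": genes[5:10]})
        ranked = en.rank_genes(toy_matrix, toy_matrix.samples_of("SII"),
                               toy_matrix.samples_of("normal"))
        res = en.nes_fdr(ranked, coll, n_perm=50, seed=4, mode="phenotype",
                         em=toy_matrix,
                         group_a=toy_matrix.samples_of("SII"),
                         group_b=toy_matrix.samples_of("normal"))
        assert len(res) == 2 and res["fdr_q"].between(0, 1).all()


class TestFilter:
    def make(self, **overrides):
        base = {"name": "s", "es": 0.8, "nes": 2.0, "pvalue": 0.01,
                "fdr_q": 0.1, "leading_edge": [], "tissue_class": "other"}
        return {**base, **overrides}

    def test_q_above_threshold_dropped(self):
        df = pd.DataFrame([self.make(fdr_q=0.3)])
        assert en.filter_enrichments(df).empty

    def test_exact_thresholds_retained(self):
        df = pd.DataFrame([self.make(fdr_q=0.25, es=0.50, nes=1.5)])
        assert len(en.filter_enrichments(df)) == 1

    def test_top_k_by_abs_nes(self):
        rows = [self.make(name=f"s{i}", nes=1.5 + i * 0.01)
                for i in range(40)]
        out = en.filter_enrichments(pd.DataFrame(rows), top_k=30)
        assert len(out) == 30
        assert out["nes"].min() >= 1.5 + 9 * 0.01

    def test_negative_es_retained_by_magnitude(self):
        df = pd.DataFrame([self.make(es=-0.7, nes=-2.0)])
        assert len(en.filter_enrichments(df)) == 1


class TestLeadingEdgeOverlap:
    def frame(self, edges: dict) -> pd.DataFrame:
        return pd.DataFrame({"name": list(edges),
                             "leading_edge": [sorted(v) for v in
                                              edges.values()]})

    def test_planted_full_overlap(self):
        shared = [f"x{i}" for i in range(24)]
        edges = {f"t{i}": set(shared) | {f"u{i}"} for i in range(10)}
        s = en.leading_edge_overlap(self.frame(edges))
        assert (s.n_genes, s.n_terms) == (24, 10)

    def test_disjoint_edges_zero(self):
        edges = {"a": {"x"}, "b": {"y"}, "c": {"z"}}
        s = en.leading_edge_overlap(self.frame(edges))
        assert (s.n_genes, s.n_terms) == (0, 0)

    def test_random_instances_vs_pairwise_oracle(self, rng):
        for _ in range(100):
            n_sets = int(rng.integers(2, 10))
            genes = [f"g{i}" for i in range(int(rng.integers(3, 50)))]
            edges = {
                f"t{i}": {g for g in genes if rng.random() < 0.3}
                for i in range(n_sets)}
            s = en.leading_edge_overlap(self.frame(edges))
            shared = {g for g in genes
                      if sum(g in e for e in edges.values()) >= 2}
            terms = sum(1 for e in edges.values() if e & shared)
            assert (s.n_genes, s.n_terms) == (len(shared), terms)


class TestOra:
    def test_full_set_has_minimal_p(self, rng):
        genes = [f"g{i}" for i in range(20)]
        sets = {f"S{i}": genes[i * 4:(i + 1) * 4] for i in range(5)}
        coll = GeneSetCollection(sets)
        res = en.ora(sets["S2"], coll, genes).set_index("name")
        assert res["pvalue"].idxmin() == "S2"

    def test_exhaustive_tail_sum_oracle(self):
        universe = [f"g{i}" for i in range(20)]
        members = universe[:6]
        query = universe[2:9]  # 4 hits out of 7 drawn
        coll = GeneSetCollection({"S": members})
        p = en.ora(query, coll, universe)["pvalue"].iloc[0]
        # oracle: sum over the hypergeometric tail via explicit binomials
        hits = len(set(query) & set(members))
        expected = sum(
            math.comb(6, k) * math.comb(14, 7 - k) / math.comb(20, 7)
            for k in range(hits, min(6, 7) + 1))
        assert p == pytest.approx(expected, abs=1e-12)

    def test_empty_query_rejected(self):
        coll = GeneSetCollection({"S": ["a"]})
        with pytest.raises(ValueError):
            en.ora([], coll, ["a", "b"])
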