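"""Enrichment score vs hand running-sum oracle; permutation and redundancy tests."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from survscreen.enrichment import (RankedList, common_enriched, enrichment_score,
                                   enrichment_significance, meet_min,
                                   redundancy_clusters, spearman_rank_metric)
from survscreen.io import ExpressionMatrix, GeneSet


def running_sum_oracle(metric, hits, weight):
    """Step-by-step walk: hit += |m|^w / sum_hits, miss -= 1/(N-Nh)."""
    metric = np.asarray(metric, float)
    N, nh = len(metric), int(np.sum(hits))
    w = np.abs(metric) ** weight if weight else np.ones(N)
    denom = np.sum(w[np.asarray(hits, bool)])
    walk, cur, best = [], 0.0, 0.0
    for i in range(N):
        cur += w[i] / denom if hits[i] else -1.0 / (N - nh)
        walk.append(cur)
    return walk[int(np.argmax(np.abs(walk)))]


class TestSpearmanRanking:
    def make_matrix(self, rng, g=10, n=6):
        vals = rng.normal(size=(g, n))
        return ExpressionMatrix([f"g{i}" for i in range(g)], [f"s{j}" for j in range(n)], vals)

    def test_identical_and_inverted_genes(self, rng):
        base = rng.normal(size=8)
        m = ExpressionMatrix(["idx", "same", "anti"], [f"s{j}" for j in range(8)],
                             np.vstack([base, base, -base]))
        ranked = spearman_rank_metric(m, "idx")
        assert ranked.gene_ids[0] == "same" and ranked.metric[0] == pytest.approx(1.0)
        assert ranked.gene_ids[-1] == "anti" and ranked.metric[-1] == pytest.approx(-1.0)
        assert "idx" not in ranked.gene_ids

    def test_matches_rank_then_pearson_oracle(self, rng):
        m = self.make_matrix(rng)
        ranked = spearman_rank_metric(m, "g0")
        for gid, rho in zip(ranked.gene_ids, ranked.metric):
            ref = spearmanr(m.gene("g0"), m.gene(gid)).statistic
            assert rho == pytest.approx(ref, abs=1e-12)

    def test_constant_gene_zero_with_warning(self, rng):
        m = ExpressionMatrix(["idx", "flat"], [f"s{j}" for j in range(6)],
                             np.vstack([rng.normal(size=6), np.ones(6)]))
        ranked = spearman_rank_metric(m, "idx")
        assert ranked.metric[ranked.gene_ids.index("flat")] == 0.0


class TestEnrichmentScore:
    def test_maximal_enrichment_top_loaded(self):
        # N=10, Nh=3, all members in the top 3, weight 0 -> ES = 1
        ranked = RankedList([f"g{i}" for i in range(10)], np.linspace(2, 0.1, 10))
        gs = GeneSet("top", {"g0", "g1", "g2"})
        assert enrichment_score(ranked, gs, weight_exponent=0) == pytest.approx(1.0)

    def test_set_covering_ranking_rejected(self):
        ranked = RankedList(["a", "b", "c"], [3.0, 2.0, 1.0])
        with pytest.raises(ValueError):
            enrichment_score(ranked, GeneSet("all", {"a", "b", "c"}))

    def test_no_members_in_ranking_rejected(self):
        ranked = RankedList(["a", "b", "c"], [3.0, 2.0, 1.0])
        with pytest.raises(ValueError):
            enrichment_score(ranked, GeneSet("other", {"x"}))

    @pytest.mark.parametrize("weight", [0, 1.0])
    def test_matches_hand_running_sum(self, weight):
        # N=8, members at positions 2 and 5 (1-based)
        metric = np.array([0.9, 0.7, 0.5, 0.3, 0.2, -0.1, -0.4, -0.8])
        ranked = RankedList([f"g{i}" for i in range(8)], metric)
        gs = GeneSet("s", {"g1", "g4"})
        hits = [g in gs.members for g in ranked.gene_ids]
        assert enrichment_score(ranked, gs, weight) == pytest.approx(
            running_sum_oracle(metric, hits, weight), abs=1e-12)

    def test_random_placement_mean_near_zero(self, rng):
        N, nh = 1000, 50
        metric = np.sort(rng.normal(size=N))[::-1]
        ranked = RankedList([f"g{i}" for i in range(N)], metric)
        es = []
        for _ in range(300):
            members = rng.choice(N, nh, replace=False)
            es.append(enrichment_score(ranked, GeneSet("r", {f"g{i}" for i in members}), 0))
        assert abs(np.mean(es)) < 0.05


class TestSignificance:
    def test_planted_set_significant(self, rng):
        N = 400
        metric = np.linspace(3, -3, N)
        ranked = RankedList([f"g{i}" for i in range(N)], metric)
        planted = GeneSet("planted", {f"g{i}" for i in range(15)})
        rand = [GeneSet(f"r{k}", {f"g{i}" for i in rng.choice(N, 15, replace=False)})
                for k in range(10)]
        res = enrichment_significance(ranked, [planted, *rand], n_perm=500, seed=1)
        assert res[0].fdr_q < 0.05
        assert res[0].es > 0

    def test_same_seed_identical(self, rng):
        N = 100
        ranked = RankedList([f"g{i}" for i in range(N)], np.linspace(1, -1, N))
        sets = [GeneSet(f"r{k}", {f"g{i}" for i in rng.choice(N, 8, replace=False)})
                for k in range(5)]
        a = enrichment_significance(ranked, sets, n_perm=200, seed=9)
        b = enrichment_significance(ranked, sets, n_perm=200, seed=9)
        assert [r.p for r in a] == [r.p for r in b]

    def test_bh_fdr_monotone(self, rng):
        N = 200
        ranked = RankedList([f"g{i}" for i in range(N)], np.linspace(1, -1, N))
        sets = [GeneSet(f"r{k}", {f"g{i}" for i in rng.choice(N, 10, replace=False)})
                for k in range(12)]
        res = enrichment_significance(ranked, sets, n_perm=200, seed=2)
        res_sorted = sorted(res, key=lambda r: r.p)
        qs = [r.fdr_q for r in res_sorted]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))


class TestMeetMin:
    def test_identity_disjoint_and_partial(self):
        assert meet_min({"a", "b"}, {"a", "b"}) == 1.0
        assert meet_min({"a"}, {"b"}) == 0.0
        assert meet_min({"a", "b", "c"}, {"b", "c", "d"}) == pytest.approx(2 / 3)

    def test_one_iff_subset(self, rng):
        universe = list("abcdefghij")
        for _ in range(50):
            a = set(rng.choice(universe, rng.integers(1, 8), replace=False))
            b = set(rng.choice(universe, rng.integers(1, 8), replace=False))
            is_nested = a <= b or b <= a
            assert (meet_min(a, b) == 1.0) == is_nested

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            meet_min(set(), {"a"})


class TestRedundancyClusters:
    def test_two_families_block_structure(self):
        fam1 = [GeneSet(f"f1_{i}", {f"a{j}" for j in range(10)} | {f"u{i}"}) for i in range(4)]
        fam2 = [GeneSet(f"f2_{i}", {f"b{j}" for j in range(10)} | {f"v{i}"}) for i in range(4)]
        labels, sim, _ = redundancy_clusters(fam1 + fam2, k=2)
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[4]
        assert np.allclose(sim.values, sim.values.T)
        assert np.allclose(np.diag(sim.values), 1.0)

    def test_identical_sets_single_cluster(self):
        sets = [GeneSet(f"s{i}", {"a", "b"}) for i in range(4)]
        labels, _, _ = redundancy_clusters(sets, height=0.5)
        assert len(set(labels)) == 1

    def test_average_linkage_merge_heights(self):
        """Dendrogram merge heights equal a hand-computed agglomeration trace."""
        sets = [GeneSet("A", {1, 2}), GeneSet("B", {1, 2}), GeneSet("C", {1, 3}),
                GeneSet("D", {4, 5}), GeneSet("E", {4, 6}), GeneSet("F", {7, 8})]
        _, sim, Z = redundancy_clusters(sets, k=2)
        # hand trace: A-B merge at 0; C joins at 1-0.5=0.5; D-E at 0.5;
        # F joins D,E at 1.0; final merge of the two families at 1.0
        heights = sorted(Z[:, 2])
        assert heights == pytest.approx([0.0, 0.5, 0.5, 1.0, 1.0], abs=1e-12)

    def test_k_exceeds_sets_raises(self):
        with pytest.raises(ValueError):
            redundancy_clusters([GeneSet("a", {"x"}), GeneSet("b", {"y"})], k=3)


def test_common_enriched_requires_sign_agreement():
    from survscreen.enrichment import EnrichmentResult
    a = [EnrichmentResult("s1", 0.5, 0.001, 0.01), EnrichmentResult("s2", 0.5, 0.001, 0.01)]
    b = [EnrichmentResult("s1", 0.4, 0.001, 0.01), EnrichmentResult("s2", -0.4, 0.001, 0.01)]
    assert common_enriched([a, b]) == ["s1"]
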