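import itertools

import numpy as np
import pandas as pd
import pytest

from radbench import enrichment as enr


def brute_force_es(metric, hit_mask, weight_p):
    """Independent loop-based running-sum oracle for the enrichment score."""
    N = len(metric)
    n_set = int(np.sum(hit_mask))
    w = [abs(m) ** weight_p for m in metric]
    total = sum(w[i] for i in range(N) if hit_mask[i])
    if total == 0:
        w = [1.0] * N
        total = n_set
    running, best = 0.0, 0.0
    for i in range(N):
        if hit_mask[i]:
            running += w[i] / total
        else:
            running -= 1.0 / (N - n_set)
        if abs(running) > abs(best):
            best = running
    return best


def _collection(sets, universe):
    return enr.GeneSetCollection(sets=sets, universe=list(universe))


class TestOra:
    def test_exact_full_overlap_probability(self):
        universe = [f"g{i}" for i in range(10)]
        coll = _collection({"S": universe[:5]}, universe)
        res = enr.ora(universe[:5], coll, min_overlap=2)
        # drawing 5 of 10 and hitting all 5 set members: 1 / C(10,5)
        assert res.table.loc[0, "p"] == pytest.approx(1 / 252)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(12)]
        members = list(rng.choice(universe, 5, replace=False))
        sig = list(rng.choice(universe, 4, replace=False))
        coll = _collection({"S": members}, universe)
        res = enr.ora(sig, coll, min_overlap=1)
        observed = len(set(members) & set(sig))
        count = sum(
            1 for draw in itertools.combinations(universe, len(sig))
            if len(set(draw) & set(members)) >= observed)
        expected = count / len(list(itertools.combinations(universe, len(sig))))
        assert res.table.loc[0, "p"] == pytest.approx(expected, rel=1e-12)

    def test_min_overlap_excludes_single_gene_hits(self):
        universe = [f"g{i}" for i in range(20)]
        coll = _collection({"S1": universe[:5], "S2": universe[10:15]},
                           universe)
        sig = [universe[0], universe[15], universe[16]]
        res = enr.ora(sig, coll, min_overlap=2)
        assert len(res.table) == 0  # S1 overlaps once, S2 not at all

    def test_out_of_universe_genes_dropped_with_warning(self):
        universe = [f"g{i}" for i in range(10)]
        coll = _collection({"S": universe[:4]}, universe)
        with pytest.warns(UserWarning, match="dropped"):
            res = enr.ora(universe[:3] + ["alien"], coll, min_overlap=2)
        assert res.params["signature_size"] == 3

    def test_empty_universe_rejected(self):
        coll = _collection({}, [])
        with pytest.raises(ValueError, match="empty universe"):
            enr.ora(["g1"], coll)


class TestEnrichmentScore:
    def test_top_gene_set_scores_one(self):
        metric = np.array([3.0, 2.0, 1.0, 0.5])
        hit = np.array([True, False, False, False])
        assert enr.enrichment_score(metric, hit, weight_p=0) == pytest.approx(1.0)

    def test_alternating_set_minimizes_magnitude(self):
        metric = -np.arange(10, dtype=float)  # strictly decreasing, tie-free
        alternating = np.zeros(10, dtype=bool)
        alternating[::2] = True
        es_alt = abs(enr.enrichment_score(metric, alternating, weight_p=0))
        for idx in itertools.combinations(range(10), 5):
            hit = np.zeros(10, dtype=bool)
            hit[list(idx)] = True
            assert abs(enr.enrichment_score(metric, hit, weight_p=0)) >= es_alt - 1e-12

    @pytest.mark.parametrize("weight_p", [0.0, 1.0, 2.0])
    def test_matches_bruteforce_oracle(self, weight_p):
        rng = np.random.default_rng(1)
        for _ in range(25):
            N = int(rng.integers(5, 21))
            metric = np.sort(rng.normal(0, 1, N))[::-1]
            n_set = int(rng.integers(1, N))
            hit = np.zeros(N, dtype=bool)
            hit[rng.choice(N, n_set, replace=False)] = True
            got = enr.enrichment_score(metric, hit, weight_p)
            want = brute_force_es(metric, hit, weight_p)
            assert got == pytest.approx(want, abs=1e-12)


class TestGseaPreranked:
    @staticmethod
    def _ranked(N=200, seed=2):
        rng = np.random.default_rng(seed)
        metric = np.sort(rng.normal(0, 1, N))[::-1]
        genes = [f"g{i}" for i in range(N)]
        return genes, metric

    def test_top_loaded_set_significant(self):
        genes, metric = self._ranked()
        coll = _collection({"top": genes[:15], "random": genes[5::13]}, genes)
        res = enr.gsea_preranked(genes, metric, coll, n_perm=500, seed=0)
        row = res.table.set_index("set").loc["top"]
        assert row["es"] > 0 and row["p"] < 0.01

    def test_permutation_p_stable_under_more_permutations(self):
        genes, metric = self._ranked(seed=3)
        coll = _collection({"S": genes[::7][:20]}, genes)
        p_small = enr.gsea_preranked(genes, metric, coll, n_perm=500,
                                     seed=1).table.loc[0, "p"]
        p_big = enr.gsea_preranked(genes, metric, coll, n_perm=5000,
                                   seed=2).table.loc[0, "p"]
        mc_se = np.sqrt(p_big * (1 - p_big) / 500)
        assert abs(p_small - p_big) <= 3 * mc_se + 1e-9

    def test_set_size_filters(self):
        genes, metric = self._ranked()
        coll = _collection({"tiny": genes[:2], "ok": genes[:10]}, genes)
        res = enr.gsea_preranked(genes, metric, coll, min_set=5, n_perm=200,
                                 seed=0)
        assert list(res.table["set"]) == ["ok"]

    def test_low_n_perm_warns(self):
        genes, metric = self._ranked()
        coll = _collection({"S": genes[:10]}, genes)
        with pytest.warns(UserWarning, match="n_perm"):
            enr.gsea_preranked(genes, metric, coll, n_perm=50, seed=0)

    def test_fdr_controlled_under_null_sets(self):
        """Random sets on a random ranking: the BH-significant fraction stays
        at or below the nominal level on average (50 replicates)."""
        fracs = []
        for rep in range(50):
            rng = np.random.default_rng(300 + rep)
            N = 150
            genes = [f"g{i}" for i in range(N)]
            metric = np.sort(rng.normal(0, 1, N))[::-1]
            sets = {f"S{j}": list(rng.choice(genes, 15, replace=False))
                    for j in range(20)}
            res = enr.gsea_preranked(genes, metric, _collection(sets, genes),
                                     n_perm=200, seed=rep)
            fracs.append((res.table["p_adj"] < 0.05).mean())
        assert np.mean(fracs) <= 0.05


class TestHrDifferenceRanking:
    @staticmethod
    def _scan(log_hrs: dict, label):
        from radbench.genescan import GeneScanResult

        table = pd.DataFrame(
            {"hr": np.exp(list(log_hrs.values())),
             "log_hr": list(log_hrs.values()),
             "se": 0.1, "p": 0.5, "converged": True},
            index=list(log_hrs))
        return GeneScanResult(table=table, group_label=label,
                              n_genes_tested=len(log_hrs), n_failed=0)

    def test_identical_scans_give_zero_metric(self):
        scan = self._scan({"a": 0.3, "b": -0.2}, "OS_RT")
        genes, metric = enr.hr_difference_ranking(scan, scan)
        assert np.allclose(metric, 0.0)

    def test_single_discordant_gene_ranks_first(self):
        rt = self._scan({"a": np.log(2.0), "b": 0.0, "c": 0.0}, "OS_RT")
        nort = self._scan({"a": 0.0, "b": 0.0, "c": 0.0}, "OS_noRT")
        genes, metric = enr.hr_difference_ranking(rt, nort)
        assert genes[0] == "a"
        assert metric[0] == pytest.approx(np.log(2.0))

    def test_disjoint_universes_rejected(self):
        rt = self._scan({"a": 0.1}, "OS_RT")
        nort = self._scan({"b": 0.1}, "OS_noRT")
        with pytest.raises(ValueError, match="share no genes"):
            enr.hr_difference_ranking(rt, nort)


class TestBhAdjust:
    def test_direct_step_up_evaluation(self):
        got = enr.bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(got, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert enr.bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_equal_unchanged(self):
        assert np.allclose(enr.bh_adjust([0.1] * 5), 0.1)

    def test_monotone_after_sorting(self):
        rng = np.random.default_rng(4)
        p = np.sort(rng.uniform(0, 1, 50))
        adj = enr.bh_adjust(p)
        assert np.all(np.diff(adj) >= -1e-15)
        assert np.all(adj >= p)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            enr.bh_adjust([0.1, 1.5])


class TestReduceTerms:
    @staticmethod
    def _result(rows):
        return enr.EnrichmentResult(
            table=pd.DataFrame(rows), method="ora", params={})

    def test_identical_sets_form_one_cluster(self):
        universe = [f"g{i}" for i in range(10)]
        coll = _collection({"A": universe[:5], "B": universe[:5]}, universe)
        res = self._result([{"set": "A", "p": 0.001, "p_adj": 0.002},
                            {"set": "B", "p": 0.002, "p_adj": 0.003}])
        clusters = enr.reduce_terms(res, coll, 0.7, alpha=0.05)
        assert len(clusters.clusters) == 1
        assert clusters.clusters[0]["representative"] == "A"
        assert set(clusters.clusters[0]["members"]) == {"A", "B"}

    def test_disjoint_sets_stay_singletons(self):
        universe = [f"g{i}" for i in range(10)]
        coll = _collection({"A": universe[:3], "B": universe[5:8]}, universe)
        res = self._result([{"set": "A", "p": 0.001, "p_adj": 0.002},
                            {"set": "B", "p": 0.002, "p_adj": 0.003}])
        clusters = enr.reduce_terms(res, coll, 0.7, alpha=0.05)
        assert len(clusters.clusters) == 2

    def test_chain_follows_greedy_hand_trace(self):
        # A~B J=0.8 >= 0.7; B~C J=0.8; A~C J=4/10 < 0.7.
        # Greedy: A (most significant) absorbs B; C left as singleton.
        A = [f"g{i}" for i in range(1, 10)]           # 1..9
        B = [f"g{i}" for i in range(2, 11)]           # 2..10 (J(A,B)=8/10)
        C = [f"g{i}" for i in range(3, 12)]           # 3..11 (J(B,C)=8/10)
        universe = [f"g{i}" for i in range(1, 12)]
        coll = _collection({"A": A, "B": B, "C": C}, universe)
        assert enr.jaccard(A, B) == pytest.approx(0.8)
        assert enr.jaccard(B, C) == pytest.approx(0.8)
        assert enr.jaccard(A, C) < 0.7
        res = self._result([{"set": "A", "p": 0.001, "p_adj": 0.001},
                            {"set": "B", "p": 0.002, "p_adj": 0.002},
                            {"set": "C", "p": 0.003, "p_adj": 0.003}])
        clusters = enr.reduce_terms(res, coll, 0.7, alpha=0.05)
        assert [c["representative"] for c in clusters.clusters] == ["A", "C"]
        assert set(clusters.clusters[0]["members"]) == {"A", "B"}

    def test_no_significant_sets_gives_empty_clustering(self):
        universe = [f"g{i}" for i in range(5)]
        coll = _collection({"A": universe[:3]}, universe)
        res = self._result([{"set": "A", "p": 0.5, "p_adj": 0.8}])
        assert enr.reduce_terms(res, coll, 0.7).clusters == []
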