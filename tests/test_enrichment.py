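"""Enrichment score, permutation null, NES/FDR and leading edge."""

import itertools

import numpy as np
import pandas as pd
import pytest

import pentamsea as pm
from pentamsea.enrichment import MSEA, sample_null
from pentamsea.sets import MotifSet, MotifSetCollection

from conftest import brute_force_es


class TestEnrichmentScore:
    def test_single_top_member(self, toy_ranking):
        es, peak = pm.enrichment_score(toy_ranking, {toy_ranking.index[0]})
        assert es == pytest.approx(1.0)
        assert peak == 1

    def test_single_bottom_member(self, toy_ranking):
        members = {toy_ranking.index[-1]}
        es, peak = pm.enrichment_score(toy_ranking, members)
        oracle_es, oracle_peak, _ = brute_force_es(
            toy_ranking.to_numpy(), toy_ranking.index.isin(members))
        assert es == pytest.approx(oracle_es)
        assert peak == oracle_peak
        assert es == pytest.approx(-1.0)

    def test_six_item_hand_walk(self):
        """metrics (3,2,1,−1,−2,−3), set = top two items: the running sum
        climbs to (3+2)/5 = 1 after rank 2 and that is the extreme."""
        ranked = pd.Series([3.0, 2.0, 1.0, -1.0, -2.0, -3.0],
                           index=list("abcdef"))
        es, peak = pm.enrichment_score(ranked, {"a", "b"})
        assert es == pytest.approx(1.0)
        assert peak == 2

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_matches_brute_force_on_all_subsets(self, toy_ranking, p):
        metric = toy_ranking.to_numpy()
        names = list(toy_ranking.index)
        for size in range(1, 10):
            for combo in itertools.combinations(range(10), size):
                mask = np.zeros(10, bool)
                mask[list(combo)] = True
                es, peak = pm.enrichment_score(
                    toy_ranking, {names[i] for i in combo}, p)
                oes, opeak, walk = brute_force_es(metric, mask, p)
                assert es == pytest.approx(oes), combo
                # the reported peak attains the extreme (position ties at
                # equal running-sum values are legitimate)
                assert walk[peak - 1] == pytest.approx(es), combo

    def test_es_bounds_and_closure(self, toy_ranking):
        rng = np.random.default_rng(0)
        for _ in range(50):
            size = rng.integers(1, 9)
            members = set(rng.choice(toy_ranking.index, size, replace=False))
            es, peak, rs = pm.enrichment_score(
                toy_ranking, members, return_running_sum=True)
            assert -1 - 1e-9 <= es <= 1 + 1e-9
            assert abs(rs[-1]) < 1e-9  # running sum returns to zero

    def test_unweighted_equals_classical_ks(self, toy_ranking):
        """p=0 reduces to the maximal signed ECDF difference between member
        and non-member rank distributions."""
        names = list(toy_ranking.index)
        rng = np.random.default_rng(1)
        for _ in range(20):
            members = set(rng.choice(names, 4, replace=False))
            es, _ = pm.enrichment_score(toy_ranking, members, 0.0)
            hit = toy_ranking.index.isin(members)
            f_hit = np.cumsum(hit) / hit.sum()
            f_miss = np.cumsum(~hit) / (~hit).sum()
            d = f_hit - f_miss
            expected = d.max() if d.max() >= -d.min() else d.min()
            assert es == pytest.approx(expected)

    def test_zero_metric_set_falls_back_to_unweighted(self):
        ranked = pd.Series([2.0, 1.0, 0.0, 0.0, -1.0], index=list("abcde"))
        es, _ = pm.enrichment_score(ranked, {"c", "d"}, 1.0)
        es0, _ = pm.enrichment_score(ranked, {"c", "d"}, 0.0)
        assert es == pytest.approx(es0)

    def test_monotone_transform_invariance_at_p0(self, toy_ranking):
        transformed = pd.Series(np.exp(toy_ranking.to_numpy() / 2),
                                index=toy_ranking.index)
        members = {"g1", "g4", "g7"}
        assert pm.enrichment_score(toy_ranking, members, 0.0) == \
            pm.enrichment_score(transformed, members, 0.0)

    def test_degenerate_sets_rejected(self, toy_ranking):
        with pytest.raises(ValueError):
            pm.enrichment_score(toy_ranking, set())
        with pytest.raises(ValueError):
            pm.enrichment_score(toy_ranking, set(toy_ranking.index))

    def test_reversal_negates_es(self):
        # continuous metric: exact running-sum ties (where the sign
        # preference breaks antisymmetry) have probability zero
        rng = np.random.default_rng(2)
        metric = np.sort(rng.normal(0, 2, 40))[::-1]
        ranked = pd.Series(metric, index=[f"g{i}" for i in range(40)])
        reversed_ranking = ranked.iloc[::-1]
        for _ in range(20):
            members = set(rng.choice(ranked.index, 5, replace=False))
            es_fwd, _ = pm.enrichment_score(ranked, members)
            es_rev, _ = pm.enrichment_score(reversed_ranking, members)
            assert es_rev == pytest.approx(-es_fwd)


class TestNull:
    def test_seeded_determinism(self, toy_ranking):
        a = sample_null(toy_ranking, 3, 100, rng=42)
        b = sample_null(toy_ranking, 3, 100, rng=42)
        assert np.array_equal(a, b)

    def test_null_mean_near_zero_on_symmetric_metric(self):
        rng = np.random.default_rng(3)
        metric = np.sort(rng.normal(0, 1, 200))[::-1]
        ranked = pd.Series(metric, index=[f"g{i}" for i in range(200)])
        null = sample_null(ranked, 10, 2000, rng=7)
        se = null.std(ddof=1) / np.sqrt(len(null))
        assert abs(null.mean()) < 3 * se + 0.02

    def test_degenerate_but_legal_size(self, toy_ranking):
        null = sample_null(toy_ranking, 9, 10, rng=0)
        assert len(null) == 10

    def test_invalid_nperm(self, toy_ranking):
        with pytest.raises(ValueError):
            sample_null(toy_ranking, 3, 0, rng=0)


class TestNormalizeAndFdr:
    def test_zero_es(self):
        res = pd.DataFrame({"es": [0.0], "size": [3]})
        nulls = {3: np.array([0.5, -0.5, 0.2, -0.2])}
        out = pm.normalize_and_fdr(res, nulls)
        assert out.loc[0, "nes"] == 0.0
        assert out.loc[0, "p_nominal"] == pytest.approx(1.0)

    def test_nes_is_es_over_samesign_null_mean(self):
        res = pd.DataFrame({"es": [0.6, -0.4], "size": [3, 3]})
        nulls = {3: np.array([0.3, 0.1, 0.2, -0.2, -0.4])}
        out = pm.normalize_and_fdr(res, nulls)
        assert out.loc[0, "nes"] == pytest.approx(0.6 / 0.2)
        assert out.loc[1, "nes"] == pytest.approx(-0.4 / 0.3)

    def test_no_same_sign_null_gives_nan(self):
        res = pd.DataFrame({"es": [0.6], "size": [2]})
        nulls = {2: np.array([-0.1, -0.2, -0.3])}
        out = pm.normalize_and_fdr(res, nulls)
        assert np.isnan(out.loc[0, "nes"])


class TestLeadingEdge:
    def test_set_entirely_above_positive_peak(self, toy_ranking):
        tags, lst, signal = pm.leading_edge(toy_ranking, {"g0", "g1"}, 2, 1)
        assert tags == 1.0
        assert lst == pytest.approx(0.2)

    def test_list_at_half(self, toy_ranking):
        _, lst, _ = pm.leading_edge(toy_ranking, {"g0"}, 5, 1)
        assert lst == pytest.approx(0.5)

    def test_matches_brute_force(self, toy_ranking):
        rng = np.random.default_rng(4)
        for _ in range(20):
            members = set(rng.choice(toy_ranking.index, 3, replace=False))
            es, peak = pm.enrichment_score(toy_ranking, members)
            sign = 1 if es >= 0 else -1
            tags, lst, signal = pm.leading_edge(toy_ranking, members, peak, sign)
            ranks = [i + 1 for i, g in enumerate(toy_ranking.index)
                     if g in members]
            N, m = 10, 3
            if sign > 0:
                exp_tags = sum(r <= peak for r in ranks) / m
                exp_list = peak / N
            else:
                exp_tags = sum(r >= peak for r in ranks) / m
                exp_list = (N - peak + 1) / N
            assert tags == pytest.approx(exp_tags)
            assert lst == pytest.approx(exp_list)
            exp_signal = min(1.0, max(0.0, exp_tags * (1 - exp_list) * N / (N - m)))
            assert signal == pytest.approx(exp_signal)


class TestGseapyCrossCheck:
    def test_es_agrees_with_gseapy_prerank(self):
        """Independent implementation check: the weighted-KS ES of random
        sets on a random ranking matches gseapy's preranked ES."""
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(11)
        N = 80
        names = [f"g{i:02d}" for i in range(N)]
        metric = np.sort(rng.normal(0, 1, N))[::-1]
        ranked = pd.Series(metric, index=names)
        gene_sets = {f"s{j}": list(rng.choice(names, 10, replace=False))
                     for j in range(6)}
        res = gseapy.prerank(
            rnk=pd.DataFrame({"gene": names, "score": metric}),
            gene_sets=gene_sets, permutation_num=20, min_size=2, max_size=60,
            seed=7, outdir=None, no_plot=True).res2d.set_index("Term")
        for name, members in gene_sets.items():
            es, _ = pm.enrichment_score(ranked, members)
            assert es == pytest.approx(float(res.loc[name, "ES"]), abs=1e-9)


class TestRunMsea:
    def test_same_seed_byte_identical(self, ctx, filtered_sets, default_sim):
        matrix, _ = default_sim
        sub = MotifSetCollection(filtered_sets.by_layer("pos1"))
        a = pm.run_msea(matrix, sub, n_perm=100, seed=17, ctx=ctx)
        b = pm.run_msea(matrix, sub, n_perm=100, seed=17, ctx=ctx)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_results_schema_and_invariants(self, ctx, filtered_sets,
                                           default_sim):
        matrix, _ = default_sim
        sub = MotifSetCollection(filtered_sets.by_layer("pos2"))
        res = pm.run_msea(matrix, sub, n_perm=200, seed=17, ctx=ctx)
        assert list(res.columns) == ["set_id", "layer", "size", "es", "nes",
                                     "p_nominal", "fdr_q", "tags", "list",
                                     "signal", "peak_rank", "significant"]
        assert len(res) == 64
        ok = np.isfinite(res["nes"])
        # sign(nes) == sign(es) wherever es != 0
        nz = ok & (res["es"] != 0)
        assert (np.sign(res.loc[nz, "nes"]) == np.sign(res.loc[nz, "es"])).all()
        assert res["es"].between(-1, 1).all()
        for col in ("p_nominal", "fdr_q", "tags", "list", "signal"):
            assert res.loc[ok, col].between(0, 1).all(), col
        # significance definition
        expected = ok & (res["fdr_q"] < 0.05) & (res["list"] < 0.5)
        assert (res["significant"] == expected).all()

    def test_reversal_negates_nes(self, toy_ranking):
        """Reversing the ranking flips ES exactly and NES approximately
        (the null is re-sampled, so magnitudes agree only statistically)."""
        rng = np.random.default_rng(5)
        N = 300
        metric = np.sort(rng.normal(0, 5, N))[::-1]
        ranked = pd.Series(metric, index=[f"g{i}" for i in range(N)])
        members = [f"g{i}" for i in range(0, 40, 2)]
        # a minimal duck-typed set/collection over non-pentamer names
        est = MSEA(n_permutations=500, random_state=9)

        class FakeSet:
            set_id, layer = "fake", "non_positional"
            members = tuple()
            size = 20

        fake = FakeSet()
        fake.members = tuple(members)

        class FakeColl(list):
            def by_id(self):
                return {"fake": fake}

        est.fit(ranked, FakeColl([fake]))
        fwd = est.results_.iloc[0]
        est_rev = MSEA(n_permutations=500, random_state=9)
        est_rev.fit(ranked.iloc[::-1], FakeColl([fake]))
        rev = est_rev.results_.iloc[0]
        assert rev["es"] == pytest.approx(-fwd["es"])
        assert np.sign(rev["nes"]) == -np.sign(fwd["nes"])
        assert abs(rev["nes"]) == pytest.approx(abs(fwd["nes"]), rel=0.25)
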