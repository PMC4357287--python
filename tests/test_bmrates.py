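import numpy as np
import pandas as pd
import pytest
from scipy import stats

import plastevol as pe
from plastevol.bmrates import BMModelSpec, aicc, bm_loglik, bm_loglik_peel

from conftest import random_tree


def star_tree(n, length=1.0):
    newick = "(" + ",".join(f"t{i}:{length}" for i in range(n)) + ");"
    return pe.parse_trees(newick)[0]


def single_regime_painting(tree, label="g"):
    return pe.paint_by_clades(tree, {l: label for l in tree.tip_labels},
                              background=label)


class TestPaintFromHistory:
    def test_no_losses_paints_all_ingroup_dm(self, ref_dataset):
        ds = ref_dataset
        tree = ds.tree
        # a history that stays in state 1 inside the clade
        segments = [list(s) for s in ds.history.segments]
        node_states = ds.history.node_states.copy()
        for node in range(tree.n_nodes):
            if segments[node] and ds.groups2[tree.tip_labels[node]] == "Dip" \
                    if node < tree.n_tips else False:
                pass
        hist = ds.history
        painting = pe.paint_from_history(tree, hist, ds.groups2)
        lens = painting.regime_total_lengths()
        assert set(lens) == {"Rh", "Dm", "Mn"}
        # total painted length must cover the whole tree
        assert sum(lens.values()) == pytest.approx(tree.total_length())

    def test_terminal_loss_splits_edge(self):
        tree = pe.parse_trees("((d1:1,d2:1):1,r1:2);")[0]
        groups = {"d1": "Dip", "d2": "Dip", "r1": "Rh"}
        node_states = np.zeros(tree.n_nodes, dtype=int)
        segments = [[] for _ in range(tree.n_nodes)]
        d1, d2, r1 = (tree.tip_index(x) for x in ("d1", "d2", "r1"))
        mrca = tree.parent[d1]
        node_states[mrca] = 1
        node_states[d2] = 1
        segments[mrca] = [(1.0, 1)]
        segments[d2] = [(1.0, 1)]
        segments[d1] = [(0.4, 1), (0.6, 0)]  # loss part-way down
        segments[r1] = [(2.0, 0)]
        hist = pe.CharacterHistory(tree=tree, segments=segments,
                                   node_states=node_states)
        painting = pe.paint_from_history(tree, hist, groups)
        assert painting.segments[d1] == [(0.4, "Dm"), (0.6, "Mn")]
        assert painting.segments[r1] == [(2.0, "Rh")]

    def test_missing_tip_in_group_table_rejected(self, ref_dataset):
        ds = ref_dataset
        with pytest.raises(ValueError, match="absent"):
            pe.paint_from_history(ds.tree, ds.history,
                                  ds.groups2.iloc[:-1])


class TestBMLoglik:
    def test_star_tree_hand_computation(self):
        tree = star_tree(2)
        painting = single_regime_painting(tree)
        ll, root = bm_loglik(tree, {"t0": 0.0, "t1": 2.0}, painting,
                             {"g": 1.0})
        assert root == pytest.approx(1.0)
        assert ll == pytest.approx(2 * stats.norm.logpdf(1.0), abs=1e-9)

    def test_single_regime_reduces_to_sigma2_C(self, rng):
        tree = random_tree(rng, 12)
        x = rng.normal(size=12)
        painting = single_regime_painting(tree)
        sigma2 = 1.7
        ll, root = bm_loglik(tree, x, painting, {"g": sigma2})
        V = sigma2 * tree.vcv()
        one = np.ones(12)
        a = one @ np.linalg.solve(V, x) / (one @ np.linalg.solve(V, one))
        resid = x - a
        expected = stats.multivariate_normal.logpdf(resid, cov=V)
        assert ll == pytest.approx(expected, abs=1e-8)

    def test_equal_rates_match_single_rate_for_any_painting(self, ref_dataset):
        ds = ref_dataset
        ll_multi, _ = bm_loglik(ds.tree, ds.trait, ds.painting,
                                {"Rh": 2.2, "Dm": 2.2, "Mn": 2.2})
        single = single_regime_painting(ds.tree)
        ll_single, _ = bm_loglik(ds.tree, ds.trait, single, {"g": 2.2})
        assert ll_multi == pytest.approx(ll_single, abs=1e-8)

    def test_peeling_equals_mvn_route(self, ref_dataset):
        ds = ref_dataset
        rates = {"Rh": 0.8, "Dm": 2.5, "Mn": 7.0}
        ll1, r1 = bm_loglik(ds.tree, ds.trait, ds.painting, rates)
        ev = np.zeros(ds.tree.n_nodes)
        for node, segs in enumerate(ds.painting.segments):
            ev[node] = sum(rates[g] * l for l, g in segs)
        ll2, r2 = bm_loglik_peel(ds.tree, ds.trait, ev)
        assert ll1 == pytest.approx(ll2, abs=1e-8)
        assert r1 == pytest.approx(r2, abs=1e-10)

    def test_rescaling_branches_and_rates_is_invariant(self, rng):
        tree = random_tree(rng, 10)
        x = rng.normal(size=10)
        painting = single_regime_painting(tree)
        ll1, _ = bm_loglik(tree, x, painting, {"g": 3.0})
        c = 4.0
        scaled = tree.rescaled(tree.total_length() * c)
        painting2 = single_regime_painting(scaled)
        ll2, _ = bm_loglik(scaled, x, painting2, {"g": 3.0 / c})
        assert ll1 == pytest.approx(ll2, abs=1e-8)


class TestFitAndCompare:
    def test_star_tree_ml_is_ss_over_n(self):
        tree = star_tree(4)
        painting = single_regime_painting(tree)
        spec = BMModelSpec.from_mapping("1", {"g": 1})
        fit = pe.fit_multirate(tree, {"t0": 0, "t1": 0, "t2": 3, "t3": 3.0},
                               painting, spec)
        assert fit.rates[1] == pytest.approx(2.25, rel=1e-4)

    def test_aicc_arithmetic(self):
        assert aicc(-10.0, 2, 10) == pytest.approx(24 + 12 / 7)

    def test_aicc_requires_enough_observations(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 9, 10)

    def test_lrt_chi_square_quantile(self):
        fits = []
        tree = star_tree(10)
        painting = single_regime_painting(tree)
        # synthetic fits: nested pair differing by the 3.841 critical value
        f0 = pe.BMFit(model=BMModelSpec.from_mapping("1,1,1",
                                                     {"Rh": 1, "Dm": 1, "Mn": 1}),
                      rates={1: 1.0}, regime_rates={}, root=0.0,
                      loglik=-20.0, K=2, n=90, aicc=aicc(-20.0, 2, 90))
        f1 = pe.BMFit(model=BMModelSpec.from_mapping("1,2,2",
                                                     {"Rh": 1, "Dm": 2, "Mn": 2}),
                      rates={1: 1.0, 2: 2.0}, regime_rates={}, root=0.0,
                      loglik=-20.0 + 3.841 / 2, K=3, n=90,
                      aicc=aicc(-20.0 + 3.841 / 2, 3, 90))
        _, lrt = pe.compare_models([f0, f1])
        assert lrt.iloc[0]["p"] == pytest.approx(0.0500, abs=5e-4)

    def test_equal_fits_have_zero_delta(self):
        spec = BMModelSpec.from_mapping("1,2,1", {"Rh": 1, "Dm": 2, "Mn": 1})
        f = pe.BMFit(model=spec, rates={1: 1.0, 2: 1.0}, regime_rates={},
                     root=0.0, loglik=-30.0, K=3, n=50,
                     aicc=aicc(-30.0, 3, 50))
        table, _ = pe.compare_models([f, f])
        assert (table["dAICc"] == 0).all()

    def test_worse_nested_alternative_flags_pathology(self):
        f0 = pe.BMFit(model=BMModelSpec.from_mapping("1,1,1",
                                                     {"Rh": 1, "Dm": 1, "Mn": 1}),
                      rates={1: 1.0}, regime_rates={}, root=0.0,
                      loglik=-10.0, K=2, n=90, aicc=aicc(-10.0, 2, 90))
        f1 = pe.BMFit(model=BMModelSpec.from_mapping("1,2,3",
                                                     {"Rh": 1, "Dm": 2, "Mn": 3}),
                      rates={1: 1.0, 2: 1.0, 3: 1.0}, regime_rates={},
                      root=0.0, loglik=-11.0, K=4, n=90,
                      aicc=aicc(-11.0, 4, 90))
        with pytest.raises(RuntimeError, match="pathology"):
            pe.compare_models([f0, f1])

    def test_nesting_relation(self):
        models = {m.name: m for m in pe.standard_models()}
        assert models["1,1,1"].nests_within(models["1,2,3"])
        assert models["1,2,2"].nests_within(models["1,2,3"])
        assert not models["1,2,2"].nests_within(models["1,2,1"])
        assert not models["1,2,3"].nests_within(models["1,2,2"])

    def test_three_rate_recovery_on_reference_data(self, ref_dataset):
        ds = ref_dataset
        spec = [m for m in pe.standard_models() if m.name == "1,2,3"][0]
        fit = pe.fit_multirate(ds.tree, ds.trait, ds.painting, spec)
        true = ds.config.regime_rates
        for g in ("Rh", "Dm", "Mn"):
            assert fit.regime_rates[g] == pytest.approx(true[g], rel=0.6)


class TestModelAverage:
    def _fit(self, name, mapping, rates, ll):
        spec = BMModelSpec.from_mapping(name, mapping)
        regime_rates = {g: rates[i] for g, i in mapping.items()}
        return pe.BMFit(model=spec, rates=rates, regime_rates=regime_rates,
                        root=0.0, loglik=ll, K=len(set(mapping.values())) + 1,
                        n=90, aicc=aicc(ll, len(set(mapping.values())) + 1, 90))

    def test_identical_fits_have_zero_sd(self):
        f = self._fit("1,1,1", {"Rh": 1, "Dm": 1, "Mn": 1}, {1: 2.0}, -5.0)
        out = pe.model_average([f, f], scheme="best")
        assert (out["mean_rate"] == 2.0).all()
        assert (out["sd_rate"] == 0.0).all()

    def test_mean_of_two_single_model_fits(self):
        f1 = self._fit("1,1,1", {"Rh": 1, "Dm": 1, "Mn": 1}, {1: 1.0}, -5.0)
        f2 = self._fit("1,1,1", {"Rh": 1, "Dm": 1, "Mn": 1}, {1: 3.0}, -5.0)
        out = pe.model_average([f1, f2])
        assert (out["mean_rate"] == 2.0).all()

    def test_akaike_weights_average_within_reconstruction(self):
        fa = self._fit("1,1,1", {"Rh": 1, "Dm": 1, "Mn": 1}, {1: 1.0}, -5.0)
        fb = self._fit("1,2,2", {"Rh": 1, "Dm": 2, "Mn": 2},
                       {1: 1.0, 2: 5.0}, -5.0 + 1.061)  # equal AICc at n=90
        out = pe.model_average([[fa, fb]], scheme="akaike")
        w = np.exp(-0.5 * (fa.aicc - min(fa.aicc, fb.aicc)))
        assert 1.0 < out.loc["Dm", "mean_rate"] < 5.0


class TestHPD:
    def test_shortest_interval(self):
        samples = np.concatenate([np.zeros(90), np.ones(10) * 50])
        lo, hi = pe.hpd_interval(samples, prob=0.9)
        assert (lo, hi) == (0.0, 0.0)

    def test_covers_requested_mass(self, rng):
        samples = rng.normal(size=20_000)
        lo, hi = pe.hpd_interval(samples, prob=0.95)
        assert lo == pytest.approx(-1.96, abs=0.1)
        assert hi == pytest.approx(1.96, abs=0.1)


class TestBranchRateMCMC:
    def test_fixed_seed_reproducible(self, rng):
        tree = random_tree(rng, 20)
        x = rng.normal(size=20)
        t1 = pe.mcmc_branch_rates(tree, x, generations=2000,
                                  sample_every=20, seed=3, n_chains=1)
        t2 = pe.mcmc_branch_rates(tree, x, generations=2000,
                                  sample_every=20, seed=3, n_chains=1)
        np.testing.assert_array_equal(t1.rates, t2.rates)

    def test_clock_count_bounded(self, rng):
        tree = random_tree(rng, 20)
        x = rng.normal(size=20)
        trace = pe.mcmc_branch_rates(tree, x, generations=3000,
                                     sample_every=20, seed=1, n_chains=1,
                                     max_clocks=3)
        assert trace.n_clocks.max() <= 3

    def test_single_rate_data_prefers_one_clock(self):
        wins = 0
        for rep in range(6):
            tree = pe.simulate_tree(30, seed=700 + rep)
            painting = single_regime_painting(tree)
            x = pe.simulate_bm_regimes(tree, painting, {"g": 1.0}, seed=rep)
            trace = pe.mcmc_branch_rates(tree, x, generations=6000,
                                         sample_every=10, seed=rep,
                                         n_chains=1)
            p1 = (trace.n_clocks == 1).mean()
            wins += p1 >= 0.5
        assert wins >= 4

    def test_fast_clade_detected(self):
        wins = 0
        for rep in range(5):
            left = pe.simulate_tree(15, seed=800 + rep,
                                    labels=[f"a{i}" for i in range(15)])
            right = pe.simulate_tree(15, seed=900 + rep,
                                     labels=[f"b{i}" for i in range(15)])
            tree = pe.join_trees(left, right, 0.5, 0.5)
            groups = {l: ("fast" if l.startswith("a") else "slow")
                      for l in tree.tip_labels}
            painting = pe.paint_by_clades(tree, groups, background="slow")
            x = pe.simulate_bm_regimes(tree, painting,
                                       {"fast": 20.0, "slow": 1.0}, seed=rep)
            trace = pe.mcmc_branch_rates(tree, x, generations=8000,
                                         sample_every=10, seed=rep,
                                         n_chains=1)
            edge_groups = np.array(
                [segs[-1][1] if segs else None
                 for segs in painting.segments], dtype=object)
            summ, _ = pe.group_rate_test(trace, edge_groups, n_perm=100,
                                         seed=rep)
            wins += summ.loc["fast", "mean"] > summ.loc["slow", "mean"]
        assert wins >= 4

    def test_constant_trait_rejected(self, rng):
        tree = random_tree(rng, 10)
        with pytest.raises(ValueError, match="constant"):
            pe.mcmc_branch_rates(tree, np.ones(10), generations=100,
                                 sample_every=10, seed=0)


class TestGroupRateTest:
    def _trace(self, tree, rates_row, n_samples=200):
        rates = np.tile(rates_row, (n_samples, 1))
        return pe.BranchRateTrace(tree=tree, rates=rates,
                                  n_clocks=np.ones(n_samples, dtype=int),
                                  acceptance={})

    def test_identical_rates_not_significant(self, rng):
        tree = random_tree(rng, 12)
        row = np.ones(tree.n_nodes)
        trace = self._trace(tree, row)
        groups = np.array(["A"] * tree.n_nodes, dtype=object)
        groups[: tree.n_nodes // 2] = "B"
        groups[tree.root] = None
        _, pair = pe.group_rate_test(trace, groups, n_perm=500, seed=1)
        assert pair.iloc[0]["p"] == pytest.approx(1.0)

    def test_disjoint_supports_give_smallest_p(self, rng):
        tree = random_tree(rng, 12)
        row = np.ones(tree.n_nodes)
        groups = np.array(["A"] * tree.n_nodes, dtype=object)
        groups[: tree.n_nodes // 2] = "B"
        row[: tree.n_nodes // 2] = 100.0
        groups[tree.root] = None
        trace = self._trace(tree, row)
        n_perm = 400
        _, pair = pe.group_rate_test(trace, groups, n_perm=n_perm, seed=2)
        assert pair.iloc[0]["p"] < 0.02

    def test_empty_group_rejected(self, rng):
        tree = random_tree(rng, 6)
        trace = self._trace(tree, np.ones(tree.n_nodes))
        groups = np.array([None] * tree.n_nodes, dtype=object)
        with pytest.raises(ValueError):
            pe.group_rate_test(trace, groups, n_perm=10, seed=0)
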