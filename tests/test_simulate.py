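import numpy as np
import pandas as pd
import pytest

import plastevol as pe
from plastevol.simulate import SimConfig


class TestSimulateTree:
    def test_tip_count_and_reproducibility(self):
        t1 = pe.simulate_tree(30, birth=1.0, death=0.0, seed=42)
        t2 = pe.simulate_tree(30, birth=1.0, death=0.0, seed=42)
        assert t1.n_tips == 30
        assert t1.to_newick() == t2.to_newick()
        assert (t1.edge_length[t1.parent >= 0] > 0).all()

    def test_two_tips_is_a_cherry(self):
        t = pe.simulate_tree(2, seed=1)
        assert t.n_tips == 2
        assert len(t.children[t.root]) == 2

    def test_birth_must_exceed_death(self):
        with pytest.raises(ValueError):
            pe.simulate_tree(10, birth=0.5, death=0.5, seed=0)

    def test_yule_depth_matches_closed_form(self):
        # pure birth b=1: E[depth of an n-tip tree] = sum_{k=2}^{n} 1/k
        n = 8
        expected = sum(1.0 / k for k in range(2, n + 1))
        depths = []
        for s in range(600):
            t = pe.simulate_tree(n, birth=1.0, death=0.0, seed=s)
            depths.append(t.node_depths()[: t.n_tips].max())
        se = np.std(depths) / np.sqrt(len(depths))
        assert np.mean(depths) == pytest.approx(expected, abs=4 * se)

    def test_birth_death_returns_requested_tips(self):
        t = pe.simulate_tree(20, birth=1.0, death=0.4, seed=7)
        assert t.n_tips == 20


class TestSimulateMk2:
    def test_absorbing_state(self):
        t = pe.simulate_tree(12, seed=3)
        states, hist = pe.simulate_mk2(t, q01=0.0, q10=1.0, root_state=0,
                                       seed=1)
        assert (states == 0).all()
        assert hist.transition_counts() == (0, 0)

    def test_reproducible(self):
        t = pe.simulate_tree(12, seed=3)
        s1, h1 = pe.simulate_mk2(t, 0.4, 0.6, seed=9)
        s2, h2 = pe.simulate_mk2(t, 0.4, 0.6, seed=9)
        assert (s1 == s2).all()
        assert h1.segments == h2.segments

    def test_transition_count_matches_poisson_expectation(self):
        # symmetric rates: expected transitions = q * total tree length
        t = pe.simulate_tree(10, seed=5)
        q = 0.3
        total = t.total_length()
        counts = []
        for s in range(1500):
            root = int(np.random.default_rng(s).uniform() < 0.5)
            _, h = pe.simulate_mk2(t, q, q, root_state=root, seed=s)
            counts.append(sum(h.transition_counts()))
        se = np.std(counts) / np.sqrt(len(counts))
        assert np.mean(counts) == pytest.approx(q * total, abs=4 * se)

    def test_history_is_internally_consistent(self):
        t = pe.simulate_tree(15, seed=4)
        _, h = pe.simulate_mk2(t, 0.5, 0.5, seed=2)
        h.validate()


class TestSimulateBMRegimes:
    def test_zero_rates_return_root_value(self):
        t = pe.simulate_tree(10, seed=2)
        _, h = pe.simulate_mk2(t, 0.3, 0.3, seed=1)
        vals = pe.simulate_bm_regimes(t, h, {0: 0.0, 1: 0.0},
                                      root_value=1.7, seed=0)
        assert (vals == 1.7).all()

    def test_tip_variance_matches_depth(self):
        t = pe.simulate_tree(6, seed=11)
        painting = pe.paint_by_clades(t, {l: "all" for l in t.tip_labels},
                                      background="all")
        draws = np.array([
            pe.simulate_bm_regimes(t, painting, {"all": 1.0}, seed=s).values
            for s in range(2500)])
        depths = t.node_depths()[: t.n_tips]
        np.testing.assert_allclose(draws.var(axis=0), depths, rtol=0.15)

    def test_sister_covariance_matches_shared_path(self):
        t = pe.parse_trees("((A:1,B:1):0.7,C:1.7);")[0]
        painting = pe.paint_by_clades(t, {l: "g" for l in "ABC"},
                                      background="g")
        draws = np.array([
            pe.simulate_bm_regimes(t, painting, {"g": 1.0}, seed=s).values
            for s in range(3000)])
        i, j = t.tip_index("A"), t.tip_index("B")
        cov = np.cov(draws[:, i], draws[:, j])[0, 1]
        assert cov == pytest.approx(0.7, abs=0.1)

    def test_unpainted_regime_errors(self):
        t = pe.simulate_tree(5, seed=0)
        _, h = pe.simulate_mk2(t, 0.5, 0.5, seed=1)
        with pytest.raises(ValueError, match="no rate"):
            pe.simulate_bm_regimes(t, h, {0: 1.0}, seed=0)


class TestSimulateLandmarks:
    def _units(self):
        return pd.DataFrame([
            {"species": "a", "morph": "monomorphic", "group": "G1"},
            {"species": "b", "morph": "monomorphic", "group": "G2"},
        ])

    def test_noise_free_specimens_congruent_to_template(self):
        units = self._units().iloc[:1]
        out = pe.simulate_landmarks(units, n_specimens=3, noise_sd=0.0,
                                    species_scatter_sd=0.0,
                                    size_lognormal=(0.0, 0.0), seed=1)
        for cfg in out:
            d = pe.procrustes_distance(cfg.coords, pe.DEFAULT_TEMPLATE)
            assert d < 1e-9

    def test_groups_separable_in_shape_space(self):
        # distinct group deformations must separate on PC1 of form space
        units = pd.concat([self._units()] * 10, ignore_index=True)
        units["species"] = [f"sp{i}" for i in range(len(units))]
        bend = np.zeros_like(pe.DEFAULT_TEMPLATE)
        bend[:, 0] = (pe.DEFAULT_TEMPLATE[:, 1] - 0.5) * 0.4
        out = pe.simulate_landmarks(
            units, group_deformations={"G2": bend}, n_specimens=4,
            noise_sd=0.01, species_scatter_sd=0.01, seed=2)
        means = pe.species_average(out)
        shape = pe.gpa(means)
        res = pe.pca(pe.form_space(shape))
        groups = units.set_index("species")["group"]
        pc1 = res.scores["PC1"]
        g1 = pc1[[u for u in pc1.index if groups[u] == "G1"]]
        g2 = pc1[[u for u in pc1.index if groups[u] == "G2"]]
        assert min(g2.min() - g1.max(), g1.min() - g2.max()) > 0 or \
            abs(g1.mean() - g2.mean()) > 3 * max(g1.std(), g2.std())

    def test_reproducible(self):
        out1 = pe.simulate_landmarks(self._units(), seed=5)
        out2 = pe.simulate_landmarks(self._units(), seed=5)
        for a, b in zip(out1, out2):
            np.testing.assert_array_equal(a.coords, b.coords)

    def test_degenerate_template_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pe.simulate_landmarks(self._units(),
                                  template=np.zeros((11, 2)), seed=0)


class TestThresholdPair:
    def test_perfect_correlation_gives_linear_liabilities(self):
        t = pe.simulate_tree(25, seed=8)
        _, _, liab = pe.simulate_threshold_pair(t, rho=1.0, seed=1)
        c = np.corrcoef(liab["liability1"], liab["liability2"])[0, 1]
        assert c == pytest.approx(1.0, abs=1e-9)

    def test_zero_correlation_centred_on_zero(self):
        t = pe.simulate_tree(20, seed=9)
        cors = []
        for s in range(300):
            _, _, liab = pe.simulate_threshold_pair(t, rho=0.0, seed=s)
            cors.append(np.corrcoef(liab["liability1"],
                                    liab["liability2"])[0, 1])
        assert np.mean(cors) == pytest.approx(0.0, abs=0.1)

    def test_ordinal_range_and_cut_validation(self):
        t = pe.simulate_tree(30, seed=10)
        _, ordinal, _ = pe.simulate_threshold_pair(t, rho=0.5, seed=3)
        assert ordinal.between(0, 9).all()
        with pytest.raises(ValueError, match="increasing"):
            pe.simulate_threshold_pair(t, rho=0.5, ordinal_cuts=[1, 1, 2],
                                       seed=0)


class TestInduction:
    def test_extreme_probabilities(self):
        tab = pe.simulate_induction(1.0, 0.0, n_per_plate=50, seed=1)
        pooled = pe.pool_replicates(tab)
        assert pooled.loc["treatment", "Eu"] == 150
        assert pooled.loc["control", "Eu"] == 0

    def test_reproducible(self):
        t1 = pe.simulate_induction(0.4, 0.1, seed=3)
        t2 = pe.simulate_induction(0.4, 0.1, seed=3)
        pd.testing.assert_frame_equal(t1, t2)

    def test_plate_size_bound(self):
        with pytest.raises(ValueError):
            pe.simulate_induction(0.5, 0.5, n_per_plate=300, seed=0)


class TestReferenceDataset:
    def test_shape_matches_study_design(self, ref_dataset):
        ds = ref_dataset
        assert ds.tree.n_tips == 90
        assert ds.history.transition_counts() == (1, 10)
        counts = ds.groups3.value_counts()
        assert counts["Rh"] == 36
        assert counts["Dm"] + counts["Mn"] == 54
        assert counts["Dm"] >= ds.config.min_group_tips
        lo, hi = ds.config.mn_tips_range
        assert lo <= counts["Mn"] <= hi

    def test_deterministic_regeneration(self, ref_dataset):
        again = pe.reference_dataset(seed=1)
        assert again.tree.to_newick() == ref_dataset.tree.to_newick()
        pd.testing.assert_series_equal(again.trait, ref_dataset.trait)
        np.testing.assert_array_equal(again.landmarks[0].coords,
                                      ref_dataset.landmarks[0].coords)

    def test_downstream_validators_accept_it(self, ref_dataset):
        from plastevol.pipeline import validate_inputs
        ds = ref_dataset
        assert validate_inputs(ds).empty
        ds.history.validate()
        ds.painting.validate()
        assert set(ds.structure_matrix.index) == set(ds.tree.tip_labels)

    def test_dimorphism_structure(self, ref_dataset):
        ds = ref_dataset
        # single gain on the radiation stem, all outgroup tips state 0
        assert (ds.tip_states[ds.groups2 == "Rh"] == 0).all()
        assert (ds.groups3[ds.tip_states == 1] == "Dm").all()
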