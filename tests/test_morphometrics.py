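import io

import numpy as np
import pandas as pd
import pytest

import plastevol as pe
from plastevol.morphometrics import TPSError, _normalize, _optimal_rotation

UNIT_SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


def random_config(rng, k=11):
    return rng.normal(size=(k, 2))


def similarity_transform(rng, coords):
    angle = rng.uniform(0, 2 * np.pi)
    rot = np.array([[np.cos(angle), -np.sin(angle)],
                    [np.sin(angle), np.cos(angle)]])
    scale = rng.lognormal(sigma=0.5)
    shift = rng.normal(size=2) * 3
    return coords @ rot.T * scale + shift


class TestCentroidSize:
    def test_unit_square(self):
        assert pe.centroid_size(UNIT_SQUARE) == pytest.approx(np.sqrt(2))

    def test_homogeneity_and_rigid_invariance(self, rng):
        c = random_config(rng)
        assert pe.centroid_size(2 * c) == pytest.approx(
            2 * pe.centroid_size(c))
        angle = 0.3
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        assert pe.centroid_size(c @ rot.T + 5.0) == pytest.approx(
            pe.centroid_size(c))

    def test_matches_per_landmark_summation_oracle(self, rng):
        c = random_config(rng)
        centroid = c.mean(axis=0)
        oracle = np.sqrt(sum(((p - centroid) ** 2).sum() for p in c))
        assert pe.centroid_size(c) == pytest.approx(oracle, rel=1e-12)

    def test_degenerate_configuration_rejected(self):
        with pytest.raises(ValueError):
            pe.centroid_size(np.ones((11, 2)))


TPS_TEXT = """LM=11
0.0 0.0
1.0 0.1
2.0 0.2
3.0 0.3
4.0 0.4
5.0 0.5
6.0 0.6
7.0 0.7
8.0 0.8
9.0 0.9
10.0 1.0
IMAGE=img1.jpg
ID=sp1__St__1
SCALE=0.5
"""


class TestTPS:
    def test_parse_record_with_scale(self):
        configs = pe.read_tps(io.StringIO(TPS_TEXT))
        assert len(configs) == 1
        c = configs[0]
        assert c.coords.shape == (11, 2)
        assert c.coords[10, 0] == pytest.approx(5.0)  # SCALE applied
        assert c.species == "sp1" and c.morph == "St"

    def test_wrong_landmark_count_rejected(self):
        bad = TPS_TEXT.replace("LM=11", "LM=10")
        with pytest.raises(TPSError, match="LM=10"):
            pe.read_tps(io.StringIO(bad))

    def test_write_read_roundtrip(self, tmp_path, ref_dataset):
        path = tmp_path / "out.tps"
        subset = ref_dataset.landmarks[:20]
        pe.write_tps(subset, path)
        back = pe.read_tps(path)
        assert len(back) == 20
        for a, b in zip(subset, back):
            np.testing.assert_allclose(a.coords, b.coords, rtol=1e-9)
            assert a.specimen_id == b.specimen_id

    def test_record_count_preserved(self, ref_dataset, tmp_path):
        path = tmp_path / "all.tps"
        pe.write_tps(ref_dataset.landmarks, path)
        assert len(pe.read_tps(path)) == len(ref_dataset.landmarks)


class TestGPA:
    def test_similarity_copies_align_exactly(self, rng):
        base = random_config(rng)
        copy = similarity_transform(rng, base)
        out = pe.gpa(np.stack([base, copy]))
        np.testing.assert_allclose(out.aligned[0], out.aligned[1], atol=1e-9)
        assert pe.procrustes_distance(base, copy) < 1e-9

    def test_rotated_copy_machine_precision(self, rng):
        base = random_config(rng)
        angle = np.pi / 6
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        out = pe.gpa(np.stack([base, base @ rot.T]))
        np.testing.assert_allclose(out.aligned[0], out.aligned[1], atol=1e-12)

    def test_output_invariant_to_input_transforms(self, rng):
        configs = [random_config(rng) for _ in range(4)]
        ref = pe.gpa(np.stack(configs))
        jittered = [similarity_transform(rng, c) for c in configs]
        out = pe.gpa(np.stack(jittered))
        # aligned shapes agree up to a common rotation; compare via
        # Procrustes distances to the consensus
        for a, b in zip(ref.aligned, out.aligned):
            assert pe.procrustes_distance(a, b) < 1e-7

    def test_consensus_is_centred_with_unit_size(self, rng):
        configs = np.stack([random_config(rng) for _ in range(5)])
        out = pe.gpa(configs)
        np.testing.assert_allclose(out.consensus.mean(axis=0), 0, atol=1e-12)
        assert pe.centroid_size(out.consensus) == pytest.approx(1.0)

    def test_two_config_residual_matches_closed_form(self, rng):
        # partial Procrustes: d^2 = 2 - 2 * sum of (sign-corrected)
        # singular values of X'Y for unit-size centred X, Y
        x, y = _normalize(random_config(rng)), _normalize(random_config(rng))
        s = np.linalg.svd(x.T @ y, compute_uv=False)
        if np.linalg.det(x.T @ y) < 0:
            s[-1] = -s[-1]
        closed = np.sqrt(max(2.0 - 2.0 * s.sum(), 0.0))
        assert pe.procrustes_distance(x, y) == pytest.approx(closed, rel=1e-9)

    def test_rejects_mismatched_landmark_counts(self, rng):
        with pytest.raises(ValueError):
            pe.gpa([pe.LandmarkConfig("a", random_config(rng)),
                    pe.LandmarkConfig("b", random_config(rng, k=5))])


class TestSpeciesAverage:
    def test_single_specimen_unit_is_itself(self, rng):
        c = pe.LandmarkConfig("s1", random_config(rng), species="sp",
                              morph="monomorphic")
        out = pe.species_average([c])
        assert len(out) == 1
        assert pe.procrustes_distance(out[0].coords, c.coords) < 1e-9

    def test_mirrored_pair_averages_to_midpoint(self):
        base = _normalize(np.array(
            [[0, 0], [1, 0], [2, 0.5], [1, 1], [0, 1], [0.5, 0.5],
             [1.5, 0.2], [0.2, 0.8], [1.8, 0.8], [0.9, 0.3], [1.1, 0.7]]))
        delta = np.zeros_like(base)
        delta[0] = [0.05, -0.02]
        a = pe.LandmarkConfig("a", base + delta, species="sp")
        b = pe.LandmarkConfig("b", base - delta, species="sp")
        out = pe.species_average([a, b])
        assert pe.procrustes_distance(out[0].coords, base) < 5e-3

    def test_dimorphic_species_yield_two_units(self, rng):
        configs = [
            pe.LandmarkConfig("1", random_config(rng), species="sp",
                              morph="St"),
            pe.LandmarkConfig("2", random_config(rng), species="sp",
                              morph="Eu"),
        ]
        units = {u.specimen_id for u in pe.species_average(configs)}
        assert units == {"sp_St", "sp_Eu"}

    def test_mean_centroid_size_carried(self, rng):
        c1 = random_config(rng)
        configs = [pe.LandmarkConfig("1", c1, species="sp"),
                   pe.LandmarkConfig("2", 3 * c1, species="sp")]
        out = pe.species_average(configs)
        assert out[0].centroid_size == pytest.approx(
            2 * pe.centroid_size(c1))


class TestFormSpace:
    def _shape(self, rng, n=4):
        configs = np.stack([random_config(rng) for _ in range(n)])
        return pe.gpa(configs)

    def test_log_size_column(self, rng):
        shape = self._shape(rng, 2)
        sizes = pd.Series({"config1": np.e, "config2": 1.0})
        form = pe.form_space(shape, sizes)
        assert form.shape[1] == 23
        assert form.loc["config1", "logCS"] == pytest.approx(1.0)
        assert form.loc["config2", "logCS"] == pytest.approx(0.0)

    def test_shape_only_matrix(self, rng):
        assert pe.form_space(self._shape(rng)).shape[1] == 22

    def test_nonpositive_size_rejected(self, rng):
        shape = self._shape(rng, 2)
        with pytest.raises(ValueError):
            pe.form_space(shape, pd.Series({"config1": -1.0, "config2": 1.0}))


class TestPCA:
    def test_collinear_points_load_on_one_axis(self):
        X = pd.DataFrame({"a": [0, 1, 2, 3.0], "b": [0, 2, 4, 6.0]})
        res = pe.pca(X)
        assert res.proportions[0] == pytest.approx(1.0)

    def test_eigenvalues_conserve_total_variance(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 6)))
        res = pe.pca(X)
        assert res.eigenvalues.sum() == pytest.approx(
            X.var(ddof=1).sum(), rel=1e-10)
        assert res.proportions.sum() == pytest.approx(1.0)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()

    def test_scores_reconstruct_centered_data(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 4)))
        res = pe.pca(X)
        centered = X - X.mean()
        np.testing.assert_allclose(
            res.scores.to_numpy() @ res.loadings.to_numpy().T,
            centered.to_numpy(), atol=1e-10)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            pe.pca(pd.DataFrame(np.ones((5, 3))))

    def test_size_dominates_pc1_when_size_varies_most(self, ref_dataset):
        units = pe.species_average(ref_dataset.landmarks)
        shape = pe.gpa(units)
        sizes = pd.Series({u.specimen_id: u.centroid_size for u in units})
        res = pe.pca(pe.form_space(shape, sizes))
        logcs = res.loadings.loc["logCS", "PC1"]
        assert abs(logcs) >= res.loadings["PC1"].abs().drop("logCS").max()


class TestPhyloPCA:
    def test_star_tree_equals_standard_pca(self, rng):
        n = 8
        newick = "(" + ",".join(f"t{i}:1" for i in range(n)) + ");"
        tree = pe.parse_trees(newick)[0]
        X = pd.DataFrame(rng.normal(size=(n, 3)),
                         index=[f"t{i}" for i in range(n)])
        std = pe.pca(X)
        phy = pe.phylo_pca(X, tree)
        for k in range(3):
            a = std.scores.iloc[:, k].to_numpy()
            b = phy.scores.loc[std.scores.index].iloc[:, k].to_numpy()
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8
        np.testing.assert_allclose(std.proportions, phy.proportions,
                                   rtol=1e-8)

    def test_two_tip_tree_hand_calculation(self):
        tree = pe.parse_trees("(A:2,B:1);")[0]
        X = pd.DataFrame({"x": [3.0, -1.0]}, index=["A", "B"])
        # GLS mean under C = diag(2,1): a = (x_A/2 + x_B) / (1/2 + 1)
        a = (3.0 / 2 + (-1.0)) / (1.5)
        res = pe.phylo_pca(X, tree)
        d = X["x"] - a
        assert abs(res.scores.loc["A", "PC1"] - res.scores.loc["B", "PC1"]
                   ) == pytest.approx(abs(d["A"] - d["B"]))

    def test_row_tip_mismatch_reported(self, rng):
        tree = pe.parse_trees("(A:1,(B:1,C:1):1);")[0]
        X = pd.DataFrame(rng.normal(size=(3, 2)), index=["A", "B", "X"])
        with pytest.raises(ValueError, match="X"):
            pe.phylo_pca(X, tree)

    def test_pc1_carries_most_evolutionary_variance(self, ref_dataset):
        # on the study-shaped preset, phylogenetic form-PC1 dominates,
        # which is what justifies using PC1 alone for rate inference
        ds = ref_dataset
        units = pe.species_average(ds.landmarks)
        keep = {u.species: u for u in units if u.morph != "Eu"}
        shape = pe.gpa(list(keep.values()))
        sizes = pd.Series({u.specimen_id: u.centroid_size
                           for u in keep.values()})
        form = pe.form_space(shape, sizes)
        form.index = list(keep.keys())
        res = pe.phylo_pca(form, ds.tree)
        assert res.proportions[0] >= 0.5
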