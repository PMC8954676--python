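"""Scoring network: builds, closed-form forwards, ensemble, training, screen."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from voxscreen.posegrid import GridSpec, VoxelGrid
from voxscreen.reference import shape_chain_reference
from voxscreen.scorer import (
    BuildError, EnsembleParams, LayerSpec, TrainConfig, TrainingDivergedError,
    build_model, default_architecture, ensemble_score, load_model, mse,
    predict_pose, save_model, screen, small_architecture, train,
)
from voxscreen.sitefinder import flood_site


def random_grids(n, grid_n=8, density=0.05, seed=0):
    rng = np.random.default_rng(seed)
    spec = GridSpec(n=grid_n)
    return [VoxelGrid((rng.random((14, grid_n, grid_n, grid_n)) < density
                       ).astype(np.uint8), spec, np.zeros(3))
            for _ in range(n)]


class TestBuildModel:
    def test_default_architecture_shape_chain(self):
        m = build_model(default_architecture(), GridSpec(n=30), rng_seed=0)
        ref = shape_chain_reference(30)
        assert m.flat_features == ref["flat_features"] == 1728

    def test_kernel_exceeding_extent(self):
        layers = [LayerSpec("conv3d", filters=4, kernel=3),
                  LayerSpec("flatten"),
                  LayerSpec("dense", filters=1, activation="linear")]
        spec = GridSpec(n=8)
        # 8 -> 6 is fine; shrink the grid below the kernel via pooling
        bad = [LayerSpec("conv3d", filters=4, kernel=3),
               LayerSpec("maxpool"), LayerSpec("maxpool"),
               LayerSpec("conv3d", filters=4, kernel=3)]
        with pytest.raises(BuildError, match="layer 3"):
            build_model(bad, spec, rng_seed=0)
        build_model(layers, spec, rng_seed=0)  # must not raise

    def test_same_seed_identical_parameters(self):
        a = build_model(small_architecture(), GridSpec(n=16), rng_seed=5)
        b = build_model(small_architecture(), GridSpec(n=16), rng_seed=5)
        for pa, pb in zip(a.parameters, b.parameters):
            np.testing.assert_array_equal(pa, pb)

    def test_non_scalar_output_rejected(self):
        layers = [LayerSpec("flatten"),
                  LayerSpec("dense", filters=3, activation="linear")]
        with pytest.raises(BuildError):
            build_model(layers, GridSpec(n=8), rng_seed=0)

    def test_invalid_layer_spec(self):
        with pytest.raises(ValueError):
            LayerSpec("conv3d", filters=8, kernel=5)
        with pytest.raises(ValueError):
            LayerSpec("warp")


class TestPredictPose:
    def test_zero_grid_finite(self):
        m = build_model(small_architecture(), GridSpec(n=16), rng_seed=0)
        g = VoxelGrid(np.zeros((14, 16, 16, 16), dtype=np.uint8),
                      GridSpec(n=16), np.zeros(3))
        assert np.isfinite(predict_pose(m, g))

    def test_identical_grids_identical_scores(self):
        m = build_model(small_architecture(), GridSpec(n=16), rng_seed=0)
        g1, = random_grids(1, grid_n=16, seed=1)
        g2 = VoxelGrid(g1.values.copy(), g1.spec, g1.origin)
        assert predict_pose(m, g1) == predict_pose(m, g2)

    def test_shape_mismatch(self):
        m = build_model(small_architecture(), GridSpec(n=16), rng_seed=0)
        g, = random_grids(1, grid_n=8)
        with pytest.raises(ValueError):
            predict_pose(m, g)

    def test_linear_micro_model_closed_form(self):
        """A flatten+linear model is an affine map with hand-checkable value."""
        m = build_model([LayerSpec("flatten"),
                         LayerSpec("dense", filters=1, activation="linear")],
                        GridSpec(n=8), rng_seed=0)
        dense = m.layers[-1]
        g, = random_grids(1, grid_n=8, density=0.1, seed=2)
        x = g.values.astype(np.float32).ravel()
        expected = float(x @ dense.W[:, 0] + dense.b[0])
        assert predict_pose(m, g) == pytest.approx(expected, rel=1e-6)


class TestEnsembleScore:
    def test_fixed_point(self):
        for beta in (0.0, 1.0, 17.0):
            assert ensemble_score([2, 2, 2], EnsembleParams(beta)) == 2

    def test_beta_zero_is_mean(self):
        assert ensemble_score([1, 3], EnsembleParams(0.0)) == \
            pytest.approx(2.0, abs=1e-12)

    def test_large_beta_is_max(self):
        assert ensemble_score([1, 3], EnsembleParams(50.0)) == \
            pytest.approx(3.0, abs=1e-9)

    def test_overflow_safety(self):
        s = ensemble_score([1000.0, 1001.0], EnsembleParams(1.0))
        assert np.isfinite(s) and 1000.0 <= s <= 1001.0

    def test_empty_input(self):
        with pytest.raises(ValueError):
            ensemble_score([], EnsembleParams())

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=8),
           st.floats(0, 20))
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_beta0_mean(self, scores, beta):
        val = ensemble_score(scores, EnsembleParams(beta))
        assert min(scores) - 1e-9 <= val <= max(scores) + 1e-9
        assert ensemble_score(scores, EnsembleParams(0.0)) == \
            pytest.approx(np.mean(scores), abs=1e-12)

    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=6),
           st.floats(0.1, 5), st.floats(0.01, 2))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_maximal_score(self, scores, beta, bump):
        # the softmax-weighted mean is not monotone in an arbitrary input
        # (raising a far-below-average score can lower the average), but it
        # is monotone in the maximal score and shift-equivariant
        idx = int(np.argmax(scores))
        bumped = list(scores)
        bumped[idx] += bump
        p = EnsembleParams(beta)
        assert ensemble_score(bumped, p) >= ensemble_score(scores, p) - 1e-9

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=6),
           st.floats(0.1, 5), st.floats(-3, 3))
    @settings(max_examples=100, deadline=None)
    def test_shift_equivariance(self, scores, beta, shift):
        p = EnsembleParams(beta)
        shifted = [s + shift for s in scores]
        assert ensemble_score(shifted, p) == \
            pytest.approx(ensemble_score(scores, p) + shift, abs=1e-9)


class TestTrain:
    def test_zero_learning_rate_keeps_parameters(self):
        grids = random_grids(6, grid_n=8, seed=3)
        data = [(g, float(k)) for k, g in enumerate(grids)]
        m = build_model([LayerSpec("flatten"),
                         LayerSpec("dense", filters=1, activation="linear")],
                        GridSpec(n=8), rng_seed=0)
        before = [p.copy() for p in m.parameters]
        m, hist = train(m, data, TrainConfig(batch_size=3, learning_rate=0.0,
                                             epochs=4, rng_seed=0))
        for a, b in zip(before, m.parameters):
            np.testing.assert_array_equal(a, b)
        # history constant up to batch-partition rounding (float32 sums)
        assert max(hist) - min(hist) < 1e-5

    def test_same_seed_identical_history(self):
        grids = random_grids(8, grid_n=8, seed=4)
        data = [(g, float(k % 3)) for k, g in enumerate(grids)]

        def run():
            m = build_model([LayerSpec("flatten"),
                             LayerSpec("dense", filters=4),
                             LayerSpec("dense", filters=1,
                                       activation="linear")],
                            GridSpec(n=8), rng_seed=1)
            return train(m, data, TrainConfig(batch_size=4, epochs=5,
                                              rng_seed=2))[1]

        assert run() == run()

    def test_divergence_raises(self):
        grids = random_grids(4, grid_n=8, seed=5)
        data = [(g, 1e30) for g in grids]  # squared error overflows float32
        m = build_model([LayerSpec("flatten"),
                         LayerSpec("dense", filters=1, activation="linear")],
                        GridSpec(n=8), rng_seed=0)
        with pytest.raises(TrainingDivergedError):
            train(m, data, TrainConfig(batch_size=4, epochs=3, rng_seed=0))

    def test_memorizes_small_set(self):
        """Capacity sanity at reduced width: 8 examples to near-zero MSE."""
        grids = random_grids(8, grid_n=16, density=0.03, seed=6)
        labels = np.random.default_rng(7).uniform(0, 8, size=8)
        data = list(zip(grids, labels))
        m = build_model(small_architecture(), GridSpec(n=16), rng_seed=0)
        m, _ = train(m, data, TrainConfig(batch_size=8, learning_rate=1e-2,
                                          epochs=120, rng_seed=0))
        assert mse(m, data) < 0.01


class TestScreen:
    @pytest.fixture(scope="class")
    def setup(self, big_pocket):
        struct, seed = big_pocket
        site = flood_site(struct, seed)
        m = build_model(small_architecture(), GridSpec(n=16), rng_seed=0)
        return m, struct, site

    def test_library_of_one(self, setup, small_ligands):
        m, struct, site = setup
        res = screen(m, small_ligands[:1], struct, site, n_poses=2,
                     grid_spec=GridSpec(n=16), rng_seed=0)
        assert len(res) == 1 and res[0].rank == 1

    def test_identical_compounds_tie_broken_by_id(self, setup, small_ligands):
        m, struct, site = setup
        lig = small_ligands[0]
        from voxscreen.chemio import MolGraph
        twin = MolGraph("zz-twin", "", list(lig.atoms), list(lig.bonds),
                        coords=lig.coords.copy())
        other = MolGraph("aa-twin", "", list(lig.atoms), list(lig.bonds),
                         coords=lig.coords.copy())
        res = screen(m, [twin, other], struct, site, n_poses=2,
                     grid_spec=GridSpec(n=16), rng_seed=0)
        assert res[0].score == res[1].score  # identical content, same stream
        assert [r.compound_id for r in res] == ["aa-twin", "zz-twin"]

    def test_bitwise_determinism(self, setup, small_ligands):
        m, struct, site = setup
        a = screen(m, small_ligands[:3], struct, site, n_poses=2,
                   grid_spec=GridSpec(n=16), rng_seed=4)
        b = screen(m, small_ligands[:3], struct, site, n_poses=2,
                   grid_spec=GridSpec(n=16), rng_seed=4)
        assert [(r.rank, r.compound_id, r.score) for r in a] == \
            [(r.rank, r.compound_id, r.score) for r in b]


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path):
        m = build_model(small_architecture(), GridSpec(n=16), rng_seed=3)
        path = tmp_path / "model.npz"
        save_model(m, path)
        back = load_model(path)
        g, = random_grids(1, grid_n=16, seed=8)
        assert predict_pose(m, g) == predict_pose(back, g)
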