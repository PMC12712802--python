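"""Forward operator and MAP reconstruction: consistency, convergence,
round-trip recovery and dynamic-range resolvability."""

import numpy as np
import pytest

from mpimet import (
    MAPModel,
    ScannerConfig,
    UNRESOLVABLE,
    build_operator,
    make_point_sources,
    min_resolvable_separation,
    reconstruct_baseline,
    reconstruct_map,
    resolvability,
    simulate_projection,
    simulate_scan,
)


class TestForwardOperator:
    def test_shape_contract(self, small_operator, small_config):
        n_rows = (len(small_config.angles) * len(small_config.harmonics)
                  * small_config.n_samples)
        assert small_operator.shape == (n_rows, 33 * 33)

    def test_one_hot_matches_simulator(self, tracer, small_config, small_operator):
        """Operator columns reproduce simulate_projection of point voxels."""
        rng = np.random.default_rng(0)
        for i in rng.integers(0, small_operator.n_voxels, 5):
            x = np.zeros(small_operator.n_voxels)
            x[i] = 1.0
            via_op = small_operator.apply(x).reshape(small_operator.signal_shape)
            img = x.reshape(small_operator.image_shape)
            for a, angle in enumerate(small_config.angles):
                sim = simulate_projection(img, tracer, small_config, angle)
                scale = max(np.abs(sim).max(), 1e-300)
                assert np.abs(via_op[a] - sim).max() / scale < 1e-6

    def test_adjoint_dot_product(self, small_operator, rng):
        for _ in range(5):
            x = rng.standard_normal(small_operator.n_voxels)
            y = rng.standard_normal(small_operator.n_rows)
            lhs = small_operator.apply(x) @ y
            rhs = x @ small_operator.adjoint(y)
            assert abs(lhs - rhs) <= 1e-8 * max(abs(lhs), abs(rhs), 1e-300)

    def test_matrix_free_matches_explicit(self, tracer, small_config,
                                          small_operator, rng):
        mf = build_operator(tracer, small_config, mode="matrix-free")
        x = rng.standard_normal(mf.n_voxels)
        y = rng.standard_normal(mf.n_rows)
        assert np.allclose(mf.apply(x), small_operator.apply(x), atol=1e-10)
        assert np.allclose(mf.adjoint(y), small_operator.adjoint(y), atol=1e-10)

    def test_oversized_grid_requires_matrix_free(self, tracer):
        cfg = ScannerConfig(fov=(60.0, 60.0), grid=(241, 241), angles=(0.0,))
        with pytest.raises(ValueError, match="matrix-free"):
            build_operator(tracer, cfg)
        assert build_operator(tracer, cfg, mode="matrix-free").n_voxels == 58081


class TestMAPReconstruction:
    def test_point_source_round_trip(self, tracer, small_config, small_operator):
        ph = make_point_sources([(2.5, -3.0)], [10.0], small_config)
        sig = simulate_scan(ph, tracer, small_config)
        res = reconstruct_map(sig, small_operator)
        true_idx = np.unravel_index(np.argmax(ph.concentration), ph.shape)
        rec_idx = np.unravel_index(np.argmax(res.image), res.image.shape)
        assert abs(rec_idx[0] - true_idx[0]) <= 1
        assert abs(rec_idx[1] - true_idx[1]) <= 1

    def test_zero_signal_zero_image(self, small_operator):
        res = MAPModel(np.zeros(small_operator.n_rows), small_operator).fit(50)
        assert not res.image.any()

    def test_objective_monotone_nonincreasing(self, tracer, small_config,
                                              small_operator):
        ph = make_point_sources([(0.0, 0.0), (4.0, 2.0)], [5.0, 2.0], small_config)
        sig = simulate_scan(ph, tracer, small_config, noise_sd=0.1, seed=7)
        res = reconstruct_map(sig, small_operator, n_iter=100)
        assert np.all(np.diff(res.objective_trace) <= 1e-9 * res.objective_trace[0])

    def test_final_residual_below_initial(self, tracer, small_config, small_operator):
        ph = make_point_sources([(1.0, 1.0)], [3.0], small_config)
        sig = simulate_scan(ph, tracer, small_config)
        res = reconstruct_map(sig, small_operator, n_iter=100)
        y = sig.ravel()
        final = np.linalg.norm(small_operator.apply(res.image) - y)
        assert final <= np.linalg.norm(y)

    def test_image_nonnegative(self, tracer, small_config, small_operator):
        ph = make_point_sources([(0.0, 0.0)], [1.0], small_config)
        sig = simulate_scan(ph, tracer, small_config, noise_sd=0.05, seed=3)
        res = reconstruct_map(sig, small_operator, n_iter=60)
        assert np.all(res.image >= 0)

    def test_mass_ratio_preserved(self, tracer, small_config, small_operator):
        """Noise-free signals from 1x and 8.5x phantoms reconstruct to an
        exactly scaled pair: total signal ratio 8.5 within 1%."""
        pos = [(2.0, 0.0)]
        lo = simulate_scan(make_point_sources(pos, [1.0], small_config),
                           tracer, small_config)
        hi = simulate_scan(make_point_sources(pos, [8.5], small_config),
                           tracer, small_config)
        r_lo = reconstruct_map(lo, small_operator, n_iter=100)
        r_hi = reconstruct_map(hi, small_operator, n_iter=100)
        assert r_hi.total_signal / r_lo.total_signal == pytest.approx(8.5, rel=0.01)

    def test_k_point_relative_mass_recovery(self, tracer):
        """Well-separated sources: peak positions within 1 voxel, local
        mass shares within 5%.

        Four angles (two leave a diagonal pair underdetermined — the classic
        limited-angle ghost) and a light prior (the quantification regime;
        the default ridge trades a small mass-share bias for stability).
        """
        cfg = ScannerConfig(fov=(16.5, 16.5), grid=(33, 33),
                            angles=(0.0, 45.0, 90.0, 135.0))
        op = build_operator(tracer, cfg)
        positions = [(-4.0, -4.0), (4.0, 4.0)]
        masses = [6.0, 3.0]
        ph = make_point_sources(positions, masses, cfg)
        sig = simulate_scan(ph, tracer, cfg)
        res = reconstruct_map(sig, op, n_iter=600,
                              prior_weight=1e-6 * op.norm_sq_estimate())
        nx, ny = cfg.grid
        dx, dy = cfg.spacing
        recovered = []
        for (px, py), mass in zip(positions, masses):
            col = int(round(px / dx + (nx - 1) / 2.0))
            row = int(round(py / dy + (ny - 1) / 2.0))
            window = res.image[row - 3:row + 4, col - 3:col + 4]
            pk = np.unravel_index(np.argmax(window), window.shape)
            assert abs(pk[0] - 3) <= 1 and abs(pk[1] - 3) <= 1
            recovered.append(window.sum())
        ratio = recovered[0] / recovered[1]
        assert ratio == pytest.approx(masses[0] / masses[1], rel=0.05)

    def test_negative_prior_weight_rejected(self, small_operator):
        with pytest.raises(ValueError):
            MAPModel(np.zeros(small_operator.n_rows), small_operator,
                     prior_weight=-1.0)

    def test_shape_mismatch_rejected(self, small_operator):
        with pytest.raises(ValueError, match="does not match"):
            MAPModel(np.zeros(small_operator.n_rows + 1), small_operator)

    def test_volume_signal_reconstructs_per_slice(self, tracer, small_config,
                                                  small_operator):
        from mpimet.phantoms import VoxelPhantom
        ph2d = make_point_sources([(2.0, 1.0)], [5.0], small_config)
        vol = np.stack([ph2d.concentration, np.zeros_like(ph2d.concentration)])
        ph3d = VoxelPhantom(vol, spacing=(1.0,) + ph2d.spacing)
        sig = simulate_scan(ph3d, tracer, small_config)
        res = reconstruct_map(sig, small_operator, n_iter=60)
        assert res.image.shape == vol.shape
        assert res.image[1].sum() == pytest.approx(0.0, abs=1e-12)
        assert res.image[0].sum() > 0


class TestBaseline:
    def test_point_source_blob_near_truth(self, tracer, small_config,
                                          small_operator):
        ph = make_point_sources([(2.0, -2.0)], [1.0], small_config)
        sig = simulate_scan(ph, tracer, small_config)
        img = reconstruct_baseline(sig, small_operator)
        true_idx = np.unravel_index(np.argmax(ph.concentration), ph.shape)
        rec_idx = np.unravel_index(np.argmax(np.abs(img)), img.shape)
        assert abs(rec_idx[0] - true_idx[0]) <= 1
        assert abs(rec_idx[1] - true_idx[1]) <= 1

    def test_zero_signal_zero_image(self, small_operator):
        img = reconstruct_baseline(np.zeros(small_operator.n_rows), small_operator)
        assert not img.any()

    def test_linear_in_signal(self, small_operator, rng):
        y = rng.standard_normal(small_operator.n_rows)
        a = small_operator.adjoint(y)
        b = small_operator.adjoint(2.0 * y)
        assert np.allclose(b, 2.0 * a, atol=1e-10)


class TestResolvability:
    def test_well_separated_equal_sources(self, tracer, small_config,
                                          small_operator):
        ph = make_point_sources([(-4.0, 0.0), (4.0, 0.0)], [5.0, 5.0],
                                small_config)
        sig = simulate_scan(ph, tracer, small_config)
        res = reconstruct_map(sig, small_operator)
        assert resolvability(res.image, (-4.0, 0.0), (4.0, 0.0), small_config)

    def test_single_source_second_query_false(self, tracer, small_config,
                                              small_operator):
        ph = make_point_sources([(0.0, 0.0)], [5.0], small_config)
        sig = simulate_scan(ph, tracer, small_config)
        res = reconstruct_map(sig, small_operator)
        assert not resolvability(res.image, (0.0, 0.0), (5.0, 0.0), small_config)

    def test_coincident_positions_rejected(self, small_config):
        img = np.zeros((33, 33))
        with pytest.raises(ValueError, match="coincide"):
            resolvability(img, (0.0, 0.0), (0.1, 0.1), small_config)

    def test_min_separation_monotone_in_ratio(self, tracer):
        cfg = ScannerConfig(fov=(24.5, 24.5), grid=(49, 49), angles=(0.0, 90.0))
        op = build_operator(tracer, cfg)
        s10 = min_resolvable_separation(10.0, tracer, cfg, step=0.5,
                                        n_iter=80, operator=op)
        s1000 = min_resolvable_separation(1000.0, tracer, cfg, step=0.5,
                                          n_iter=80, operator=op)
        s1 = min_resolvable_separation(1.0, tracer, cfg, step=0.5,
                                       n_iter=80, operator=op)
        assert s10 != UNRESOLVABLE
        assert s1 <= s1000
        assert s10 <= s1000

    def test_ratio_below_one_rejected(self, tracer, small_config):
        with pytest.raises(ValueError):
            min_resolvable_separation(0.5, tracer, small_config)
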