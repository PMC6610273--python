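import dataclasses
import warnings

import numpy as np
import pytest
from scipy import sparse

from tenoquant.image_model import GeometryError, Grid, VolumetricImage
from tenoquant.phantom import simulate_acquisition
from tenoquant.srr import (
    ForwardOperator,
    SRRConfig,
    axis_average_matrix,
    build_forward_operator,
    default_target_grid,
    laplacian,
    linear_upsample,
    nearest_upsample,
    objective,
    reconstruct,
)


class TestAxisAverageMatrix:
    def test_rows_sum_to_one(self):
        m = axis_average_matrix(50, 0.5, 0.25, 7, 3.3, 1.5, 3.0)
        np.testing.assert_allclose(np.asarray(m.sum(axis=1)).ravel(), 1.0)

    def test_gap_voxels_excluded(self):
        # window 3.0 at spacing 3.3 with 0.3 mm voxels: each inter-slice gap
        # is exactly one voxel cell, which must receive no weight at all
        m = axis_average_matrix(110, 0.3, 0.15, 10, 3.3, 1.5, 3.0)
        col_weight = np.asarray(m.sum(axis=0)).ravel()
        gap_cols = [10 + 11 * k for k in range(9)]
        np.testing.assert_allclose(col_weight[gap_cols], 0.0)
        np.testing.assert_allclose(m.toarray().sum(), 10.0)

    def test_degenerate_window_is_nearest_neighbor(self):
        m = axis_average_matrix(10, 1.0, 0.0, 5, 2.0, 0.0, 0.5)
        dense = m.toarray()
        assert np.all(dense.sum(axis=1) == 1)
        assert np.all((dense == 0) | (dense == 1))

    def test_matches_brute_force_overlap(self):
        n_in, sp_in, o_in = 30, 0.7, 0.35
        n_out, sp_out, o_out, w = 5, 3.3, 1.9, 3.0
        m = axis_average_matrix(n_in, sp_in, o_in, n_out, sp_out, o_out, w).toarray()
        ref = np.zeros((n_out, n_in))
        for j in range(n_out):
            c = o_out + j * sp_out
            for i in range(n_in):
                p = o_in + i * sp_in
                ov = min(p + sp_in / 2, c + w / 2) - max(p - sp_in / 2, c - w / 2)
                ref[j, i] = max(0.0, ov)
            ref[j] /= ref[j].sum()
        np.testing.assert_allclose(m, ref, atol=1e-12)


class TestForwardOperator:
    def _ops(self, clean_truth):
        ax = simulate_acquisition(clean_truth, "axial")
        co = simulate_acquisition(clean_truth, "coronal")
        grid = default_target_grid([ax, co], 0.8)
        return [build_forward_operator(s, grid) for s in [ax, co]], [ax, co], grid

    def test_adjoint_identity(self, clean_truth, rng):
        ops, scans, grid = self._ops(clean_truth)
        for op, s in zip(ops, scans):
            x = rng.normal(size=grid.shape)
            y = rng.normal(size=s.voxels.shape)
            lhs = float(np.sum(op(x) * y))
            rhs = float(np.sum(x * op.adjoint(y)))
            assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_constant_preserved(self, clean_truth):
        ops, _, grid = self._ops(clean_truth)
        for op in ops:
            np.testing.assert_allclose(op(np.full(grid.shape, 3.0)), 3.0, atol=1e-10)

    def test_disjoint_grids_rejected(self, clean_truth):
        ax = simulate_acquisition(clean_truth, "axial")
        far = Grid((4, 4, 4), (1, 1, 1), (500.0, 500.0, 500.0))
        with pytest.raises(GeometryError):
            build_forward_operator(ax, far)


class TestLaplacian:
    def test_symmetric(self, rng):
        x = rng.normal(size=(6, 5, 4))
        y = rng.normal(size=(6, 5, 4))
        assert float(np.sum(laplacian(x) * y)) == pytest.approx(
            float(np.sum(x * laplacian(y))), rel=1e-12)

    def test_annihilates_constants(self):
        np.testing.assert_allclose(laplacian(np.full((5, 5, 5), 7.0)), 0.0, atol=1e-12)

    def test_negative_semidefinite_quadratic_form(self, rng):
        # negative-Laplacian sign convention: x.Lx = -sum of squared
        # neighbor differences; only L^2 enters the regularizer
        for _ in range(5):
            x = rng.normal(size=(5, 6, 7))
            assert float(np.sum(x * laplacian(x))) <= 1e-10

    def test_matches_neighbor_count_formula(self, rng):
        x = rng.normal(size=(4, 4, 4))
        out = laplacian(x)
        # interior voxel: sum of neighbors - 6*x
        i, j, k = 2, 1, 2
        nb = (x[i - 1, j, k] + x[i + 1, j, k] + x[i, j - 1, k]
              + x[i, j + 1, k] + x[i, j, k - 1] + x[i, j, k + 1])
        assert out[i, j, k] == pytest.approx(nb - 6 * x[i, j, k], rel=1e-10)


@pytest.fixture(scope="module")
def scans(clean_truth):
    return (clean_truth,
            simulate_acquisition(clean_truth, "axial"),
            simulate_acquisition(clean_truth, "coronal"))


class TestReconstruct:
    def test_objective_monotone_nonincreasing(self, scans):
        _, ax, co = scans
        cfg = SRRConfig(target_spacing=0.8, max_iter=15, tol=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, info = reconstruct([ax, co], cfg, return_info=True)
        h = info["objective"]
        assert all(b <= a + 1e-8 * abs(a) for a, b in zip(h, h[1:]))

    def test_objective_below_any_upsampled_input(self, scans):
        # the solver must end at a lower objective than every warm start
        _, ax, co = scans
        cfg = SRRConfig(target_spacing=0.8, max_iter=60)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = reconstruct([ax, co], cfg)
        ops, _ = _ops_for(rec, [ax, co])
        final = objective(rec.voxels, ops, [ax, co], cfg.lambda_reg)
        for s in (ax, co):
            start = objective(linear_upsample(s, rec.grid).voxels,
                              ops, [ax, co], cfg.lambda_reg)
            assert final < start

    def test_beats_upsampling_of_worse_scan(self, scans):
        truth, ax, co = scans
        cfg = SRRConfig(target_spacing=0.8, max_iter=60)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = reconstruct([ax, co], cfg)
        ref = _resample_truth(truth, rec.grid)
        rmse = lambda v: float(np.sqrt(np.mean((v - ref) ** 2)))
        worst = max(rmse(linear_upsample(ax, rec.grid).voxels),
                    rmse(linear_upsample(co, rec.grid).voxels))
        assert rmse(rec.voxels) < worst

    def test_zero_lambda_recovers_data_consistent_solution(self, scans):
        _, ax, co = scans
        cfg = SRRConfig(lambda_reg=0.0, target_spacing=0.8, max_iter=80)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec, info = reconstruct([ax, co], cfg, return_info=True)
        # objective without regularization equals the data misfit
        assert info["objective"][-1] == pytest.approx(
            objective(rec.voxels, *_ops_for(rec, [ax, co]), 0.0))

    def test_empty_scan_list_rejected(self):
        with pytest.raises(ValueError):
            reconstruct([])

    def test_output_plane_tag(self, scans):
        _, ax, co = scans
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = reconstruct([ax, co], SRRConfig(target_spacing=1.2, max_iter=10))
        assert rec.plane == "isotropic-SRR"
        assert rec.spacing == (1.2, 1.2, 1.2)

    def test_constant_input_reconstructs_constant(self):
        vox_ax = np.full((20, 20, 6), 11.0)
        vox_co = np.full((20, 8, 20), 11.0)
        ax = VolumetricImage(vox_ax, (1.0, 1.0, 3.3), (0.5, 0.5, 1.5),
                             plane="axial", slice_thickness=3.0)
        co = VolumetricImage(vox_co, (1.0, 2.2, 1.0), (0.5, 1.0, 0.5),
                             plane="coronal", slice_thickness=2.0)
        rec = reconstruct([ax, co], SRRConfig(target_spacing=1.0, max_iter=200, tol=1e-10))
        np.testing.assert_allclose(rec.voxels, 11.0, atol=1e-5)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SRRConfig(lambda_reg=-0.1)
        with pytest.raises(ValueError):
            SRRConfig(target_spacing=0.0)


def _resample_truth(truth, grid):
    from tenoquant.srr import _resample_to

    return _resample_to(truth.image, grid, 1)


def _ops_for(rec, scans):
    ops = [build_forward_operator(s, rec.grid) for s in scans]
    return ops, scans


class TestUpsampling:
    def test_nearest_preserves_value_set(self, clean_truth):
        ax = simulate_acquisition(clean_truth, "axial")
        grid = default_target_grid([ax], 0.8)
        up = nearest_upsample(ax, grid)
        assert set(np.unique(up.voxels)) <= set(np.unique(ax.voxels))

    def test_linear_within_data_range(self, clean_truth):
        co = simulate_acquisition(clean_truth, "coronal")
        grid = default_target_grid([co], 0.8)
        up = linear_upsample(co, grid)
        assert up.voxels.min() >= co.voxels.min() - 1e-9
        assert up.voxels.max() <= co.voxels.max() + 1e-9

    def test_disjoint_scans_rejected(self, clean_truth):
        ax = simulate_acquisition(clean_truth, "axial")
        shifted = VolumetricImage(ax.voxels, ax.spacing,
                                  (ax.origin[0] + 1000, ax.origin[1], ax.origin[2]),
                                  plane="axial", slice_thickness=3.0)
        with pytest.raises(GeometryError):
            default_target_grid([ax, shifted], 0.8)
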