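import numpy as np
import pandas as pd
import pytest

from attractorscape import (BasinBoundary, DensityLandscape, attractor_boundary,
                            deviation_matrix, lln_fit, miv, point_in_basin, rv,
                            sample_ensembles, spd_landscape,
                            trajectory_for_genes, whole_transcriptome_trajectory)
from attractorscape.attractor_landscape import corrected_mi
from conftest import make_expr


def winding_number_inside(point, poly):
    """Winding-number point-in-polygon oracle (independent of ray casting)."""
    x, y = point
    wn = 0
    n = len(poly) - 1
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[i + 1]
        if y1 <= y:
            if y2 > y and (x2 - x1) * (y - y1) - (x - x1) * (y2 - y1) > 0:
                wn += 1
        elif y2 <= y and (x2 - x1) * (y - y1) - (x - x1) * (y2 - y1) < 0:
            wn -= 1
    return wn != 0


def gaussian_landscape(sigma=0.1, grid_size=121, extent=0.6):
    g = np.linspace(-extent, extent, grid_size)
    xx, yy = np.meshgrid(g, g, indexing="ij")
    z = np.exp(-(xx**2 + yy**2) / (2 * sigma**2))
    return DensityLandscape(rv_grid=g, miv_grid=g, z=z,
                            peaks=[(0.0, 0.0, 1.0)], bandwidths=[],
                            n_superimposed=1)


class TestDeviationAndRv:
    def test_constant_gene_row_is_zero(self):
        em = make_expr([[5, 5, 5], [2, 4, 6]], [0, 1, 2], ["a"])
        dm = deviation_matrix(em, "a")
        np.testing.assert_allclose(dm.values.loc["g0"], 0.0)
        np.testing.assert_allclose(dm.values.loc["g1"], [-2, 0, 2])

    def test_deviation_linearity(self):
        vals = np.random.default_rng(0).lognormal(1, 1, (20, 4))
        em1 = make_expr(vals, [0, 1, 2, 5], ["a"])
        em2 = make_expr(2 * vals, [0, 1, 2, 5], ["a"])
        d1 = deviation_matrix(em1, "a").values.to_numpy()
        d2 = deviation_matrix(em2, "a").values.to_numpy()
        np.testing.assert_allclose(d2, 2 * d1)

    def test_rv_self_orthogonal_antipodal(self):
        v = np.array([1.0, -2.0, 1.0])
        assert rv(v, v) == pytest.approx(1.0)
        assert rv(v, np.array([2.0, 1.0, 0.0])) == pytest.approx(0.0)
        assert rv(v, -v) == pytest.approx(-1.0)

    def test_rv_zero_norm_rejected(self):
        with pytest.raises(ZeroDivisionError):
            rv(np.zeros(3), np.ones(3))


class TestMiv:
    def test_scaled_copy_gives_one(self):
        rng = np.random.default_rng(2)
        v0 = rng.normal(size=500)
        assert miv(3 * v0, v0, rng=0) == pytest.approx(
            miv(v0, v0, rng=0), abs=1e-9)

    def test_shuffled_vector_near_zero(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            v0 = rng.normal(size=1000)
            vi = rng.permutation(v0)
            vals.append(miv(vi, v0, rng=seed))
        assert np.mean(vals) <= 0.05

    def test_zero_denominator_rejected(self):
        v0 = np.random.default_rng(3).normal(size=100)
        with pytest.raises(ZeroDivisionError):
            miv(v0, v0, denom=0.0)


class TestTrajectories:
    def test_trajectory_starts_at_unit_point(self, small_tpm):
        expr, _ = small_tpm
        traj = trajectory_for_genes(expr, expr.gene_ids[:50], seed=0)
        assert tuple(traj.points.iloc[0]) == (1.0, 1.0)

    def test_ensemble_rv_in_range_and_sd_shrinks_with_n(self, small_tpm):
        expr, _ = small_tpm
        e25 = sample_ensembles(expr, 25, repeats=40, seed=0, scale="log")
        e100 = sample_ensembles(expr, 100, repeats=40, seed=0, scale="log")
        assert np.all(e25.rv_samples >= -1) and np.all(e25.rv_samples <= 1)
        sd25 = e25.sds().drop(index=0.0)
        sd100 = e100.sds().drop(index=0.0)
        assert (sd100["rv"] < sd25["rv"]).all()

    def test_exhaustive_draw_has_zero_sd(self, small_tpm):
        expr, _ = small_tpm
        n = len(expr.gene_ids)
        ens = sample_ensembles(expr, n, repeats=5, seed=0)
        np.testing.assert_allclose(ens.rv_samples.std(axis=0), 0, atol=1e-12)

    def test_oversized_element_rejected(self, small_tpm):
        expr, _ = small_tpm
        with pytest.raises(ValueError):
            sample_ensembles(expr, len(expr.gene_ids) + 1)


class TestLlnFit:
    def test_noiseless_recovery(self):
        ns = [25, 50, 100, 200, 400]
        sds = {n: 2.0 / np.sqrt(n) + 0.1 for n in ns}
        alpha, c, rmse = lln_fit(sds)
        assert alpha == pytest.approx(2.0, abs=1e-9)
        assert c == pytest.approx(0.1, abs=1e-9)
        assert rmse == pytest.approx(0.0, abs=1e-12)

    def test_iid_means_have_zero_offset(self):
        rng = np.random.default_rng(5)
        sds = {}
        for n in (25, 50, 100, 200, 400, 800):
            means = rng.normal(size=(2000, n)).mean(axis=1)
            sds[n] = means.std()
        alpha, c, rmse = lln_fit(sds)
        assert abs(c) < 2 * 1.0 / np.sqrt(25) / np.sqrt(2000) * 3
        assert alpha == pytest.approx(1.0, rel=0.05)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            lln_fit({25: 0.1, 100: 0.05})


class TestLandscapeGeometry:
    def test_single_cloud_gives_one_peak(self):
        rng = np.random.default_rng(6)
        pts = rng.normal([0.5, 0.5], 0.02, size=(100, 2))
        from attractorscape import EnsembleDistribution
        ens = EnsembleDistribution(
            element_size=100, repeats=100, time_points=[0.0, 1.0],
            rv_samples=np.column_stack([pts[:, 0], pts[:, 0]]),
            miv_samples=np.column_stack([pts[:, 1], pts[:, 1]]))
        land = spd_landscape(ens)
        assert len(land.peaks) == 1
        assert land.major_peak[0] == pytest.approx(0.5, abs=0.02)

    def test_two_separated_clouds_give_two_peaks(self):
        rng = np.random.default_rng(7)
        a = rng.normal([0.0, 0.0], 0.02, size=(100, 2))
        b = rng.normal([1.0, 1.0], 0.02, size=(100, 2))
        from attractorscape import EnsembleDistribution
        ens = EnsembleDistribution(
            element_size=100, repeats=100, time_points=[0.0, 1.0],
            rv_samples=np.column_stack([a[:, 0], b[:, 0]]),
            miv_samples=np.column_stack([a[:, 1], b[:, 1]]))
        land = spd_landscape(ens)
        assert len(land.peaks) == 2

    def test_total_mass_matches_superimposed_count(self, small_tpm):
        expr, _ = small_tpm
        ens = sample_ensembles(expr, 50, repeats=50, seed=1)
        land = spd_landscape(ens)
        assert land.total_mass() == pytest.approx(land.n_superimposed,
                                                  rel=0.02)

    def test_gaussian_boundary_at_inflection_radius(self):
        land = gaussian_landscape(sigma=0.1)
        b = attractor_boundary(land)
        cell = land.rv_grid[1] - land.rv_grid[0]
        radii = np.linalg.norm(b.polyline, axis=1)
        assert np.all(np.abs(radii - 0.1) <= cell + 1e-9)

    def test_boundary_encloses_peak(self):
        land = gaussian_landscape()
        b = attractor_boundary(land)
        assert point_in_basin((0.0, 0.0), b)
        assert not point_in_basin((0.55, 0.55), b)

    def test_smaller_sigma_shrinks_enclosed_boundary(self):
        areas = []
        for sigma in (0.15, 0.1, 0.05):
            b = attractor_boundary(gaussian_landscape(sigma=sigma))
            x, y = b.polyline[:, 0], b.polyline[:, 1]
            areas.append(0.5 * abs(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1])))
        assert areas[0] > areas[1] > areas[2]

    def test_ray_casting_agrees_with_winding_oracle(self):
        b = attractor_boundary(gaussian_landscape())
        rng = np.random.default_rng(8)
        pts = rng.uniform(-0.6, 0.6, size=(1000, 2))
        for p in pts:
            assert point_in_basin(p, b) == winding_number_inside(p, b.polyline)

    def test_open_polyline_rejected(self):
        poly = np.array([[0, 0], [1, 0], [1, 1.0]])
        with pytest.raises(ValueError, match="not closed"):
            point_in_basin((0.5, 0.5), BasinBoundary(polyline=poly, level=0.5))


class TestReproducibility:
    def test_landscape_bit_identical_under_fixed_seed(self, small_tpm):
        expr, _ = small_tpm
        a = sample_ensembles(expr, 30, repeats=20, seed=11)
        b = sample_ensembles(expr, 30, repeats=20, seed=11)
        assert np.array_equal(a.rv_samples, b.rv_samples)
        assert np.array_equal(a.miv_samples, b.miv_samples)
        za = spd_landscape(a).z
        zb = spd_landscape(b).z
        assert np.array_equal(za, zb)
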