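"""Weighted KDE closed forms, Ripley's-K calibration, bandwidth selection,
and HMR arithmetic/monotonicity."""

import numpy as np
import pytest

import disparity as dp
from disparity.errors import ConfigError, InsufficientDataError, ValidationError
from disparity.hmr_kde import RipleyResult, band_raster, read_asc, write_asc


def grid_with_anchor_at_center(h, cell=None, half_cells=40):
    """Grid whose central cell center sits exactly at the origin."""
    cell = cell if cell is not None else h / 4
    n = 2 * half_cells + 1
    x0 = -(half_cells + 0.5) * cell
    return dp.RasterGrid(x0=x0, y0=x0, cell=cell, nx=n, ny=n), half_cells


class TestWeightedKde:
    def test_single_point_closed_form_at_anchor(self):
        h, w = 2.0, 3.0
        grid, mid = grid_with_anchor_at_center(h)
        surf = dp.weighted_kde(np.array([[0.0, 0.0]]), np.array([w]), h, grid)
        assert surf.values[mid, mid] == pytest.approx(w / (2 * np.pi * 1 * h * h))

    def test_zero_weights_zero_surface(self, rng):
        grid, _ = grid_with_anchor_at_center(1.0)
        pts = rng.uniform(-2, 2, size=(5, 2))
        surf = dp.weighted_kde(pts, np.zeros(5), 1.0, grid)
        assert np.all(surf.values == 0)

    def test_grid_mass(self, rng):
        """Integral equals (sum w)/n within 1% (margin 4h, cell <= h/4)."""
        h = 1.5
        pts = rng.uniform(-3, 3, size=(12, 2))
        wts = rng.uniform(0.5, 4.0, size=12)
        grid = dp.RasterGrid(x0=-3 - 4 * h, y0=-3 - 4 * h, cell=h / 4,
                             nx=int((6 + 8 * h) / (h / 4)) + 1,
                             ny=int((6 + 8 * h) / (h / 4)) + 1)
        surf = dp.weighted_kde(pts, wts, h, grid)
        assert surf.integral() == pytest.approx(wts.sum() / 12, rel=0.01)

    def test_bandwidth_scaling(self):
        """Doubling h quarters the anchor height but keeps the mass."""
        w = 2.0
        h1, h2 = 1.0, 2.0
        grid, mid = grid_with_anchor_at_center(h1, cell=h1 / 8, half_cells=120)
        s1 = dp.weighted_kde(np.array([[0.0, 0.0]]), np.array([w]), h1, grid)
        s2 = dp.weighted_kde(np.array([[0.0, 0.0]]), np.array([w]), h2, grid)
        assert s1.values[mid, mid] / s2.values[mid, mid] == pytest.approx(4.0)
        assert s1.integral() == pytest.approx(s2.integral(), rel=0.01)

    def test_invalid_bandwidth(self):
        grid, _ = grid_with_anchor_at_center(1.0)
        with pytest.raises(ConfigError):
            dp.weighted_kde(np.zeros((1, 2)), np.ones(1), 0.0, grid)


class TestRipley:
    def test_csr_torus_calibration(self):
        """K-hat tracks pi d^2 on torus-wrapped uniform points."""
        passes = 0
        n_seeds = 10
        d_grid = np.linspace(5, 25, 21)
        for seed in range(n_seeds):
            pts = np.random.default_rng(seed).uniform(0, 100, size=(1000, 2))
            rip = dp.ripley_k(pts, torus_domain=(100.0, 100.0), d_grid=d_grid)
            if np.max(np.abs(rip.diff) / rip.theoretical) < 0.10:
                passes += 1
        assert passes >= int(0.9 * n_seeds)

    def test_two_clusters_select_between_sd_and_separation(self, rng):
        sd, sep = 50.0, 1000.0
        a = rng.normal([0, 0], sd, size=(60, 2))
        b = rng.normal([sep, 0], sd, size=(60, 2))
        pts = np.vstack([a, b])
        rip = dp.ripley_k(pts, area=(sep + 6 * sd) * 12 * sd,
                          d_grid=np.linspace(10, 1200, 120))
        h = dp.select_bandwidth(rip)
        assert sd <= h <= sep

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            dp.ripley_k(np.zeros((5, 2)))


class TestSelectBandwidth:
    def _ripley(self, d, diff):
        d = np.asarray(d, dtype=float)
        diff = np.asarray(diff, dtype=float)
        theo = np.pi * d ** 2
        return RipleyResult(d=d, K=theo + diff, theoretical=theo, diff=diff,
                            area=1.0, n_points=10)

    def test_unimodal_peak(self):
        rip = self._ripley([1, 2, 3, 4], [0.1, 0.5, 0.3, 0.0])
        assert dp.select_bandwidth(rip) == 2.0

    def test_tie_takes_smaller_distance(self):
        rip = self._ripley([1, 2, 3, 4], [0.1, 0.5, 0.5, 0.0])
        assert dp.select_bandwidth(rip) == 2.0

    def test_monotone_diff_hits_boundary_with_warning(self):
        rip = self._ripley([1, 2, 3], [0.1, 0.2, 0.3])
        with pytest.warns(UserWarning, match="boundary"):
            assert dp.select_bandwidth(rip) == 3.0

    def test_dispersed_pattern_falls_back(self):
        rip = self._ripley([1, 2, 3], [-0.1, -0.2, -0.3])
        with pytest.warns(UserWarning, match="fallback"):
            assert dp.select_bandwidth(rip, fallback=470.0) == 470.0


class TestHmr:
    def _surfaces(self, rng, n=20):
        h = 2.0
        pts = rng.uniform(0, 10, size=(n, 2))
        grid = dp.default_grid(pts, h, n_cells=40)
        w = {k: rng.uniform(1, 5, size=n) for k in ("d", "t", "m")}
        return pts, w, h, grid

    def test_zero_mortality_is_exact_sum(self, rng):
        pts, w, h, grid = self._surfaces(rng)
        diag = dp.weighted_kde(pts, w["d"], h, grid)
        treat = dp.weighted_kde(pts, w["t"], h, grid)
        mort = dp.weighted_kde(pts, np.zeros(len(pts)), h, grid)
        hmr = dp.compute_hmr(diag, treat, mort)
        np.testing.assert_array_equal(hmr.values, diag.values + treat.values)

    def test_zero_healthcare_is_zero(self, rng):
        pts, w, h, grid = self._surfaces(rng)
        zero = dp.weighted_kde(pts, np.zeros(len(pts)), h, grid)
        mort = dp.weighted_kde(pts, w["m"], h, grid)
        hmr = dp.compute_hmr(zero, zero, mort)
        assert np.all(hmr.values == 0)

    def test_grid_mismatch_rejected(self, rng):
        pts, w, h, grid = self._surfaces(rng)
        other = dp.RasterGrid(x0=grid.x0, y0=grid.y0, cell=grid.cell,
                              nx=grid.nx + 1, ny=grid.ny)
        a = dp.weighted_kde(pts, w["d"], h, grid)
        b = dp.weighted_kde(pts, w["t"], h, other)
        m = dp.weighted_kde(pts, w["m"], h, grid)
        with pytest.raises(ValidationError, match="grids"):
            dp.compute_hmr(a, b, m)

    def test_monotone_in_weights(self, rng):
        pts, w, h, grid = self._surfaces(rng)
        treat = dp.weighted_kde(pts, w["t"], h, grid)
        mort = dp.weighted_kde(pts, w["m"], h, grid)
        base = dp.compute_hmr(dp.weighted_kde(pts, w["d"], h, grid), treat, mort)
        w_up = w["d"].copy()
        w_up[3] += 2.0
        up = dp.compute_hmr(dp.weighted_kde(pts, w_up, h, grid), treat, mort)
        assert np.all(up.values >= base.values)
        m_up = w["m"].copy()
        m_up[5] += 2.0
        down = dp.compute_hmr(dp.weighted_kde(pts, w["d"], h, grid), treat,
                              dp.weighted_kde(pts, m_up, h, grid))
        assert np.all(down.values <= base.values)

    def test_band_classification(self):
        grid = dp.RasterGrid(x0=0, y0=0, cell=1, nx=2, ny=2)
        raster = dp.HmrRaster(grid=grid,
                              values=np.array([[1.0, 5.0], [0.2, 1.05]]),
                              bandwidth=1.0)
        bands = dp.classify_hmr(raster, tolerance=0.1)
        assert bands["n_cells"].sum() == 4
        by = bands.set_index("band")["n_cells"]
        assert by["high"] == 1 and by["low"] == 1 and by["near_parity"] == 2
        codes = band_raster(raster, tolerance=0.1)
        assert codes.tolist() == [[1, 2], [0, 1]]


class TestCentroidExtraction:
    def test_weights_match_quinquennial_panel(self, small_study):
        lattice, _, panel = small_study
        rates = dp.spatial_eb_smooth(panel, dp.build_queen_weights(lattice))
        quinq = dp.quinquennial_mean(rates)
        pts, wts = dp.extract_centroids(lattice, quinq, "2013-2017")
        assert pts.shape == (36, 2)
        sub = quinq[(quinq["period"] == "2013-2017")
                    & (quinq["indicator"] == "death")]
        lookup = sub.set_index("region_id")["mean_rate"]
        for i, rid in enumerate(lattice.region_ids):
            assert wts["death"][i] == lookup[rid]

    def test_missing_rate_reported(self, small_study):
        lattice, _, panel = small_study
        rates = dp.spatial_eb_smooth(panel, dp.build_queen_weights(lattice))
        quinq = dp.quinquennial_mean(rates)
        quinq = quinq[quinq["region_id"] != lattice.region_ids[0]]
        with pytest.raises(ValidationError, match=lattice.region_ids[0]):
            dp.extract_centroids(lattice, quinq, "2013-2017")


class TestAsciiGrid:
    def test_round_trip(self, tmp_path, rng):
        grid = dp.RasterGrid(x0=-5.0, y0=2.0, cell=0.5, nx=7, ny=4)
        values = rng.normal(size=(4, 7))
        path = tmp_path / "r.asc"
        write_asc(grid, values, path)
        g2, v2 = read_asc(path)
        assert g2 == grid
        np.testing.assert_allclose(v2, values, rtol=1e-6)
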