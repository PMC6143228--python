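"""Kernel density UDs and the four bandwidth selectors."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

import rangebridge as rb
from rangebridge.kde import DegenerateDataError, lscv_score
from conftest import brownian_track, make_track


def _unit_variance_points(n, seed=0):
    """2D sample rescaled so each axis has sample variance exactly 1."""
    rng = np.random.default_rng(seed)
    xy = rng.standard_normal((n, 2))
    xy -= xy.mean(axis=0)
    xy /= xy.std(axis=0, ddof=1)
    return xy


class TestHref:
    def test_formula_at_unit_variance(self):
        track = make_track(_unit_variance_points(64))
        bw = rb.href_bandwidth(track)
        assert bw.h_x == pytest.approx(64 ** (-1 / 6))
        assert bw.h_x == bw.h_y

    def test_scale_equivariance(self):
        track = make_track(_unit_variance_points(50, seed=1))
        doubled = make_track(2 * track.xy)
        assert rb.href_bandwidth(doubled).h_x == pytest.approx(
            2 * rb.href_bandwidth(track).h_x
        )

    def test_identical_points_degenerate(self):
        with pytest.raises(DegenerateDataError):
            rb.href_bandwidth(make_track([(3, 3)] * 10))


class TestLscv:
    def test_interior_minimizer_converges(self):
        track = make_track(100 * _unit_variance_points(80, seed=2))
        bw = rb.lscv_bandwidth(track)
        assert bw.converged
        hs = [h for h, _ in bw.search_trace]
        assert min(hs) < bw.h_x < max(hs)

    def test_duplicated_clusters_hit_lower_boundary(self):
        # two tight clusters of exactly coincident fixes: CV(h) -> -inf as
        # h -> 0, the classic LSCV failure
        pts = [(0.0, 0.0)] * 20 + [(500.0, 0.0)] * 20
        bw = rb.lscv_bandwidth(make_track(pts))
        assert not bw.converged
        hs = [h for h, _ in bw.search_trace]
        assert bw.h_x == pytest.approx(min(hs))

    def test_score_matches_quadrature_oracle(self):
        # CV(h) = int f^2 - (2/n) sum_i f_{-i}(x_i), by brute numerics
        rng = np.random.default_rng(3)
        xy = rng.uniform(0, 30, size=(10, 2))
        track = make_track(xy)
        n = len(xy)
        from scipy.spatial.distance import pdist

        d2 = pdist(xy, "sqeuclidean")
        for h in (5.0, 10.0, 20.0):
            # quadrature of the squared mixture over a wide grid
            lim = 6 * h + 40
            g = np.linspace(-lim, lim + 30, 900)
            dx = g[1] - g[0]
            gx, gy = np.meshgrid(g, g, indexing="ij")
            f = np.zeros_like(gx)
            for x, y in xy:
                f += np.exp(
                    -((gx - x) ** 2 + (gy - y) ** 2) / (2 * h * h)
                ) / (2 * np.pi * h * h)
            f /= n
            int_f2 = (f**2).sum() * dx * dx
            loo = 0.0
            for i in range(n):
                others = np.delete(xy, i, axis=0)
                di = ((others - xy[i]) ** 2).sum(axis=1)
                loo += (
                    np.exp(-di / (2 * h * h)).sum()
                    / (2 * np.pi * h * h)
                    / (n - 1)
                )
            oracle = int_f2 - 2.0 / n * loo
            assert lscv_score(d2, n, h) == pytest.approx(oracle, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(rb.InsufficientDataError):
            rb.lscv_bandwidth(make_track([(0, 0), (1, 1), (2, 0), (3, 1)]))


class TestPlugin:
    def test_gaussian_reference_rate(self):
        rng = np.random.default_rng(4)
        track = make_track(rng.standard_normal((10_000, 2)), dt_h=0.01)
        bw = rb.plugin_bandwidth(track)
        ref = 1.06 * 10_000 ** (-0.2)
        assert bw.h_x == pytest.approx(ref, rel=0.15)
        assert bw.h_y == pytest.approx(ref, rel=0.15)

    def test_per_axis_equivariance(self):
        rng = np.random.default_rng(5)
        xy = rng.standard_normal((200, 2))
        base = rb.plugin_bandwidth(make_track(xy))
        scaled = rb.plugin_bandwidth(make_track(xy * [3.0, 1.0]))
        assert scaled.h_x == pytest.approx(3 * base.h_x, rel=1e-9)
        assert scaled.h_y == pytest.approx(base.h_y, rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(rb.InsufficientDataError):
            rb.plugin_bandwidth(brownian_track(10.0, 4))


class TestKdeUd:
    def test_single_relocation_gaussian(self):
        track = make_track([(500.0, 500.0)])
        grid = rb.GridSpec(0, 0, 10.0, 100, 100)
        ud = rb.kde_ud(track, rb.manual_bandwidth(50.0), grid)
        assert ud.cell_mass.sum() == pytest.approx(1.0, abs=1e-6)
        r, c = grid.cell_of(500.0, 500.0)
        assert ud.cell_mass.max() == ud.cell_mass[r, c]

    def test_cell_values_match_mixture_oracle(self):
        rng = np.random.default_rng(6)
        xy = rng.uniform(100, 900, size=(40, 2))
        track = make_track(xy)
        grid = rb.GridSpec(0, 0, 20.0, 50, 50)
        bw = rb.manual_bandwidth(60.0)
        ud = rb.kde_ud(track, bw, grid)
        raw = np.empty(grid.shape)
        for rr in range(grid.n_rows):
            for cc in range(grid.n_cols):
                cx, cy = grid.cell_center(rr, cc)
                raw[rr, cc] = np.mean(
                    np.exp(
                        -((cx - xy[:, 0]) ** 2 + (cy - xy[:, 1]) ** 2)
                        / (2 * 60.0**2)
                    )
                    / (2 * np.pi * 60.0**2)
                )
        expected = raw * grid.cell_area_m2
        expected /= expected.sum()
        cells = rng.integers(0, 50, size=(20, 2))
        for rr, cc in cells:
            assert ud.cell_mass[rr, cc] == pytest.approx(
                expected[rr, cc], rel=1e-10
            )

    def test_mirror_symmetry(self):
        track = make_track([(-100, 0), (100, 0), (-50, 40), (50, 40)])
        grid = rb.GridSpec(-200, -200, 20.0, 20, 20)
        ud = rb.kde_ud(track, rb.manual_bandwidth(40.0), grid)
        np.testing.assert_allclose(ud.cell_mass, ud.cell_mass[:, ::-1], atol=1e-15)

    def test_grid_must_cover_track(self):
        track = make_track([(0, 0), (1000, 1000)])
        grid = rb.GridSpec(0, 0, 10.0, 10, 10)
        with pytest.raises(rb.ConfigurationError):
            rb.kde_ud(track, rb.manual_bandwidth(10.0), grid)

    def test_nonconverged_bandwidth_refused(self):
        pts = [(0.0, 0.0)] * 10 + [(500.0, 0.0)] * 10
        track = make_track(pts)
        bw = rb.lscv_bandwidth(track)
        grid = rb.GridSpec(-100, -100, 10.0, 80, 30)
        with pytest.raises(rb.ConfigurationError, match="converge"):
            rb.kde_ud(track, bw, grid)


class TestSmoothingDirection:
    def _multisite_track(self):
        # oversampled revisitation of 10 discrete sites in two clusters
        rng = np.random.default_rng(4)
        sites = np.vstack(
            [[i * 60, 0] for i in range(5)]
            + [[400 + i * 60, 300] for i in range(5)]
        )
        pts = np.vstack([s + rng.normal(0, 8, (20, 2)) for s in sites])
        return make_track(pts)

    def test_href_oversmooths_lscv_undersmooths(self):
        track = self._multisite_track()
        grid = rb.make_reference_grid([track], 5.0, 100.0)
        bw_h, bw_l = rb.href_bandwidth(track), rb.lscv_bandwidth(track)
        assert bw_l.converged and bw_l.h_x < bw_h.h_x
        reg_h = rb.isopleth_region(rb.kde_ud(track, bw_h, grid), 0.95)
        reg_l = rb.isopleth_region(rb.kde_ud(track, bw_l, grid), 0.95)
        _, n_h = ndimage.label(reg_h.mask())
        _, n_l = ndimage.label(reg_l.mask())
        assert n_h < n_l  # fewer patches ...
        assert reg_h.area_ha > reg_l.area_ha  # ... each larger

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_halving_h_concentrates_core(self, seed):
        track = brownian_track(100.0, 150, seed=seed)
        grid = rb.make_reference_grid([track], 10.0, 200.0)
        for h in (160.0, 80.0, 40.0):
            a_big = rb.isopleth_region(
                rb.kde_ud(track, rb.manual_bandwidth(h), grid), 0.50
            ).area_ha
            a_small = rb.isopleth_region(
                rb.kde_ud(track, rb.manual_bandwidth(h / 2), grid), 0.50
            ).area_ha
            assert a_small <= a_big + 1e-9


def test_match_bandwidth_to_area_hits_target():
    track = brownian_track(100.0, 200, seed=8)
    grid = rb.make_reference_grid([track], 10.0, 300.0)
    target = 12.0  # hectares at the 95% isopleth
    bw = rb.kde.match_bandwidth_to_area(track, grid, target)
    assert bw.converged
    area = rb.isopleth_region(rb.kde_ud(track, bw, grid), 0.95).area_ha
    assert area == pytest.approx(target, rel=0.05)
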