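"""AUC scoring, Manly selection ratios, sigma2m summaries, comparison."""

import numpy as np
import pandas as pd
import pytest

import rangebridge as rb
from rangebridge.evaluate import auc_from_scores, presence_mask
from rangebridge.grids import DegenerateDataError
from conftest import brownian_track, make_track


def brute_force_auc(presence, absence):
    wins = sum(
        1.0 if p > a else (0.5 if p == a else 0.0)
        for p in presence
        for a in absence
    )
    return wins / (len(presence) * len(absence))


class TestAuc:
    def test_perfect_separation(self):
        track = make_track([(15, 15), (35, 15)])
        grid = rb.GridSpec(0, 0, 10.0, 5, 5)
        m = np.zeros((5, 5))
        m[1, 1] = 0.6
        m[1, 3] = 0.4
        ud = rb.UDRaster(grid, m)
        assert rb.home_range_auc(ud, track) == 1.0

    def test_constant_scores_are_random(self):
        track = make_track([(15, 15)])
        grid = rb.GridSpec(0, 0, 10.0, 4, 4)
        ud = rb.UDRaster(grid, np.full((4, 4), 1 / 16))
        assert rb.home_range_auc(ud, track) == 0.5

    def test_half_tie_example(self):
        assert auc_from_scores(
            np.array([0.9, 0.5]), np.array([0.5, 0.1])
        ) == pytest.approx(0.875)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        is_presence = rng.random(n) < 0.3
        if is_presence.sum() in (0, n):
            is_presence[:2] = [True, False]
        fast = auc_from_scores(scores[is_presence], scores[~is_presence])
        slow = brute_force_auc(scores[is_presence], scores[~is_presence])
        assert fast == pytest.approx(slow, abs=1e-12)

    def test_random_permutations_center_on_half(self):
        rng = np.random.default_rng(42)
        scores = rng.random(60)
        aucs = []
        for _ in range(500):
            perm = rng.permutation(scores)
            aucs.append(auc_from_scores(perm[:20], perm[20:]))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_no_absence_cells_degenerate(self):
        grid = rb.GridSpec(0, 0, 10.0, 2, 1)
        ud = rb.UDRaster(grid, np.array([[0.5, 0.5]]))
        track = make_track([(5, 5), (15, 5)])
        with pytest.raises(DegenerateDataError):
            rb.home_range_auc(ud, track)


def _habitat_checkerboard():
    grid = rb.GridSpec(0, 0, 10.0, 4, 4)
    codes = np.zeros((4, 4), dtype=int)
    codes[:, 2:] = 1
    return rb.HabitatRaster(grid, codes, {0: "A", 1: "B"})


def _region(grid, cells, level=0.5):
    return rb.IsoplethRegion(level, frozenset(cells), grid, level)


class TestSelectionRatios:
    def test_identical_composition_gives_unit_ratios(self):
        hab = _habitat_checkerboard()
        used = _region(hab.grid, {(0, 0), (0, 2)})
        avail = _region(hab.grid, {(0, 0), (1, 1), (0, 2), (1, 3)}, 0.99)
        tab = rb.selection_ratios(used, avail, hab)
        assert (tab["ratio"] == 1.0).all()
        assert (tab["classification"] == "proportional").all()

    def test_double_use_is_more_than_available(self):
        hab = _habitat_checkerboard()
        # used: 2/5 habitat B; available: 2/10 habitat B
        used = _region(hab.grid, {(0, 0), (1, 0), (2, 0), (0, 2), (0, 3)})
        avail_cells = {(r, c) for r in range(4) for c in range(2)} | {
            (0, 2), (0, 3)}
        avail = _region(hab.grid, avail_cells, 0.99)
        tab = rb.selection_ratios(used, avail, hab).set_index("habitat")
        assert tab.loc["B", "ratio"] == pytest.approx(2.0)
        assert tab.loc["B", "classification"] == "more than available"

    def test_habitat_absent_from_available_is_undefined(self):
        hab = _habitat_checkerboard()
        used = _region(hab.grid, {(0, 0), (0, 2)})
        avail = _region(hab.grid, {(0, 0), (1, 0)}, 0.99)
        tab = rb.selection_ratios(used, avail, hab).set_index("habitat")
        assert tab.loc["B", "classification"] == "undefined"
        assert np.isnan(tab.loc["B", "ratio"])

    def test_invariant_to_code_relabeling(self):
        hab = _habitat_checkerboard()
        relabeled = rb.HabitatRaster(
            hab.grid, 7 - hab.codes * 3, {7: "A", 4: "B"}
        )
        used = _region(hab.grid, {(0, 0), (0, 2), (1, 2)})
        avail = _region(
            hab.grid, {(0, 0), (1, 0), (0, 2), (1, 2), (2, 2)}, 0.99
        )
        a = rb.selection_ratios(used, avail, hab).set_index("habitat")["ratio"]
        b = rb.selection_ratios(used, avail, relabeled).set_index("habitat")["ratio"]
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())


class TestVarianceByCategory:
    def test_two_habitat_recovery(self):
        # high-mobility half of the range vs. stationary half
        rng = np.random.default_rng(0)
        xy_a = np.cumsum(rng.normal(0, 10, (150, 2)), axis=0)  # sigma2m 100
        xy_b = xy_a[-1] + [2000, 0] + np.cumsum(
            rng.normal(0, 1, (150, 2)), axis=0
        )
        track = make_track(np.vstack([xy_a, xy_b]))
        grid = rb.make_reference_grid([track], 50.0, 300.0)
        codes = np.zeros(grid.shape, dtype=int)
        split_col = int(grid.cell_of(xy_a[-1, 0] + 1000, 0)[1])
        codes[:, split_col:] = 1
        hab = rb.HabitatRaster(grid, codes, {0: "A", 1: "B"})
        prof = rb.dbbmm_variance_profile(track)
        tab = rb.variance_by_category(prof, track, hab)
        hab_rows = tab[tab["grouping"] == "habitat"].set_index("category")
        assert hab_rows.loc["A", "mean"] > hab_rows.loc["B", "mean"]

    def test_single_habitat_single_row(self):
        track = brownian_track(10.0, 50, seed=1)
        grid = rb.make_reference_grid([track], 50.0, 100.0)
        hab = rb.HabitatRaster(
            grid, np.zeros(grid.shape, dtype=int), {0: "only"}
        )
        prof = rb.VarianceProfile.constant(10.0, len(track))
        tab = rb.variance_by_category(prof, track, hab)
        assert (tab[tab["grouping"] == "habitat"]["category"] == "only").all()
        assert len(tab[tab["grouping"] == "habitat"]) == 1

    def test_seasonal_null_homogeneity(self):
        # a single-state track has no seasonal sigma2m structure; SEs are
        # computed on a window-spaced subsample because overlapping dBBMM
        # windows autocorrelate neighboring per-location values
        track = brownian_track(50.0, 2000, dt_h=5.0, seed=9)
        prof = rb.dbbmm_variance_profile(track)
        seasons = np.array(rb.assign_seasons(track))
        sub = np.arange(0, len(track), prof.window)
        vals, labs = prof.per_location[sub], seasons[sub]
        names = sorted(set(labs))
        assert len(names) == 3
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                va, vb = vals[labs == a], vals[labs == b]
                se = np.hypot(
                    va.std(ddof=1) / np.sqrt(len(va)),
                    vb.std(ddof=1) / np.sqrt(len(vb)),
                )
                assert abs(va.mean() - vb.mean()) < 2 * se


class TestCompareEstimators:
    def test_completeness_on_small_fixture(self):
        track = brownian_track(200.0, 250, error_sd=5.5, seed=6)
        grid = rb.make_reference_grid([track], 25.0, 200.0)
        res = rb.compare_estimators([track], grid)
        methods = set(res.table["method"])
        assert methods == set(rb.ALL_METHODS)
        # every method reported at least one row for the animal
        for m in rb.ALL_METHODS:
            assert (res.table["method"] == m).any()

    def test_failures_are_flagged_not_fatal(self):
        # coincident-cluster track: LSCV cannot converge, rest proceed
        pts = [(0.0, 0.0)] * 30 + [(500.0, 0.0)] * 30
        track = make_track(pts, error_sd=5.5)
        grid = rb.make_reference_grid([track], 25.0, 200.0)
        res = rb.compare_estimators(
            [track], grid, methods=("kde_href", "kde_lscv")
        )
        assert any(f[1] == "kde_lscv" for f in res.flags)
        assert ("T", "kde_href", "all") in res.uds


class TestSeasonalReruns:
    def test_by_season_adds_consistent_seasonal_rows(self):
        # ~7 months spanning dry and rainy seasons
        import dataclasses
        from datetime import date
        from rangebridge.simulate import default_study_configs, simulate_track

        cfg = dataclasses.replace(
            default_study_configs(2)[0],
            start=date(2014, 4, 1), end=date(2014, 11, 1),
        )
        track, _ = simulate_track(cfg)
        grid = rb.make_reference_grid([track], 25.0, 200.0)
        res = rb.compare_estimators(
            [track], grid, methods=("kde_href", "bbmm", "dbbmm"),
            by_season=True,
        )
        seasons = set(res.table["season"])
        assert {"all", "dry", "rainy"} <= seasons
        # seasonal 99% regions stay inside (a buffer of) the full-range one
        for method in ("bbmm", "dbbmm"):
            full = res.regions[(track.animal_id, method, "all", 0.99)]
            for s in ("dry", "rainy"):
                reg = res.regions.get((track.animal_id, method, s, 0.99))
                if reg is None:
                    continue
                j, frac_in_full, _ = rb.region_overlap(reg, full)
                assert frac_in_full > 0.80
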