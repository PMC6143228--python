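"""Estimator scoring and cross-method comparison.

AUC: a home-range UD is scored as a pixel classifier.  Presence cells are
grid cells containing at least one relocation, all remaining cells of the
reference grid are pseudo-absences, and the cell's UD mass is the score;
AUC is the Mann-Whitney concordance statistic with ties counted half.  The
same grid and extent must be used across methods (AUC is scale dependent).

Habitat selection follows Manly's design-II selection ratio w_i = u_i/a_i,
with the 50% isopleth as the used region and the 99% isopleth as the
available region, both as cell-count proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import kde as kde_mod
from .bridge import (
    DbbmmConfig,
    VarianceProfile,
    compute_bb_ud,
    dbbmm_variance_profile,
    estimate_sigma2m,
)
from .grids import (
    DegenerateDataError,
    GridSpec,
    HabitatRaster,
    IsoplethRegion,
    UDRaster,
    isopleth_region,
)
from .mcp import percent_mcp
from .telemetry import (
    ConfigurationError,
    DEFAULT_SEASONS,
    SeasonScheme,
    Track,
    assign_seasons,
)

logger = logging.getLogger("rangebridge")

DEFAULT_LEVELS = (0.50, 0.95, 0.99)

#: The seven methods of the comparison framework, in reporting order.
ALL_METHODS = (
    "mcp",
    "kde_href",
    "kde_lscv",
    "kde_plugin",
    "kde_h100",
    "bbmm",
    "dbbmm",
)


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def presence_mask(grid: GridSpec, track: Track) -> np.ndarray:
    """Boolean grid mask of cells containing at least one relocation."""
    xy = track.xy
    if not grid.contains(xy[:, 0], xy[:, 1]).all():
        raise ConfigurationError("all relocations must lie inside the grid")
    row, col = grid.cell_of(xy[:, 0], xy[:, 1])
    mask = np.zeros(grid.shape, dtype=bool)
    mask[row, col] = True
    return mask


def auc_from_scores(presence: np.ndarray, absence: np.ndarray) -> float:
    """Mann-Whitney AUC of presence vs. absence scores (ties count half)."""
    n1, n0 = len(presence), len(absence)
    if n1 == 0 or n0 == 0:
        raise DegenerateDataError("AUC needs both presence and absence cells")
    ranks = rankdata(np.concatenate([presence, absence]))
    r1 = ranks[:n1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def home_range_auc(ud: UDRaster, track: Track) -> float:
    """AUC of the UD as a presence/pseudo-absence pixel classifier."""
    mask = presence_mask(ud.grid, track)
    scores = ud.cell_mass
    return auc_from_scores(scores[mask], scores[~mask])


# ---------------------------------------------------------------------------
# Habitat selection (Manly ratios)
# ---------------------------------------------------------------------------

def selection_ratios(
    used: IsoplethRegion,
    available: IsoplethRegion,
    habitat: HabitatRaster,
) -> pd.DataFrame:
    """Manly selection table: per habitat u_i, a_i, w_i = u_i/a_i.

    u_i and a_i are cell-count proportions of each habitat within the used
    (typically 50% isopleth) and available (99% isopleth) regions.  A
    habitat present in the used region but absent from the available one
    gets classification 'undefined' and a flagged (NaN) ratio.
    """
    if used.grid != habitat.grid or available.grid != habitat.grid:
        raise ConfigurationError("regions and habitat must share one grid")
    if not used.cells or not available.cells:
        raise DegenerateDataError("selection needs nonempty regions")
    if not used.cells <= available.cells:
        logger.warning(
            "used region is not contained in the available region "
            "(%d stray cells)", len(used.cells - available.cells)
        )
    codes = habitat.codes
    u_codes = np.array([codes[r, c] for r, c in used.cells])
    a_codes = np.array([codes[r, c] for r, c in available.cells])
    rows = []
    for code in sorted(set(u_codes.tolist()) | set(a_codes.tolist())):
        u = float((u_codes == code).mean())
        a = float((a_codes == code).mean())
        if a == 0.0:
            w, cls = float("nan"), "undefined"
        else:
            w = u / a
            cls = (
                "proportional"
                if abs(w - 1.0) <= 1e-9
                else ("more than available" if w > 1.0 else "less than available")
            )
        rows.append(
            dict(habitat=habitat.legend[int(code)], code=int(code),
                 used=u, available=a, ratio=w, classification=cls)
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Motion variance summaries
# ---------------------------------------------------------------------------

def variance_by_category(
    profile: VarianceProfile,
    track: Track,
    habitat: HabitatRaster | None = None,
    scheme: SeasonScheme = DEFAULT_SEASONS,
) -> pd.DataFrame:
    """Mean/SE/n of per-location sigma2m per habitat and per season.

    Fixes outside the habitat raster are assigned 'unknown' and counted.
    """
    n = len(track)
    if len(profile.per_location) != n:
        raise ConfigurationError("profile is not aligned to the track")
    seasons = assign_seasons(track, scheme)
    habitats = (
        [habitat.category_at(r.x, r.y) for r in track.relocations]
        if habitat is not None
        else ["all"] * n
    )
    df = pd.DataFrame(
        {"sigma2m": profile.per_location, "season": seasons, "habitat": habitats}
    )
    out = []
    for kind in ("habitat", "season"):
        g = df.groupby(kind)["sigma2m"]
        agg = pd.DataFrame(
            {"mean": g.mean(), "se": g.sem(), "n": g.size()}
        ).reset_index(names="category")
        agg.insert(0, "grouping", kind)
        out.append(agg)
    return pd.concat(out, ignore_index=True)


def variance_profile_table(
    profile: VarianceProfile,
    track: Track,
    habitat: HabitatRaster | None = None,
    scheme: SeasonScheme = DEFAULT_SEASONS,
) -> pd.DataFrame:
    """Analysis-ready per-fix table (timestamp, sigma2m, season, habitat) —
    the export consumed by downstream mixed-model analyses."""
    return pd.DataFrame(
        {
            "animal_id": track.animal_id,
            "timestamp": track.timestamps.strftime("%Y-%m-%dT%H:%M:%SZ"),
            "sigma2m": profile.per_location,
            "season": assign_seasons(track, scheme),
            "habitat": (
                [habitat.category_at(r.x, r.y) for r in track.relocations]
                if habitat is not None
                else "all"
            ),
        }
    )


# ---------------------------------------------------------------------------
# Cross-method comparison
# ---------------------------------------------------------------------------

@dataclass
class EvaluationResult:
    """Tidy per-animal x method x season metric table plus raw artifacts."""

    table: pd.DataFrame
    uds: dict = field(default_factory=dict)  # (animal, method, season) -> UDRaster
    regions: dict = field(default_factory=dict)  # (animal, method, season, level)
    selection: dict = field(default_factory=dict)  # (animal, method, season) -> DF
    profiles: dict = field(default_factory=dict)  # (animal, season) -> VarianceProfile
    flags: list = field(default_factory=list)


#: Inter-fix gap (hours) above which a season-filtered track is treated as
#: separate contiguous blocks for the bridge methods.
SEASON_BLOCK_GAP_H = 72.0


def contiguous_blocks(track: Track, max_gap_h: float) -> list[np.ndarray]:
    """Index arrays of runs whose inter-fix gaps are all <= max_gap_h."""
    gaps = np.diff(track.times_h)
    cut = np.flatnonzero(gaps > max_gap_h) + 1
    return np.split(np.arange(len(track)), cut)


def _blockwise_profile(
    track: Track, dynamic: bool, dbbmm_config: DbbmmConfig, gap_h: float
) -> VarianceProfile:
    """Per-interval sigma2m for a (possibly gappy) season-filtered track,
    refit independently on each season-contiguous block.

    Blocks shorter than the dBBMM window fall back to a constant (BBMM)
    fit; blocks with fewer than 3 fixes inherit the pooled estimate.
    Cross-block intervals receive the mean of the adjacent block edges (the
    UD excludes them via max_lag_h anyway).
    """
    n = len(track)
    pooled: float | None = None
    per_loc = np.empty(n)
    for idx in contiguous_blocks(track, gap_h):
        block = track.subset(np.isin(np.arange(n), idx))
        if len(block) >= max(dbbmm_config.window if dynamic else 3, 3):
            if dynamic:
                per_loc[idx] = dbbmm_variance_profile(block, dbbmm_config).per_location
            else:
                per_loc[idx] = estimate_sigma2m(block).value
        else:
            if pooled is None:
                pooled = estimate_sigma2m(track).value
            per_loc[idx] = pooled
    per_int = 0.5 * (per_loc[:-1] + per_loc[1:])
    return VarianceProfile(per_loc, per_int, dbbmm_config.window,
                           dbbmm_config.margin, 0)


def _build_ud(track: Track, method: str, grid: GridSpec, *,
              dbbmm_config: DbbmmConfig, manual_h: float,
              profiles_out: dict, season: str) -> UDRaster:
    if method == "kde_href":
        return kde_mod.kde_ud(track, kde_mod.href_bandwidth(track), grid)
    if method == "kde_lscv":
        return kde_mod.kde_ud(track, kde_mod.lscv_bandwidth(track), grid)
    if method == "kde_plugin":
        return kde_mod.kde_ud(track, kde_mod.plugin_bandwidth(track), grid)
    if method == "kde_h100":
        return kde_mod.kde_ud(track, kde_mod.manual_bandwidth(manual_h), grid)
    if method not in ("bbmm", "dbbmm"):
        raise ConfigurationError(f"unknown method {method!r}")
    dynamic = method == "dbbmm"
    if season == "all":
        # one contiguous tracking period: single fit over the whole path
        if dynamic:
            profile: VarianceProfile | float = dbbmm_variance_profile(
                track, dbbmm_config
            )
            profiles_out[(track.animal_id, season)] = profile
        else:
            profile = estimate_sigma2m(track).value
        return compute_bb_ud(track, profile, grid,
                             max_lag_h=dbbmm_config.max_lag_h)
    # season-filtered fixes: refit per season-contiguous block and exclude
    # the cross-block bridging intervals from the UD
    profile = _blockwise_profile(track, dynamic, dbbmm_config, SEASON_BLOCK_GAP_H)
    if dynamic:
        profiles_out[(track.animal_id, season)] = profile
    return compute_bb_ud(track, profile, grid, max_lag_h=SEASON_BLOCK_GAP_H)


def compare_estimators(
    tracks: list[Track],
    grid: GridSpec,
    habitat: HabitatRaster | None = None,
    methods: tuple[str, ...] = ALL_METHODS,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    mcp_percent: float = 95.0,
    manual_h: float = 100.0,
    dbbmm_config: DbbmmConfig | None = None,
    by_season: bool = False,
    scheme: SeasonScheme = DEFAULT_SEASONS,
) -> EvaluationResult:
    """Run every requested estimator per animal on the SAME reference grid
    and assemble the comparison table (AUC, areas, complexities, selection
    ratios, flags).

    MCP contributes geometry only (no AUC, no selection).  With
    ``by_season=True`` each season's contiguous fixes are re-analyzed from
    scratch (sigma2m refit per season) and reported alongside the full
    track.  Estimator failures are flagged rows, not pipeline aborts.
    """
    dbbmm_config = dbbmm_config or DbbmmConfig()
    result = EvaluationResult(table=pd.DataFrame())
    rows: list[dict] = []

    def add(animal, method, season, metric, value, flag=""):
        rows.append(dict(animal=animal, method=method, season=season,
                         metric=metric, value=value, flag=flag))

    for track in tracks:
        season_tracks: list[tuple[str, Track]] = [("all", track)]
        if by_season:
            labels = np.asarray(assign_seasons(track, scheme))
            for s_name in sorted(set(labels.tolist())):
                try:
                    season_tracks.append((s_name, track.subset(labels == s_name)))
                except Exception:
                    continue
        for season, sub in season_tracks:
            for method in methods:
                aid = track.animal_id
                try:
                    if method == "mcp":
                        region = percent_mcp(sub, mcp_percent)
                        add(aid, method, season, f"area_ha_{mcp_percent:g}",
                            region.area_ha)
                        add(aid, method, season,
                            f"complexity_{mcp_percent:g}",
                            region.perimeter_m / region.area_ha)
                        continue
                    ud = _build_ud(
                        sub, method, grid, dbbmm_config=dbbmm_config,
                        manual_h=manual_h, profiles_out=result.profiles,
                        season=season,
                    )
                    result.uds[(aid, method, season)] = ud
                    add(aid, method, season, "auc", home_range_auc(ud, sub))
                    regs = {}
                    for lvl in levels:
                        reg = isopleth_region(ud, lvl)
                        regs[lvl] = reg
                        result.regions[(aid, method, season, lvl)] = reg
                        add(aid, method, season, f"area_ha_{100 * lvl:g}",
                            reg.area_ha)
                        add(aid, method, season, f"complexity_{100 * lvl:g}",
                            reg.complexity)
                    if habitat is not None and 0.50 in regs and 0.99 in regs:
                        result.selection[(aid, method, season)] = selection_ratios(
                            regs[0.50], regs[0.99], habitat
                        )
                except Exception as exc:  # noqa: BLE001 - flagged, not fatal
                    msg = f"{type(exc).__name__}: {exc}"
                    result.flags.append((aid, method, season, msg))
                    add(aid, method, season, "error", float("nan"), msg)
                    logger.warning("%s/%s/%s failed: %s", aid, method, season, msg)

    result.table = pd.DataFrame(rows)
    return result
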