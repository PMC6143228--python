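"""Configuration-driven end-to-end pipeline.

Stages (each writes its artifacts plus a manifest recording the config
hash and seed; identical config + seed reproduce identical outputs):

simulate   synthetic tracks + ground truth + habitat raster
estimate   UD rasters (.asc), variance profiles, bandwidth diagnostics,
           isopleth regions (GeoJSON) and their metric tables
evaluate   tidy evaluation table (AUC/areas/complexities), selection
           tables, seasonal overlap
report     human-readable summary + sigma2m time-series figure

The YAML config is validated strictly (unknown keys rejected).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import evaluate as ev
from .bridge import DbbmmConfig
from .grids import (
    GridSpec,
    HabitatRaster,
    make_reference_grid,
    read_ascii_grid,
    region_metrics_table,
    region_overlap,
    region_to_geojson_feature,
    write_ascii_grid,
    write_geojson,
)
from .kde import href_bandwidth, lscv_bandwidth, manual_bandwidth, plugin_bandwidth
from .mcp import mcp_to_geojson_feature, percent_mcp
from .simulate import (
    DEFAULT_HABITATS,
    SimConfig,
    default_study_configs,
    generate_habitat_map,
    simulate_track,
    truth_table,
)
from .telemetry import (
    ConfigurationError,
    DEFAULT_SEASONS,
    EQUAL_SEASONS,
    movement_summary_table,
    read_tracks_csv,
    write_tracks_csv,
)

logger = logging.getLogger("rangebridge")

_FLOAT_FMT = "%.10g"


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridConfig(_Strict):
    # 15 m cells resolve the stopover-scale bridge SDs (~GPS error) that
    # separate core-area estimates between methods
    cell_size: float = 15.0  # meters
    buffer: float = 250.0  # meters around the joint bounding box


class DbbmmSection(_Strict):
    window: int = 11
    margin: int = 3
    max_lag_h: float | None = None

    def to_config(self) -> DbbmmConfig:
        return DbbmmConfig(self.window, self.margin, "bic", self.max_lag_h)


class HabitatSection(_Strict):
    categories: dict[str, float] = Field(
        default_factory=lambda: {k: v for k, v in DEFAULT_HABITATS}
    )
    patchiness_m: float = 300.0


class SimulateSection(_Strict):
    n_animals: int = 2
    start: date | None = None
    end: date | None = None
    error_sd: float = 5.5
    habitat: HabitatSection = Field(default_factory=HabitatSection)


class PipelineConfig(_Strict):
    seed: int = 0
    tracks_csv: str | None = None  # use field data instead of simulating
    habitat_asc: str | None = None
    habitat_legend_csv: str | None = None
    grid: GridConfig = Field(default_factory=GridConfig)
    methods: list[str] = Field(default_factory=lambda: list(ev.ALL_METHODS))
    isopleth_levels: list[float] = [0.50, 0.95, 0.99]
    mcp_percent: float = 95.0
    manual_h: float = 100.0
    dbbmm: DbbmmSection = Field(default_factory=DbbmmSection)
    season_scheme: str = "default"  # default (unequal months) or equal
    by_season: bool = False
    stopover_threshold_m: float = 15.0
    error_default: float = 5.5
    simulate: SimulateSection = Field(default_factory=SimulateSection)

    @field_validator("methods")
    @classmethod
    def _known_methods(cls, v: list[str]) -> list[str]:
        unknown = set(v) - set(ev.ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")
        return v

    @property
    def scheme(self):
        if self.season_scheme == "default":
            return DEFAULT_SEASONS
        if self.season_scheme == "equal":
            return EQUAL_SEASONS
        raise ConfigurationError(
            f"season_scheme must be 'default' or 'equal', got {self.season_scheme!r}"
        )


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_manifest(out: Path, stage: str, config: PipelineConfig,
                    artifacts: list[str]) -> None:
    manifest = {
        "stage": stage,
        "config_hash": config_hash(config),
        "seed": config.seed,
        "artifacts": sorted(artifacts),
    }
    (out / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2))


def _csv(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path.name


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def run_simulate(config: PipelineConfig, out: Path) -> list[str]:
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulate
    configs = default_study_configs(config.seed)[: sim.n_animals]
    if len(configs) < sim.n_animals:
        extra = [
            SimConfig(animal_id=f"SYN{k + 1}", seed=config.seed * 1000 + k)
            for k in range(len(configs), sim.n_animals)
        ]
        configs = configs + extra
    overrides = {"error_sd": sim.error_sd}
    if sim.start:
        overrides["start"] = sim.start
    if sim.end:
        overrides["end"] = sim.end
    configs = [dataclasses.replace(c, **overrides) for c in configs]

    artifacts = []
    tracks, truths = [], []
    for c in configs:
        track, truth = simulate_track(c)
        tracks.append(track)
        truths.append(truth)
    write_tracks_csv(tracks, out / "tracks.csv")
    artifacts.append("tracks.csv")
    artifacts.append(_csv(pd.concat([truth_table(t) for t in truths]),
                          out / "truth.csv"))
    artifacts.append(
        _csv(movement_summary_table(tracks, config.stopover_threshold_m),
             out / "movement_summary.csv")
    )
    grid = make_reference_grid(tracks, config.grid.cell_size, config.grid.buffer)
    cats = sorted(sim.habitat.categories.items())
    habitat = generate_habitat_map(cats, grid, sim.habitat.patchiness_m,
                                   seed=config.seed + 17)
    write_ascii_grid(out / "habitat.asc", grid, habitat.codes)
    artifacts.append("habitat.asc")
    legend = pd.DataFrame(
        sorted(habitat.legend.items()), columns=["code", "habitat"]
    )
    artifacts.append(_csv(legend, out / "habitat_legend.csv"))
    _write_manifest(out, "simulate", config, artifacts)
    return artifacts


def _load_inputs(config: PipelineConfig, out: Path):
    tracks_path = Path(config.tracks_csv) if config.tracks_csv else out / "tracks.csv"
    if not tracks_path.exists():
        raise ConfigurationError(
            f"no tracks at {tracks_path}; run the simulate stage or set tracks_csv"
        )
    tracks = read_tracks_csv(tracks_path, error_default=config.error_default)
    grid = make_reference_grid(tracks, config.grid.cell_size, config.grid.buffer)

    habitat = None
    asc = Path(config.habitat_asc) if config.habitat_asc else out / "habitat.asc"
    leg = (
        Path(config.habitat_legend_csv)
        if config.habitat_legend_csv
        else out / "habitat_legend.csv"
    )
    if asc.exists() and leg.exists():
        hgrid, codes = read_ascii_grid(asc)
        legend_df = pd.read_csv(leg)
        legend = dict(zip(legend_df["code"], legend_df["habitat"]))
        if hgrid == grid:
            habitat = HabitatRaster(grid, codes.astype(int), legend)
        else:
            logger.warning("habitat raster grid differs from reference grid; "
                           "habitat selection skipped")
    return tracks, grid, habitat


def _run_analysis(config: PipelineConfig, out: Path):
    tracks, grid, habitat = _load_inputs(config, out)
    return ev.compare_estimators(
        tracks,
        grid,
        habitat=habitat,
        methods=tuple(config.methods),
        levels=tuple(config.isopleth_levels),
        mcp_percent=config.mcp_percent,
        manual_h=config.manual_h,
        dbbmm_config=config.dbbmm.to_config(),
        by_season=config.by_season,
        scheme=config.scheme,
    ), tracks, grid, habitat


def run_estimate(config: PipelineConfig, out: Path) -> list[str]:
    out.mkdir(parents=True, exist_ok=True)
    result, tracks, grid, habitat = _run_analysis(config, out)
    artifacts = []
    ud_dir = out / "uds"
    ud_dir.mkdir(exist_ok=True)
    for (aid, method, season), ud in result.uds.items():
        name = f"uds/{aid}_{method}_{season}.asc"
        write_ascii_grid(out / name, grid, ud.cell_mass)
        artifacts.append(name)
    # variance profiles (the analysis-ready sigma2m table)
    prof_rows = []
    for (aid, season), profile in result.profiles.items():
        track = next(t for t in tracks if t.animal_id == aid)
        if season == "all":
            prof_rows.append(
                ev.variance_profile_table(profile, track, habitat, config.scheme)
            )
    if prof_rows:
        artifacts.append(_csv(pd.concat(prof_rows), out / "variance_profiles.csv"))
    # bandwidth diagnostics incl. the LSCV search trace
    bw_rows, trace_rows = [], []
    for t in tracks:
        for maker, nm in (
            (href_bandwidth, "href"),
            (lscv_bandwidth, "lscv"),
            (plugin_bandwidth, "plugin"),
        ):
            try:
                bw = maker(t)
            except Exception as exc:  # noqa: BLE001
                bw_rows.append(dict(animal=t.animal_id, method=nm, h_x=np.nan,
                                    h_y=np.nan, converged=False, note=str(exc)))
                continue
            bw_rows.append(dict(animal=t.animal_id, method=nm, h_x=bw.h_x,
                                h_y=bw.h_y, converged=bw.converged, note=""))
            for h, score in bw.search_trace:
                trace_rows.append(dict(animal=t.animal_id, h=h, cv_score=score))
        bw = manual_bandwidth(config.manual_h)
        bw_rows.append(dict(animal=t.animal_id, method="manual", h_x=bw.h_x,
                            h_y=bw.h_y, converged=True, note=""))
    artifacts.append(_csv(pd.DataFrame(bw_rows), out / "bandwidths.csv"))
    if trace_rows:
        artifacts.append(_csv(pd.DataFrame(trace_rows), out / "lscv_trace.csv"))
    # isopleth regions and MCP polygons as GeoJSON + metric table
    features = [
        region_to_geojson_feature(
            reg, {"animal": aid, "method": method, "season": season}
        )
        for (aid, method, season, _lvl), reg in result.regions.items()
    ]
    for t in tracks:
        try:
            features.append(
                mcp_to_geojson_feature(
                    percent_mcp(t, config.mcp_percent),
                    {"animal": t.animal_id, "method": "mcp",
                     "percent": config.mcp_percent},
                )
            )
        except Exception:  # noqa: BLE001 - degenerate geometry already flagged
            pass
    write_geojson(out / "regions.geojson", features)
    artifacts.append("regions.geojson")
    artifacts.append(
        _csv(region_metrics_table(result.regions), out / "region_metrics.csv")
    )
    _write_manifest(out, "estimate", config, artifacts)
    return artifacts


def run_evaluate(config: PipelineConfig, out: Path) -> list[str]:
    out.mkdir(parents=True, exist_ok=True)
    result, tracks, grid, habitat = _run_analysis(config, out)
    artifacts = [_csv(result.table, out / "evaluation.csv")]
    sel_rows = []
    for (aid, method, season), df in result.selection.items():
        df = df.assign(animal=aid, method=method, season=season)
        sel_rows.append(df)
    if sel_rows:
        artifacts.append(_csv(pd.concat(sel_rows), out / "selection_ratios.csv"))
    # seasonal overlap of same-method regions
    if config.by_season:
        rows = []
        keys = list(result.regions)
        for i, ka in enumerate(keys):
            for kb in keys[i + 1:]:
                aid, method, sa, lvl = ka
                if (kb[0], kb[1], kb[3]) != (aid, method, lvl) or kb[2] == sa:
                    continue
                if sa == "all" or kb[2] == "all":
                    continue
                j, fa, fb = region_overlap(result.regions[ka], result.regions[kb])
                rows.append(dict(animal=aid, method=method, level=lvl,
                                 season_a=sa, season_b=kb[2], jaccard=j,
                                 frac_a_in_b=fa, frac_b_in_a=fb))
        if rows:
            artifacts.append(_csv(pd.DataFrame(rows), out / "season_overlap.csv"))
    if result.flags:
        flags = pd.DataFrame(result.flags,
                             columns=["animal", "method", "season", "flag"])
        artifacts.append(_csv(flags, out / "flags.csv"))
    _write_manifest(out, "evaluate", config, artifacts)
    return artifacts


def run_report(config: PipelineConfig, out: Path) -> list[str]:
    out.mkdir(parents=True, exist_ok=True)
    artifacts = []
    lines = [
        "rangebridge pipeline report",
        "===========================",
        f"config hash : {config_hash(config)}",
        f"seed        : {config.seed}",
        f"dBBMM window: {config.dbbmm.window}  margin: {config.dbbmm.margin}",
        f"grid        : cell {config.grid.cell_size} m, buffer {config.grid.buffer} m",
        f"methods     : {', '.join(config.methods)}",
        f"isopleths   : {', '.join(f'{100 * l:g}%' for l in config.isopleth_levels)}",
        "",
    ]
    ev_path = out / "evaluation.csv"
    if ev_path.exists():
        table = pd.read_csv(ev_path)
        wide = (
            table[table["season"] == "all"]
            .pivot_table(index=["animal", "method"], columns="metric",
                         values="value", aggfunc="first")
            .round(4)
        )
        lines += ["Full-track evaluation (season = all):", wide.to_string(), ""]
    ms_path = out / "movement_summary.csv"
    if ms_path.exists():
        lines += ["Movement summaries:",
                  pd.read_csv(ms_path).round(2).to_string(index=False), ""]
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    artifacts.append("report.txt")

    prof_path = out / "variance_profiles.csv"
    if prof_path.exists():
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        prof = pd.read_csv(prof_path, parse_dates=["timestamp"])
        fig, ax = plt.subplots(figsize=(9, 4))
        for aid, grp in prof.groupby("animal_id"):
            ax.plot(grp["timestamp"], grp["sigma2m"], lw=0.8, label=str(aid))
        ax.set_ylabel(r"$\sigma^2_m$ (m$^2$/h)")
        ax.set_xlabel("date")
        ax.legend()
        fig.autofmt_xdate()
        fig.tight_layout()
        fig.savefig(out / "sigma2m_timeseries.png", dpi=120)
        plt.close(fig)
        artifacts.append("sigma2m_timeseries.png")
    _write_manifest(out, "report", config, artifacts)
    return artifacts


_STAGES = {
    "simulate": run_simulate,
    "estimate": run_estimate,
    "evaluate": run_evaluate,
    "report": run_report,
}


def run_pipeline(config: PipelineConfig, command: str, out: str | Path) -> list[str]:
    """Run one pipeline stage; returns the artifact names written."""
    if command not in _STAGES:
        raise ConfigurationError(
            f"unknown command {command!r}; expected one of {sorted(_STAGES)}"
        )
    return _STAGES[command](config, Path(out))
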