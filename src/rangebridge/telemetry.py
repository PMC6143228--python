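"""Track data model, CSV ingestion, seasonal labeling, and movement statistics.

Coordinates are assumed to be in a projected metric CRS (e.g. UTM); all
distances are Euclidean and in meters.  The package never reprojects.
Timestamps are stored at second resolution in UTC.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("rangebridge")

#: Default per-axis GPS location-error SD in meters (handheld-GPS accuracy
#: typical of VHF radio-tracking field studies).
DEFAULT_ERROR_SD = 5.5

#: Default stationary-step threshold in meters (~2.7x the default GPS error,
#: separating positional jitter from true movement).
DEFAULT_STOPOVER_THRESHOLD = 15.0


class TrackFormatError(ValueError):
    """Malformed track CSV (missing column, bad timestamp, duplicates)."""


class TrackValidationError(ValueError):
    """Track content violates an invariant (ordering, finiteness)."""


class ConfigurationError(ValueError):
    """Invalid configuration (season schemes, grids, windows ...)."""


class InsufficientDataError(ValueError):
    """Operation needs more relocations than the track provides."""


@dataclass(frozen=True)
class Relocation:
    """One time-stamped fix: UTC timestamp, easting/northing in meters, and
    the per-axis location-error SD (isotropic) in meters."""

    timestamp: pd.Timestamp
    x: float
    y: float
    error_sd: float = DEFAULT_ERROR_SD

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise TrackValidationError("relocation coordinates must be finite")
        if not (self.error_sd >= 0.0):
            raise TrackValidationError("error_sd must be >= 0")


@dataclass(frozen=True)
class Track:
    """Ordered, strictly time-increasing relocations of one animal."""

    animal_id: str
    relocations: tuple[Relocation, ...]
    crs_note: str = "projected metric CRS (unspecified)"

    def __post_init__(self) -> None:
        if len(self.relocations) < 1:
            raise TrackValidationError("a track needs at least one relocation")
        ts = [r.timestamp for r in self.relocations]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise TrackValidationError(
                f"timestamps of track {self.animal_id!r} must be strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.relocations)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex([r.timestamp for r in self.relocations])

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of easting/northing in meters."""
        return np.array([(r.x, r.y) for r in self.relocations], dtype=float)

    @property
    def error_sd(self) -> np.ndarray:
        return np.array([r.error_sd for r in self.relocations], dtype=float)

    @property
    def times_h(self) -> np.ndarray:
        """Elapsed hours since the first fix, one value per relocation."""
        t = self.timestamps
        return (t - t[0]).total_seconds().to_numpy() / 3600.0

    def subset(self, mask: Sequence[bool] | np.ndarray, suffix: str = "") -> "Track":
        """New track keeping relocations where mask is True."""
        kept = tuple(r for r, m in zip(self.relocations, mask) if m)
        if not kept:
            raise InsufficientDataError("subset would produce an empty track")
        return Track(self.animal_id + suffix, kept, self.crs_note)


# ---------------------------------------------------------------------------
# CSV ingestion / export
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("animal_id", "timestamp", "x", "y")


def _parse_timestamps(raw: pd.Series) -> pd.DatetimeIndex:
    parsed = pd.to_datetime(raw, utc=True, errors="coerce", format="ISO8601")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        # +2: one for the header row, one for 0- vs 1-based line numbers
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise TrackFormatError(
            f"non-parseable timestamp {raw[bad].iloc[0]!r} at line {line}"
        )
    return pd.DatetimeIndex(parsed).floor("s")


def read_tracks_csv(
    path: str | Path, error_default: float = DEFAULT_ERROR_SD
) -> list[Track]:
    """Read one or more animals from a track CSV.

    Expected columns: ``animal_id,timestamp,x,y[,error_sd]``.  Rows are
    sorted by timestamp per animal (a warning is logged when re-ordering was
    needed); a missing ``error_sd`` column is filled with *error_default*;
    duplicate timestamps within one animal are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise TrackFormatError(f"track CSV {path} lacks required column {col!r}")
    if "error_sd" not in df.columns:
        df["error_sd"] = float(error_default)
    else:
        df["error_sd"] = df["error_sd"].fillna(float(error_default))
    df["timestamp"] = _parse_timestamps(df["timestamp"])

    tracks: list[Track] = []
    for animal_id, grp in df.groupby("animal_id", sort=True):
        if grp["timestamp"].duplicated().any():
            dup = grp.loc[grp["timestamp"].duplicated(), "timestamp"].iloc[0]
            raise TrackValidationError(
                f"duplicate timestamp {dup} for animal {animal_id!r}"
            )
        if not grp["timestamp"].is_monotonic_increasing:
            logger.warning(
                "track %r rows were out of time order; sorted ascending", animal_id
            )
            grp = grp.sort_values("timestamp", kind="stable")
        relocs = tuple(
            Relocation(ts, float(x), float(y), float(e))
            for ts, x, y, e in zip(
                grp["timestamp"], grp["x"], grp["y"], grp["error_sd"]
            )
        )
        tracks.append(Track(str(animal_id), relocs))
    return tracks


def read_track_csv(path: str | Path, error_default: float = DEFAULT_ERROR_SD) -> Track:
    """Read a single-animal track CSV (see :func:`read_tracks_csv`)."""
    tracks = read_tracks_csv(path, error_default=error_default)
    if len(tracks) != 1:
        raise TrackFormatError(
            f"expected exactly one animal_id in {path}, found {len(tracks)}"
        )
    return tracks[0]


def write_tracks_csv(tracks: Iterable[Track], path: str | Path) -> None:
    """Write tracks to CSV; round-trips losslessly through read_tracks_csv."""
    rows = []
    for tr in tracks:
        for r in tr.relocations:
            rows.append(
                {
                    "animal_id": tr.animal_id,
                    "timestamp": r.timestamp.strftime("%Y-%m-%dT%H:%M:%SZ"),
                    "x": r.x,
                    "y": r.y,
                    "error_sd": r.error_sd,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Seasons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeasonScheme:
    """Named month sets that partition months 1..12."""

    month_sets: Mapping[str, frozenset[int]]

    def __post_init__(self) -> None:
        all_months: list[int] = []
        for name, months in self.month_sets.items():
            if not months:
                raise ConfigurationError(f"season {name!r} has no months")
            all_months.extend(months)
        if sorted(all_months) != list(range(1, 13)):
            raise ConfigurationError(
                "season month sets must partition months 1-12 exactly"
            )

    def season_of_month(self, month: int) -> str:
        for name, months in self.month_sets.items():
            if month in months:
                return name
        raise ConfigurationError(f"month {month} not covered by scheme")


def _scheme(d: dict[str, Iterable[int]]) -> SeasonScheme:
    return SeasonScheme({k: frozenset(v) for k, v in d.items()})


#: Field-calendar seasons: cold Dec-Feb, dry Mar-Jun, rainy Jul-Nov
#: (unequal lengths; the study-site convention).
DEFAULT_SEASONS = _scheme(
    {"cold": {12, 1, 2}, "dry": {3, 4, 5, 6}, "rainy": {7, 8, 9, 10, 11}}
)

#: Alternative equal-length splitter: three 4-month seasons anchored on the
#: same cold-season onset (December).
EQUAL_SEASONS = _scheme(
    {"cold": {12, 1, 2, 3}, "dry": {4, 5, 6, 7}, "rainy": {8, 9, 10, 11}}
)


def assign_seasons(track: Track, scheme: SeasonScheme = DEFAULT_SEASONS) -> list[str]:
    """Label every relocation with its season (a function of month only)."""
    return [scheme.season_of_month(r.timestamp.month) for r in track.relocations]


# ---------------------------------------------------------------------------
# Movement statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MovementSummary:
    animal_id: str
    n_fixes: int
    mean_step_m: float
    max_step_m: float
    total_path_m: float
    max_displacement_m: float
    stopover_fraction: float
    tracking_days: float


def movement_summary(
    track: Track, stopover_threshold: float = DEFAULT_STOPOVER_THRESHOLD
) -> MovementSummary:
    """Descriptive movement statistics over consecutive-fix Euclidean steps.

    stopover_fraction is the fraction of steps shorter than
    *stopover_threshold* (stationary shelter use vs. true movement).
    """
    if len(track) < 2:
        raise InsufficientDataError("movement_summary needs at least 2 relocations")
    xy = track.xy
    steps = np.hypot(*np.diff(xy, axis=0).T)
    displacement = np.hypot(xy[:, 0] - xy[0, 0], xy[:, 1] - xy[0, 1])
    span = track.timestamps[-1] - track.timestamps[0]
    return MovementSummary(
        animal_id=track.animal_id,
        n_fixes=len(track),
        mean_step_m=float(steps.mean()),
        max_step_m=float(steps.max()),
        total_path_m=float(steps.sum()),
        max_displacement_m=float(displacement.max()),
        stopover_fraction=float((steps < stopover_threshold).mean()),
        tracking_days=float(span.total_seconds() / 86400.0),
    )


def movement_summary_table(
    tracks: Iterable[Track], stopover_threshold: float = DEFAULT_STOPOVER_THRESHOLD
) -> pd.DataFrame:
    """One MovementSummary row per animal, as a DataFrame."""
    return pd.DataFrame(
        [dataclasses.asdict(movement_summary(t, stopover_threshold)) for t in tracks]
    )
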