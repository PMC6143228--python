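"""Shared fixtures: handmade tracks and the default two-animal study fixture."""

from __future__ import annotations

import dataclasses
from datetime import date

import numpy as np
import pandas as pd
import pytest

import rangebridge as rb
from rangebridge.simulate import (
    BehaviorState,
    SimConfig,
    default_study_configs,
    generate_habitat_map,
    simulate_track,
)


def make_track(
    points,
    dt_h: float = 1.0,
    error_sd: float = 0.0,
    animal_id: str = "T",
    times_h=None,
) -> rb.Track:
    """Track from a coordinate list with regular (or explicit) fix times."""
    points = np.asarray(points, dtype=float)
    if times_h is None:
        times_h = np.arange(len(points)) * dt_h
    t0 = pd.Timestamp("2020-01-01", tz="UTC")
    relocs = tuple(
        rb.Relocation(t0 + pd.Timedelta(hours=float(h)), float(x), float(y), error_sd)
        for h, (x, y) in zip(times_h, points)
    )
    return rb.Track(animal_id, relocs)


def brownian_track(
    sigma2m: float,
    n_steps: int,
    dt_h: float = 1.0,
    error_sd: float = 0.0,
    seed: int = 0,
    animal_id: str = "BM",
) -> rb.Track:
    """Pure single-state Brownian track (no diurnal structure)."""
    rng = np.random.default_rng(seed)
    inc = rng.normal(0.0, np.sqrt(sigma2m * dt_h), size=(n_steps, 2))
    xy = np.vstack([[0.0, 0.0], np.cumsum(inc, axis=0)])
    if error_sd > 0:
        xy = xy + rng.normal(0.0, error_sd, size=xy.shape)
    return make_track(xy, dt_h=dt_h, error_sd=error_sd, animal_id=animal_id)


def two_state_config(seed: int, n_days: int = 50) -> SimConfig:
    """Hourly two-state fixture with a true sigma2m ratio of 10:1."""
    return SimConfig(
        animal_id=f"TS{seed}",
        states=(
            BehaviorState("low", 5.0, 100.0),
            BehaviorState("high", 50.0, 100.0),
        ),
        schedule=tuple(np.arange(24.0).tolist()),
        start=date(2014, 3, 1),
        end=date(2014, 3, 1) + pd.Timedelta(days=n_days).to_pytimedelta(),
        error_sd=0.0,
        cold_season_fixes_per_day=24,
        diurnal_rest=False,
        seed=seed,
    )


@pytest.fixture(scope="session")
def study_fixture():
    """The default two-animal stopover fixture with habitat and grid."""
    configs = default_study_configs(0)
    pairs = [simulate_track(c) for c in configs]
    tracks = [t for t, _ in pairs]
    truths = [tr for _, tr in pairs]
    grid = rb.make_reference_grid(tracks, 15.0, 250.0)
    habitat = generate_habitat_map(
        sorted(dict(rb.simulate.DEFAULT_HABITATS).items()), grid, 300.0, seed=17
    )
    return dict(tracks=tracks, truths=truths, grid=grid, habitat=habitat)


@pytest.fixture(scope="session")
def study_comparison(study_fixture):
    """Full cross-method comparison on the default fixture (computed once)."""
    return rb.compare_estimators(
        study_fixture["tracks"],
        study_fixture["grid"],
        habitat=study_fixture["habitat"],
    )
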