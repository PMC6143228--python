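"""Brownian bridge movement models (BBMM) and the dynamic variant (dBBMM).

The Brownian motion variance sigma^2_m (m^2/h) quantifies path
irregularity/mobility.  It is estimated by maximum likelihood on a
leave-one-out construction: every second interior fix is predicted by the
Brownian bridge spanning its two neighbors,

    alpha_i = (t_i - t_{i-1}) / (t_{i+1} - t_{i-1})
    mu_i    = z_{i-1} + alpha_i (z_{i+1} - z_{i-1})
    v_i     = (t_{i+1} - t_{i-1}) alpha_i (1 - alpha_i) sigma2m
              + (1 - alpha_i)^2 delta_{i-1}^2 + alpha_i^2 delta_{i+1}^2
              + delta_i^2

where delta are per-fix GPS error SDs.  The observed middle fix's own
error delta_i^2 is added because the observation is the bridge value plus
independent GPS noise.  The alternating (odd) interior index set keeps any
fix from serving as both predictor and predictand.

The dynamic model slides a window of ``window`` fixes along the track and,
per window, compares a single-sigma2m model against a one-breakpoint model
(sigma2m estimated separately per part) by BIC over the window's
leave-one-out terms; per-fix sigma2m is averaged over all windows scoring
that fix.  UDs integrate the bridge density over each interval (trapezoid
rule in the bridge position alpha), weight intervals by duration, and
normalize on the shared reference grid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .grids import GridSpec, UDRaster
from .telemetry import (
    ConfigurationError,
    InsufficientDataError,
    Track,
)

logger = logging.getLogger("rangebridge")

TWO_PI = 2.0 * math.pi

#: Bridge evaluation is truncated beyond this many SDs of a node's mean
#: (mass error < 1e-5 per node).
TRUNCATE_SD = 4.5


@dataclass(frozen=True)
class BridgeParams:
    """One bridge segment: total lag T (h), position alpha in [0, 1],
    endpoint GPS error SDs (m), and motion variance sigma2m (m^2/h)."""

    T: float
    alpha: float
    delta_start: float
    delta_end: float
    sigma2m: float

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ConfigurationError("bridge lag T must be positive")
        if not (0.0 <= self.alpha <= 1.0):
            raise ConfigurationError("alpha must lie in [0, 1]")
        if self.sigma2m < 0:
            raise ConfigurationError("sigma2m must be >= 0")

    @property
    def variance(self) -> float:
        """Per-axis bridge variance s(alpha) in m^2."""
        a = self.alpha
        return (
            self.T * a * (1.0 - a) * self.sigma2m
            + (1.0 - a) ** 2 * self.delta_start**2
            + a**2 * self.delta_end**2
        )


def bridge_density(
    params: BridgeParams,
    start: tuple[float, float],
    end: tuple[float, float],
    at: tuple[float, float],
) -> float:
    """Isotropic bivariate normal bridge density (per m^2) at ``at``.

    When s(alpha) = 0 the bridge is a point mass: density is 0 except at
    the mean itself, where 0.0 is returned as a documented sentinel (the
    true density is a Dirac delta; UD construction handles this case by
    assigning the cell mass directly).
    """
    a = params.alpha
    mx = start[0] + a * (end[0] - start[0])
    my = start[1] + a * (end[1] - start[1])
    s = params.variance
    d2 = (at[0] - mx) ** 2 + (at[1] - my) ** 2
    if s == 0.0:
        return 0.0
    return math.exp(-d2 / (2.0 * s)) / (TWO_PI * s)


# ---------------------------------------------------------------------------
# Leave-one-out likelihood machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _LooTerms:
    """Precomputed leave-one-out constants for interior fixes 1..n-2.

    For interior fix i the per-axis variance is v_i = a_i*sigma2m + c_i and
    the squared deviation from the bridge mean is d2_i.  Arrays are indexed
    by j = i - 1.
    """

    a: np.ndarray
    c: np.ndarray
    d2: np.ndarray

    @property
    def n_interior(self) -> int:
        return len(self.a)


def _loo_terms(track: Track) -> _LooTerms:
    t = track.times_h
    z = track.xy
    d = track.error_sd
    t0, t1, t2 = t[:-2], t[1:-1], t[2:]
    tt = t2 - t0
    alpha = (t1 - t0) / tt
    mu = z[:-2] + alpha[:, None] * (z[2:] - z[:-2])
    dev = z[1:-1] - mu
    return _LooTerms(
        a=tt * alpha * (1.0 - alpha),
        c=(1.0 - alpha) ** 2 * d[:-2] ** 2 + alpha**2 * d[2:] ** 2 + d[1:-1] ** 2,
        d2=(dev**2).sum(axis=1),
    )


def default_index_set(n: int, start: int = 1) -> np.ndarray:
    """Alternating interior fix indices (1, 3, 5, ...) for an n-fix track."""
    return np.arange(start, n - 1, 2)


def _nll_from_terms(terms: _LooTerms, sigma2m: float, idx: np.ndarray) -> float:
    """Negative log likelihood of the isotropic bivariate bridge normals."""
    j = idx - 1
    v = terms.a[j] * sigma2m + terms.c[j]
    d2 = terms.d2[j]
    if (v <= 0).any():
        # degenerate bridge variance: flagged as an infinite penalty
        return math.inf
    return float((np.log(TWO_PI * v) + d2 / (2.0 * v)).sum())


def loo_neg_log_likelihood(
    track: Track, sigma2m: float, index_set: Sequence[int] | None = None
) -> float:
    """Leave-one-out negative log likelihood of sigma2m on a track.

    ``index_set`` defaults to every second interior fix (1, 3, 5, ...).
    """
    n = len(track)
    if n < 3:
        raise InsufficientDataError("need >= 3 relocations for the LOO likelihood")
    if sigma2m < 0:
        raise ConfigurationError("sigma2m must be >= 0")
    idx = (
        np.asarray(index_set, dtype=int)
        if index_set is not None
        else default_index_set(n)
    )
    if len(idx) == 0 or idx.min() < 1 or idx.max() > n - 2:
        raise ConfigurationError("index_set must contain interior indices only")
    return _nll_from_terms(_loo_terms(track), sigma2m, idx)


@dataclass(frozen=True)
class Sigma2mEstimate:
    value: float  # m^2/h
    nll: float
    at_bound: bool
    bracket: tuple[float, float]

    def __float__(self) -> float:
        return self.value


def _default_bracket(track: Track) -> tuple[float, float]:
    steps = np.hypot(*np.diff(track.xy, axis=0).T)
    lags = np.diff(track.times_h)
    hi = 10.0 * float(steps.max()) ** 2 / float(lags.min())
    return (1e-8, max(hi, 1e-6))


def _minimize_sigma2m(
    terms: _LooTerms, idx: np.ndarray, bracket: tuple[float, float]
) -> Sigma2mEstimate:
    lo, hi = bracket
    if not (0 <= lo < hi):
        raise ConfigurationError("invalid sigma2m bracket")
    lo = max(lo, 1e-12)
    log_lo, log_hi = math.log(lo), math.log(hi)
    res = minimize_scalar(
        lambda u: _nll_from_terms(terms, math.exp(u), idx),
        bounds=(log_lo, log_hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    u = float(res.x)
    at_bound = u - log_lo < 1e-4 or log_hi - u < 1e-4
    return Sigma2mEstimate(math.exp(u), float(res.fun), at_bound, (lo, hi))


def estimate_sigma2m(
    track: Track,
    bracket: tuple[float, float] | None = None,
    index_set: Sequence[int] | None = None,
) -> Sigma2mEstimate:
    """Maximum-likelihood Brownian motion variance (m^2/h) on a track.

    Bounded scalar optimization (in log space) within ``bracket``; default
    bracket is [1e-8, 10 * max_step^2 / min_lag].  A solution at either
    bracket end is flagged via ``at_bound``.
    """
    n = len(track)
    if n < 3:
        raise InsufficientDataError("need >= 3 relocations to estimate sigma2m")
    idx = (
        np.asarray(index_set, dtype=int)
        if index_set is not None
        else default_index_set(n)
    )
    est = _minimize_sigma2m(_loo_terms(track), idx, bracket or _default_bracket(track))
    if est.at_bound:
        logger.warning(
            "sigma2m estimate %.4g for %r is at the bracket boundary %s",
            est.value,
            track.animal_id,
            est.bracket,
        )
    return est


# ---------------------------------------------------------------------------
# Dynamic variance profile (sliding window + change point)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DbbmmConfig:
    window: int = 11
    margin: int = 3
    criterion: str = "bic"
    max_lag_h: float | None = None

    def __post_init__(self) -> None:
        if self.margin < 1:
            raise ConfigurationError("margin must be >= 1")
        if self.window < 2 * self.margin + 1:
            raise ConfigurationError("window must be >= 2*margin + 1")
        if self.criterion.lower() != "bic":
            raise ConfigurationError(f"unknown criterion {self.criterion!r}")


@dataclass(frozen=True)
class VarianceProfile:
    """Per-location and per-interval sigma2m (m^2/h) along a track."""

    per_location: np.ndarray  # (n,)
    per_interval: np.ndarray  # (n-1,)
    window: int
    margin: int
    n_breaks: int  # windows where the one-breakpoint model won

    def __post_init__(self) -> None:
        if (self.per_location < 0).any() or (self.per_interval < 0).any():
            raise ConfigurationError("variance profile must be nonnegative")
        if len(self.per_interval) != len(self.per_location) - 1:
            raise ConfigurationError("profile lengths are inconsistent")

    @classmethod
    def constant(cls, sigma2m: float, n: int) -> "VarianceProfile":
        return cls(
            np.full(n, float(sigma2m)), np.full(n - 1, float(sigma2m)), n, 0, 0
        )


def dbbmm_variance_profile(track: Track, config: DbbmmConfig | None = None) -> VarianceProfile:
    """Sliding-window change-point estimate of sigma2m along a track.

    Per window of ``window`` consecutive fixes, a single-variance model is
    compared (BIC over the window's alternating leave-one-out terms; ties
    favor no breakpoint) against every one-breakpoint split leaving at
    least ``margin`` fixes on both sides, each part's sigma2m maximized
    over the leave-one-out terms centered in that part.  Every non-margin
    fix of the window records the sigma2m of its part under the winning
    model; the final per-location value is the mean over all windows
    scoring that fix, with the unscored track ends inheriting the nearest
    scored value.  Per-interval sigma2m is the mean of its endpoints.
    """
    config = config or DbbmmConfig()
    n = len(track)
    W, m = config.window, config.margin
    if n < W:
        raise InsufficientDataError(
            f"track has {n} fixes; window of {W} needs at least that many"
        )
    terms = _loo_terms(track)
    bracket = _default_bracket(track)
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    n_breaks = 0

    for s in range(n - W + 1):
        # window term set: every second interior fix of the window
        t_all = np.arange(s + 1, s + W - 1, 2)
        est0 = _minimize_sigma2m(terms, t_all, bracket)
        k_terms = len(t_all)
        bic0 = 2.0 * est0.nll + 1.0 * math.log(k_terms)

        best = None  # (bic, b, sig1, sig2)
        for b in range(m, W - m + 1):  # part1 = fixes [s, s+b), part2 = rest
            t1 = t_all[t_all < s + b]
            t2 = t_all[t_all >= s + b]
            if len(t1) == 0 or len(t2) == 0:
                continue
            e1 = _minimize_sigma2m(terms, t1, bracket)
            e2 = _minimize_sigma2m(terms, t2, bracket)
            bic = 2.0 * (e1.nll + e2.nll) + 2.0 * math.log(k_terms)
            if best is None or bic < best[0]:
                best = (bic, b, e1.value, e2.value)

        lo_fix, hi_fix = s + m, s + W - m  # non-margin fixes [lo, hi)
        if best is not None and best[0] < bic0 - 1e-9:
            n_breaks += 1
            _, b, sig1, sig2 = best
            for p in range(lo_fix, hi_fix):
                sums[p] += sig1 if p < s + b else sig2
                counts[p] += 1
        else:
            sums[lo_fix:hi_fix] += est0.value
            counts[lo_fix:hi_fix] += 1

    per_loc = np.full(n, np.nan)
    scored = counts > 0
    per_loc[scored] = sums[scored] / counts[scored]
    # track ends never scored inherit the nearest scored value
    scored_idx = np.flatnonzero(scored)
    first, last = scored_idx[0], scored_idx[-1]
    per_loc[:first] = per_loc[first]
    per_loc[last + 1 :] = per_loc[last]
    per_int = 0.5 * (per_loc[:-1] + per_loc[1:])
    return VarianceProfile(per_loc, per_int, W, m, n_breaks)


# ---------------------------------------------------------------------------
# Bridge-integrated utilization distributions
# ---------------------------------------------------------------------------

def compute_bb_ud(
    track: Track,
    profile: VarianceProfile | float,
    grid: GridSpec,
    n_alpha: int = 25,
    max_lag_h: float | None = None,
) -> UDRaster:
    """Bridge-integrated UD on the reference grid.

    ``profile`` is either a constant sigma2m (BBMM) or a VarianceProfile
    (dBBMM).  Each interval's bridge density is averaged over ``n_alpha``
    equally spaced alpha nodes with trapezoid weights, the interval is
    weighted by its duration, and intervals longer than ``max_lag_h`` (when
    given) are excluded and logged.  The evaluation of each node is
    truncated beyond 4.5 SD; the result is renormalized to mass 1.
    """
    n = len(track)
    if n < 2:
        raise InsufficientDataError("need >= 2 relocations to build a bridge UD")
    if n_alpha < 2:
        raise ConfigurationError("n_alpha must be >= 2")
    xy = track.xy
    if not grid.contains(xy[:, 0], xy[:, 1]).all():
        raise ConfigurationError("grid does not cover all relocations")
    sig = (
        profile.per_interval
        if isinstance(profile, VarianceProfile)
        else np.full(n - 1, float(profile))
    )
    if len(sig) != n - 1:
        raise ConfigurationError("variance profile is not aligned to the track")
    delta = track.error_sd
    lags = np.diff(track.times_h)

    alphas = np.linspace(0.0, 1.0, n_alpha)
    w_alpha = np.ones(n_alpha)
    w_alpha[0] = w_alpha[-1] = 0.5
    w_alpha /= w_alpha.sum()

    xc, yc = grid.x_centers, grid.y_centers
    cs = grid.cell_size
    acc = np.zeros(grid.shape)
    n_skipped = 0
    for i in range(n - 1):
        T = lags[i]
        if max_lag_h is not None and T > max_lag_h:
            n_skipped += 1
            continue
        z0, z1 = xy[i], xy[i + 1]
        d0, d1 = delta[i], delta[i + 1]
        for a, w in zip(alphas, w_alpha):
            mx = z0[0] + a * (z1[0] - z0[0])
            my = z0[1] + a * (z1[1] - z0[1])
            s = T * a * (1.0 - a) * sig[i] + (1.0 - a) ** 2 * d0**2 + a**2 * d1**2
            wt = w * T
            if s <= 0.0:
                row, col = grid.cell_of(mx, my)
                acc[int(row), int(col)] += wt / grid.cell_area_m2
                continue
            sd = math.sqrt(s)
            r = TRUNCATE_SD * sd
            c0 = max(0, int((mx - r - grid.origin_x) // cs))
            c1 = min(grid.n_cols, int((mx + r - grid.origin_x) // cs) + 1)
            r0 = max(0, int((my - r - grid.origin_y) // cs))
            r1 = min(grid.n_rows, int((my + r - grid.origin_y) // cs) + 1)
            if c0 >= c1 or r0 >= r1:
                continue
            gx = np.exp(-0.5 * ((xc[c0:c1] - mx) / sd) ** 2)
            gy = np.exp(-0.5 * ((yc[r0:r1] - my) / sd) ** 2)
            acc[r0:r1, c0:c1] += (wt / (TWO_PI * s)) * np.outer(gy, gx)
    if n_skipped:
        logger.info("compute_bb_ud: excluded %d intervals longer than %s h",
                    n_skipped, max_lag_h)
    mass = acc * grid.cell_area_m2
    total = mass.sum()
    if total <= 0:
        raise ConfigurationError("bridge UD mass vanished on this grid")
    return UDRaster(grid, mass / total)
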