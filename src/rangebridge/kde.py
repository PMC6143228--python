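"""Fixed bivariate kernel density estimation with four bandwidth selectors.

Selectors
---------
href      ad hoc bivariate normal-reference rule,
          h = sqrt((var_x + var_y)/2) * n^(-1/6), one common h per axis.
lscv      least-squares cross-validation over a multiplicative grid around
          href; the LSCV score has the closed pairwise form
          CV(h) = (1/(4 pi h^2 n^2)) * sum_ij exp(-d_ij^2 / (4 h^2))
                  - (2/(2 pi h^2 n (n-1))) * sum_{i != j} exp(-d_ij^2 / (2 h^2)).
          A minimizer on the grid boundary is reported as non-convergence
          (the classic failure mode with many duplicated/clustered fixes).
plugin    per-axis two-stage direct plug-in (Sheather-Jones family) with a
          normal-reference start for the 8th-derivative functional.
manual    user-chosen h (the "h100" convention: a round value, default
          100 m, picked to approximate a movement-model home range).

The UD is the product-Gaussian mixture evaluated at cell centers, converted
to cell masses and renormalized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .grids import GridSpec, UDRaster
from .telemetry import ConfigurationError, InsufficientDataError, Track


class DegenerateDataError(ValueError):
    """No spread in the data: bandwidth selection impossible."""


@dataclass(frozen=True)
class BandwidthSpec:
    method: str  # href | lscv | plugin | manual
    h_x: float
    h_y: float
    converged: bool = True
    search_trace: tuple[tuple[float, float], ...] = ()  # (h, score) pairs

    def __post_init__(self) -> None:
        if self.converged and not (self.h_x > 0 and self.h_y > 0):
            raise ConfigurationError("converged bandwidths must be positive")


def manual_bandwidth(h: float = 100.0) -> BandwidthSpec:
    """Manually selected common bandwidth (default 100 m, 'h100')."""
    if h <= 0:
        raise ConfigurationError("manual bandwidth must be positive")
    return BandwidthSpec("manual", h, h)


def href_bandwidth(track: Track) -> BandwidthSpec:
    """Bivariate normal-reference rule: sqrt(mean per-axis var) * n^(-1/6)."""
    xy = track.xy
    n = len(xy)
    if n < 2:
        raise InsufficientDataError("href needs at least 2 relocations")
    var = xy.var(axis=0, ddof=1)
    s2 = 0.5 * (var[0] + var[1])
    if s2 <= 0:
        raise DegenerateDataError("all relocations identical; href undefined")
    h = math.sqrt(s2) * n ** (-1.0 / 6.0)
    return BandwidthSpec("href", h, h)


def lscv_score(d2: np.ndarray, n: int, h: float) -> float:
    """Closed-form least-squares CV criterion for a common-h Gaussian kernel.

    ``d2``: condensed squared pairwise distances (i < j), ``n``: sample size.
    """
    h2 = h * h
    int_f2 = (n + 2.0 * np.exp(-d2 / (4.0 * h2)).sum()) / (4.0 * math.pi * h2 * n * n)
    loo = np.exp(-d2 / (2.0 * h2)).sum() / (math.pi * h2 * n * (n - 1.0))
    return float(int_f2 - 2.0 * loo)


def lscv_bandwidth(
    track: Track,
    grid_points: int = 100,
    span: tuple[float, float] = (0.05, 2.0),
) -> BandwidthSpec:
    """Least-squares cross-validation over a log-spaced multiplicative grid
    ``span`` x href.  converged=False when the minimizer sits on either grid
    boundary (undersmoothing collapse or monotone score)."""
    n = len(track)
    if n < 5:
        raise InsufficientDataError("LSCV needs at least 5 relocations")
    h_ref = href_bandwidth(track).h_x
    d2 = pdist(track.xy, "sqeuclidean")
    hs = h_ref * np.logspace(math.log10(span[0]), math.log10(span[1]), grid_points)
    scores = np.array([lscv_score(d2, n, h) for h in hs])
    k = int(np.argmin(scores))
    converged = 0 < k < len(hs) - 1
    return BandwidthSpec(
        "lscv",
        float(hs[k]),
        float(hs[k]),
        converged=converged,
        search_trace=tuple(zip(hs.tolist(), scores.tolist())),
    )


# ---- two-stage direct plug-in (univariate, per axis) ----------------------

_SQRT2PI = math.sqrt(2.0 * math.pi)


def _phi_deriv_sum(x: np.ndarray, g: float, order: int, chunk: int = 256) -> float:
    """sum_ij K^(order)((x_i - x_j)/g) for the Gaussian kernel, including the
    diagonal, via the Hermite-polynomial form of phi derivatives.  Evaluated
    in row blocks to keep memory O(chunk * n)."""
    total = 0.0
    for start in range(0, len(x), chunk):
        u = (x[start : start + chunk, None] - x[None, :]) / g
        u2 = u * u
        if order == 4:
            poly = u2 * u2 - 6.0 * u2 + 3.0
        elif order == 6:
            poly = u2 * u2 * u2 - 15.0 * u2 * u2 + 45.0 * u2 - 15.0
        else:  # pragma: no cover
            raise ValueError(order)
        total += float((np.exp(-0.5 * u2) / _SQRT2PI * poly).sum())
    return total


def _dpik(x: np.ndarray) -> float:
    """Two-stage direct plug-in bandwidth for one axis (Gaussian kernel)."""
    n = len(x)
    sd = x.std(ddof=1)
    if sd <= 0:
        raise DegenerateDataError("zero variance on one axis; plug-in undefined")
    # stage 0: normal reference for psi_8
    psi8 = 105.0 / (32.0 * math.sqrt(math.pi) * sd**9)
    # stage 1: estimate psi_6 with bandwidth g1
    k6_0 = -15.0 / _SQRT2PI
    g1 = (-2.0 * k6_0 / (psi8 * n)) ** (1.0 / 9.0)
    psi6 = _phi_deriv_sum(x, g1, 6) / (n * n * g1**7)
    # stage 2: estimate psi_4 with bandwidth g2
    k4_0 = 3.0 / _SQRT2PI
    g2 = (-2.0 * k4_0 / (psi6 * n)) ** (1.0 / 7.0)
    psi4 = _phi_deriv_sum(x, g2, 4) / (n * n * g2**5)
    # final AMISE-optimal h: R(K)=1/(2 sqrt(pi)), mu_2(K)=1
    return (1.0 / (2.0 * math.sqrt(math.pi) * psi4 * n)) ** 0.2


def plugin_bandwidth(track: Track) -> BandwidthSpec:
    """Per-axis two-stage direct plug-in bandwidths (Gaussian kernel)."""
    n = len(track)
    if n < 10:
        raise InsufficientDataError("plug-in needs at least 10 relocations")
    xy = track.xy
    return BandwidthSpec("plugin", _dpik(xy[:, 0]), _dpik(xy[:, 1]))


# ---- UD construction ------------------------------------------------------

def kde_ud(track: Track, bw: BandwidthSpec, grid: GridSpec) -> UDRaster:
    """Product-Gaussian mixture evaluated at cell centers -> normalized
    cell masses on the shared reference grid."""
    if not bw.converged:
        raise ConfigurationError(
            f"bandwidth ({bw.method}) did not converge; no UD is defined"
        )
    xy = track.xy
    if not grid.contains(xy[:, 0], xy[:, 1]).all():
        raise ConfigurationError("grid does not cover all relocations")
    gx = np.exp(
        -0.5 * ((grid.x_centers[None, :] - xy[:, 0][:, None]) / bw.h_x) ** 2
    )
    gy = np.exp(
        -0.5 * ((grid.y_centers[None, :] - xy[:, 1][:, None]) / bw.h_y) ** 2
    )
    dens = gy.T @ gx  # (n_rows, n_cols)
    dens /= 2.0 * math.pi * bw.h_x * bw.h_y * len(xy)
    mass = dens * grid.cell_area_m2
    total = mass.sum()
    if total <= 0:
        raise DegenerateDataError("KDE mass vanished on this grid")
    return UDRaster(grid, mass / total)


def match_bandwidth_to_area(
    track: Track,
    grid: GridSpec,
    target_area_ha: float,
    level: float = 0.95,
    tol: float = 0.02,
    max_iter: int = 40,
) -> BandwidthSpec:
    """Manual-bandwidth helper: bisect h so the KDE's ``level`` isopleth
    area approximates ``target_area_ha`` (e.g. a movement-model home range).

    Isopleth area grows monotonically with h on the scales of interest;
    returns the best h found within ``tol`` relative area error (or after
    ``max_iter`` bisections, flagged via converged=False).
    """
    from .grids import isopleth_region

    def area(h: float) -> float:
        return isopleth_region(kde_ud(track, manual_bandwidth(h), grid), level).area_ha

    lo, hi = grid.cell_size / 4.0, 10.0 * href_bandwidth(track).h_x
    if not (area(lo) <= target_area_ha <= area(hi)):
        raise ConfigurationError(
            "target area is outside the range achievable on this grid"
        )
    h = lo
    for _ in range(max_iter):
        h = math.sqrt(lo * hi)
        a = area(h)
        if abs(a - target_area_ha) <= tol * target_area_ha:
            return BandwidthSpec("manual", h, h)
        if a < target_area_ha:
            lo = h
        else:
            hi = h
    return BandwidthSpec("manual", h, h, converged=False)
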