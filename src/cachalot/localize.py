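"""Bearing estimation, 2D target motion analysis, and click depth.

A towed linear pair only resolves the conical angle θ between an arrival
and the array axis; intersecting the bearing cones measured from many
positions along the track (target motion analysis, TMA) yields a 2D
position under a stationary-source, surface-target model. Because the
cone encodes the full 3D direction, the TMA "perpendicular distance" of
a deep whale is really a perpendicular *slant* range — biased high for
whales near the trackline, which is exactly the bias the depth
correction in :mod:`cachalot.distance` removes.

Depth itself comes from the slant delay τ between the direct click and
its surface-reflected echo. With the hydrophone at depth h, a whale at
depth z and direct-path (radial) distance D, the image-source geometry
gives ``(D + cτ)² − D² = 4 z h``, hence the closed form

    z = c·τ·(2D + c·τ) / (4h).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .simulate import BathymetryGrid

__all__ = [
    "BearingSeries",
    "Localization2D",
    "ClickDepth",
    "EventDepthSummary",
    "DepthRejectionReason",
    "bearing_from_delay",
    "tma_simplex",
    "truncate_events",
    "click_depth",
    "event_depth_summary",
    "reject_by_seafloor",
]

MAX_CLICK_DEPTH_M = 4000.0
TRUNCATION_M = 6500.0
MIN_CLICKS_PER_EVENT = 8
#: residual RMS (radians) above which a TMA solution counts as non-converged
TMA_RESIDUAL_MAX_RAD = np.deg2rad(5.0)


class DepthRejectionReason(str, enum.Enum):
    none = "none"
    exceeds_seafloor = "exceeds_seafloor"
    too_few_clicks = "too_few_clicks"


@dataclass
class BearingSeries:
    """Per-click conical bearings with the array position at each click."""

    times_s: np.ndarray
    theta_rad: np.ndarray  # angle from array axis, [0, pi]
    array_x_m: np.ndarray  # hydrophone along-track position at click time
    array_depth_m: float = 7.5

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.theta_rad = np.asarray(self.theta_rad, dtype=float)
        self.array_x_m = np.asarray(self.array_x_m, dtype=float)
        if not (self.times_s.size == self.theta_rad.size == self.array_x_m.size):
            raise ValueError("times, bearings and array positions must align")
        if np.any(self.theta_rad < 0) or np.any(self.theta_rad > np.pi):
            raise ValueError("conical bearings must lie in [0, pi]")


@dataclass
class Localization2D:
    """2D TMA solution: planar position and perpendicular slant range."""

    x_m: float
    y_m: float
    slant_range_m: float
    error_m: float
    converged: bool
    residual_rms_rad: float = np.nan


@dataclass
class ClickDepth:
    """Depth of a single click with delta-method variance components."""

    z_m: float
    variance_m2: float = 0.0
    truncated: bool = False
    variance_components: dict = field(default_factory=dict)


@dataclass
class EventDepthSummary:
    """Average click depth of an event with propagated uncertainty."""

    n_clicks_with_tau: int
    average_depth_m: float
    sd_m: float
    accepted: bool
    rejection_reason: DepthRejectionReason = DepthRejectionReason.none


def bearing_from_delay(delta_t_s, pair_spacing_m: float, c: float):
    """Conical bearing θ = arccos(c·Δt / spacing) from a pair delay.

    Delays implying |cos θ| > 1 (physically impossible for a plane wave)
    are clipped to the endfire directions with a warning.
    """
    if pair_spacing_m <= 0:
        raise ValueError("pair spacing must be positive")
    if c <= 0:
        raise ValueError("sound speed must be positive")
    ratio = np.asarray(delta_t_s, dtype=float) * c / pair_spacing_m
    if np.any(np.abs(ratio) > 1):
        warnings.warn("bearing delay exceeds endfire; clipping", stacklevel=2)
        ratio = np.clip(ratio, -1.0, 1.0)
    theta = np.arccos(ratio)
    return float(theta) if theta.ndim == 0 else theta


def _predicted_theta(x: float, y: float, array_x: np.ndarray) -> np.ndarray:
    dx = x - array_x
    rng = np.hypot(dx, y)
    with np.errstate(invalid="ignore"):
        ct = np.where(rng > 0, dx / np.maximum(rng, 1e-12), 0.0)
    return np.arccos(np.clip(ct, -1.0, 1.0))


def tma_simplex(
    bearings: BearingSeries,
    n_restarts: int = 5,
    seed: int = 0,
    xatol_m: float = 1e-3,
) -> Localization2D:
    """2D target motion analysis by Nelder–Mead bearing-residual descent.

    Minimizes ``Σ (θ_obs − θ_pred(x, y))²`` over the planar position of a
    stationary source at the surface. Restarts from a coarse
    first/last-bearing triangulation plus random perturbations. A
    solution is flagged non-converged when the optimizer fails or the
    bearing residual RMS exceeds 5°.

    Raises :class:`ValueError` with fewer than 3 bearings or less than
    100 m of track spanned (the event is not localizable).
    """
    ax = bearings.array_x_m
    th = bearings.theta_rad
    if ax.size < 3:
        raise ValueError("need at least 3 bearings for TMA")
    if ax.max() - ax.min() < 100.0:
        raise ValueError("bearings must span at least 100 m of track")

    def cost(p: np.ndarray) -> float:
        r = th - _predicted_theta(p[0], p[1], ax)
        return float(np.dot(r, r))

    # crude triangulation of first/last bearings for the initial vertex
    x0, x1 = ax[0], ax[-1]
    t0, t1 = th[0], th[-1]
    denom = 1.0 / np.tan(t0) - 1.0 / np.tan(t1) if (t0 % np.pi) and (t1 % np.pi) else 0.0
    if denom:
        y_init = abs((x1 - x0) / denom)
        x_init = x0 + y_init / np.tan(t0)
    else:
        y_init = 1000.0
        x_init = 0.5 * (x0 + x1)
    y_init = float(np.clip(y_init, 10.0, 50_000.0))

    rng = np.random.default_rng(seed)
    best = None
    starts = [(x_init, y_init)]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(
            (x_init + rng.normal(0, 500.0), max(10.0, y_init * rng.uniform(0.3, 3.0)))
        )
    ok = False
    for p0 in starts:
        res = optimize.minimize(
            cost,
            np.asarray(p0, dtype=float),
            method="Nelder-Mead",
            options={"xatol": xatol_m, "fatol": 1e-12, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
            ok = bool(res.success)

    x_hat, y_hat = float(best.x[0]), abs(float(best.x[1]))
    resid_rms = float(np.sqrt(best.fun / ax.size))
    # a near-constant bearing series carries no crossing information:
    # the fit may sit anywhere on the cone, so it does not count as
    # converged (mirrors events rejected for lack of bearing convergence)
    bearing_span = float(th.max() - th.min())
    converged = (
        ok
        and resid_rms <= TMA_RESIDUAL_MAX_RAD
        and bearing_span >= np.deg2rad(10.0)
    )
    error = _tma_error(cost, np.array([x_hat, y_hat]), ax.size)
    return Localization2D(x_hat, y_hat, y_hat, error, converged, resid_rms)


def _tma_error(cost, p: np.ndarray, n: int) -> float:
    """Range error from the residual curvature of the bearing SSR."""
    step = max(1.0, 1e-3 * abs(p[1]))
    f0 = cost(p)
    fp = cost(p + np.array([0.0, step]))
    fm = cost(p - np.array([0.0, step]))
    curv = (fp - 2 * f0 + fm) / step**2
    if curv <= 0 or n <= 2:
        return np.inf
    sigma2 = f0 / max(n - 2, 1)
    return float(np.sqrt(2.0 * sigma2 / curv))


def truncate_events(events: list, w: float = TRUNCATION_M, key=None) -> list:
    """Keep events with perpendicular slant range ≤ w (boundary inclusive)."""
    if key is None:
        key = lambda e: e.slant_range_m  # noqa: E731
    return [e for e in events if key(e) <= w]


def click_depth(tau_s, D_m, h_m, c_ms, *,
                sd_tau_s=0.0, sd_D_m=0.0, sd_h_m=0.0):
    """Closed-form click depth from slant delay via image-source geometry.

    ``z = c·τ·(2D + c·τ) / (4h)`` with D the radial (direct-path)
    distance to the whale and h the hydrophone depth. Depths beyond
    4000 m are flagged ``truncated`` and excluded from event averages —
    they are overwhelmingly false echo detections.

    Optional input standard deviations propagate by the delta method:
    ``∂z/∂τ = c(D + cτ)/(2h)``, ``∂z/∂D = cτ/(2h)``, ``∂z/∂h = −z/h``.
    """
    if h_m <= 0:
        raise ValueError("hydrophone depth must be positive (degenerate geometry)")
    if c_ms <= 0:
        raise ValueError("sound speed must be positive")
    if np.any(np.asarray(tau_s) < 0) or np.any(np.asarray(D_m) <= 0):
        raise ValueError("tau must be >= 0 and D > 0")

    tau = np.asarray(tau_s, dtype=float)
    D = np.asarray(D_m, dtype=float)
    z = c_ms * tau * (2.0 * D + c_ms * tau) / (4.0 * h_m)

    dz_dtau = c_ms * (D + c_ms * tau) / (2.0 * h_m)
    dz_dD = c_ms * tau / (2.0 * h_m)
    dz_dh = -z / h_m
    comp = {
        "tau": (dz_dtau * sd_tau_s) ** 2,
        "D": (dz_dD * sd_D_m) ** 2,
        "h": (dz_dh * sd_h_m) ** 2,
    }
    var = comp["tau"] + comp["D"] + comp["h"]

    if z.ndim == 0:
        return ClickDepth(float(z), float(var), bool(z > MAX_CLICK_DEPTH_M),
                          {k: float(v) for k, v in comp.items()})
    return [
        ClickDepth(float(zi), float(vi), bool(zi > MAX_CLICK_DEPTH_M))
        for zi, vi in zip(z, var)
    ]


def event_depth_summary(
    click_depths: list[ClickDepth] | np.ndarray,
    variances_m2: np.ndarray | None = None,
    min_clicks: int = MIN_CLICKS_PER_EVENT,
) -> EventDepthSummary:
    """Average depth of an event with uncertainty adjusted for click count.

    The average is the unweighted mean of the accepted (non-truncated)
    click depths. Its variance combines the between-click sample variance
    with the mean propagated per-click variance, both divided by n:

        SD² = (s²(z) + mean(σ²_click)) / n
    """
    if isinstance(click_depths, (list, tuple)) and click_depths and isinstance(
        click_depths[0], ClickDepth
    ):
        kept = [cd for cd in click_depths if not cd.truncated]
        z = np.array([cd.z_m for cd in kept])
        v = np.array([cd.variance_m2 for cd in kept])
    else:
        z = np.asarray(click_depths, dtype=float)
        v = np.zeros_like(z) if variances_m2 is None else np.asarray(variances_m2, float)

    n = z.size
    if n < min_clicks:
        return EventDepthSummary(n, np.nan, np.nan, False,
                                 DepthRejectionReason.too_few_clicks)
    sample_var = float(np.var(z, ddof=1)) if n > 1 else 0.0
    sd = float(np.sqrt((sample_var + float(v.mean())) / n))
    return EventDepthSummary(n, float(z.mean()), sd, True, DepthRejectionReason.none)


def reject_by_seafloor(
    summary: EventDepthSummary,
    position_xy: tuple[float, float],
    bathymetry: BathymetryGrid,
) -> EventDepthSummary:
    """Reject a 3D localization whose average depth exceeds the seafloor.

    The comparison is strict: an average depth exactly at the seafloor is
    kept. Raises if the position falls outside the bathymetry grid.
    """
    seafloor = bathymetry.depth_at(*position_xy)
    if summary.accepted and summary.average_depth_m > seafloor:
        return EventDepthSummary(
            summary.n_clicks_with_tau, summary.average_depth_m, summary.sd_m,
            False, DepthRejectionReason.exceeds_seafloor,
        )
    return summary
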