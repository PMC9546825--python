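"""Depth-corrected perpendicular distances and distance sampling.

A towed array measures a perpendicular *slant* range D to each whale; a
whale at depth z below the surface sits at true horizontal distance
``sqrt(D² − z²)``. Correcting distances this way (coercing to 0 when the
depth reaches the slant range — the whale is under the trackline)
repairs the first-bin deficit that slant ranges produce and is the bias
this analysis exists to remove.

The distance-sampling engine is conventional: a detection function
``g(x) = key(x)·[1 + Σ a_j p_j(·)]`` with uniform, half-normal
(``exp(−x²/2σ²)``) or hazard-rate (``1 − exp(−(x/σ)^−b)``) key and
cosine / simple-polynomial / Hermite-polynomial series adjustments, fit
by maximum likelihood on ``f(x) = g(x)/∫₀ʷ g``; model selection by AIC
with Kolmogorov–Smirnov and Cramér–von Mises goodness of fit; effective
strip half-width ``ESW = ∫₀ʷ g(x)dx / g(0)``; density
``D̂ = n / (2·ESW·L)`` and abundance ``N̂ = D̂·A`` with a two-component
CV (encounter rate + ESW).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special
from sklearn.base import BaseEstimator

__all__ = [
    "correct_distance",
    "coercion_rate",
    "relative_decrease_pct",
    "assumed_depth",
    "DetectionFunction",
    "fit_detection_function",
    "fit_model_set",
    "select_model",
    "gof",
    "AbundanceEstimate",
    "estimate_abundance",
]

DEFAULT_TRUNCATION_M = 6500.0
_EPS = 1e-12


# ---------------------------------------------------------------------------
# depth correction


def correct_distance(slant_m, depth_m):
    """Horizontal perpendicular distance ``sqrt(D² − z²)``.

    Coerced to 0 when the depth reaches or exceeds the slant range: the
    whale is diving directly below the trackline.
    """
    D = np.asarray(slant_m, dtype=float)
    z = np.asarray(depth_m, dtype=float)
    if np.any(D < 0) or np.any(z < 0):
        raise ValueError("slant range and depth must be non-negative")
    out = np.sqrt(np.maximum(D * D - z * z, 0.0))
    out = np.where(z >= D, 0.0, out)
    return float(out) if out.ndim == 0 else out


def coercion_rate(corrected_m) -> float:
    """Percent of corrected distances coerced to exactly 0."""
    x = np.asarray(corrected_m, dtype=float)
    if x.size == 0:
        raise ValueError("empty distance set")
    return 100.0 * float(np.count_nonzero(x == 0.0)) / x.size


def relative_decrease_pct(reference, value) -> float:
    """Percent decrease of ``value`` relative to ``reference``."""
    return 100.0 * (float(reference) - float(value)) / float(reference)


def assumed_depth(depths_m, weights=None, rule: str = "Q1") -> float:
    """Assumed depth for events without a 3D localization.

    Computed over the accepted event average depths, weighted by the
    number of clicks with a measured slant delay. ``rule`` is ``Q1``
    (default — the quartile that keeps the corrected-distance
    distribution workable), ``mean`` or ``Q3``. Weighted quantiles use
    linear interpolation of the weighted empirical CDF at plotting
    positions ``p_i = (C_i − w_i)/(W − w_n)`` (the weighted analogue of
    type-7 interpolation; reduces to it for equal weights).
    """
    z = np.asarray(depths_m, dtype=float)
    if z.size == 0:
        raise ValueError("no event depths supplied")
    w = np.ones_like(z) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if rule == "mean":
        return float(np.average(z, weights=w))
    if rule not in ("Q1", "Q3"):
        raise ValueError(f"unknown assumed-depth rule: {rule!r}")
    q = 0.25 if rule == "Q1" else 0.75
    order = np.argsort(z)
    zs, ws = z[order], w[order]
    if zs.size == 1:
        return float(zs[0])
    cw = np.cumsum(ws)
    p = (cw - ws) / (cw[-1] - ws[-1])
    return float(np.interp(q, p, zs))


# ---------------------------------------------------------------------------
# detection function


def _key_g(key: str, x: np.ndarray, sigma: float, shape: float) -> np.ndarray:
    if key == "uniform":
        return np.ones_like(x)
    if key == "half_normal":
        return np.exp(-(x * x) / (2.0 * sigma * sigma))
    if key == "hazard_rate":
        with np.errstate(divide="ignore", over="ignore"):
            r = np.where(x > 0, (x / sigma) ** (-shape), np.inf)
        return 1.0 - np.exp(-r)
    raise ValueError(f"unknown key function: {key!r}")


def _adjustment_series(
    adjustment: str | None, orders, x: np.ndarray, scale: float
) -> np.ndarray:
    """Σ a_j p_j — returns the basis matrix (len(orders), len(x))."""
    if adjustment is None or not orders:
        return np.zeros((0, x.size))
    xs = x / scale
    rows = []
    for j in orders:
        if adjustment == "cosine":
            rows.append(np.cos(j * np.pi * xs))
        elif adjustment == "simple_poly":
            rows.append(xs ** (2 * j))
        elif adjustment == "hermite_poly":
            rows.append(special.eval_hermite(2 * j, xs))
        else:
            raise ValueError(f"unknown adjustment family: {adjustment!r}")
    return np.vstack(rows)


class DetectionFunction(BaseEstimator):
    """MLE detection-function fit, sklearn-estimator style.

    Parameters
    ----------
    key : {"uniform", "half_normal", "hazard_rate"}
    adjustment : {None, "cosine", "simple_poly", "hermite_poly"}
    orders : tuple of int
        Adjustment orders j (cosine uses cos(jπx/w), simple polynomial
        (x/w)^(2j), Hermite H_{2j} of x/σ — or x/w for the uniform key).
    w : float
        Truncation distance (m); all fitted distances must lie in [0, w].

    Fitted attributes (set by :meth:`fit`): ``sigma_``, ``shape_``,
    ``coefs_``, ``loglik_``, ``aic_``, ``n_params_``, ``esw_``,
    ``esw_se_``, ``p_``, ``p_cv_``, ``converged_``, ``n_``, and the GOF
    results ``ks_p_`` / ``cvm_p_`` once :func:`gof` has run.
    """

    def __init__(
        self,
        key: str = "half_normal",
        adjustment: str | None = None,
        orders: tuple = (),
        w: float = DEFAULT_TRUNCATION_M,
    ):
        self.key = key
        self.adjustment = adjustment
        self.orders = tuple(orders)
        self.w = w

    # -- parameter packing: optimizer works on an unconstrained vector
    def _n_key_params(self) -> int:
        return {"uniform": 0, "half_normal": 1, "hazard_rate": 2}[self.key]

    def _unpack(self, params: np.ndarray) -> tuple[float, float, np.ndarray]:
        nk = self._n_key_params()
        sigma = float(np.exp(params[0])) if nk >= 1 else self.w
        shape = float(np.exp(params[1])) if nk >= 2 else 1.0
        return sigma, shape, np.asarray(params[nk:], dtype=float)

    def _adj_scale(self, sigma: float) -> float:
        if self.adjustment == "hermite_poly" and self.key != "uniform":
            return sigma
        return self.w

    def _g_raw(self, x: np.ndarray, sigma: float, shape: float, coefs: np.ndarray):
        g = _key_g(self.key, x, sigma, shape)
        if coefs.size:
            basis = _adjustment_series(
                self.adjustment, self.orders, x, self._adj_scale(sigma)
            )
            g = g * (1.0 + coefs @ basis)
        return g

    def _nll(self, params: np.ndarray, x: np.ndarray) -> float:
        if np.any(np.abs(params) > 50):
            return 1e12
        sigma, shape, coefs = self._unpack(params)
        gx = self._g_raw(x, sigma, shape, coefs)
        gq = self._g_raw(self._qx, sigma, shape, coefs)
        penalty = 0.0
        neg = gq < _EPS
        if np.any(neg) or np.any(gx < _EPS):
            penalty = 1e4 * (
                float(np.sum(np.minimum(gq, 0.0) ** 2))
                + float(np.sum(np.minimum(gx, 0.0) ** 2))
                + 1.0
            )
            gq = np.maximum(gq, _EPS)
            gx = np.maximum(gx, _EPS)
        mu = float(self._qw @ gq)
        if not np.isfinite(mu) or mu <= 0:
            return 1e12
        return float(-(np.log(gx).sum() - x.size * np.log(mu)) + penalty)

    def fit(self, x, y=None):
        """Fit by maximum likelihood on distances ``x`` in [0, w]."""
        x = np.asarray(x, dtype=float).ravel()
        if np.any(x < 0) or np.any(x > self.w):
            raise ValueError("distances must lie within [0, w]")
        if x.size < 1:
            raise ValueError("no distances to fit")
        self.n_ = int(x.size)

        # Gauss–Legendre nodes on [0, w] for the normalizing integral
        nodes, weights = np.polynomial.legendre.leggauss(256)
        self._qx = 0.5 * self.w * (nodes + 1.0)
        self._qw = 0.5 * self.w * weights

        nk = self._n_key_params()
        p0 = []
        if nk >= 1:
            sigma0 = max(float(np.sqrt(np.mean(x * x))), 1e-3 * self.w)
            if self.key == "hazard_rate":
                sigma0 = max(float(np.median(x)), 1e-3 * self.w)
            p0.append(np.log(sigma0))
        if nk >= 2:
            p0.append(np.log(2.5))
        p0 += [0.0] * len(self.orders)
        p0 = np.asarray(p0, dtype=float)

        self.n_params_ = p0.size
        if p0.size == 0:
            # uniform key, no adjustments: nothing to estimate
            self._params_ = p0
            self.sigma_, self.shape_, self.coefs_ = self._unpack(p0)
            self.loglik_ = -self._nll(p0, x)
            self.converged_ = True
        else:
            res = optimize.minimize(
                self._nll, p0, args=(x,), method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 4000, "maxfev": 6000},
            )
            self._params_ = res.x
            self.sigma_, self.shape_, self.coefs_ = self._unpack(res.x)
            self.loglik_ = -float(res.fun)
            self.converged_ = bool(res.success) and np.isfinite(res.fun)
        self.aic_ = 2.0 * self.n_params_ - 2.0 * self.loglik_
        self._x_fit = x

        self.esw_ = self._esw(self._params_)
        self.p_ = self.esw_ / self.w
        if not (0.0 < self.esw_ <= self.w * (1 + 1e-9)):
            # a g(0) far below the fitted maximum makes ESW > w: the model is
            # not a usable detection function, so it leaves the selection set
            self.converged_ = False
        self.esw_se_, self._cov_ = self._esw_se(x)
        self.p_cv_ = self.esw_se_ / self.esw_ if self.esw_ > 0 else np.nan
        self._check_monotone()
        return self

    # -- fitted-surface helpers -------------------------------------------
    def g(self, x):
        """Detection probability, rescaled so g(0) = 1."""
        x = np.asarray(x, dtype=float)
        g0 = self._g0()
        return self._g_raw(x, self.sigma_, self.shape_, self.coefs_) / g0

    def _g0(self) -> float:
        g0 = float(self._g_raw(np.array([0.0]), self.sigma_, self.shape_, self.coefs_)[0])
        if g0 <= 0:
            raise RuntimeError("fitted g(0) is non-positive")
        return g0

    def pdf(self, x):
        """Fitted distance density f(x) = g(x)/∫₀ʷ g."""
        x = np.asarray(x, dtype=float)
        sigma, shape, coefs = self.sigma_, self.shape_, self.coefs_
        mu = float(self._qw @ np.maximum(
            self._g_raw(self._qx, sigma, shape, coefs), _EPS))
        return np.maximum(self._g_raw(x, sigma, shape, coefs), _EPS) / mu

    def cdf(self, x):
        """Fitted distance CDF by cumulative quadrature."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        grid = np.linspace(0.0, self.w, 4097)
        pdf = self.pdf(grid)
        cum = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(grid))])
        cum /= cum[-1]
        out = np.interp(x, grid, cum)
        return float(out[0]) if np.isscalar(x) or out.size == 1 else out

    def _esw(self, params: np.ndarray) -> float:
        sigma, shape, coefs = self._unpack(params)
        if self.key == "half_normal" and not coefs.size:
            # closed form: σ√(π/2)·erf(w/(σ√2))
            return float(
                sigma * np.sqrt(np.pi / 2.0) * special.erf(self.w / (sigma * np.sqrt(2.0)))
            )
        g0 = float(self._g_raw(np.array([0.0]), sigma, shape, coefs)[0])
        gq = self._g_raw(self._qx, sigma, shape, coefs)
        return float(self._qw @ gq) / max(g0, _EPS)

    def _esw_se(self, x: np.ndarray):
        """Delta-method SE of the ESW from the observed information."""
        p = self._params_
        if p.size == 0:
            return 0.0, np.zeros((0, 0))
        h = 1e-4
        k = p.size
        H = np.empty((k, k))
        grad = np.empty(k)
        f0 = self._nll(p, x)
        for i in range(k):
            ei = np.zeros(k); ei[i] = h
            fp, fm = self._nll(p + ei, x), self._nll(p - ei, x)
            H[i, i] = (fp - 2 * f0 + fm) / h**2
            grad[i] = (self._esw(p + ei) - self._esw(p - ei)) / (2 * h)
        for i in range(k):
            for j in range(i + 1, k):
                ei = np.zeros(k); ei[i] = h
                ej = np.zeros(k); ej[j] = h
                H[i, j] = H[j, i] = (
                    self._nll(p + ei + ej, x) - self._nll(p + ei - ej, x)
                    - self._nll(p - ei + ej, x) + self._nll(p - ei - ej, x)
                ) / (4 * h * h)
        try:
            cov = np.linalg.inv(H)
            var = float(grad @ cov @ grad)
            if var < 0:
                raise np.linalg.LinAlgError
            return float(np.sqrt(var)), cov
        except np.linalg.LinAlgError:
            return np.nan, np.full((k, k), np.nan)

    def _check_monotone(self) -> None:
        grid = np.linspace(0.0, self.w, 512)
        gg = self.g(grid)
        if np.any(np.diff(gg) > 1e-6) or np.any(gg > 1 + 1e-6):
            warnings.warn(
                "fitted detection function is not monotone decreasing from g(0)=1",
                stacklevel=2,
            )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw distances from the fitted f by inverse-CDF interpolation."""
        grid = np.linspace(0.0, self.w, 4097)
        pdf = self.pdf(grid)
        cum = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(grid))])
        cum /= cum[-1]
        return np.interp(rng.uniform(0, 1, n), cum, grid)


def fit_detection_function(
    distances,
    key: str = "half_normal",
    adjustment: str | None = None,
    orders: tuple = (),
    w: float = DEFAULT_TRUNCATION_M,
) -> DetectionFunction:
    """Fit one detection-function model (thin wrapper over the estimator)."""
    return DetectionFunction(key=key, adjustment=adjustment, orders=orders, w=w).fit(
        distances
    )


#: the candidate model space: each key with no adjustment plus the
#: conventional series — cosine orders {2, 3}, simple polynomial {2, 4},
#: Hermite polynomial {4}
MODEL_SPACE: tuple[tuple[str, str | None, tuple], ...] = tuple(
    (key, adj, orders)
    for key in ("half_normal", "hazard_rate", "uniform")
    for adj, orders in (
        (None, ()),
        ("cosine", (2,)),
        ("cosine", (2, 3)),
        ("simple_poly", (2,)),
        ("simple_poly", (2, 4)),
        ("hermite_poly", (4,)),
    )
)


def fit_model_set(
    distances,
    w: float = DEFAULT_TRUNCATION_M,
    model_space=MODEL_SPACE,
) -> list[DetectionFunction]:
    """Fit the whole candidate model space; non-converged fits are kept
    (flagged) so the comparison table is complete, but excluded from
    selection."""
    fits = []
    for key, adj, orders in model_space:
        try:
            fits.append(fit_detection_function(distances, key, adj, orders, w))
        except Exception:  # noqa: BLE001 — a failed candidate is not fatal
            continue
    return fits


def select_model(fits: list[DetectionFunction]) -> DetectionFunction:
    """Lowest-AIC converged fit; AIC ties break toward fewer parameters."""
    ok = [f for f in fits if getattr(f, "converged_", False)]
    if not ok:
        raise ValueError("no converged detection-function fit")
    return min(ok, key=lambda f: (round(f.aic_, 6), f.n_params_))


def comparison_table(fits: list[DetectionFunction]) -> pd.DataFrame:
    """Model-comparison table (key, adjustment, AIC, ΔAIC, GOF, ESW, P)."""
    rows = []
    aics = [f.aic_ for f in fits if getattr(f, "converged_", False)]
    best = min(aics) if aics else np.nan
    for f in fits:
        rows.append(
            {
                "key": f.key,
                "adjustment": f.adjustment or "none",
                "orders": ",".join(map(str, f.orders)),
                "n_params": f.n_params_,
                "AIC": f.aic_,
                "dAIC": f.aic_ - best,
                "KS_p": getattr(f, "ks_p_", np.nan),
                "CvM_p": getattr(f, "cvm_p_", np.nan),
                "ESW_m": f.esw_,
                "ESW_SE_m": f.esw_se_,
                "P": f.p_,
                "P_CV": f.p_cv_,
                "converged": f.converged_,
            }
        )
    return pd.DataFrame(rows).sort_values("AIC", ignore_index=True)


# ---------------------------------------------------------------------------
# goodness of fit


def _ks_cvm_stats(fit: DetectionFunction, x: np.ndarray) -> tuple[float, float]:
    xs = np.sort(x)
    n = xs.size
    F = np.atleast_1d(fit.cdf(xs))
    i = np.arange(1, n + 1)
    ks = float(np.max(np.maximum(i / n - F, F - (i - 1) / n)))
    cvm = float(1.0 / (12 * n) + np.sum((F - (2 * i - 1) / (2 * n)) ** 2))
    return ks, cvm


def gof(
    fit: DetectionFunction,
    distances,
    n_boot: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Kolmogorov–Smirnov and Cramér–von Mises p-values.

    Statistics are computed on the fitted CDF; p-values come from a
    parametric bootstrap (simulate from the fitted model, refit the same
    model specification, recompute the statistics). The fit object gains
    ``ks_p_``, ``cvm_p_``, ``ks_stat_``, ``cvm_stat_``.
    """
    x = np.asarray(distances, dtype=float).ravel()
    ks_obs, cvm_obs = _ks_cvm_stats(fit, x)
    rng = np.random.default_rng(seed)
    ks_ge = cvm_ge = 0
    for _ in range(n_boot):
        xb = fit.sample(x.size, rng)
        fb = DetectionFunction(**fit.get_params())
        try:
            fb.fit(xb)
            ks_b, cvm_b = _ks_cvm_stats(fb, xb)
        except Exception:  # noqa: BLE001 — count failed refits as extreme
            ks_b = cvm_b = np.inf
        ks_ge += ks_b >= ks_obs
        cvm_ge += cvm_b >= cvm_obs
    ks_p = (1 + ks_ge) / (n_boot + 1)
    cvm_p = (1 + cvm_ge) / (n_boot + 1)
    fit.ks_stat_, fit.cvm_stat_ = ks_obs, cvm_obs
    fit.ks_p_, fit.cvm_p_ = float(ks_p), float(cvm_p)
    return float(ks_p), float(cvm_p)


# ---------------------------------------------------------------------------
# density and abundance


@dataclass
class AbundanceEstimate:
    """Line-transect density/abundance with a two-component CV."""

    n: int
    effort_km: float
    esw_m: float
    area_km2: float | None
    density_per_km2: float
    abundance: float | None
    cv_encounter: float
    cv_esw: float
    cv: float
    se_density: float
    se_abundance: float | None

    def lognormal_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Log-normal CI for the abundance (or density × area = 1)."""
        from scipy.stats import norm

        target = self.abundance if self.abundance is not None else self.density_per_km2
        if target <= 0 or not np.isfinite(self.cv):
            return (0.0, np.inf)
        zq = norm.ppf(0.5 + level / 2)
        c = np.exp(zq * np.sqrt(np.log(1.0 + self.cv**2)))
        return (target / c, target * c)


def encounter_rate_cv(leg_lengths_km, leg_counts) -> float:
    """CV of the encounter rate n/L across transect legs (R2 estimator)."""
    l = np.asarray(leg_lengths_km, dtype=float)
    c = np.asarray(leg_counts, dtype=float)
    if l.size != c.size or l.size == 0:
        raise ValueError("leg lengths and counts must align")
    if np.any(l <= 0):
        raise ValueError("leg lengths must be positive")
    L = float(l.sum())
    n = float(c.sum())
    k = l.size
    if k < 2:
        warnings.warn("single transect leg: encounter-rate CV undefined", stacklevel=2)
        return np.nan
    er = n / L
    var = k / (L * L * (k - 1)) * float(np.sum(l * l * (c / l - er) ** 2))
    return float(np.sqrt(var) / er) if er > 0 else np.nan


def estimate_abundance(
    fit: DetectionFunction | None = None,
    *,
    n: int,
    L_km: float,
    A_km2: float | None = None,
    esw_m: float | None = None,
    esw_cv: float | None = None,
    leg_lengths_km=None,
    leg_counts=None,
) -> AbundanceEstimate:
    """Density ``D̂ = n/(2·ESW·L)`` and abundance ``N̂ = D̂·A``.

    The ESW (and its CV, by the delta method on the MLE information) come
    from ``fit`` unless given directly. ``CV²(D̂) = CV²(n/L) + CV²(ESW)``
    with the encounter-rate component estimated across transect legs;
    without leg data that component is 0 (and flagged NaN CV upstream if
    a single leg was supplied). No group-size term: detections are
    treated as single foraging whales.
    """
    if L_km <= 0:
        raise ValueError("effort must be positive")
    if esw_m is None:
        if fit is None:
            raise ValueError("need a fitted detection function or an ESW")
        if not fit.converged_:
            raise ValueError("detection-function fit did not converge")
        esw_m = fit.esw_
        esw_cv = fit.p_cv_ if esw_cv is None else esw_cv
    esw_cv = 0.0 if esw_cv is None or not np.isfinite(esw_cv) else float(esw_cv)

    esw_km = esw_m / 1000.0
    density = n / (2.0 * esw_km * L_km) if n > 0 else 0.0

    if leg_lengths_km is not None and leg_counts is not None:
        cv_er = encounter_rate_cv(leg_lengths_km, leg_counts)
    else:
        cv_er = 0.0
    cv_er_eff = 0.0 if not np.isfinite(cv_er) else cv_er
    cv = float(np.sqrt(cv_er_eff**2 + esw_cv**2))

    abundance = density * A_km2 if A_km2 is not None else None
    return AbundanceEstimate(
        n=n,
        effort_km=L_km,
        esw_m=esw_m,
        area_km2=A_km2,
        density_per_km2=density,
        abundance=abundance,
        cv_encounter=cv_er,
        cv_esw=esw_cv,
        cv=cv,
        se_density=density * cv,
        se_abundance=abundance * cv if abundance is not None else None,
    )
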