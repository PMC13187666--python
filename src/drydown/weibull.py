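"""Weibull vulnerability curves: quantile algebra, fitting, and confidence intervals.

The curve describes the fraction of embolized xylem area as a function of
water potential ``psi`` (MPa, signed negative).  All algebra is done on
tension ``|psi|``:

    F(psi) = 1 - exp(-(|psi| / scale) ** shape)

``scale`` is the tension (MPa, positive) at which F = 1 - 1/e, and ``shape``
controls steepness.  Quantile thresholds are returned as signed water
potentials, so ``quantile(curve, 0.5)`` is the (negative) psi at 50 %
embolized area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy import stats as sps

from .exceptions import ConfigError, FitError

__all__ = [
    "WeibullVC",
    "VCFitResult",
    "fraction",
    "quantile",
    "solve_from_two_quantiles",
    "fit_vc",
    "ci_thresholds",
]

#: Quantile fractions reported in threshold tables (12, 50, 88 %).
REPORT_FRACTIONS = (0.12, 0.50, 0.88)


@dataclass(frozen=True)
class WeibullVC:
    """Two-parameter Weibull vulnerability curve on tension.

    Parameters
    ----------
    scale : float
        Tension scale in MPa (> 0); the tension at 63.2 % embolized area.
    shape : float
        Dimensionless steepness (> 0).
    """

    scale: float
    shape: float

    def __post_init__(self) -> None:
        if not (self.scale > 0 and np.isfinite(self.scale)):
            raise ConfigError(f"scale must be a positive finite number, got {self.scale}")
        if not (self.shape > 0 and np.isfinite(self.shape)):
            raise ConfigError(f"shape must be a positive finite number, got {self.shape}")

    def fraction(self, psi):
        return fraction(psi, self)

    def quantile(self, p):
        return quantile(self, p)


@dataclass
class VCFitResult:
    """Result of a vulnerability-curve fit with optional confidence intervals.

    ``psi_ov12/50/88`` are the signed water potentials at 12/50/88 %
    embolized area.  ``ci`` maps each report fraction to a
    ``(low, high)`` signed-psi interval (low is the more negative bound's
    *less* negative end, i.e. intervals satisfy ``low <= point <= high``).
    """

    curve: WeibullVC
    psi_ov12: float
    psi_ov50: float
    psi_ov88: float
    rss: float
    n_points: int
    converged: bool = True
    message: str = ""
    ci: dict[float, tuple[float, float]] = field(default_factory=dict)
    ci_method: str | None = None
    ci_level: float | None = None

    @classmethod
    def from_curve(cls, curve: WeibullVC, rss: float, n_points: int, **kw) -> "VCFitResult":
        q12, q50, q88 = (quantile(curve, p) for p in REPORT_FRACTIONS)
        return cls(curve=curve, psi_ov12=q12, psi_ov50=q50, psi_ov88=q88,
                   rss=rss, n_points=n_points, **kw)


def _as_tension(psi) -> np.ndarray:
    psi = np.asarray(psi, dtype=float)
    if np.any(psi > 0):
        raise ConfigError("water potential must be <= 0 MPa (signed-negative convention)")
    return np.abs(psi)


def fraction(psi, curve: WeibullVC):
    """Embolized-area fraction F(psi) in [0, 1] for signed psi <= 0.

    Uses ``expm1`` so that tiny tensions do not lose precision.
    """
    tension = _as_tension(psi)
    out = -np.expm1(-((tension / curve.scale) ** curve.shape))
    return float(out) if np.isscalar(psi) or np.ndim(psi) == 0 else out

def quantile(curve: WeibullVC, p):
    """Signed water potential at embolized-area fraction ``p`` (0 < p < 1)."""
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr <= 0) | (p_arr >= 1)):
        raise ConfigError(f"quantile fraction must lie in (0, 1), got {p}")
    out = -curve.scale * (-np.log1p(-p_arr)) ** (1.0 / curve.shape)
    return float(out) if np.ndim(p) == 0 else out


def solve_from_two_quantiles(psi_a: float, p_a: float,
                             psi_b: float, p_b: float) -> WeibullVC:
    """Solve the unique Weibull curve passing through two quantile constraints.

    Given F(psi_a) = p_a and F(psi_b) = p_b the closed form is::

        shape = ln[ ln(1 - p_b) / ln(1 - p_a) ] / ln(|psi_b| / |psi_a|)
        scale = |psi_a| / (-ln(1 - p_a)) ** (1 / shape)

    Raises
    ------
    ConfigError
        If the tensions or fractions coincide (degenerate system) or the
        constraints imply a non-positive shape (inconsistent ordering).
    """
    ta, tb = float(_as_tension(psi_a)), float(_as_tension(psi_b))
    for p in (p_a, p_b):
        if not 0 < p < 1:
            raise ConfigError(f"fractions must lie in (0, 1), got {p}")
    if ta == tb:
        raise ConfigError("degenerate constraints: equal tensions")
    if p_a == p_b:
        raise ConfigError("degenerate constraints: equal fractions")
    shape = np.log(np.log1p(-p_b) / np.log1p(-p_a)) / np.log(tb / ta)
    if not shape > 0 or not np.isfinite(shape):
        raise ConfigError(
            "inconsistent constraints: larger fraction must occur at larger tension")
    scale = ta / (-np.log1p(-p_a)) ** (1.0 / shape)
    return WeibullVC(scale=scale, shape=shape)


# ---------------------------------------------------------------------------
# Least-squares fitting
# ---------------------------------------------------------------------------

def _extract_xy(points, fractions=None):
    """Accept an OVSeries-like object (psi + percent) or two arrays."""
    if fractions is None:
        psi = np.asarray(points.psi, dtype=float)
        y = np.asarray(points.percent, dtype=float) / 100.0
    else:
        psi = np.asarray(points, dtype=float)
        y = np.asarray(fractions, dtype=float)
    ok = np.isfinite(psi) & np.isfinite(y)
    return psi[ok], y[ok]


def _crossing_init(tension: np.ndarray, y: np.ndarray) -> WeibullVC:
    """Initial curve from the empirical 12 % / 88 % crossing tensions.

    Falls back to a regression on the complementary-log-log scale, then to a
    broad default, when the data do not bracket both crossings.
    """
    order = np.argsort(tension)
    t_sorted, y_sorted = tension[order], y[order]
    # make y weakly monotone for crossing lookup
    y_mono = np.maximum.accumulate(y_sorted)

    def crossing(level):
        idx = np.searchsorted(y_mono, level)
        if idx == 0 or idx >= len(t_sorted):
            return None
        y0, y1 = y_mono[idx - 1], y_mono[idx]
        t0, t1 = t_sorted[idx - 1], t_sorted[idx]
        if y1 == y0:
            return 0.5 * (t0 + t1)
        return t0 + (level - y0) * (t1 - t0) / (y1 - y0)

    t12, t88 = crossing(0.12), crossing(0.88)
    if t12 is not None and t88 is not None and t88 > t12 > 0:
        try:
            return solve_from_two_quantiles(-t12, 0.12, -t88, 0.88)
        except ConfigError:
            pass
    # cloglog regression: ln(-ln(1-y)) = shape*ln(t) - shape*ln(scale)
    interior = (y > 0.01) & (y < 0.99) & (tension > 0)
    if interior.sum() >= 2:
        x = np.log(tension[interior])
        z = np.log(-np.log1p(-y[interior]))
        slope, intercept = np.polyfit(x, z, 1)
        if slope > 0:
            return WeibullVC(scale=float(np.exp(-intercept / slope)),
                             shape=float(slope))
    return WeibullVC(scale=float(np.median(tension[tension > 0]) or 1.0), shape=3.0)


def _residual_and_jac(theta, tension, y):
    """Residuals and analytic Jacobian in log-parameter space."""
    log_scale, log_shape = theta
    scale, shape = np.exp(log_scale), np.exp(log_shape)
    with np.errstate(over="ignore"):
        u = (tension / scale) ** shape
        eu = np.exp(-np.minimum(u, 700.0))
    res = (1.0 - eu) - y
    # dF/dlog(scale) = -shape * u * exp(-u);  dF/dlog(shape) = shape*u*ln(t/scale)*exp(-u)
    with np.errstate(divide="ignore", invalid="ignore"):
        logt = np.where(tension > 0, np.log(np.maximum(tension, 1e-300) / scale), 0.0)
    core = u * eu
    jac = np.column_stack([-shape * core, shape * core * logt])
    return res, jac


def fit_vc(points, fractions=None, *, init: WeibullVC | None = None,
           weights=None, min_points: int = 4) -> VCFitResult:
    """Least-squares Weibull fit of embolized fraction versus psi.

    Parameters
    ----------
    points
        Either an OVSeries-like object with ``psi`` and ``percent``
        attributes, or an array of signed psi values (then ``fractions``
        must hold the matching fractions in [0, 1]).
    init
        Optional starting curve; default is derived from the empirical
        12 % / 88 % crossings (robust at extreme shapes).
    weights
        Optional per-point weights on the residuals (unweighted default).

    Raises
    ------
    AnalysisError-like ConfigError for insufficient data; FitError when the
    optimizer does not converge.
    """
    psi, y = _extract_xy(points, fractions)
    if len(psi) < min_points:
        raise ConfigError(f"need at least {min_points} points, got {len(psi)}")
    tension = _as_tension(psi)
    if not (np.any(y < 0.5) and np.any(y > 0.5)):
        warnings.warn("data do not span the 50% level; fit may be poorly "
                      "constrained and intervals wide", stacklevel=2)
    if init is None:
        init = _crossing_init(tension, y)
    w = np.ones_like(y) if weights is None else np.sqrt(np.asarray(weights, float))

    def fun(theta):
        res, _ = _residual_and_jac(theta, tension, y)
        return w * res

    def jac(theta):
        _, j = _residual_and_jac(theta, tension, y)
        return w[:, None] * j

    theta0 = np.log([init.scale, init.shape])
    sol = optimize.least_squares(fun, theta0, jac=jac, method="trf",
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise FitError("vulnerability-curve fit did not converge",
                       diagnostics={"status": sol.status, "message": sol.message,
                                    "cost": sol.cost, "x": sol.x.tolist()})
    curve = WeibullVC(scale=float(np.exp(sol.x[0])), shape=float(np.exp(sol.x[1])))
    rss = float(2.0 * sol.cost)
    return VCFitResult.from_curve(curve, rss=rss, n_points=len(psi),
                                  converged=True, message=sol.message)


# ---------------------------------------------------------------------------
# Confidence intervals
# ---------------------------------------------------------------------------

def _bootstrap_ci(psi, y, fit: VCFitResult, B, level, rng, ps, resample="case"):
    n = len(psi)
    if resample == "residual":
        pred = fraction(psi, fit.curve)
        resid = y - pred
        # center and inflate for the 2 fitted parameters
        resid = (resid - resid.mean()) * np.sqrt(n / max(n - 2, 1))
    elif resample != "case":
        raise ConfigError(f"unknown resampling unit {resample!r} "
                          "(use 'case' or 'residual')")
    qs = {p: [] for p in ps}
    failures = 0
    for _ in range(B):
        try:
            if resample == "case":
                idx = rng.integers(0, n, size=n)
                res = fit_vc(psi[idx], y[idx], init=fit.curve)
            else:
                yb = pred + rng.choice(resid, size=n, replace=True)
                res = fit_vc(psi, yb, init=fit.curve)
        except (ConfigError, FitError):
            failures += 1
            continue
        for p in ps:
            qs[p].append(quantile(res.curve, p))
    if failures > 0.2 * B:
        warnings.warn(f"{failures}/{B} bootstrap refits failed", stacklevel=3)
    alpha = 1.0 - level
    ci = {}
    for p in ps:
        vals = np.asarray(qs[p])
        lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
        ci[p] = (float(lo), float(hi))
    return ci


def _profile_ci(psi, y, fit: VCFitResult, level, ps):
    """SSR-profile (likelihood-ratio under Gaussian errors) intervals.

    For each report fraction the curve is reparameterized by the signed
    threshold ``psi_p``; the profile minimizes SSR over shape at fixed
    psi_p and the interval is where the profile SSR stays below
    ``SSR_min * (1 + F(1, n-2, level) / (n - 2))``.
    """
    tension = _as_tension(psi)
    n = len(psi)
    if n <= 2:
        raise ConfigError("profiling needs more than 2 points")
    ssr_min = fit.rss
    crit = ssr_min * (1.0 + sps.f.ppf(level, 1, n - 2) / (n - 2))
    # zero-residual (noise-free) data: the profile is positive everywhere
    # except at the estimate, so the interval degenerates to the point
    crit = max(crit, 1e-15)

    def profile_ssr(t_p, p):
        """min over shape of SSR with scale tied to the threshold t_p."""
        lam = -np.log1p(-p)

        def ssr_of_logshape(ls):
            shape = np.exp(ls)
            scale = t_p / lam ** (1.0 / shape)
            pred = -np.expm1(-((tension / scale) ** shape))
            return float(np.sum((pred - y) ** 2))

        res = optimize.minimize_scalar(ssr_of_logshape,
                                       bounds=(np.log(1e-2), np.log(1e3)),
                                       method="bounded",
                                       options={"xatol": 1e-10})
        return res.fun

    ci = {}
    for p in ps:
        t_hat = abs(quantile(fit.curve, p))

        def g(t_p, p=p):
            return profile_ssr(t_p, p) - crit

        # expand outward from the estimate until the profile crosses the cutoff
        def find_root(direction):
            step = max(0.01, 0.05 * t_hat)
            t_prev = t_hat
            if g(t_hat) >= 0:  # degenerate profile (e.g. noise-free data)
                return t_hat
            for _ in range(200):
                t_next = t_prev + direction * step
                if t_next <= 1e-9:
                    return 1e-9  # unbounded below on this side
                if g(t_next) > 0:
                    lo, hi = sorted((t_prev, t_next))
                    return optimize.brentq(g, lo, hi, xtol=1e-8)
                t_prev = t_next
                step *= 1.6
            return t_prev  # effectively unbounded

        t_low_tension = find_root(-1.0)   # less tension -> less negative psi
        t_high_tension = find_root(+1.0)
        ci[p] = (float(-t_high_tension), float(-t_low_tension))
    return ci


def ci_thresholds(points, fractions=None, *, method: str = "bootstrap",
                  B: int = 1000, level: float = 0.95,
                  rng: np.random.Generator | int | None = None,
                  resample: str = "case",
                  ps=REPORT_FRACTIONS, fit: VCFitResult | None = None) -> VCFitResult:
    """Attach 95 % (by default) confidence intervals for the report thresholds.

    ``method="bootstrap"`` does percentile intervals over ``B`` refits;
    ``method="profile"`` profiles the residual sum of squares.  The bootstrap
    ``resample`` unit is ``"case"`` (data points, the default) or
    ``"residual"`` (centered model residuals on the fixed psi design —
    better calibrated when the psi grid is a fixed schedule rather than a
    random sample).  Returns a new :class:`VCFitResult` with ``ci`` populated.
    """
    psi, y = _extract_xy(points, fractions)
    if fit is None:
        fit = fit_vc(psi, y)
    if not 0 < level < 1:
        raise ConfigError(f"level must be in (0, 1), got {level}")
    if method == "bootstrap":
        if B < 200:
            warnings.warn(f"B={B} bootstrap replicates is low; intervals will be "
                          "noisy (recommend B >= 200)", stacklevel=2)
        if rng is None or isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        ci = _bootstrap_ci(psi, y, fit, B, level, rng, ps, resample=resample)
    elif method == "profile":
        ci = _profile_ci(psi, y, fit, level, ps)
    else:
        raise ConfigError(f"unknown CI method {method!r} (use 'bootstrap' or 'profile')")
    out = VCFitResult.from_curve(fit.curve, rss=fit.rss, n_points=fit.n_points,
                                 converged=fit.converged, message=fit.message)
    out.ci = ci
    out.ci_method = method
    out.ci_level = level
    return out
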