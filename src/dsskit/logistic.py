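"""Four-parameter logistic (4PL) dose-response model.

The model in log10-concentration space is

    R(x) = R_min + (R_max - R_min) / (1 + 10^(s * (m - x)))

with bottom/top asymptotes ``R_min <= R_max`` in percent inhibition,
``m = log10(IC50 in nM)`` the half-maximal point relative to the curve's own
asymptotes, and slope ``s > 0`` so inhibition is non-decreasing with dose.
Fitting is deterministic bounded nonlinear least squares with a fixed
multi-start over the slope and a coarse fallback grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .curves import DoseResponseCurve

__all__ = [
    "LogisticFit",
    "InsufficientDataError",
    "UnattainedLevelError",
    "predict_response",
    "invert_response",
    "fit_logistic",
    "FourParameterLogistic",
]

# slope box: strictly positive so "inhibition increases with dose" is structural
S_MIN, S_MAX = 0.1, 10.0
# IC50 extrapolation allowed up to 100x beyond the tested window
M_MARGIN = 2.0
_FLAT_TOL = 1e-8  # response range below this is a degenerate plateau


class InsufficientDataError(ValueError):
    """Fewer than three distinct concentrations: the 4PL is not estimable."""


class UnattainedLevelError(ValueError):
    """Requested response level lies outside the open interval (R_min, R_max)."""


@dataclass(frozen=True)
class LogisticFit:
    """Fitted 4PL parameters plus diagnostics.

    ``log_ic50`` is in log10(nM); ``ic50`` (property) in nM.  ``converged``
    is False when only the fallback grid search produced the parameters.
    """

    r_min: float
    r_max: float
    log_ic50: float
    slope: float
    converged: bool = True
    rss: float = 0.0
    n_points: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_min <= self.r_max <= 100.0):
            raise ValueError(f"require 0 <= r_min <= r_max <= 100, got ({self.r_min}, {self.r_max})")
        if not self.slope > 0:
            raise ValueError("slope must be > 0")
        if not np.isfinite(self.log_ic50):
            raise ValueError("log_ic50 must be finite")

    @property
    def ic50(self) -> float:
        """Relative IC50 in nM (midpoint between the curve's own asymptotes)."""
        return float(10.0 ** self.log_ic50)


_LN10 = np.log(10.0)


def _model(x, r_min, r_max, m, s):
    # 1/(1+10^(s(m-x))) computed via expit-style stable form
    t = s * (m - np.asarray(x, dtype=float))
    return r_min + (r_max - r_min) / (1.0 + np.power(10.0, np.clip(t, -300, 300)))


def _jacobian(theta, x, y):
    r_min, r_max, m, s = theta
    t = np.clip(s * (m - x), -300, 300)
    p = 10.0 ** t
    g = 1.0 / (1.0 + p)
    dg_dt = -p * _LN10 * g * g
    J = np.empty((x.size, 4))
    J[:, 0] = 1.0 - g
    J[:, 1] = g
    J[:, 2] = (r_max - r_min) * dg_dt * s
    J[:, 3] = (r_max - r_min) * dg_dt * (m - x)
    return J


def _logit_start(x, y):
    """Linearized start: log10((r_max-y)/(y-r_min)) is linear in x with slope -s."""
    r0, r1 = float(y.min()), float(y.max())
    eps = 1e-10 * (r1 - r0)
    mask = (y > r0 + eps) & (y < r1 - eps)
    if mask.sum() < 2:
        return None
    ly = np.log10((r1 - y[mask]) / (y[mask] - r0))
    A = np.vstack([np.ones(int(mask.sum())), -x[mask]]).T
    coef, *_ = np.linalg.lstsq(A, ly, rcond=None)
    sm, s_est = coef
    if not np.isfinite(s_est) or s_est <= 0:
        return None
    return float(sm / s_est), float(s_est)


def predict_response(fit: LogisticFit, x):
    """Evaluate R(x) at log10 concentration(s) ``x`` (percent inhibition)."""
    out = _model(x, fit.r_min, fit.r_max, fit.log_ic50, fit.slope)
    return float(out) if np.ndim(x) == 0 else out


def invert_response(fit: LogisticFit, level: float) -> float:
    """Unique log10 concentration where R(x) equals ``level``.

    Requires ``r_min < level < r_max``; outside that open interval the curve
    never (or always) attains the level and :class:`UnattainedLevelError` is
    raised for the caller to decide.
    """
    if not (fit.r_min < level < fit.r_max):
        raise UnattainedLevelError(
            f"level {level} outside open response range ({fit.r_min}, {fit.r_max})"
        )
    return fit.log_ic50 - np.log10((fit.r_max - level) / (level - fit.r_min)) / fit.slope


def _initial_m(x, y, r_lo, r_hi):
    """Dose (log10) whose observed response is nearest the half-maximum."""
    half = 0.5 * (r_lo + r_hi)
    return float(x[np.argmin(np.abs(y - half))])


def fit_logistic(curve: DoseResponseCurve, max_nfev: int = 100) -> LogisticFit:
    """Fit the 4PL to one curve by bounded deterministic least squares.

    Box constraints: r_min, r_max in [0, 100]; m within the tested log10
    window widened by 2 (100x extrapolation cap); s in [0.1, 10].  A fixed
    multi-start over s in {0.5, 1, 2} plus a data-driven linearized (logit
    regression) start, best RSS wins with ties broken toward the earlier
    start, makes the fit fully deterministic.  Flat curves
    (response range ~ 0) skip optimization: the asymptotes carry all the
    information and m is unidentifiable, so m is pinned mid-window.
    """
    x = curve.log10_concentrations
    y = np.asarray(curve.responses, dtype=float)
    if np.unique(x).size < 3:
        raise InsufficientDataError(
            f"{curve.sample_id}/{curve.drug_id}: need >= 3 distinct concentrations, "
            f"got {np.unique(x).size}"
        )
    n = x.size
    m_lo, m_hi = x.min() - M_MARGIN, x.max() + M_MARGIN

    if np.ptp(y) < _FLAT_TOL:
        level = float(np.clip(np.mean(y), 0.0, 100.0))
        return LogisticFit(level, level, 0.5 * (x.min() + x.max()), 1.0,
                           converged=True, rss=0.0, n_points=n)

    r_lo0 = float(np.clip(y.min(), 0.0, 100.0))
    r_hi0 = float(np.clip(y.max(), 0.0, 100.0))
    m0 = float(np.clip(_initial_m(x, y, r_lo0, r_hi0), m_lo, m_hi))
    lower = np.array([0.0, 0.0, m_lo, S_MIN])
    upper = np.array([100.0, 100.0, m_hi, S_MAX])

    def residuals(theta):
        return _model(x, *theta) - y

    starts = [(m0, 0.5), (m0, 1.0), (m0, 2.0)]
    extra = _logit_start(x, y)
    if extra is not None:
        starts.append(extra)
    best = None
    for m_start, s_start in starts:
        theta0 = np.clip(np.array([r_lo0, r_hi0, m_start, s_start]), lower, upper)
        try:
            sol = least_squares(residuals, theta0, jac=lambda th: _jacobian(th, x, y),
                                bounds=(lower, upper), method="trf",
                                xtol=2.3e-16, ftol=2.3e-16, gtol=None,
                                x_scale="jac", max_nfev=max_nfev)
        except Exception:
            continue
        rss = float(np.sum(sol.fun ** 2))
        if best is None or rss < best[0] - 1e-12:
            best = (rss, sol.x)

    if best is None:
        return _grid_fallback(x, y, m_lo, m_hi, n)

    rss, (r_min, r_max, m, s) = best
    if r_max < r_min:
        # s>0 makes the model increasing only when r_max>r_min; a reversed
        # optimum means the data is truly decreasing -> flat line per contract
        level = float(np.clip(np.mean(y), 0.0, 100.0))
        flat_rss = float(np.sum((y - level) ** 2))
        return LogisticFit(level, level, 0.5 * (x.min() + x.max()), 1.0,
                           converged=True, rss=flat_rss, n_points=n)
    return LogisticFit(float(r_min), float(r_max), float(m), float(s),
                       converged=True, rss=rss, n_points=n)


def _grid_fallback(x, y, m_lo, m_hi, n) -> LogisticFit:
    """Coarse deterministic (m, s) grid search when least squares fails."""
    r_lo = float(np.clip(np.min(y), 0, 100))
    r_hi = float(np.clip(np.max(y), 0, 100))
    best = (np.inf, m_lo, 1.0)
    for m in np.linspace(m_lo, m_hi, 41):
        for s in np.geomspace(S_MIN, S_MAX, 21):
            rss = float(np.sum((_model(x, r_lo, r_hi, m, s) - y) ** 2))
            if rss < best[0] - 1e-12:
                best = (rss, float(m), float(s))
    rss, m, s = best
    return LogisticFit(r_lo, r_hi, m, s, converged=False, rss=rss, n_points=n)


class FourParameterLogistic(RegressorMixin, BaseEstimator):
    """sklearn-style 4PL regressor on (log10 concentration, % inhibition) data.

    Parameters
    ----------
    max_nfev : int
        Function-evaluation budget per least-squares start.

    Attributes
    ----------
    r_min_, r_max_ : float
        Bottom/top asymptotes (% inhibition).
    log_ic50_ : float
        log10 of the relative IC50 (nM).
    slope_ : float
        Slope at the IC50 (> 0).
    converged_ : bool
    rss_ : float
    fit_result_ : LogisticFit
    """

    def __init__(self, max_nfev: int = 100):
        self.max_nfev = max_nfev

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("X and y must have the same length")
        order = np.argsort(x)
        curve = DoseResponseCurve("_", "_", 10.0 ** x[order], y[order])
        res = fit_logistic(curve, max_nfev=self.max_nfev)
        self.fit_result_ = res
        self.r_min_, self.r_max_ = res.r_min, res.r_max
        self.log_ic50_, self.slope_ = res.log_ic50, res.slope
        self.converged_, self.rss_ = res.converged, res.rss
        return self

    def predict(self, X):
        return predict_response(self.fit_result_, np.asarray(X, dtype=float).reshape(-1))

    def inverse(self, level: float) -> float:
        """Log10 concentration at which the fitted curve attains ``level``."""
        return invert_response(self.fit_result_, level)
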