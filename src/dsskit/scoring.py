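"""Drug sensitivity scores from fitted dose-response curves.

DSS is the analytic area between the fitted 4PL curve and an activity
threshold ``A_min`` over the tested log10-concentration window, normalized
to a 0-100 scale.  Three variants:

* DSS1 - raw normalized area,
* DSS2 - DSS1 penalized for a low top asymptote (x log10(R_max)/2),
* DSS3 - DSS2 penalized for a narrow active dose window.

The discrete Activity Area (AA) comparator, relative IC50 extraction and
differential scoring against control samples (dDSS) live here too, plus a
``DrugSensitivityScorer`` transformer turning a long well table into a
samples x drugs :class:`~dsskit.curves.ScoreMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .curves import DoseResponseCurve, ScoreMatrix, curves_from_frame, _validate_drt_frame
from .logistic import (
    InsufficientDataError,
    LogisticFit,
    UnattainedLevelError,
    fit_logistic,
    invert_response,
)

__all__ = [
    "ScoreSettings",
    "IntegralResult",
    "integral_above",
    "dss",
    "activity_area",
    "relative_ic50",
    "differential_scores",
    "score_curves",
    "fits_to_frame",
    "DrugSensitivityScorer",
]

DSS_METRICS = ("DSS1", "DSS2", "DSS3")
METRICS = DSS_METRICS + ("AA", "IC50")
LN10 = np.log(10.0)


@dataclass(frozen=True)
class ScoreSettings:
    """Scoring settings: activity threshold and integration window.

    a_min : percent inhibition below which response counts as baseline noise
            (default 10); lower bound of the DSS integral.
    x_lo, x_hi : log10(nM) bounds of the concentration window the score is
            computed over.  ``None`` means "use each curve's own tested range".
    metric : which score :func:`score_curves` emits.
    """

    a_min: float = 10.0
    x_lo: float | None = None
    x_hi: float | None = None
    metric: str = "DSS2"

    def __post_init__(self) -> None:
        if not (0.0 <= self.a_min < 100.0):
            raise ValueError("a_min must be in [0, 100)")
        if self.x_lo is not None and self.x_hi is not None and not self.x_lo < self.x_hi:
            raise ValueError("require x_lo < x_hi")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; expected one of {METRICS}")

    def window_for(self, curve: DoseResponseCurve) -> tuple[float, float]:
        x = curve.log10_concentrations
        lo = self.x_lo if self.x_lo is not None else float(x.min())
        hi = self.x_hi if self.x_hi is not None else float(x.max())
        return lo, hi

    def as_dict(self) -> dict:
        return {"a_min": self.a_min, "x_lo": self.x_lo, "x_hi": self.x_hi}


@dataclass(frozen=True)
class IntegralResult:
    """Closed-form integral of (R(x) - a_min) over the active window [x1, x2]."""

    i_value: float
    x1: float
    x2: float


def _antiderivative(x, r_min, r_max, m, s, a_min):
    # F(x) = r_min*x + (r_max-r_min)/(s ln10) * ln(1 + 10^(s(x-m))) - a_min*x
    # ln(1+10^t) = logaddexp(0, t*ln10), stable for large |t|
    t = s * (x - m)
    return (r_min - a_min) * x + (r_max - r_min) / (s * LN10) * np.logaddexp(0.0, t * LN10)


def integral_above(fit: LogisticFit, settings: ScoreSettings,
                   window: tuple[float, float] | None = None) -> IntegralResult:
    """Analytic integral of the response above ``a_min`` over the window.

    The active window starts where the fitted curve crosses ``a_min`` (or at
    ``x_lo`` if the bottom asymptote already exceeds it) and runs to ``x_hi``.
    A curve whose top asymptote never reaches ``a_min`` integrates to zero.
    """
    if window is None:
        if settings.x_lo is None or settings.x_hi is None:
            raise ValueError("settings lack a window; pass one explicitly")
        x_lo, x_hi = settings.x_lo, settings.x_hi
    else:
        x_lo, x_hi = window
    a = settings.a_min

    if fit.r_max <= a:
        return IntegralResult(0.0, x_hi, x_hi)
    if fit.r_min >= a:
        x1 = x_lo
    else:
        x1 = max(x_lo, invert_response(fit, a))
        if x1 >= x_hi:
            return IntegralResult(0.0, x_hi, x_hi)
    x2 = x_hi
    val = (_antiderivative(x2, fit.r_min, fit.r_max, fit.log_ic50, fit.slope, a)
           - _antiderivative(x1, fit.r_min, fit.r_max, fit.log_ic50, fit.slope, a))
    return IntegralResult(float(max(val, 0.0)), float(x1), float(x2))


def dss(fit: LogisticFit, settings: ScoreSettings,
        window: tuple[float, float] | None = None, metric: str | None = None) -> float:
    """Drug sensitivity score (DSS1/DSS2/DSS3) on the 0-100 scale.

    This is the single formula layer for the score algebra:

        DSS1 = 100 * I / ((100 - a_min) * (x_hi - x_lo))
        DSS2 = DSS1 * log10(max(R_max, 1)) / 2
        DSS3 = DSS2 * (x2 - x1) / (x_hi - x_lo)

    so DSS3 <= DSS2 <= DSS1, all zero exactly when the integral is zero.
    """
    metric = (metric or settings.metric).upper()
    if metric not in DSS_METRICS:
        raise ValueError(f"unknown DSS metric {metric!r}")
    if window is None:
        window = (settings.x_lo, settings.x_hi)
        if window[0] is None or window[1] is None:
            raise ValueError("settings lack a window; pass one explicitly")
    x_lo, x_hi = window
    res = integral_above(fit, settings, window)
    if res.i_value <= 0.0:
        return 0.0
    width = x_hi - x_lo
    dss1 = 100.0 * res.i_value / ((100.0 - settings.a_min) * width)
    if metric == "DSS1":
        return float(dss1)
    dss2 = dss1 * np.log10(max(fit.r_max, 1.0)) / 2.0
    if metric == "DSS2":
        return float(dss2)
    return float(dss2 * (res.x2 - res.x1) / width)


def activity_area(responses: Sequence[float]) -> float:
    """Discrete Activity Area: sum of per-dose inhibition fractions.

    ``AA = sum_i max(0, response_i) / 100`` - zero with no activity, equal to
    the number of doses at 100 % inhibition everywhere.
    """
    resp = np.asarray(responses, dtype=float)
    if resp.size == 0:
        raise ValueError("activity_area needs at least one response")
    return float(np.sum(np.clip(resp, 0.0, None)) / 100.0)


def relative_ic50(fit: LogisticFit, settings: ScoreSettings) -> float:
    """Relative IC50 in nM, NaN for curves that never reach ``a_min``."""
    if fit.r_max <= settings.a_min:
        return float("nan")
    return fit.ic50


def differential_scores(matrix: ScoreMatrix, control_sample_ids: Iterable[str]) -> ScoreMatrix:
    """Differential score: per drug, subtract the mean over control samples.

    Controls are centered too (their mean includes themselves), so per drug
    the control dDSS values sum to zero; residual control spread reflects
    control-to-control variability.  Drugs with no non-missing control value
    come back all-missing.
    """
    controls = [str(c) for c in control_sample_ids]
    if matrix.metric not in DSS_METRICS:
        raise ValueError(f"differential scoring needs a DSS matrix, got {matrix.metric}")
    present = [c for c in controls if c in matrix.values.index]
    if not present:
        raise ValueError("no control sample ids present in the score matrix")
    control_mean = matrix.values.loc[present].mean(axis=0, skipna=True)
    vals = matrix.values.sub(control_mean, axis=1)
    vals.loc[:, control_mean.isna()] = np.nan
    settings = dict(matrix.settings)
    settings["controls"] = ";".join(present)
    settings["base_metric"] = matrix.metric
    return ScoreMatrix(values=vals, metric="dDSS", settings=settings)


def fits_to_frame(fits: dict[tuple[str, str], LogisticFit]) -> pd.DataFrame:
    """Tabulate per-curve fits (sample, drug, asymptotes, IC50 nM, slope, ...)."""
    rows = []
    for (sample, drug), f in fits.items():
        rows.append({
            "sample_id": sample, "drug_id": drug, "r_min": f.r_min,
            "r_max": f.r_max, "ic50_nM": f.ic50, "slope": f.slope,
            "converged": f.converged, "rss": f.rss, "n_points": f.n_points,
        })
    return pd.DataFrame(rows)


def score_curves(curves: Sequence[DoseResponseCurve], settings: ScoreSettings,
                 ) -> tuple[ScoreMatrix, dict[tuple[str, str], LogisticFit]]:
    """Fit every curve and assemble the requested score into a ScoreMatrix.

    Curves with fewer than three distinct doses score as missing.  AA is
    computed from the observed responses (no fit needed, but the fit is still
    reported when estimable); IC50 is the fitted relative IC50 in nM.
    """
    fits: dict[tuple[str, str], LogisticFit] = {}
    cells: dict[tuple[str, str], float] = {}
    for curve in curves:
        key = (curve.sample_id, curve.drug_id)
        fit = None
        try:
            fit = fit_logistic(curve)
            fits[key] = fit
        except InsufficientDataError:
            pass
        metric = settings.metric
        if metric == "AA":
            cells[key] = activity_area(curve.responses)
        elif fit is None:
            cells[key] = float("nan")
        elif metric == "IC50":
            cells[key] = relative_ic50(fit, settings)
        else:
            cells[key] = dss(fit, settings, window=settings.window_for(curve))

    samples = sorted({k[0] for k in cells})
    drugs = sorted({k[1] for k in cells})
    vals = pd.DataFrame(np.nan, index=samples, columns=drugs)
    for (s, d), v in cells.items():
        vals.loc[s, d] = v
    meta = settings.as_dict()
    return ScoreMatrix(values=vals, metric=settings.metric, settings=meta), fits


class DrugSensitivityScorer(TransformerMixin, BaseEstimator):
    """Transformer: long dose-response table -> samples x drugs score matrix.

    Parameters mirror :class:`ScoreSettings`; ``control_sample_ids`` switches
    the output to differential scores (dDSS) against those samples.

    Attributes
    ----------
    fits_ : dict[(sample_id, drug_id), LogisticFit]
    score_matrix_ : ScoreMatrix for the base metric
    """

    def __init__(self, metric: str = "DSS2", a_min: float = 10.0,
                 x_lo: float | None = None, x_hi: float | None = None,
                 control_sample_ids: Sequence[str] | None = None):
        self.metric = metric
        self.a_min = a_min
        self.x_lo = x_lo
        self.x_hi = x_hi
        self.control_sample_ids = control_sample_ids

    def _settings(self) -> ScoreSettings:
        return ScoreSettings(a_min=self.a_min, x_lo=self.x_lo, x_hi=self.x_hi,
                             metric=self.metric.upper())

    def fit(self, X: pd.DataFrame, y=None):
        curves = curves_from_frame(_validate_drt_frame(X))
        self.score_matrix_, self.fits_ = score_curves(curves, self._settings())
        return self

    def transform(self, X: pd.DataFrame | None = None) -> pd.DataFrame:
        """Return the score matrix (recomputed if a new table is given)."""
        if X is not None:
            self.fit(X)
        mat = self.score_matrix_
        if self.control_sample_ids:
            mat = differential_scores(mat, self.control_sample_ids)
        return mat.values

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        self.fit(X)
        return self.transform(None)
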