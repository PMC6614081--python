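"""Seasonal trend in monthly admission counts.

Admissions are aggregated by calendar month of the admission date and fitted
with a log-linear Poisson model containing a linear trend and the first
seasonal harmonic:

    log mu_t = b0 + b1 * trend_t + a * sin(2*pi*m_t/12) + b * cos(2*pi*m_t/12)

where m_t is the calendar month (1..12) and trend_t is the centred month
index in years.  The model is fitted by iteratively reweighted least squares
(Fisher scoring).  The seasonal component is summarised by its amplitude
sqrt(a^2 + b^2) on the log scale and by the calendar month maximising it.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FittingError


def monthly_counts(episodes: pd.DataFrame, window) -> pd.Series:
    """Admission counts per calendar month over ``window`` (zero-filled).

    Parameters
    ----------
    episodes
        Table with an ``admission_date`` column.
    window
        (start, end) dates; months outside are dropped, months with no
        admissions appear with count 0.
    """
    start, end = window
    if pd.Timestamp(start) > pd.Timestamp(end):
        raise ValueError("window start must not be after window end")
    months = pd.period_range(start=start, end=end, freq="M")
    adm = pd.to_datetime(episodes["admission_date"])
    in_win = (adm >= pd.Timestamp(start)) & (adm <= pd.Timestamp(end))
    per = adm[in_win].dt.to_period("M")
    counts = per.value_counts().reindex(months, fill_value=0).sort_index()
    counts.name = "admissions"
    counts.index.name = "month"
    return counts


@dataclass
class SeasonalFit:
    """Fitted seasonal Poisson model."""

    intercept: float
    trend: float          # per year, log scale
    sin_coef: float
    cos_coef: float
    amplitude: float      # sqrt(a^2 + b^2), log scale
    peak_month: int       # calendar month maximising the seasonal component
    deviance: float
    n_iter: int
    coef: np.ndarray
    months: pd.PeriodIndex

    def predict(self, months: pd.PeriodIndex | None = None) -> pd.Series:
        months = self.months if months is None else months
        X = _design(months, self.months)
        return pd.Series(np.exp(X @ self.coef), index=months, name="fitted")

    def as_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "trend_per_year": self.trend,
            "sin_coef": self.sin_coef,
            "cos_coef": self.cos_coef,
            "amplitude": self.amplitude,
            "peak_month": int(self.peak_month),
            "deviance": self.deviance,
            "n_iter": self.n_iter,
        }


def _design(months: pd.PeriodIndex, ref: pd.PeriodIndex) -> np.ndarray:
    """Design matrix; the trend is centred on the fitting window."""
    m = months.month.to_numpy()
    i = np.array([(p - ref[0]).n for p in months], dtype=float)
    centre = (len(ref) - 1) / 2.0
    trend = (i - centre) / 12.0
    ang = 2 * np.pi * m / 12.0
    return np.column_stack(
        [np.ones(len(months)), trend, np.sin(ang), np.cos(ang)]
    )


def _deviance(y, mu):
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return 2.0 * np.sum(term - (y - mu))


def poisson_loglik(y, mu):
    """Poisson log-likelihood up to the data-only constant."""
    return float(np.sum(y * np.log(mu) - mu))


def fit_seasonal_poisson(
    series: pd.Series, max_iter: int = 100, tol: float = 1e-10
) -> SeasonalFit:
    """Fit the trend + first-harmonic Poisson model by IRLS.

    Requires at least 12 contiguous months and a non-degenerate (not
    all-zero) series.  Convergence is declared when the relative deviance
    change drops below ``tol``; non-convergence raises
    :class:`~psyepi.errors.FittingError` carrying the deviance trace.
    """
    if len(series) < 12:
        raise ValueError("need at least 12 months of counts")
    y = series.to_numpy(dtype=float)
    if np.any(y < 0):
        raise ValueError("counts must be >= 0")
    if np.all(y == 0):
        raise ValueError("all counts are zero; nothing to fit")
    months = pd.PeriodIndex(series.index, freq="M")
    X = _design(months, months)

    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-8))
    dev = np.inf
    trace = []
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = np.exp(np.clip(eta, -30, 30))
        z = eta + (y - mu) / mu
        W = mu
        XtW = X.T * W
        beta = np.linalg.solve(XtW @ X, XtW @ z)
        new_dev = _deviance(y, np.exp(np.clip(X @ beta, -30, 30)))
        trace.append(new_dev)
        # relative criterion with an offset so near-zero deviances converge
        if np.isfinite(dev) and abs(dev - new_dev) <= tol * (abs(new_dev) + 0.1):
            dev = new_dev
            break
        dev = new_dev
    else:
        raise FittingError(
            f"IRLS did not converge in {max_iter} iterations", trace
        )

    a, b = beta[2], beta[3]
    amp = float(np.hypot(a, b))
    cal = np.arange(1, 13)
    seas = a * np.sin(2 * np.pi * cal / 12.0) + b * np.cos(2 * np.pi * cal / 12.0)
    peak = int(cal[np.argmax(seas)])
    return SeasonalFit(
        intercept=float(beta[0]),
        trend=float(beta[1]),
        sin_coef=float(a),
        cos_coef=float(b),
        amplitude=amp,
        peak_month=peak,
        deviance=float(dev),
        n_iter=it,
        coef=beta,
        months=months,
    )
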