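"""Nonparametric competing-risks estimation: Aalen-Johansen and Kaplan-Meier.

Discharge to the community competes with transfer to a general ward and death
on the ward.  The cause-specific cumulative incidence function (CIF) is
estimated by the Aalen-Johansen product-limit construction: at each distinct
time t_j with n_j subjects at risk and d_kj cause-k events,

    S(t_j)     = S(t_{j-1}) * (1 - sum_k d_kj / n_j)
    CIF_k(t_j) = CIF_k(t_{j-1}) + S(t_{j-1}) * d_kj / n_j

Censored subjects leave the risk set after their censoring time; events at a
tied time are processed jointly, and events precede censorings at ties.  The
curves are right-continuous step functions, so evaluation exactly at an event
time includes that time's events.  By construction the identity
``sum_k CIF_k(t) + S(t) = 1`` holds at every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CENSORED = "censored"


@dataclass
class CIFCurve:
    """Step functions of cause-specific cumulative incidence.

    Attributes
    ----------
    times
        Sorted distinct observation times (event or censoring).
    cif
        Per cause, the cumulative incidence immediately after each time.
    survival
        All-cause event-free probability after each time.
    n_at_risk
        Number at risk just before each time.
    n
        Sample size.
    variance
        Optional per-cause CIF variance estimates (Aalen-type).
    """

    times: np.ndarray
    cif: dict
    survival: np.ndarray
    n_at_risk: np.ndarray
    n: int
    variance: dict | None = None

    @property
    def causes(self) -> tuple:
        return tuple(self.cif)

    def as_frame(self) -> pd.DataFrame:
        """Tidy export: one row per (time, cause)."""
        rows = []
        for cause, vals in self.cif.items():
            rows.append(
                pd.DataFrame(
                    {
                        "time": self.times,
                        "cause": cause,
                        "cif": vals,
                        "survival": self.survival,
                        "n_at_risk": self.n_at_risk,
                    }
                )
            )
        if not rows:  # survival-only curve
            rows.append(
                pd.DataFrame(
                    {
                        "time": self.times,
                        "cause": "any",
                        "cif": 1.0 - self.survival,
                        "survival": self.survival,
                        "n_at_risk": self.n_at_risk,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _prepare(durations, events):
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=object)
    if t.ndim != 1 or len(t) == 0:
        raise ValueError("sample must be a nonempty 1-d array of durations")
    if len(e) != len(t):
        raise ValueError("durations and events must have equal length")
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("durations must be finite and positive")
    return t, e


def aalen_johansen(durations, events, causes=None, variance: bool = False) -> CIFCurve:
    """Aalen-Johansen estimator of cause-specific cumulative incidence.

    Parameters
    ----------
    durations
        Days from admission to the event or censoring (positive).
    events
        Cause label per subject; ``"censored"`` for censored follow-up.
    causes
        Cause labels to estimate; defaults to the sorted labels observed.
        An all-censored sample yields valid all-zero curves.
    variance
        Also compute the Aalen-type variance of each CIF.
    """
    t, e = _prepare(durations, events)
    if causes is None:
        causes = sorted(set(e) - {CENSORED})
    causes = list(causes)
    if CENSORED in causes:
        raise ValueError("'censored' is not an event cause")
    unknown = set(e) - set(causes) - {CENSORED}
    if unknown:
        raise ValueError(f"unknown event labels {sorted(unknown)}")

    times = np.unique(t)
    k = len(times)
    idx = np.searchsorted(times, t)
    # counts per distinct time
    d = np.zeros((len(causes), k))
    for ci, cause in enumerate(causes):
        np.add.at(d[ci], idx[e == cause], 1)
    total_obs = np.bincount(idx, minlength=k).astype(float)
    n_at_risk = len(t) - np.concatenate([[0.0], np.cumsum(total_obs)[:-1]])

    d_tot = d.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(n_at_risk > 0, d_tot / n_at_risk, 0.0)
    s_prev = np.concatenate([[1.0], np.cumprod(1.0 - frac)])[:-1]
    survival = s_prev * (1.0 - frac)
    cif = {}
    for ci, cause in enumerate(causes):
        with np.errstate(divide="ignore", invalid="ignore"):
            inc = np.where(n_at_risk > 0, s_prev * d[ci] / n_at_risk, 0.0)
        cif[cause] = np.cumsum(inc)

    var = None
    if variance:
        var = {
            cause: _aalen_variance(
                cif[cause], s_prev, d[ci], d_tot, n_at_risk
            )
            for ci, cause in enumerate(causes)
        }
    return CIFCurve(
        times=times,
        cif=cif,
        survival=survival,
        n_at_risk=n_at_risk,
        n=len(t),
        variance=var,
    )


def _aalen_variance(F, s_prev, d_k, d_tot, n):
    """Pointwise variance of one CIF (Marubini-Valsecchi form), vectorised.

    Each term depends on F(t) - F(t_j) for steps j <= t; expanding the
    squares turns every sum into a cumulative sum.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(
            (n > 0) & (n - d_tot > 0), d_tot / (n * (n - d_tot)), 0.0
        )
        v = np.where(n > 0, s_prev * d_k / n**2, 0.0)
        g = np.where(n > 0, s_prev**2 * (n - d_k) * d_k / n**3, 0.0)
    A = np.cumsum(u)
    B = np.cumsum(F * u)
    C = np.cumsum(F**2 * u)
    D = np.cumsum(v)
    E = np.cumsum(F * v)
    G = np.cumsum(g)
    var = (F**2 * A - 2 * F * B + C) + G - 2 * (F * D - E)
    return np.maximum(var, 0.0)


def km_event_free(durations, events) -> CIFCurve:
    """Kaplan-Meier product-limit estimate of all-cause event-free survival.

    Any non-censored label counts as an event.  Returned as a
    :class:`CIFCurve` with an empty ``cif`` mapping.
    """
    t, e = _prepare(durations, events)
    collapsed = np.where(e == CENSORED, CENSORED, "event")
    curve = aalen_johansen(t, collapsed, causes=["event"])
    return CIFCurve(
        times=curve.times,
        cif={},
        survival=curve.survival,
        n_at_risk=curve.n_at_risk,
        n=curve.n,
    )


def cif_at(curve: CIFCurve, cause: str, t) -> float:
    """Right-continuous CIF value at time(s) ``t`` (0 before the first step)."""
    if cause not in curve.cif:
        raise ValueError(
            f"unknown cause {cause!r}; curve has {sorted(curve.cif)}"
        )
    tt = np.asarray(t, dtype=float)
    idx = np.searchsorted(curve.times, tt, side="right") - 1
    vals = np.where(idx >= 0, curve.cif[cause][np.maximum(idx, 0)], 0.0)
    return float(vals) if np.isscalar(t) or tt.ndim == 0 else vals


def survival_at(curve: CIFCurve, t) -> float:
    """Right-continuous event-free survival at time(s) ``t`` (1 before steps)."""
    tt = np.asarray(t, dtype=float)
    idx = np.searchsorted(curve.times, tt, side="right") - 1
    vals = np.where(idx >= 0, curve.survival[np.maximum(idx, 0)], 1.0)
    return float(vals) if np.isscalar(t) or tt.ndim == 0 else vals


def sample_from_episodes(episodes: pd.DataFrame):
    """(durations, events) arrays from an outcome-assigned episode table."""
    return (
        episodes["event_time"].to_numpy(dtype=float),
        episodes["outcome"].to_numpy(dtype=object),
    )
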