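"""Piecewise-constant cause-specific hazards with closed-form cumulative incidence.

Length of stay is modelled in days since admission with competing causes of
episode termination (discharge to community, transfer to a general ward, death
on the ward).  Each cause has a constant daily hazard on the intervals
[0, 90), [90, 180), [180, 270), [270, inf) — a change-point structure that
matches the segmented discharge pattern of acute psychiatric units, where
discharge intensity drops after the 90-day certification horizon.

For constant hazards h_k on an interval with total hazard H, the cumulative
incidence of cause k gained over [a, t] is

    dCIF_k = (h_k / H) * S(a) * (1 - exp(-H * (t - a)))

which both evaluates the model CIF exactly and inverts it: given target CIF
values at the interval endpoints the hazards have a unique closed-form
solution, computed interval by interval by :func:`calibrate_hazards`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError

#: interval left endpoints in days; the last interval is open-ended
BREAKS = (0.0, 90.0, 180.0, 270.0)

#: horizons (days) at which printed cumulative-incidence tables are evaluated
HORIZONS = (90, 180, 270, 360)


@dataclass(frozen=True)
class PiecewiseHazards:
    """Cause-specific daily hazards, one rate per cause per interval.

    Parameters
    ----------
    rates
        Mapping cause label -> sequence of daily hazards, one per interval
        of :data:`BREAKS`.
    breaks
        Interval left endpoints in days (ascending, starting at 0).
    """

    rates: Mapping[str, tuple]
    breaks: tuple = BREAKS

    def __post_init__(self):
        object.__setattr__(
            self,
            "rates",
            {c: tuple(float(x) for x in r) for c, r in self.rates.items()},
        )
        for cause, r in self.rates.items():
            if len(r) != len(self.breaks):
                raise ConfigError(
                    f"cause_hazards[{cause!r}]: expected {len(self.breaks)} rates, got {len(r)}"
                )
            if any(x < 0 for x in r):
                raise ConfigError(f"cause_hazards[{cause!r}]: hazards must be >= 0")

    @property
    def causes(self) -> tuple:
        return tuple(self.rates)

    def _rate_matrix(self) -> np.ndarray:
        """(n_causes, n_intervals) array of rates in cause order."""
        return np.array([self.rates[c] for c in self.causes], dtype=float)

    def total_rates(self) -> np.ndarray:
        return self._rate_matrix().sum(axis=0)

    def cumulative_hazard(self, t) -> np.ndarray:
        """All-cause cumulative hazard Lambda(t), vectorised over t."""
        t = np.asarray(t, dtype=float)
        b = np.asarray(self.breaks)
        # exposure inside each interval
        upper = np.append(b[1:], np.inf)
        expo = np.clip(t[..., None] - b, 0.0, upper - b)
        return expo @ self.total_rates()

    def survival(self, t) -> np.ndarray:
        """All-cause event-free probability S(t) = exp(-Lambda(t))."""
        return np.exp(-self.cumulative_hazard(t))

    def cif(self, cause: str, t) -> np.ndarray:
        """Closed-form cumulative incidence of `cause` at time(s) t."""
        if cause not in self.rates:
            raise KeyError(f"unknown cause {cause!r}")
        t = np.asarray(t, dtype=float)
        b = np.asarray(self.breaks)
        upper = np.append(b[1:], np.inf)
        H = self.total_rates()
        hk = np.asarray(self.rates[cause])
        s_start = np.exp(-self.cumulative_hazard(b))  # S at interval starts
        out = np.zeros(np.broadcast(t, np.array(0.0)).shape, dtype=float)
        tt = np.atleast_1d(t).astype(float)
        acc = np.zeros_like(tt)
        for i in range(len(b)):
            dt = np.clip(tt - b[i], 0.0, upper[i] - b[i])
            if H[i] > 0:
                acc += (hk[i] / H[i]) * s_start[i] * (-np.expm1(-H[i] * dt))
        out[...] = acc.reshape(out.shape) if out.shape else acc[0]
        return out if out.shape else float(acc[0])

    def total_cif(self, t):
        """Probability that any cause has occurred by t: 1 - S(t)."""
        return 1.0 - self.survival(t)

    def sample(self, rng: np.random.Generator, n: int):
        """Draw n (time, cause) pairs by inverting the cumulative hazard.

        Returns
        -------
        times : float ndarray
            Event times in days; ``inf`` where no cause ever fires
            (possible only if the last interval's total hazard is 0).
        causes : object ndarray
            Cause labels; ``None`` where time is ``inf``.
        """
        b = np.asarray(self.breaks)
        width = np.append(np.diff(b), np.inf)
        H = self.total_rates()
        lam_start = np.concatenate([[0.0], np.cumsum(H[:-1] * width[:-1])])
        e = rng.exponential(size=n)
        # interval containing each exponential draw
        lam_end = lam_start + H * width  # inf-safe: last width inf
        with np.errstate(invalid="ignore"):
            idx = np.searchsorted(np.nan_to_num(lam_end, nan=np.inf), e, side="left")
        idx = np.minimum(idx, len(b) - 1)
        times = np.full(n, np.inf)
        ok = H[idx] > 0
        times[ok] = b[idx[ok]] + (e[ok] - lam_start[idx[ok]]) / H[idx[ok]]
        # residual mass that never fires stays at inf
        never = ~ok | (times > 1e12)
        times[never] = np.inf
        # cause draw conditional on the firing interval
        mat = self._rate_matrix()  # (n_causes, n_int)
        with np.errstate(divide="ignore", invalid="ignore"):
            probs = np.where(H > 0, mat / H, 0.0)
        cum = np.cumsum(probs, axis=0)
        u = rng.random(n)
        cause_idx = (u[None, :] > cum[:, idx]).sum(axis=0)
        cause_idx = np.minimum(cause_idx, mat.shape[0] - 1)
        labels = np.array(self.causes, dtype=object)
        causes = np.where(never, None, labels[cause_idx])
        return times, causes


def calibrate_hazards(
    targets: Mapping[str, Sequence[float]],
    horizons: Sequence[float] = HORIZONS,
    percent: bool = False,
) -> PiecewiseHazards:
    """Solve piecewise-constant cause-specific hazards from target CIF values.

    Parameters
    ----------
    targets
        Mapping cause -> cumulative incidence at each horizon (nondecreasing).
        Values are proportions in [0, 1], or percentages if ``percent=True``.
    horizons
        Interval right endpoints in days; the fitted hazard of the final
        interval also applies beyond the last horizon.
    percent
        Interpret target values as percentages.

    Returns
    -------
    PiecewiseHazards whose closed-form CIF reproduces every target exactly
    (to floating-point round-off).

    Raises
    ------
    ConfigError
        If targets decrease, or an interval's total increment is infeasible
        (exceeds the survival mass entering the interval).
    """
    horizons = [float(h) for h in horizons]
    causes = list(targets)
    tgt = np.array([[float(v) for v in targets[c]] for c in causes])
    if percent:
        tgt = tgt / 100.0
    if tgt.shape[1] != len(horizons):
        raise ConfigError("each cause needs one target per horizon")
    if np.any(tgt < 0) or np.any(tgt > 1):
        raise ConfigError("CIF targets must lie in [0, 1]")
    inc = np.diff(np.hstack([np.zeros((len(causes), 1)), tgt]), axis=1)
    if np.any(inc < -1e-12):
        raise ConfigError("CIF targets must be nondecreasing per cause")
    inc = np.clip(inc, 0.0, None)
    widths = np.diff([0.0] + horizons)
    rates = np.zeros_like(inc)
    s = 1.0
    for j, w in enumerate(widths):
        dtot = inc[:, j].sum()
        if dtot > 0:
            if dtot >= s:
                raise ConfigError(
                    f"interval {j}: total CIF increment {dtot:.6g} exceeds "
                    f"available survival mass {s:.6g}"
                )
            big_h = -np.log1p(-dtot / s) / w
            rates[:, j] = big_h * inc[:, j] / dtot
        s -= dtot
    breaks = tuple([0.0] + horizons[:-1])
    return PiecewiseHazards({c: tuple(rates[i]) for i, c in enumerate(causes)}, breaks)
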