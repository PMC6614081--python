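"""Episode construction from stay records and cohort selection rules.

A single admission episode runs from the date of admission to a psychiatric
ward (from the community or a general ward) until discharge to the community,
transfer to a general ward, or death — concatenating consecutive stays of the
same patient across wards and hospitals.  Two stays chain when the next admit
date falls within ``gap_days`` of the previous discharge date.

Cohort rules:

* episodes already in progress at the study-window start (prevalent) are
  excluded, as are episodes entirely outside the window;
* the patient must be verifiably enrolled before the admission (an enrollment
  marker in an earlier month, or any earlier claim);
* patients ever hospitalised in two hospitals simultaneously are excluded
  wholesale (identification-code errors).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataValidationError

OUTCOME_CAUSES = ("community", "general_ward", "death")


@dataclass
class CohortFilterLog:
    """Accounting of episodes removed by each cohort rule."""

    n_input: int = 0
    removed_prevalent: int = 0
    removed_out_of_window: int = 0
    removed_enrollment_unverified: int = 0
    removed_same_day_multi_hospital: int = 0
    n_retained: int = 0

    @property
    def n_removed(self) -> int:
        return (
            self.removed_prevalent
            + self.removed_out_of_window
            + self.removed_enrollment_unverified
            + self.removed_same_day_multi_hospital
        )

    def as_frame(self) -> pd.DataFrame:
        rows = [
            ("input", self.n_input),
            ("removed_prevalent", self.removed_prevalent),
            ("removed_out_of_window", self.removed_out_of_window),
            ("removed_enrollment_unverified", self.removed_enrollment_unverified),
            ("removed_same_day_multi_hospital", self.removed_same_day_multi_hospital),
            ("retained", self.n_retained),
        ]
        return pd.DataFrame(rows, columns=["rule", "count"])


def _as_day(x) -> pd.Timestamp:
    return pd.Timestamp(x)


def link_segments(
    stays: pd.DataFrame, gap_days: int = 1, return_assignments: bool = False
):
    """Chain stay records of each patient into admission episodes.

    Two consecutive stays of one patient belong to the same episode iff the
    next admit date is at most ``gap_days`` after the previous discharge
    date.  An open stay (no discharge date) always terminates its chain.

    Returns an episode table (one row per episode) whose attributes come
    from the admitting (first) segment: fee type at admission, admitting
    hospital and its prefecture, legal admission type, demographics.  The
    transfer flag is true iff the episode spans two or more hospitals.

    With ``return_assignments=True`` additionally returns the input stays
    annotated with their ``episode_id``.
    """
    if gap_days < 0:
        raise ValueError("gap_days must be >= 0")
    required = {"patient_id", "hospital_id", "admit_date", "discharge_date"}
    missing = required - set(stays.columns)
    if missing:
        raise DataValidationError(f"stays table lacks columns {sorted(missing)}")
    s = stays.copy()
    s["admit_date"] = pd.to_datetime(s["admit_date"])
    s["discharge_date"] = pd.to_datetime(s["discharge_date"])
    bad = s["discharge_date"].notna() & (s["discharge_date"] < s["admit_date"])
    if bad.any():
        rows = s.index[bad].tolist()[:5]
        raise DataValidationError(f"discharge before admission in stay rows {rows}")

    s = s.sort_values(
        ["patient_id", "admit_date", "discharge_date"], kind="stable"
    ).reset_index(drop=True)
    pid = s["patient_id"].to_numpy()
    admit = s["admit_date"].to_numpy()
    disc = s["discharge_date"].to_numpy()
    prev_pid = np.roll(pid, 1)
    prev_disc = np.roll(disc, 1)
    gap = np.timedelta64(int(gap_days), "D")
    with np.errstate(invalid="ignore"):
        chained = (
            (pid == prev_pid)
            & ~pd.isna(prev_disc)
            & (admit <= prev_disc + gap)
        )
    chained[0] = False
    episode_id = np.cumsum(~chained)
    s["episode_id"] = episode_id

    g = s.groupby("episode_id", sort=True)
    first = s.drop_duplicates("episode_id", keep="first").set_index("episode_id")
    # terminal segment: the row with the latest discharge; open stays sort last
    last = (
        s.assign(_rank=s["discharge_date"].fillna(pd.Timestamp.max))
        .sort_values(["episode_id", "_rank"], kind="stable")
        .drop_duplicates("episode_id", keep="last")
        .set_index("episode_id")
    )

    episodes = pd.DataFrame(
        {
            "patient_id": first["patient_id"],
            "admission_date": g["admit_date"].min(),
            "end_date": last["discharge_date"],
            "destination_final": last["destination"]
            if "destination" in s.columns
            else None,
            "n_segments": g.size(),
            "transfer": g["hospital_id"].nunique() >= 2,
            "fee_type": first["ward_fee_code"]
            if "ward_fee_code" in s.columns
            else None,
            "admitting_hospital": first["hospital_id"],
            "prefecture": first["prefecture"] if "prefecture" in s.columns else None,
        }
    )
    for col in ("legal_admission", "ect", "diagnosis", "sex", "age_group"):
        if col in s.columns:
            episodes[col] = g[col].agg("any") if col == "ect" else first[col]
    episodes = episodes.reset_index()
    if return_assignments:
        return episodes, s
    return episodes


def assign_outcome(
    episodes: pd.DataFrame,
    observation_end: dt.date,
    max_days: int = 365,
) -> pd.DataFrame:
    """Attach the competing-risks outcome and event time to each episode.

    Follow-up is administratively censored at the earlier of
    ``observation_end`` and ``max_days`` after admission.  An episode whose
    terminal destination is community / general ward / death on or before
    that boundary gets that outcome at its event time (days from admission,
    floored at 1); otherwise it is censored at the boundary.

    A terminal destination of ``other_hospital`` means the transfer chain
    was never closed and is rejected.
    """
    out = episodes.copy()
    adm = pd.to_datetime(out["admission_date"])
    end = pd.to_datetime(out["end_date"])
    dest = out["destination_final"]
    bad = end.notna() & (dest == "other_hospital")
    if bad.any():
        ids = out.loc[bad, "episode_id"].tolist()[:5]
        raise DataValidationError(
            f"episodes {ids}: terminal destination 'other_hospital' "
            "(unterminated transfer chain)"
        )
    censor_date = np.minimum(
        np.datetime64(pd.Timestamp(observation_end), "ns"),
        (adm + pd.Timedelta(days=int(max_days))).to_numpy(),
    )
    censor_date = pd.Series(censor_date, index=out.index)
    is_event = end.notna() & dest.isin(OUTCOME_CAUSES) & (end <= censor_date)
    out["outcome"] = np.where(is_event, dest, "censored")
    end_eff = end.where(is_event, censor_date)
    out["analysis_end_date"] = end_eff
    days = (end_eff - adm).dt.days
    out["event_time"] = np.maximum(1, days.to_numpy())
    return out


def _overlapping_patients(stays: pd.DataFrame) -> set:
    """Patients with two strictly overlapping stays at different hospitals.

    Boundary contact (discharge day == next admit day) is the normal
    transfer pattern and does not count; only proper interval overlap does.
    Open stays extend to +inf.
    """
    s = stays[["patient_id", "hospital_id", "admit_date", "discharge_date"]].copy()
    s["admit_date"] = pd.to_datetime(s["admit_date"])
    s["discharge_date"] = pd.to_datetime(s["discharge_date"]).fillna(pd.Timestamp.max)
    s = s.sort_values(["patient_id", "admit_date"], kind="stable")
    flagged = set()
    for pid, grp in s.groupby("patient_id", sort=False):
        if len(grp) < 2:
            continue
        a = grp["admit_date"].to_numpy()
        d = grp["discharge_date"].to_numpy()
        h = grp["hospital_id"].to_numpy()
        # cheap screen: next admit strictly before running max discharge
        run_max = np.maximum.accumulate(d)
        if not (a[1:] < run_max[:-1]).any():
            continue
        k = len(grp)
        for i in range(k):
            for j in range(i + 1, k):
                if h[i] != h[j] and a[j] < d[i] and a[i] < d[j]:
                    flagged.add(pid)
                    break
            if pid in flagged:
                break
    return flagged


def apply_cohort_filters(
    episodes: pd.DataFrame,
    enrollment: pd.DataFrame,
    window_start: dt.date,
    window_end: dt.date,
    stays: pd.DataFrame | None = None,
    extra_claims: pd.DataFrame | None = None,
):
    """Apply the new-admission cohort rules; returns (episodes, log).

    Rules, in order (an episode is counted under the first rule it fails):

    1. window: episodes admitted before ``window_start`` are prevalent if
       still in the ward at the window start, otherwise out-of-window;
       episodes admitted after ``window_end`` are out-of-window.
    2. enrollment: the patient needs an enrollment marker in a month strictly
       before the admission month, or any claim dated strictly before the
       admission date (earlier stays, ``extra_claims`` rows).
    3. identification errors: all episodes of any patient with two strictly
       overlapping stays at different hospitals are removed (requires
       ``stays``).
    """
    log = CohortFilterLog(n_input=len(episodes))
    if len(episodes) == 0:
        return episodes.copy(), log
    ep = episodes.copy()
    ws = pd.Timestamp(window_start)
    we = pd.Timestamp(window_end)
    adm = pd.to_datetime(ep["admission_date"])
    end = pd.to_datetime(ep["end_date"])

    in_ward_at_start = end.isna() | (end >= ws)
    prevalent = (adm < ws) & in_ward_at_start
    out_of_window = ((adm < ws) & ~in_ward_at_start) | (adm > we)
    log.removed_prevalent = int(prevalent.sum())
    log.removed_out_of_window = int(out_of_window.sum())
    keep = ~(prevalent | out_of_window)

    # enrollment verification
    adm_month = adm.dt.to_period("M")
    verified = pd.Series(False, index=ep.index)
    if enrollment is not None and len(enrollment):
        marks = enrollment.copy()
        month = pd.PeriodIndex(marks["month"].astype(str), freq="M")
        first_mark = (
            pd.Series(month, index=marks.index)
            .groupby(marks["patient_id"].to_numpy())
            .min()
        )
        fm = ep["patient_id"].map(first_mark)
        verified |= fm.notna() & (fm < adm_month)
    claim_dates = []
    if extra_claims is not None and len(extra_claims):
        date_col = "admit_date" if "admit_date" in extra_claims.columns else "date"
        claim_dates.append(
            extra_claims[["patient_id", date_col]].rename(columns={date_col: "date"})
        )
    if stays is not None and len(stays):
        claim_dates.append(
            stays[["patient_id", "admit_date"]].rename(columns={"admit_date": "date"})
        )
    if claim_dates:
        all_claims = pd.concat(claim_dates, ignore_index=True)
        all_claims["date"] = pd.to_datetime(all_claims["date"])
        first_claim = all_claims.groupby("patient_id")["date"].min()
        fc = ep["patient_id"].map(first_claim)
        verified |= fc.notna() & (fc < adm)
    unverified = keep & ~verified
    log.removed_enrollment_unverified = int(unverified.sum())
    keep &= verified

    # same-day multi-hospital exclusions
    if stays is not None and len(stays):
        flagged = _overlapping_patients(stays)
        if flagged:
            collided = keep & ep["patient_id"].isin(flagged)
            log.removed_same_day_multi_hospital = int(collided.sum())
            keep &= ~collided

    out = ep.loc[keep].reset_index(drop=True)
    log.n_retained = len(out)
    assert log.n_retained + log.n_removed == log.n_input
    return out, log


def classify_admission(episodes: pd.DataFrame) -> pd.DataFrame:
    """Derive the admission type: planned / voluntary / involuntary.

    A planned admission is operationally defined as electroconvulsive
    therapy anywhere in the episode with a total stay of at most 3 days;
    all other episodes carry the legal admission flag (voluntary or
    involuntary) of the admitting segment.  Requires ``event_time``.
    """
    out = episodes.copy()
    planned = out["ect"].astype(bool) & (out["event_time"] <= 3)
    out["admission_type"] = np.where(planned, "planned", out["legal_admission"])
    return out


def classify_route(
    episodes: pd.DataFrame, general_ward_stays: pd.DataFrame | None
) -> pd.DataFrame:
    """Derive the admission route: from a general ward or from the community.

    Route is ``general_ward`` iff a general-ward stay of the same patient
    ends on the admission date or the day before; otherwise ``community``.
    """
    out = episodes.copy()
    out["route"] = "community"
    if general_ward_stays is None or len(general_ward_stays) == 0:
        return out
    gw = general_ward_stays.copy()
    gw["discharge_date"] = pd.to_datetime(gw["discharge_date"])
    key = set(zip(gw["patient_id"].to_numpy(), gw["discharge_date"].to_numpy()))
    adm = pd.to_datetime(out["admission_date"]).to_numpy()
    pid = out["patient_id"].to_numpy()
    day = np.timedelta64(1, "D")
    hit = np.fromiter(
        (
            (p, a) in key or (p, a - day) in key
            for p, a in zip(pid, adm)
        ),
        dtype=bool,
        count=len(out),
    )
    out.loc[hit, "route"] = "general_ward"
    return out
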