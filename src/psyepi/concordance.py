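"""Episode-based vs. single-hospital ("630 survey"-style) indicators.

The annual facility survey defines an admission and its discharge from a
single hospital's records: a transfer in from another psychiatric hospital
looks like a new admission, and a transfer out is not a community discharge
and ends the hospital's knowledge of the patient.  This module builds that
single-hospital view of the raw stay records, computes prefecture-level
indicators under both definitions, and correlates them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .survival import aalen_johansen, cif_at, sample_from_episodes

INDICATORS = (
    "admissions",
    "admissions_by_age",
    "admissions_by_diagnosis",
    "community_discharge_proportion",
)


def single_hospital_view(
    stays: pd.DataFrame, window=None, gap_days: int = 1
) -> pd.DataFrame:
    """Pseudo-admissions as each hospital would report them in isolation.

    Consecutive stays of a patient *within the same hospital* are chained
    under the same gap rule as episode linkage; every chain is one
    pseudo-admission.  The terminal destination is whatever that hospital
    recorded — ``other_hospital`` (transfer out) is not a community
    discharge.  ``window`` optionally restricts to admissions inside
    (start, end).
    """
    s = stays.copy()
    s["admit_date"] = pd.to_datetime(s["admit_date"])
    s["discharge_date"] = pd.to_datetime(s["discharge_date"])
    s = s.sort_values(
        ["patient_id", "hospital_id", "admit_date", "discharge_date"], kind="stable"
    ).reset_index(drop=True)
    pid = s["patient_id"].to_numpy()
    hid = s["hospital_id"].to_numpy()
    admit = s["admit_date"].to_numpy()
    prev_disc = np.roll(s["discharge_date"].to_numpy(), 1)
    same = (pid == np.roll(pid, 1)) & (hid == np.roll(hid, 1))
    gap = np.timedelta64(int(gap_days), "D")
    with np.errstate(invalid="ignore"):
        chained = same & ~pd.isna(prev_disc) & (admit <= prev_disc + gap)
    if len(chained):
        chained[0] = False
    s["pseudo_id"] = np.cumsum(~chained)

    first = s.drop_duplicates("pseudo_id", keep="first").set_index("pseudo_id")
    last = (
        s.assign(_rank=s["discharge_date"].fillna(pd.Timestamp.max))
        .sort_values(["pseudo_id", "_rank"], kind="stable")
        .drop_duplicates("pseudo_id", keep="last")
        .set_index("pseudo_id")
    )
    out = pd.DataFrame(
        {
            "patient_id": first["patient_id"],
            "hospital_id": first["hospital_id"],
            "prefecture": first["prefecture"] if "prefecture" in s.columns else None,
            "admit_date": first["admit_date"],
            "end_date": last["discharge_date"],
            "destination_final": last["destination"]
            if "destination" in s.columns
            else None,
        }
    )
    for col in ("diagnosis", "sex", "age_group", "ward_fee_code"):
        if col in s.columns:
            out[col] = first[col]
    out["duration"] = np.maximum(
        1, (out["end_date"] - out["admit_date"]).dt.days
    )
    out = out.reset_index()
    if window is not None:
        start, end = window
        out = out[
            (out["admit_date"] >= pd.Timestamp(start))
            & (out["admit_date"] <= pd.Timestamp(end))
        ].reset_index(drop=True)
    return out


def _count_table(df, prefectures, indicator, level_col=None):
    rows = []
    if level_col is None:
        counts = df.groupby("prefecture").size()
        for p in prefectures:
            rows.append(
                {
                    "indicator": indicator,
                    "level": "all",
                    "prefecture": p,
                    "value": int(counts.get(p, 0)),
                }
            )
    else:
        counts = df.groupby(["prefecture", level_col]).size()
        for lev in sorted(df[level_col].dropna().unique()):
            for p in prefectures:
                rows.append(
                    {
                        "indicator": indicator,
                        "level": lev,
                        "prefecture": p,
                        "value": int(counts.get((p, lev), 0)),
                    }
                )
    return rows


def prefecture_indicators(
    data: pd.DataFrame,
    mode: str = "episode",
    horizon: int = 360,
    prefectures=None,
) -> pd.DataFrame:
    """Prefecture-level indicator table under one of the two definitions.

    Indicators: admission counts (overall, by age group, by diagnosis) and
    the proportion (%) discharged to the community within ``horizon`` days.
    In ``episode`` mode the proportion is the Aalen-Johansen cumulative
    incidence at the horizon; in ``single_hospital`` mode it is the crude
    within-hospital proportion (transfers out count as not discharged).
    Prefectures without admissions keep their count rows (0) and get a
    missing, flagged proportion.
    """
    if mode not in ("episode", "single_hospital"):
        raise ValueError("mode must be 'episode' or 'single_hospital'")
    df = data
    if prefectures is None:
        prefectures = sorted(df["prefecture"].dropna().unique())
    rows = []
    rows += _count_table(df, prefectures, "admissions")
    if "age_group" in df.columns:
        rows += _count_table(df, prefectures, "admissions_by_age", "age_group")
    if "diagnosis" in df.columns:
        rows += _count_table(df, prefectures, "admissions_by_diagnosis", "diagnosis")
    for p in prefectures:
        sub = df[df["prefecture"] == p]
        if len(sub) == 0:
            val = np.nan
        elif mode == "episode":
            durations, events = sample_from_episodes(sub)
            curve = aalen_johansen(durations, events)
            val = (
                100.0 * cif_at(curve, "community", horizon)
                if "community" in curve.cif
                else 0.0
            )
        else:
            hit = (sub["destination_final"] == "community") & (
                sub["duration"] <= horizon
            )
            val = 100.0 * hit.mean()
        rows.append(
            {
                "indicator": "community_discharge_proportion",
                "level": "all",
                "prefecture": p,
                "value": val,
            }
        )
    out = pd.DataFrame(rows)
    out["undefined"] = out["value"].isna()
    return out


def pearson(x, y) -> float:
    """Product-moment correlation of two equal-length vectors.

    Requires length >= 3 and nonconstant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float((xc * yc).sum() / (sx * sy))


def correlate_indicators(
    episode_table: pd.DataFrame, single_table: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation across prefectures, per indicator/level pair.

    Prefecture rows missing in either table (or undefined) are dropped
    pairwise; groups left with fewer than 3 prefectures or a constant
    vector report a missing correlation.
    """
    merged = episode_table.merge(
        single_table,
        on=["indicator", "level", "prefecture"],
        suffixes=("_episode", "_single"),
    ).dropna(subset=["value_episode", "value_single"])
    rows = []
    for (ind, lev), grp in merged.groupby(["indicator", "level"], sort=False):
        try:
            r = pearson(grp["value_episode"], grp["value_single"])
        except ValueError:
            r = np.nan
        rows.append(
            {
                "indicator": ind,
                "level": lev,
                "n_prefectures": len(grp),
                "pearson_r": r,
            }
        )
    return pd.DataFrame(rows)
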