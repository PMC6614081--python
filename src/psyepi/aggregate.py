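"""Descriptive tables: cohort characteristics, stratified cumulative
incidence, and hospital-level discharge-rate rank groups.

The hospital-level "discharge rate within 90 days" is the crude proportion
of a hospital's episodes discharged to the community within the horizon (not
a competing-risks estimate): published rank-group ranges that include exact
0.0 and 100.0 endpoints indicate simple proportions, and competing events
are rare at 90 days.  Hospitals with fewer than ``min_patients`` episodes
are excluded; the remainder are sorted by rate (ties broken by hospital id)
and cut into five near-equal groups when a fee type has at least 20 eligible
hospitals, otherwise three.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .hazards import HORIZONS
from .survival import aalen_johansen, cif_at, sample_from_episodes

#: characteristic blocks of the cohort description, in display order
DESCRIBE_BLOCKS = (
    ("route", "route"),
    ("fee_type", "fee_type"),
    ("admission_type", "admission_type"),
    ("transfer", "transfer"),
    ("sex", "sex"),
    ("age_group", "age_group"),
    ("diagnosis", "diagnosis"),
)


def describe_cohort(episodes: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per characteristic block (Table-1 style).

    Only blocks whose column is present are reported; the transfer flag is
    rendered as with/without.  Percentages within a block sum to 100.
    """
    n = len(episodes)
    rows = []
    for block, col in DESCRIBE_BLOCKS:
        if col not in episodes.columns:
            continue
        vals = episodes[col]
        if col == "transfer":
            vals = np.where(vals.astype(bool), "with", "without")
            vals = pd.Series(vals)
        counts = vals.value_counts()
        for level, c in counts.items():
            rows.append(
                {
                    "block": block,
                    "level": level,
                    "n": int(c),
                    "pct": 100.0 * c / n if n else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=["block", "level", "n", "pct"])


def cif_by_stratum(
    episodes: pd.DataFrame,
    stratum: str = "fee_type",
    horizons: Sequence[int] = HORIZONS,
    cause: str = "community",
    levels: Sequence | None = None,
) -> pd.DataFrame:
    """Aalen-Johansen cumulative incidence (%) of ``cause`` at ``horizons``,
    estimated separately within each level of ``stratum`` (Table-2 style).

    Levels with no episodes are kept as flagged rows with missing values.
    """
    if levels is None:
        levels = list(pd.unique(episodes[stratum]))
    rows = []
    for level in levels:
        sub = episodes[episodes[stratum] == level]
        row = {"stratum": stratum, "level": level, "n": len(sub), "empty": len(sub) == 0}
        if len(sub):
            durations, events = sample_from_episodes(sub)
            curve = aalen_johansen(durations, events)
            for h in horizons:
                row[f"cif_{h}d"] = (
                    100.0 * cif_at(curve, cause, h) if cause in curve.cif else 0.0
                )
        else:
            for h in horizons:
                row[f"cif_{h}d"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class HospitalRateTable:
    """Hospital-level discharge rates with rank groups, per fee type."""

    hospitals: pd.DataFrame  # fee_type, hospital_id, n, rate, group
    groups: pd.DataFrame     # fee_type, group, n_hospitals, rate_min, rate_max
    summary: pd.DataFrame    # fee_type, n_hospitals, n_eligible, n_groups


def _group_sizes(n: int, g: int) -> np.ndarray:
    """Split n into g near-equal parts; remainders go to the lowest groups."""
    base, rem = divmod(n, g)
    sizes = np.full(g, base)
    sizes[:rem] += 1
    return sizes


def hospital_rates(
    episodes: pd.DataFrame,
    horizon: int = 90,
    min_patients: int = 10,
    cause: str = "community",
) -> HospitalRateTable:
    """Crude per-hospital discharge rates within ``horizon`` days, ranked.

    Episodes are attributed to the admitting hospital.  Within each fee
    type, hospitals with at least ``min_patients`` episodes are sorted by
    rate (ascending, ties by hospital id) and grouped into quintiles
    (>= 20 hospitals) or tertiles (< 20); each group reports its (min, max)
    rate range.
    """
    ep = episodes.copy()
    ep["_hit"] = (ep["outcome"] == cause) & (ep["event_time"] <= horizon)
    per_hosp = (
        ep.groupby(["fee_type", "admitting_hospital"], sort=True)
        .agg(n=("_hit", "size"), rate=("_hit", "mean"))
        .reset_index()
        .rename(columns={"admitting_hospital": "hospital_id"})
    )
    per_hosp["rate"] = 100.0 * per_hosp["rate"]

    hosp_rows, group_rows, summary_rows = [], [], []
    for fee_type, grp in per_hosp.groupby("fee_type", sort=True):
        elig = grp[grp["n"] >= min_patients].sort_values(
            ["rate", "hospital_id"], kind="stable"
        )
        n_elig = len(elig)
        n_groups = 0
        if n_elig:
            n_groups = 5 if n_elig >= 20 else 3
            n_groups = min(n_groups, n_elig)
            sizes = _group_sizes(n_elig, n_groups)
            labels = np.repeat(np.arange(1, n_groups + 1), sizes)
            elig = elig.assign(group=labels)
            hosp_rows.append(elig)
            for gid, gg in elig.groupby("group"):
                group_rows.append(
                    {
                        "fee_type": fee_type,
                        "group": int(gid),
                        "n_hospitals": len(gg),
                        "rate_min": gg["rate"].min(),
                        "rate_max": gg["rate"].max(),
                    }
                )
        summary_rows.append(
            {
                "fee_type": fee_type,
                "n_hospitals": len(grp),
                "n_eligible": n_elig,
                "n_groups": n_groups,
            }
        )
    hospitals = (
        pd.concat(hosp_rows, ignore_index=True)
        if hosp_rows
        else pd.DataFrame(columns=["fee_type", "hospital_id", "n", "rate", "group"])
    )
    return HospitalRateTable(
        hospitals=hospitals,
        groups=pd.DataFrame(
            group_rows,
            columns=["fee_type", "group", "n_hospitals", "rate_min", "rate_max"],
        ),
        summary=pd.DataFrame(summary_rows),
    )
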