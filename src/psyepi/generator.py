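"""Synthetic claims generator.

Produces an NDB-like claims extract with known latent truth: latent admission
episodes (ground truth for every downstream stage) and the stay-level claim
rows they fragment into, including inter-hospital transfer fragmentation, a
withheld publicly-funded subpopulation, monthly enrollment markers, prior
general-ward stays for general-ward-route admissions, and prevalent patients
already hospitalised at the study-window start.

Every stochastic concern draws from its own named random stream derived from
the config seed, so toggling one feature (e.g. transfers) does not shift the
draws of another.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .config import CAUSES, GeneratorConfig
from .errors import ConfigError

STREAM_NAMES = (
    "dates", "attrs", "events", "transfers", "planned",
    "withhold", "prevalent", "hospitals", "enrollment",
)

#: sentinel event time for episodes whose latent cause never fires
NEVER = np.inf


def _streams(seed: int) -> dict:
    return {
        name: np.random.default_rng(np.random.SeedSequence((int(seed), i)))
        for i, name in enumerate(STREAM_NAMES)
    }


class ClaimsBundle(NamedTuple):
    """Raw claim tables emitted by :func:`emit_claims`."""

    stays: pd.DataFrame
    enrollment: pd.DataFrame
    general_ward_stays: pd.DataFrame


def _month_range(start, end) -> pd.PeriodIndex:
    return pd.period_range(start=start, end=end, freq="M")


def _choice(rng, labels, probs, n):
    labels = list(labels)
    p = np.asarray([probs[k] for k in labels], dtype=float)
    idx = rng.choice(len(labels), size=n, p=p / p.sum())
    return np.array(labels, dtype=object)[idx]


def hospital_table(config: GeneratorConfig) -> pd.DataFrame:
    """Deterministic hospital directory: id, prefecture, unit (fee) type.

    Hospitals are partitioned across fee types proportionally to the
    admission mix (at least one hospital per type) and assigned to
    prefectures round-robin.
    """
    fts = list(config.fee_type_mix)
    w = np.array([config.fee_type_mix[f] for f in fts], dtype=float)
    n = config.n_hospitals
    alloc = np.maximum(1, np.floor(w / w.sum() * n).astype(int))
    # trim/grow to exactly n, adjusting the largest strata
    while alloc.sum() > n:
        alloc[np.argmax(alloc)] -= 1
    order = np.argsort(-w)
    i = 0
    while alloc.sum() < n:
        alloc[order[i % len(fts)]] += 1
        i += 1
    fee = np.repeat(np.array(fts, dtype=object), alloc)
    ids = np.arange(n)
    return pd.DataFrame(
        {
            "hospital_id": ids,
            "prefecture": ids % config.n_prefectures,
            "fee_type": fee,
        }
    )


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw the latent episode cohort implied by the config.

    Returns one row per latent episode with the true admission date, event
    time and cause, all Table-1-style attributes, the admitting hospital and
    an optional single inter-hospital transfer (day offset + destination
    hospital).  Includes ``prevalent_frac * n_patients`` additional patients
    admitted before the window start (``prevalent=True``).
    """
    config.validate()
    rng = _streams(config.seed)
    hospitals = hospital_table(config)

    n_new = int(config.n_patients)
    n_prev = int(round(config.prevalent_frac * n_new))
    n = n_new + n_prev
    prevalent = np.zeros(n, dtype=bool)
    prevalent[n_new:] = True

    # --- admission dates: seasonal monthly intensity, uniform within month
    months = _month_range(config.window_start, config.window_end)
    m = months.month.to_numpy()
    log_w = config.seasonal_amplitude * np.cos(
        2 * np.pi * (m - config.peak_month) / 12.0
    )
    w = np.exp(log_w)
    # expected counts proportional to intensity * month length
    ndays = np.array([p.days_in_month for p in months], dtype=float)
    pm = w * ndays
    pm /= pm.sum()
    mi = rng["dates"].choice(len(months), size=n_new, p=pm)
    day_u = rng["dates"].random(n_new)
    starts = months.to_timestamp().to_numpy()[mi]
    offs = np.floor(day_u * ndays[mi]).astype("timedelta64[D]")
    admission = np.empty(n, dtype="datetime64[D]")
    admission[:n_new] = starts.astype("datetime64[D]") + offs
    # prevalent patients: admitted 1..180 days before the window start
    back = 1 + np.floor(rng["prevalent"].random(n_prev) * 180).astype(int)
    admission[n_new:] = (
        np.datetime64(config.window_start, "D") - back.astype("timedelta64[D]")
    )

    # --- attributes
    a = rng["attrs"]
    fee = _choice(a, config.fee_type_mix, config.fee_type_mix, n)
    lp = config.admission_type_probs
    legal = _choice(
        a,
        ["voluntary", "involuntary"],
        {
            "voluntary": lp["voluntary"] / (lp["voluntary"] + lp["involuntary"]),
            "involuntary": lp["involuntary"] / (lp["voluntary"] + lp["involuntary"]),
        },
        n,
    )
    route = _choice(a, config.route_probs, config.route_probs, n)
    sex = _choice(a, config.sex_probs, config.sex_probs, n)
    age = _choice(a, config.age_probs, config.age_probs, n)
    diag = _choice(a, config.diagnosis_probs, config.diagnosis_probs, n)

    # --- admitting hospital: uniform within the fee type's hospital pool
    pools = {ft: g["hospital_id"].to_numpy() for ft, g in hospitals.groupby("fee_type")}
    hosp = np.empty(n, dtype=int)
    hu = rng["hospitals"].random(n)
    for ft, pool in pools.items():
        mask = fee == ft
        hosp[mask] = pool[np.floor(hu[mask] * len(pool)).astype(int)]
    prefecture = hosp % config.n_prefectures

    # --- latent event times and causes from the fee type's hazards
    times = np.empty(n, dtype=float)
    cause = np.empty(n, dtype=object)
    for ft in config.fee_type_mix:
        mask = fee == ft
        k = int(mask.sum())
        if k == 0:
            continue
        t, c = config.hazards_for(ft).sample(rng["events"], k)
        times[mask] = t
        cause[mask] = c
    event_day = np.where(np.isfinite(times), np.maximum(1, np.ceil(times)), NEVER)
    cause = np.where(np.isfinite(times), cause, "none")
    # prevalent stays must straddle the window start: shift the remaining
    # time beyond the pre-window backdate so discharge falls on/after it
    event_day[n_new:] = np.where(
        np.isfinite(event_day[n_new:]), event_day[n_new:] + back, NEVER
    )

    # --- planned admissions: mark ECT among short stays so that the marginal
    # planned share equals admission_type_probs["planned"] in expectation,
    # without perturbing the hazard-implied event-time distribution
    p_planned = lp.get("planned", 0.0)
    ect = np.zeros(n, dtype=bool)
    if p_planned > 0:
        pu = rng["planned"].random(n)
        for ft in config.fee_type_mix:
            mask = fee == ft
            if not mask.any():
                continue
            p_short = float(config.hazards_for(ft).total_cif(3.0))
            p_mark = min(1.0, p_planned / p_short) if p_short > 0 else 0.0
            ect |= mask & (event_day <= 3) & (pu < p_mark)
    # ECT in ordinary (longer) admissions; never classified as planned
    long_u = rng["planned"].random(n)
    ect |= (event_day > 3) & (long_u < config.ect_unplanned_rate)

    # --- transfers: at most one inter-hospital transfer per episode; the
    # assignment probability is inflated by 1/P(stay >= 2 days) so the
    # realised transfer prevalence matches transfer_prob
    tr = rng["transfers"]
    tu, du, hu2 = tr.random(n), tr.random(n), tr.random(n)
    transfer_day = np.full(n, np.nan)
    transfer_hosp = np.full(n, np.nan)
    if config.transfer_prob > 0:
        for ft in config.fee_type_mix:
            mask = fee == ft
            if not mask.any():
                continue
            p_elig = 1.0 - float(config.hazards_for(ft).total_cif(1.0))
            p_adj = min(1.0, config.transfer_prob / p_elig) if p_elig > 0 else 0.0
            pick = mask & (event_day >= 2) & (tu < p_adj)
            horizon = np.where(np.isfinite(event_day[pick]), event_day[pick], 1460.0)
            transfer_day[pick] = 1 + np.floor(du[pick] * (horizon - 1))
        moved = ~np.isnan(transfer_day)
        shift = 1 + np.floor(hu2[moved] * (config.n_hospitals - 1)).astype(int)
        transfer_hosp[moved] = (hosp[moved] + shift) % config.n_hospitals

    return pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "prevalent": prevalent,
            "admission_date": pd.to_datetime(admission),
            "event_day": event_day,
            "cause": cause,
            "fee_type": fee,
            "hospital_id": hosp,
            "prefecture": prefecture,
            "transfer_day": transfer_day,
            "transfer_hospital": transfer_hosp,
            "legal_admission": legal,
            "ect": ect,
            "route": route,
            "sex": sex,
            "age_group": age,
            "diagnosis": diag,
        }
    )


def emit_claims(latent: pd.DataFrame, config: GeneratorConfig) -> ClaimsBundle:
    """Fragment latent episodes into claim-style stay rows.

    An episode with a transfer yields two stay rows whose dates meet on the
    transfer day, the first carrying destination ``other_hospital``.  Stays
    still open at ``config.observation_end`` have no discharge date and no
    destination.  A ``public_fund_frac`` share of episodes is silently
    withheld.  Enrollment markers cover the two months preceding each
    emitted patient's first admission, and general-ward-route episodes get a
    prior general-ward stay ending on the admission date.
    """
    rng = _streams(config.seed)
    hospitals = hospital_table(config)
    fee_of_hosp = hospitals.set_index("hospital_id")["fee_type"]

    keep = rng["withhold"].random(len(latent)) >= config.public_fund_frac
    ep = latent.loc[keep].reset_index(drop=True)

    obs_end = np.datetime64(config.observation_end, "D")
    adm = ep["admission_date"].to_numpy().astype("datetime64[D]")
    cutoff = (obs_end - adm).astype(int).astype(float)  # days of visibility

    has_tr = ep["transfer_day"].notna().to_numpy() & (
        ep["transfer_day"].to_numpy() <= cutoff
    )
    event_day = ep["event_day"].to_numpy()
    closed = event_day <= cutoff

    def seg_frame(idx, admit, discharge, dest, hosp):
        hosp = np.asarray(hosp, dtype=int)
        return pd.DataFrame(
            {
                "patient_id": ep.loc[idx, "patient_id"].to_numpy(),
                "hospital_id": hosp,
                "prefecture": hosp % config.n_prefectures,
                "ward_fee_code": fee_of_hosp.loc[hosp].to_numpy(),
                "admit_date": pd.to_datetime(admit),
                "discharge_date": pd.to_datetime(discharge),
                "legal_admission": ep.loc[idx, "legal_admission"].to_numpy(),
                "destination": dest,
                "ect": ep.loc[idx, "ect"].to_numpy(),
                "diagnosis": ep.loc[idx, "diagnosis"].to_numpy(),
                "sex": ep.loc[idx, "sex"].to_numpy(),
                "age_group": ep.loc[idx, "age_group"].to_numpy(),
            }
        )

    frames = []
    # first (or only) segments
    idx0 = ep.index.to_numpy()
    end_day = np.where(closed, event_day, np.nan)
    first_end = np.where(has_tr, ep["transfer_day"].to_numpy(), end_day)
    first_admit = adm
    first_disc = np.where(
        np.isnan(first_end),
        np.datetime64("NaT", "D"),
        adm + np.nan_to_num(first_end, posinf=0.0).astype("timedelta64[D]"),
    )
    first_dest = np.where(
        has_tr,
        "other_hospital",
        np.where(closed, ep["cause"].to_numpy(), None),
    )
    frames.append(
        seg_frame(idx0, first_admit, first_disc, first_dest, ep["hospital_id"])
    )
    # second segments for visible transfers
    if has_tr.any():
        i2 = ep.index[has_tr].to_numpy()
        adm2 = adm[has_tr] + ep.loc[has_tr, "transfer_day"].to_numpy().astype(
            "timedelta64[D]"
        )
        disc2 = np.where(
            closed[has_tr],
            adm[has_tr]
            + np.nan_to_num(event_day[has_tr], posinf=0.0).astype("timedelta64[D]"),
            np.datetime64("NaT", "D"),
        )
        dest2 = np.where(closed[has_tr], ep.loc[has_tr, "cause"].to_numpy(), None)
        frames.append(
            seg_frame(
                i2, adm2, disc2, dest2,
                ep.loc[has_tr, "transfer_hospital"].to_numpy().astype(int),
            )
        )
    stays = pd.concat(frames, ignore_index=True)
    # fee code of the admitting segment reflects the episode's unit type
    # (the hospital pool construction makes these agree, but the latent fee
    # type is authoritative for the first segment)
    first_mask = np.zeros(len(stays), dtype=bool)
    first_mask[: len(ep)] = True
    stays.loc[first_mask, "ward_fee_code"] = ep["fee_type"].to_numpy()
    stays = stays.sort_values(
        ["patient_id", "admit_date", "discharge_date"], kind="stable"
    ).reset_index(drop=True)
    stays["destination"] = stays["destination"].where(
        stays["discharge_date"].notna(), None
    )

    # --- enrollment markers: two months before each first admission
    first_adm = ep.groupby("patient_id")["admission_date"].min()
    per = first_adm.dt.to_period("M")
    enrollment = pd.DataFrame(
        {
            "patient_id": np.repeat(first_adm.index.to_numpy(), 2),
            "month": np.stack([(per - 2).astype(str), (per - 1).astype(str)], axis=1).ravel(),
        }
    ).sort_values(["patient_id", "month"], kind="stable").reset_index(drop=True)

    # --- prior general-ward stays for general-ward-route admissions
    gw = ep[ep["route"] == "general_ward"]
    gw_len = 3 + np.floor(rng["enrollment"].random(len(gw)) * 28).astype(int)
    gw_admit = gw["admission_date"].to_numpy().astype("datetime64[D]") - gw_len.astype(
        "timedelta64[D]"
    )
    general_ward_stays = pd.DataFrame(
        {
            "patient_id": gw["patient_id"].to_numpy(),
            "admit_date": pd.to_datetime(gw_admit),
            "discharge_date": gw["admission_date"].to_numpy(),
        }
    ).reset_index(drop=True)

    return ClaimsBundle(stays, enrollment, general_ward_stays)


def inject_id_errors(
    stays: pd.DataFrame, collision_rate: float, seed: int
) -> pd.DataFrame:
    """Merge a sampled fraction of patient ids to mimic identification errors.

    Each sampled patient's id is replaced by another patient's id, producing
    pseudo-patients whose stay histories interleave — including, possibly,
    simultaneous stays in two hospitals, which the cohort filters must catch.
    ``collision_rate=0`` returns the input unchanged.
    """
    if not 0.0 <= collision_rate <= 1.0:
        raise ConfigError("collision_rate: must lie in [0, 1]")
    if collision_rate == 0.0:
        return stays
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 977)))
    patients = np.sort(stays["patient_id"].unique())
    n = len(patients)
    k = int(round(collision_rate * n))
    if k == 0:
        return stays
    victims = rng.choice(patients, size=k, replace=False)
    # partner differs from victim by construction
    pos = np.searchsorted(patients, victims)
    shift = 1 + np.floor(rng.random(k) * (n - 1)).astype(int)
    partners = patients[(pos + shift) % n]
    mapping = dict(zip(victims.tolist(), partners.tolist()))
    out = stays.copy()
    out["patient_id"] = out["patient_id"].map(lambda p: mapping.get(p, p))
    return out.sort_values(
        ["patient_id", "admit_date", "discharge_date"], kind="stable"
    ).reset_index(drop=True)
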