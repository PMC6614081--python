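"""Generator configuration and study-condition defaults.

The defaults encode the study conditions of the Japanese psychiatric-admission
setting the package emulates: the fee-type mix of psychiatric units, the
community-discharge cumulative-incidence profile of each unit type, the
overall competing-event (general-ward transfer, in-ward death) profile, the
transfer prevalence, and the July-peaked seasonal admission intensity.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, fields
from typing import Mapping

import numpy as np
import yaml

from .errors import ConfigError
from .hazards import HORIZONS, PiecewiseHazards, calibrate_hazards

CAUSES = ("community", "general_ward", "death")

#: hospital-fee categories of psychiatric units (ward reimbursement types),
#: grouped by payment plan; the numeric suffix is the patient-to-nurse ratio.
FEE_TYPES = (
    "psych_unit_10to1",
    "psych_unit_13to1",
    "psych_unit_15to1",
    "psych_unit_18to1",
    "psych_unit_20to1",
    "specialized_psych_unit",
    "advanced_psych_unit_7to1",
    "advanced_psych_unit_10to1",
    "advanced_psych_unit_13to1",
    "advanced_psych_unit_15to1",
    "psych_emergency_unit",
    "psych_acute_care_unit",
    "psych_emergency_physical_unit",
    "child_adolescent_psych_unit",
    "chronic_psych_care_unit",
    "dementia_care_unit",
)

FEE_TYPE_PLAN = dict(
    zip(
        FEE_TYPES,
        ["fee_for_service"] * 6 + ["advanced_hospital"] * 4 + ["per_diem"] * 6,
    )
)

# national admission counts by fee type (two fiscal years); used only to set
# the default fee-type mix proportions
_FEE_TYPE_COUNTS = (
    11119, 30721, 237973, 9416, 2485, 2183,
    4355, 7576, 12668, 3839,
    69697, 115089, 3034, 4388, 47763, 43676,
)

DEFAULT_FEE_TYPE_MIX = dict(
    zip(FEE_TYPES, (np.array(_FEE_TYPE_COUNTS) / sum(_FEE_TYPE_COUNTS)).tolist())
)

#: community-discharge cumulative incidence (%) at 90/180/270/360 days by
#: unit type — the per-stratum length-of-stay profiles the generator targets
COMMUNITY_CIF_BY_FEE_TYPE = {
    "psych_unit_10to1": (86.2, 92.2, 93.7, 94.3),
    "psych_unit_13to1": (74.3, 88.2, 91.4, 92.7),
    "psych_unit_15to1": (57.2, 73.5, 78.7, 81.4),
    "psych_unit_18to1": (53.8, 67.8, 73.5, 76.2),
    "psych_unit_20to1": (52.0, 72.7, 79.1, 81.8),
    "specialized_psych_unit": (47.9, 65.6, 71.1, 74.4),
    "advanced_psych_unit_7to1": (93.8, 97.5, 98.4, 98.7),
    "advanced_psych_unit_10to1": (90.6, 96.5, 97.8, 98.1),
    "advanced_psych_unit_13to1": (79.8, 93.7, 96.2, 97.1),
    "advanced_psych_unit_15to1": (75.9, 91.6, 95.2, 96.9),
    "psych_emergency_unit": (79.2, 92.5, 94.9, 96.0),
    "psych_acute_care_unit": (75.1, 91.0, 93.7, 94.8),
    "psych_emergency_physical_unit": (80.2, 92.1, 94.8, 95.7),
    "child_adolescent_psych_unit": (59.9, 84.6, 92.6, 95.9),
    "chronic_psych_care_unit": (52.2, 65.6, 70.9, 74.1),
    "dementia_care_unit": (38.3, 55.7, 63.4, 68.0),
}

#: overall-population cumulative-incidence profile (%): the 90- and 360-day
#: community values are the national estimates; the 180/270-day values are the
#: admission-weighted aggregate of the per-unit-type profiles above
OVERALL_CIF_PROFILE = {
    "community": (64.1, 79.2, 83.5, 85.7),
    "general_ward": (0.15, 0.22, 0.27, 0.3),
    "death": (1.4, 2.2, 2.7, 3.1),
}

DEFAULT_ADMISSION_TYPE_PROBS = {"voluntary": 0.644, "involuntary": 0.351, "planned": 0.005}
DEFAULT_ROUTE_PROBS = {"community": 0.853, "general_ward": 0.147}
DEFAULT_SEX_PROBS = {"men": 0.441, "women": 0.559}
DEFAULT_AGE_PROBS = {"0-19": 0.029, "20-39": 0.185, "40-64": 0.343, "65-74": 0.165, "75+": 0.278}
DEFAULT_DIAGNOSIS_PROBS = {"F0": 0.202, "F1": 0.061, "F2": 0.339, "F3": 0.225, "other": 0.173}


def competing_profile_for(community_profile, overall=OVERALL_CIF_PROFILE):
    """Competing-event (general-ward, death) CIF profile for a stratum.

    Only the overall competing-event incidences are known; per-stratum ones
    are imputed by scaling the overall profile in proportion to the stratum's
    residual non-community probability at 360 days, so high-discharge units
    get proportionally small competing incidences (and the calibration stays
    feasible, since community + competing mass cannot exceed 1).
    """
    c360 = community_profile[-1]
    scale = (100.0 - c360) / (100.0 - overall["community"][-1])
    return {
        "general_ward": tuple(v * scale for v in overall["general_ward"]),
        "death": tuple(v * scale for v in overall["death"]),
    }


def fee_type_cif_profiles() -> dict:
    """Full per-fee-type CIF target profiles (%, all three causes)."""
    out = {}
    for ft, comm in COMMUNITY_CIF_BY_FEE_TYPE.items():
        prof = {"community": comm}
        prof.update(competing_profile_for(comm))
        out[ft] = prof
    return out


def default_cause_hazards() -> dict:
    """Per-fee-type piecewise hazards calibrated to the default CIF profiles."""
    return {
        ft: calibrate_hazards(prof, HORIZONS, percent=True)
        for ft, prof in fee_type_cif_profiles().items()
    }


def overall_cause_hazards(profile: Mapping | None = None) -> PiecewiseHazards:
    """Single hazard set calibrated to the overall-population CIF profile."""
    return calibrate_hazards(profile or OVERALL_CIF_PROFILE, HORIZONS, percent=True)


def _check_probs(name: str, probs: Mapping[str, float]):
    vals = np.array(list(probs.values()), dtype=float)
    if np.any(vals < 0):
        raise ConfigError(f"{name}: probabilities must be >= 0")
    if abs(vals.sum() - 1.0) > 1e-9:
        raise ConfigError(f"{name}: probabilities must sum to 1 (got {vals.sum():.12g})")


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic claims generator.

    Attributes
    ----------
    n_patients
        Number of incident (new-admission) patients; one episode each.
    n_hospitals, n_prefectures
        Facility geography; each hospital hosts one unit type and belongs to
        one prefecture.
    window_start, window_end
        Study window for new admissions (Japanese fiscal years 2014-2015 by
        default).
    observation_end
        Claims-availability boundary; stays still open here are emitted
        without a discharge date.
    fee_type_mix
        Admission probability per unit type.
    cause_hazards
        Per unit type, piecewise-constant daily hazards of the three
        competing causes of episode termination.
    transfer_prob
        Per-episode probability of one inter-hospital transfer.
    admission_type_probs
        Marginal shares of voluntary / involuntary / planned admissions;
        "planned" is realised as electroconvulsive therapy with a stay of at
        most 3 days.
    route_probs
        Admission route: from the community vs. from a general ward.
    seasonal_amplitude, peak_month
        Log-linear seasonal admission intensity
        ``exp(amplitude * cos(2*pi*(month - peak_month)/12))``.
    public_fund_frac
        Share of latent episodes withheld from the emitted claims, emulating
        publicly funded claims absent from the database.
    prevalent_frac
        Extra patients (relative to ``n_patients``) already hospitalised at
        ``window_start``; their episodes must be excluded downstream.
    ect_unplanned_rate
        Rate of electroconvulsive therapy among episodes longer than 3 days
        (never classified as planned).
    """

    n_patients: int = 20_000
    n_hospitals: int = 400
    n_prefectures: int = 47
    window_start: dt.date = dt.date(2014, 4, 1)
    window_end: dt.date = dt.date(2016, 3, 31)
    observation_end: dt.date = dt.date(2016, 9, 30)
    fee_type_mix: dict = field(default_factory=lambda: dict(DEFAULT_FEE_TYPE_MIX))
    cause_hazards: dict = field(default_factory=default_cause_hazards)
    transfer_prob: float = 0.026
    admission_type_probs: dict = field(default_factory=lambda: dict(DEFAULT_ADMISSION_TYPE_PROBS))
    route_probs: dict = field(default_factory=lambda: dict(DEFAULT_ROUTE_PROBS))
    sex_probs: dict = field(default_factory=lambda: dict(DEFAULT_SEX_PROBS))
    age_probs: dict = field(default_factory=lambda: dict(DEFAULT_AGE_PROBS))
    diagnosis_probs: dict = field(default_factory=lambda: dict(DEFAULT_DIAGNOSIS_PROBS))
    seasonal_amplitude: float = 0.1
    peak_month: int = 7
    public_fund_frac: float = 0.0
    prevalent_frac: float = 0.05
    ect_unplanned_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self):
        for name in ("n_patients", "n_hospitals", "n_prefectures"):
            if int(getattr(self, name)) <= 0:
                raise ConfigError(f"{name}: must be a positive integer")
        if self.window_start >= self.window_end:
            raise ConfigError("window_start: must precede window_end")
        if self.observation_end < self.window_end:
            raise ConfigError("observation_end: must be on or after window_end")
        for name in ("fee_type_mix", "admission_type_probs", "route_probs",
                     "sex_probs", "age_probs", "diagnosis_probs"):
            _check_probs(name, getattr(self, name))
        for name in ("transfer_prob", "public_fund_frac", "prevalent_frac",
                     "ect_unplanned_rate"):
            v = float(getattr(self, name))
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: must lie in [0, 1]")
        if int(self.peak_month) not in range(1, 13):
            raise ConfigError("peak_month: must be in 1..12")
        if float(self.seasonal_amplitude) < 0:
            raise ConfigError("seasonal_amplitude: must be >= 0")
        missing = set(self.fee_type_mix) - set(self.cause_hazards)
        if missing:
            raise ConfigError(f"cause_hazards: missing fee types {sorted(missing)}")

    def hazards_for(self, fee_type: str) -> PiecewiseHazards:
        return self.cause_hazards[fee_type]

    def with_uniform_hazards(self, hazards: PiecewiseHazards) -> "GeneratorConfig":
        """Copy of the config in which every fee type shares one hazard set."""
        cfg = self.replace()
        cfg.cause_hazards = {ft: hazards for ft in cfg.fee_type_mix}
        return cfg

    def replace(self, **kw) -> "GeneratorConfig":
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update(kw)
        return GeneratorConfig(**d)

    # ---- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, dt.date):
                v = v.isoformat()
            elif f.name == "cause_hazards":
                v = {
                    ft: {"breaks": list(h.breaks),
                         "rates": {c: list(r) for c, r in h.rates.items()}}
                    for ft, h in v.items()
                }
            d[f.name] = v
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        for name in ("window_start", "window_end", "observation_end"):
            if name in d and isinstance(d[name], str):
                d[name] = dt.date.fromisoformat(d[name])
        if "cause_hazards" in d and d["cause_hazards"] is not None:
            ch = {}
            for ft, spec in d["cause_hazards"].items():
                if isinstance(spec, PiecewiseHazards):
                    ch[ft] = spec
                else:
                    ch[ft] = PiecewiseHazards(
                        {c: tuple(r) for c, r in spec["rates"].items()},
                        tuple(spec.get("breaks", (0.0, 90.0, 180.0, 270.0))),
                    )
            d["cause_hazards"] = ch
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
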