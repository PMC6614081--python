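"""End-to-end orchestration: generate/load claims, build episodes, estimate,
aggregate, and write the report bundle.

Two modes: ``simulate`` runs the synthetic generator and then the analysis;
``analyze`` runs the analysis on provided stay / enrollment / general-ward
tables.  Every output is a delimited text table; a manifest records the
config hash, seed and row counts so identical seeded runs are verifiable.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as pio
from .aggregate import cif_by_stratum, describe_cohort, hospital_rates
from .concordance import (
    correlate_indicators,
    prefecture_indicators,
    single_hospital_view,
)
from .config import GeneratorConfig
from .episodes import (
    apply_cohort_filters,
    assign_outcome,
    classify_admission,
    classify_route,
    link_segments,
)
from .errors import ConfigError
from .generator import emit_claims, generate_cohort, inject_id_errors
from .seasonal import fit_seasonal_poisson, monthly_counts
from .survival import aalen_johansen, sample_from_episodes


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "simulate"
    outdir: str = "psyepi_out"
    seed: int = 0
    generator: GeneratorConfig | None = None
    stays_path: str | None = None
    enrollment_path: str | None = None
    general_ward_path: str | None = None
    horizons: tuple = (90, 180, 270, 360)
    gap_days: int = 1
    min_patients: int = 10
    censor_date: dt.date = dt.date(2016, 9, 30)
    max_days: int = 365
    window_start: dt.date = dt.date(2014, 4, 1)
    window_end: dt.date = dt.date(2016, 3, 31)
    collision_rate: float = 0.0
    write_inputs: bool = True

    def validate(self):
        if self.mode not in ("simulate", "analyze"):
            raise ConfigError("mode: must be 'simulate' or 'analyze'")
        if list(self.horizons) != sorted(self.horizons):
            raise ConfigError("horizons: must be sorted ascending")
        if self.mode == "analyze":
            for name in ("stays_path", "enrollment_path"):
                p = getattr(self, name)
                if not p:
                    raise ConfigError(f"{name}: required in analyze mode")
                if not Path(p).exists():
                    raise FileNotFoundError(p)
            gw = self.general_ward_path
            if gw and not Path(gw).exists():
                raise FileNotFoundError(gw)
        if self.mode == "simulate" and self.generator is None:
            self.generator = GeneratorConfig(seed=self.seed)

    def to_dict(self) -> dict:
        d = {
            k: (v.isoformat() if isinstance(v, dt.date) else v)
            for k, v in self.__dict__.items()
            if k != "generator"
        }
        d["horizons"] = list(self.horizons)
        d["generator"] = self.generator.to_dict() if self.generator else None
        return d


def _config_hash(cfg: RunConfig) -> str:
    d = cfg.to_dict()
    # hash the analytic configuration only, not filesystem locations
    for key in ("outdir", "stays_path", "enrollment_path", "general_ward_path"):
        d.pop(key, None)
    blob = yaml.safe_dump(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def build_analysis_cohort(
    stays: pd.DataFrame,
    enrollment: pd.DataFrame,
    general_ward_stays: pd.DataFrame | None,
    cfg: RunConfig,
):
    """Stays -> linked, filtered, classified, outcome-assigned episodes."""
    episodes = link_segments(stays, gap_days=cfg.gap_days)
    episodes = assign_outcome(episodes, cfg.censor_date, cfg.max_days)
    episodes, log = apply_cohort_filters(
        episodes,
        enrollment,
        cfg.window_start,
        cfg.window_end,
        stays=stays,
        extra_claims=general_ward_stays,
    )
    episodes = classify_admission(episodes)
    episodes = classify_route(episodes, general_ward_stays)
    return episodes, log


def synthetic_cohort(gen: GeneratorConfig, gap_days: int = 1, collision_rate: float = 0.0):
    """Generate claims and build the analysis cohort in memory.

    Runs the full chain — generation, fragmentation, optional id-error
    injection, linkage, outcome assignment, cohort filters, classification —
    and returns ``(episodes, log, ClaimsBundle)``.
    """
    latent = generate_cohort(gen)
    stays, enrollment, gw = emit_claims(latent, gen)
    if collision_rate > 0:
        stays = inject_id_errors(stays, collision_rate, gen.seed)
    cfg = RunConfig(
        mode="simulate",
        generator=gen,
        gap_days=gap_days,
        censor_date=gen.observation_end,
        window_start=gen.window_start,
        window_end=gen.window_end,
        write_inputs=False,
    )
    episodes, log = build_analysis_cohort(stays, enrollment, gw, cfg)
    from .generator import ClaimsBundle

    return episodes, log, ClaimsBundle(stays, enrollment, gw)


def run(cfg: RunConfig) -> dict:
    """Execute the configured pipeline; writes the report bundle to
    ``cfg.outdir`` and returns the result tables keyed by output name."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if cfg.mode == "simulate":
        gen = cfg.generator
        latent = generate_cohort(gen)
        stays, enrollment, gw = emit_claims(latent, gen)
        if cfg.collision_rate > 0:
            stays = inject_id_errors(stays, cfg.collision_rate, gen.seed)
        if cfg.write_inputs:
            pio.write_stays(stays, outdir / "stays.csv")
            pio.write_enrollment(enrollment, outdir / "enrollment.csv")
            pio.write_general_ward_stays(gw, outdir / "general_ward_stays.csv")
            pio.write_latent(latent, outdir / "latent_truth.csv")
    else:
        stays = pio.read_stays(cfg.stays_path)
        enrollment = pio.read_enrollment(cfg.enrollment_path)
        gw = (
            pio.read_general_ward_stays(cfg.general_ward_path)
            if cfg.general_ward_path
            else None
        )

    episodes, log = build_analysis_cohort(stays, enrollment, gw, cfg)

    results = {}
    results["exclusion_log"] = log.as_frame()
    results["table1_cohort"] = describe_cohort(episodes)

    counts = monthly_counts(episodes, (cfg.window_start, cfg.window_end))
    fig1 = counts.rename("admissions").reset_index()
    fig1["month"] = fig1["month"].astype(str)
    try:
        fit = fit_seasonal_poisson(counts)
        results["seasonal_fit"] = pd.DataFrame([fit.as_dict()])
    except Exception as exc:  # degenerate tiny cohorts
        results["seasonal_fit"] = pd.DataFrame([{"error": str(exc)}])
    results["fig1_monthly_admissions"] = fig1

    durations, events = sample_from_episodes(episodes)
    curve = aalen_johansen(durations, events)
    results["fig2_cif_curves"] = curve.as_frame()

    results["table2_cif_by_fee_type"] = cif_by_stratum(
        episodes, "fee_type", cfg.horizons
    )
    hr = hospital_rates(episodes, horizon=cfg.horizons[0], min_patients=cfg.min_patients)
    results["table3_hospital_rates"] = hr.groups
    results["table3_hospital_rates_detail"] = hr.hospitals
    results["table3_hospital_summary"] = hr.summary

    window = (cfg.window_start, cfg.window_end)
    pseudo = single_hospital_view(stays, window=window, gap_days=cfg.gap_days)
    tab_e = prefecture_indicators(episodes, mode="episode")
    tab_s = prefecture_indicators(pseudo, mode="single_hospital")
    results["prefecture_indicators_episode"] = tab_e
    results["prefecture_indicators_single_hospital"] = tab_s
    results["table4_correlations"] = correlate_indicators(tab_e, tab_s)

    for name, df in results.items():
        df.to_csv(outdir / f"{name}.csv", index=False)

    manifest = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "mode": cfg.mode,
        "n_stays": int(len(stays)),
        "n_episodes": int(len(episodes)),
        "row_counts": {k: int(len(v)) for k, v in results.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    results["episodes"] = episodes
    return results
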