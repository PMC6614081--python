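import numpy as np
import pandas as pd
import pytest

import psyepi as pe


def binom_tol(p: float, n: int, z: float = 2.576) -> float:
    """Half-width of a normal-approximation binomial interval, in points (%)."""
    return 100.0 * z * np.sqrt(p * (1.0 - p) / n)


@pytest.fixture(scope="session")
def default_cfg() -> pe.GeneratorConfig:
    return pe.GeneratorConfig(n_patients=20_000, seed=11)


@pytest.fixture(scope="session")
def bundle(default_cfg):
    """Latent cohort plus emitted claims at n=20,000."""
    latent = pe.generate_cohort(default_cfg)
    stays, enrollment, gw = pe.emit_claims(latent, default_cfg)
    return latent, stays, enrollment, gw


@pytest.fixture(scope="session")
def cohort(default_cfg, bundle):
    """Fully built analysis cohort (linked, filtered, classified)."""
    _, stays, enrollment, gw = bundle
    eps = pe.link_segments(stays)
    eps = pe.assign_outcome(eps, default_cfg.observation_end)
    eps, _ = pe.apply_cohort_filters(
        eps,
        enrollment,
        default_cfg.window_start,
        default_cfg.window_end,
        stays=stays,
        extra_claims=gw,
    )
    eps = pe.classify_admission(eps)
    eps = pe.classify_route(eps, gw)
    return eps


def make_stays(rows) -> pd.DataFrame:
    """Hand-build a stay table from (patient, hospital, admit, discharge,
    destination) tuples; dates are ISO strings, None for open stays."""
    recs = []
    for pid, hosp, admit, disc, dest in rows:
        recs.append(
            {
                "patient_id": pid,
                "hospital_id": hosp,
                "prefecture": hosp % 47,
                "ward_fee_code": "psych_unit_15to1",
                "admit_date": pd.Timestamp(admit),
                "discharge_date": pd.Timestamp(disc) if disc else pd.NaT,
                "legal_admission": "voluntary",
                "destination": dest,
                "ect": False,
                "diagnosis": "F2",
                "sex": "women",
                "age_group": "40-64",
            }
        )
    return pd.DataFrame(recs)
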