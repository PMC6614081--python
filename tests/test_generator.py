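"""Synthetic claims generator: determinism, marginals, fragmentation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import psyepi as pe
from psyepi.errors import ConfigError
from tests.conftest import binom_tol

Z_MULTI = 3.29  # 99.9% normal quantile: many marginal levels checked jointly


class TestDeterminism:
    def test_same_seed_same_cohort_and_claims(self):
        cfg = pe.GeneratorConfig(n_patients=2_000, seed=123)
        a = pe.generate_cohort(cfg)
        b = pe.generate_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)
        sa = pe.emit_claims(a, cfg)
        sb = pe.emit_claims(b, cfg)
        for x, y in zip(sa, sb):
            pd.testing.assert_frame_equal(x, y)

    def test_different_seed_differs(self):
        a = pe.generate_cohort(pe.GeneratorConfig(n_patients=2_000, seed=1))
        b = pe.generate_cohort(pe.GeneratorConfig(n_patients=2_000, seed=2))
        assert not a["admission_date"].equals(b["admission_date"])


class TestConfigValidation:
    def test_bad_probability_vector_names_field(self):
        with pytest.raises(ConfigError, match="route_probs"):
            pe.GeneratorConfig(route_probs={"community": 0.9, "general_ward": 0.2})

    def test_bad_peak_month_rejected(self):
        with pytest.raises(ConfigError, match="peak_month"):
            pe.GeneratorConfig(peak_month=13)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ConfigError, match="public_fund_frac"):
            pe.GeneratorConfig(public_fund_frac=1.5)


class TestSeasonality:
    def test_flat_intensity_is_uniform_up_to_month_length(self):
        cfg = pe.GeneratorConfig(
            n_patients=20_000, seed=3, seasonal_amplitude=0.0, prevalent_frac=0.0
        )
        lat = pe.generate_cohort(cfg)
        months = lat["admission_date"].dt.to_period("M")
        counts = months.value_counts().sort_index()
        ndays = np.array([p.days_in_month for p in counts.index], dtype=float)
        expected = len(lat) * ndays / ndays.sum()
        res = stats.chisquare(counts.to_numpy(), expected)
        assert res.pvalue > 0.01

    def test_modal_admission_month_is_july(self):
        cfg = pe.GeneratorConfig(
            n_patients=50_000, seed=4, seasonal_amplitude=0.1, prevalent_frac=0.0
        )
        lat = pe.generate_cohort(cfg)
        by_cal_month = lat["admission_date"].dt.month.value_counts()
        assert by_cal_month.idxmax() == 7


class TestMarginals:
    def test_attribute_shares_recover_config_probabilities(self, default_cfg, bundle):
        latent, _, _, _ = bundle
        lat = latent[~latent["prevalent"]]
        n = len(lat)
        checks = {
            "fee_type": default_cfg.fee_type_mix,
            "route": default_cfg.route_probs,
            "sex": default_cfg.sex_probs,
            "age_group": default_cfg.age_probs,
            "diagnosis": default_cfg.diagnosis_probs,
        }
        for col, probs in checks.items():
            shares = lat[col].value_counts(normalize=True)
            for level, p in probs.items():
                got = 100 * shares.get(level, 0.0)
                assert abs(got - 100 * p) < binom_tol(p, n, Z_MULTI), (col, level)

    def test_transfer_prevalence_matches_config(self, default_cfg, bundle):
        latent, _, _, _ = bundle
        lat = latent[~latent["prevalent"]]
        share = lat["transfer_day"].notna().mean()
        assert abs(share - default_cfg.transfer_prob) * 100 < binom_tol(
            default_cfg.transfer_prob, len(lat), Z_MULTI
        )

    def test_transfer_prob_zero_yields_no_transfers(self):
        cfg = pe.GeneratorConfig(n_patients=3_000, seed=9, transfer_prob=0.0)
        lat = pe.generate_cohort(cfg)
        assert lat["transfer_day"].isna().all()


class TestEmission:
    def test_fragmentation_is_lossless(self, default_cfg, bundle):
        """Segments of one latent episode tile [admission, event/censor]."""
        latent, stays, _, _ = bundle
        obs_end = pd.Timestamp(default_cfg.observation_end)
        s = stays.sort_values(["patient_id", "admit_date"]).reset_index(drop=True)
        joined = s.merge(
            latent[["patient_id", "admission_date", "event_day"]], on="patient_id"
        )
        g = joined.groupby("patient_id")
        assert (g["admit_date"].min() == g["admission_date"].first()).all()
        # within-patient contiguity: each later segment starts where the
        # previous one discharged
        prev_disc = s.groupby("patient_id")["discharge_date"].shift(1)
        later = s.groupby("patient_id").cumcount() > 0
        assert (s.loc[later, "admit_date"] == prev_disc[later]).all()
        # chain terminus: discharge at the true event, or open at obs end
        term = s.groupby("patient_id").tail(1).merge(latent, on="patient_id")
        closed = term["discharge_date"].notna()
        end_day = (
            term.loc[closed, "discharge_date"] - term.loc[closed, "admission_date"]
        ).dt.days
        assert (end_day.to_numpy() == term.loc[closed, "event_day"].to_numpy()).all()
        cutoff = (obs_end - term.loc[~closed, "admission_date"]).dt.days
        assert (term.loc[~closed, "event_day"].to_numpy() > cutoff.to_numpy()).all()

    def test_transfer_episode_splits_into_contiguous_segments(self, default_cfg, bundle):
        latent, stays, _, _ = bundle
        cutoff = (
            pd.Timestamp(default_cfg.observation_end) - latent["admission_date"]
        ).dt.days
        visible = latent["transfer_day"].notna() & (latent["transfer_day"] <= cutoff)
        moved = latent[visible].iloc[0]
        seg = stays[stays["patient_id"] == moved["patient_id"]]
        assert len(seg) == 2
        first, second = seg.iloc[0], seg.iloc[1]
        assert first["destination"] == "other_hospital"
        assert first["discharge_date"] == second["admit_date"]
        assert first["hospital_id"] != second["hospital_id"]

    def test_public_fund_withholding_rate(self):
        cfg = pe.GeneratorConfig(
            n_patients=20_000, seed=6, public_fund_frac=0.19, prevalent_frac=0.0
        )
        lat = pe.generate_cohort(cfg)
        stays, _, _ = pe.emit_claims(lat, cfg)
        ratio = stays["patient_id"].nunique() / len(lat)
        assert abs(ratio - 0.81) * 100 < binom_tol(0.81, len(lat), Z_MULTI)

    def test_enrollment_markers_precede_first_admission(self, bundle):
        latent, stays, enrollment, _ = bundle
        assert set(stays["patient_id"]) == set(enrollment["patient_id"])
        first = stays.groupby("patient_id")["admit_date"].min().dt.to_period("M")
        marks = enrollment.assign(
            month=pd.PeriodIndex(enrollment["month"], freq="M")
        )
        first_mark = marks.groupby("patient_id")["month"].min()
        assert (first_mark < first.loc[first_mark.index]).all()

    def test_general_ward_route_gets_prior_general_ward_stay(self, bundle):
        latent, stays, _, gw = bundle
        routed = latent.loc[
            ~latent["patient_id"].isin(gw["patient_id"]), "route"
        ]
        assert (routed == "community").all()
        merged = gw.merge(
            latent[["patient_id", "admission_date"]], on="patient_id"
        )
        assert (merged["discharge_date"] == merged["admission_date"]).all()

    def test_prevalent_patients_straddle_window_start(self, default_cfg, bundle):
        latent, stays, _, _ = bundle
        ws = pd.Timestamp(default_cfg.window_start)
        prev = latent[latent["prevalent"]]
        assert len(prev) == round(default_cfg.prevalent_frac * default_cfg.n_patients)
        seg = stays[stays["patient_id"].isin(prev["patient_id"])]
        starts = seg.groupby("patient_id")["admit_date"].min()
        ends = seg.groupby("patient_id")["discharge_date"].max()
        assert (starts < ws).all()
        assert (ends.isna() | (ends >= ws)).all()


class TestIdErrors:
    def test_rate_zero_is_identity(self, bundle):
        _, stays, _, _ = bundle
        out = pe.inject_id_errors(stays, 0.0, seed=1)
        pd.testing.assert_frame_equal(out, stays)

    def test_merged_fraction_matches_rate(self, bundle):
        _, stays, _, _ = bundle
        n0 = stays["patient_id"].nunique()
        out = pe.inject_id_errors(stays, 0.01, seed=2)
        merged = n0 - out["patient_id"].nunique()
        assert abs(merged / n0 - 0.01) * 100 < binom_tol(0.01, n0, Z_MULTI)

    def test_rate_out_of_range_rejected(self, bundle):
        _, stays, _, _ = bundle
        with pytest.raises(ConfigError):
            pe.inject_id_errors(stays, 1.5, seed=1)
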