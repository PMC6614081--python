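"""Episode linkage, outcome assignment, cohort filters, classification."""

import numpy as np
import pandas as pd
import pytest

import psyepi as pe
from psyepi.errors import DataValidationError
from tests.conftest import binom_tol, make_stays


class TestLinkage:
    def test_single_stay_is_one_episode_without_transfer(self):
        stays = make_stays([(1, 10, "2014-06-01", "2014-07-01", "community")])
        eps = pe.link_segments(stays)
        assert len(eps) == 1
        row = eps.iloc[0]
        assert not row["transfer"]
        assert row["n_segments"] == 1
        assert row["destination_final"] == "community"

    def test_interhospital_transfer_chains_into_one_episode(self):
        stays = make_stays(
            [
                (1, 10, "2014-06-01", "2014-07-01", "other_hospital"),
                (1, 20, "2014-07-01", "2014-08-20", "community"),
            ]
        )
        stays.loc[0, "ward_fee_code"] = "psych_emergency_unit"
        eps = pe.link_segments(stays)
        assert len(eps) == 1
        row = eps.iloc[0]
        assert row["transfer"]
        assert row["fee_type"] == "psych_emergency_unit"  # admitting segment
        assert row["admitting_hospital"] == 10
        assert row["admission_date"] == pd.Timestamp("2014-06-01")
        assert row["end_date"] == pd.Timestamp("2014-08-20")

    @pytest.mark.parametrize(
        "gap_days,n_expected", [(0, 2), (1, 1), (3, 1)]
    )
    def test_gap_rule_controls_chaining(self, gap_days, n_expected):
        # readmission one day after discharge
        stays = make_stays(
            [
                (1, 10, "2014-06-01", "2014-07-01", "other_hospital"),
                (1, 20, "2014-07-02", "2014-08-20", "community"),
            ]
        )
        assert len(pe.link_segments(stays, gap_days=gap_days)) == n_expected

    def test_distinct_patients_never_chain(self):
        stays = make_stays(
            [
                (1, 10, "2014-06-01", "2014-07-01", "community"),
                (2, 10, "2014-07-01", "2014-08-01", "community"),
            ]
        )
        assert len(pe.link_segments(stays)) == 2

    def test_discharge_before_admit_rejected(self):
        stays = make_stays([(1, 10, "2014-06-10", "2014-06-01", "community")])
        with pytest.raises(DataValidationError):
            pe.link_segments(stays)

    def test_every_stay_lands_in_exactly_one_episode(self, bundle):
        _, stays, _, _ = bundle
        eps, assigned = pe.link_segments(stays, return_assignments=True)
        assert len(assigned) == len(stays)
        assert assigned["episode_id"].nunique() == len(eps)
        assert eps["n_segments"].sum() == len(stays)

    def test_round_trip_recovers_latent_episodes(self, default_cfg, bundle):
        """Fragmentation then linkage reproduces the latent truth exactly."""
        latent, stays, _, _ = bundle
        eps = pe.link_segments(stays)
        assert len(eps) == len(latent)
        merged = eps.merge(
            latent, on="patient_id", suffixes=("", "_true"), validate="1:1"
        )
        assert (merged["admission_date"] == merged["admission_date_true"]).all()
        cutoff = (
            pd.Timestamp(default_cfg.observation_end) - merged["admission_date"]
        ).dt.days
        closed = merged["event_day"] <= cutoff
        end_day = (merged["end_date"] - merged["admission_date"]).dt.days
        assert (end_day[closed] == merged.loc[closed, "event_day"]).all()
        assert merged.loc[~closed, "end_date"].isna().all()
        visible_tr = merged["transfer_day"].notna() & (
            merged["transfer_day"] <= cutoff
        )
        assert (merged["transfer"] == visible_tr).all()
        assert (merged["fee_type"] == merged["fee_type_true"]).all()

    def test_linkage_invariant_to_row_order(self, bundle):
        _, stays, _, _ = bundle
        shuffled = stays.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = pe.link_segments(stays).sort_values(
            ["patient_id", "admission_date"]
        ).reset_index(drop=True)
        b = pe.link_segments(shuffled).sort_values(
            ["patient_id", "admission_date"]
        ).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            a.drop(columns="episode_id"), b.drop(columns="episode_id")
        )


class TestOutcome:
    def _one(self, admit, discharge, dest, observation_end="2016-09-30"):
        stays = make_stays([(1, 10, admit, discharge, dest)])
        eps = pe.link_segments(stays)
        return pe.assign_outcome(eps, pd.Timestamp(observation_end).date()).iloc[0]

    def test_event_before_censor_keeps_outcome_and_time(self):
        row = self._one("2014-06-01", "2014-07-16", "community")
        assert row["outcome"] == "community"
        assert row["event_time"] == 45

    def test_open_stay_censored_at_observation_end(self):
        row = self._one("2016-03-01", None, None)
        assert row["outcome"] == "censored"
        assert row["event_time"] == 213

    def test_long_stay_censored_at_max_days(self):
        row = self._one("2014-06-01", "2015-07-06", "community")  # day 400
        assert row["outcome"] == "censored"
        assert row["event_time"] == 365

    def test_same_day_discharge_floored_to_one_day(self):
        row = self._one("2014-06-01", "2014-06-01", "death")
        assert row["outcome"] == "death"
        assert row["event_time"] == 1

    def test_unterminated_transfer_chain_rejected(self):
        stays = make_stays([(1, 10, "2014-06-01", "2014-07-01", "other_hospital")])
        eps = pe.link_segments(stays)
        with pytest.raises(DataValidationError):
            pe.assign_outcome(eps, pd.Timestamp("2016-09-30").date())

    def test_outcomes_match_latent_truth(self, default_cfg, bundle):
        latent, stays, _, _ = bundle
        eps = pe.assign_outcome(
            pe.link_segments(stays), default_cfg.observation_end
        )
        merged = eps.merge(latent, on="patient_id", suffixes=("", "_true"))
        cutoff = (
            pd.Timestamp(default_cfg.observation_end) - merged["admission_date"]
        ).dt.days
        boundary = np.minimum(cutoff, 365)
        is_event = merged["event_day"] <= boundary
        expect = np.where(is_event, merged["cause"], "censored")
        assert (merged["outcome"] == expect).all()
        expect_t = np.where(is_event, merged["event_day"], np.maximum(1, boundary))
        assert (merged["event_time"] == expect_t).all()


def _enroll(pairs):
    return pd.DataFrame(pairs, columns=["patient_id", "month"])


class TestCohortFilters:
    WS, WE = pd.Timestamp("2014-04-01").date(), pd.Timestamp("2016-03-31").date()

    def _filter(self, stays, enrollment, **kw):
        eps = pe.assign_outcome(
            pe.link_segments(stays), pd.Timestamp("2016-09-30").date()
        )
        return pe.apply_cohort_filters(
            eps, enrollment, self.WS, self.WE, stays=stays, **kw
        )

    def test_prevalent_at_window_start_removed(self):
        stays = make_stays([(1, 10, "2014-03-15", "2014-05-01", "community")])
        out, log = self._filter(stays, _enroll([(1, "2014-01")]))
        assert len(out) == 0
        assert log.removed_prevalent == 1

    def test_episode_ended_before_window_is_out_of_window(self):
        stays = make_stays([(1, 10, "2014-02-01", "2014-03-10", "community")])
        out, log = self._filter(stays, _enroll([(1, "2014-01")]))
        assert len(out) == 0
        assert log.removed_out_of_window == 1

    def test_enrollment_unverified_removed(self):
        stays = make_stays([(1, 10, "2014-06-01", "2014-07-01", "community")])
        out, log = self._filter(stays, _enroll([]))
        assert len(out) == 0
        assert log.removed_enrollment_unverified == 1

    def test_marker_in_admission_month_does_not_verify(self):
        stays = make_stays([(1, 10, "2014-06-15", "2014-07-01", "community")])
        out, _ = self._filter(stays, _enroll([(1, "2014-06")]))
        assert len(out) == 0

    def test_earlier_claim_verifies_enrollment(self):
        stays = make_stays([(1, 10, "2014-06-01", "2014-07-01", "community")])
        claims = pd.DataFrame(
            {"patient_id": [1], "date": [pd.Timestamp("2014-05-20")]}
        )
        out, log = self._filter(stays, _enroll([]), extra_claims=claims)
        assert len(out) == 1
        assert log.n_retained == 1

    def test_same_day_multi_hospital_patient_fully_removed(self):
        stays = make_stays(
            [
                (1, 10, "2014-06-01", "2014-08-01", "community"),
                (1, 20, "2014-06-20", "2014-07-10", "community"),
                (1, 10, "2015-02-01", "2015-03-01", "community"),
            ]
        )
        out, log = self._filter(stays, _enroll([(1, "2014-01")]))
        assert len(out) == 0
        assert log.removed_same_day_multi_hospital > 0

    def test_transfer_boundary_contact_is_not_a_collision(self):
        stays = make_stays(
            [
                (1, 10, "2014-06-01", "2014-07-01", "other_hospital"),
                (1, 20, "2014-07-01", "2014-08-01", "community"),
            ]
        )
        out, log = self._filter(stays, _enroll([(1, "2014-01")]))
        assert len(out) == 1
        assert log.removed_same_day_multi_hospital == 0

    def test_injected_id_collisions_are_caught(self, default_cfg, bundle):
        _, stays, enrollment, _ = bundle
        collided = pe.inject_id_errors(stays, 0.02, seed=3)
        eps = pe.assign_outcome(
            pe.link_segments(collided), default_cfg.observation_end
        )
        _, log = pe.apply_cohort_filters(
            eps,
            enrollment,
            default_cfg.window_start,
            default_cfg.window_end,
            stays=collided,
        )
        assert log.removed_same_day_multi_hospital > 0

    def test_log_is_conserved_and_empty_input_ok(self):
        out, log = pe.apply_cohort_filters(
            pd.DataFrame(columns=["patient_id", "admission_date", "end_date"]),
            _enroll([]),
            self.WS,
            self.WE,
        )
        assert len(out) == 0 and log.n_input == 0 and log.n_removed == 0

    def test_full_accounting_on_generated_cohort(self, default_cfg, bundle):
        _, stays, enrollment, gw = bundle
        eps = pe.assign_outcome(
            pe.link_segments(stays), default_cfg.observation_end
        )
        out, log = pe.apply_cohort_filters(
            eps, enrollment, default_cfg.window_start, default_cfg.window_end,
            stays=stays, extra_claims=gw,
        )
        assert log.n_input == len(eps)
        assert log.n_retained + log.n_removed == log.n_input
        assert log.n_retained == default_cfg.n_patients  # prevalent all removed


class TestClassification:
    def _episode(self, ect, event_time, legal="involuntary"):
        return pd.DataFrame(
            {
                "patient_id": [1],
                "ect": [ect],
                "event_time": [event_time],
                "legal_admission": [legal],
            }
        )

    @pytest.mark.parametrize(
        "ect,event_time,expected",
        [
            (True, 3, "planned"),
            (True, 10, "involuntary"),
            (False, 2, "involuntary"),
            (True, 1, "planned"),
        ],
    )
    def test_planned_requires_ect_and_short_stay(self, ect, event_time, expected):
        out = pe.classify_admission(self._episode(ect, event_time))
        assert out["admission_type"].iloc[0] == expected

    def test_route_from_general_ward_stay_ending_at_admission(self):
        eps = pd.DataFrame(
            {
                "patient_id": [1, 2, 3],
                "admission_date": pd.to_datetime(
                    ["2014-06-01", "2014-06-01", "2014-06-01"]
                ),
            }
        )
        gw = pd.DataFrame(
            {
                "patient_id": [1, 2],
                "admit_date": pd.to_datetime(["2014-05-20", "2014-05-20"]),
                "discharge_date": pd.to_datetime(["2014-06-01", "2014-05-31"]),
            }
        )
        out = pe.classify_route(eps, gw)
        assert list(out["route"]) == ["general_ward", "general_ward", "community"]

    def test_no_general_ward_stays_means_community(self):
        eps = pd.DataFrame(
            {"patient_id": [1], "admission_date": pd.to_datetime(["2014-06-01"])}
        )
        assert pe.classify_route(eps, None)["route"].iloc[0] == "community"

    def test_route_shares_recover_config(self, default_cfg, cohort):
        share = (cohort["route"] == "community").mean()
        assert abs(share - 0.853) * 100 < binom_tol(0.853, len(cohort), 3.29)
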