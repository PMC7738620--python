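"""The synthetic cohort generator: profiles, calendar, fatigue dynamics,
observables, tachograms, and artifact injection."""

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal

from orthohrv.hrv import spectral_powers, time_domain_indices
from orthohrv.sessions import RRSeries, assemble_session
from orthohrv.simulate import (
    SimulationConfig,
    build_event_calendar,
    fatigue_dynamics,
    inject_ectopic_artifacts,
    simulate_athletes,
    simulate_cohort,
    simulate_orthostatic_rr,
)


class TestAthletes:
    def test_zero_variance_gives_identical_profiles(self):
        config = SimulationConfig(
            n_athletes=3,
            vo2max_sd=0.0,
            hr_max_sd=0.0,
            training_load_sd=0.0,
            years_sd=0.0,
        )
        profiles = simulate_athletes(config)
        assert (profiles["vo2max"] == 53.6).all()
        assert (profiles["hr_max"] == 185.7).all()
        assert (profiles["training_load"] == 187.5).all()

    def test_sample_mean_consistent_with_configured_moments(self):
        profiles = simulate_athletes(SimulationConfig(n_athletes=10_000, seed=4))
        se = 5.2 / np.sqrt(10_000)
        assert abs(profiles["vo2max"].mean() - 53.6) < 3 * se

    def test_determinism(self):
        a = simulate_athletes(SimulationConfig(seed=9))
        b = simulate_athletes(SimulationConfig(seed=9))
        assert_frame_equal(a, b)

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_athletes=0)


class TestCalendar:
    def test_default_structure(self):
        cal = build_event_calendar(SimulationConfig(seed=0))
        counts = cal["day_type"].value_counts()
        assert counts["stage"] == 21
        assert counts["baseline"] == 4
        assert counts["rest"] == 2
        assert counts["post"] == 1
        assert (np.diff(cal["day_index"]) == 1).all()

    def test_distance_zero_exactly_on_non_stage_days(self):
        cal = build_event_calendar(SimulationConfig(seed=0))
        assert (cal.loc[cal["day_type"] != "stage", "stage_distance_km"] == 0).all()
        assert (cal.loc[cal["day_type"] == "stage", "stage_distance_km"] > 0).all()

    def test_no_stages_degenerates_to_baseline_and_post(self):
        cal = build_event_calendar(
            SimulationConfig(seed=0, n_stages=0, rest_after_stages=())
        )
        assert set(cal["day_type"]) == {"baseline", "post"}

    def test_rest_days_follow_configured_stages(self):
        cal = build_event_calendar(SimulationConfig(seed=0))
        rest_positions = cal.index[cal["day_type"] == "rest"]
        for pos in rest_positions:
            assert cal.loc[pos - 1, "day_type"] == "stage"
        assert list(cal.loc[rest_positions - 1, "stage_number"]) == [9, 15]


class TestFatigueDynamics:
    def test_zero_workload_stays_zero(self):
        fat = fatigue_dynamics(np.zeros(10), rho=0.5, kappa=1.0)
        assert (fat.values == 0).all()

    def test_direct_recurrence(self):
        fat = fatigue_dynamics([100.0, 0.0], rho=0.5, kappa=1.0)
        assert list(fat.values) == [100.0, 50.0]

    def test_geometric_steady_state(self):
        rho, kappa, c = 0.8, 0.3, 10.0
        fat = fatigue_dynamics(np.full(300, c), rho=rho, kappa=kappa)
        assert fat.values[-1] == pytest.approx(kappa * c / (1 - rho), rel=1e-9)

    def test_rest_day_strictly_decreases_fatigue(self):
        fat = fatigue_dynamics([100.0, 100.0, 0.0], rho=0.7, kappa=0.1)
        assert fat.values[2] < fat.values[1]

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            fatigue_dynamics([1.0], rho=1.0, kappa=0.1)


class TestObservables:
    def test_intercept_only_truth_is_constant(self):
        config = SimulationConfig(
            seed=2,
            n_athletes=3,
            noise_sd=0.0,
            delta_rr_coefficients={"intercept": 210.0},
        )
        cohort = simulate_cohort(config)
        assert (cohort.records["delta_rr_mean"] == 210.0).all()

    def test_mean_rr_targets_consistent_with_delta(self, default_cohort):
        rec = default_cohort.records
        np.testing.assert_allclose(
            rec["mean_rr_supine"] - rec["mean_rr_standing"],
            rec["delta_rr_mean"],
            atol=1e-9,
        )

    def test_rpe_only_on_stage_days(self, default_cohort):
        rec = default_cohort.records
        assert rec.loc[rec["day_type"] != "stage", "rpe"].isna().all()
        stage_rpe = rec.loc[rec["day_type"] == "stage", "rpe"]
        assert stage_rpe.between(0, 10).all()

    def test_items_within_ordinal_scale(self, default_cohort):
        rec = default_cohort.records
        for item in ("perceived_fatigue", "sleep_quality", "doms", "stress"):
            assert rec[item].between(1, 7).all()
        assert (rec["wb"] == rec[["perceived_fatigue", "sleep_quality", "doms", "stress"]].sum(axis=1)).all()

    def test_ols_recovers_generating_coefficients_within_three_se(self):
        config = SimulationConfig(seed=31, n_athletes=500, noise_sd=30.0)
        cohort = simulate_cohort(config)
        df = cohort.records[cohort.records["day_type"] == "stage"]
        assert len(df) >= 10_000
        from orthohrv.models import fit_ols

        fit = fit_ols(
            df["delta_rr_mean"],
            df[["vo2max", "training_load", "hr_max", "rpe", "perceived_fatigue"]],
        )
        truth = cohort.truth["delta_rr_coefficients"]
        names = ("vo2max", "training_load", "hr_max", "rpe", "perceived_fatigue")
        for i, name in enumerate(("intercept",) + names):
            expected = truth[name] if name != "intercept" else truth["intercept"]
            z = abs(fit.coefficients[i] - expected) / fit.standard_errors[i]
            assert z < 3.0, f"{name}: z={z:.2f}"

    def test_post_rest_mornings_show_recovered_delta(self):
        config = SimulationConfig(seed=13, n_athletes=60)
        cohort = simulate_cohort(config)
        rec = cohort.records.sort_values(["athlete_id", "day_index"])
        rec["prev_type"] = rec.groupby("athlete_id")["day_type"].shift(1)
        post_rest = rec.loc[rec["prev_type"] == "rest", "delta_rr_mean"]
        post_stage = rec.loc[rec["prev_type"] == "stage", "delta_rr_mean"]
        assert post_rest.mean() > post_stage.mean()

    def test_misaligned_fatigue_series_rejected(self):
        from orthohrv.simulate import LatentFatigueSeries, emit_observables

        config = SimulationConfig(seed=1, n_athletes=1)
        profiles = simulate_athletes(config)
        calendar = build_event_calendar(config)
        bad = {
            profiles.loc[0, "athlete_id"]: LatentFatigueSeries(
                values=np.zeros(3), rho=0.5, kappa=0.1
            )
        }
        with pytest.raises(ValueError, match="length"):
            emit_observables(profiles, calendar, bad, config)


class TestDeterminism:
    def test_same_seed_reproduces_records_exactly(self):
        a = simulate_cohort(SimulationConfig(seed=77, n_athletes=4))
        b = simulate_cohort(SimulationConfig(seed=77, n_athletes=4))
        assert_frame_equal(a.records, b.records)
        assert_frame_equal(a.profiles, b.profiles)
        assert a.truth["linear_predictor"] == b.truth["linear_predictor"]

    def test_same_seed_reproduces_tachograms_exactly(self, rr_cohort):
        again = simulate_cohort(rr_cohort.config, include_rr=True)
        for s1, s2 in zip(rr_cohort.sessions, again.sessions):
            assert np.array_equal(s1.supine.intervals, s2.supine.intervals)
            assert np.array_equal(s1.standing.intervals, s2.standing.intervals)

    def test_different_seeds_differ(self):
        a = simulate_cohort(SimulationConfig(seed=1, n_athletes=4))
        b = simulate_cohort(SimulationConfig(seed=2, n_athletes=4))
        assert not a.records["delta_rr_mean"].equals(b.records["delta_rr_mean"])


class TestOrthostaticRR:
    def _config(self, **kw):
        return SimulationConfig(seed=0, **kw)

    def test_zero_rmssd_target_gives_constant_series(self, rng):
        session = simulate_orthostatic_rr(1000.0, 700.0, 0.0, 0.0, self._config(), rng)
        assert np.ptp(session.supine.intervals) == 0.0
        assert session.supine.intervals[0] == 1000.0

    def test_mean_targets_hit_exactly(self, rng):
        session = simulate_orthostatic_rr(1000.0, 700.0, 40.0, 15.0, self._config(), rng)
        assert session.supine.intervals.mean() == pytest.approx(1000.0, abs=1e-9)
        assert session.standing.intervals.mean() == pytest.approx(700.0, abs=1e-9)
        assert session.supine.duration_s >= 420.0

    def test_rmssd_targets_hit(self, rng):
        session = simulate_orthostatic_rr(1000.0, 700.0, 40.0, 15.0, self._config(), rng)
        _, _, rmssd_sup, _ = time_domain_indices(session.supine)
        _, _, rmssd_sta, _ = time_domain_indices(session.standing)
        assert rmssd_sup == pytest.approx(40.0, rel=1e-9)
        assert rmssd_sta == pytest.approx(15.0, rel=1e-9)

    def test_downstream_delta_matches_construction(self, rng):
        session = simulate_orthostatic_rr(1000.0, 700.0, 30.0, 12.0, self._config(), rng)
        delta = session.supine.intervals.mean() - session.standing.intervals.mean()
        assert delta == pytest.approx(300.0, abs=1e-9)

    def test_hf_only_modulation_dominates_hf_band(self, rng):
        config = self._config(hf_share=1.0, lf_share=0.0)
        session = simulate_orthostatic_rr(1000.0, 700.0, 35.0, 12.0, config, rng)
        sp = spectral_powers(session.supine)
        assert sp.hf_nu > 0.9

    def test_infeasible_rmssd_target_rejected(self, rng):
        with pytest.raises(ValueError, match="[Ii]nfeasible"):
            simulate_orthostatic_rr(350.0, 700.0, 2000.0, 15.0, self._config(), rng)

    def test_out_of_range_mean_rejected(self, rng):
        with pytest.raises(ValueError, match="300"):
            simulate_orthostatic_rr(250.0, 700.0, 30.0, 15.0, self._config(), rng)


class TestEctopicInjection:
    def test_zero_fraction_is_identity(self, rng):
        clean = RRSeries(np.full(400, 800.0))
        out = inject_ectopic_artifacts(clean, 0.0, rng)
        assert np.array_equal(out.intervals, clean.intervals)

    def test_exact_corrupted_beat_count(self, rng):
        clean = RRSeries(np.full(400, 800.0))
        out = inject_ectopic_artifacts(clean, 0.03, rng)
        assert int((out.intervals != clean.intervals).sum()) == 12

    def test_cumulative_time_preserved(self, rng):
        clean = RRSeries(np.full(500, 850.0))
        out = inject_ectopic_artifacts(clean, 0.1, rng)
        assert out.intervals.sum() == pytest.approx(clean.intervals.sum(), abs=1e-6)

    def test_excessive_fraction_rejected(self, rng):
        with pytest.raises(ValueError, match="0.2"):
            inject_ectopic_artifacts(RRSeries(np.full(100, 800.0)), 0.25, rng)

    def test_round_trip_with_correction_restores_mean(self, rng):
        from orthohrv.sessions import correct_artifacts

        clean = RRSeries(np.full(400, 850.0))
        corrupted = inject_ectopic_artifacts(clean, 0.03, rng)
        corrected, fraction = correct_artifacts(corrupted, threshold_ms=250.0)
        assert fraction < 0.05
        assert abs(corrected.intervals.mean() - 850.0) < 2.0


class TestGenerativeConsistency:
    def test_pipeline_measured_delta_matches_linear_predictor(self):
        """With no generative noise, running the raw tachograms through QC,
        windowing, and the HRV stage reproduces the configured linear
        predictor to within 2 ms for every athlete-day."""
        config = SimulationConfig(
            seed=19,
            n_athletes=2,
            n_stages=3,
            n_baseline=1,
            rest_after_stages=(),
            n_post=0,
            noise_sd=0.0,
            standing_rr_day_sd=0.0,
        )
        cohort = simulate_cohort(config, include_rr=True)
        lp = cohort.truth["linear_predictor"]
        for session in cohort.sessions:
            qc = assemble_session(
                session.supine,
                session.standing,
                athlete_id=session.athlete_id,
                day_index=session.day_index,
            )
            assert qc.quality_flag == "ok"
            measured = qc.supine.intervals.mean() - qc.standing.intervals.mean()
            expected = lp[session.athlete_id][session.day_index]
            assert measured == pytest.approx(expected, abs=2.0)
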