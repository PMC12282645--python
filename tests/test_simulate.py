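import dataclasses

import numpy as np
import pandas as pd
import pytest

from nightscratch.intervals import Interval, iou, normalize_track, total_duration
from nightscratch.simulate import (
    CohortSpec,
    DeviceModel,
    RaterModel,
    StudyConfig,
    analytic_icc,
    apply_device_model,
    apply_rater_model,
    default_config,
    simulate_study,
)


def small_config(seed=0, **overrides):
    """A single-cohort study small enough for fast unit tests."""
    base = dict(
        cohorts=(CohortSpec("Mild AD", 4, 3.5, 17.4),),
        nights_per_participant=3,
        seed=seed,
    )
    base.update(overrides)
    return dataclasses.replace(StudyConfig(), **base)


class TestConfigValidation:
    def test_bad_cohort_rejected(self):
        with pytest.raises(ValueError, match="n_participants"):
            CohortSpec("X", 0, 2.0, 10.0)

    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError, match="miss_prob"):
            RaterModel(miss_prob=1.5)
        with pytest.raises(ValueError, match="split_prob"):
            DeviceModel(split_prob=-0.1)

    def test_bad_components_rejected(self):
        with pytest.raises(ValueError, match="outcome_components"):
            dataclasses.replace(StudyConfig(), outcome_components={"norm_duration": (1.0, -0.5, 0.5)})


class TestSimulateStudy:
    def test_expected_night_counts(self):
        study = simulate_study(default_config(seed=1))
        truth_tso = study.events[(study.events.source == "Truth") & (study.events.kind == "tso")]
        assert len(truth_tso) == 28 * 8
        assert study.participants.shape[0] == 28
        assert study.participants["cohort"].value_counts().to_dict() == {
            "Moderate AD": 14, "Mild AD": 9, "HV": 5,
        }

    def test_same_seed_byte_identical(self):
        a = simulate_study(small_config(seed=7))
        b = simulate_study(small_config(seed=7))
        assert a.events.to_csv(index=False) == b.events.to_csv(index=False)
        assert a.pros.to_csv(index=False) == b.pros.to_csv(index=False)

    def test_different_seed_differs(self):
        a = simulate_study(small_config(seed=7))
        b = simulate_study(small_config(seed=8))
        assert a.events.to_csv(index=False) != b.events.to_csv(index=False)

    def test_truth_is_postprocessing_fixed_point(self, track):
        from nightscratch.intervals import filter_min_duration, merge_gaps

        study = simulate_study(small_config(seed=3))
        ev = study.events
        scratch = ev[(ev.source == "Truth") & (ev.kind == "scratch")]
        for (_, _), grp in scratch.groupby(["participant_id", "night_id"]):
            t = normalize_track(grp[["start_s", "end_s"]].to_numpy())
            done = filter_min_duration(merge_gaps(t, 3.0), 2.0)
            assert np.array_equal(t.intervals, done.intervals)

    def test_hv_participants_have_no_pro(self):
        study = simulate_study(default_config(seed=2))
        hv = set(study.participants[study.participants.cohort == "HV"].participant_id)
        assert not (set(study.pros.participant_id) & hv)

    def test_itch_couples_to_scratch(self):
        """Nights rated itch 0 scratch less than nights rated mild or worse."""
        study = simulate_study(default_config(seed=4))
        ev = study.events
        scratch = ev[(ev.source == "Truth") & (ev.kind == "scratch")].copy()
        scratch["dur"] = scratch.end_s - scratch.start_s
        per_night = scratch.groupby(["participant_id", "night_id"])["dur"].sum()
        morning = study.pros[study.pros.administration == "morning"].copy()
        morning["night_id"] = (
            pd.to_datetime(morning["date"]) - pd.Timedelta(days=1)
        ).dt.date.astype(str)
        joined = morning.set_index(["participant_id", "night_id"]).join(
            per_night.rename("scratch_s"), how="inner"
        )
        no_itch = joined[joined.itch_nrs == 0]["scratch_s"].fillna(0)
        mild = joined[(joined.itch_nrs >= 1) & (joined.itch_nrs <= 3)]["scratch_s"].fillna(0)
        assert no_itch.median() < mild.median()


class TestRaterModel:
    def _truth(self, track):
        return track([(200 * i, 200 * i + 8) for i in range(30)], source="Truth")

    def test_zero_noise_is_identity(self, track, rng):
        truth = self._truth(track)
        out = apply_rater_model(truth, RaterModel.zero(), rng, Interval(0, 6000))
        assert np.array_equal(out.intervals, truth.intervals)

    def test_total_miss_is_empty(self, track, rng):
        truth = self._truth(track)
        model = RaterModel(miss_prob=1.0, false_bout_rate_per_h=0.0)
        out = apply_rater_model(truth, model, rng, Interval(0, 6000))
        assert out.is_empty

    def test_moderate_noise_iou_band(self, track):
        """Jitter 1 s, miss 5%, 0.2 false bouts/h lands in a moderate IoU band."""
        rng = np.random.default_rng(11)
        model = RaterModel(boundary_jitter_sd_s=1.0, miss_prob=0.05, false_bout_rate_per_h=0.2)
        window = Interval(0.0, 8 * 3600.0)
        truth = track([(900.0 * i, 900.0 * i + 8.0) for i in range(32)], source="Truth")
        for _ in range(10):
            out = apply_rater_model(truth, model, rng, window)
            assert 0.6 <= iou(out, truth) <= 0.98


class TestDeviceModel:
    def test_identity_model(self, track, rng):
        truth = track([(100, 110), (500, 520)], source="Truth")
        tso = Interval(0, 8 * 3600)
        scratch, sleep = apply_device_model(truth, tso, DeviceModel.identity(), rng)
        assert np.array_equal(scratch.intervals, truth.intervals)
        assert sleep.intervals.tolist() == [[tso.start_s, tso.end_s]]

    def test_detection_probability_increases_with_duration(self):
        m = DeviceModel.emerald_like()
        p = m.detect_prob(np.array([2.0, 5.0, 20.0]))
        assert np.all(np.diff(p) > 0)

    def test_endpoint_bias_shifts_duration(self, track, rng):
        truth = track([], source="Truth")
        tso = Interval(0, 8 * 3600)
        model = DeviceModel(tso_start_bias_s=-720.0, tso_end_bias_s=720.0)
        _, sleep = apply_device_model(truth, tso, model, rng)
        dur_h = total_duration(sleep) / 3600.0
        assert dur_h == pytest.approx(8.4)  # +0.2 h at both ends


class TestAnalyticIcc:
    def test_examples(self):
        cfg = dataclasses.replace(
            StudyConfig(),
            outcome_components={"a": (1.0, 0.5, 0.5), "b": (1.0, 0.0, 0.0)},
        )
        out = analytic_icc(cfg)
        assert out["a"] == pytest.approx(0.75)
        assert out["b"] == pytest.approx(1.0)

    def test_pipeline_recovers_analytic_value(self):
        """End-to-end: fitting data simulated from the config's components
        recovers the closed-form ICC within +-0.05."""
        from nightscratch.agreement import fit_variance_components, icc_from_components
        from nightscratch.simulate import simulate_log_outcomes

        cfg = StudyConfig()
        target = analytic_icc(cfg)["norm_duration"]
        ests = []
        for r in range(20):
            df = simulate_log_outcomes(
                28, 8, ["Ref", "DHT"], cfg.outcome_components["norm_duration"], seed=900 + r
            )
            ests.append(icc_from_components(fit_variance_components(df)))
        assert abs(np.mean(ests) - target) < 0.05
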