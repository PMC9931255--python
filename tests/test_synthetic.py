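"""Generator contracts: cohort composition, signal model, ground truth, I/O."""

import json

import numpy as np
import pytest

from msgait import io, synthetic
from msgait.features import rms_ap
from msgait.types import ConfigurationError, EmptySegmentError

from conftest import make_profile

FS = 31.25


class TestGenerateCohort:
    def test_study_scale_composition(self):
        cohort = synthetic.generate_cohort(38, 21 / 38, effect_config={}, seed=1)
        labels = [p.fall_label for p in cohort]
        assert labels.count("faller") == 21
        assert labels.count("non_faller") == 17

    def test_zero_fraction_means_no_fallers(self):
        cohort = synthetic.generate_cohort(10, 0.0, effect_config={"ap_amplitude": 0.5}, seed=7)
        assert all(p.fall_label == "non_faller" for p in cohort)

    def test_deterministic_under_seed(self):
        a = synthetic.generate_cohort(12, 0.5, seed=3)
        b = synthetic.generate_cohort(12, 0.5, seed=3)
        assert [(p.subject_id, p.stride_time_mean, p.ap_amplitude) for p in a] == [
            (p.subject_id, p.stride_time_mean, p.ap_amplitude) for p in b
        ]

    def test_effect_multiplier_recovered_in_group_means(self):
        cohort = synthetic.generate_cohort(200, 0.5, effect_config={"rms_ap": 0.85}, seed=3)
        fal = np.mean([p.ap_amplitude for p in cohort if p.is_faller])
        non = np.mean([p.ap_amplitude for p in cohort if not p.is_faller])
        assert fal / non == pytest.approx(0.85, abs=0.04)

    def test_unknown_effect_parameter_rejected(self):
        with pytest.raises(ConfigurationError):
            synthetic.generate_cohort(10, 0.5, effect_config={"cadence_wobble": 2.0}, seed=0)

    def test_missing_surveys_blanked(self):
        cohort = synthetic.generate_cohort(20, 0.5, seed=4, missing_surveys={"NSI": 3})
        n_missing = sum(np.isnan(p.surveys["NSI"]) for p in cohort)
        assert n_missing == 3

    def test_profile_invariants_hold(self):
        for p in synthetic.generate_cohort(50, 0.5, seed=9):
            assert 0.5 <= p.stride_time_mean <= 3.0
            assert p.stride_time_cv >= 0
            assert 0.5 < p.duty_factor_mean < 0.8
            assert p.ap_amplitude > 0


class TestWalkingSegment:
    def test_zero_variance_gait_is_perfectly_regular(self):
        prof = make_profile(stride_time_cv=0.0)
        _, _, contacts, foot_offs = synthetic.synth_walking_segment(prof, 10, seed=2)
        durations = np.diff(contacts)
        assert np.allclose(durations, durations[0])
        duty = (foot_offs[:-1] - contacts[:-1]) / durations
        assert np.allclose(duty, 0.62)

    def test_stride_time_mean_recovered(self):
        prof = make_profile(stride_time_mean=1.16)
        durations = np.concatenate(
            [
                np.diff(synthetic.synth_walking_segment(prof, 50, seed=s)[2])
                for s in (5, 6, 7)
            ]
        )
        assert durations.mean() == pytest.approx(1.16, rel=0.02)

    def test_ap_rms_scales_exactly_with_amplitude(self):
        prof1 = make_profile(ap_amplitude=0.15)
        prof2 = make_profile(ap_amplitude=0.30)
        c1, _, _, _ = synthetic.synth_walking_segment(prof1, 20, seed=8)
        c2, _, _, _ = synthetic.synth_walking_segment(prof2, 20, seed=8)
        assert rms_ap(c2) / rms_ap(c1) == pytest.approx(2.0, rel=1e-9)

    def test_event_ordering_invariant(self, walking_segment):
        _, _, _, contacts, foot_offs = walking_segment
        for k in range(len(contacts) - 1):
            assert contacts[k] < foot_offs[k] < contacts[k + 1]

    def test_requested_mean_and_cv_reproduced_at_large_n(self):
        prof = make_profile(stride_time_mean=1.3, stride_time_cv=0.08)
        _, _, contacts, _ = synthetic.synth_walking_segment(prof, 250, seed=6)
        d = np.diff(contacts)
        assert d.mean() == pytest.approx(1.3, rel=0.05)
        assert d.std(ddof=1) / d.mean() == pytest.approx(0.08, rel=0.25)

    def test_empty_segment_rejected(self, profile):
        with pytest.raises(EmptySegmentError):
            synthetic.synth_walking_segment(profile, 0, seed=1)


class TestSubjectRecording:
    def test_bout_mix_proportions(self, profile):
        mix = {"short": 0.61, "medium": 0.32, "long": 0.07}
        _, _, gt = synthetic.generate_subject_recording(profile, duration_h=3.0,
                                                        bout_mix=mix, seed=13)
        durations = np.array([e - s for s, e in gt.bout_intervals])
        shares = {
            "short": np.mean(durations <= 8),
            "medium": np.mean((durations >= 12) & (durations <= 28)),
            "long": np.mean(durations >= 32),
        }
        for cls, want in mix.items():
            assert shares[cls] == pytest.approx(want, abs=0.03)

    def test_degenerate_mixture_gives_only_short_bouts(self, profile):
        _, _, gt = synthetic.generate_subject_recording(
            profile, duration_h=0.2, bout_mix={"short": 1.0, "medium": 0.0, "long": 0.0}, seed=2
        )
        assert all(e - s <= 8 for s, e in gt.bout_intervals)

    def test_bitwise_determinism(self, profile):
        a = synthetic.generate_subject_recording(profile, duration_h=0.1, seed=9)
        b = synthetic.generate_subject_recording(profile, duration_h=0.1, seed=9)
        assert np.array_equal(a[0].data, b[0].data)
        assert np.array_equal(a[1].data, b[1].data)
        assert a[2].bout_intervals == b[2].bout_intervals
        assert np.array_equal(a[2].window_labels, b[2].window_labels)

    def test_window_labels_match_bout_intervals(self, subject_recording):
        _, chest, _, gt = subject_recording
        gait_time = 4.0 * gt.window_labels.sum()
        bout_time = sum(e - s for s, e in gt.bout_intervals)
        assert gait_time == pytest.approx(bout_time, abs=4.0)

    def test_invalid_mix_rejected(self, profile):
        with pytest.raises(ConfigurationError):
            synthetic.generate_subject_recording(
                profile, duration_h=0.1, bout_mix={"short": 0.5, "medium": 0.2, "long": 0.2},
                seed=0,
            )


class TestDatasetRoundTrip:
    def test_signals_events_and_manifest(self, tmp_path, profile):
        chest, thigh, gt = synthetic.generate_subject_recording(profile, duration_h=0.05, seed=17)
        manifest = synthetic.write_dataset(
            [profile], {profile.subject_id: (chest, thigh)}, {profile.subject_id: gt}, tmp_path
        )
        files = manifest["subjects"][profile.subject_id]
        assert set(files) >= {"chest", "thigh", "annotations"}

        rec = io.read_recording(tmp_path / files["chest"], profile.subject_id, "chest")
        assert np.allclose(rec.data, chest.data, atol=0, rtol=0)  # full stored precision
        assert rec.fs == pytest.approx(chest.fs, rel=1e-9)

        gt2 = io.read_annotations(tmp_path / files["annotations"])
        assert gt2.bout_intervals == [tuple(map(float, b)) for b in gt.bout_intervals]
        for ev_a, ev_b in zip(gt.gait_events, gt2.gait_events):
            assert np.allclose(np.asarray(ev_a), np.asarray(ev_b))

        ann = json.loads((tmp_path / files["annotations"]).read_text())
        assert len(ann["windows"]) == len(gt.window_labels)


class TestParameterSampler:
    def test_matches_signal_pipeline_statistically(self, profile):
        """The fast bout-parameter sampler tracks the full signal path."""
        from msgait import strides as st
        from msgait.features import temporal_parameters

        rng = np.random.default_rng(0)
        sampled = synthetic.sample_bout_parameters(profile, 200, "medium", rng)

        means, rmss = [], []
        for seed in range(25):
            chest, thigh, contacts, _ = synthetic.synth_walking_segment(profile, 15, seed=600 + seed)
            det, _ = st.detect_gait_events(thigh, FS)
            tp = temporal_parameters(det)
            means.append(tp["stride_time_mean_s"])
            rmss.append(rms_ap(chest))
        assert np.mean(means) == pytest.approx(sampled["stride_time_mean_s"].mean(), rel=0.03)
        assert np.mean(rmss) == pytest.approx(sampled["rms_ap_g"].mean(), rel=0.06)
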