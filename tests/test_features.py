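"""Gait-parameter computations: temporal statistics, RMS, spectral spread,
sample entropy, Lyapunov exponent, and the 8/9/11 feature dispatch."""

import numpy as np
import pytest

from msgait import features, strides, synthetic
from msgait.types import (
    InsufficientStridesError,
    Stride,
    UndefinedFeatureError,
    WalkingBout,
)

from conftest import make_profile

FS = 31.25


def _strides_from(times):
    """times: list of (stride, stance) tuples laid head to tail."""
    out, t = [], 0.0
    for stride, stance in times:
        out.append(Stride(t, t + stance, t + stride))
        t += stride
    return out


class TestTemporalParameters:
    def test_identical_strides_reproduce_inputs(self):
        s = _strides_from([(1.16, 0.71)] * 5)
        p = features.temporal_parameters(s)
        assert p["stride_time_mean_s"] == pytest.approx(1.16)
        assert p["stance_time_mean_s"] == pytest.approx(0.71)
        assert p["swing_time_mean_s"] == pytest.approx(0.45)
        assert p["stride_time_cv"] == pytest.approx(0.0, abs=1e-12)
        assert p["duty_factor_cv"] == pytest.approx(0.0, abs=1e-12)
        assert p["duty_factor_mean"] == pytest.approx(0.71 / 1.16)

    def test_hand_computed_cv(self):
        s = _strides_from([(1.0, 0.6), (1.2, 0.72)])
        p = features.temporal_parameters(s)
        assert p["stride_time_mean_s"] == pytest.approx(1.1)
        # n-1 SD of {1.0, 1.2} is 0.1414; CV = 0.1414/1.1
        assert p["stride_time_cv"] == pytest.approx(np.std([1.0, 1.2], ddof=1) / 1.1)
        assert p["stride_time_cv"] == pytest.approx(0.1285, abs=5e-4)

    def test_cv_scale_invariance(self):
        base = [(1.0, 0.6), (1.2, 0.72), (1.1, 0.68)]
        p1 = features.temporal_parameters(_strides_from(base))
        p2 = features.temporal_parameters(_strides_from([(2 * a, 2 * b) for a, b in base]))
        assert p2["stride_time_mean_s"] == pytest.approx(2 * p1["stride_time_mean_s"])
        assert p2["stride_time_cv"] == pytest.approx(p1["stride_time_cv"])
        assert p2["duty_factor_mean"] == pytest.approx(p1["duty_factor_mean"])

    def test_insufficient_strides(self):
        with pytest.raises(InsufficientStridesError):
            features.temporal_parameters(_strides_from([(1.16, 0.71)]))


class TestRmsAp:
    def test_zero_signal(self):
        assert features.rms_ap(np.zeros((3, 100))) == 0.0

    def test_sinusoid_closed_form(self):
        t = np.arange(int(30 * FS)) / FS
        a = 0.37
        x = np.vstack([np.zeros_like(t), np.zeros_like(t), a * np.sin(2 * np.pi * 0.9 * t)])
        assert features.rms_ap(x) == pytest.approx(a / np.sqrt(2), rel=1e-2)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=500)
        expect = np.sqrt(np.mean((v - v.mean()) ** 2))
        assert features.rms_ap(v) == pytest.approx(expect, rel=1e-12)

    def test_offset_invariance(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=500)
        assert features.rms_ap(v + 5.0) == pytest.approx(features.rms_ap(v), rel=1e-12)


class TestFreqDispersion:
    def test_pure_tone_near_zero(self):
        t = np.arange(int(60 * FS)) / FS
        x = np.sin(2 * np.pi * 1.0 * t)
        assert features.freq_dispersion_ml(x, FS) < 0.15

    def test_white_noise_uniform_psd_closed_form(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=int(120 * FS))
        expect = (FS / 2) / np.sqrt(12)  # ~4.51 Hz
        assert features.freq_dispersion_ml(x, FS) == pytest.approx(expect, rel=0.03)

    def test_amplitude_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=int(30 * FS))
        assert features.freq_dispersion_ml(7 * x, FS) == pytest.approx(
            features.freq_dispersion_ml(x, FS), rel=1e-9
        )

    def test_zero_signal_undefined(self):
        with pytest.raises(UndefinedFeatureError):
            features.freq_dispersion_ml(np.zeros(1000), FS)


class TestEntropyRatio:
    def test_self_ratio_is_one(self):
        rng = np.random.default_rng(7)
        x = np.vstack([rng.normal(size=1500)] * 3)
        assert features.entropy_ratio(x, x) == pytest.approx(1.0)

    def test_reciprocity(self):
        rng = np.random.default_rng(8)
        a = np.vstack([rng.normal(size=1200)] * 3)
        t = np.arange(1200) / FS
        b = np.vstack([np.sin(2 * np.pi * 0.9 * t) + 0.1 * rng.normal(size=1200)] * 3)
        assert features.entropy_ratio(a, b) * features.entropy_ratio(b, a) == pytest.approx(1.0)

    def test_noisy_thigh_vs_periodic_chest_exceeds_one(self):
        rng = np.random.default_rng(9)
        t = np.arange(1500) / FS
        thigh = np.vstack([rng.normal(size=1500)] * 3)
        chest = np.vstack([np.sin(2 * np.pi * 0.9 * t) + 0.05 * rng.normal(size=1500)] * 3)
        assert features.entropy_ratio(thigh, chest) > 1.0


class TestMaxLyapunov:
    def _periodic(self, dur=70.0, noise=0.0, seed=10):
        rng = np.random.default_rng(seed)
        t = np.arange(int(dur * FS)) / FS
        x = np.sin(2 * np.pi * 0.86 * t) + 0.3 * np.sin(2 * np.pi * 1.72 * t)
        return x + noise * rng.normal(size=len(t))

    def test_periodic_signal_near_zero(self):
        assert features.max_lyapunov(self._periodic(), FS, 0.86) <= 0.05

    def test_noise_monotonically_inflates_estimate(self):
        vals = [features.max_lyapunov(self._periodic(noise=nl), FS, 0.86)
                for nl in (0.0, 0.1, 0.3)]
        assert vals[0] <= vals[1] <= vals[2] + 1e-9

    def test_time_reversed_input_is_finite(self):
        v = features.max_lyapunov(self._periodic(noise=0.1)[::-1], FS, 0.86)
        assert np.isfinite(v)

    def test_too_short_series_rejected(self):
        with pytest.raises(UndefinedFeatureError):
            features.max_lyapunov(self._periodic(dur=3.0), FS, 0.86)


class TestExtractBoutParameters:
    def _bout(self, duration_s, seed, context="home"):
        prof = make_profile()
        n = int(np.ceil(duration_s / prof.stride_time_mean)) + 2
        chest, thigh, _, _ = synthetic.synth_walking_segment(prof, n, seed=seed)
        n_samp = int(duration_s * FS)
        b = WalkingBout(bout_id=0, subject_id="s", start_s=0.0, end_s=duration_s, fs=FS,
                        chest_view=chest[:, :n_samp], thigh_view=thigh[:, :n_samp],
                        context=context)
        assert strides.detect_bout_events(b)
        return b

    @pytest.mark.parametrize("duration,cls,arity", [(8, "short", 8), (40, "long", 9),
                                                    (60, "lab", 11)])
    def test_feature_arity_by_class(self, duration, cls, arity):
        row = self._bout(duration, seed=duration, context="lab" if cls == "lab" else "home")
        out = features.extract_bout_parameters(row, cls)
        feat_cols = [k for k in out if k in features.FEATURES_BY_CLASS["lab"]]
        assert len(feat_cols) == arity
        assert set(feat_cols) == set(features.FEATURES_BY_CLASS[cls])

    def test_constant_offset_invariance(self):
        b = self._bout(24, seed=77)
        out1 = features.extract_bout_parameters(b, "medium")
        b.chest_view = b.chest_view + 0.5
        b.thigh_view = b.thigh_view + 0.25
        out2 = features.extract_bout_parameters(b, "medium")
        for k in features.FEATURES_BY_CLASS["medium"]:
            assert out2[k] == pytest.approx(out1[k], rel=1e-9)

    def test_parameter_recovery_regression(self):
        """Bout-level estimates track generator truth with slope ~1, R^2 >= 0.9."""
        rng = np.random.default_rng(0)
        truths, ests = [], []
        for i in range(12):
            mu = float(rng.uniform(0.95, 1.5))
            prof = make_profile(stride_time_mean=mu, stride_time_cv=0.05)
            chest, thigh, contacts, _ = synthetic.synth_walking_segment(prof, 20, seed=800 + i)
            det, _ = strides.detect_gait_events(thigh, FS)
            p = features.temporal_parameters(det)
            truths.append(np.diff(contacts).mean())
            ests.append(p["stride_time_mean_s"])
        slope, intercept = np.polyfit(truths, ests, 1)
        resid = np.array(ests) - (slope * np.array(truths) + intercept)
        r2 = 1 - resid.var() / np.var(ests)
        assert slope == pytest.approx(1.0, abs=0.1)
        assert r2 >= 0.9
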