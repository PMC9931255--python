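"""Synthetic dual-sensor free-living accelerometry with full ground truth.

This module emulates the study conditions the pipeline is built for: a cohort
of ambulatory persons with MS (fallers and non-fallers), each wearing a chest
and a right-thigh accelerometer (31.25 Hz, axes [vertical, ML, AP], gravity as
+1 g on the vertical channel) during daily life.  Recordings interleave
quasi-periodic walking bouts with low-amplitude non-gait filler, and every
sample of truth is retained: bout intervals, per-stride foot-contact/foot-off
times, per-window gait labels, and the per-subject gait parameters the signals
were synthesized from.

Signal model, per stride of duration T with foot contact at t0 and duty
factor d:

* an impact transient (Gaussian kernel, ~35 ms wide) at each ipsilateral foot
  contact, a smaller one at the contralateral contact (t0 + T/2), and a
  negative kernel at foot off (t0 + d*T) — these carry the event timing;
* harmonics at stride (1/T) and step (2/T) frequency phase-locked to the
  contact — these carry the cadence the PSD stage estimates;
* white measurement noise.

The chest AP channel is normalized so its RMS equals the subject's
``ap_amplitude`` exactly; chest ML mixes a stride harmonic with low-passed
noise whose width tracks ``ml_bandwidth``.  Fallers differ from non-fallers
exactly by configured multipliers on named profile parameters (default:
lower AP amplitude, slightly lower duty factor, the directions of the study's
faller/non-faller contrasts).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .types import (
    AX_AP,
    AX_ML,
    AX_V,
    AccelRecording,
    ConfigurationError,
    EmptySegmentError,
    GroundTruth,
    SubjectProfile,
    SURVEY_FIELDS,
)

FS_HOME = 31.25  # Hz, free-living sampling rate
WINDOW_S = 4.0

#: baseline (non-faller) parameter distributions: (mean, sd, low, high).
#: Centres sit on the study's free-living medians (stride time 1.16 s, duty
#: factor 0.62, RMS AP 0.15 g for non-fallers, Freqd ML ~0.6 Hz); between-
#: subject spreads are chosen as realistic for mildly impaired ambulatory
#: cohorts (~7% stride-time, ~13% amplitude CV).
BASELINE_DISTRIBUTIONS = {
    "stride_time_mean": (1.16, 0.08, 0.90, 1.60),
    "stride_time_cv": (0.07, 0.015, 0.02, 0.15),
    "duty_factor_mean": (0.62, 0.012, 0.55, 0.72),
    "ap_amplitude": (0.15, 0.02, 0.06, 0.40),
    "ml_bandwidth": (0.60, 0.08, 0.30, 1.20),
}

#: default faller effect: multiplicative shifts in the directions of the
#: study's faller vs non-faller contrasts (median RMS AP 0.13 vs 0.15 ->
#: x0.867; median duty factor 0.61 vs 0.62 -> x0.984).
DEFAULT_FALLER_EFFECTS = {
    "ap_amplitude": 0.13 / 0.15,
    "duty_factor_mean": 0.61 / 0.62,
}

_EFFECT_ALIASES = {"rms_ap": "ap_amplitude"}

#: survey score distributions per group: field -> (mean, sd) for
#: (faller, non_faller), clipped to instrument ranges.
SURVEY_DISTRIBUTIONS = {
    "ABC": ((75.0, 18.8), (91.4, 15.5), (0.0, 100.0)),
    "EDSS": ((3.3, 1.4), (2.3, 1.0), (0.0, 10.0)),
    "MFIS": ((39.8, 17.9), (29.2, 16.7), (0.0, 84.0)),
    "MSWS": ((55.0, 23.3), (27.5, 11.5), (0.0, 100.0)),
    "NSI": ((56.6, 17.2), (46.6, 22.2), (0.0, 100.0)),
}

AGE_DISTRIBUTIONS = {"faller": (56.0, 9.05), "non_faller": (45.0, 12.92)}
MALE_FRACTION = {"faller": 5 / 21, "non_faller": 7 / 17}

#: per-stride duty-factor variability (unitless CV), a within-subject constant
_DUTY_CV = 0.045

#: bout-duration classes in 4-s steps (window quantization)
BOUT_CLASS_DURATIONS = {
    "short": np.arange(4, 12, 4),      # {4, 8} s
    "medium": np.arange(12, 32, 4),    # {12, ..., 28} s
    "long": np.arange(32, 124, 4),     # {32, ..., 120} s
}
DEFAULT_BOUT_MIX = {"short": 0.61, "medium": 0.32, "long": 0.07}


def _truncated_normal(rng, mean, sd, low, high, size=None):
    """Truncated normal by rejection; degenerates to the mean at sd=0."""
    if sd == 0:
        x = np.full(size if size is not None else (), float(mean))
        return np.clip(x, low, high)
    x = rng.normal(mean, sd, size=size)
    for _ in range(100):
        bad = (x < low) | (x > high)
        if not np.any(bad):
            break
        x = np.where(bad, rng.normal(mean, sd, size=np.shape(x)), x)
    return np.clip(x, low, high)


def generate_cohort(
    n_subjects: int,
    faller_fraction: float,
    effect_config: dict | None = None,
    seed: int = 0,
    missing_surveys: dict | None = None,
) -> list[SubjectProfile]:
    """Draw a cohort of subject profiles.

    Fallers and non-fallers are drawn from the same baseline distributions;
    faller profiles are then multiplied, parameter by parameter, by
    ``effect_config`` (default :data:`DEFAULT_FALLER_EFFECTS`; pass ``{}`` for
    identical groups).  ``missing_surveys`` maps a survey field to a count of
    entries to blank (NaN) across the cohort, emulating incomplete forms.
    """
    if n_subjects < 2:
        raise ConfigurationError("need at least 2 subjects")
    if not (0 <= faller_fraction <= 1):
        raise ConfigurationError("faller_fraction must be in [0, 1]")
    if effect_config is None:
        effect_config = dict(DEFAULT_FALLER_EFFECTS)
    effects = {}
    for key, mult in effect_config.items():
        canon = _EFFECT_ALIASES.get(key, key)
        if canon not in BASELINE_DISTRIBUTIONS:
            raise ConfigurationError(f"effect_config names unknown parameter {key!r}")
        effects[canon] = float(mult)

    rng = np.random.default_rng(seed)
    n_fallers = int(round(n_subjects * faller_fraction))
    labels = ["faller"] * n_fallers + ["non_faller"] * (n_subjects - n_fallers)

    cohort = []
    for i, label in enumerate(labels):
        params = {
            name: float(_truncated_normal(rng, *dist))
            for name, dist in BASELINE_DISTRIBUTIONS.items()
        }
        if label == "faller":
            for name, mult in effects.items():
                lo, hi = BASELINE_DISTRIBUTIONS[name][2:]
                params[name] = float(np.clip(params[name] * mult, lo, hi))
        surveys = {}
        for field, (fal, non, (lo, hi)) in SURVEY_DISTRIBUTIONS.items():
            mean, sd = fal if label == "faller" else non
            surveys[field] = float(np.clip(rng.normal(mean, sd), lo, hi))
        age = float(np.clip(rng.normal(*AGE_DISTRIBUTIONS[label]), 18, 90))
        sex = "M" if rng.random() < MALE_FRACTION[label] else "F"
        cohort.append(
            SubjectProfile(
                subject_id=f"S{i:03d}",
                fall_label=label,
                surveys=surveys,
                age=age,
                sex=sex,
                **params,
            )
        )

    if missing_surveys:
        for field, count in missing_surveys.items():
            if field not in SURVEY_FIELDS:
                raise ConfigurationError(f"unknown survey field {field!r}")
            idx = rng.choice(n_subjects, size=min(count, n_subjects), replace=False)
            for j in idx:
                cohort[j].surveys[field] = float("nan")
    return cohort


def _add_kernel(out: np.ndarray, fs: float, center_s: float, width_s: float, amp: float):
    """Accumulate a Gaussian kernel evaluated on the sample grid."""
    half = 4.0 * width_s
    i0 = max(0, int(np.floor((center_s - half) * fs)))
    i1 = min(out.size, int(np.ceil((center_s + half) * fs)) + 1)
    if i0 >= i1:
        return
    t = np.arange(i0, i1) / fs
    out[i0:i1] += amp * np.exp(-0.5 * ((t - center_s) / width_s) ** 2)


def _stride_harmonics(n: int, fs: float, contacts: np.ndarray, amps: tuple):
    """Harmonics at stride and step frequency, phase-locked to each contact."""
    out = np.zeros(n)
    t = np.arange(n) / fs
    for k in range(len(contacts) - 1):
        t0, t1 = contacts[k], contacts[k + 1]
        T = t1 - t0
        sel = (t >= t0) & (t < t1)
        tau = (t[sel] - t0) / T
        out[sel] += amps[0] * np.cos(2 * np.pi * tau) + amps[1] * np.cos(4 * np.pi * tau)
    return out


def synth_walking_segment(
    profile: SubjectProfile,
    n_strides: int,
    fs: float = FS_HOME,
    seed=None,
):
    """Synthesize one continuous walking segment with exact event truth.

    Returns ``(chest, thigh, contacts, foot_offs)`` where chest/thigh are
    3xT arrays in g and contacts/foot_offs are event times in seconds on the
    segment's own time base (contacts has ``n_strides + 1`` entries; stride k
    runs from contacts[k] to contacts[k+1]).
    """
    if n_strides < 1:
        raise EmptySegmentError("a walking segment needs at least one stride")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    mu, cv, duty = profile.stride_time_mean, profile.stride_time_cv, profile.duty_factor_mean
    durations = _truncated_normal(rng, mu, cv * mu, 0.5, 3.0, size=n_strides + 1)
    contacts = np.concatenate([[0.0], np.cumsum(durations[:n_strides])])
    # a zero-CV profile denotes perfectly regular gait: all stride-level
    # variability (durations and duty factors) switches off together
    duty_sd = _DUTY_CV * duty if cv > 0 else 0.0
    duties = _truncated_normal(rng, duty, duty_sd, 0.46, 0.80, size=n_strides + 1)
    # the final contact's stance uses an extrapolated stride so its foot off
    # stays inside the segment
    stride_for_fo = np.append(np.diff(contacts), durations[n_strides])
    foot_offs = contacts + duties * stride_for_fo

    total_s = foot_offs[-1] + 0.15
    n = int(np.ceil(total_s * fs))

    def event_train(imp_amp, contra_amp, fo_amp, harm_amps, noise_sd):
        x = np.zeros(n)
        for k, fc in enumerate(contacts):
            _add_kernel(x, fs, fc, 0.035, imp_amp)
            if k < len(contacts) - 1:
                T = contacts[k + 1] - contacts[k]
                _add_kernel(x, fs, fc + 0.5 * T, 0.035, contra_amp)
        for fo in foot_offs:
            _add_kernel(x, fs, fo, 0.045, fo_amp)
        x += _stride_harmonics(n, fs, contacts, harm_amps)
        x += rng.normal(0.0, noise_sd, n)
        return x

    # chest: attenuated impacts, trunk sway harmonics
    chest_ap = event_train(0.9, 0.6, -0.45, (0.30, 0.45), 0.06)
    chest_ap -= chest_ap.mean()
    chest_ap *= profile.ap_amplitude / _rms(chest_ap)

    chest_ml = _ml_channel(rng, n, fs, contacts, profile.ml_bandwidth)
    chest_v = 1.0 + 0.25 * event_train(0.8, 0.7, 0.0, (0.15, 0.55), 0.05)

    # thigh: sharper impacts and a deeper swing-initiation dip (event channel)
    thigh_ap = 0.5 * event_train(1.0, 0.55, -0.55, (0.25, 0.40), 0.05)
    thigh_ml = 0.12 * (rng.normal(0, 1, n) * 0.5 + _stride_harmonics(n, fs, contacts, (0.8, 0.2)))
    thigh_v = 1.0 + 0.35 * event_train(0.9, 0.6, -0.3, (0.2, 0.5), 0.05)

    chest = np.vstack([chest_v, chest_ml, chest_ap])
    thigh = np.vstack([thigh_v, thigh_ml, thigh_ap])
    return chest, thigh, contacts, foot_offs


def _rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


def _ml_channel(rng, n, fs, contacts, ml_bandwidth):
    """Chest ML: stride-frequency sway plus low-passed noise.

    The noise cutoff scales with ml_bandwidth so the PSD-weighted spectral
    spread of the channel increases monotonically with the profile parameter.
    """
    cutoff = min(np.sqrt(12.0) * ml_bandwidth, 0.45 * fs)
    noise = rng.normal(0, 1, n)
    b, a = sps.butter(4, cutoff / (fs / 2), btype="low")
    noise = sps.filtfilt(b, a, noise)
    sway = _stride_harmonics(n, fs, contacts, (1.0, 0.25))
    x = 0.6 * sway + 1.0 * noise / max(_rms(noise), 1e-12)
    return 0.10 * x


def _nongait_filler(rng, n, fs, amplitude):
    """Band-limited postural noise plus occasional posture-shift transients."""
    x = rng.normal(0, 1.0, (3, n))
    if n > 18:  # filtfilt needs padding room
        b, a = sps.butter(2, min(6.0, 0.45 * fs) / (fs / 2), btype="low")
        x = sps.filtfilt(b, a, x, axis=1)
        x /= np.maximum(np.sqrt(np.mean(x**2, axis=1, keepdims=True)), 1e-12)
    x *= amplitude
    n_shift = rng.poisson(n / fs / 60.0)  # ~one posture shift per minute
    for _ in range(n_shift):
        c = rng.uniform(0, n / fs)
        ax = rng.integers(0, 3)
        _add_kernel(x[ax], fs, c, 0.3, rng.normal(0, 3 * amplitude))
    x[AX_V] += 1.0
    return x


def generate_subject_recording(
    profile: SubjectProfile,
    duration_h: float,
    bout_mix: dict | None = None,
    seed: int = 0,
    fs: float = FS_HOME,
):
    """Simulate one free-living wear period for a subject.

    Walking bouts with 4-s-quantized durations drawn from the short/medium/
    long mixture are interleaved with non-gait filler at ~10% of walking
    amplitude.  Returns (chest AccelRecording, thigh AccelRecording,
    GroundTruth).
    """
    if duration_h <= 0:
        raise ConfigurationError("duration_h must be positive")
    bout_mix = dict(DEFAULT_BOUT_MIX if bout_mix is None else bout_mix)
    if abs(sum(bout_mix.values()) - 1.0) > 1e-9:
        raise ConfigurationError(f"bout_mix fractions must sum to 1, got {bout_mix}")
    classes = sorted(bout_mix)
    probs = np.array([bout_mix[c] for c in classes])

    rng = np.random.default_rng(seed)
    total_n = int(round(duration_h * 3600 * fs))
    window_n = int(round(WINDOW_S * fs))

    chest = np.empty((3, total_n))
    thigh = np.empty((3, total_n))
    walk_amp = 0.5 * profile.ap_amplitude  # reference for the 10% filler level

    bout_intervals, gait_events = [], []
    cursor = 0  # sample index, always a multiple of window_n

    def fill(n_fill):
        nonlocal cursor
        n_fill = min(n_fill, total_n - cursor)
        if n_fill <= 0:
            return
        chest[:, cursor : cursor + n_fill] = _nongait_filler(rng, n_fill, fs, 0.1 * walk_amp)
        thigh[:, cursor : cursor + n_fill] = _nongait_filler(rng, n_fill, fs, 0.1 * walk_amp)
        cursor += n_fill

    # leading gap
    fill(int(rng.integers(2, 8)) * window_n)
    while cursor < total_n:
        cls = classes[rng.choice(len(classes), p=probs)]
        dur_s = float(rng.choice(BOUT_CLASS_DURATIONS[cls]))
        n_bout = int(round(dur_s * fs))
        if cursor + n_bout > total_n:
            fill(total_n - cursor)
            break
        n_strides = int(np.ceil(dur_s / (profile.stride_time_mean * 0.8))) + 2
        c_seg, t_seg, contacts, foot_offs = synth_walking_segment(
            profile, n_strides, fs=fs, seed=rng
        )
        if c_seg.shape[1] < n_bout:  # pad with trailing quiet stance (rare)
            pad = n_bout - c_seg.shape[1]
            c_seg = np.pad(c_seg, ((0, 0), (0, pad)), mode="edge")
            t_seg = np.pad(t_seg, ((0, 0), (0, pad)), mode="edge")
        c_seg = c_seg[:, :n_bout].copy()
        t_seg = t_seg[:, :n_bout].copy()
        c_seg[AX_V] += 1.0 - np.mean(c_seg[AX_V])  # keep +1 g offset after trim
        start_s = cursor / fs
        events = [
            (start_s + fc, start_s + fo)
            for fc, fo in zip(contacts, foot_offs)
            if fo < dur_s - 1.0 / fs
        ]
        chest[:, cursor : cursor + n_bout] = c_seg
        thigh[:, cursor : cursor + n_bout] = t_seg
        bout_intervals.append((start_s, start_s + dur_s))
        gait_events.append(events)
        cursor += n_bout
        gap_n = int(rng.integers(1, 12)) * window_n
        fill(min(gap_n, total_n - cursor))

    n_windows = total_n // window_n
    labels = np.zeros(n_windows, dtype=int)
    for s, e in bout_intervals:
        w0 = int(round(s / WINDOW_S))
        w1 = int(round(e / WINDOW_S))
        labels[w0:w1] = 1

    gt = GroundTruth(bout_intervals=bout_intervals, gait_events=gait_events, window_labels=labels)
    gt.validate()
    rec_c = AccelRecording(profile.subject_id, "chest", fs, chest)
    rec_t = AccelRecording(profile.subject_id, "thigh_right", fs, thigh)
    return rec_c, rec_t, gt


def generate_lab_recording(profile: SubjectProfile, seed: int = 0, fs: float = 250.0,
                           duration_s: float = 60.0):
    """Simulate the one-minute hallway walk at the lab sampling rate.

    Returns (chest AccelRecording, thigh AccelRecording); the walk is one
    continuous bout trimmed to exactly ``duration_s``.
    """
    rng = np.random.default_rng(seed)
    n_strides = int(np.ceil(duration_s / (profile.stride_time_mean * 0.8))) + 2
    chest, thigh, _, _ = synth_walking_segment(profile, n_strides, fs=fs, seed=rng)
    n = int(round(duration_s * fs))
    if chest.shape[1] < n:
        pad = n - chest.shape[1]
        chest = np.pad(chest, ((0, 0), (0, pad)), mode="edge")
        thigh = np.pad(thigh, ((0, 0), (0, pad)), mode="edge")
    chest, thigh = chest[:, :n].copy(), thigh[:, :n].copy()
    chest[AX_V] += 1.0 - np.mean(chest[AX_V])
    return (
        AccelRecording(profile.subject_id, "chest", fs, chest),
        AccelRecording(profile.subject_id, "thigh_right", fs, thigh),
    )


# --- parameter-level fast path -------------------------------------------

#: representative stride counts per duration class (duration / stride time)
_CLASS_STRIDE_RANGE = {"short": (3, 7), "medium": (10, 24), "long": (28, 80), "lab": (45, 55)}
#: relative estimation noise of bout-level RMS AP / Freqd ML by class
_CLASS_EST_NOISE = {"short": 0.06, "medium": 0.04, "long": 0.025, "lab": 0.02}


def sample_bout_parameters(
    profile: SubjectProfile,
    n_bouts: int,
    duration_class: str = "short",
    rng=None,
) -> pd.DataFrame:
    """Draw bout-level gait-parameter estimates directly from a profile.

    Statistical shortcut for experiments that need many cohorts: per bout,
    stride times and duty factors are drawn exactly as the signal generator
    draws them and summarized exactly as the feature stage summarizes detected
    strides; signal-level features get the profile value plus class-dependent
    estimation noise.  A calibration test checks this path against the full
    signal pipeline.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    lo, hi = _CLASS_STRIDE_RANGE[duration_class]
    noise = _CLASS_EST_NOISE[duration_class]
    mu, cv, duty = profile.stride_time_mean, profile.stride_time_cv, profile.duty_factor_mean
    rows = []
    for b in range(n_bouts):
        n_str = int(rng.integers(lo, hi + 1))
        st = _truncated_normal(rng, mu, cv * mu, 0.5, 3.0, size=n_str)
        df = _truncated_normal(rng, duty, _DUTY_CV * duty, 0.46, 0.80, size=n_str)
        stance = df * st
        swing = st - stance
        row = {
            "stride_time_mean_s": st.mean(),
            "stance_time_mean_s": stance.mean(),
            "swing_time_mean_s": swing.mean(),
            "stride_time_cv": st.std(ddof=1) / st.mean(),
            "duty_factor_mean": df.mean(),
            "duty_factor_cv": df.std(ddof=1) / df.mean(),
            "rms_ap_g": profile.ap_amplitude * (1 + rng.normal(0, noise)),
            "freqd_ml_hz": profile.ml_bandwidth * (1 + rng.normal(0, noise)),
            "duration_class": duration_class,
            "n_strides": n_str,
        }
        if duration_class in ("long", "lab"):
            row["entropy_ratio"] = float(np.clip(rng.normal(2.5, 0.35), 0.5, None))
        if duration_class == "lab":
            row["ly_ap_per_s"] = abs(rng.normal(0.01, 0.004))
            row["ly_ml_per_s"] = abs(rng.normal(0.013, 0.004))
        rows.append(row)
    out = pd.DataFrame(rows)
    out.insert(0, "subject_id", profile.subject_id)
    return out


# --- on-disk dataset ------------------------------------------------------


def write_dataset(cohort, recordings, ground_truths, out_dir, lab_recordings=None) -> dict:
    """Write a cohort to disk: per-subject sensor CSVs, annotation JSONs, a
    cohort table, and a manifest.  Round-trips losslessly through
    :func:`msgait.io.read_recording` / :func:`msgait.io.read_annotations`.

    ``recordings`` maps subject_id -> (chest, thigh); ``ground_truths`` maps
    subject_id -> GroundTruth.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"subjects": {}, "cohort_table": "cohort.csv"}

    rows = []
    for prof in cohort:
        row = {
            "subject_id": prof.subject_id,
            "fall_label": prof.fall_label,
            "age": prof.age,
            "sex": prof.sex,
            "stride_time_mean": prof.stride_time_mean,
            "stride_time_cv": prof.stride_time_cv,
            "duty_factor_mean": prof.duty_factor_mean,
            "ap_amplitude": prof.ap_amplitude,
            "ml_bandwidth": prof.ml_bandwidth,
        }
        for f in SURVEY_FIELDS:
            row[f] = prof.surveys.get(f, float("nan"))
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / "cohort.csv", index=False)

    for prof in cohort:
        sid = prof.subject_id
        if sid not in recordings:
            continue
        chest, thigh = recordings[sid]
        files = {}
        for rec, tag in ((chest, "chest"), (thigh, "thigh")):
            fname = f"{sid}_{tag}.csv"
            t = np.arange(rec.n_samples) / rec.fs
            df = pd.DataFrame(
                {
                    "time_s": t,
                    "acc_v_g": rec.data[AX_V],
                    "acc_ml_g": rec.data[AX_ML],
                    "acc_ap_g": rec.data[AX_AP],
                }
            )
            df.to_csv(out_dir / fname, index=False, float_format="%.17g")
            files[tag] = fname
        gt = ground_truths[sid]
        ann = {
            "bouts": [
                {
                    "start_s": float(s),
                    "end_s": float(e),
                    "events": [[float(fc), float(fo)] for fc, fo in ev],
                }
                for (s, e), ev in zip(gt.bout_intervals, gt.gait_events)
            ],
            "windows": [int(w) for w in gt.window_labels],
        }
        fname = f"{sid}_annotations.json"
        (out_dir / fname).write_text(json.dumps(ann))
        files["annotations"] = fname
        if lab_recordings and sid in lab_recordings:
            for rec, tag in zip(lab_recordings[sid], ("lab_chest", "lab_thigh")):
                fname = f"{sid}_{tag}.csv"
                t = np.arange(rec.n_samples) / rec.fs
                pd.DataFrame(
                    {
                        "time_s": t,
                        "acc_v_g": rec.data[AX_V],
                        "acc_ml_g": rec.data[AX_ML],
                        "acc_ap_g": rec.data[AX_AP],
                    }
                ).to_csv(out_dir / fname, index=False, float_format="%.17g")
                files[tag] = fname
        manifest["subjects"][sid] = files

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
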