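"""Foot-contact / foot-off detection from thigh acceleration.

Architecture: cadence first, events second.  The stride and step frequencies
are estimated from an averaged periodogram of the mean-removed thigh AP
channel; a zero-phase filter bank centred on those frequencies then yields a
stride-band signal (used to gate one contact per stride cycle) and a
step-band signal (whose gated peaks are the foot contacts).  Foot offs are
the sharp swing-initiation troughs of a low-passed event signal inside each
contact-to-contact cycle.  Sub-sample timing comes from parabolic
interpolation around each discrete extremum.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .types import (
    AX_AP,
    CadenceEstimate,
    CadenceNotFoundError,
    MsgaitError,
    Stride,
)

#: stride-frequency search band, Hz.  0.4-1.3 Hz covers stride times of
#: roughly 0.77-2.5 s, i.e. the validated slow-to-fast walking range.
STRIDE_BAND_HZ = (0.4, 1.3)
#: peak power must exceed this multiple of the median in-band power
PEAK_TO_MEDIAN_MIN = 10.0
#: relative bandwidth of the bank filters
RELATIVE_BANDWIDTH = 0.20


def estimate_cadence(thigh_bout: np.ndarray, fs: float) -> CadenceEstimate:
    """Estimate stride and step frequency from the thigh AP periodogram.

    Averaged periodogram (10-s segments or the full bout if shorter, 50%
    overlap).  The stride frequency is the dominant peak in
    :data:`STRIDE_BAND_HZ`; the step frequency is the dominant peak within
    +/-20% of twice the stride frequency.  Raises
    :class:`CadenceNotFoundError` when no peak rises above the noise floor.
    """
    ap = np.asarray(thigh_bout)[AX_AP]
    ap = ap - ap.mean()
    if len(ap) < 4 * fs - 0.5:  # half-sample tolerance for inferred rates
        raise CadenceNotFoundError("bout shorter than 4 s")
    nperseg = min(int(10 * fs), len(ap))
    freqs, psd = sps.welch(ap, fs=fs, nperseg=nperseg, noverlap=nperseg // 2, detrend="constant")

    in_band = (freqs >= STRIDE_BAND_HZ[0]) & (freqs <= STRIDE_BAND_HZ[1])
    ref = (freqs >= 0.2) & (freqs <= fs / 2)
    floor = np.median(psd[ref])
    if not np.any(in_band) or floor <= 0:
        raise CadenceNotFoundError("no spectral content in the stride band")
    k = np.flatnonzero(in_band)[np.argmax(psd[in_band])]
    if psd[k] < PEAK_TO_MEDIAN_MIN * floor:
        raise CadenceNotFoundError("stride-band peak below the noise floor")
    # harmonic disambiguation: if half the dominant frequency also carries a
    # clear peak, the dominant peak was the step harmonic
    half = freqs[k] / 2.0
    if half >= 0.3:
        near_half = (freqs >= 0.85 * half) & (freqs <= 1.15 * half)
        if np.any(near_half):
            k_half = np.flatnonzero(near_half)[np.argmax(psd[near_half])]
            if psd[k_half] >= 0.10 * psd[k] and psd[k_half] >= PEAK_TO_MEDIAN_MIN * floor:
                k = k_half
    stride_freq = _refine_peak(freqs, psd, k)

    lo, hi = 0.8 * 2 * stride_freq, 1.2 * 2 * stride_freq
    step_band = (freqs >= lo) & (freqs <= min(hi, fs / 2))
    if not np.any(step_band):
        raise CadenceNotFoundError("step band empty")
    k2 = np.flatnonzero(step_band)[np.argmax(psd[step_band])]
    step_freq = _refine_peak(freqs, psd, k2)
    return CadenceEstimate(stride_freq=float(stride_freq), step_freq=float(step_freq),
                           psd_peak_power=float(psd[k]))


def _refine_peak(freqs, psd, k):
    """Parabolic refinement of a periodogram peak location."""
    if 0 < k < len(psd) - 1:
        y0, y1, y2 = psd[k - 1], psd[k], psd[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            return freqs[k] + np.clip(delta, -0.5, 0.5) * (freqs[1] - freqs[0])
    return freqs[k]


def _bandpass(x, fs, center, rel_bw=RELATIVE_BANDWIDTH, order=4):
    lo, hi = center * (1 - rel_bw), center * (1 + rel_bw)
    if not (0 < lo < hi < fs / 2):
        raise MsgaitError(f"filter band [{lo:.3f}, {hi:.3f}] Hz outside (0, {fs / 2}) Hz")
    sos = sps.butter(order, [lo, hi], btype="band", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def bank_filter(thigh_bout: np.ndarray, cadence: CadenceEstimate, fs: float):
    """Zero-phase band-passes centred at stride and step frequency."""
    ap = np.asarray(thigh_bout)[AX_AP]
    ap = ap - ap.mean()
    stride_sig = _bandpass(ap, fs, cadence.stride_freq)
    step_sig = _bandpass(ap, fs, cadence.step_freq)
    return stride_sig, step_sig


def _parabolic_vertex(y, i):
    if 0 < i < len(y) - 1:
        denom = y[i - 1] - 2 * y[i] + y[i + 1]
        if denom != 0:
            return i + np.clip(0.5 * (y[i - 1] - y[i + 1]) / denom, -0.5, 0.5)
    return float(i)


def detect_gait_events(thigh_bout: np.ndarray, fs: float, cadence: CadenceEstimate | None = None):
    """Detect strides in one bout.  Returns (list of Stride, CadenceEstimate).

    Cadence failure propagates as :class:`CadenceNotFoundError`; callers
    treat it (and <2 strides) as grounds for bout removal.
    """
    thigh_bout = np.asarray(thigh_bout)
    if cadence is None:
        cadence = estimate_cadence(thigh_bout, fs)
    stride_sig, step_sig = bank_filter(thigh_bout, cadence, fs)

    # event signal: low-passed AP with the two narrowband (harmonic)
    # components subtracted, which leaves the sharp impact / swing-initiation
    # transients and removes the harmonics' own extrema
    ap = thigh_bout[AX_AP] - thigh_bout[AX_AP].mean()
    cutoff = min(4.0 * cadence.step_freq, 0.45 * fs)
    sos = sps.butter(4, cutoff, btype="low", fs=fs, output="sos")
    event_sig = sps.sosfiltfilt(sos, ap) - stride_sig - step_sig

    # foot contacts: event-signal peaks in the positive (ipsilateral)
    # half-cycle of the stride-band signal, one per stride cycle (largest
    # peak wins, earliest on ties)
    cand, _ = sps.find_peaks(event_sig, distance=max(1, int(0.4 / cadence.step_freq * fs)))
    cand = cand[stride_sig[cand] > 0]
    min_dist = max(1, int(0.6 / cadence.stride_freq * fs))
    keep: list[int] = []
    for p in cand:
        if keep and p - keep[-1] < min_dist:
            if event_sig[p] > event_sig[keep[-1]]:
                keep[-1] = p
        else:
            keep.append(int(p))
    contacts = np.array([_parabolic_vertex(event_sig, p) for p in keep]) / fs

    if len(contacts) < 2:
        return [], cadence

    strides = []
    for c0, c1 in zip(contacts[:-1], contacts[1:]):
        d = c1 - c0
        i0 = int(np.ceil((c0 + 0.45 * d) * fs))
        i1 = int(np.floor((c0 + 0.82 * d) * fs))
        if i1 <= i0 or i1 >= len(event_sig):
            continue
        j = i0 + int(np.argmin(event_sig[i0 : i1 + 1]))
        fo = _parabolic_vertex(-event_sig, j) / fs
        s = Stride(foot_contact_s=float(c0), foot_off_s=float(fo), next_contact_s=float(c1))
        if s.is_ordered():
            strides.append(s)
    return strides, cadence


def detect_bout_events(bout, config=None):
    """Run detection on a WalkingBout in place; returns True when usable."""
    try:
        strides, cadence = detect_gait_events(bout.thigh_view, bout.fs)
    except CadenceNotFoundError:
        bout.strides, bout.cadence = [], None
        return False
    bout.strides, bout.cadence = strides, cadence
    return len(strides) >= 2


def filter_valid(bouts, validity_ranges: dict):
    """Drop invalid strides and under-populated bouts; log every count.

    Bout-level rule: fewer than two strides (before or after stride-level
    removal) removes the bout.  Stride-level rules come from
    ``validity_ranges`` (keys: stride_time_s, duty_factor, stance_time_s,
    swing_time_s).
    """
    log = {
        "n_bouts_before": len(bouts),
        "n_strides_before": int(sum(len(b.strides) for b in bouts)),
        "n_bouts_removed_lt2_strides": 0,
        "n_strides_removed_range": 0,
        "n_bouts_removed_after_stride_filter": 0,
    }
    retained = []
    for bout in bouts:
        if len(bout.strides) < 2:
            log["n_bouts_removed_lt2_strides"] += 1
            continue
        kept = []
        for s in bout.strides:
            values = {
                "stride_time_s": s.stride_time_s,
                "duty_factor": s.duty_factor,
                "stance_time_s": s.stance_time_s,
                "swing_time_s": s.swing_time_s,
            }
            ok = all(
                lo <= values[k] <= hi
                for k, (lo, hi) in validity_ranges.items()
                if k in values
            )
            if ok:
                kept.append(s)
            else:
                log["n_strides_removed_range"] += 1
        if len(kept) < 2:
            log["n_bouts_removed_after_stride_filter"] += 1
            continue
        bout.strides = kept
        retained.append(bout)
    log["n_bouts_after"] = len(retained)
    log["n_strides_after"] = int(sum(len(b.strides) for b in retained))
    log["n_bouts_removed"] = log["n_bouts_before"] - log["n_bouts_after"]
    return retained, log
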