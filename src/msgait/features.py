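"""Per-bout gait parameters: temporal statistics and signal-level stability.

Temporal parameters (stride/stance/swing time, duty factor, their CVs) come
from the detected strides; signal-level measures come from the mean-removed
chest and thigh acceleration:

* RMS AP — root mean square of the chest anterior-posterior channel (g);
* Freqd ML — PSD-weighted spectral standard deviation of the chest
  medial-lateral channel (Hz), a spread measure of lateral motion;
* entropy ratio — sample entropy (m=2, r=0.2*SD) of the thigh resultant
  acceleration divided by the chest's, for long bouts (>= 32 s);
* largest Lyapunov exponent — Rosenstein divergence-curve estimate on a
  chest channel (1/s), for the one-minute lab bouts.

Feature-vector arity is a function of the duration class alone: 8 features
for short/medium/all-home bouts, 9 for long (adds the entropy ratio), 11 for
lab (adds both Lyapunov exponents).
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .types import (
    AX_AP,
    AX_ML,
    InsufficientStridesError,
    UndefinedFeatureError,
)

FEATURES_BASE = [
    "stride_time_mean_s",
    "stance_time_mean_s",
    "swing_time_mean_s",
    "stride_time_cv",
    "duty_factor_mean",
    "duty_factor_cv",
    "rms_ap_g",
    "freqd_ml_hz",
]
FEATURES_BY_CLASS = {
    "short": FEATURES_BASE,
    "medium": FEATURES_BASE,
    "all_home": FEATURES_BASE,
    "long": FEATURES_BASE + ["entropy_ratio"],
    "lab": FEATURES_BASE + ["entropy_ratio", "ly_ap_per_s", "ly_ml_per_s"],
}


def temporal_parameters(strides) -> dict:
    """Bout means and CVs of the per-stride temporal parameters.

    CV = sample standard deviation (n-1 denominator) over the mean.
    """
    if len(strides) < 2:
        raise InsufficientStridesError("temporal parameters need >= 2 strides")
    st = np.array([s.stride_time_s for s in strides])
    stance = np.array([s.stance_time_s for s in strides])
    swing = np.array([s.swing_time_s for s in strides])
    duty = np.array([s.duty_factor for s in strides])
    return {
        "stride_time_mean_s": float(st.mean()),
        "stance_time_mean_s": float(stance.mean()),
        "swing_time_mean_s": float(swing.mean()),
        "stride_time_cv": float(st.std(ddof=1) / st.mean()),
        "duty_factor_mean": float(duty.mean()),
        "duty_factor_cv": float(duty.std(ddof=1) / duty.mean()),
    }


def rms_ap(chest_bout: np.ndarray, fs: float | None = None) -> float:
    """RMS of the mean-removed chest AP channel, in g."""
    ap = np.asarray(chest_bout)
    if ap.ndim == 2:
        ap = ap[AX_AP]
    if ap.size == 0:
        raise UndefinedFeatureError("empty channel")
    ap = ap - ap.mean()
    return float(np.sqrt(np.mean(ap**2)))


def freq_dispersion_ml(chest_bout: np.ndarray, fs: float) -> float:
    """PSD-weighted spectral standard deviation of the chest ML channel (Hz).

    sqrt( sum P(f) (f - fbar)^2 / sum P(f) ), fbar the PSD-weighted mean
    frequency, over (0, fs/2] of the mean-removed channel.
    """
    ml = np.asarray(chest_bout)
    if ml.ndim == 2:
        ml = ml[AX_ML]
    ml = ml - ml.mean()
    if not np.any(ml):
        raise UndefinedFeatureError("all-zero ML channel has no dispersion")
    nperseg = min(int(10 * fs), len(ml))
    freqs, psd = sps.welch(ml, fs=fs, nperseg=nperseg, noverlap=nperseg // 2, detrend="constant")
    sel = freqs > 0
    f, p = freqs[sel], psd[sel]
    total = p.sum()
    if total <= 0:
        raise UndefinedFeatureError("zero spectral power")
    fbar = float(np.sum(p * f) / total)
    return float(np.sqrt(np.sum(p * (f - fbar) ** 2) / total))


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy: -ln( A / B ) with template length m, tolerance r.

    A and B count pairs of m+1- and m-length templates within Chebyshev
    distance r (default 0.2 * SD of the series); self-matches excluded.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if r is None:
        r = 0.2 * x.std()
    if n <= m + 1 or r <= 0:
        raise UndefinedFeatureError("series too short or zero tolerance")

    def count(mm):
        templates = np.lib.stride_tricks.sliding_window_view(x, mm)
        total = 0
        for i in range(len(templates) - 1):
            d = np.max(np.abs(templates[i + 1 :] - templates[i]), axis=1)
            total += int(np.count_nonzero(d <= r))
        return total

    b = count(m)
    a = count(m + 1)
    if b == 0 or a == 0:
        raise UndefinedFeatureError("no template matches at this tolerance")
    return float(-np.log(a / b))


def _resultant(bout: np.ndarray) -> np.ndarray:
    mag = np.linalg.norm(np.asarray(bout, dtype=float), axis=0)
    return mag - mag.mean()


def entropy_ratio(thigh_bout: np.ndarray, chest_bout: np.ndarray,
                  max_samples: int = 2000) -> float:
    """Thigh over chest sample entropy of the resultant acceleration.

    Both series are truncated to ``max_samples`` (~64 s at 31.25 Hz) so the
    quadratic template search stays cheap on very long bouts; the truncation
    is applied identically to both sensors.
    """
    thigh = _resultant(thigh_bout)[:max_samples]
    chest = _resultant(chest_bout)[:max_samples]
    if thigh.shape != chest.shape:
        raise UndefinedFeatureError("thigh and chest bouts must have equal length")
    se_t = sample_entropy(thigh)
    se_c = sample_entropy(chest)
    if se_c == 0:
        raise UndefinedFeatureError("chest sample entropy is zero")
    return float(se_t / se_c)


def max_lyapunov(channel: np.ndarray, fs: float, stride_freq: float,
                 dim: int = 5) -> float:
    """Largest Lyapunov exponent via the divergence-curve method (1/s).

    Delay embedding of dimension ``dim``; the delay is the first minimum of
    the autocorrelation, capped at a quarter stride period.  Each embedded
    point's nearest neighbour (outside one stride period in time) seeds a
    divergence curve; the mean log divergence is fit over 0-0.5 stride
    periods and the slope reported per second.
    """
    x = np.asarray(channel, dtype=float)
    x = x - x.mean()
    stride_period = int(round(fs / stride_freq))
    # delay: first autocorrelation minimum, capped at 1/4 stride period
    max_lag = max(2, stride_period // 4)
    ac = np.correlate(x, x, mode="full")[len(x) - 1 : len(x) - 1 + max_lag + 2]
    delay = max_lag
    for lag in range(1, max_lag + 1):
        if ac[lag] >= ac[lag - 1]:  # autocorrelation stopped decreasing
            delay = max(1, lag - 1)
            break
    delay = max(1, min(delay, max_lag))

    n_emb = len(x) - (dim - 1) * delay
    if n_emb < 3 * stride_period:
        raise UndefinedFeatureError("too few embedded points for a Lyapunov fit")
    emb = np.stack([x[i * delay : i * delay + n_emb] for i in range(dim)], axis=1)

    horizon = max(2, stride_period // 2)
    usable = n_emb - horizon
    if usable < stride_period:
        raise UndefinedFeatureError("too few embedded points for a Lyapunov fit")
    pts = emb[:usable]
    # nearest neighbour with a Theiler window of one stride period
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=2)
    idx = np.arange(usable)
    theiler = np.abs(idx[:, None] - idx[None, :]) < stride_period
    d2[theiler] = np.inf
    nn = np.argmin(d2, axis=1)
    has_nn = np.isfinite(d2[idx, nn])
    i_idx, j_idx = idx[has_nn], nn[has_nn]
    if len(i_idx) == 0:
        raise UndefinedFeatureError("no valid nearest neighbours")

    eps = 1e-12
    log_div = np.empty((len(i_idx), horizon + 1))
    for k in range(horizon + 1):
        diff = emb[i_idx + k] - emb[j_idx + k]
        log_div[:, k] = np.log(np.linalg.norm(diff, axis=1) + eps)
    curve = log_div.mean(axis=0)
    t = np.arange(horizon + 1) / fs
    slope = float(np.polyfit(t, curve, 1)[0])
    return slope


def extract_bout_parameters(bout, duration_class: str, lyapunov_on_long: bool = False) -> dict:
    """Dispatch the feature computations for one retained bout.

    Returns a dict holding exactly the class's feature set (8/9/11 values)
    plus bookkeeping columns; raises if any component feature fails so that
    partial vectors are never emitted.
    """
    feats = dict(temporal_parameters(bout.strides))
    feats["rms_ap_g"] = rms_ap(bout.chest_view)
    feats["freqd_ml_hz"] = freq_dispersion_ml(bout.chest_view, bout.fs)
    if duration_class in ("long", "lab"):
        feats["entropy_ratio"] = entropy_ratio(bout.thigh_view, bout.chest_view)
    compute_ly = duration_class == "lab" or (lyapunov_on_long and duration_class == "long")
    if compute_ly:
        sf = bout.cadence.stride_freq if bout.cadence else 1.0 / feats["stride_time_mean_s"]
        feats["ly_ap_per_s"] = max_lyapunov(bout.chest_view[AX_AP], bout.fs, sf)
        feats["ly_ml_per_s"] = max_lyapunov(bout.chest_view[AX_ML], bout.fs, sf)
    expected = FEATURES_BY_CLASS[duration_class]
    missing = [f for f in expected if f not in feats]
    if missing:
        raise UndefinedFeatureError(f"missing features {missing}")
    out = {k: feats[k] for k in expected}
    out.update(
        subject_id=bout.subject_id,
        bout_id=bout.bout_id,
        context=bout.context,
        duration_class=duration_class,
        duration_s=bout.duration_s,
        n_strides=len(bout.strides),
    )
    return out
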