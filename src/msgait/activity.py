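"""Gait / non-gait window classification and walking-bout assembly.

Recordings are tiled into non-overlapping 4-s windows; each window stacks the
six acceleration channels (chest then thigh) and is labelled gait or
non-gait.  Two classifiers share one contract:

* a BiLSTM window classifier (215 hidden units, 40% dropout, Adam by
  default; reduced sizes are selectable for small experiments), trained on
  labelled synthetic windows;
* a deterministic spectral fallback that thresholds band power in the
  0.4-3 Hz gait band of the thigh AP channel — no training required.

Maximal runs of consecutive gait windows become walking bouts; a single
non-gait window separates bouts.
"""

from __future__ import annotations

import numpy as np

from .nn import SequenceClassifier
from .types import AccelRecording, InputError, TrainingError, WalkingBout

GAIT_BAND_HZ = (0.4, 3.0)


def window_signal(chest: AccelRecording, thigh: AccelRecording, window_s: float = 4.0):
    """Tile paired recordings into 6 x n windows (chest rows then thigh).

    Returns an array of shape (n_windows, 6, n_samples); a trailing partial
    window is dropped.  Recordings are trimmed to their common length.
    """
    if abs(chest.fs - thigh.fs) > 1e-9:
        raise InputError("chest and thigh recordings must share a sampling rate")
    fs = chest.fs
    n = min(chest.n_samples, thigh.n_samples)
    w = int(round(window_s * fs))
    n_windows = n // w
    if n_windows == 0:
        return np.empty((0, 6, w))
    stacked = np.vstack([chest.data[:, : n_windows * w], thigh.data[:, : n_windows * w]])
    return stacked.reshape(6, n_windows, w).transpose(1, 0, 2)


# --- deterministic spectral fallback -------------------------------------


class SpectralGaitDetector:
    """Gait detector from relative band power in the locomotor band.

    A window is gait when the 0.4-3 Hz band of the mean-removed thigh AP
    channel carries both (a) at least ``power_threshold`` g^2 of absolute
    band power and (b) more than half the total dynamic power.  The absolute
    floor rejects near-silent postural windows whose noise happens to sit in
    band.
    """

    def __init__(self, fs: float, power_threshold: float = 1e-3):
        self.fs = fs
        self.power_threshold = power_threshold

    def scores(self, windows: np.ndarray) -> np.ndarray:
        out = np.empty(len(windows))
        for i, win in enumerate(windows):
            ap = win[5] - win[5].mean()  # thigh AP channel
            n = len(ap)
            spec = np.abs(np.fft.rfft(ap)) ** 2 * 2.0 / n**2  # per-bin variance
            freqs = np.fft.rfftfreq(n, 1.0 / self.fs)
            band = (freqs >= GAIT_BAND_HZ[0]) & (freqs <= GAIT_BAND_HZ[1])
            band_var = float(spec[band].sum())
            total_var = float(spec[1:].sum())
            rel = band_var / total_var if total_var > 0 else 0.0
            out[i] = rel if band_var > self.power_threshold else 0.0
        return out

    def classify(self, windows: np.ndarray):
        scores = self.scores(windows)
        return (scores > 0.5).astype(int), scores


# --- learned classifier ---------------------------------------------------


class WindowClassifier:
    """BiLSTM gait/non-gait window classifier (thin wrap of SequenceClassifier)."""

    def __init__(self, bilstm_units: int = 215, dropout: float = 0.40, seed: int = 0, lr: float = 1e-2):
        self.model = SequenceClassifier(
            layers=[("lstm", bilstm_units, True), ("dropout", dropout)],
            n_features=6,
            seed=seed,
            lr=lr,
        )
        self.window_shape = None

    def fit(self, windows: np.ndarray, labels, epochs: int = 10, batch_size: int = 32):
        labels = np.asarray(labels, dtype=int)
        if len(np.unique(labels)) < 2:
            raise TrainingError("window training set holds a single class")
        self.window_shape = windows.shape[1:]
        seqs = [w.T for w in windows]  # (time, channels)
        self.model.fit(seqs, labels, epochs=epochs, batch_size=batch_size)
        return self

    def classify(self, windows: np.ndarray):
        if self.window_shape is not None and windows.shape[1:] != self.window_shape:
            raise InputError(
                f"window shape {windows.shape[1:]} does not match training shape {self.window_shape}"
            )
        scores = self.model.decision_scores([w.T for w in windows])
        return (scores > 0.5).astype(int), scores


def train_window_classifier(
    windows: np.ndarray,
    labels,
    bilstm_units: int = 215,
    dropout: float = 0.40,
    epochs: int = 10,
    seed: int = 0,
    holdout_fraction: float = 0.2,
):
    """Train the window classifier and report held-out accuracy.

    Returns ``(classifier, holdout_accuracy)``; the held-out split is seeded
    and stratification-free (labels are expected roughly balanced).
    """
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(windows))
    n_hold = max(1, int(round(holdout_fraction * len(windows))))
    hold, train = order[:n_hold], order[n_hold:]
    clf = WindowClassifier(bilstm_units=bilstm_units, dropout=dropout, seed=seed)
    clf.fit(windows[train], labels[train], epochs=epochs)
    pred, _ = clf.classify(windows[hold])
    acc = float(np.mean(pred == labels[hold]))
    return clf, acc


def classify_windows(classifier, windows: np.ndarray):
    """Label windows with either classifier behind the shared contract."""
    return classifier.classify(windows)


def assemble_bouts(window_labels, window_s: float = 4.0, subject_id: str = "", fs: float = 31.25):
    """Concatenate maximal runs of gait windows into WalkingBouts.

    One non-gait window splits bouts; bout durations are run length times the
    window length.
    """
    labels = np.asarray(window_labels, dtype=int)
    bouts = []
    start = None
    for i, lab in enumerate(np.append(labels, 0)):
        if lab == 1 and start is None:
            start = i
        elif lab != 1 and start is not None:
            bouts.append(
                WalkingBout(
                    bout_id=len(bouts),
                    subject_id=subject_id,
                    start_s=start * window_s,
                    end_s=i * window_s,
                    fs=fs,
                )
            )
            start = None
    return bouts


def attach_views(bouts, chest: AccelRecording, thigh: AccelRecording):
    """Slice the paired recordings into each bout (in place)."""
    for b in bouts:
        i0 = int(round(b.start_s * chest.fs))
        i1 = int(round(b.end_s * chest.fs))
        b.chest_view = chest.data[:, i0:i1]
        b.thigh_view = thigh.data[:, i0:i1]
        b.fs = chest.fs
    return bouts
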