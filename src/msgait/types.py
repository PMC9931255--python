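"""Core domain types for free-living gait analysis.

The pipeline operates on tri-axial acceleration from two body-worn sensors
(medial chest and right anterior thigh).  Axis order is fixed throughout as
``[vertical, medial-lateral, anterior-posterior]`` in units of g, with gravity
represented as a constant +1 g offset on the vertical channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

AXES = ("v", "ml", "ap")
#: row indices into the 3xT signal matrices
AX_V, AX_ML, AX_AP = 0, 1, 2

SURVEY_FIELDS = ("ABC", "EDSS", "MFIS", "MSWS", "NSI")


class MsgaitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MsgaitError):
    """A configuration value violates an invariant."""


class SchemaError(MsgaitError):
    """A file does not conform to the expected schema."""


class DataError(MsgaitError):
    """Input data violate a structural requirement (e.g. non-monotone time)."""


class DependencyError(MsgaitError):
    """A pipeline stage was requested without its upstream products."""


class CadenceNotFoundError(MsgaitError):
    """No cadence peak rises above the noise floor; the bout is invalid."""


class InsufficientStridesError(MsgaitError):
    """Fewer strides than the operation requires."""


class EmptySegmentError(MsgaitError):
    """A walking segment of zero strides was requested."""


class UndefinedFeatureError(MsgaitError):
    """A feature is undefined for this input (zero signal, zero entropy...)."""


class TrainingError(MsgaitError):
    """A classifier cannot be trained on the provided data."""


class InputError(MsgaitError):
    """Model input does not match the trained input shape."""


@dataclass
class AccelRecording:
    """One sensor's tri-axial acceleration stream.

    ``data`` is a 3xT float array in g, axes [vertical, ML, AP].
    """

    subject_id: str
    location: str  # "chest" | "thigh_right"
    fs: float
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != 3:
            raise DataError(f"expected 3xT data, got shape {self.data.shape}")
        if self.data.shape[1] == 0:
            raise DataError("empty recording")
        if not np.all(np.isfinite(self.data)):
            raise DataError("non-finite samples in recording")
        if self.fs <= 0:
            raise DataError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class SubjectProfile:
    """Ground-truth gait and survey parameters for one synthetic subject."""

    subject_id: str
    fall_label: str  # "faller" | "non_faller"
    stride_time_mean: float  # s
    stride_time_cv: float  # unitless fraction
    duty_factor_mean: float  # stance/stride, unitless
    ap_amplitude: float  # g, RMS of the chest AP channel during gait
    ml_bandwidth: float  # Hz, spectral width of chest ML motion
    surveys: dict = field(default_factory=dict)  # ABC/EDSS/MFIS/MSWS/NSI, may hold NaN
    age: float = 50.0
    sex: str = "F"

    def __post_init__(self) -> None:
        if not (0.5 <= self.stride_time_mean <= 3.0):
            raise ConfigurationError("stride_time_mean outside [0.5, 3.0] s")
        if self.stride_time_cv < 0:
            raise ConfigurationError("stride_time_cv must be >= 0")
        if not (0.5 < self.duty_factor_mean < 0.8):
            raise ConfigurationError("duty_factor_mean outside (0.5, 0.8)")
        if self.ap_amplitude <= 0:
            raise ConfigurationError("ap_amplitude must be positive")

    @property
    def is_faller(self) -> bool:
        return self.fall_label == "faller"


@dataclass
class GroundTruth:
    """Generator-side truth for one subject recording.

    bout_intervals: disjoint, sorted (start_s, end_s) pairs.
    gait_events: per bout, ordered list of (foot_contact_s, foot_off_s).
    window_labels: one 0/1 label per 4-s window (1 = gait).
    """

    bout_intervals: list
    gait_events: list
    window_labels: np.ndarray

    def validate(self) -> None:
        prev_end = -np.inf
        for (s, e), events in zip(self.bout_intervals, self.gait_events):
            if not s < e:
                raise DataError("empty bout interval")
            if s < prev_end:
                raise DataError("overlapping bout intervals")
            prev_end = e
            prev_fc = -np.inf
            for fc, fo in events:
                if not (s - 1e-9 <= fc < fo <= e + 1e-9):
                    raise DataError("event outside its bout")
                if fc <= prev_fc:
                    raise DataError("events out of order")
                prev_fc = fc


@dataclass
class Stride:
    """One detected stride: contact-to-contact of the instrumented limb."""

    foot_contact_s: float
    foot_off_s: float
    next_contact_s: float

    @property
    def stride_time_s(self) -> float:
        return self.next_contact_s - self.foot_contact_s

    @property
    def stance_time_s(self) -> float:
        return self.foot_off_s - self.foot_contact_s

    @property
    def swing_time_s(self) -> float:
        return self.next_contact_s - self.foot_off_s

    @property
    def duty_factor(self) -> float:
        return self.stance_time_s / self.stride_time_s

    def is_ordered(self) -> bool:
        return self.foot_contact_s < self.foot_off_s < self.next_contact_s


@dataclass
class CadenceEstimate:
    stride_freq: float  # Hz
    step_freq: float  # Hz
    psd_peak_power: float  # g^2/Hz


@dataclass
class WalkingBout:
    """A contiguous gait interval with paired chest+thigh signal views."""

    bout_id: int
    subject_id: str
    start_s: float
    end_s: float
    fs: float
    chest_view: Optional[np.ndarray] = None  # 3 x n
    thigh_view: Optional[np.ndarray] = None  # 3 x n
    strides: list = field(default_factory=list)
    cadence: Optional[CadenceEstimate] = None
    context: str = "home"  # "home" | "lab"

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s
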