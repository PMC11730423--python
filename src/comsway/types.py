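"""Core data containers shared across the package.

All quantities are SI internally (m, rad, s, N); millimetres and degrees
appear only at the reporting layer.  The body reference frame is X forward,
Y right, Z down, so a static accelerometer reads approximately (0, 0, -g).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

#: Standard gravity used throughout (m/s^2).
GRAVITY = 9.81


class ComswayError(Exception):
    """Base class for all package errors."""


class FormatError(ComswayError):
    """A file does not match the expected CSV dialect."""


class ConfigError(ComswayError):
    """Inconsistent trial configuration (duplicate placements, missing IMU...)."""


class SyncError(ComswayError):
    """Streams share no overlapping time window."""


class ParameterError(ComswayError):
    """A numeric parameter is outside its valid range."""


class WindowError(ComswayError):
    """A requested time window is too short or outside the record."""


class DegeneratePoseError(ComswayError):
    """Calibration poses are too close to parallel to define a frame."""


class StateError(ComswayError):
    """An operation was called on data in the wrong state (frame, grid, ...)."""


class UnloadedPlateError(ComswayError):
    """The force plate is (mostly) unloaded; CoP is undefined."""


class DegenerateTrialError(ComswayError):
    """Too few shear zero crossings for zero-point reconstruction."""


class UndefinedCorrelationError(ComswayError):
    """Pearson correlation undefined (zero variance input)."""


class Placement(str, Enum):
    """The six instrumented sites."""

    HEAD = "head"
    STERNUM = "sternum"
    BACK = "back"
    RIGHT_THIGH = "right_thigh"
    RIGHT_SHANK = "right_shank"
    LEFT_SHANK = "left_shank"


class Segment(str, Enum):
    """Modelled body segments of the kinematic chain (feet are ground-fixed)."""

    LEFT_SHANK = "left_shank"
    RIGHT_SHANK = "right_shank"
    LEFT_THIGH = "left_thigh"
    RIGHT_THIGH = "right_thigh"
    LOWER_TRUNK = "lower_trunk"
    UPPER_TRUNK = "upper_trunk"
    HEAD = "head"


#: Segment each placement is mounted on.
SEGMENT_OF_PLACEMENT: dict[Placement, Segment] = {
    Placement.HEAD: Segment.HEAD,
    Placement.STERNUM: Segment.UPPER_TRUNK,
    Placement.BACK: Segment.LOWER_TRUNK,
    Placement.RIGHT_THIGH: Segment.RIGHT_THIGH,
    Placement.RIGHT_SHANK: Segment.RIGHT_SHANK,
    Placement.LEFT_SHANK: Segment.LEFT_SHANK,
}


class Frame(str, Enum):
    SENSOR = "sensor"
    BODY = "body"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Stance(str, Enum):
    NARROW = "narrow"
    HIP = "hip"
    SHOULDER = "shoulder"


class Axis(str, Enum):
    """Horizontal sway axes: AP uses pitch angles, ML uses roll angles."""

    AP = "ap"
    ML = "ml"


@dataclass
class Participant:
    sex: Sex
    stature: float  # m
    mass: float  # kg

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        if not 1.2 <= self.stature <= 2.2:
            raise ParameterError(
                f"stature {self.stature} m outside plausible range [1.2, 2.2]"
            )
        if self.mass <= 0:
            raise ParameterError("mass must be positive")


def _check_time(time: np.ndarray, what: str) -> None:
    if time.ndim != 1 or time.size < 2:
        raise FormatError(f"{what}: time must be a 1-D array with >= 2 samples")
    if not np.all(np.diff(time) > 0):
        raise FormatError(f"{what}: time must be strictly increasing")


@dataclass
class ImuRecording:
    """One IMU stream: specific force (m/s^2) and angular rate (rad/s)."""

    placement: Placement
    time: np.ndarray
    accel: np.ndarray  # (n, 3) m/s^2
    gyro: np.ndarray  # (n, 3) rad/s
    frame: Frame = Frame.SENSOR
    rate: float | None = None

    def __post_init__(self) -> None:
        self.placement = Placement(self.placement)
        self.frame = Frame(self.frame)
        self.time = np.asarray(self.time, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        _check_time(self.time, f"IMU {self.placement.value}")
        n = self.time.size
        for name, arr in (("accel", self.accel), ("gyro", self.gyro)):
            if arr.shape != (n, 3):
                raise FormatError(
                    f"IMU {self.placement.value}: {name} must have shape ({n}, 3)"
                )

    @property
    def n_samples(self) -> int:
        return self.time.size

    def copy(self) -> "ImuRecording":
        return replace(
            self,
            time=self.time.copy(),
            accel=self.accel.copy(),
            gyro=self.gyro.copy(),
        )


@dataclass
class ForcePlateRecording:
    """Force-plate channels; Z-down convention so a loaded plate has Fz < 0."""

    time: np.ndarray
    force: np.ndarray  # (n, 3) N
    moment: np.ndarray  # (n, 3) N*m about the plate origin
    plate_origin_height: float = 0.0  # m
    rate: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.moment = np.asarray(self.moment, dtype=float)
        _check_time(self.time, "force plate")
        n = self.time.size
        for name, arr in (("force", self.force), ("moment", self.moment)):
            if arr.shape != (n, 3):
                raise FormatError(f"force plate: {name} must have shape ({n}, 3)")

    @property
    def n_samples(self) -> int:
        return self.time.size

    def copy(self) -> "ForcePlateRecording":
        return replace(
            self,
            time=self.time.copy(),
            force=self.force.copy(),
            moment=self.moment.copy(),
        )


@dataclass
class TrialBundle:
    """All synchronized streams and metadata for one quiet-stance trial."""

    imus: dict[Placement, ImuRecording]
    participant: Participant
    stance: Stance = Stance.NARROW
    forceplate: ForcePlateRecording | None = None
    rate: float | None = None

    def __post_init__(self) -> None:
        self.stance = Stance(self.stance)
        if not self.imus:
            raise ConfigError("a trial needs at least one IMU")
        for placement, rec in self.imus.items():
            if Placement(placement) != rec.placement:
                raise ConfigError(
                    f"placement key {placement} does not match recording "
                    f"{rec.placement.value}"
                )

    @property
    def placements(self) -> frozenset[Placement]:
        return frozenset(self.imus)


@dataclass
class DisplacementSeries:
    """Horizontal CoM (or CoP/marker) displacement along AP and ML."""

    time: np.ndarray
    ap: np.ndarray  # m
    ml: np.ndarray  # m
    source: str = "imu_model"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.ap = np.asarray(self.ap, dtype=float)
        self.ml = np.asarray(self.ml, dtype=float)
        if not (self.time.shape == self.ap.shape == self.ml.shape):
            raise FormatError("displacement series: time/ap/ml length mismatch")

    def axis(self, axis: Axis | str) -> np.ndarray:
        return self.ap if Axis(axis) is Axis.AP else self.ml

    def demeaned(self) -> "DisplacementSeries":
        return DisplacementSeries(
            time=self.time,
            ap=self.ap - np.mean(self.ap),
            ml=self.ml - np.mean(self.ml),
            source=self.source,
        )


@dataclass
class OrientationSeries:
    """Pitch/roll time series of one IMU (rad); positive = forward/rightward lean."""

    time: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray
    placement: Placement | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pitch = np.asarray(self.pitch, dtype=float)
        self.roll = np.asarray(self.roll, dtype=float)
        if not (self.time.shape == self.pitch.shape == self.roll.shape):
            raise FormatError("orientation series: length mismatch")

    def angle(self, axis: Axis | str) -> np.ndarray:
        """AP sway is driven by pitch, ML sway by roll."""
        return self.pitch if Axis(axis) is Axis.AP else self.roll


@dataclass
class ComboSpec:
    """Which IMUs feed the AP and the ML estimate; budget = |union|."""

    ap_placements: frozenset[Placement]
    ml_placements: frozenset[Placement]

    def __post_init__(self) -> None:
        self.ap_placements = frozenset(Placement(p) for p in self.ap_placements)
        self.ml_placements = frozenset(Placement(p) for p in self.ml_placements)
        if not self.ap_placements or not self.ml_placements:
            raise ConfigError("both AP and ML placement sets must be non-empty")

    @property
    def union(self) -> frozenset[Placement]:
        return self.ap_placements | self.ml_placements

    @property
    def budget(self) -> int:
        """Total number of unique IMUs the combination requires."""
        return len(self.union)
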