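"""Two-static-pose sensor-to-body calibration.

Each IMU is mounted in an arbitrary orientation.  Recording the mean specific
force in two static poses — upright, and with the segment pitched forward —
fixes a rotation from the sensor frame to the body frame (X forward, Y right,
Z down):

* the body Z axis is opposite the upright gravity reading,
* the approximate X axis is opposite the pitched-forward gravity reading,
* Y = normalize(Z x X'), then X = Y x Z (Gram-Schmidt: only the plane spanned
  by the pitched reading matters, not the exact pitch angle).

Convention (project-wide): ``v_body = R @ v_sensor`` with the body axes as
the *rows* of R.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .types import (
    GRAVITY,
    DegeneratePoseError,
    Frame,
    ImuRecording,
    Placement,
    StateError,
    WindowError,
)


@dataclass
class BodyRotation:
    """Orthonormal sensor-to-body rotation for one placement."""

    matrix: np.ndarray  # (3, 3), rows are the body axes in sensor coordinates
    placement: Placement | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("rotation matrix must be 3x3")
        if not np.allclose(self.matrix @ self.matrix.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(self.matrix), 1.0, atol=1e-8):
            raise ValueError("rotation matrix must have determinant +1")


def mean_specific_force(
    recording: ImuRecording, window: tuple[float, float]
) -> np.ndarray:
    """Arithmetic mean of the accelerometer over a static window (>= 1 s)."""
    t0, t1 = window
    if t1 - t0 < 1.0:
        raise WindowError(f"window [{t0}, {t1}] shorter than 1 s")
    if t0 < recording.time[0] - 1e-9 or t1 > recording.time[-1] + 1e-9:
        raise WindowError(f"window [{t0}, {t1}] outside the recording")
    mask = (recording.time >= t0) & (recording.time <= t1)
    if not np.any(mask):
        raise WindowError(f"window [{t0}, {t1}] contains no samples")
    return recording.accel[mask].mean(axis=0)


def mean_gyro(recording: ImuRecording, window: tuple[float, float]) -> np.ndarray:
    """Mean angular rate over a static window — the gyroscope bias estimate."""
    t0, t1 = window
    if t1 - t0 < 1.0:
        raise WindowError(f"window [{t0}, {t1}] shorter than 1 s")
    mask = (recording.time >= t0) & (recording.time <= t1)
    if not np.any(mask):
        raise WindowError(f"window [{t0}, {t1}] contains no samples")
    return recording.gyro[mask].mean(axis=0)


def two_pose_rotation(
    f_upright: np.ndarray,
    f_pitched: np.ndarray,
    placement: Placement | None = None,
) -> BodyRotation:
    """Sensor-to-body rotation from the two static specific-force readings."""
    f_upright = np.asarray(f_upright, dtype=float)
    f_pitched = np.asarray(f_pitched, dtype=float)
    for name, f in (("upright", f_upright), ("pitched", f_pitched)):
        mag = np.linalg.norm(f)
        if not 0.5 * GRAVITY <= mag <= 1.5 * GRAVITY:
            raise DegeneratePoseError(
                f"{name} pose |f| = {mag:.2f} m/s^2 outside [0.5 g, 1.5 g]"
            )
    z = -f_upright / np.linalg.norm(f_upright)
    x_approx = -f_pitched / np.linalg.norm(f_pitched)
    cos_angle = abs(float(np.dot(z, x_approx)))
    if cos_angle > np.cos(np.deg2rad(15.0)):
        raise DegeneratePoseError(
            "calibration poses are within 15 deg of parallel; "
            "the body X-Z plane is undefined"
        )
    y = np.cross(z, x_approx)
    y = y / np.linalg.norm(y)
    x = np.cross(y, z)
    return BodyRotation(matrix=np.vstack([x, y, z]), placement=placement)


def apply_rotation(recording: ImuRecording, rotation: BodyRotation) -> ImuRecording:
    """Rotate accel and gyro sample-wise into the body frame."""
    if recording.frame is Frame.BODY:
        raise StateError(
            f"IMU {recording.placement.value} is already in the body frame"
        )
    R = rotation.matrix
    return replace(
        recording,
        accel=recording.accel @ R.T,
        gyro=recording.gyro @ R.T,
        frame=Frame.BODY,
    )


def remove_gyro_bias(recording: ImuRecording, bias: np.ndarray) -> ImuRecording:
    """Subtract a constant gyroscope bias (estimated from a static window)."""
    return replace(recording, gyro=recording.gyro - np.asarray(bias, dtype=float))


def calibrate_recording(
    recording: ImuRecording,
    upright_window: tuple[float, float],
    pitched_window: tuple[float, float],
    subtract_gyro_bias: bool = True,
) -> tuple[ImuRecording, BodyRotation]:
    """Full calibration path: bias removal, pose averaging, rotation to body."""
    f_up = mean_specific_force(recording, upright_window)
    f_pitch = mean_specific_force(recording, pitched_window)
    rotation = two_pose_rotation(f_up, f_pitch, placement=recording.placement)
    if subtract_gyro_bias:
        recording = remove_gyro_bias(recording, mean_gyro(recording, upright_window))
    return apply_rotation(recording, rotation), rotation


def write_calibrations(path: str, rotations: dict[Placement, BodyRotation]) -> None:
    """Export calibrations as 9-number CSV rows keyed by placement."""
    lines = ["placement,r11,r12,r13,r21,r22,r23,r31,r32,r33"]
    for placement in sorted(rotations, key=lambda p: p.value):
        flat = ",".join(f"{v:.17g}" for v in rotations[placement].matrix.ravel())
        lines.append(f"{placement.value},{flat}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_calibrations(path: str) -> dict[Placement, BodyRotation]:
    out: dict[Placement, BodyRotation] = {}
    lines = Path(path).read_text().strip().splitlines()
    for line in lines[1:]:
        fields = line.split(",")
        placement = Placement(fields[0])
        matrix = np.array([float(v) for v in fields[1:10]]).reshape(3, 3)
        out[placement] = BodyRotation(matrix=matrix, placement=placement)
    return out
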