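"""Complementary-filter pitch/roll estimation for body-frame IMU streams.

The filter blends the gyroscope integral (accurate at high frequency, drifts
at low frequency) with the accelerometer inclination (noisy and contaminated
by linear acceleration, but drift-free)::

    theta_t = (1 - k) * (theta_{t-1} + omega_t * dt) + k * theta_accel_t

Per-step weight ``k = dt / (tau + dt)`` makes the accelerometer path a
first-order low-pass with time constant ``tau`` (default 1 s: quiet-stance
sway energy lives below ~2 Hz, so the accelerometer corrects drift without
passing much motion artefact).

Axis conventions (body frame X forward, Y right, Z down):

* pitch: positive = forward lean (X tilts toward Z); rate = ``-gyro_y``
  (a *positive* rotation about the rightward Y axis tips the body backward
  in a Z-down right-handed frame, hence the sign),
* roll: positive = rightward lean (Y tilts toward Z); rate = ``+gyro_x``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .types import (
    GRAVITY,
    Frame,
    ImuRecording,
    OrientationSeries,
    ParameterError,
    StateError,
)


@dataclass
class FilterParams:
    """Complementary-filter tuning.

    Either give the per-step accelerometer weight ``k`` directly or leave it
    None to derive it from ``tau`` (seconds) at the recording's sample rate.
    ``init_window`` seconds of accelerometer tilt are averaged to initialize
    the angle.  ``gate_accel``, off by default, holds the previous
    accelerometer angle whenever |f| leaves [0.5 g, 1.5 g].
    """

    k: float | None = None
    tau: float = 1.0
    init_window: float = 1.0
    gate_accel: bool = False

    def weight(self, dt: float) -> float:
        if self.k is not None:
            k = self.k
        else:
            if self.tau <= 0:
                raise ParameterError("tau must be positive")
            k = dt / (self.tau + dt)
        if not 0.0 < k < 1.0:
            raise ParameterError(f"accel weight k={k} must lie in (0, 1)")
        return k


def accel_tilt(f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inclination (pitch, roll) from a body-frame specific-force sample(s).

    ``pitch = atan2(-f_x, -f_z)``, ``roll = atan2(-f_y, -f_z)``: a static
    upright sensor reads (0, 0, -g) and maps to (0, 0).
    """
    f = np.asarray(f, dtype=float)
    pitch = np.arctan2(-f[..., 0], -f[..., 2])
    roll = np.arctan2(-f[..., 1], -f[..., 2])
    return pitch, roll


def accel_valid(f: np.ndarray) -> np.ndarray:
    """True where |f| lies inside the trustworthy band [0.5 g, 1.5 g]."""
    mag = np.linalg.norm(np.asarray(f, dtype=float), axis=-1)
    return (mag >= 0.5 * GRAVITY) & (mag <= 1.5 * GRAVITY)


def _forward_fill(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Replace invalid samples with the previous valid one."""
    if valid.all():
        return values
    idx = np.where(valid, np.arange(valid.size), 0)
    np.maximum.accumulate(idx, out=idx)
    out = values[idx]
    if not valid[0]:
        first = np.argmax(valid)
        out[: first] = values[first] if valid.any() else values[0]
    return out


def _uniform_dt(time: np.ndarray) -> float:
    dt = np.diff(time)
    if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise StateError(
            "complementary filter needs a uniform time base; resample first"
        )
    return float(dt[0])


def complementary_filter(
    recording: ImuRecording, params: FilterParams | None = None
) -> OrientationSeries:
    """Estimate pitch and roll of a body-frame IMU recording."""
    if recording.frame is not Frame.BODY:
        raise StateError(
            f"IMU {recording.placement.value} must be calibrated to the body "
            "frame before orientation estimation"
        )
    params = params or FilterParams()
    dt = _uniform_dt(recording.time)
    k = params.weight(dt)
    if recording.time[-1] - recording.time[0] <= params.init_window:
        raise StateError("recording shorter than the filter init window")

    pitch_acc, roll_acc = accel_tilt(recording.accel)
    if params.gate_accel:
        valid = accel_valid(recording.accel)
        pitch_acc = _forward_fill(pitch_acc, valid)
        roll_acc = _forward_fill(roll_acc, valid)

    n_init = max(1, int(round(params.init_window / dt)))
    rates = {
        "pitch": -recording.gyro[:, 1],
        "roll": recording.gyro[:, 0],
    }
    acc_angles = {"pitch": pitch_acc, "roll": roll_acc}
    out = {}
    for axis in ("pitch", "roll"):
        theta_acc = acc_angles[axis]
        theta0 = float(np.mean(theta_acc[:n_init]))
        # One-pole recursion y[n] = (1-k) y[n-1] + u[n] via lfilter.
        u = (1.0 - k) * rates[axis] * dt + k * theta_acc
        zi = np.array([(1.0 - k) * theta0])
        y, _ = lfilter([1.0], [1.0, -(1.0 - k)], u, zi=zi)
        out[axis] = y
    return OrientationSeries(
        time=recording.time,
        pitch=out["pitch"],
        roll=out["roll"],
        placement=recording.placement,
    )
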