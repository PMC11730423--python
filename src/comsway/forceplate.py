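"""Force-plate reference estimators of whole-body CoM displacement.

Two estimators are provided:

* :func:`zero_point_com` — zero-point-to-zero-point double integration.
  Whenever the horizontal shear force crosses zero, the horizontal CoM
  acceleration is zero and the CoM projection coincides with the CoP.
  Between consecutive crossings the shear is integrated twice
  (acceleration = shear / mass) with CoP boundary conditions pinning both
  ends, which determines the free initial velocity of each interval.  A
  final 10 Hz zero-phase low-pass removes the small discontinuities the
  piecewise solution leaves at the seams.

* :func:`lowpass_cop_com` — the simple alternative: the CoP is itself a
  low-pass-filtered image of the CoM, so filtering the CoP at a cutoff well
  below the plate's spectrum (default 0.5 Hz) approximates the CoM.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import butter_dualpass
from .types import (
    DegenerateTrialError,
    DisplacementSeries,
    ForcePlateRecording,
    ParameterError,
    UnloadedPlateError,
)

#: Vertical load below which the CoP is considered undefined (N).
MIN_LOAD_N = 50.0

#: Minimum spacing between kept zero crossings (samples); closer crossings
#: are noise chatter around zero shear and are merged.
MIN_CROSSING_GAP = 4


@dataclass
class CopSeries:
    """Centre of pressure (m): x = AP, y = ML; NaN where the plate is unloaded."""

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray


def compute_cop(fp: ForcePlateRecording) -> CopSeries:
    """CoP from plate forces and moments.

    With the Z-down convention and the moment reference a height ``z0``
    below the plate surface::

        CoP_x = (-M_y + F_x * z0) / (-F_z)
        CoP_y = ( M_x + F_y * z0) / (-F_z)

    Signs are fixed so a forward CoM lean yields positive CoP_x.
    """
    fz = fp.force[:, 2]
    loaded = np.abs(fz) > MIN_LOAD_N
    if np.mean(loaded) < 0.99:
        raise UnloadedPlateError(
            f"|Fz| <= {MIN_LOAD_N} N on {100 * (1 - np.mean(loaded)):.1f}% "
            "of samples; participant not on the plate"
        )
    z0 = fp.plate_origin_height
    with np.errstate(divide="ignore", invalid="ignore"):
        x = (-fp.moment[:, 1] + fp.force[:, 0] * z0) / (-fz)
        y = (fp.moment[:, 0] + fp.force[:, 1] * z0) / (-fz)
    x = np.where(loaded, x, np.nan)
    y = np.where(loaded, y, np.nan)
    return CopSeries(time=fp.time.copy(), x=x, y=y)


def _zero_crossings(acc: np.ndarray, time: np.ndarray) -> np.ndarray:
    """Sub-sample zero-crossing times of a sampled signal, chatter-merged."""
    s = np.sign(acc)
    # carry the previous sign through exact zeros so a touch-and-return
    # does not register twice
    for i in range(1, s.size):
        if s[i] == 0:
            s[i] = s[i - 1]
    idx = np.where(s[:-1] * s[1:] < 0)[0]
    if idx.size == 0:
        return np.empty(0)
    # linear sub-sample interpolation of the crossing instant
    frac = acc[idx] / (acc[idx] - acc[idx + 1])
    crossing_idx = idx + frac
    keep = [0]
    for i in range(1, crossing_idx.size):
        if crossing_idx[i] - crossing_idx[keep[-1]] >= MIN_CROSSING_GAP:
            keep.append(i)
    crossing_idx = crossing_idx[keep]
    dt = time[1] - time[0]
    return time[0] + crossing_idx * dt


def _double_integrals(acc: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact cumulative single and double integrals of piecewise-linear acc.

    V is the trapezoid cumulative integral (exact for linear segments); X
    uses the closed-form increment ``V_i*dt + (2 a_i + a_{i+1}) dt^2 / 6``,
    exact when acc is linear between samples.
    """
    v_inc = 0.5 * (acc[:-1] + acc[1:]) * dt
    V = np.concatenate([[0.0], np.cumsum(v_inc)])
    x_inc = V[:-1] * dt + (2.0 * acc[:-1] + acc[1:]) * dt * dt / 6.0
    X = np.concatenate([[0.0], np.cumsum(x_inc)])
    return V, X


def _eval_integrals(
    t: float,
    time: np.ndarray,
    acc: np.ndarray,
    V: np.ndarray,
    X: np.ndarray,
) -> tuple[float, float]:
    """V(t), X(t) at an arbitrary instant via the local linear-acc polynomial."""
    dt = time[1] - time[0]
    i = int(np.clip(np.floor((t - time[0]) / dt), 0, time.size - 2))
    tau = t - time[i]
    slope = (acc[i + 1] - acc[i]) / dt
    v = V[i] + acc[i] * tau + 0.5 * slope * tau * tau
    x = X[i] + V[i] * tau + 0.5 * acc[i] * tau * tau + slope * tau**3 / 6.0
    return v, x


def zero_point_com(
    cop: np.ndarray,
    shear: np.ndarray,
    mass: float,
    rate: float,
    time: np.ndarray | None = None,
    apply_filter: bool = True,
    filter_cutoff: float = 10.0,
) -> np.ndarray:
    """Zero-point-to-zero-point CoM reconstruction along one axis (m).

    Parameters
    ----------
    cop, shear
        CoP (m) and horizontal shear force (N) along the same axis, on a
        uniform grid.
    mass
        Participant mass (kg): CoM acceleration = shear / mass.
    rate
        Sample rate (Hz).
    apply_filter
        Apply the final 10 Hz dual-pass low-pass (disable to inspect the raw
        piecewise reconstruction, e.g. for boundary-condition checks).
    """
    cop = np.asarray(cop, dtype=float)
    shear = np.asarray(shear, dtype=float)
    if cop.shape != shear.shape or cop.ndim != 1:
        raise ParameterError("cop and shear must be 1-D arrays of equal length")
    if mass <= 0 or rate <= 0:
        raise ParameterError("mass and rate must be positive")
    n = cop.size
    dt = 1.0 / rate
    if time is None:
        time = np.arange(n) * dt
    if (n - 1) * dt < 10.0:
        raise DegenerateTrialError("trial shorter than 10 s")

    acc = shear / mass
    if np.all(acc == 0.0):
        # No horizontal dynamics at all: the CoM projection sits on the CoP.
        com = cop.copy()
        return butter_dualpass(com, filter_cutoff, 4, rate) if apply_filter else com

    t_cross = _zero_crossings(acc, time)
    if t_cross.size < 3:
        raise DegenerateTrialError(
            f"only {t_cross.size} shear zero crossings found (>= 3 required)"
        )

    V, X = _double_integrals(acc, dt)
    # CoP and integrals at the crossing instants.
    cop_c = np.interp(t_cross, time, cop)
    VX = np.array([_eval_integrals(t, time, acc, V, X) for t in t_cross])
    V_c, X_c = VX[:, 0], VX[:, 1]

    # Per-interval free initial velocity from the two-point boundary solve.
    span = np.diff(t_cross)
    v0 = (np.diff(cop_c) - (np.diff(X_c) - V_c[:-1] * span)) / span

    # Map every sample to its interval; samples before the first crossing use
    # the first interval's solution extended backward (velocity continuity),
    # samples after the last crossing use the last interval's.
    j = np.clip(np.searchsorted(t_cross, time) - 1, 0, v0.size - 1)
    rel = time - t_cross[j]
    com = cop_c[j] + v0[j] * rel + (X - X_c[j]) - V_c[j] * rel
    if apply_filter:
        com = butter_dualpass(com, filter_cutoff, 4, rate)
    return com


def zero_point_crossing_residuals(
    cop: np.ndarray,
    shear: np.ndarray,
    mass: float,
    rate: float,
) -> np.ndarray:
    """|CoM - CoP| at every detected crossing of the raw reconstruction."""
    cop = np.asarray(cop, dtype=float)
    shear = np.asarray(shear, dtype=float)
    n = cop.size
    dt = 1.0 / rate
    time = np.arange(n) * dt
    acc = shear / mass
    t_cross = _zero_crossings(acc, time)
    com = zero_point_com(cop, shear, mass, rate, apply_filter=False)
    # evaluate the piecewise solution exactly at the crossing instants
    V, X = _double_integrals(acc, dt)
    cop_c = np.interp(t_cross, time, cop)
    VX = np.array([_eval_integrals(t, time, acc, V, X) for t in t_cross])
    V_c, X_c = VX[:, 0], VX[:, 1]
    span = np.diff(t_cross)
    v0 = (np.diff(cop_c) - (np.diff(X_c) - V_c[:-1] * span)) / span
    res = []
    for k, t in enumerate(t_cross):
        j = min(max(k - 1, 0), v0.size - 1) if k == t_cross.size - 1 else min(k, v0.size - 1)
        rel = t - t_cross[j]
        v, x = _eval_integrals(t, time, acc, V, X)
        value = cop_c[j] + v0[j] * rel + (x - X_c[j]) - V_c[j] * rel
        res.append(abs(value - cop_c[k]))
    return np.asarray(res)


def zero_point_displacement(
    fp: ForcePlateRecording,
    mass: float,
    prefilter_cutoff: float = 10.0,
) -> DisplacementSeries:
    """Both-axis zero-point CoM estimate from a force-plate recording.

    Plate channels are low-pass filtered at 10 Hz (dual-pass Butterworth)
    before CoP computation and integration, mirroring the standard
    quiet-stance processing chain.
    """
    dt = np.diff(fp.time)
    rate = 1.0 / float(dt[0])
    fp_filtered = ForcePlateRecording(
        time=fp.time,
        force=butter_dualpass(fp.force, prefilter_cutoff, 4, rate),
        moment=butter_dualpass(fp.moment, prefilter_cutoff, 4, rate),
        plate_origin_height=fp.plate_origin_height,
        rate=rate,
    )
    cop = compute_cop(fp_filtered)
    ap = zero_point_com(cop.x, fp_filtered.force[:, 0], mass, rate, time=fp.time)
    ml = zero_point_com(cop.y, fp_filtered.force[:, 1], mass, rate, time=fp.time)
    return DisplacementSeries(
        time=fp.time.copy(), ap=ap, ml=ml, source="forceplate_zero_point"
    )


def lowpass_cop_com(
    cop: CopSeries, cutoff: float = 0.5, rate: float | None = None
) -> DisplacementSeries:
    """Low-pass-filtered CoP as a CoM estimate (demeaned)."""
    if cutoff >= 10.0:
        raise ParameterError("low-pass CoP cutoff must be below 10 Hz")
    if rate is None:
        rate = 1.0 / float(cop.time[1] - cop.time[0])
    ap = butter_dualpass(cop.x, cutoff, 4, rate)
    ml = butter_dualpass(cop.y, cutoff, 4, rate)
    return DisplacementSeries(
        time=cop.time.copy(),
        ap=ap - np.mean(ap),
        ml=ml - np.mean(ml),
        source="forceplate_lowpass_cop",
    )
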