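"""Reading, writing, synchronization and the shared zero-phase low-pass filter.

CSV dialects
------------
IMU files:         header ``time_s,ax,ay,az,gx,gy,gz`` (m/s^2, rad/s)
Force-plate files: header ``time_s,fx,fy,fz,mx,my,mz`` (N, N*m)

Trial configuration is a TOML file naming the stream files, placements,
participant and stance; see :func:`read_trial_config`.
"""
from __future__ import annotations

import math
import os
import tomllib
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .types import (
    ConfigError,
    ForcePlateRecording,
    FormatError,
    Frame,
    ImuRecording,
    ParameterError,
    Participant,
    Placement,
    Stance,
    SyncError,
    TrialBundle,
)

IMU_COLUMNS = ["time_s", "ax", "ay", "az", "gx", "gy", "gz"]
FP_COLUMNS = ["time_s", "fx", "fy", "fz", "mx", "my", "mz"]

_FLOAT_FMT = "%.17g"  # lossless round-trip for float64


def _read_csv(path: str | os.PathLike, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in columns:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    counts = df.columns.value_counts()
    dupes = [c for c in columns if counts.get(c, 0) > 1]
    if dupes:
        raise FormatError(f"{path}: duplicate column '{dupes[0]}'")
    return df[columns]


def read_imu_csv(path: str | os.PathLike, placement: Placement,
                 frame: Frame = Frame.SENSOR) -> ImuRecording:
    df = _read_csv(path, IMU_COLUMNS)
    return ImuRecording(
        placement=placement,
        time=df["time_s"].to_numpy(float),
        accel=df[["ax", "ay", "az"]].to_numpy(float),
        gyro=df[["gx", "gy", "gz"]].to_numpy(float),
        frame=frame,
    )


def write_imu_csv(path: str | os.PathLike, rec: ImuRecording) -> None:
    df = pd.DataFrame(
        np.column_stack([rec.time, rec.accel, rec.gyro]), columns=IMU_COLUMNS
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_forceplate_csv(path: str | os.PathLike,
                        plate_origin_height: float = 0.0) -> ForcePlateRecording:
    df = _read_csv(path, FP_COLUMNS)
    return ForcePlateRecording(
        time=df["time_s"].to_numpy(float),
        force=df[["fx", "fy", "fz"]].to_numpy(float),
        moment=df[["mx", "my", "mz"]].to_numpy(float),
        plate_origin_height=plate_origin_height,
    )


def write_forceplate_csv(path: str | os.PathLike, rec: ForcePlateRecording) -> None:
    df = pd.DataFrame(
        np.column_stack([rec.time, rec.force, rec.moment]), columns=FP_COLUMNS
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trial(
    imu_paths: Mapping[Placement | str, str | os.PathLike],
    fp_path: str | os.PathLike | None,
    participant: Participant,
    stance: Stance = Stance.NARROW,
    frame: Frame = Frame.SENSOR,
    plate_origin_height: float = 0.0,
) -> TrialBundle:
    """Load one trial from per-stream CSV files (unsynchronized)."""
    imus: dict[Placement, ImuRecording] = {}
    for placement, path in imu_paths.items():
        placement = Placement(placement)
        if placement in imus:
            raise ConfigError(f"duplicate placement '{placement.value}'")
        imus[placement] = read_imu_csv(path, placement, frame=frame)
    fp = None
    if fp_path is not None:
        fp = read_forceplate_csv(fp_path, plate_origin_height=plate_origin_height)
    return TrialBundle(imus=imus, participant=participant, stance=stance,
                       forceplate=fp)


def write_trial(out_dir: str | os.PathLike, bundle: TrialBundle) -> dict[str, str]:
    """Write all streams of a bundle as CSVs; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for placement, rec in sorted(bundle.imus.items(), key=lambda kv: kv[0].value):
        p = out / f"imu_{placement.value}.csv"
        write_imu_csv(p, rec)
        paths[placement.value] = str(p)
    if bundle.forceplate is not None:
        p = out / "forceplate.csv"
        write_forceplate_csv(p, bundle.forceplate)
        paths["forceplate"] = str(p)
    return paths


def read_trial_config(path: str | os.PathLike) -> dict:
    """Parse a trial TOML config.

    Schema::

        rate = 250.0
        stance = "narrow"          # narrow | hip | shoulder
        frame = "body"             # sensor | body
        [participant]
        sex = "male"
        stature = 1.74
        mass = 74.0
        [imu.back]
        path = "imu_back.csv"
        [imu.back.calibration]     # optional, sensor-frame trials only
        upright = [0.0, 5.0]
        pitched = [6.0, 11.0]
        [forceplate]               # optional
        path = "forceplate.csv"
        origin_height = 0.0
    """
    path = Path(path)
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    try:
        participant = Participant(
            sex=raw["participant"]["sex"],
            stature=float(raw["participant"]["stature"]),
            mass=float(raw["participant"]["mass"]),
        )
    except KeyError as exc:
        raise ConfigError(f"{path}: missing participant field {exc}") from exc
    imus = raw.get("imu", {})
    if not imus:
        raise ConfigError(f"{path}: no [imu.*] sections")
    base = path.parent
    imu_entries = {}
    for name, entry in imus.items():
        placement = Placement(name)
        if "path" not in entry:
            raise ConfigError(f"{path}: [imu.{name}] missing 'path'")
        imu_entries[placement] = {
            "path": str((base / entry["path"])),
            "calibration": entry.get("calibration"),
        }
    fp_entry = raw.get("forceplate")
    if fp_entry is not None:
        fp_entry = {
            "path": str(base / fp_entry["path"]),
            "origin_height": float(fp_entry.get("origin_height", 0.0)),
        }
    return {
        "participant": participant,
        "stance": Stance(raw.get("stance", "narrow")),
        "frame": Frame(raw.get("frame", "sensor")),
        "rate": float(raw.get("rate", 250.0)),
        "imus": imu_entries,
        "forceplate": fp_entry,
    }


def load_trial(config_path: str | os.PathLike) -> tuple[TrialBundle, dict]:
    """Read a trial config and all the streams it names."""
    cfg = read_trial_config(config_path)
    imu_paths = {p: e["path"] for p, e in cfg["imus"].items()}
    fp_path = cfg["forceplate"]["path"] if cfg["forceplate"] else None
    origin_h = cfg["forceplate"]["origin_height"] if cfg["forceplate"] else 0.0
    bundle = read_trial(
        imu_paths, fp_path, cfg["participant"], stance=cfg["stance"],
        frame=cfg["frame"], plate_origin_height=origin_h,
    )
    return bundle, cfg


# ---------------------------------------------------------------------------
# Resampling / synchronization
# ---------------------------------------------------------------------------

def _common_grid(starts: list[float], ends: list[float], rate: float) -> np.ndarray:
    t0 = max(starts)
    t1 = min(ends)
    if t1 - t0 < 1.0:
        raise SyncError(
            f"streams overlap for only {max(t1 - t0, 0.0):.3f} s (< 1 s)"
        )
    n = int(math.floor((t1 - t0) * rate + 1e-9)) + 1
    return t0 + np.arange(n) / rate


def _interp_columns(t_new: np.ndarray, t: np.ndarray, arr: np.ndarray) -> np.ndarray:
    out = np.empty((t_new.size, arr.shape[1]))
    for j in range(arr.shape[1]):
        out[:, j] = np.interp(t_new, t, arr[:, j])
    return out


def resample_sync(bundle: TrialBundle, rate: float) -> TrialBundle:
    """Linearly interpolate every stream onto one uniform grid at `rate`.

    The grid spans the overlap of all streams; no extrapolation occurs.
    """
    if rate <= 0:
        raise ParameterError("rate must be positive")
    starts = [rec.time[0] for rec in bundle.imus.values()]
    ends = [rec.time[-1] for rec in bundle.imus.values()]
    if bundle.forceplate is not None:
        starts.append(bundle.forceplate.time[0])
        ends.append(bundle.forceplate.time[-1])
    grid = _common_grid(starts, ends, rate)

    imus = {}
    for placement, rec in bundle.imus.items():
        imus[placement] = ImuRecording(
            placement=placement,
            time=grid.copy(),
            accel=_interp_columns(grid, rec.time, rec.accel),
            gyro=_interp_columns(grid, rec.time, rec.gyro),
            frame=rec.frame,
            rate=rate,
        )
    fp = None
    if bundle.forceplate is not None:
        old = bundle.forceplate
        fp = ForcePlateRecording(
            time=grid.copy(),
            force=_interp_columns(grid, old.time, old.force),
            moment=_interp_columns(grid, old.time, old.moment),
            plate_origin_height=old.plate_origin_height,
            rate=rate,
        )
    return TrialBundle(
        imus=imus,
        participant=bundle.participant,
        stance=bundle.stance,
        forceplate=fp,
        rate=rate,
    )


# ---------------------------------------------------------------------------
# Zero-phase Butterworth low-pass
# ---------------------------------------------------------------------------

def butter_dualpass(
    series: np.ndarray,
    cutoff: float = 10.0,
    order: int = 4,
    rate: float = 250.0,
) -> np.ndarray:
    """Dual-pass (forward-backward, zero-phase) Butterworth low-pass.

    A 4th-order design applied in both directions: the magnitude response is
    squared (two cascaded -3 dB points at `cutoff`, so a unit sinusoid at the
    cutoff emerges at amplitude ~0.5) and the phase response cancels.
    Reflective padding avoids start-up transients; its length scales with the
    filter's settling time (at least one cutoff period).
    """
    series = np.asarray(series, dtype=float)
    nyq = rate / 2.0
    if not 0 < cutoff < nyq:
        raise ParameterError(
            f"cutoff {cutoff} Hz must lie in (0, Nyquist={nyq} Hz)"
        )
    n = series.shape[-1] if series.ndim == 1 else series.shape[0]
    if n <= 3 * order:
        raise ParameterError("series too short for the requested filter order")
    sos = butter(order, cutoff / nyq, btype="low", output="sos")
    padlen = min(n - 1, max(3 * order, int(math.ceil(rate / cutoff))))
    if series.ndim == 1:
        return sosfiltfilt(sos, series, padtype="even", padlen=padlen)
    return sosfiltfilt(sos, series, axis=0, padtype="even", padlen=padlen)
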