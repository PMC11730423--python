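"""Seeded generator of physically consistent quiet-stance trials.

The generator emulates the measurement triangle the estimation pipeline is
validated against: ground-truth segment angles drive (a) body-frame IMU
streams (gyroscope = exact body angular rate + bias + noise; accelerometer
= specific force at the mount point including the linear acceleration of
the mount), (b) force-plate channels built from the inverted-pendulum
zero-moment relation (CoP = CoM - (H/g) * CoM_accel, shear = m * CoM_accel),
and (c) the ground-truth whole-body CoM plus a lumbar-point displacement
that stands in for a low-back motion-capture marker.

Angle trajectories are band-limited Gaussian processes: white noise is
brick-wall band-limited to [f_lo, f_hi] (default 0.05-1.5 Hz) with a
second-order low-pass amplitude shaping (knee 0.35 Hz) inside the band —
quiet-stance sway concentrates its power below ~0.5 Hz — then scaled to the
target amplitude.  All segments share a common lean per axis; the left and
right leg differ only by small independent jitter; the ML trunk-stack angle
is ``c * leg_angle + independent`` so negative ``c`` plants upper/lower-body
counter-rotation.

Default amplitudes are expressed as target whole-body CoM RMS per stance
(narrow AP 4.86 / ML 4.21 mm; hip 4.33 / 2.04; shoulder 4.11 / 1.69 —
published human quiet-stance values) and converted to lean angles through
the participant's own CoM height; an explicit per-axis angle RMS (deg)
overrides this.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .anthropometry import Anthropometry, anthropometry_for, TRUNK_STACK
from .types import (
    GRAVITY,
    Axis,
    DisplacementSeries,
    ForcePlateRecording,
    Frame,
    ImuRecording,
    ParameterError,
    Participant,
    Placement,
    Segment,
    SEGMENT_OF_PLACEMENT,
    Sex,
    Stance,
    TrialBundle,
)

#: Per-stance target whole-body CoM RMS (mm): (AP, ML).
STANCE_SWAY_RMS_MM: dict[Stance, tuple[float, float]] = {
    Stance.NARROW: (4.86, 4.21),
    Stance.HIP: (4.33, 2.04),
    Stance.SHOULDER: (4.11, 1.69),
}

#: Per-stance default ML trunk/leg coupling: counter-rotation grows with
#: stance width (negative = trunk opposes the legs).
STANCE_COUNTER_ROTATION: dict[Stance, float] = {
    Stance.NARROW: 0.6,
    Stance.HIP: 0.0,
    Stance.SHOULDER: -0.5,
}

#: Relative weight of each segment's independent angle jitter.  Independent
#: motion grows up the chain: the legs move nearly as rigid links while the
#: upper trunk flexes and the head is actively stabilized in space, which
#: decouples it from trunk sway.
SEGMENT_JITTER_WEIGHT: dict[Segment, float] = {
    Segment.LEFT_SHANK: 1.0,
    Segment.RIGHT_SHANK: 1.0,
    Segment.LEFT_THIGH: 1.0,
    Segment.RIGHT_THIGH: 1.0,
    Segment.LOWER_TRUNK: 1.0,
    Segment.UPPER_TRUNK: 1.5,
    Segment.HEAD: 2.5,
}

#: IMU mount points: (segment, fraction along segment from its distal joint).
MOUNT_POINTS: dict[Placement, tuple[Segment, float]] = {
    Placement.HEAD: (Segment.HEAD, 0.75),
    Placement.STERNUM: (Segment.UPPER_TRUNK, 0.85),
    Placement.BACK: (Segment.LOWER_TRUNK, 0.50),
    Placement.RIGHT_THIGH: (Segment.RIGHT_THIGH, 0.29),
    Placement.RIGHT_SHANK: (Segment.RIGHT_SHANK, 0.49),
    Placement.LEFT_SHANK: (Segment.LEFT_SHANK, 0.49),
}


@dataclass
class SimConfig:
    """Study conditions for one synthetic trial."""

    duration: float = 120.0  # s
    rate: float = 250.0  # Hz
    stance: Stance = Stance.NARROW
    participant: Participant = field(
        default_factory=lambda: Participant(Sex.MALE, 1.74, 74.0)
    )
    band: tuple[float, float] = (0.05, 1.5)  # Hz
    spectral_knee_hz: float = 0.35
    ap_angle_rms_deg: float | None = None  # None -> derive from stance table
    ml_angle_rms_deg: float | None = None
    counter_rotation: float | None = None  # None -> stance default
    trunk_indep_frac: float = 1.0  # ML trunk independent component, rel. legs
    head_coupling: float = 0.6  # head-in-space stabilization attenuates head
    # rotation relative to its supporting trunk (vestibulocollic reflex)
    jitter_frac: float = 0.1  # per-segment angle jitter, rel. common mode
    amplitude_factor: float = 1.0  # participant-level sway scale
    sternum_wobble_deg: float = 0.5  # respiratory/soft-tissue mount wobble, RMS
    accel_noise: float = 0.05  # m/s^2, white, per axis
    gyro_noise: float = 0.02  # rad/s, white, per axis
    gyro_bias_sd: float = 0.01  # rad/s, constant per IMU axis
    fp_force_noise: float = 0.1  # N
    fp_moment_noise: float = 0.05  # N*m
    seed: int = 0

    def __post_init__(self) -> None:
        self.stance = Stance(self.stance)
        f_lo, f_hi = self.band
        if not 0 < f_lo < f_hi < self.rate / 2:
            raise ParameterError("band must satisfy 0 < f_lo < f_hi < rate/2")
        if self.duration * self.rate < 1000:
            raise ParameterError("duration * rate must be >= 1000 samples")
        if self.counter_rotation is not None and not -1 <= self.counter_rotation <= 1:
            raise ParameterError("counter_rotation must lie in [-1, 1]")

    @property
    def effective_counter_rotation(self) -> float:
        if self.counter_rotation is not None:
            return self.counter_rotation
        return STANCE_COUNTER_ROTATION[self.stance]


@dataclass
class SyntheticTrial:
    """A trial bundle plus its ground truth."""

    bundle: TrialBundle
    truth_angles: dict[Axis, dict[Segment, np.ndarray]]
    truth_com: DisplacementSeries
    lumbar: DisplacementSeries
    config: SimConfig
    anthropometry: Anthropometry


# ---------------------------------------------------------------------------
# Band-limited noise
# ---------------------------------------------------------------------------

def band_limited_noise(
    n: int,
    rate: float,
    band: tuple[float, float],
    rng: np.random.Generator,
    knee_hz: float | None = 0.35,
) -> np.ndarray:
    """Unit-RMS Gaussian noise confined to ``band``, low-pass shaped in-band."""
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    spectrum = np.fft.rfft(rng.standard_normal(n))
    mask = (freqs >= band[0]) & (freqs <= band[1])
    shape = mask.astype(float)
    if knee_hz is not None and knee_hz > 0:
        shape = shape / (1.0 + (freqs / knee_hz) ** 2)
    series = np.fft.irfft(spectrum * shape, n)
    rms = np.sqrt(np.mean(series**2))
    if rms == 0:
        raise ParameterError("band too narrow for the record length")
    return series / rms


# ---------------------------------------------------------------------------
# Ground-truth angles and forward kinematics
# ---------------------------------------------------------------------------

def generate_angle_trajectories(
    config: SimConfig,
    anthro: Anthropometry | None = None,
    rng: np.random.Generator | None = None,
) -> dict[Axis, dict[Segment, np.ndarray]]:
    """Per-segment, per-axis ground-truth angle series (rad)."""
    anthro = anthro or anthropometry_for(config.participant)
    rng = rng or np.random.default_rng(config.seed)
    n = int(round(config.duration * config.rate))
    noise = lambda: band_limited_noise(  # noqa: E731
        n, config.rate, config.band, rng, config.spectral_knee_hz
    )
    c = config.effective_counter_rotation
    jit = config.jitter_frac

    angles: dict[Axis, dict[Segment, np.ndarray]] = {}

    # AP: one whole-body lean shared by every segment, plus small jitter.
    # The head is partially stabilized in space, so it follows its support
    # with attenuated gain and extra independent motion.
    common_ap = noise()
    angles[Axis.AP] = {}
    for seg in Segment:
        gain = config.head_coupling if seg is Segment.HEAD else 1.0
        angles[Axis.AP][seg] = gain * common_ap + jit * SEGMENT_JITTER_WEIGHT[
            seg
        ] * noise()
    # ML: legs share a common lean; the trunk stack is coupled to it by c
    # plus an independent component.
    common_leg = noise()
    trunk_ml = c * common_leg + config.trunk_indep_frac * noise()
    angles[Axis.ML] = {}
    for seg in Segment:
        base = trunk_ml if seg in TRUNK_STACK else common_leg
        gain = config.head_coupling if seg is Segment.HEAD else 1.0
        angles[Axis.ML][seg] = gain * base + jit * SEGMENT_JITTER_WEIGHT[
            seg
        ] * noise()

    # Scale each axis so the ground-truth whole-body CoM RMS matches the
    # target amplitude.  The unit-RMS draws are first brought into the
    # milliradian regime (where sin is linear to ~1e-5 relative) before the
    # forward-kinematic amplitude is measured, so one rescale suffices;
    # truth is recomputed from the final angles downstream.
    provisional = 0.005  # rad
    for axis, override_deg, col in (
        (Axis.AP, config.ap_angle_rms_deg, 0),
        (Axis.ML, config.ml_angle_rms_deg, 1),
    ):
        if override_deg is not None:
            common = common_ap if axis is Axis.AP else common_leg
            target_rad = math.radians(override_deg) * config.amplitude_factor
            scale = target_rad / np.sqrt(np.mean(common**2))
        else:
            target_mm = STANCE_SWAY_RMS_MM[config.stance][col]
            target_m = config.amplitude_factor * target_mm / 1000.0
            for seg in Segment:
                angles[axis][seg] = angles[axis][seg] * provisional
            com = _forward_kinematics_com(angles[axis], anthro)
            com = com - np.mean(com)
            scale = target_m / np.sqrt(np.mean(com**2))
        for seg in Segment:
            angles[axis][seg] = angles[axis][seg] * scale
    return angles


def _forward_kinematics_com(
    axis_angles: dict[Segment, np.ndarray], anthro: Anthropometry
) -> np.ndarray:
    """Whole-body CoM by explicit joint positions (independent of the
    telescoped per-segment formulation in :mod:`comsway.model`)."""
    seg = anthro.segments
    sin = {s: np.sin(axis_angles[s]) for s in Segment}
    # joint positions, ground up
    knee = {
        "left": seg[Segment.LEFT_SHANK].length * sin[Segment.LEFT_SHANK],
        "right": seg[Segment.RIGHT_SHANK].length * sin[Segment.RIGHT_SHANK],
    }
    hip = {
        "left": knee["left"] + seg[Segment.LEFT_THIGH].length * sin[Segment.LEFT_THIGH],
        "right": knee["right"]
        + seg[Segment.RIGHT_THIGH].length * sin[Segment.RIGHT_THIGH],
    }
    hip_mid = 0.5 * (hip["left"] + hip["right"])
    trunk_top = hip_mid + seg[Segment.LOWER_TRUNK].length * sin[Segment.LOWER_TRUNK]
    shoulder = trunk_top + seg[Segment.UPPER_TRUNK].length * sin[Segment.UPPER_TRUNK]
    com_pos = {
        Segment.LEFT_SHANK: seg[Segment.LEFT_SHANK].com_height
        * sin[Segment.LEFT_SHANK],
        Segment.RIGHT_SHANK: seg[Segment.RIGHT_SHANK].com_height
        * sin[Segment.RIGHT_SHANK],
        Segment.LEFT_THIGH: knee["left"]
        + seg[Segment.LEFT_THIGH].com_height * sin[Segment.LEFT_THIGH],
        Segment.RIGHT_THIGH: knee["right"]
        + seg[Segment.RIGHT_THIGH].com_height * sin[Segment.RIGHT_THIGH],
        Segment.LOWER_TRUNK: hip_mid
        + seg[Segment.LOWER_TRUNK].com_height * sin[Segment.LOWER_TRUNK],
        Segment.UPPER_TRUNK: trunk_top
        + seg[Segment.UPPER_TRUNK].com_height * sin[Segment.UPPER_TRUNK],
        Segment.HEAD: shoulder + seg[Segment.HEAD].com_height * sin[Segment.HEAD],
    }
    total = np.zeros_like(hip_mid)
    for segment, pos in com_pos.items():
        total += seg[segment].mass_fraction * pos
    return total


def truth_com(
    angles: dict[Axis, dict[Segment, np.ndarray]],
    anthro: Anthropometry,
    time: np.ndarray,
) -> tuple[DisplacementSeries, DisplacementSeries]:
    """(whole-body CoM, lumbar-point displacement) from ground-truth angles.

    The lumbar point is the back-IMU mount on the lower trunk; its linear
    displacement stands in for a low-back motion-capture marker.
    """
    com = DisplacementSeries(
        time=time,
        ap=_forward_kinematics_com(angles[Axis.AP], anthro),
        ml=_forward_kinematics_com(angles[Axis.ML], anthro),
        source="truth",
    )
    lumbar_xy, _ = _mount_trajectory(angles, anthro, Placement.BACK)
    lumbar = DisplacementSeries(
        time=time,
        ap=lumbar_xy[Axis.AP],
        ml=lumbar_xy[Axis.ML],
        source="lumbar_point",
    )
    return com, lumbar


def _chain_below(segment: Segment) -> list[Segment]:
    """Segments whose full length translates a point on `segment`."""
    if segment in (Segment.LEFT_SHANK, Segment.RIGHT_SHANK):
        return []
    if segment is Segment.LEFT_THIGH:
        return [Segment.LEFT_SHANK]
    if segment is Segment.RIGHT_THIGH:
        return [Segment.RIGHT_SHANK]
    stack = {
        Segment.LOWER_TRUNK: [],
        Segment.UPPER_TRUNK: [Segment.LOWER_TRUNK],
        Segment.HEAD: [Segment.LOWER_TRUNK, Segment.UPPER_TRUNK],
    }
    return stack[segment]


def _mount_trajectory(
    angles: dict[Axis, dict[Segment, np.ndarray]],
    anthro: Anthropometry,
    placement: Placement,
) -> tuple[dict[Axis, np.ndarray], np.ndarray]:
    """Horizontal (per-axis) and vertical position of an IMU mount point."""
    segment, fraction = MOUNT_POINTS[placement]
    seg = anthro.segments
    d = fraction * seg[segment].length
    trunk_mounted = segment in TRUNK_STACK
    horizontal: dict[Axis, np.ndarray] = {}
    pitch_all = angles[Axis.AP]
    roll_all = angles[Axis.ML]
    for axis in Axis:
        ax_angles = angles[axis]
        x = d * np.sin(ax_angles[segment])
        for below in _chain_below(segment):
            x = x + seg[below].length * np.sin(ax_angles[below])
        if trunk_mounted:
            # hip translation averaged over both legs
            hip = 0.5 * (
                seg[Segment.LEFT_SHANK].length * np.sin(ax_angles[Segment.LEFT_SHANK])
                + seg[Segment.LEFT_THIGH].length * np.sin(ax_angles[Segment.LEFT_THIGH])
                + seg[Segment.RIGHT_SHANK].length
                * np.sin(ax_angles[Segment.RIGHT_SHANK])
                + seg[Segment.RIGHT_THIGH].length
                * np.sin(ax_angles[Segment.RIGHT_THIGH])
            )
            x = x + hip
        horizontal[axis] = x
    # vertical position (Z down, relative to the ankle): -sum l cos(pitch)cos(roll)
    z = -d * np.cos(pitch_all[segment]) * np.cos(roll_all[segment])
    for below in _chain_below(segment):
        z = z - seg[below].length * np.cos(pitch_all[below]) * np.cos(roll_all[below])
    if trunk_mounted:
        z_hip = np.zeros_like(z)
        for shank, thigh in (
            (Segment.LEFT_SHANK, Segment.LEFT_THIGH),
            (Segment.RIGHT_SHANK, Segment.RIGHT_THIGH),
        ):
            for s in (shank, thigh):
                z_hip = z_hip - 0.5 * seg[s].length * np.cos(pitch_all[s]) * np.cos(
                    roll_all[s]
                )
        z = z + z_hip
    return horizontal, z


# ---------------------------------------------------------------------------
# IMU synthesis
# ---------------------------------------------------------------------------

def _central_diff(x: np.ndarray, dt: float) -> np.ndarray:
    return np.gradient(x, dt, edge_order=2)


def _segment_rotation(pitch: np.ndarray, roll: np.ndarray) -> np.ndarray:
    """World-from-body rotation R = Ry(-pitch) @ Rx(roll), per sample.

    Body frame X forward, Y right, Z down; positive pitch = forward lean,
    positive roll = rightward lean.  Returns shape (n, 3, 3).
    """
    ct, st = np.cos(pitch), np.sin(pitch)
    cf, sf = np.cos(roll), np.sin(roll)
    n = pitch.size
    R = np.empty((n, 3, 3))
    # Ry(-t) = [[ct,0,-st],[0,1,0],[st,0,ct]]; Rx(f) = [[1,0,0],[0,cf,-sf],[0,sf,cf]]
    R[:, 0, 0] = ct
    R[:, 0, 1] = -st * sf
    R[:, 0, 2] = -st * cf
    R[:, 1, 0] = 0.0
    R[:, 1, 1] = cf
    R[:, 1, 2] = -sf
    R[:, 2, 0] = st
    R[:, 2, 1] = ct * sf
    R[:, 2, 2] = ct * cf
    return R


def _body_angular_rate(
    pitch: np.ndarray, roll: np.ndarray, dt: float
) -> np.ndarray:
    """Exact body-frame angular velocity of R = Ry(-pitch) Rx(roll).

    omega = (roll_rate, -pitch_rate * cos(roll), pitch_rate * sin(roll)).
    """
    dp = _central_diff(pitch, dt)
    dr = _central_diff(roll, dt)
    return np.column_stack([dr, -dp * np.cos(roll), dp * np.sin(roll)])


def synthesize_imu(
    angles: dict[Axis, dict[Segment, np.ndarray]],
    placement: Placement,
    anthro: Anthropometry,
    config: SimConfig,
    rng: np.random.Generator,
    time: np.ndarray,
    mount_rotation: np.ndarray | None = None,
) -> ImuRecording:
    """Body-frame (or, with a mounting rotation, sensor-frame) IMU stream."""
    segment = SEGMENT_OF_PLACEMENT[placement]
    if MOUNT_POINTS[placement][0] != segment:
        raise ParameterError(f"{placement.value} has no mount point defined")
    dt = 1.0 / config.rate
    pitch = angles[Axis.AP][segment]
    roll = angles[Axis.ML][segment]
    if placement is Placement.STERNUM and config.sternum_wobble_deg > 0:
        # Respiration and chest-wall soft tissue rock a sternum-mounted IMU
        # relative to the thorax; an L3 back mount is nearly free of this.
        # The wobble rotates the sensor without displacing the body, so it
        # perturbs the measured orientation only, never the ground truth.
        amp = math.radians(config.sternum_wobble_deg)
        n = pitch.size
        wob_band = (0.15, 0.45)  # breathing-rate band, Hz
        pitch = pitch + amp * band_limited_noise(
            n, config.rate, wob_band, rng, knee_hz=None
        )
        roll = roll + amp * band_limited_noise(
            n, config.rate, wob_band, rng, knee_hz=None
        )
    horizontal, z = _mount_trajectory(angles, anthro, placement)

    # world-frame mount acceleration (Z down)
    ax = _central_diff(_central_diff(horizontal[Axis.AP], dt), dt)
    ay = _central_diff(_central_diff(horizontal[Axis.ML], dt), dt)
    az = _central_diff(_central_diff(z, dt), dt)
    a_world = np.column_stack([ax, ay, az])
    f_world = a_world - np.array([0.0, 0.0, GRAVITY])  # specific force

    R = _segment_rotation(pitch, roll)  # world <- body
    accel = np.einsum("nij,nj->ni", R.transpose(0, 2, 1), f_world)
    gyro = _body_angular_rate(pitch, roll, dt)

    bias = rng.normal(0.0, config.gyro_bias_sd, size=3)
    accel = accel + rng.normal(0.0, config.accel_noise, size=accel.shape)
    gyro = gyro + bias + rng.normal(0.0, config.gyro_noise, size=gyro.shape)

    frame = Frame.BODY
    if mount_rotation is not None:
        # sensor reading = R_mount^T applied? v_body = R @ v_sensor, so
        # v_sensor = R^T v_body with R the mounting (sensor-to-body) rotation.
        Rm = np.asarray(mount_rotation, dtype=float)
        accel = accel @ Rm
        gyro = gyro @ Rm
        frame = Frame.SENSOR
    return ImuRecording(
        placement=placement,
        time=time,
        accel=accel,
        gyro=gyro,
        frame=frame,
        rate=config.rate,
    )


def synthesize_calibration_poses(
    mount_rotation: np.ndarray, pitch_angle_deg: float = 90.0
) -> tuple[np.ndarray, np.ndarray]:
    """Sensor-frame mean specific forces of the two static calibration poses.

    The upright pose reads gravity along body -Z; the pitched pose tips the
    segment forward by ``pitch_angle_deg`` so gravity acquires a -X
    component.  ``mount_rotation`` is the sensor-to-body rotation the
    calibration should recover (v_body = R v_sensor).
    """
    theta = math.radians(pitch_angle_deg)
    f_up_body = np.array([0.0, 0.0, -GRAVITY])
    f_pitch_body = np.array(
        [-GRAVITY * math.sin(theta), 0.0, -GRAVITY * math.cos(theta)]
    )
    Rm = np.asarray(mount_rotation, dtype=float)
    return f_up_body @ Rm, f_pitch_body @ Rm


# ---------------------------------------------------------------------------
# Force-plate synthesis
# ---------------------------------------------------------------------------

def synthesize_forceplate(
    com: DisplacementSeries,
    anthro: Anthropometry,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> ForcePlateRecording:
    """Plate channels consistent with a CoM trajectory.

    Horizontal shear = m * CoM acceleration; Fz = -m g (vertical dynamics
    neglected); the CoP follows the zero-moment inverted-pendulum relation
    CoP = CoM - (H/g) * CoM_accel with H the static CoM height; moments are
    built so :func:`comsway.forceplate.compute_cop` returns exactly that CoP.
    """
    dt = float(com.time[1] - com.time[0])
    mass = anthro.total_mass
    H = anthro.com_height_above_floor
    acc = {ax: _central_diff(_central_diff(com.axis(ax), dt), dt) for ax in Axis}
    n = com.time.size
    fx = mass * acc[Axis.AP]
    fy = mass * acc[Axis.ML]
    fz = np.full(n, -mass * GRAVITY)
    cop_x = com.ap - (H / GRAVITY) * acc[Axis.AP]
    cop_y = com.ml - (H / GRAVITY) * acc[Axis.ML]
    # invert the CoP formula (plate origin height taken as zero)
    my = cop_x * fz
    mx = cop_y * (-fz)
    mz = np.zeros(n)
    force = np.column_stack([fx, fy, fz])
    moment = np.column_stack([mx, my, mz])
    if rng is not None:
        force = force + rng.normal(0.0, config.fp_force_noise, size=force.shape)
        moment = moment + rng.normal(0.0, config.fp_moment_noise, size=moment.shape)
    return ForcePlateRecording(
        time=com.time.copy(), force=force, moment=moment,
        plate_origin_height=0.0, rate=config.rate,
    )


# ---------------------------------------------------------------------------
# Trial assembly
# ---------------------------------------------------------------------------

def make_trial(
    config: SimConfig,
    placements: tuple[Placement, ...] = tuple(Placement),
    noise: bool = True,
    mount_rotations: dict[Placement, np.ndarray] | None = None,
) -> SyntheticTrial:
    """Assemble a complete seeded synthetic trial.

    With ``noise=False`` all sensor noise, gyro bias and plate noise are
    suppressed (the angle trajectories themselves are unchanged), which
    isolates algorithmic error from measurement error.
    """
    cfg = config if noise else replace(
        config,
        accel_noise=0.0,
        gyro_noise=0.0,
        gyro_bias_sd=0.0,
        fp_force_noise=0.0,
        fp_moment_noise=0.0,
        sternum_wobble_deg=0.0,
    )
    rng = np.random.default_rng(cfg.seed)
    anthro = anthropometry_for(cfg.participant)
    n = int(round(cfg.duration * cfg.rate))
    time = np.arange(n) / cfg.rate
    angles = generate_angle_trajectories(cfg, anthro, rng)
    com, lumbar = truth_com(angles, anthro, time)
    imus = {}
    for placement in placements:
        rot = None if mount_rotations is None else mount_rotations.get(placement)
        imus[placement] = synthesize_imu(
            angles, placement, anthro, cfg, rng, time, mount_rotation=rot
        )
    fp = synthesize_forceplate(com, anthro, cfg, rng if noise else None)
    bundle = TrialBundle(
        imus=imus,
        participant=cfg.participant,
        stance=cfg.stance,
        forceplate=fp,
        rate=cfg.rate,
    )
    return SyntheticTrial(
        bundle=bundle,
        truth_angles=angles,
        truth_com=com,
        lumbar=lumbar,
        config=cfg,
        anthropometry=anthro,
    )


def _antithetic_factors(
    n: int, rel_sd: float, rng: np.random.Generator, clip: float = 0.8
) -> np.ndarray:
    """Multiplicative scatter factors with cohort mean exactly 1.

    Drawn in antithetic pairs (1 + d, 1 - d) with |d| <= clip, so any
    even-sized cohort is balanced around the population mean while keeping
    the marginal spread ``rel_sd``.
    """
    half = (n + 1) // 2
    d = np.clip(np.abs(rng.normal(0.0, rel_sd, size=half)), 0.0, clip)
    factors = np.empty(2 * half)
    factors[0::2] = 1.0 + d
    factors[1::2] = 1.0 - d
    return factors[:n]


def make_cohort(
    n_participants: int = 16,
    base_config: SimConfig | None = None,
    seed: int = 0,
    amplitude_rel_sd: float = 0.43,
    stature_sd: float = 0.12,
) -> list[SyntheticTrial]:
    """A balanced virtual cohort: one trial per virtual participant.

    Participants alternate sex; stature and sway amplitude scatter are drawn
    antithetically so the cohort mean sits on the population values (mean
    stature 1.74 m; amplitude scatter relative SD 0.43 matching published
    narrow-stance between-participant spread).
    """
    base = base_config or SimConfig()
    rng = np.random.default_rng(seed)
    amp = _antithetic_factors(n_participants, amplitude_rel_sd, rng)
    stat_d = _antithetic_factors(n_participants, stature_sd / 1.74, rng, clip=0.15)
    trial_seeds = rng.integers(0, 2**31 - 1, size=n_participants)
    trials = []
    for i in range(n_participants):
        participant = Participant(
            sex=Sex.MALE if i % 2 == 0 else Sex.FEMALE,
            stature=float(np.clip(1.74 * stat_d[i], 1.5, 2.0)),
            mass=float(np.clip(74.0 * stat_d[i] ** 2, 45.0, 110.0)),
        )
        cfg = replace(
            base,
            participant=participant,
            amplitude_factor=base.amplitude_factor * float(amp[i]),
            seed=int(trial_seeds[i]),
        )
        trials.append(make_trial(cfg))
    return trials
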