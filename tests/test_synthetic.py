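import numpy as np
import pytest

from comsway.anthropometry import anthropometry_for
from comsway.calibration import two_pose_rotation
from comsway.evaluation import pearson_r
from comsway.forceplate import compute_cop
from comsway.io import load_trial
from comsway.model import com_from_angles, SegmentAngles, estimate_com
from comsway.orientation import accel_tilt
from comsway.pipeline import write_synthetic_trial
from comsway.simulate import (
    SimConfig,
    _forward_kinematics_com,
    band_limited_noise,
    generate_angle_trajectories,
    make_cohort,
    make_trial,
    synthesize_calibration_poses,
    synthesize_forceplate,
    synthesize_imu,
)
from comsway.types import (
    Axis,
    ComboSpec,
    Placement,
    Segment,
    SEGMENT_OF_PLACEMENT,
)


def _static_angles(n, pitch=0.0, roll=0.0):
    return {
        Axis.AP: {s: np.full(n, pitch) for s in Segment},
        Axis.ML: {s: np.full(n, roll) for s in Segment},
    }


class TestAngleGeneration:
    def test_same_seed_reproduces_bitwise(self):
        a = make_trial(SimConfig(seed=7, duration=10.0))
        b = make_trial(SimConfig(seed=7, duration=10.0))
        assert np.array_equal(a.truth_com.ap, b.truth_com.ap)
        for p in Placement:
            assert np.array_equal(
                a.bundle.imus[p].accel, b.bundle.imus[p].accel
            )
            assert np.array_equal(a.bundle.imus[p].gyro, b.bundle.imus[p].gyro)
        assert np.array_equal(
            a.bundle.forceplate.moment, b.bundle.forceplate.moment
        )

    def test_spectral_mass_confined_to_band(self, rng):
        rate, n = 250.0, 30000
        x = band_limited_noise(n, rate, (0.05, 1.5), rng)
        spec = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(n, 1 / rate)
        outside = spec[(freqs < 0.05) | (freqs > 1.5)].sum()
        assert outside / spec.sum() < 0.05

    def test_amplitude_linearity_in_angle_rms(self):
        cfgs = [
            SimConfig(seed=5, duration=20.0, ap_angle_rms_deg=a,
                      ml_angle_rms_deg=a)
            for a in (0.2, 0.4)
        ]
        trials = [make_trial(c, noise=False) for c in cfgs]
        r = np.std(trials[1].truth_com.ap) / np.std(trials[0].truth_com.ap)
        assert r == pytest.approx(2.0, rel=0.01)

    def test_default_narrow_cohort_matches_human_sway_scale(self):
        # small cohort version; the full 16-trial check is in acceptance
        trials = make_cohort(6, SimConfig(duration=30.0), seed=3)
        rms = [np.std(t.truth_com.ap) * 1e3 for t in trials]
        assert np.mean(rms) == pytest.approx(4.86, abs=1.0)


class TestTruthCom:
    def test_zero_angles_zero_everywhere(self):
        cfg = SimConfig(seed=1, duration=10.0)
        anthro = anthropometry_for(cfg.participant)
        angles = _static_angles(100)[Axis.AP]
        assert np.allclose(_forward_kinematics_com(angles, anthro), 0.0)

    def test_dual_path_equivalence_with_chain_model(self, rng):
        cfg = SimConfig(seed=9, duration=10.0)
        anthro = anthropometry_for(cfg.participant)
        angles = generate_angle_trajectories(cfg, anthro,
                                             np.random.default_rng(9))
        for axis in Axis:
            fk = _forward_kinematics_com(angles[axis], anthro)
            chain = com_from_angles(
                SegmentAngles(axis=axis, angles=angles[axis]), anthro
            )
            assert np.max(np.abs(fk - chain)) < 1e-12

    def test_uniform_angle_is_equivalent_pendulum(self):
        cfg = SimConfig(seed=1, duration=10.0)
        anthro = anthropometry_for(cfg.participant)
        theta = 0.02
        angles = {s: np.full(5, theta) for s in Segment}
        com = _forward_kinematics_com(angles, anthro)
        assert np.allclose(
            com, anthro.effective_com_height * np.sin(theta), atol=1e-15
        )


class TestSynthesizeImu:
    def _static_imu(self, placement, pitch=0.0, roll=0.0):
        cfg = SimConfig(seed=1, duration=10.0)
        anthro = anthropometry_for(cfg.participant)
        n = int(cfg.duration * cfg.rate)
        time = np.arange(n) / cfg.rate
        rng = np.random.default_rng(0)
        angles = _static_angles(n, pitch, roll)
        cfg_clean = SimConfig(
            seed=1, duration=10.0, accel_noise=0.0, gyro_noise=0.0,
            gyro_bias_sd=0.0, sternum_wobble_deg=0.0,
        )
        return synthesize_imu(angles, placement, anthro, cfg_clean, rng, time)

    @pytest.mark.parametrize("placement", [Placement.BACK, Placement.LEFT_SHANK])
    def test_static_single_axis_tilt_recovered_exactly(self, placement):
        rec = self._static_imu(placement, pitch=0.05)
        p, r = accel_tilt(rec.accel[rec.time.size // 2])
        assert p == pytest.approx(0.05, abs=1e-10)
        assert r == pytest.approx(0.0, abs=1e-10)
        rec = self._static_imu(placement, roll=-0.03)
        p, r = accel_tilt(rec.accel[rec.time.size // 2])
        assert r == pytest.approx(-0.03, abs=1e-10)
        assert p == pytest.approx(0.0, abs=1e-10)

    def test_static_combined_tilt_second_order_accurate(self):
        rec = self._static_imu(Placement.BACK, pitch=0.05, roll=0.04)
        p, r = accel_tilt(rec.accel[100])
        # combined tilts couple at second order: error ~ pitch*roll^2/2
        assert p == pytest.approx(0.05, abs=1e-4)
        assert r == pytest.approx(0.04, abs=1e-4)

    def test_gyro_matches_angle_derivative(self):
        cfg = SimConfig(seed=4, duration=10.0, accel_noise=0.0,
                        gyro_noise=0.0, gyro_bias_sd=0.0)
        anthro = anthropometry_for(cfg.participant)
        rng = np.random.default_rng(4)
        angles = generate_angle_trajectories(cfg, anthro, rng)
        n = int(cfg.duration * cfg.rate)
        time = np.arange(n) / cfg.rate
        rec = synthesize_imu(angles, Placement.BACK, anthro, cfg, rng, time)
        seg = SEGMENT_OF_PLACEMENT[Placement.BACK]
        dp = np.gradient(angles[Axis.AP][seg], 1 / cfg.rate, edge_order=2)
        # small-angle: pitch rate = -gyro_y
        assert np.allclose(-rec.gyro[:, 1], dp, atol=1e-5)

    def test_mounting_rotation_recovered_by_calibration(self):
        a = np.deg2rad(20.0)
        mount = np.array(
            [[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]]
        )
        f_up, f_pitch = synthesize_calibration_poses(mount)
        rot = two_pose_rotation(f_up, f_pitch)
        assert np.allclose(rot.matrix, mount, atol=1e-8)


class TestSynthesizeForceplate:
    def test_static_com_gives_static_plate(self):
        cfg = SimConfig(seed=1, duration=10.0)
        anthro = anthropometry_for(cfg.participant)
        n = int(cfg.duration * cfg.rate)
        from comsway.types import DisplacementSeries

        com = DisplacementSeries(
            time=np.arange(n) / cfg.rate,
            ap=np.full(n, 0.01),
            ml=np.full(n, -0.005),
            source="truth",
        )
        fp = synthesize_forceplate(com, anthro, cfg, rng=None)
        assert np.allclose(fp.force[:, 0], 0.0, atol=1e-9)
        assert np.allclose(fp.force[:, 2], -anthro.total_mass * 9.81)
        cop = compute_cop(fp)
        assert np.allclose(cop.x, 0.01, atol=1e-12)
        assert np.allclose(cop.y, -0.005, atol=1e-12)

    def test_cop_round_trip_through_plate_channels(self, clean_trial):
        anthro = clean_trial.anthropometry
        fp = clean_trial.bundle.forceplate
        cop = compute_cop(fp)
        dt = 1 / clean_trial.config.rate
        for axis, series in (("x", clean_trial.truth_com.ap),
                             ("y", clean_trial.truth_com.ml)):
            acc = np.gradient(
                np.gradient(series, dt, edge_order=2), dt, edge_order=2
            )
            expected = series - (anthro.com_height_above_floor / 9.81) * acc
            assert np.max(np.abs(getattr(cop, axis) - expected)) < 1e-12

    def test_shear_double_integrates_back_to_truth(self, clean_trial):
        # trapezoid double integral of F/m with truth boundary conditions
        fp = clean_trial.bundle.forceplate
        truth = clean_trial.truth_com.ap
        dt = 1 / clean_trial.config.rate
        acc = fp.force[:, 0] / clean_trial.anthropometry.total_mass
        v = np.concatenate([[0.0], np.cumsum((acc[:-1] + acc[1:]) * dt / 2)])
        x = np.concatenate([[0.0], np.cumsum((v[:-1] + v[1:]) * dt / 2)])
        # fit the two free constants (v0, x0) to the truth and compare
        t = clean_trial.truth_com.time
        A = np.column_stack([np.ones_like(t), t])
        coef, *_ = np.linalg.lstsq(A, truth - x, rcond=None)
        recon = x + A @ coef
        # interior only: central-difference acceleration is off at the edges
        interior = slice(10, -10)
        assert np.max(np.abs(recon[interior] - truth[interior])) < 1e-6


class TestTrialAssembly:
    def test_round_trip_through_files(self, tmp_path, clean_trial):
        write_synthetic_trial(tmp_path / "trial", clean_trial)
        bundle, cfg = load_trial(tmp_path / "trial" / "trial.toml")
        for p in Placement:
            assert np.allclose(
                bundle.imus[p].accel, clean_trial.bundle.imus[p].accel,
                atol=1e-12, rtol=0,
            )
        assert np.allclose(
            bundle.forceplate.force, clean_trial.bundle.forceplate.force,
            atol=1e-12, rtol=0,
        )
        assert bundle.participant.stature == clean_trial.bundle.participant.stature

    def test_six_imu_estimate_recovers_truth(self, short_trial):
        combo = ComboSpec(frozenset(Placement), frozenset(Placement))
        est = estimate_com(short_trial.bundle, combo, short_trial.anthropometry)
        for axis in Axis:
            truth = short_trial.truth_com.axis(axis)
            r = pearson_r(est.axis(axis), truth - truth.mean())
            assert r > 0.9

    def test_counter_rotation_defeats_single_back_imu(self):
        cfg = SimConfig(seed=6, duration=30.0, counter_rotation=-0.6)
        trial = make_trial(cfg)
        anthro = trial.anthropometry
        truth_ml = trial.truth_com.ml - trial.truth_com.ml.mean()
        single = estimate_com(
            trial.bundle,
            ComboSpec(frozenset({Placement.BACK}), frozenset({Placement.BACK})),
            anthro,
        )
        multi = estimate_com(
            trial.bundle,
            ComboSpec(
                frozenset({Placement.LEFT_SHANK, Placement.RIGHT_SHANK}),
                frozenset(
                    {Placement.LEFT_SHANK, Placement.RIGHT_SHANK, Placement.BACK}
                ),
            ),
            anthro,
        )
        r_single = pearson_r(single.ml, truth_ml)
        r_multi = pearson_r(multi.ml, truth_ml)
        assert r_single < r_multi
        assert r_multi > 0.9
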