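# Methods

This note records the models implemented in `comsway`, their assumptions,
the defaults that matter, and the choices made where the design was
genuinely open. Units are SI internally (m, rad, s, N); reporting layers
use mm and degrees. The body frame is X forward, Y right, Z down
(right-handed), so a static accelerometer reads (0, 0, −g). Positive pitch
is forward lean, positive roll rightward lean; with Z down this means the
pitch rate is −gyro_y and the roll rate is +gyro_x.

## Sensor calibration

Each IMU is mapped to the body frame from two 5 s static poses: upright
(gravity defines −Z) and segment pitched forward (gravity acquires a −X
component). Gram–Schmidt (Y = Ẑ×X̂′ normalized, X = Y×Z) makes the result
exact for *any* pitch amplitude in (15°, 165°) provided the pitched pose
stays in the body X–Z plane; poses within 15° of parallel are rejected as
degenerate. Window endpoints come from the trial config — no automatic
motion detection. The mean gyroscope reading over the upright window is
subtracted from the whole trial as a bias estimate: an uncompensated bias
b would otherwise appear in the complementary-filter output as a constant
offset b·τ (harmless for correlations after demeaning, but wrong in
absolute angle).

## Orientation estimation

Pitch and roll are estimated per axis by a first-order complementary
filter, θ_t = (1−k)(θ_{t−1} + ωΔt) + k·θ_accel, with k = Δt/(τ+Δt) and
default τ = 1 s. Quiet-stance sway lives below ~2 Hz, so a 1 s time
constant lets the accelerometer correct gyro drift while attenuating
motion artefact; τ is exposed because no canonical value exists. The angle
is initialized from the mean accelerometer inclination over the first 1 s.
The two axes are treated as decoupled small-angle channels (sway angles
are a fraction of a degree; cross-axis coupling is second order).

Accelerometer inclination is contaminated by the linear acceleration of
the mount point. The filter passes this error through a first-order
low-pass of cutoff 1/(2πτ) ≈ 0.16 Hz, leaving a residual that grows with
mount height: on noise-free synthetic trials the RMSE is ~0.01° at the
shanks, ~0.05° at the back, ~0.10° at the head, mean ~0.045° across the
six sites. This is a physical limit of accelerometer-corrected
orientation, not a numerical artefact; validation bounds on noise-free
orientation error are therefore stated as means over the six placements.
No |f|-gating of the accelerometer is applied by default (a gate flag
exists).

## Chain model

The kinematic chain has seven moving segments — two shanks, two thighs,
lower trunk (pelvis+abdomen), upper trunk (thorax, with the hanging arms'
mass folded in), head — above ground-fixed feet whose mass enters the
normalization with zero displacement. Joint heights follow the classic
stature proportions (ankle 0.039 H, knee 0.285 H, hip 0.530 H, trunk split
0.670 H, shoulder 0.818 H); mass fractions and segment CoM positions come
from an embedded sex-specific table assembled from published adjusted
segment-inertia parameters. The resulting equivalent-pendulum CoM height
is 0.520 H (male) / 0.515 H (female), inside the textbook 0.50–0.65 band.

Per axis the displacement is computed with the full sine (no small-angle
truncation — exact and costless). The two leg chains are averaged at the
hip to translate the trunk stack; with symmetric leg parameters this makes
the uniform-angle case telescope exactly to H_eff·sin θ, the single
inverted pendulum. Segments without an IMU borrow the angle of the closest
instrumented segment: own sensor first; candidates on the same side of the
hip joint whenever any exists; then minimal hops on the adjacency chain
(shank–thigh–lower trunk–upper trunk–head, both thighs meeting at the
lower trunk); ties resolved toward the most inferior candidate, then
lexicographically. The estimate is demeaned per trial: orientation offsets
and integration constants carry no information about sway.

## Force-plate reference estimators

CoP is computed as CoP_x = (−M_y + F_x z₀)/(−F_z), CoP_y = (M_x + F_y z₀)/
(−F_z) (signs fixed so a forward lean gives positive CoP_x; note this
moment convention is what the bundled simulator inverts, not the textbook
r×F construction), masked and rejected when |F_z| ≤ 50 N.

The zero-point-to-zero-point estimator uses the identity that at instants
of zero horizontal shear the CoM projection coincides with the CoP. Shear
zero crossings are located by sign change with linear sub-sample
interpolation; crossings closer than 4 samples are merged (noise chatter).
Between consecutive crossings the acceleration (shear/mass) is double
integrated with both endpoints pinned to the CoP, which determines the
interval's free initial velocity in closed form. The double integral is
exact for shear that is piecewise linear between samples (velocity by
trapezoid; position increment V_iΔt + (2a_i + a_{i+1})Δt²/6). Samples
before the first and after the last crossing extend the adjacent
interval's solution (velocity continuity). A 10 Hz dual-pass Butterworth
pass removes the residual seam discontinuities, mirroring the standard
processing chain in which all channels are also pre-filtered at 10 Hz.
Degenerate inputs: identically zero shear returns the CoP itself (the CoM
projection sits on the CoP); fewer than 3 crossings is an error.

The low-pass-CoP alternative filters the CoP at a configurable cutoff
(default 0.5 Hz) and demeans. On synthetic trials the zero-point method
reconstructs truth to ~0.03 mm RMSE; the low-pass alternative tracks truth
at r ≈ 0.96–0.97 with ~1.2–1.5 mm RMSE.

All zero-phase filtering uses a 4th-order Butterworth in second-order
sections applied forward and backward (squared magnitude, zero phase) with
reflective padding whose length scales with the filter's settling time
(at least one cutoff period) — a 12-sample pad is far too short for
sub-hertz cutoffs at 250 Hz.

## Metrics, statistics and the sensor-budget search

Sway metrics are the maximum range (max−min) and RMS of the demeaned
series, in mm. RMSE demeans both series first. Correlations are averaged
through the Fisher z-transform: per-trial r → within-participant z-mean →
cross-participant z-mean for selection; reported means are arithmetic on r
to match the conventional presentation. One-sided paired t-tests (df =
n−1, no multiplicity correction) compare a chosen combination's
z-transformed correlations against the lumbar-marker reference.

The search enumerates every (AP subset, ML subset) pair whose union fits
the sensor budget N — the two axes need not use the same sensors.
Pairs whose cross-participant mean r falls below 0.8 on either axis are
excluded (a per-trial exclusion mode exists); survivors are ranked by the
mean of the two axis means, with deterministic tie-breaks (smaller union,
then lexicographic placement order). If every pair is excluded the budget
is reported infeasible ("N/A").

## Synthetic data generator

The generator is the package's study stand-in: it defines the conditions
under which everything is validated.

**Angles.** Per axis, white Gaussian noise is brick-wall band-limited to
[0.05, 1.5] Hz with a second-order low-pass amplitude shaping (knee
0.35 Hz) inside the band — quiet-stance CoM spectra concentrate power
below ~0.5 Hz, and a flat band to 1.5 Hz would imply unrealistically large
mount-point accelerations. All segments share a common AP lean; ML legs
share a common lean and the trunk stack follows c·(leg) plus an
independent component of equal magnitude (hip-strategy trunk motion is
comparable to leg lean in narrow stance). The coupling c defaults per
stance to +0.6 (narrow), 0.0 (hip), −0.5 (shoulder): counter-rotation
grows with stance width. Per-segment independent jitter (10% of the
common mode) is graded up the chain (legs and lower trunk ×1, upper trunk
×1.5, head ×2.5) and the head follows its support with gain 0.6 —
vestibulocollic head stabilization decouples the head from trunk sway.

**Amplitudes.** Defaults are expressed as target whole-body CoM RMS per
stance (narrow 4.86/4.21 mm AP/ML; hip 4.33/2.04; shoulder 4.11/1.69 —
published human quiet-stance values) and converted to angle scale through
the participant's own forward kinematics; an explicit per-axis angle RMS
(deg) overrides this. Virtual cohorts draw between-participant amplitude
scatter (relative SD 0.43) and stature scatter (SD 0.12 m around 1.74 m,
mass scaled with stature²; sexes alternate) in antithetic pairs, so an
even-sized cohort is balanced exactly on the population mean while keeping
realistic marginal spread.

**IMUs.** Each placement has a mount point (segment, fraction along it).
The gyroscope is the exact body angular rate of R = Ry(−pitch)·Rx(roll)
plus a constant per-axis bias (SD 0.01 rad/s) and white noise (SD
0.02 rad/s); the accelerometer is the specific force at the mount point —
gravity tilt plus the second-order-accurate central-difference linear
acceleration of the mount — plus white noise (SD 0.05 m/s²). The sternum
IMU additionally rocks with a respiratory/soft-tissue wobble (0.5° RMS,
0.15–0.45 Hz) that perturbs the measurement but never the ground truth —
chest mounts are known to breathe; an L3 back mount barely does. An
optional mounting rotation exercises the calibration path. `noise=False`
switches off every measurement artefact while leaving the motion itself
unchanged.

**Force plate.** Horizontal shear = m·(CoM acceleration); F_z = −m·g
(vertical dynamics are second order in quiet stance and neglecting them
keeps the CoP relation exact); CoP from the zero-moment inverted-pendulum
relation CoP = CoM − (H/g)·CoM̈ with H the static CoM height above the
floor; moments constructed so the CoP formula above inverts exactly.
Optional white noise: 0.1 N force, 0.05 N·m moment channels.

**What the simulator does not emulate:** stepping or perturbed stance,
knee/hip flexion kinematics, vertical CoM motion, soft-tissue artefact at
non-sternum sites, non-Gaussian or non-stationary sway, and real
anthropometric idiosyncrasies. Passing tests therefore demonstrate
algorithmic correctness and noise robustness under a faithful rigid-chain
sway model — not performance on any particular human population.

## Validated behaviour (computed by the test suite / acceptance script)

* Chain model ≡ explicit forward kinematics to 1e−12; single-sensor case
  ≡ H_eff·sin θ exactly.
* Zero-point reconstruction: ~0.03 mm RMSE per axis on noisy 120 s trials
  (bound: ≤ 1 mm); boundary conditions honoured to < 1e−9 m at crossings.
* Default narrow-stance cohort: mean AP CoM RMS 4.86 mm (by construction
  of the amplitude calibration; the acceptance script recomputes it).
* Complementary filter: < 0.2° RMSE on a noisy 0.3 Hz, 2° sway signal;
  noise-free trial mean across placements < 0.05°.
* Six-IMU end-to-end recovery: r ≈ 0.98–0.99 vs truth per axis under
  default noise (bound: ≥ 0.9).
* With ML counter-rotation c = −0.6 the budget search includes the back
  IMU in the ML set from budget 4, and a lone back IMU is strictly worse
  than shanks+back — the single-sensor ML failure mode.

## Problem sizes

Unit tests simulate 10–30 s records (100–250 Hz); the end-to-end and
reference-accuracy checks use the full 120 s, 250 Hz trial length, and
cohort-level checks use 6–16 virtual participants (the combination-search
cohort runs 60 s at 100 Hz). The whole suite runs in well under a minute
on one CPU.

## Known limitations

* The complementary filter's accelerometer path is contaminated by mount
  linear acceleration; upper-body noise-free orientation error (~0.1° at
  the head) is irreducible at τ = 1 s without model-based compensation.
* The CoP moment convention matches the bundled simulator; plates wired to
  the textbook r×F convention need their moment signs adapted at import.
* The anthropometric table is a single embedded source; population-
  specific tables must be swapped in by editing one module-level dict.
* Left-thigh placements are not part of the placement enum (the study
  hardware instrumented only the right thigh); adding one is a mechanical
  extension of the placement→segment map and mount table.
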