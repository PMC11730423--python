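"""Estimate whole-body CoM sway from the recommended four IMUs.

AP sway is estimated from the two shanks plus the right thigh; ML sway from
the two shanks plus the back (L3) IMU — four unique sensors in total.  The
estimate is compared against the force-plate reference (zero-point-to-zero-
point double integration): the Pearson correlation tells you whether the
IMU estimate tracks the reference waveform, the RMSE how far apart they are
in millimetres.
"""
from comsway import (
    ComboSpec,
    Placement,
    SimConfig,
    estimate_com,
    evaluate_series,
    make_trial,
    zero_point_displacement,
)

trial = make_trial(SimConfig(seed=1, duration=120.0))

combo = ComboSpec(
    ap_placements={Placement.LEFT_SHANK, Placement.RIGHT_SHANK,
                   Placement.RIGHT_THIGH},
    ml_placements={Placement.LEFT_SHANK, Placement.RIGHT_SHANK,
                   Placement.BACK},
)
print(f"sensor budget: {combo.budget} unique IMUs")

estimate = estimate_com(trial.bundle, combo, trial.anthropometry)
reference = zero_point_displacement(
    trial.bundle.forceplate, trial.anthropometry.total_mass
).demeaned()

result = evaluate_series(estimate, reference)
print(f"AP: r = {result.r_ap:.3f}, RMSE = {result.rmse_ap_mm:.2f} mm")
print(f"ML: r = {result.r_ml:.3f}, RMSE = {result.rmse_ml_mm:.2f} mm")
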