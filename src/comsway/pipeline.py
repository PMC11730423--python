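"""Higher-level plumbing: per-trial subset correlations and cohort tables.

These helpers run the full estimation chain (orientation -> segment
assignment -> chain kinematics) once per IMU and then reuse the orientation
series across every placement subset, which keeps the exhaustive
combination search cheap.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .anthropometry import Anthropometry, anthropometry_for
from .evaluation import nonempty_subsets, pearson_r
from .forceplate import zero_point_displacement
from .io import write_trial
from .model import assign_axis_angles, com_from_angles
from .orientation import FilterParams, complementary_filter
from .simulate import SimConfig, SyntheticTrial
from .types import (
    Axis,
    DisplacementSeries,
    Placement,
    TrialBundle,
)


def orientations_for_trial(
    bundle: TrialBundle, params: FilterParams | None = None
) -> dict[Placement, object]:
    return {
        p: complementary_filter(rec, params)
        for p, rec in sorted(bundle.imus.items(), key=lambda kv: kv[0].value)
    }


def subset_correlations(
    bundle: TrialBundle,
    reference: DisplacementSeries,
    anthro: Anthropometry | None = None,
    params: FilterParams | None = None,
    subsets: list[frozenset[Placement]] | None = None,
) -> pd.DataFrame:
    """Correlation of the IMU CoM estimate with a reference, per axis and per
    non-empty placement subset.  Returns columns axis, combo, r."""
    anthro = anthro or anthropometry_for(bundle.participant)
    orientations = orientations_for_trial(bundle, params)
    if subsets is None:
        subsets = nonempty_subsets(bundle.placements)
    rows = []
    for axis in Axis:
        ref = reference.axis(axis)
        ref = ref - np.mean(ref)
        for combo in subsets:
            angles = assign_axis_angles(orientations, combo, axis)
            est = com_from_angles(angles, anthro)
            rows.append(
                {
                    "axis": axis.value,
                    "combo": combo,
                    "r": pearson_r(est - np.mean(est), ref),
                }
            )
    return pd.DataFrame(rows)


def cohort_correlation_table(
    trials: list[SyntheticTrial],
    reference: str = "forceplate",
    params: FilterParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(combo table, reference table) for a synthetic cohort.

    ``reference`` selects what the IMU estimate is correlated against:
    ``"forceplate"`` (zero-point CoM, as in a real study) or ``"truth"``.
    The reference table holds the lumbar-point-vs-reference correlations
    (the motion-capture stand-in) for the comparison t-tests.
    """
    combo_rows = []
    ref_rows = []
    for i, trial in enumerate(trials):
        if reference == "forceplate":
            ref_series = zero_point_displacement(
                trial.bundle.forceplate, trial.anthropometry.total_mass
            )
        elif reference == "truth":
            ref_series = trial.truth_com
        else:
            raise ValueError("reference must be 'forceplate' or 'truth'")
        table = subset_correlations(
            trial.bundle, ref_series, trial.anthropometry, params
        )
        table["participant"] = i
        table["trial"] = 0
        combo_rows.append(table)
        for axis in Axis:
            a = trial.lumbar.axis(axis)
            b = ref_series.axis(axis)
            ref_rows.append(
                {
                    "participant": i,
                    "trial": 0,
                    "axis": axis.value,
                    "r": pearson_r(a - np.mean(a), b - np.mean(b)),
                }
            )
    return pd.concat(combo_rows, ignore_index=True), pd.DataFrame(ref_rows)


def write_synthetic_trial(out_dir: str, trial: SyntheticTrial) -> None:
    """Write a synthetic trial as the CSV dialects the readers accept, plus
    ground-truth files and a ready-to-use trial.toml."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_trial(out, trial.bundle)
    truth = pd.DataFrame(
        {
            "time_s": trial.truth_com.time,
            "com_ap_m": trial.truth_com.ap,
            "com_ml_m": trial.truth_com.ml,
            "lumbar_ap_m": trial.lumbar.ap,
            "lumbar_ml_m": trial.lumbar.ml,
        }
    )
    truth.to_csv(out / "truth.csv", index=False, float_format="%.17g")
    participant = trial.bundle.participant
    lines = [
        f"rate = {trial.config.rate}",
        f'stance = "{trial.bundle.stance.value}"',
        'frame = "body"',
        "",
        "[participant]",
        f'sex = "{participant.sex.value}"',
        f"stature = {participant.stature}",
        f"mass = {participant.mass}",
        "",
    ]
    for placement in sorted(trial.bundle.imus, key=lambda p: p.value):
        lines += [f"[imu.{placement.value}]",
                  f'path = "imu_{placement.value}.csv"', ""]
    lines += ["[forceplate]", 'path = "forceplate.csv"', "origin_height = 0.0", ""]
    (out / "trial.toml").write_text("\n".join(lines))
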