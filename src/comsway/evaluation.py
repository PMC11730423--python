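"""Sway metrics, correlation statistics, and the IMU-combination search.

The combination search enumerates every (AP subset, ML subset) pair whose
union fits a sensor budget N, scores each pair by the mean of its two
axis-mean correlations with the reference CoM, excludes pairs whose mean
correlation falls below a threshold (default 0.8) on either axis, and picks
the best survivor.  Correlation averaging goes through the Fisher
z-transform (variance stabilization); reported means are arithmetic on r to
mirror the usual presentation.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    Axis,
    ComboSpec,
    Placement,
    StateError,
    UndefinedCorrelationError,
)


# ---------------------------------------------------------------------------
# Elementary metrics
# ---------------------------------------------------------------------------

def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation of two equal-length series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise StateError("pearson_r needs two 1-D series of equal length >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedCorrelationError("zero-variance input")
    return float(stats.pearsonr(a, b).statistic)


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square error between two demeaned series, in mm.

    Inputs are in metres; both are demeaned before differencing so that
    arbitrary integration constants / reference offsets do not count.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise StateError("rmse needs equal-length series")
    a = a - np.mean(a)
    b = b - np.mean(b)
    return float(np.sqrt(np.mean((a - b) ** 2)) * 1000.0)


def sway_stats(series: np.ndarray) -> tuple[float, float]:
    """(maximum sway range, RMS sway) of a displacement series, in mm."""
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise StateError("sway_stats needs at least 2 samples")
    rng = float((series.max() - series.min()) * 1000.0)
    centred = series - series.mean()
    rms = float(np.sqrt(np.mean(centred**2)) * 1000.0)
    return rng, rms


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Variance-stabilizing transform z = atanh(r)."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise UndefinedCorrelationError("|r| must be < 1 for the Fisher transform")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher(z: float | np.ndarray) -> float | np.ndarray:
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def paired_t_one_sided(
    x: np.ndarray, y: np.ndarray, direction: str = "greater"
) -> tuple[float, float]:
    """One-sided paired t-test on per-participant values.

    ``direction="greater"`` tests mean(x - y) > 0.  No multiplicity
    correction is applied.  Zero-variance, zero-mean differences yield the
    degenerate (t=0, p=0.5).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise StateError("paired test needs two 1-D samples of equal length >= 3")
    if direction not in ("greater", "less"):
        raise StateError("direction must be 'greater' or 'less'")
    d = x - y
    if np.std(d, ddof=1) == 0:
        if np.mean(d) == 0:
            return 0.0, 0.5
        return (np.inf if (np.mean(d) > 0) == (direction == "greater") else -np.inf,
                0.0 if (np.mean(d) > 0) == (direction == "greater") else 1.0)
    res = stats.ttest_rel(x, y, alternative=direction)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Per-trial evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationResult:
    """Agreement of an estimate with a reference, per axis, for one trial."""

    reference: str
    r_ap: float
    r_ml: float
    rmse_ap_mm: float
    rmse_ml_mm: float
    range_ap_mm: float
    range_ml_mm: float
    rms_ap_mm: float
    rms_ml_mm: float

    def r(self, axis: Axis | str) -> float:
        return self.r_ap if Axis(axis) is Axis.AP else self.r_ml


def evaluate_series(estimate, reference) -> EvaluationResult:
    """Compare two :class:`DisplacementSeries` on a shared grid."""
    if estimate.time.shape != reference.time.shape:
        raise StateError("estimate and reference are not on the same grid")
    out = {}
    for axis in Axis:
        a = estimate.axis(axis)
        b = reference.axis(axis)
        out[axis] = (
            pearson_r(a, b),
            rmse(a, b),
            *sway_stats(a),
        )
    return EvaluationResult(
        reference=reference.source,
        r_ap=out[Axis.AP][0],
        r_ml=out[Axis.ML][0],
        rmse_ap_mm=out[Axis.AP][1],
        rmse_ml_mm=out[Axis.ML][1],
        range_ap_mm=out[Axis.AP][2],
        range_ml_mm=out[Axis.ML][2],
        rms_ap_mm=out[Axis.AP][3],
        rms_ml_mm=out[Axis.ML][3],
    )


# ---------------------------------------------------------------------------
# Combination search
# ---------------------------------------------------------------------------

def nonempty_subsets(
    placements: frozenset[Placement] | set[Placement],
) -> list[frozenset[Placement]]:
    items = sorted(placements, key=lambda p: p.value)
    out = []
    for size in range(1, len(items) + 1):
        out.extend(frozenset(c) for c in itertools.combinations(items, size))
    return out


def combo_label(placements: frozenset[Placement]) -> str:
    return "+".join(sorted(p.value for p in placements))


@dataclass
class ComboSearchResult:
    """Outcome of the search at one sensor budget."""

    budget: int
    threshold: float
    ap_combo: frozenset[Placement] | None
    ml_combo: frozenset[Placement] | None
    mean_r_ap: float = np.nan
    mean_r_ml: float = np.nan
    sd_r_ap: float = np.nan
    sd_r_ml: float = np.nan
    t_ap: float = np.nan
    p_ap: float = np.nan
    t_ml: float = np.nan
    p_ml: float = np.nan
    n_participants: int = 0
    excluded_combos: int = 0

    @property
    def feasible(self) -> bool:
        """False when every candidate pair fell below the threshold (N/A row)."""
        return self.ap_combo is not None

    @property
    def spec(self) -> ComboSpec | None:
        if not self.feasible:
            return None
        return ComboSpec(ap_placements=self.ap_combo, ml_placements=self.ml_combo)


REQUIRED_TABLE_COLUMNS = ("participant", "axis", "combo", "r")


def participant_mean_r(table: pd.DataFrame) -> pd.DataFrame:
    """Within-participant Fisher-z average of per-trial correlations.

    Expects columns participant, axis, combo, r (combo = frozenset of
    placements); returns one row per (participant, axis, combo).
    """
    for col in REQUIRED_TABLE_COLUMNS:
        if col not in table.columns:
            raise StateError(f"correlation table missing column '{col}'")
    df = table.copy()
    df["z"] = np.arctanh(np.clip(df["r"].to_numpy(float), -0.999999999, 0.999999999))
    grouped = (
        df.groupby(["participant", "axis", "combo"], sort=True)["z"]
        .mean()
        .reset_index()
    )
    grouped["r"] = np.tanh(grouped["z"].to_numpy(float))
    return grouped


def _axis_summary(per_participant: pd.DataFrame, axis: Axis,
                  combo: frozenset[Placement]) -> tuple[np.ndarray, np.ndarray]:
    sel = per_participant[
        (per_participant["axis"] == axis.value)
        & (per_participant["combo"] == combo)
    ].sort_values("participant")
    return sel["r"].to_numpy(float), sel["z"].to_numpy(float)


def search_best_combos(
    table: pd.DataFrame,
    budget: int,
    threshold: float = 0.8,
    reference_table: pd.DataFrame | None = None,
    exclusion: str = "mean",
) -> ComboSearchResult:
    """Select the best (AP, ML) placement pair within a sensor budget.

    Parameters
    ----------
    table
        Per-trial correlations: columns participant, trial, axis ("ap"/"ml"),
        combo (frozenset of placements), r.  Every non-empty subset of the
        available placements must be present for both axes.
    budget
        Maximum number of unique IMUs in the AP/ML union.
    threshold
        Pairs whose cross-participant mean r (Fisher-z averaged) falls below
        this on either axis are excluded; if all pairs are excluded the
        result is infeasible (an "N/A" budget row).
    reference_table
        Optional per-trial correlations of the reference displacement
        (e.g. the lumbar marker) with the plate CoM, same columns minus
        'combo'; enables the one-sided paired t-test reference-vs-combo.
    exclusion
        "mean" applies the threshold to the cross-participant mean r
        (default); "per_trial" additionally requires every single trial of
        the winning pair to clear it.
    """
    if budget < 1:
        raise StateError("budget must be >= 1")
    if exclusion not in ("mean", "per_trial"):
        raise StateError("exclusion must be 'mean' or 'per_trial'")
    per_part = participant_mean_r(table)
    combos = sorted(
        {c for c in table["combo"].unique()}, key=lambda c: (len(c), combo_label(c))
    )

    def mean_sd(axis: Axis, combo: frozenset[Placement]) -> tuple[float, float, float]:
        r_vals, z_vals = _axis_summary(per_part, axis, combo)
        if r_vals.size == 0:
            raise StateError(f"no correlations for combo {combo_label(combo)}")
        # selection statistic: Fisher-z mean, back-transformed
        z_mean = float(np.tanh(np.mean(z_vals)))
        return z_mean, float(np.mean(r_vals)), float(np.std(r_vals, ddof=1)) if r_vals.size > 1 else 0.0

    cache = {
        (axis, combo): mean_sd(axis, combo)
        for axis in Axis
        for combo in combos
    }

    best_key = None
    best = None
    excluded = 0
    for ap_combo in combos:
        for ml_combo in combos:
            if len(ap_combo | ml_combo) > budget:
                continue
            ap_sel, _, _ = cache[(Axis.AP, ap_combo)]
            ml_sel, _, _ = cache[(Axis.ML, ml_combo)]
            if ap_sel < threshold or ml_sel < threshold:
                excluded += 1
                continue
            if exclusion == "per_trial":
                ap_ok = (table[(table["axis"] == Axis.AP.value)
                               & (table["combo"] == ap_combo)]["r"] >= threshold).all()
                ml_ok = (table[(table["axis"] == Axis.ML.value)
                               & (table["combo"] == ml_combo)]["r"] >= threshold).all()
                if not (ap_ok and ml_ok):
                    excluded += 1
                    continue
            score = 0.5 * (ap_sel + ml_sel)
            key = (
                -score,
                len(ap_combo | ml_combo),
                combo_label(ap_combo),
                combo_label(ml_combo),
            )
            if best_key is None or key < best_key:
                best_key = key
                best = (ap_combo, ml_combo)

    if best is None:
        return ComboSearchResult(
            budget=budget, threshold=threshold, ap_combo=None, ml_combo=None,
            excluded_combos=excluded,
        )

    ap_combo, ml_combo = best
    _, ap_mean, ap_sd = cache[(Axis.AP, ap_combo)]
    _, ml_mean, ml_sd = cache[(Axis.ML, ml_combo)]
    result = ComboSearchResult(
        budget=budget,
        threshold=threshold,
        ap_combo=ap_combo,
        ml_combo=ml_combo,
        mean_r_ap=ap_mean,
        mean_r_ml=ml_mean,
        sd_r_ap=ap_sd,
        sd_r_ml=ml_sd,
        excluded_combos=excluded,
    )
    result.n_participants = per_part["participant"].nunique()
    if reference_table is not None:
        ref = reference_table.copy()
        ref["combo"] = [frozenset()] * len(ref)
        ref_part = participant_mean_r(ref)
        for axis, combo in ((Axis.AP, ap_combo), (Axis.ML, ml_combo)):
            _, z_est = _axis_summary(per_part, axis, combo)
            ref_sel = ref_part[ref_part["axis"] == axis.value].sort_values(
                "participant"
            )
            z_ref = ref_sel["z"].to_numpy(float)
            if z_ref.size == z_est.size and z_ref.size >= 3:
                # is the reference correlation higher than the IMU combo's?
                t, p = paired_t_one_sided(z_ref, z_est, direction="greater")
                if axis is Axis.AP:
                    result.t_ap, result.p_ap = t, p
                else:
                    result.t_ml, result.p_ml = t, p
    return result


def search_all_budgets(
    table: pd.DataFrame,
    max_budget: int = 6,
    threshold: float = 0.8,
    reference_table: pd.DataFrame | None = None,
) -> list[ComboSearchResult]:
    return [
        search_best_combos(table, n, threshold, reference_table)
        for n in range(1, max_budget + 1)
    ]


def results_to_frame(results: list[ComboSearchResult]) -> pd.DataFrame:
    """Flatten search results into a table-shaped DataFrame (one row/budget)."""
    rows = []
    for res in results:
        rows.append(
            {
                "budget": res.budget,
                "ap_combo": combo_label(res.ap_combo) if res.feasible else "N/A",
                "ml_combo": combo_label(res.ml_combo) if res.feasible else "N/A",
                "mean_r_ap": res.mean_r_ap,
                "sd_r_ap": res.sd_r_ap,
                "mean_r_ml": res.mean_r_ml,
                "sd_r_ml": res.sd_r_ml,
                "t_ap": res.t_ap,
                "p_ap": res.p_ap,
                "t_ml": res.t_ml,
                "p_ml": res.p_ml,
            }
        )
    return pd.DataFrame(rows)
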