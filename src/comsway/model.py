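"""Multi-segment inverted-pendulum CoM model.

Per axis (AP from pitch angles, ML from roll angles) each segment's CoM
displacement is

    CoM_i = h_i * sin(theta_i) + sum_{n below i} l_n * sin(theta_n)

i.e. the segment's own lever plus the translation of everything beneath it
(full sine, no small-angle approximation), and the whole-body CoM is the
mass-fraction-weighted sum

    CoM = sum_i m_i * CoM_i

with the ground-fixed feet contributing zero displacement.  The two leg
chains are averaged at the hip to translate the trunk stack.

When a segment has no IMU of its own, its angle is borrowed from the
*anatomically closest* instrumented segment: candidates on the same side of
the hip joint are preferred whenever any exists, distance is counted in hops
on the segment-adjacency chain, and ties go to the most inferior candidate
(this reproduces, e.g., thigh <- shank and sternum <- back).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anthropometry import Anthropometry, LEG_SEGMENTS, TRUNK_STACK
from .orientation import FilterParams, complementary_filter
from .types import (
    Axis,
    ComboSpec,
    ConfigError,
    DisplacementSeries,
    Placement,
    Segment,
    SEGMENT_OF_PLACEMENT,
    StateError,
    TrialBundle,
)

#: Kinematic chain adjacency (undirected).
SEGMENT_ADJACENCY: dict[Segment, tuple[Segment, ...]] = {
    Segment.LEFT_SHANK: (Segment.LEFT_THIGH,),
    Segment.RIGHT_SHANK: (Segment.RIGHT_THIGH,),
    Segment.LEFT_THIGH: (Segment.LEFT_SHANK, Segment.LOWER_TRUNK),
    Segment.RIGHT_THIGH: (Segment.RIGHT_SHANK, Segment.LOWER_TRUNK),
    Segment.LOWER_TRUNK: (
        Segment.LEFT_THIGH,
        Segment.RIGHT_THIGH,
        Segment.UPPER_TRUNK,
    ),
    Segment.UPPER_TRUNK: (Segment.LOWER_TRUNK, Segment.HEAD),
    Segment.HEAD: (Segment.UPPER_TRUNK,),
}

#: Segments below the hip joint.
BELOW_HIP = frozenset(LEG_SEGMENTS)

# Tie-break order: most inferior first (same level -> left before right).
_INFERIORITY_RANK: dict[Segment, int] = {
    Segment.LEFT_SHANK: 0,
    Segment.RIGHT_SHANK: 0,
    Segment.LEFT_THIGH: 1,
    Segment.RIGHT_THIGH: 1,
    Segment.LOWER_TRUNK: 2,
    Segment.UPPER_TRUNK: 3,
    Segment.HEAD: 4,
}


def segment_hops(a: Segment, b: Segment) -> int:
    """Shortest hop count between two segments on the adjacency chain."""
    if a == b:
        return 0
    frontier = {a}
    seen = {a}
    hops = 0
    while frontier:
        hops += 1
        nxt = set()
        for seg in frontier:
            for nb in SEGMENT_ADJACENCY[seg]:
                if nb == b:
                    return hops
                if nb not in seen:
                    seen.add(nb)
                    nxt.add(nb)
        frontier = nxt
    raise RuntimeError("adjacency graph is connected; unreachable")


def resolve_angle_sources(
    available: frozenset[Placement] | set[Placement],
) -> dict[Segment, Placement]:
    """Map every modelled segment to the placement that supplies its angle."""
    available = frozenset(Placement(p) for p in available)
    if not available:
        raise ConfigError("at least one placement is required")
    own: dict[Segment, Placement] = {
        SEGMENT_OF_PLACEMENT[p]: p for p in available
    }
    out: dict[Segment, Placement] = {}
    for segment in Segment:
        if segment in own:
            out[segment] = own[segment]
            continue
        candidates = list(available)
        same_side = [
            p
            for p in candidates
            if (SEGMENT_OF_PLACEMENT[p] in BELOW_HIP) == (segment in BELOW_HIP)
        ]
        if same_side:
            candidates = same_side
        out[segment] = min(
            candidates,
            key=lambda p: (
                segment_hops(segment, SEGMENT_OF_PLACEMENT[p]),
                _INFERIORITY_RANK[SEGMENT_OF_PLACEMENT[p]],
                p.value,
            ),
        )
    return out


@dataclass
class SegmentAngles:
    """Per-segment angle series for one axis, with provenance."""

    axis: Axis
    angles: dict[Segment, np.ndarray]
    provenance: dict[Segment, Placement] | None = None

    def __post_init__(self) -> None:
        missing = [s for s in Segment if s not in self.angles]
        if missing:
            raise StateError(
                f"missing angle series for segment(s): "
                f"{', '.join(s.value for s in missing)}"
            )
        lengths = {np.asarray(a).shape for a in self.angles.values()}
        if len(lengths) != 1:
            raise StateError("segment angle series have mismatched lengths")


def segment_com_displacement(
    angles: SegmentAngles, anthro: Anthropometry
) -> dict[Segment, np.ndarray]:
    """Horizontal displacement of every segment's CoM (m) for one axis."""
    sin = {s: np.sin(np.asarray(angles.angles[s], dtype=float)) for s in Segment}
    seg = anthro.segments
    out: dict[Segment, np.ndarray] = {}
    # Leg chains, rooted at the ground.
    for shank, thigh in (
        (Segment.LEFT_SHANK, Segment.LEFT_THIGH),
        (Segment.RIGHT_SHANK, Segment.RIGHT_THIGH),
    ):
        out[shank] = seg[shank].com_height * sin[shank]
        out[thigh] = seg[shank].length * sin[shank] + seg[thigh].com_height * sin[thigh]
    # Hip translation = mean of the two leg-top displacements.
    hip = 0.5 * (
        seg[Segment.LEFT_SHANK].length * sin[Segment.LEFT_SHANK]
        + seg[Segment.LEFT_THIGH].length * sin[Segment.LEFT_THIGH]
        + seg[Segment.RIGHT_SHANK].length * sin[Segment.RIGHT_SHANK]
        + seg[Segment.RIGHT_THIGH].length * sin[Segment.RIGHT_THIGH]
    )
    # Trunk stack rides on the hip.
    below = hip
    for segment in TRUNK_STACK:
        out[segment] = below + seg[segment].com_height * sin[segment]
        below = below + seg[segment].length * sin[segment]
    return out


def whole_body_com(
    displacements: dict[Segment, np.ndarray], anthro: Anthropometry
) -> np.ndarray:
    """Mass-fraction-weighted sum over segments (feet contribute zero)."""
    lengths = {np.asarray(d).shape for d in displacements.values()}
    if len(lengths) != 1:
        raise StateError("segment displacement series have mismatched lengths")
    total = np.zeros(next(iter(lengths)))
    for segment, disp in displacements.items():
        total = total + anthro.segments[Segment(segment)].mass_fraction * disp
    return total


def com_from_angles(
    angles: SegmentAngles, anthro: Anthropometry
) -> np.ndarray:
    """Whole-body CoM displacement for one axis from segment angles (m)."""
    return whole_body_com(segment_com_displacement(angles, anthro), anthro)


def assign_axis_angles(
    orientations: dict[Placement, "object"],
    placements: frozenset[Placement] | set[Placement],
    axis: Axis,
) -> SegmentAngles:
    """Build per-segment angles for one axis from per-IMU orientation series."""
    sources = resolve_angle_sources(frozenset(placements))
    angles = {
        segment: orientations[placement].angle(axis)
        for segment, placement in sources.items()
    }
    return SegmentAngles(axis=axis, angles=angles, provenance=sources)


def estimate_com(
    trial: TrialBundle,
    combo: ComboSpec,
    anthro: Anthropometry,
    filter_params: FilterParams | None = None,
    orientations: dict[Placement, "object"] | None = None,
) -> DisplacementSeries:
    """End-to-end IMU CoM estimate for one trial (demeaned, both axes).

    ``orientations`` may carry precomputed per-IMU orientation series (e.g.
    when evaluating many combinations of the same trial); otherwise the
    complementary filter is run on every IMU in the combination.
    """
    missing = [p.value for p in combo.union if p not in trial.imus]
    if missing:
        raise ConfigError(f"combo references absent IMU(s): {', '.join(missing)}")
    if orientations is None:
        orientations = {
            p: complementary_filter(trial.imus[p], filter_params)
            for p in sorted(combo.union, key=lambda p: p.value)
        }
    series = {}
    for axis, placements in (
        (Axis.AP, combo.ap_placements),
        (Axis.ML, combo.ml_placements),
    ):
        angles = assign_axis_angles(orientations, placements, axis)
        com = com_from_angles(angles, anthro)
        series[axis] = com - np.mean(com)
    time = orientations[next(iter(combo.union))].time
    return DisplacementSeries(
        time=time, ap=series[Axis.AP], ml=series[Axis.ML], source="imu_model"
    )
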