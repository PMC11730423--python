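"""Sex-specific anthropometric scaling of the kinematic chain.

The model only needs the participant's stature, mass and sex.  Segment mass
fractions come from an embedded table assembled from published adjusted
segment-inertia parameters (de Leva-style, Zatsiorsky-derived); joint
heights as fractions of stature follow the classic Drillis-Contini
proportions.  Two simplifications suit quiet stance:

* the arms hang and travel with the thorax, so arm mass is folded into the
  upper trunk;
* the feet stay on the ground, so they carry mass (entering the
  normalization) but zero horizontal displacement.

Modelled segments, distal joint -> proximal joint:

===========  =======================  ===============
segment      span (fraction stature)  notes
===========  =======================  ===============
shank        ankle 0.039 -> knee 0.285
thigh        knee 0.285 -> hip 0.530
lower trunk  hip 0.530 -> 0.670       pelvis + abdomen (back/L3 IMU)
upper trunk  0.670 -> shoulder 0.818  thorax + arms (sternum IMU)
head         0.818 -> vertex 1.000    head + neck
===========  =======================  ===============
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import ParameterError, Participant, Segment, Sex

# Joint heights as fractions of stature (Drillis-Contini proportions).
ANKLE_HEIGHT_FRACTION = 0.039
KNEE_HEIGHT_FRACTION = 0.285
HIP_HEIGHT_FRACTION = 0.530
TRUNK_SPLIT_FRACTION = 0.670
SHOULDER_HEIGHT_FRACTION = 0.818

#: Segment length as a fraction of stature.
SEGMENT_LENGTH_FRACTION: dict[Segment, float] = {
    Segment.LEFT_SHANK: KNEE_HEIGHT_FRACTION - ANKLE_HEIGHT_FRACTION,
    Segment.RIGHT_SHANK: KNEE_HEIGHT_FRACTION - ANKLE_HEIGHT_FRACTION,
    Segment.LEFT_THIGH: HIP_HEIGHT_FRACTION - KNEE_HEIGHT_FRACTION,
    Segment.RIGHT_THIGH: HIP_HEIGHT_FRACTION - KNEE_HEIGHT_FRACTION,
    Segment.LOWER_TRUNK: TRUNK_SPLIT_FRACTION - HIP_HEIGHT_FRACTION,
    Segment.UPPER_TRUNK: SHOULDER_HEIGHT_FRACTION - TRUNK_SPLIT_FRACTION,
    Segment.HEAD: 1.0 - SHOULDER_HEIGHT_FRACTION,
}

# Mass fractions of total body mass.  Limb values are per side; the trunk is
# split at the pelvis/abdomen boundary; arm mass (upper arm + forearm + hand,
# both sides) is folded into the upper trunk; feet are listed separately.
_MASS_FRACTIONS: dict[Sex, dict[str, float]] = {
    Sex.MALE: {
        "shank": 0.0433,
        "thigh": 0.1416,
        "lower_trunk": 0.2750,   # pelvis 0.1117 + abdomen 0.1633
        "upper_trunk": 0.2584,   # thorax 0.1596 + arms 2*(0.0271+0.0162+0.0061)
        "head": 0.0694,
        "feet": 0.0274,          # 2 * 0.0137
    },
    Sex.FEMALE: {
        "shank": 0.0481,
        "thigh": 0.1478,
        "lower_trunk": 0.2712,   # pelvis 0.1247 + abdomen 0.1465
        "upper_trunk": 0.2443,   # thorax 0.1545 + arms 2*(0.0255+0.0138+0.0056)
        "head": 0.0668,
        "feet": 0.0258,          # 2 * 0.0129
    },
}

# Segment CoM position as a fraction of segment length, measured from the
# distal (lower) joint.
_COM_FRACTIONS: dict[Sex, dict[str, float]] = {
    Sex.MALE: {
        "shank": 0.558,
        "thigh": 0.590,
        "lower_trunk": 0.50,
        "upper_trunk": 0.50,
        "head": 0.55,
    },
    Sex.FEMALE: {
        "shank": 0.552,
        "thigh": 0.639,
        "lower_trunk": 0.50,
        "upper_trunk": 0.50,
        "head": 0.55,
    },
}

_SEGMENT_KEY = {
    Segment.LEFT_SHANK: "shank",
    Segment.RIGHT_SHANK: "shank",
    Segment.LEFT_THIGH: "thigh",
    Segment.RIGHT_THIGH: "thigh",
    Segment.LOWER_TRUNK: "lower_trunk",
    Segment.UPPER_TRUNK: "upper_trunk",
    Segment.HEAD: "head",
}

LEG_SEGMENTS = (
    Segment.LEFT_SHANK,
    Segment.RIGHT_SHANK,
    Segment.LEFT_THIGH,
    Segment.RIGHT_THIGH,
)
TRUNK_STACK = (Segment.LOWER_TRUNK, Segment.UPPER_TRUNK, Segment.HEAD)


@dataclass
class SegmentParams:
    length: float  # m, distal -> proximal joint
    com_height: float  # m, distal joint -> segment CoM
    mass_fraction: float


@dataclass
class Anthropometry:
    """Scaled chain geometry and mass distribution for one participant."""

    stature: float
    total_mass: float
    sex: Sex
    segments: dict[Segment, SegmentParams]
    feet_mass_fraction: float
    ankle_height: float = field(init=False)

    def __post_init__(self) -> None:
        self.ankle_height = ANKLE_HEIGHT_FRACTION * self.stature
        total = self.feet_mass_fraction + sum(
            s.mass_fraction for s in self.segments.values()
        )
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"mass fractions sum to {total}, not 1")

    def segment_base_height(self, segment: Segment) -> float:
        """Height of the segment's distal joint above the *ankle* (m)."""
        if segment in (Segment.LEFT_SHANK, Segment.RIGHT_SHANK):
            return 0.0
        if segment in (Segment.LEFT_THIGH, Segment.RIGHT_THIGH):
            return self.segments[Segment.LEFT_SHANK].length
        hip = self.hip_height
        if segment is Segment.LOWER_TRUNK:
            return hip
        if segment is Segment.UPPER_TRUNK:
            return hip + self.segments[Segment.LOWER_TRUNK].length
        return (
            hip
            + self.segments[Segment.LOWER_TRUNK].length
            + self.segments[Segment.UPPER_TRUNK].length
        )

    @property
    def hip_height(self) -> float:
        """Hip joint height above the ankle (m); top of either leg chain."""
        return (
            self.segments[Segment.LEFT_SHANK].length
            + self.segments[Segment.LEFT_THIGH].length
        )

    @property
    def effective_com_height(self) -> float:
        """Whole-body CoM height above the ankle (m).

        This is the lever arm of the equivalent single inverted pendulum:
        with every segment at a common lean angle theta the whole-body CoM
        displacement telescopes to ``effective_com_height * sin(theta)``.
        """
        return sum(
            p.mass_fraction * (self.segment_base_height(s) + p.com_height)
            for s, p in self.segments.items()
        )

    @property
    def com_height_above_floor(self) -> float:
        """Static whole-body CoM height above the floor, feet included (m)."""
        h = sum(
            p.mass_fraction
            * (self.segment_base_height(s) + p.com_height + self.ankle_height)
            for s, p in self.segments.items()
        )
        # feet CoM roughly at half the ankle height
        h += self.feet_mass_fraction * 0.5 * self.ankle_height
        return h


def build_anthropometry(
    sex: Sex | str, stature: float, mass: float
) -> Anthropometry:
    """Scale the embedded table to a participant."""
    sex = Sex(sex)
    if not 1.2 <= stature <= 2.2:
        raise ParameterError(f"stature {stature} m outside [1.2, 2.2]")
    if mass <= 0:
        raise ParameterError("mass must be positive")
    fractions = _MASS_FRACTIONS[sex]
    com_fr = _COM_FRACTIONS[sex]
    raw_total = fractions["feet"] + sum(
        fractions[_SEGMENT_KEY[s]] for s in Segment
    )
    norm = 1.0 / raw_total  # exact renormalization of the embedded table
    segments: dict[Segment, SegmentParams] = {}
    for segment in Segment:
        key = _SEGMENT_KEY[segment]
        length = SEGMENT_LENGTH_FRACTION[segment] * stature
        segments[segment] = SegmentParams(
            length=length,
            com_height=com_fr[key] * length,
            mass_fraction=fractions[key] * norm,
        )
    return Anthropometry(
        stature=stature,
        total_mass=mass,
        sex=sex,
        segments=segments,
        feet_mass_fraction=fractions["feet"] * norm,
    )


def anthropometry_for(participant: Participant) -> Anthropometry:
    return build_anthropometry(participant.sex, participant.stature,
                               participant.mass)
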