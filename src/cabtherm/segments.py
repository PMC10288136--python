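"""Body segmentation shared by every module.

The body is split into 14 segments (head, chest/trunk, paired upper and
lower arms, hands, upper and lower legs, feet).  Every per-segment vector
in the package is ordered by :data:`SEGMENTS`.
"""

from __future__ import annotations

from enum import Enum


class SegmentId(str, Enum):
    """The 14 body segments, in canonical order."""

    HEAD = "head"
    CHEST = "chest"
    L_UPPER_ARM = "l_upper_arm"
    R_UPPER_ARM = "r_upper_arm"
    L_LOWER_ARM = "l_lower_arm"
    R_LOWER_ARM = "r_lower_arm"
    L_HAND = "l_hand"
    R_HAND = "r_hand"
    L_UPPER_LEG = "l_upper_leg"
    R_UPPER_LEG = "r_upper_leg"
    L_LOWER_LEG = "l_lower_leg"
    R_LOWER_LEG = "r_lower_leg"
    L_FOOT = "l_foot"
    R_FOOT = "r_foot"


SEGMENTS: tuple[SegmentId, ...] = tuple(SegmentId)
N_SEGMENTS = len(SEGMENTS)
SEGMENT_INDEX = {s: i for i, s in enumerate(SEGMENTS)}

#: left<->right mirror map (head and chest map to themselves)
MIRROR: dict[SegmentId, SegmentId] = {
    SegmentId.HEAD: SegmentId.HEAD,
    SegmentId.CHEST: SegmentId.CHEST,
    SegmentId.L_UPPER_ARM: SegmentId.R_UPPER_ARM,
    SegmentId.R_UPPER_ARM: SegmentId.L_UPPER_ARM,
    SegmentId.L_LOWER_ARM: SegmentId.R_LOWER_ARM,
    SegmentId.R_LOWER_ARM: SegmentId.L_LOWER_ARM,
    SegmentId.L_HAND: SegmentId.R_HAND,
    SegmentId.R_HAND: SegmentId.L_HAND,
    SegmentId.L_UPPER_LEG: SegmentId.R_UPPER_LEG,
    SegmentId.R_UPPER_LEG: SegmentId.L_UPPER_LEG,
    SegmentId.L_LOWER_LEG: SegmentId.R_LOWER_LEG,
    SegmentId.R_LOWER_LEG: SegmentId.L_LOWER_LEG,
    SegmentId.L_FOOT: SegmentId.R_FOOT,
    SegmentId.R_FOOT: SegmentId.L_FOOT,
}

#: The seven measurement sites of the Hardy/DuBois mean-skin-temperature
#: formula, with their weights (weights sum to 1 exactly).
SEVEN_SITES: tuple[tuple[SegmentId, float], ...] = (
    (SegmentId.HEAD, 0.07),
    (SegmentId.CHEST, 0.35),
    (SegmentId.L_LOWER_ARM, 0.14),
    (SegmentId.L_HAND, 0.05),
    (SegmentId.L_UPPER_LEG, 0.19),
    (SegmentId.L_LOWER_LEG, 0.13),
    (SegmentId.L_FOOT, 0.07),
)
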