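"""Rule-based staging of oncosis progression.

Four ordered stages on top of a not-oncotic baseline; later (more severe)
rules win, so the mapping is total and deterministic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

__all__ = ["OncosisFeature", "OncosisStage", "stage_oncosis", "stage_cohort", "estimate_bleb_count"]


class OncosisStage(str, Enum):
    NOT_ONCOTIC = "not_oncotic"
    TRANSITION = "transition"  # normal cells / oncosis transition
    EARLY = "early"
    LATE = "late"
    NECROSIS_TRANSITION = "necrosis_transition"


_SEVERITY = {
    OncosisStage.NOT_ONCOTIC: 0,
    OncosisStage.TRANSITION: 1,
    OncosisStage.EARLY: 2,
    OncosisStage.LATE: 3,
    OncosisStage.NECROSIS_TRANSITION: 4,
}


@dataclass(frozen=True)
class OncosisFeature:
    bleb_count: int = 0
    max_bleb_area: int = 0
    spindle_shape_lost: bool = False
    nucleus_swollen: bool = False
    karyolysis_or_membrane_rupture: bool = False
    rel_mass: float = 1.0  # vs cohort mean
    annexin_pos: bool = False
    pi_pos: bool = False

    def __post_init__(self) -> None:
        if self.bleb_count < 0 or self.max_bleb_area < 0:
            raise ValueError("counts must be >= 0")
        if self.rel_mass <= 0:
            raise ValueError("rel_mass must be > 0")


def stage_oncosis(f: OncosisFeature) -> OncosisStage:
    """First matching rule in severity order 4 -> 1 wins.

    (4) double-positive with karyolysis / membrane rupture; (3)
    double-positive with nuclear swelling or persisting blebs; (2)
    annexin+/PI- with blebs; (1) double-negative blebbing with above-average
    mass; anything else is not oncotic.
    """
    if f.annexin_pos and f.pi_pos and f.karyolysis_or_membrane_rupture:
        return OncosisStage.NECROSIS_TRANSITION
    if f.annexin_pos and f.pi_pos and (f.nucleus_swollen or f.bleb_count >= 1):
        return OncosisStage.LATE
    if f.annexin_pos and not f.pi_pos and f.bleb_count >= 1:
        return OncosisStage.EARLY
    if (not f.annexin_pos) and (not f.pi_pos) and f.bleb_count >= 1 and f.rel_mass > 1:
        return OncosisStage.TRANSITION
    return OncosisStage.NOT_ONCOTIC


def stage_cohort(features: list[OncosisFeature]) -> tuple[list[OncosisStage], dict[str, int]]:
    """Stage every record (input order preserved) and histogram the result."""
    if not features:
        raise ValueError("empty feature list")
    stages = [stage_oncosis(f) for f in features]
    hist = Counter(s.value for s in stages)
    return stages, {s.value: hist.get(s.value, 0) for s in OncosisStage}


def estimate_bleb_count(
    cell_mask: np.ndarray,
    opening_radius: int = 5,
    min_bleb_area: int = 6,
) -> tuple[int, int]:
    """Best-effort bleb detection on a binary cell footprint.

    Morphological opening removes protrusions narrower than the opening
    radius; connected residue components above ``min_bleb_area`` are counted
    as blebs. Heuristic only — validated against generator truth, not
    against curated data. Returns ``(bleb_count, max_bleb_area)``.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    body = ndimage.binary_opening(cell_mask, structure=disk(opening_radius))
    residue = cell_mask & ~body
    labels, n = ndimage.label(residue)
    if n == 0:
        return 0, 0
    areas = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    areas = areas[areas >= min_bleb_area]
    return int(len(areas)), int(areas.max()) if len(areas) else 0


def severity(stage: OncosisStage) -> int:
    return _SEVERITY[stage]
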