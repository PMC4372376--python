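"""Trajectory linking and size-trajectory classification.

Per-frame cell measurements are linked by greedy mutual-nearest-centroid
matching, each complete track is classified as increase / decrease /
no-change from its relative surface-area series, and cohort statistics
(class fractions, mass stability, decrease-vs-rest mass ratio) are
summarised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .quant import CellMeasure

__all__ = [
    "Track",
    "TrajectoryClass",
    "CohortSummary",
    "link_tracks",
    "classify_trajectory",
    "cohort_summary",
]


class TrajectoryClass(str, Enum):
    NO_CHANGE = "no_change"
    INCREASE = "increase"
    DECREASE = "decrease"


@dataclass
class Track:
    cell_id: int
    frames: list[int]
    area_series: list[int]
    mass_series: list[float]
    centroid_series: list[tuple[float, float]]
    complete: bool = True

    def __post_init__(self) -> None:
        if not (len(self.frames) == len(self.area_series) == len(self.mass_series)):
            raise ValueError("track series lengths differ")
        if any(b <= a for a, b in zip(self.frames, self.frames[1:])):
            raise ValueError("frames must be strictly increasing")

    @property
    def rel_area_series(self) -> np.ndarray:
        a0 = self.area_series[0]
        return np.asarray(self.area_series, dtype=float) / a0

    @property
    def rel_mass_change(self) -> float:
        m0 = self.mass_series[0]
        return abs(self.mass_series[-1] - m0) / m0


@dataclass
class CohortSummary:
    fractions: dict[str, float]  # percentages per class, sum to 100
    mass_stable_fraction: float  # % of cells with rel_mass_change < mass_tol
    mass_tol: float
    mass_ratio_decrease_vs_rest: float
    n_complete: int


def _match_frame(
    heads: list[tuple[int, tuple[float, float]]],
    nxt: list[CellMeasure],
    max_disp: float,
) -> dict[int, int]:
    """Greedy mutual-nearest matching; returns head-index -> next-index."""
    if not heads or not nxt:
        return {}
    hp = np.array([h[1] for h in heads])
    np_ = np.array([m.centroid for m in nxt])
    d = np.hypot(hp[:, None, 0] - np_[None, :, 0], hp[:, None, 1] - np_[None, :, 1])
    matches: dict[int, int] = {}
    for i in range(len(heads)):
        j = int(np.argmin(d[i]))
        if d[i, j] > max_disp:
            continue
        # mutual nearest: the detection must also prefer this head,
        # ties resolved by smaller index (argmin is first-occurrence)
        if int(np.argmin(d[:, j])) == i:
            matches[i] = j
    return matches


def link_tracks(
    per_frame_measures: list[list[CellMeasure]],
    max_disp: float = 20.0,
    min_length_fraction: float = 0.8,
) -> list[Track]:
    """Link detections across frames into tracks.

    Tracks are seeded from frame 0 only; detections appearing mid-sequence
    are left as orphans (no new track). A track broken before
    ``min_length_fraction`` of the sequence is flagged incomplete and
    excluded from cohort statistics downstream.
    """
    if len(per_frame_measures) < 2:
        raise ValueError("need at least 2 frames to link")
    n_frames = len(per_frame_measures)
    tracks = [
        Track(
            cell_id=k,
            frames=[0],
            area_series=[m.area_px],
            mass_series=[m.dry_mass],
            centroid_series=[m.centroid],
        )
        for k, m in enumerate(per_frame_measures[0])
    ]
    alive = list(range(len(tracks)))
    for t in range(1, n_frames):
        heads = [(i, tracks[i].centroid_series[-1]) for i in alive]
        matches = _match_frame(heads, per_frame_measures[t], max_disp)
        next_alive = []
        for hi, (ti, _) in enumerate(heads):
            if hi in matches:
                m = per_frame_measures[t][matches[hi]]
                tr = tracks[ti]
                tr.frames.append(t)
                tr.area_series.append(m.area_px)
                tr.mass_series.append(m.dry_mass)
                tr.centroid_series.append(m.centroid)
                next_alive.append(ti)
        alive = next_alive
    min_len = math.ceil(min_length_fraction * n_frames)
    for tr in tracks:
        tr.complete = len(tr.frames) >= min_len
    return tracks


def classify_trajectory(track: Track, up: float = 1.2, down: float = 0.8) -> TrajectoryClass:
    """Classify by the median relative area over the final quarter of frames."""
    n = len(track.frames)
    if n < 4:
        raise ValueError(f"track too short to classify ({n} frames, need >= 4)")
    tail = max(1, math.ceil(n / 4))
    s = float(np.median(track.rel_area_series[-tail:]))
    if s >= up:
        return TrajectoryClass.INCREASE
    if s <= down:
        return TrajectoryClass.DECREASE
    return TrajectoryClass.NO_CHANGE


def cohort_summary(
    tracks: list[Track],
    classes: list[TrajectoryClass],
    mass_tol: float = 0.07,
) -> CohortSummary:
    """Class percentages, mass-stability fraction, and decrease/rest ratio.

    Only complete tracks contribute. The mass ratio compares mean *initial*
    measured mass of decrease-class cells against all other classes.
    """
    if len(tracks) != len(classes):
        raise ValueError("tracks and classes are not aligned")
    pairs = [(t, c) for t, c in zip(tracks, classes) if t.complete]
    if not pairs:
        raise ValueError("no complete tracks to summarise")
    n = len(pairs)
    fractions = {
        cls.value: 100.0 * sum(1 for _, c in pairs if c is cls) / n
        for cls in TrajectoryClass
    }
    stable = sum(1 for t, _ in pairs if t.rel_mass_change < mass_tol)
    dec = [t.mass_series[0] for t, c in pairs if c is TrajectoryClass.DECREASE]
    rest = [t.mass_series[0] for t, c in pairs if c is not TrajectoryClass.DECREASE]
    ratio = float(np.mean(dec) / np.mean(rest)) if dec and rest else float("nan")
    return CohortSummary(
        fractions=fractions,
        mass_stable_fraction=100.0 * stable / n,
        mass_tol=mass_tol,
        mass_ratio_decrease_vs_rest=ratio,
        n_complete=n,
    )
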