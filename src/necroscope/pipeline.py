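"""End-to-end orchestration of the synthetic analysis workflow.

This is the programmatic counterpart of the CLI: simulate a cohort, render
holograms, reconstruct phase, quantify, link and classify tracks, simulate
and gate flow-cytometry events, and compare morphology against cytometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cyto, phantoms, quant, recon, track

__all__ = ["EndToEndResult", "run_synthetic_timelapse", "measure_frame", "confusion_by_fate"]


@dataclass
class EndToEndResult:
    cohort: phantoms.Cohort
    per_frame_measures: list[list[quant.CellMeasure]]
    tracks: list[track.Track]
    classes: list[track.TrajectoryClass]
    summary: track.CohortSummary
    carrier_used: tuple[float, float] = phantoms.DEFAULT_CARRIER


def measure_frame(
    phase_values: np.ndarray,
    calib: quant.Calibration,
    seg: quant.SegmentationConfig,
    frame: int,
) -> list[quant.CellMeasure]:
    mask = quant.segment_cells(phase_values, seg)
    density = quant.phase_to_mass_density(phase_values, calib)
    return quant.measure_cells(mask, density, calib, frame=frame)


def run_synthetic_timelapse(
    spec: phantoms.PhantomSpec,
    carrier: tuple[float, float] = phantoms.DEFAULT_CARRIER,
    noise_sd: float | None = None,
    calib: quant.Calibration | None = None,
    seg: quant.SegmentationConfig | None = None,
    up: float = 1.2,
    down: float = 0.8,
    mass_tol: float = 0.07,
    max_disp: float = 20.0,
) -> EndToEndResult:
    """simulate -> render -> reconstruct -> quantify -> link -> classify.

    The hologram-noise stream is derived from ``spec.seed`` so the whole run
    is reproducible from the one master seed. The carrier fed to the
    reconstruction is estimated from the first frame, not taken from the
    generator.
    """
    calib = calib or quant.Calibration(pixel_size=spec.pixel_size)
    seg = seg or quant.SegmentationConfig(exclude_border=8)
    cohort = phantoms.simulate_timelapse_cohort(spec)
    noise_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xB10B]))

    per_frame: list[list[quant.CellMeasure]] = []
    est_carrier: tuple[float, float] | None = None
    for t in range(spec.n_frames):
        canvas = cohort.phase_frame(t)
        holo = phantoms.render_hologram(canvas, carrier=carrier, noise_sd=noise_sd, rng=noise_rng)
        if est_carrier is None:
            est_carrier = recon.estimate_carrier(holo.intensity)
        phase = recon.reconstruct(
            holo.intensity, carrier=est_carrier, pixel_size=spec.pixel_size
        )
        per_frame.append(measure_frame(phase.values, calib, seg, frame=t))

    tracks = track.link_tracks(per_frame, max_disp=max_disp)
    complete = [tr for tr in tracks if tr.complete]
    classes = [track.classify_trajectory(tr, up=up, down=down) for tr in complete]
    summary = track.cohort_summary(complete, classes, mass_tol=mass_tol)
    return EndToEndResult(
        cohort=cohort,
        per_frame_measures=per_frame,
        tracks=complete,
        classes=classes,
        summary=summary,
        carrier_used=est_carrier,
    )


def confusion_by_fate(result: EndToEndResult, max_match_dist: float = 25.0) -> pd.DataFrame:
    """Confusion table of ground-truth fate vs pipeline class.

    Tracks are matched to generator cells by first-frame centroid proximity.
    """
    truth0 = result.cohort.truth[result.cohort.truth["frame"] == 0]
    tc = truth0[["centroid_row", "centroid_col"]].to_numpy()
    fates = truth0["fate"].to_numpy()
    rows = []
    for tr, cls in zip(result.tracks, result.classes):
        c = np.asarray(tr.centroid_series[0])
        d = np.hypot(tc[:, 0] - c[0], tc[:, 1] - c[1])
        j = int(np.argmin(d))
        if d[j] <= max_match_dist:
            rows.append({"fate": fates[j], "predicted": cls.value})
    df = pd.DataFrame(rows)
    return pd.crosstab(df["fate"], df["predicted"]) if len(df) else pd.DataFrame()


def fcm_vs_morphology(
    summary: track.CohortSummary,
    events: pd.DataFrame,
    control: pd.DataFrame,
    percentile: float = 99.5,
    adjusted: bool = False,
    seed: int = 0,
) -> tuple[cyto.QuadrantCounts, cyto.SizeClassCounts, cyto.ContingencyResult]:
    """Gate events against the control and compare with the morphology row."""
    gates = cyto.fit_quadrant_gates(control, percentile=percentile)
    q = cyto.quadrant_counts(events, gates)
    back = None
    if adjusted:
        q4 = events[
            (events["FL1"] >= gates.annexin_cut) & (events["FL3"] < gates.pi_cut)
        ]
        back = cyto.backgate_fsc_split(q4, seed=seed)
    size = cyto.map_to_size_classes(q, back, adjusted=adjusted)
    n = summary.n_complete
    mhm_row = [
        round(summary.fractions["no_change"] * n / 100),
        round(summary.fractions["increase"] * n / 100),
        round(summary.fractions["decrease"] * n / 100),
    ]
    fcm_tot = size.no_change + size.increase + size.decrease
    fcm_row = [
        round(100 * size.no_change / fcm_tot),
        round(100 * size.increase / fcm_tot),
        round(100 * size.decrease / fcm_tot),
    ]
    result = cyto.chi2_compare(mhm_row, fcm_row)
    return q, size, result
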