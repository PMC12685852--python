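"""Temporal EA-curve assembly, peak detection and paired validation.

A 4D study is a sequence of labelled frames; running the per-frame geometry
pipeline over it yields the effective-area curve EA(t). The frame of
maximum EA is the maximum-opening (mid-diastolic) frame used for valve-area
measurement. Frames whose annulus cannot be analysed (missing label, ring
with an uncloseable gap) are logged as gaps rather than aborting the study.

`compare_measurements` provides the agreement statistics used to validate
pipeline areas against reference (e.g. clinical-report) values: Pearson
correlation and Bland-Altman mean difference with 95% limits of agreement,
optionally stratified at the median of the pair means.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import EmptyCurveError, MVQuantError, UndefinedCorrelationError
from .geometry import analyze_frame
from .types import EACurve, LabelVolume, ValidationStats

__all__ = [
    "compute_ea_curve",
    "detect_peak_frame",
    "summarize_curve",
    "compare_measurements",
]

log = logging.getLogger("mvquant.temporal")


def compute_ea_curve(
    frames: Sequence[LabelVolume],
    pixel_size_mm: float | None = None,
    tube_radius_mm: float = 1.5,
) -> EACurve:
    """Run the frame pipeline over a sequence and assemble the EA curve.

    Frames that fail with a pipeline error are skipped and recorded in
    ``curve.gaps``; at least one frame must succeed.
    """
    if len(frames) == 0:
        raise EmptyCurveError("no frames supplied")
    indices: list[int] = []
    measurements = []
    gaps: list[int] = []
    for k, frame in enumerate(frames):
        try:
            m = analyze_frame(
                frame, frame_index=k, pixel_size_mm=pixel_size_mm,
                tube_radius_mm=tube_radius_mm,
            )
        except MVQuantError as exc:
            log.warning("frame %d skipped: %s", k, exc)
            gaps.append(k)
            continue
        indices.append(k)
        measurements.append(m)
    if not indices:
        raise EmptyCurveError("no frame produced a valid measurement")
    ea = np.array([m.effective_area_mm2 for m in measurements])
    return EACurve(frame_indices=indices, ea_mm2=ea, measurements=measurements, gaps=gaps)


def detect_peak_frame(curve: EACurve) -> int:
    """Frame number with maximum EA; ties resolve to the earliest frame."""
    ea = curve.ea_mm2
    peak_pos = int(np.argmax(ea))
    if np.sum(ea == ea[peak_pos]) > 1:
        log.info("peak EA tie; keeping earliest frame %d", curve.frame_indices[peak_pos])
    return int(curve.frame_indices[peak_pos])


def summarize_curve(curve: EACurve) -> dict:
    """Cycle summary: mean/min/max EA, peak frame and frame count."""
    return {
        "n_frames": len(curve.frame_indices),
        "peak_frame": detect_peak_frame(curve),
        "ea_mean_mm2": curve.mean_mm2,
        "ea_min_mm2": curve.min_mm2,
        "ea_max_mm2": curve.max_mm2,
    }


def compare_measurements(
    reference: np.ndarray,
    predicted: np.ndarray,
    stratify: bool = True,
) -> ValidationStats:
    """Agreement between paired reference and predicted areas.

    Computes the Pearson correlation of the two series and a Bland-Altman
    analysis of the differences (predicted - reference): mean difference and
    95% limits of agreement mean +/- 1.96 * SD. With ``stratify`` the pairs
    are split at the median of the pair means and the mean difference is
    reported per stratum.
    """
    reference = np.asarray(reference, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if reference.shape != predicted.shape or reference.ndim != 1:
        raise ValueError("reference and predicted must be equal-length 1D series")
    n = len(reference)
    if n < 3:
        raise ValueError("need at least 3 pairs for correlation")
    if np.any(~np.isfinite(reference)) or np.any(~np.isfinite(predicted)):
        raise ValueError("missing or non-finite entries in the paired series")
    if np.std(reference) == 0 or np.std(predicted) == 0:
        raise UndefinedCorrelationError("zero variance in one of the series")

    r, p = stats.pearsonr(reference, predicted)
    diffs = predicted - reference
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    strata = None
    if stratify:
        means = (reference + predicted) / 2.0
        med = float(np.median(means))
        low = means < med
        high = ~low
        strata = {}
        for name, sel in (("low", low), ("high", high)):
            if np.any(sel):
                strata[name] = {
                    "n": int(sel.sum()),
                    "mean_difference": float(diffs[sel].mean()),
                }
        strata["median_of_means"] = {"value": med}
    return ValidationStats(
        n=n,
        pearson_r=float(r),
        p_value=float(p),
        mean_difference=mean_diff,
        sd_difference=sd_diff,
        loa_lower=mean_diff - 1.96 * sd_diff,
        loa_upper=mean_diff + 1.96 * sd_diff,
        strata=strata,
    )
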