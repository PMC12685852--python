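"""Annulus reconstruction from sparse manual control points.

A clinician marks a handful of points along the mitral annulus in 3D; this
module turns them into a volumetric label: a cubic B-spline is fitted
through the points (zero smoothing, so the curve interpolates every point),
evaluated at 100 equally spaced parameter values, a cylindrical tube of
1.5 mm radius is voxelized around the resulting polyline, and connected-
component post-processing keeps the single significant component with the
highest mean world z (atrial side up), removing spurious islands.

The annulus is treated as a *closed* periodic curve by default — the mitral
annulus is anatomically a ring — but open fitting is supported for partial
traces. Tube voxelization uses exact point-to-segment distances against the
sampled polyline, which is grid-independent and monotone in the radius.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import ndimage
from scipy.interpolate import splev, splprep

from .errors import CurveBoundsError, EmptyMaskError, SplineFitError
from .types import ANNULUS_LABEL, ControlPointSet, LabelVolume, SplineCurve

__all__ = [
    "fit_spline",
    "sample_spline",
    "voxelize_tube",
    "postprocess_components",
    "build_annulus_label",
]

log = logging.getLogger("mvquant.annulus")

#: Defaults of the reconstruction pipeline.
DEFAULT_TUBE_RADIUS_MM = 1.5
DEFAULT_N_SAMPLES = 100


class FittedSpline:
    """A fitted B-spline parameterization, evaluable on [0, 1]."""

    def __init__(self, tck, closed: bool):
        self._tck = tck
        self.closed = closed

    def evaluate(self, u: np.ndarray) -> np.ndarray:
        x, y, z = splev(np.asarray(u, dtype=float), self._tck)
        return np.column_stack([x, y, z])


def fit_spline(
    cps: ControlPointSet, smoothing: float = 0.0, closed: bool = True
) -> FittedSpline:
    """Fit a cubic 3D B-spline through ordered control points.

    With ``smoothing=0`` the spline interpolates every control point. Closed
    fits are periodic; the first point must not be repeated at the end.
    """
    pts = np.asarray(cps.points, dtype=float)
    if len(pts) < 4:
        raise SplineFitError(f"need >= 4 control points, got {len(pts)}")
    step = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(step < 1e-9):
        raise SplineFitError("duplicate consecutive control points")
    if smoothing < 0:
        raise ValueError("smoothing must be non-negative")
    with warnings.catch_warnings():
        warnings.simplefilter("error")  # splprep signals bad fits via warnings
        try:
            tck, _ = splprep(pts.T, s=smoothing, per=int(closed), k=3)
        except Exception as exc:  # noqa: BLE001 - scipy raises various types
            raise SplineFitError(f"B-spline fit failed: {exc}") from exc
    return FittedSpline(tck, closed)


def sample_spline(curve: FittedSpline, n_samples: int = DEFAULT_N_SAMPLES) -> SplineCurve:
    """Evaluate the spline at ``n_samples`` equally spaced parameter values."""
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    u = np.linspace(0.0, 1.0, n_samples)
    return SplineCurve(sample_points=curve.evaluate(u), closed=curve.closed)


def _segments(curve: SplineCurve) -> tuple[np.ndarray, np.ndarray]:
    """Polyline segments (start, end), closing the loop if needed and
    dropping degenerate zero-length segments."""
    pts = curve.sample_points
    a, b = pts[:-1], pts[1:]
    if curve.closed and np.linalg.norm(pts[-1] - pts[0]) > 1e-9:
        a = np.vstack([a, pts[-1]])
        b = np.vstack([b, pts[0]])
    keep = np.linalg.norm(b - a, axis=1) > 1e-12
    return a[keep], b[keep]


def voxelize_tube(
    curve: SplineCurve,
    radius_mm: float = DEFAULT_TUBE_RADIUS_MM,
    template: LabelVolume = None,
) -> np.ndarray:
    """Binary mask of voxels whose center lies within ``radius_mm`` of the
    sampled polyline, on the template grid.

    Uses exact point-to-segment distances, restricted to the bounding box of
    the curve dilated by the radius.
    """
    if template is None:
        raise ValueError("a template LabelVolume is required")
    if radius_mm <= 0:
        raise ValueError("tube radius must be positive")
    pts = curve.sample_points
    idx = template.world_to_index(pts)
    shape = np.asarray(template.shape)
    if np.any(idx < -0.5) or np.any(idx >= shape - 0.5):
        raise CurveBoundsError("curve leaves the world bounds of the template volume")
    if radius_mm < max(template.spacing) / 2.0:
        warnings.warn(
            "tube radius below half the voxel spacing; the voxelized tube "
            "may be disconnected",
            stacklevel=2,
        )

    pad = radius_mm / min(template.spacing) + 1.0
    lo = np.maximum(np.floor(idx.min(axis=0) - pad).astype(int), 0)
    hi = np.minimum(np.ceil(idx.max(axis=0) + pad).astype(int) + 1, shape)
    grids = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij")
    box_idx = np.column_stack([g.ravel() for g in grids])
    centers = template.index_to_world(box_idx)

    a, b = _segments(curve)
    ab = b - a
    ab_len2 = (ab * ab).sum(axis=1)
    dmin = np.full(len(centers), np.inf)
    for i in range(len(a)):
        t = np.clip(((centers - a[i]) @ ab[i]) / ab_len2[i], 0.0, 1.0)
        proj = a[i] + t[:, None] * ab[i]
        d = np.linalg.norm(centers - proj, axis=1)
        np.minimum(dmin, d, out=dmin)

    mask = np.zeros(template.shape, dtype=bool)
    inside = dmin <= radius_mm
    sel = box_idx[inside]
    mask[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    if not mask.any():
        raise EmptyMaskError("voxelized tube is empty on this grid")
    return mask


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def postprocess_components(
    mask: np.ndarray, spacing=None, affine: np.ndarray | None = None
) -> np.ndarray:
    """Keep exactly one connected component of a binary mask.

    Among 26-connected components whose voxel count is at least 25% of the
    largest, the component with the highest mean world z-coordinate (atrial
    side) is retained; everything else is removed.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise EmptyMaskError("cannot post-process an empty mask")
    labeled, n = ndimage.label(mask, structure=_CONN26)
    if n == 1:
        return mask
    sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1))
    gate = sizes >= 0.25 * sizes.max()
    candidates = np.flatnonzero(gate) + 1
    best, best_z = None, -np.inf
    for comp in candidates:
        idx = np.argwhere(labeled == comp)
        if affine is not None:
            z = float((idx @ affine[:3, :3].T + affine[:3, 3])[:, 2].mean())
        elif spacing is not None:
            z = float(idx[:, 2].mean() * spacing[2])
        else:
            z = float(idx[:, 2].mean())
        log.debug("component %d: %d voxels, mean z %.2f", comp, len(idx), z)
        if z > best_z:
            best, best_z = comp, z
    log.info(
        "postprocess: kept component %s of %d (size gate passed by %d)",
        best, n, len(candidates),
    )
    return labeled == best


def build_annulus_label(
    cps: ControlPointSet,
    template: LabelVolume,
    radius_mm: float = DEFAULT_TUBE_RADIUS_MM,
    n_samples: int = DEFAULT_N_SAMPLES,
    smoothing: float = 0.0,
    closed: bool = True,
) -> LabelVolume:
    """Full reconstruction: fit, sample, voxelize, post-process, compose.

    The annulus is written as label 3 into a copy of the template. Existing
    leaflet labels (1, 2) win where the tube overlaps them: the tube radius
    is a modelling artifact while the leaflets are the thin structures of
    interest.
    """
    spline = fit_spline(cps, smoothing=smoothing, closed=closed)
    curve = sample_spline(spline, n_samples)
    mask = voxelize_tube(curve, radius_mm, template)
    mask = postprocess_components(mask, affine=template.affine)
    out = template.copy()
    writable = mask & ~np.isin(out.voxels, (1, 2))
    out.voxels[writable] = ANNULUS_LABEL
    out.label_legend.setdefault(ANNULUS_LABEL, "annulus")
    return out
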