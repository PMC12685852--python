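"""Analytic 4D mitral-valve label phantoms.

The phantom emulates the structures a labelled trans-esophageal echo (TEE)
frame carries: a saddle-shaped annulus ring (label 3) modelled as a tube of
radius ``tube_radius_mm`` around the closed curve

    c(phi) = (R cos phi, R sin phi, h cos 2phi),

two thin leaflet sheets (labels 1 anterior / 2 posterior) spanning from the
annulus inward to a frame-dependent orifice radius, and background (0).
The cos(2*phi) height modulation gives the textbook saddle with two high and
two low points. Leaflets bow toward the ventricle: their surface is offset
below the annular saddle by a linearly increasing "droop" so the sheets
attach near the ring without being swallowed by the tube label.

The orifice radius follows a smooth cosine opening schedule

    r(k) = r_min + (r_max - r_min) * (1 - cos(2 pi k / n_frames)) / 2,

so the analytic effective orifice area per frame is pi * r(k)^2 and the
maximum opening falls at mid-cycle. The whole object can be rigidly tilted
relative to the grid axes, which exercises the projection stage's handling
of oblique valve planes.

Everything about the phantom is known in closed form (valve plane, EA per
frame, peak frame, annulus centerline), so each downstream stage can be
tested against analytic truth without any image data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import PhantomSizeError, SplineFitError
from .types import ControlPointSet, LabelVolume, DEFAULT_LEGEND

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "orifice_radius",
    "make_phantom_frame",
    "make_phantom_sequence",
    "make_annulus_control_points",
    "save_phantom",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric and grid parameters of the valve phantom.

    Defaults describe a normal-sized adult mitral valve: annulus radius
    14 mm, 2 mm saddle height, 1.5 mm annulus tube, orifice opening from
    2 mm to 10 mm over 16 frames, on a 96^3 grid at 0.5 mm isotropic
    spacing.
    """

    annulus_radius_mm: float = 14.0
    saddle_height_mm: float = 2.0
    tube_radius_mm: float = 1.5
    orifice_radius_min_mm: float = 2.0
    orifice_radius_max_mm: float = 10.0
    n_frames: int = 16
    voxel_spacing_mm: tuple[float, float, float] = (0.5, 0.5, 0.5)
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    tilt_deg: float = 0.0
    leaflet_thickness_mm: float = 1.0
    #: vertical offset of the leaflet belly below the annular saddle at the
    #: ring; keeps the sheets clear of the tube label. None -> tube + thickness.
    leaflet_droop_mm: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (
            0.0
            < self.orifice_radius_min_mm
            < self.orifice_radius_max_mm
            < self.annulus_radius_mm
        ):
            raise ValueError(
                "require 0 < orifice_radius_min < orifice_radius_max < annulus_radius"
            )
        if self.tube_radius_mm <= 0 or self.annulus_radius_mm <= 0:
            raise ValueError("radii must be positive")
        if self.saddle_height_mm < 0:
            raise ValueError("saddle height must be non-negative")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacings must be positive")
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid too coarse to host a phantom")

    @property
    def droop_mm(self) -> float:
        if self.leaflet_droop_mm is not None:
            return self.leaflet_droop_mm
        return self.tube_radius_mm + self.leaflet_thickness_mm

    def tilt_matrix(self) -> np.ndarray:
        """World rotation applied to the valve (about the first grid axis)."""
        t = np.deg2rad(self.tilt_deg)
        c, s = np.cos(t), np.sin(t)
        return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])

    def affine(self) -> np.ndarray:
        """Grid affine: axis-aligned spacing, world origin at grid center."""
        sp = np.asarray(self.voxel_spacing_mm, dtype=float)
        shape = np.asarray(self.grid_shape, dtype=float)
        aff = np.eye(4)
        aff[:3, :3] = np.diag(sp)
        aff[:3, 3] = -(shape - 1.0) / 2.0 * sp
        return aff

    def check_fits(self) -> None:
        """Raise :class:`PhantomSizeError` unless the tilted phantom fits
        inside the grid with at least a two-voxel margin."""
        a, h = self.tube_radius_mm, self.saddle_height_mm
        below = self.droop_mm + self.leaflet_thickness_mm / 2.0
        r_bound = float(
            np.hypot(self.annulus_radius_mm + a, max(h + a, h + below))
        )
        sp = np.asarray(self.voxel_spacing_mm)
        half_extent = np.asarray(self.grid_shape) * sp / 2.0
        if np.any(r_bound + 2.0 * sp > half_extent):
            raise PhantomSizeError(
                f"phantom bounding radius {r_bound:.1f} mm + 2-voxel margin "
                f"exceeds grid half-extent {half_extent.min():.1f} mm"
            )


@dataclass
class PhantomTruth:
    """Analytic ground truth accompanying a phantom sequence."""

    plane_normal: np.ndarray
    plane_point: np.ndarray
    ea_per_frame_mm2: np.ndarray
    peak_frame: int
    annulus_centerline: np.ndarray  # (M, 3) ordered world points
    orifice_radii_mm: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.plane_normal = np.asarray(self.plane_normal, dtype=float)
        self.plane_point = np.asarray(self.plane_point, dtype=float)
        self.ea_per_frame_mm2 = np.asarray(self.ea_per_frame_mm2, dtype=float)
        self.annulus_centerline = np.asarray(self.annulus_centerline, dtype=float)


def orifice_radius(spec: PhantomSpec, frame_index: int) -> float:
    """Orifice radius r(k) of the cosine opening schedule, in mm."""
    k = frame_index
    r0, r1 = spec.orifice_radius_min_mm, spec.orifice_radius_max_mm
    return float(r0 + (r1 - r0) * (1.0 - np.cos(2.0 * np.pi * k / spec.n_frames)) / 2.0)


def _annulus_curve(spec: PhantomSpec, phi: np.ndarray) -> np.ndarray:
    """Saddle annulus curve in the (untilted) valve frame."""
    R, h = spec.annulus_radius_mm, spec.saddle_height_mm
    return np.column_stack([R * np.cos(phi), R * np.sin(phi), h * np.cos(2.0 * phi)])


def _valve_frame_coords(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-center coordinates expressed in the untilted valve frame."""
    aff = spec.affine()
    rot = spec.tilt_matrix()
    nx, ny, nz = spec.grid_shape
    sp = np.asarray(spec.voxel_spacing_mm)
    origin = aff[:3, 3]
    xw = (origin[0] + np.arange(nx) * sp[0])[:, None, None]
    yw = (origin[1] + np.arange(ny) * sp[1])[None, :, None]
    zw = (origin[2] + np.arange(nz) * sp[2])[None, None, :]
    # valve coords p_v = rot^T p_w; rot mixes only the (y, z) world axes
    c, s = rot[1, 1], rot[2, 1]
    xv = np.broadcast_to(xw, (nx, ny, nz))
    yv = c * yw + s * zw
    zv = -s * yw + c * zw
    return xv, np.broadcast_to(yv, (nx, ny, nz)), np.broadcast_to(zv, (nx, ny, nz))


def make_phantom_frame(spec: PhantomSpec, frame_index: int) -> LabelVolume:
    """Voxelize one cardiac frame of the phantom.

    Labels: 0 background, 1 anterior leaflet (phi in [0, pi)), 2 posterior
    leaflet, 3 annulus tube. The annulus takes precedence where the leaflet
    attachment grazes the tube.
    """
    if not 0 <= frame_index < spec.n_frames:
        raise ValueError(f"frame_index {frame_index} outside [0, {spec.n_frames})")
    spec.check_fits()

    R, a, h = spec.annulus_radius_mm, spec.tube_radius_mm, spec.saddle_height_mm
    r_t = orifice_radius(spec, frame_index)
    thick = spec.leaflet_thickness_mm
    droop = spec.droop_mm

    xv, yv, zv = _valve_frame_coords(spec)
    rho = np.hypot(xv, yv)

    labels = np.zeros(spec.grid_shape, dtype=np.uint8)

    # leaflet sheets: a graph z = surface(rho, theta) over the annular band
    band = (rho >= r_t) & (rho <= R)
    if np.any(band):
        w = (rho - r_t) / max(R - r_t, 1e-9)
        cos2t = np.where(rho > 1e-9, (xv * xv - yv * yv) / np.maximum(rho * rho, 1e-18), 1.0)
        surface = (h * cos2t - droop) * w
        leaf = band & (np.abs(zv - surface) <= thick / 2.0)
        labels[leaf & (yv >= 0.0)] = 1
        labels[leaf & (yv < 0.0)] = 2

    # annulus tube: voxels within tube_radius of the saddle curve
    cand = (np.abs(rho - R) <= a + 0.05) & (np.abs(zv) <= h + a + 0.05)
    idx = np.argwhere(cand)
    if len(idx):
        pts = np.column_stack([xv[cand], yv[cand], zv[cand]])
        n_curve = max(1024, int(8 * np.pi * R / min(spec.voxel_spacing_mm)))
        phi = np.linspace(0.0, 2.0 * np.pi, n_curve, endpoint=False)
        tree = cKDTree(_annulus_curve(spec, phi))
        d, _ = tree.query(pts, workers=-1)
        inside = d <= a
        labels[idx[inside, 0], idx[inside, 1], idx[inside, 2]] = 3

    return LabelVolume(labels, spec.affine(), dict(DEFAULT_LEGEND))


def make_phantom_sequence(spec: PhantomSpec) -> tuple[list[LabelVolume], PhantomTruth]:
    """Generate all frames plus the analytic truth record."""
    frames = [make_phantom_frame(spec, k) for k in range(spec.n_frames)]
    radii = np.array([orifice_radius(spec, k) for k in range(spec.n_frames)])
    ea = np.pi * radii**2
    rot = spec.tilt_matrix()
    phi = np.linspace(0.0, 2.0 * np.pi, 256, endpoint=False)
    centerline = _annulus_curve(spec, phi) @ rot.T
    truth = PhantomTruth(
        plane_normal=rot @ np.array([0.0, 0.0, 1.0]),
        plane_point=np.zeros(3),
        ea_per_frame_mm2=ea,
        peak_frame=int(np.argmax(radii)),
        annulus_centerline=centerline,
        orifice_radii_mm=radii,
    )
    return frames, truth


def make_annulus_control_points(spec: PhantomSpec, n_points: int = 12) -> ControlPointSet:
    """Sample sparse control points on the analytic saddle annulus curve.

    Points are ordered by angle, exactly as a clinician would place them
    walking around the ring.
    """
    if n_points < 4:
        raise SplineFitError("at least 4 control points are required for a spline fit")
    phi = 2.0 * np.pi * np.arange(n_points) / n_points
    pts = _annulus_curve(spec, phi) @ spec.tilt_matrix().T
    return ControlPointSet(points=pts, frame_of_reference="LPS")


def save_phantom(spec: PhantomSpec, out_dir: str | Path, n_control_points: int = 12):
    """Write a phantom to disk: per-frame NIfTI volumes, one 4D NIfTI,
    a Slicer markups file with annulus control points, and a truth sidecar.

    Returns the (frames, truth) pair for convenience.
    """
    from . import io as mvio  # local import to avoid a cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames, truth = make_phantom_sequence(spec)
    for k, frame in enumerate(frames):
        mvio.write_label_volume(frame, out / f"frame_{k:03d}.nii.gz")
    mvio.write_label_sequence(frames, out / "sequence_4d.nii.gz")
    cps = make_annulus_control_points(spec, n_control_points)
    mvio.write_markups(cps, out / "annulus.mrk.json")
    sidecar = {
        "spec": asdict(spec),
        "truth": {
            "plane_normal": truth.plane_normal.tolist(),
            "plane_point": truth.plane_point.tolist(),
            "ea_per_frame_mm2": truth.ea_per_frame_mm2.tolist(),
            "peak_frame": truth.peak_frame,
            "orifice_radii_mm": truth.orifice_radii_mm.tolist(),
            "annulus_centerline": truth.annulus_centerline.tolist(),
        },
    }
    (out / "truth.json").write_text(json.dumps(sidecar, indent=2))
    return frames, truth
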