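"""Core in-memory containers shared across the pipeline.

All world coordinates are millimetres. A :class:`LabelVolume` owns a 3D
integer grid together with a 4x4 affine mapping voxel index -> world mm;
every downstream measurement is carried out in world space so voxel indices
never leak into areas or distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MetadataError

#: Default legend for valve label volumes.
DEFAULT_LEGEND: dict[int, str] = {
    1: "anterior_leaflet",
    2: "posterior_leaflet",
    3: "annulus",
}

ANNULUS_LABEL = 3


@dataclass
class LabelVolume:
    """A single cardiac frame: integer labels on a regular grid.

    Parameters
    ----------
    voxels : (nx, ny, nz) integer array
        Label values; 0 is background.
    affine : (4, 4) array
        Maps homogeneous voxel indices to world coordinates in mm.
    label_legend : dict
        Names for the nonzero labels.
    """

    voxels: np.ndarray
    affine: np.ndarray
    label_legend: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LEGEND))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {self.voxels.shape}")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("label volume must have an integer dtype")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise MetadataError("affine is singular; voxel spacing undefined")
        if np.any(self.spacing <= 0):
            raise MetadataError("voxel spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel spacing in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices (may be fractional) to world mm."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        inv = np.linalg.inv(self.affine[:3, :3])
        return (pts - self.affine[:3, 3]) @ inv.T

    def world_coords(self, mask: np.ndarray) -> np.ndarray:
        """World coordinates of the centers of voxels where ``mask`` is set."""
        return self.index_to_world(np.argwhere(mask))

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.voxels.copy(), self.affine.copy(), dict(self.label_legend))


@dataclass
class ControlPointSet:
    """Ordered sparse annulus control points in world mm."""

    points: np.ndarray  # (N, 3)
    frame_of_reference: str = "LPS"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("control points must be an (N, 3) array")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class SplineCurve:
    """Dense evaluation of a fitted curve."""

    sample_points: np.ndarray  # (N, 3) world mm
    closed: bool

    def __post_init__(self) -> None:
        self.sample_points = np.asarray(self.sample_points, dtype=float)

    @property
    def polyline_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.sample_points, axis=0), axis=1).sum())


@dataclass
class CenterlinePath:
    """Spatially ordered annulus centerline."""

    points: np.ndarray  # (N, 3) world mm
    closed: bool
    n_backtracks: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)


@dataclass
class ValvePlane:
    """Best-fit valve plane: centroid, unit normal and in-plane basis."""

    centroid: np.ndarray
    normal: np.ndarray
    basis_u: np.ndarray
    basis_v: np.ndarray

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        self.basis_u = np.asarray(self.basis_u, dtype=float)
        self.basis_v = np.asarray(self.basis_v, dtype=float)

    def to_plane_coords(self, pts: np.ndarray) -> np.ndarray:
        """Orthogonally project points; return (N, 2) in-plane coordinates."""
        d = np.atleast_2d(pts) - self.centroid
        return np.column_stack([d @ self.basis_u, d @ self.basis_v])


@dataclass
class PlanarProjection:
    """Calibrated 2D rasters of structures projected onto the valve plane."""

    rasters: dict[str, np.ndarray]  # name -> 2D bool
    pixel_size_mm: tuple[float, float]
    origin_2d: np.ndarray  # (2,) plane coordinates of pixel (0, 0) corner

    @property
    def pixel_area_mm2(self) -> float:
        return float(self.pixel_size_mm[0] * self.pixel_size_mm[1])

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.rasters.values())).shape  # type: ignore[return-value]


@dataclass
class AreaMeasurement:
    """Calibrated areas for one frame."""

    frame_index: int
    structure_areas_mm2: dict[str, float]
    effective_area_mm2: float


@dataclass
class EACurve:
    """Effective-area series across a cardiac cycle.

    ``frame_indices`` are the original frame numbers of the *successful*
    frames; failed frames are recorded in ``gaps``.
    """

    frame_indices: list[int]
    ea_mm2: np.ndarray
    measurements: list[AreaMeasurement] = field(default_factory=list)
    gaps: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ea_mm2 = np.asarray(self.ea_mm2, dtype=float)
        if len(self.frame_indices) != len(self.ea_mm2):
            raise ValueError("one EA value per frame required")
        if len(self.frame_indices) == 0:
            raise ValueError("EA curve must cover at least one frame")
        if np.any(np.diff(self.frame_indices) <= 0):
            raise ValueError("frame indices must be strictly increasing")

    @property
    def peak_frame(self) -> int:
        """Frame number of maximum EA (earliest frame on ties)."""
        return int(self.frame_indices[int(np.argmax(self.ea_mm2))])

    @property
    def max_mm2(self) -> float:
        return float(self.ea_mm2.max())

    @property
    def min_mm2(self) -> float:
        return float(self.ea_mm2.min())

    @property
    def mean_mm2(self) -> float:
        return float(self.ea_mm2.mean())


@dataclass
class ValidationStats:
    """Paired-measurement agreement: Pearson r and Bland-Altman limits."""

    n: int
    pearson_r: float
    p_value: float
    mean_difference: float
    sd_difference: float
    loa_lower: float
    loa_upper: float
    strata: dict[str, dict[str, float]] | None = None

    def as_dict(self) -> dict:
        out = {
            "n": self.n,
            "pearson_r": self.pearson_r,
            "p_value": self.p_value,
            "mean_difference": self.mean_difference,
            "sd_difference": self.sd_difference,
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
        }
        if self.strata is not None:
            out["strata"] = self.strata
        return out
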