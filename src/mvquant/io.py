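"""Readers and writers for the formats the pipeline touches.

NIfTI is first-class (via nibabel); NRRD is supported through SimpleITK.
Annulus control points travel as 3D Slicer markups JSON, accepting both the
current ``"position"`` and legacy ``"Position"`` key dialects. Measurements
are written as a per-frame CSV plus a JSON summary that validates against
the shipped schema. All loaded volumes carry world-mm affines; voxel
indices never appear in measurement outputs.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from importlib import resources
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .errors import MetadataError, VolumeFormatError
from .types import (
    AreaMeasurement,
    ControlPointSet,
    DEFAULT_LEGEND,
    EACurve,
    LabelVolume,
)

__all__ = [
    "read_label_volume",
    "write_label_volume",
    "read_label_sequence",
    "write_label_sequence",
    "read_markups",
    "write_markups",
    "write_measurements",
    "read_pairs_csv",
    "validate_summary",
]

log = logging.getLogger("mvquant.io")

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def _as_int_labels(data: np.ndarray) -> np.ndarray:
    if np.issubdtype(data.dtype, np.integer):
        return data
    rounded = np.rint(data)
    if not np.allclose(data, rounded, atol=1e-6):
        raise VolumeFormatError("volume has non-integer label values")
    return rounded.astype(np.int16)


def _sitk_to_affine(img: sitk.Image) -> np.ndarray:
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    spacing = np.asarray(img.GetSpacing(), dtype=float)
    origin = np.asarray(img.GetOrigin(), dtype=float)
    aff = np.eye(4)
    aff[:3, :3] = direction @ np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def read_label_volume(path: str | Path, legend: dict[int, str] | None = None) -> LabelVolume:
    """Load a 3D integer label volume (NIfTI or NRRD) with its affine.

    Labels absent from the legend are reported with a warning but kept.
    """
    path = Path(path)
    legend = dict(DEFAULT_LEGEND) if legend is None else dict(legend)
    if _is_nifti(path):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        affine = np.asarray(img.affine, dtype=float)
    elif path.suffix.lower() == ".nrrd":
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # zyx -> xyz
        affine = _sitk_to_affine(img)
    else:
        raise VolumeFormatError(f"unsupported volume format: {path.name}")
    if data.ndim != 3:
        raise VolumeFormatError(f"expected a 3D volume, got {data.ndim}D")
    data = _as_int_labels(data)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise MetadataError(f"{path.name}: affine is singular, spacing metadata unusable")
    vol = LabelVolume(np.ascontiguousarray(data), affine, legend)
    stray = sorted(set(np.unique(data).tolist()) - {0} - set(legend))
    if stray:
        warnings.warn(f"{path.name}: labels outside the legend: {stray}", stacklevel=2)
    return vol


def write_label_volume(vol: LabelVolume, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        img = nib.Nifti1Image(vol.voxels.astype(np.uint8), vol.affine)
        nib.save(img, str(path))
    elif path.suffix.lower() == ".nrrd":
        img = sitk.GetImageFromArray(vol.voxels.astype(np.uint8).transpose(2, 1, 0))
        A = vol.affine
        spacing = np.linalg.norm(A[:3, :3], axis=0)
        img.SetSpacing(tuple(spacing))
        img.SetDirection(tuple((A[:3, :3] / spacing).ravel()))
        img.SetOrigin(tuple(A[:3, 3]))
        sitk.WriteImage(img, str(path))
    else:
        raise VolumeFormatError(f"unsupported volume format: {path.name}")
    return path


def read_label_sequence(path: str | Path, legend: dict[int, str] | None = None) -> list[LabelVolume]:
    """Load a 4D study: either one 4D NIfTI or a directory of 3D frames.

    Directory frames are taken in lexicographic filename order.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir()
            if _is_nifti(p) or p.suffix.lower() == ".nrrd"
        )
        frames = []
        for p in files:
            try:
                frames.append(read_label_volume(p, legend))
            except VolumeFormatError as exc:
                log.warning("skipping %s: %s", p.name, exc)
        if not frames:
            raise VolumeFormatError(f"no 3D label volumes found in directory {path}")
        return frames
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 3:
        return [read_label_volume(path, legend)]
    if data.ndim != 4:
        raise VolumeFormatError(f"expected 3D or 4D data, got {data.ndim}D")
    data = _as_int_labels(data)
    legend = dict(DEFAULT_LEGEND) if legend is None else dict(legend)
    return [
        LabelVolume(np.ascontiguousarray(data[..., t]), np.asarray(img.affine), dict(legend))
        for t in range(data.shape[3])
    ]


def write_label_sequence(frames: Sequence[LabelVolume], path: str | Path) -> Path:
    """Write frames as a single 4D NIfTI (shared affine required)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    for f in frames[1:]:
        if not np.allclose(f.affine, frames[0].affine):
            raise ValueError("frames of a 4D sequence must share one affine")
    stack = np.stack([f.voxels.astype(np.uint8) for f in frames], axis=-1)
    nib.save(nib.Nifti1Image(stack, frames[0].affine), str(path))
    return path


# ---------------------------------------------------------------------------
# Slicer markups


def read_markups(path: str | Path, coords: str | None = None) -> ControlPointSet:
    """Parse annulus control points from a 3D Slicer markups JSON file.

    Accepts both ``"position"`` and legacy ``"Position"`` control-point
    keys. ``coords`` overrides the coordinate-convention tag stored in the
    file (the convention is carried as a label, not converted).
    """
    path = Path(path)
    data = json.loads(path.read_text())
    try:
        markup = data["markups"][0]
        raw_points = markup["controlPoints"]
    except (KeyError, IndexError, TypeError) as exc:
        raise VolumeFormatError(f"{path.name}: not a valid markups file") from exc
    pts = []
    for cp in raw_points:
        pos = cp.get("position", cp.get("Position"))
        if pos is None or len(pos) != 3:
            raise VolumeFormatError(f"{path.name}: control point without a position")
        pts.append([float(x) for x in pos])
    if len(pts) < 4:
        raise VolumeFormatError(
            f"{path.name}: {len(pts)} control points; at least 4 required"
        )
    tag = coords or markup.get("coordinateSystem", "LPS")
    return ControlPointSet(points=np.asarray(pts), frame_of_reference=str(tag))


def write_markups(cps: ControlPointSet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "@schema": "https://raw.githubusercontent.com/slicer/slicer/master/Modules/Loadable/Markups/Resources/Schema/markups-schema-v1.0.3.json#",
        "markups": [
            {
                "type": "ClosedCurve",
                "coordinateSystem": cps.frame_of_reference,
                "controlPoints": [
                    {
                        "id": str(i + 1),
                        "label": f"A-{i + 1}",
                        "position": [float(x) for x in p],
                    }
                    for i, p in enumerate(cps.points)
                ],
            }
        ],
    }
    path.write_text(json.dumps(doc, indent=2))
    return path


# ---------------------------------------------------------------------------
# Measurements

_CSV_COLUMNS = ("frame", "anterior_mm2", "posterior_mm2", "annulus_mm2", "ea_mm2")


def write_measurements(
    measurements: Sequence[AreaMeasurement],
    curve: EACurve,
    csv_path: str | Path,
    summary_path: str | Path | None = None,
) -> dict:
    """Write one CSV row per frame plus a JSON cycle summary.

    Output is deterministic: fixed column order and fixed float formatting,
    so identical inputs produce byte-identical files.
    """
    if not measurements:
        raise ValueError("no measurements to write")
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    with csv_path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for m in measurements:
            areas = m.structure_areas_mm2
            writer.writerow(
                [
                    m.frame_index,
                    f"{areas.get('anterior_leaflet', 0.0):.6f}",
                    f"{areas.get('posterior_leaflet', 0.0):.6f}",
                    f"{areas.get('annulus', 0.0):.6f}",
                    f"{m.effective_area_mm2:.6f}",
                ]
            )
    from .temporal import summarize_curve

    summary = summarize_curve(curve)
    validate_summary(summary)
    if summary_path is not None:
        Path(summary_path).write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def read_pairs_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a paired-measurement CSV with columns reference, predicted."""
    import pandas as pd

    df = pd.read_csv(path)
    missing = {"reference", "predicted"} - set(df.columns)
    if missing:
        raise ValueError(f"pairs CSV lacks columns: {sorted(missing)}")
    return df["reference"].to_numpy(float), df["predicted"].to_numpy(float)


def validate_summary(summary: dict) -> None:
    """Check a cycle summary against the shipped schema (required keys and
    primitive types; a deliberately small validator)."""
    schema = json.loads(
        resources.files("mvquant.data").joinpath("measurement_summary.schema.json").read_text()
    )
    for key in schema["required"]:
        if key not in summary:
            raise ValueError(f"summary missing required key {key!r}")
    type_map = {"integer": (int, np.integer), "number": (int, float, np.floating, np.integer)}
    for key, spec in schema["properties"].items():
        if key in summary and not isinstance(summary[key], type_map[spec["type"]]):
            raise ValueError(f"summary key {key!r} has wrong type")
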