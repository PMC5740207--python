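"""Readers and writers for pipeline artifacts.

NIfTI is the primary image container (one 2-D file per slice, or a 3-D stack
with the TI axis last for image series, with a JSON sidecar of inversion
times). Plain delimited-text matrices are supported as a secondary,
inspection-friendly format. Geometry and reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import T1Map
from .scar_quant import LVGeometry


def _affine(pixel_spacing: float, slice_thickness: float) -> np.ndarray:
    return np.diag([pixel_spacing, pixel_spacing, slice_thickness, 1.0])


def save_t1_map(path, t1map: T1Map) -> None:
    """Write a T1 map as NIfTI plus a ``<stem>.json`` metadata sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(
        t1map.values[:, :, None].astype(np.float64),
        _affine(t1map.pixel_spacing, t1map.slice_thickness),
    )
    nib.save(img, path)
    meta = {
        "pixel_spacing_mm": t1map.pixel_spacing,
        "slice_thickness_mm": t1map.slice_thickness,
        "slice_level": t1map.slice_level,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def _sidecar(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def load_t1_map(path) -> T1Map:
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
    meta = json.loads(_sidecar(path).read_text())
    return T1Map(
        data,
        pixel_spacing=meta["pixel_spacing_mm"],
        slice_thickness=meta["slice_thickness_mm"],
        slice_level=meta["slice_level"],
    )


def save_series(path, images: np.ndarray, tis: np.ndarray, pixel_spacing: float,
                slice_thickness: float) -> None:
    """Write an image series as a 3-D NIfTI (TI axis last) + TI JSON sidecar."""
    path = Path(path)
    stack = np.moveaxis(np.asarray(images, dtype=np.float64), 0, -1)
    nib.save(nib.Nifti1Image(stack, _affine(pixel_spacing, slice_thickness)), path)
    _sidecar(path).write_text(
        json.dumps({"tis_ms": [float(t) for t in tis]}, indent=2)
    )


def load_series(path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    img = nib.load(path)
    stack = np.asarray(img.dataobj, dtype=float)
    images = np.moveaxis(stack, -1, 0)
    tis = np.array(json.loads(_sidecar(path).read_text())["tis_ms"])
    return images, tis


def save_mask(path, mask: np.ndarray, pixel_spacing: float, slice_thickness: float) -> None:
    nib.save(
        nib.Nifti1Image(
            mask[:, :, None].astype(np.uint8), _affine(pixel_spacing, slice_thickness)
        ),
        Path(path),
    )


def load_mask(path) -> np.ndarray:
    data = np.asarray(nib.load(Path(path)).dataobj)
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
    return data.astype(bool)


def save_matrix_txt(path, values: np.ndarray) -> None:
    """Secondary plain-text matrix format (tab-delimited)."""
    np.savetxt(Path(path), np.asarray(values, dtype=float), delimiter="\t", fmt="%.6g")


def load_matrix_txt(path) -> np.ndarray:
    return np.loadtxt(Path(path), delimiter="\t", ndmin=2)


def save_geometry(path, geometry: LVGeometry) -> None:
    payload = {
        "endo_contour": geometry.endo_contour.tolist(),
        "epi_contour": geometry.epi_contour.tolist(),
        "reference_point": list(geometry.reference_point),
        "slice_level": geometry.slice_level,
        "pixel_spacing_mm": geometry.pixel_spacing,
        "slice_thickness_mm": geometry.slice_thickness,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_geometry(path) -> LVGeometry:
    d = json.loads(Path(path).read_text())
    return LVGeometry(
        endo_contour=np.array(d["endo_contour"]),
        epi_contour=np.array(d["epi_contour"]),
        reference_point=tuple(d["reference_point"]),
        slice_level=d["slice_level"],
        pixel_spacing=d["pixel_spacing_mm"],
        slice_thickness=d["slice_thickness_mm"],
    )


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _to_jsonable(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def save_report(path, report: dict) -> None:
    """Deterministic JSON report (sorted keys, NaN/inf mapped to null)."""
    Path(path).write_text(json.dumps(_to_jsonable(report), indent=2, sort_keys=True) + "\n")


def load_report(path) -> dict:
    return json.loads(Path(path).read_text())
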