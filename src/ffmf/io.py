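"""Readers and writers: NIfTI / single-frame DICOM slices, ROI masks and
polygon JSON, cohort CSV with schema validation, result JSON/CSV, and
provenance sidecars."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .cohort import COLUMN_DICTIONARY
from .composition import CompartmentROI, CompositionResult, CTSlice

__all__ = [
    "read_ct_slice",
    "write_ct_slice_nifti",
    "read_roi",
    "write_roi_mask_nifti",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_composition_result",
    "write_sidecar",
]

_RANGE_CHECKS = {
    "ffmf_percent": (0.0, 100.0),
    "nihss_admission": (0, 42),
    "nihss_discharge": (0, 42),
    "mrs_prestroke": (0, 6),
    "mrs_admission": (0, 6),
    "mrs_discharge": (0, 6),
    "mrs_90d": (0, 6),
}


# -- images -----------------------------------------------------------------

def read_ct_slice(path: str | Path) -> CTSlice:
    """Load a 2D HU slice from NIfTI (.nii/.nii.gz) or single-frame DICOM.

    NIfTI: voxel values are taken as HU (after any scl_slope/inter, which
    nibabel applies), spacing from the header zooms.  DICOM: HU =
    pixel * RescaleSlope + RescaleIntercept, spacing from PixelSpacing.
    """
    path = Path(path)
    if path.suffix.lower() in {".nii", ".gz"} or path.name.endswith(".nii.gz"):
        img = nib.load(str(path))
        data = np.asanyarray(img.get_fdata())
        data = np.squeeze(data)
        if data.ndim != 2:
            raise ValueError(f"{path.name}: expected a single 2D slice, got shape {data.shape}")
        zooms = img.header.get_zooms()[:2]
        return CTSlice(data, (float(zooms[0]), float(zooms[1])), meta={"source": str(path)})
    # treat anything else as DICOM
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(float)
    if arr.ndim != 2:
        raise ValueError(f"{path.name}: expected a single-frame DICOM slice")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    hu = arr * slope + intercept
    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is None:
        raise ValueError(f"{path.name}: DICOM lacks PixelSpacing")
    return CTSlice(hu, (float(spacing[0]), float(spacing[1])), meta={"source": str(path)})


def write_ct_slice_nifti(ct: CTSlice, path: str | Path, dtype=np.int16) -> Path:
    """Write a slice as NIfTI with spacing encoded in the affine/zooms."""
    path = Path(path)
    affine = np.diag([ct.pixel_spacing_mm[0], ct.pixel_spacing_mm[1], 1.0, 1.0])
    img = nib.Nifti1Image(np.asarray(ct.hu, dtype=dtype), affine)
    img.header.set_zooms((ct.pixel_spacing_mm[0], ct.pixel_spacing_mm[1]))
    nib.save(img, str(path))
    return path


def write_roi_mask_nifti(
    left: np.ndarray, right: np.ndarray, spacing: tuple[float, float], path: str | Path
) -> Path:
    """Write left/right compartment masks as one NIfTI label image
    (0 = background, 1 = left, 2 = right)."""
    labels = np.zeros(left.shape, dtype=np.uint8)
    labels[np.asarray(left, bool)] = 1
    labels[np.asarray(right, bool)] = 2
    affine = np.diag([spacing[0], spacing[1], 1.0, 1.0])
    nib.save(nib.Nifti1Image(labels, affine), str(path))
    return Path(path)


def read_roi(path: str | Path, shape: Optional[tuple[int, int]] = None):
    """Read ROI(s) from a NIfTI label mask or a polygon JSON.

    Label mask: returns ``(left_roi, right_roi)`` from labels 1 and 2.
    Polygon JSON (``{"side": ..., "vertices_px": [[r, c], ...]}`` or a
    list of such objects): returns the ROIs in file order.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        items = payload if isinstance(payload, list) else [payload]
        rois = []
        for item in items:
            rois.append(
                CompartmentROI(item["side"], polygon=np.asarray(item["vertices_px"], float))
            )
        return tuple(rois)
    img = nib.load(str(path))
    labels = np.squeeze(np.asanyarray(img.dataobj))
    out = []
    for side, lab in (("left", 1), ("right", 2)):
        m = labels == lab
        if m.any():
            out.append(CompartmentROI(side, mask=m))
    if not out:
        raise ValueError(f"{path.name}: no labelled ROI pixels (expected labels 1/2)")
    return tuple(out)


# -- cohort tables ----------------------------------------------------------

def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cohort.to_csv(path, index=False)
    return path


def read_cohort_csv(path: str | Path, strict: bool = True) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Known columns are type- and range-checked (mRS 0-6, NIHSS 0-42, FFMF
    0-100); malformed rows are reported with their 1-based row numbers.
    Unknown columns pass through with a warning.
    """
    import logging

    path = Path(path)
    df = pd.read_csv(path)
    unknown = [c for c in df.columns if c not in COLUMN_DICTIONARY]
    if unknown:
        logging.getLogger(__name__).warning(
            "%s: unknown columns passed through: %s", path.name, unknown
        )
    problems: list[str] = []
    for col, (lo, hi) in _RANGE_CHECKS.items():
        if col not in df.columns:
            continue
        v = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[(v < lo) | (v > hi) | v.isna()].tolist()
        if bad:
            rows = ", ".join(str(i + 1) for i in bad[:20])
            problems.append(f"{col} out of range [{lo}, {hi}] in row(s) {rows}")
    if problems and strict:
        raise ValueError(f"{path.name}: validation failed: " + "; ".join(problems))
    return df


# -- results & provenance ---------------------------------------------------

def write_composition_result(
    combined: CompositionResult,
    per_side: Sequence[CompositionResult],
    path: str | Path,
) -> Path:
    """Composition result as JSON (and a one-row CSV next to it)."""
    path = Path(path)
    payload = {"combined": combined.to_dict(), "per_side": [r.to_dict() for r in per_side]}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    pd.DataFrame([combined.to_dict()]).to_csv(path.with_suffix(".csv"), index=False)
    return path


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_sidecar(path: str | Path, config: dict, seed: int) -> Path:
    """JSON provenance sidecar (<file>.provenance.json): config hash,
    seed, software version, and the config itself."""
    path = Path(path)
    sidecar = path.with_name(path.name + ".provenance.json")
    sidecar.write_text(
        json.dumps(
            {
                "file": path.name,
                "config_hash": config_hash(config),
                "seed": seed,
                "software": {"name": "ffmf", "version": __version__},
                "config": config,
            },
            indent=2,
            sort_keys=True,
            default=str,
        )
    )
    return sidecar
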