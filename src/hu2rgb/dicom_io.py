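"""Slice input/output: DICOM reading, plain-text HU grids, PNG writing.

HU values are recovered from DICOM stored values via the linear rescale
``hu = stored * RescaleSlope + RescaleIntercept`` and kept as floats
(slopes need not be integral); quantization happens only at rendering.
Plain-text whitespace-delimited HU grids serve as a trivially inspectable
fixture format.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pydicom
from PIL import Image

from .windowing import as_hu_image

__all__ = [
    "SliceRecord",
    "read_dicom_slice",
    "read_hu_grid",
    "write_hu_grid",
    "write_png",
]


@dataclass
class SliceRecord:
    """One CT slice in HU plus its provenance."""

    hu: np.ndarray
    source_id: str
    rescale_slope: float
    rescale_intercept: float


def read_dicom_slice(path) -> SliceRecord:
    """Read a single-frame CT DICOM file into HU.

    The photometric interpretation (MONOCHROME1/2) only affects display
    polarity, not stored values, so HU recovery is identical for both.
    Non-CT modalities and multi-frame objects are rejected.
    """
    ds = pydicom.dcmread(path)
    modality = getattr(ds, "Modality", None)
    if modality != "CT":
        raise ValueError(f"unsupported modality {modality!r}: expected CT")
    n_frames = int(getattr(ds, "NumberOfFrames", 1) or 1)
    if n_frames != 1:
        raise ValueError(f"multi-frame objects unsupported ({n_frames} frames)")
    for tag in ("RescaleSlope", "RescaleIntercept"):
        if getattr(ds, tag, None) is None:
            raise ValueError(f"missing required DICOM tag {tag}")
    slope = float(ds.RescaleSlope)
    intercept = float(ds.RescaleIntercept)
    hu = ds.pixel_array.astype(float) * slope + intercept
    return SliceRecord(
        hu=as_hu_image(hu),
        source_id=str(getattr(ds, "SOPInstanceUID", Path(path).name)),
        rescale_slope=slope,
        rescale_intercept=intercept,
    )


def read_hu_grid(path) -> np.ndarray:
    """Parse a whitespace-delimited rectangular numeric grid.

    Ragged rows and non-numeric tokens are rejected with the offending
    row/column position (1-based).
    """
    rows: list[list[float]] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            row = []
            for j, tok in enumerate(tokens, start=1):
                try:
                    row.append(float(tok))
                except ValueError:
                    raise ValueError(
                        f"non-numeric token {tok!r} at row {i}, column {j}"
                    ) from None
            rows.append(row)
    if not rows:
        raise ValueError(f"empty HU grid: {path}")
    width = len(rows[0])
    for i, row in enumerate(rows, start=1):
        if len(row) != width:
            raise ValueError(
                f"ragged grid: row {i} has {len(row)} columns, expected {width}"
            )
    return np.asarray(rows, dtype=float)


def write_hu_grid(values: np.ndarray, path) -> None:
    """Write a 2D HU matrix as a whitespace-delimited text grid."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError("HU grid must be 2D")
    np.savetxt(path, arr, fmt="%.6g")


def write_png(img: np.ndarray, path) -> None:
    """Write an 8-bit image as lossless PNG (gray for 2D, RGB for HxWx3)."""
    arr = np.asarray(img)
    if arr.dtype != np.uint8:
        raise ValueError(f"PNG output requires uint8, got {arr.dtype}")
    if arr.ndim == 2:
        Image.fromarray(arr, mode="L").save(path, format="PNG")
    elif arr.ndim == 3 and arr.shape[2] == 3:
        Image.fromarray(arr, mode="RGB").save(path, format="PNG")
    else:
        raise ValueError(f"unsupported image shape {arr.shape}")
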