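"""File I/O: images (PNG/TIFF/DICOM), binary masks, box tables, manifests.

Conventions (shared by every reader/writer in the package):

* images are written as 16-bit grayscale PNG, intensities on [0, 1] scaled
  by 65535 — lossless round-trip at that depth;
* masks are 8-bit PNG with values {0, 255};
* box tables are CSV with columns image_id, x, y, w, h, label, acr_level
  (plus cs for predictions); coordinates are 0-based pixels, half-open
  width/height;
* the train/test split manifest is JSON {"train": [...], "test": [...],
  "seed": int}.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .metrics import BoundingBox, Detection

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_boxes",
    "write_boxes",
    "read_detections",
    "write_detections",
    "write_split_manifest",
    "read_split_manifest",
]

BOX_COLUMNS = ["image_id", "x", "y", "w", "h", "label", "acr_level"]


def read_image(path: str | Path) -> np.ndarray:
    """Load a grayscale image as a float raster in [0, 1].

    PNG/TIFF are read at native bit depth; DICOM (.dcm) is read with
    pydicom, honoring rescale slope/intercept and inverting MONOCHROME1 so
    that brighter always means denser tissue.
    """
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        lo, hi = arr.min(), arr.max()
        arr = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
        if getattr(ds, "PhotometricInterpretation", "MONOCHROME2") == "MONOCHROME1":
            arr = 1.0 - arr
        return arr
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / np.iinfo(arr.dtype).max
    return arr.astype(float)


def write_image(path: str | Path, img: np.ndarray) -> None:
    """Write a [0, 1] float raster as 16-bit grayscale PNG."""
    img = np.asarray(img, dtype=float)
    if img.min() < 0 or img.max() > 1:
        raise ValueError("image values must lie in [0, 1]")
    iio.imwrite(Path(path), np.rint(img * 65535).astype(np.uint16))


def read_mask(path: str | Path) -> np.ndarray:
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > (np.iinfo(arr.dtype).max // 2 if np.issubdtype(arr.dtype, np.integer) else 0.5)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def _validate_box_row(row: pd.Series, idx: int) -> None:
    if row["w"] <= 0 or row["h"] <= 0:
        raise ValueError(f"row {idx}: non-positive box size w={row['w']}, h={row['h']}")
    if row["x"] < 0 or row["y"] < 0:
        raise ValueError(f"row {idx}: negative box origin x={row['x']}, y={row['y']}")


def read_boxes(path: str | Path) -> pd.DataFrame:
    """Read a ground-truth box table, validating every row."""
    df = pd.read_csv(path)
    missing = [c for c in BOX_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"box CSV missing columns: {missing}")
    for idx, row in df.iterrows():
        _validate_box_row(row, idx)
    return df


def write_boxes(path: str | Path, rows: list[dict]) -> None:
    df = pd.DataFrame(rows, columns=BOX_COLUMNS)
    df.to_csv(path, index=False)


def read_detections(path: str | Path) -> list[Detection]:
    df = pd.read_csv(path)
    needed = ["image_id", "x", "y", "w", "h", "cs"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"detection CSV missing columns: {missing}")
    dets = []
    for idx, row in df.iterrows():
        _validate_box_row(row, idx)
        dets.append(
            Detection(
                BoundingBox(int(row["x"]), int(row["y"]), int(row["w"]), int(row["h"])),
                float(row["cs"]),
                str(row["image_id"]),
            )
        )
    return dets


def write_detections(path: str | Path, dets: list[Detection]) -> None:
    rows = [
        {"image_id": d.image_id, "x": d.box.x, "y": d.box.y, "w": d.box.w, "h": d.box.h, "cs": d.cs}
        for d in dets
    ]
    pd.DataFrame(rows, columns=["image_id", "x", "y", "w", "h", "cs"]).to_csv(path, index=False)


def write_split_manifest(path: str | Path, train: list[str], test: list[str], seed: int) -> None:
    Path(path).write_text(json.dumps({"train": list(train), "test": list(test), "seed": seed}, indent=2))


def read_split_manifest(path: str | Path) -> tuple[list[str], list[str], int]:
    doc = json.loads(Path(path).read_text())
    return list(doc["train"]), list(doc["test"]), int(doc["seed"])
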