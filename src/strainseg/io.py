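"""Readers and writers for rasters, labels, audits and debug fields.

All file rasters (PNG, TIFF, CSV alike) are stored with row 0 at the
top, as image viewers expect; in-memory arrays use model-space
orientation (row 0 at the bottom, y upwards), so every reader and
writer flips the row order. Round-tripping is covered by tests.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .grid_model import PixelImage

__all__ = [
    "read_image",
    "read_mask",
    "write_image",
    "write_mask",
    "write_labels",
    "write_label_csv",
    "write_scaled_raster",
    "write_audit_json",
    "write_force_csv",
]

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}


def _read_array(path: Path) -> np.ndarray:
    if path.suffix.lower() == ".csv":
        arr = np.loadtxt(path, delimiter=",", ndmin=2)
    elif path.suffix.lower() in _IMAGE_SUFFIXES:
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:  # collapse an accidental RGB(A) to gray
            arr = arr[..., :3].mean(axis=2)
    else:
        raise ValueError(f"unsupported raster format: {path.suffix!r}")
    return arr[::-1].astype(float)  # file top row -> model top row (y up)


def read_image(path: str | Path) -> PixelImage:
    """Read a grayscale 8/16-bit PNG/TIFF or a plain CSV matrix."""
    return PixelImage(_read_array(Path(path)))


def read_mask(path: str | Path, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read a mask raster; nonzero pixels are members."""
    arr = _read_array(Path(path)) != 0
    if shape is not None and arr.shape != shape:
        raise ValueError(f"mask shape {arr.shape} does not match image {shape}")
    return arr


def _write_array(path: Path, arr: np.ndarray) -> None:
    arr = arr[::-1]  # model orientation -> file orientation
    if path.suffix.lower() == ".csv":
        np.savetxt(path, arr, delimiter=",", fmt="%.10g")
    elif path.suffix.lower() in _IMAGE_SUFFIXES:
        import imageio.v3 as iio

        iio.imwrite(path, arr)
    else:
        raise ValueError(f"unsupported raster format: {path.suffix!r}")


def write_image(path: str | Path, image: PixelImage) -> None:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        _write_array(path, image.values)
    else:
        _write_array(path, np.round(image.values).clip(0, 65535).astype(np.uint16))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        _write_array(path, mask.astype(np.uint8))
    else:
        _write_array(path, (mask.astype(np.uint8)) * np.uint8(255))


# A small qualitative palette for label images (label 0 = black).
_PALETTE = [
    (0, 0, 0),
    (230, 60, 60),
    (60, 120, 230),
    (60, 200, 90),
    (240, 200, 60),
    (170, 90, 230),
    (90, 210, 220),
    (240, 140, 60),
    (200, 200, 200),
]


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    """Write a label raster as a palette PNG."""
    from PIL import Image

    labels = np.asarray(labels)
    if labels.max() > 255:
        raise ValueError("more than 255 labels")
    img = Image.fromarray(labels[::-1].astype(np.uint8), mode="P")
    palette = []
    for k in range(256):
        palette.extend(_PALETTE[k % len(_PALETTE)] if k else (0, 0, 0))
    img.putpalette(palette)
    img.save(Path(path))


def write_label_csv(path: str | Path, labels: np.ndarray) -> None:
    _write_array(Path(path), np.asarray(labels).astype(np.int64))


def write_scaled_raster(path: str | Path, field: np.ndarray) -> None:
    """Write a non-negative scalar raster as 16-bit PNG (or CSV verbatim).

    For PNG output the field is scaled linearly to the full 16-bit
    range; the scale factor is recorded in a ``<name>.scale.txt``
    sidecar so values can be recovered.
    """
    path = Path(path)
    field = np.asarray(field, dtype=float)
    if path.suffix.lower() == ".csv":
        _write_array(path, field)
        return
    top = float(field.max())
    scale = 65535.0 / top if top > 0 else 1.0
    _write_array(path, np.round(field * scale).astype(np.uint16))
    path.with_suffix(path.suffix + ".scale.txt").write_text(
        f"stored = value * {scale!r}\n", encoding="utf-8"
    )


def write_force_csv(path: str | Path, load) -> None:
    """Force arrows as ``x,y,fx,fy`` rows (one per loaded boundary node)."""
    rows = np.column_stack(
        [
            load.positions[:, 0],
            load.positions[:, 1],
            load.magnitudes * load.normals[:, 0],
            load.magnitudes * load.normals[:, 1],
        ]
    )
    np.savetxt(Path(path), rows, delimiter=",", fmt="%.10g", header="x,y,fx,fy")


def write_audit_json(path: str | Path, result) -> None:
    """Per-ROI audit: objective, weakness, skip flag, removals, order."""
    audit = {
        "threshold": result.threshold,
        "n_segments": result.n_segments,
        "ranking": {
            "order": result.ranking.order,
            "theta": result.ranking.theta,
            "skipped": sorted(result.ranking.skipped),
            "weakness": result.ranking.weakness,
        },
        "rois": [
            {
                "id": r.roi_id,
                "objective": r.phi_star,
                "area": r.area,
                "weakness": r.weakness,
                "skipped": r.skipped,
                "iterations": r.iterations,
                "halting_cause": r.halting_cause,
                "removed": [[int(j), int(i)] for j, i in r.removed],
            }
            for r in result.records
        ],
    }
    Path(path).write_text(
        json.dumps(audit, indent=2, sort_keys=True), encoding="utf-8"
    )
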