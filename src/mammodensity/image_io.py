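"""Reading and writing mammogram images, masks, overlays and results tables.

Images are handled as integer arrays at their native bit depth (8 or 16
bit); nothing is silently rescaled to 8 bit, because the threshold search
operates on the native intensity scale and film digitiser settings vary.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "GreyscaleImage",
    "ResultRow",
    "UnsupportedImageError",
    "read_image",
    "write_mask",
    "write_overlay",
    "write_results",
    "read_results",
    "RESULTS_COLUMNS",
    "STATUS_OK",
]

#: Column order of the results CSV, fixed.
RESULTS_COLUMNS = (
    "source_id",
    "status",
    "breast_area_px",
    "dense_area_px",
    "percent_density",
    "threshold",
)

STATUS_OK = "OK"


class UnsupportedImageError(ValueError):
    """Raised for colour or otherwise unsupported image inputs."""


@dataclass
class GreyscaleImage:
    """A single-channel mammogram at native integer bit depth.

    Attributes
    ----------
    pixels : ndarray of unsigned integers, shape (height, width)
    bit_depth : 8 or 16
    source_id : opaque identifier, normally the file stem
    """

    pixels: np.ndarray
    bit_depth: int = 8
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise UnsupportedImageError(
                f"expected a 2-D greyscale array, got shape {self.pixels.shape}"
            )
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixels.size and (
            self.pixels.min() < 0 or self.pixels.max() > self.max_value
        ):
            raise ValueError("pixel intensities outside the bit-depth range")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    def copy_with(self, pixels: np.ndarray) -> "GreyscaleImage":
        return GreyscaleImage(pixels=pixels, bit_depth=self.bit_depth, source_id=self.source_id)


@dataclass
class ResultRow:
    """One line of the indexed results table.

    On failure ``status`` carries the reason code and the numeric fields
    are ``None`` (rendered as empty CSV fields).
    """

    source_id: str
    status: str = STATUS_OK
    breast_area_px: Optional[int] = None
    dense_area_px: Optional[int] = None
    percent_density: Optional[float] = None
    threshold: Optional[int] = None

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK


def read_image(path: str | Path) -> GreyscaleImage:
    """Read a greyscale PNG/TIFF/PGM image at native bit depth.

    Colour images are rejected: film digitisation yields single-channel
    data, and a colour file signals a wrong input.
    """
    path = Path(path)
    with Image.open(path) as im:
        mode = im.mode
        if mode == "L":
            arr = np.asarray(im, dtype=np.uint8)
            depth = 8
        elif mode in ("I;16", "I;16B", "I;16L"):
            arr = np.asarray(im, dtype=np.uint16)
            depth = 16
        elif mode == "I":
            arr = np.asarray(im, dtype=np.int32)
            if arr.size and (arr.min() < 0 or arr.max() > 65535):
                raise UnsupportedImageError(
                    f"{path}: integer image outside 16-bit range"
                )
            arr = arr.astype(np.uint16)
            depth = 16
        else:
            raise UnsupportedImageError(
                f"{path}: unsupported image mode {mode!r}; a greyscale "
                "(single-channel) PNG, TIFF or PGM is required"
            )
    if arr.shape[0] < 64 or arr.shape[1] < 64:
        raise UnsupportedImageError(
            f"{path}: image {arr.shape[1]}x{arr.shape[0]} below the 64-px minimum"
        )
    return GreyscaleImage(pixels=arr, bit_depth=depth, source_id=path.stem)


def _to_pil(arr: np.ndarray, bit_depth: int) -> Image.Image:
    if bit_depth == 8:
        return Image.fromarray(arr.astype(np.uint8), mode="L")
    return Image.fromarray(arr.astype(np.uint16))


def write_mask(mask: np.ndarray, path: str | Path, bit_depth: int = 8) -> None:
    """Write a binary mask as a black/white image (foreground at full scale)."""
    mask = np.asarray(mask, dtype=bool)
    full = (1 << bit_depth) - 1
    _to_pil(mask.astype(np.uint16) * full, bit_depth).save(Path(path))


def _outline(mask: np.ndarray) -> np.ndarray:
    """One-pixel 4-connected inner boundary of a binary mask."""
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return mask & ~eroded


def write_overlay(
    image: GreyscaleImage,
    breast: np.ndarray,
    dense: np.ndarray,
    path: str | Path,
    mask_path: str | Path | None = None,
) -> None:
    """Write the marked-up mammogram and the binary dense-area mask.

    The breast boundary is burned in at mid-grey, the dense-tissue
    boundary at full intensity; these are fixed, documented constants.
    ``mask_path`` defaults to ``<path stem>_mask.png``.
    """
    breast = np.asarray(breast, dtype=bool)
    dense = np.asarray(dense, dtype=bool)
    if breast.shape != image.pixels.shape or dense.shape != image.pixels.shape:
        raise ValueError("mask dimensions do not match the image")
    path = Path(path)
    if mask_path is None:
        mask_path = path.with_name(path.stem + "_mask.png")

    mid = image.max_value // 2
    overlay = image.pixels.copy()
    overlay[_outline(breast)] = mid
    overlay[_outline(dense)] = image.max_value
    _to_pil(overlay, image.bit_depth).save(path)
    write_mask(dense, mask_path, bit_depth=image.bit_depth)


def write_results(rows: Iterable[ResultRow], path: str | Path) -> None:
    """Write the indexed results table as CSV (one row per processed image).

    Percent density is rendered with two decimals; failed rows carry empty
    numeric fields.
    """
    with open(Path(path), "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESULTS_COLUMNS)
        for row in rows:
            writer.writerow(
                [
                    row.source_id,
                    row.status,
                    "" if row.breast_area_px is None else int(row.breast_area_px),
                    "" if row.dense_area_px is None else int(row.dense_area_px),
                    "" if row.percent_density is None else f"{row.percent_density:.2f}",
                    "" if row.threshold is None else int(row.threshold),
                ]
            )


def read_results(path: str | Path) -> list[ResultRow]:
    """Read back a results CSV written by :func:`write_results`."""
    rows: list[ResultRow] = []
    with open(Path(path), newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(RESULTS_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"results CSV missing columns: {sorted(missing)}")
        for rec in reader:
            rows.append(
                ResultRow(
                    source_id=rec["source_id"],
                    status=rec["status"],
                    breast_area_px=int(rec["breast_area_px"]) if rec["breast_area_px"] else None,
                    dense_area_px=int(rec["dense_area_px"]) if rec["dense_area_px"] else None,
                    percent_density=float(rec["percent_density"]) if rec["percent_density"] else None,
                    threshold=int(rec["threshold"]) if rec["threshold"] else None,
                )
            )
    return rows
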