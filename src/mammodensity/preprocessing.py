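"""Contrast improvement and noise reduction restricted to the breast area.

Both operations act only on breast pixels and leave everything outside the
mask bit-identical.  At the breast boundary, filter windows are restricted
to breast pixels (no mirroring or zero padding), so the dark background
cannot bias boundary statistics.  No standardisation across images is
performed: each mammogram is processed on its own intensity scale.
"""

from __future__ import annotations

import numpy as np

from .config import PipelineConfig
from .image_io import GreyscaleImage

__all__ = ["median_smooth", "contrast_stretch", "preprocess"]


def median_smooth(
    image: GreyscaleImage, mask: np.ndarray, radius: int = 1
) -> GreyscaleImage:
    """Median-filter the breast area, window restricted to breast pixels.

    Each breast pixel becomes the median of the (2r+1)x(2r+1) window
    intersected with the breast mask; with an even number of valid
    neighbours the lower median (an actual pixel value) is taken, keeping
    the output integer.  Non-breast pixels pass through unchanged.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.pixels.shape:
        raise ValueError("mask dimensions do not match the image")

    k = 2 * radius + 1
    h, w = image.pixels.shape
    padded = np.zeros((h + 2 * radius, w + 2 * radius), dtype=np.float32)
    padded_mask = np.zeros_like(padded, dtype=bool)
    padded[radius : radius + h, radius : radius + w] = image.pixels
    padded_mask[radius : radius + h, radius : radius + w] = mask

    stack = np.full((k * k, h, w), np.nan, dtype=np.float32)
    for i, dy in enumerate(range(-radius, radius + 1)):
        for j, dx in enumerate(range(-radius, radius + 1)):
            vals = padded[radius + dy : radius + dy + h, radius + dx : radius + dx + w]
            valid = padded_mask[radius + dy : radius + dy + h, radius + dx : radius + dx + w]
            plane = stack[i * k + j]
            plane[valid] = vals[valid]

    stack.sort(axis=0)  # NaNs sort to the end
    counts = np.sum(~np.isnan(stack), axis=0)
    # the centre pixel is always in its own window, so counts >= 1 on the mask
    idx = np.clip((counts - 1) // 2, 0, k * k - 1)
    medians = np.take_along_axis(stack, idx[None, :, :], axis=0)[0]

    out = image.pixels.copy()
    out[mask] = medians[mask].astype(out.dtype)
    return image.copy_with(out)


def _nearest_rank(sorted_vals: np.ndarray, pct: float) -> float:
    """Nearest-rank percentile on a sorted multiset."""
    n = sorted_vals.size
    rank = max(int(np.ceil(pct / 100.0 * n)), 1)
    return float(sorted_vals[rank - 1])


def contrast_stretch(
    image: GreyscaleImage,
    mask: np.ndarray,
    lo_pct: float = 1.0,
    hi_pct: float = 99.0,
) -> GreyscaleImage:
    """Linear histogram stretch of the breast pixels to the full scale.

    Intensities at or below the ``lo_pct`` nearest-rank percentile of the
    breast pixels map to 0, at or above ``hi_pct`` to the full scale,
    linearly (rounded to nearest integer) in between.  Clipping at the
    1st/99th percentiles makes the stretch robust to residual specks;
    ``lo_pct=0, hi_pct=100`` recovers a pure min-max stretch.  Degenerate
    cases (a constant breast, or equal clip points) are no-ops.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.pixels.shape:
        raise ValueError("mask dimensions do not match the image")
    vals = np.sort(image.pixels[mask].astype(np.float64))
    if vals.size == 0 or vals[0] == vals[-1]:
        return image.copy_with(image.pixels.copy())
    lo = _nearest_rank(vals, lo_pct)
    hi = _nearest_rank(vals, hi_pct)
    if hi <= lo:
        return image.copy_with(image.pixels.copy())

    full = image.max_value
    stretched = np.rint(
        np.clip((image.pixels[mask].astype(np.float64) - lo) / (hi - lo), 0.0, 1.0) * full
    )
    out = image.pixels.copy()
    out[mask] = stretched.astype(out.dtype)
    return image.copy_with(out)


def preprocess(
    image: GreyscaleImage, mask: np.ndarray, config: PipelineConfig | None = None
) -> GreyscaleImage:
    """Median smoothing followed by contrast stretching of the breast area."""
    cfg = config or PipelineConfig()
    smoothed = median_smooth(image, mask, radius=cfg.median_radius)
    return contrast_stretch(
        smoothed, mask, lo_pct=cfg.stretch_lo_pct, hi_pct=cfg.stretch_hi_pct
    )
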