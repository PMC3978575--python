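"""Per-image dense/fatty thresholding and density measurement.

Dense (fibroglandular) tissue is radiologically brighter than fatty
tissue.  For each mammogram independently — no cross-image
standardisation — an optimal intensity threshold is chosen on the
preprocessed breast pixels and everything strictly brighter is classified
as dense.  The criterion is the between-class variance of the breast
histogram (Otsu restricted to the breast area), maximised exhaustively
over the intensities actually present in the breast; it is deterministic
and exactly verifiable against a brute-force scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .breast_segmentation import BreastMask, SegmentationOutcome, segment_breast
from .config import PipelineConfig
from .image_io import GreyscaleImage, ResultRow
from .preprocessing import preprocess

__all__ = [
    "DenseMask",
    "DensityResult",
    "DensityFailure",
    "compute_threshold",
    "segment_dense",
    "measure_density",
    "process_image",
    "result_row",
]

log = logging.getLogger(__name__)


@dataclass
class DenseMask:
    """Binary dense-tissue mask, a subset of the breast mask."""

    pixels: np.ndarray

    @property
    def area_px(self) -> int:
        return int(np.count_nonzero(self.pixels))


@dataclass
class DensityResult:
    """Per-image density measurement.

    percent_density = 100 * dense_area_px / breast_area_px.  ``degenerate``
    marks near-constant breasts where no dense/fatty contrast exists (the
    threshold defaults to the maximum breast intensity, dense area 0); the
    density stage itself never fails.
    """

    source_id: str
    threshold: int
    breast_area_px: int
    dense_area_px: int
    percent_density: float
    degenerate: bool = False


@dataclass
class DensityFailure:
    """Propagated breast-segmentation failure for one image."""

    source_id: str
    reason: str


def _between_class_variance(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """J(t) for every candidate threshold t = unique breast intensity.

    Classes are (<= t) versus (> t); J = w0*w1*(mu0-mu1)^2.  The brighter
    class is the dense one by construction.
    """
    uniq, counts = np.unique(values, return_counts=True)
    counts = counts.astype(np.float64)
    total = counts.sum()
    cum_n = np.cumsum(counts)
    cum_s = np.cumsum(counts * uniq.astype(np.float64))
    w0 = cum_n / total
    w1 = 1.0 - w0
    mu0 = cum_s / cum_n
    total_s = cum_s[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu1 = (total_s - cum_s) / (total - cum_n)
    j = w0 * w1 * (mu0 - mu1) ** 2
    j[~np.isfinite(j)] = 0.0  # t = max intensity leaves the upper class empty
    return uniq, j


def compute_threshold(
    image: GreyscaleImage,
    mask: Union[BreastMask, np.ndarray],
    criterion: str = "between_class_variance",
) -> int:
    """Optimal dense/fatty threshold for one breast, chosen independently.

    Scans every intensity present within the breast and returns the
    smallest maximiser of the between-class variance criterion (smallest,
    so plateaus resolve deterministically).  A constant breast is
    degenerate: the maximum intensity is returned (dense area 0) and the
    condition is logged — this stage never hard-fails.
    """
    if criterion != "between_class_variance":
        raise ValueError(f"unknown threshold criterion: {criterion!r}")
    pix = mask.pixels if isinstance(mask, BreastMask) else np.asarray(mask, dtype=bool)
    values = image.pixels[pix]
    if values.size == 0:
        raise ValueError("empty breast mask")
    uniq = np.unique(values)
    if uniq.size == 1:
        log.info("%s: degenerate constant breast, threshold=%d",
                 image.source_id, int(uniq[0]))
        return int(uniq[0])
    cand, j = _between_class_variance(values)
    return int(cand[int(np.argmax(j))])


def segment_dense(
    image: GreyscaleImage, mask: Union[BreastMask, np.ndarray], threshold: int
) -> DenseMask:
    """Dense mask = breast pixels strictly brighter than the threshold."""
    pix = mask.pixels if isinstance(mask, BreastMask) else np.asarray(mask, dtype=bool)
    return DenseMask(pixels=pix & (image.pixels > threshold))


def measure_density(
    breast: BreastMask,
    dense: DenseMask,
    source_id: str = "",
    threshold: int = 0,
    degenerate: bool = False,
) -> DensityResult:
    """Dense area and percent density from the two masks."""
    if np.any(dense.pixels & ~breast.pixels):
        raise ValueError("dense mask is not a subset of the breast mask")
    ba = breast.area_px
    if ba == 0:
        raise ValueError("breast mask is empty")
    da = dense.area_px
    return DensityResult(
        source_id=source_id,
        threshold=int(threshold),
        breast_area_px=ba,
        dense_area_px=da,
        percent_density=100.0 * da / ba,
        degenerate=degenerate,
    )


def process_image(
    image: GreyscaleImage,
    config: PipelineConfig | None = None,
    return_masks: bool = False,
):
    """Full per-image pipeline: segment, preprocess, threshold, measure.

    Returns a :class:`DensityResult` on success or a
    :class:`DensityFailure` carrying the segmentation reason code.  With
    ``return_masks=True`` a ``(result, breast_mask, dense_mask)`` triple is
    returned on success (masks are ``None`` on failure).
    """
    cfg = config or PipelineConfig()
    seg: SegmentationOutcome = segment_breast(image, cfg)
    if not seg.ok:
        failure = DensityFailure(source_id=image.source_id, reason=seg.reason)
        return (failure, None, None) if return_masks else failure

    breast = seg.mask
    pre = preprocess(image, breast.pixels, cfg)
    values = pre.pixels[breast.pixels]
    degenerate = np.unique(values).size == 1
    t = compute_threshold(pre, breast, criterion=cfg.criterion)
    dense = segment_dense(pre, breast, t)
    result = measure_density(
        breast, dense, source_id=image.source_id, threshold=t, degenerate=degenerate
    )
    return (result, breast, dense) if return_masks else result


def result_row(outcome: Union[DensityResult, DensityFailure]) -> ResultRow:
    """Convert a pipeline outcome into a results-table row."""
    if isinstance(outcome, DensityFailure):
        return ResultRow(source_id=outcome.source_id, status=outcome.reason)
    return ResultRow(
        source_id=outcome.source_id,
        status="OK",
        breast_area_px=outcome.breast_area_px,
        dense_area_px=outcome.dense_area_px,
        percent_density=outcome.percent_density,
        threshold=outcome.threshold,
    )
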