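"""Breast-area segmentation with scanner-border and artefact handling.

Digitised film mammograms carry background clutter that is not breast
tissue: a bright frame along the image edges left by the scanner, and
detached high-intensity blobs (laterality/view tags, nameplates).  The
breast itself is a single bright region attached to one vertical image
edge (the chest wall) on a cranio-caudal view.

The segmentation strategy is deliberately simple and auditable:

1. detect and zero the bright scanner border (per-side, grown inward
   while edge rows/columns stay above a whole-image intensity percentile);
2. split background from tissue with Otsu's threshold on the
   border-stripped image;
3. keep the largest 4-connected foreground component as the breast
   candidate, fill its interior holes, and treat every other foreground
   component as an artefact;
4. reject the candidate when its relation to the image edges or its area
   is implausible — these are the characterised failure modes of the
   method, reported as data rather than raised as crashes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .config import PipelineConfig
from .image_io import GreyscaleImage

__all__ = [
    "BreastMask",
    "SegmentationOutcome",
    "FAIL_BREAST_SEGMENTATION",
    "FAIL_EMPTY_IMAGE",
    "detect_border",
    "strip_border",
    "detect_artifacts",
    "segment_breast",
]

log = logging.getLogger(__name__)

FAIL_BREAST_SEGMENTATION = "FAIL_BREAST_SEGMENTATION"
FAIL_EMPTY_IMAGE = "FAIL_EMPTY_IMAGE"

_STRUCTURE_4 = ndimage.generate_binary_structure(2, 1)


@dataclass
class BreastMask:
    """Binary breast-area mask; a single 4-connected component attached to
    one vertical image edge (the chest wall)."""

    pixels: np.ndarray
    chest_edge: str  # "left" or "right"

    @property
    def area_px(self) -> int:
        return int(np.count_nonzero(self.pixels))


@dataclass
class SegmentationOutcome:
    """Either a breast mask (success) or a failure reason code."""

    status: str  # "success" | "failure"
    mask: Optional[BreastMask] = None
    reason: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.status == "success"


def detect_border(
    image: GreyscaleImage, config: PipelineConfig | None = None
) -> dict[str, int]:
    """Measure the bright scanner frame width on each image side.

    A side's edge-adjacent rows/columns belong to the border while their
    mean intensity is at or above the ``border_percentile`` of the whole
    image; growth stops at ``max_border_frac`` of the dimension.  Returns
    widths for keys ``left``, ``right``, ``top``, ``bottom`` (0 = none).
    """
    cfg = config or PipelineConfig()
    px = image.pixels
    h, w = px.shape
    if px.size == 0 or px.min() == px.max():
        return {"left": 0, "right": 0, "top": 0, "bottom": 0}
    cut = float(np.percentile(px, cfg.border_percentile))
    col_means = px.mean(axis=0)
    row_means = px.mean(axis=1)
    max_w = int(cfg.max_border_frac * w)
    max_h = int(cfg.max_border_frac * h)

    def grow(means: np.ndarray, limit: int) -> int:
        width = 0
        while width < limit and means[width] >= cut:
            width += 1
        return width

    return {
        "left": grow(col_means, max_w),
        "right": grow(col_means[::-1], max_w),
        "top": grow(row_means, max_h),
        "bottom": grow(row_means[::-1], max_h),
    }


def border_mask(image: GreyscaleImage, config: PipelineConfig | None = None) -> np.ndarray:
    """Binary mask of the detected scanner border."""
    widths = detect_border(image, config)
    h, w = image.pixels.shape
    mask = np.zeros((h, w), dtype=bool)
    if widths["left"]:
        mask[:, : widths["left"]] = True
    if widths["right"]:
        mask[:, w - widths["right"] :] = True
    if widths["top"]:
        mask[: widths["top"], :] = True
    if widths["bottom"]:
        mask[h - widths["bottom"] :, :] = True
    return mask


def strip_border(
    image: GreyscaleImage, config: PipelineConfig | None = None
) -> GreyscaleImage:
    """Zero the bright scanner frame; interior pixels are untouched.

    A no-op (identical copy) when no border is detected.
    """
    mask = border_mask(image, config)
    out = image.pixels.copy()
    out[mask] = 0
    return image.copy_with(out)


def _foreground_labels(pixels: np.ndarray) -> tuple[np.ndarray, int]:
    """Otsu background/tissue split followed by 4-connected labelling."""
    vals = np.unique(pixels)
    if vals.size < 2:
        return np.zeros_like(pixels, dtype=np.int32), 0
    t = threshold_otsu(pixels)
    fg = pixels > t
    labels, n = ndimage.label(fg, structure=_STRUCTURE_4)
    return labels, n


def _largest_component(labels: np.ndarray, n: int, widths: dict[str, int]) -> int:
    """Index of the breast candidate: largest component, ties broken in
    favour of a component touching a vertical (effective) edge."""
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    order = np.argsort(areas)[::-1]
    best = order[0]
    if len(order) > 1 and areas[order[1]] == areas[best]:
        h, w = labels.shape
        for idx in order:
            if areas[idx] != areas[best]:
                break
            lab = idx + 1
            left = np.any(labels[:, widths["left"]] == lab)
            right = np.any(labels[:, w - 1 - widths["right"]] == lab)
            if left or right:
                return lab
    return int(best) + 1


def detect_artifacts(
    image: GreyscaleImage, config: PipelineConfig | None = None
) -> np.ndarray:
    """Mask of bright connected components detached from the breast.

    Expects a border-stripped image.  Everything bright that is not the
    single largest foreground component (tags, nameplates, specks) is an
    artefact.  A tag that overlaps the breast merges into its component
    and is, by construction, not reported here; that situation surfaces
    downstream as a segmentation failure.
    """
    cfg = config or PipelineConfig()
    labels, n = _foreground_labels(image.pixels)
    if n <= 1:
        return np.zeros_like(image.pixels, dtype=bool)
    widths = {"left": 0, "right": 0, "top": 0, "bottom": 0}
    breast_lab = _largest_component(labels, n, widths)
    return (labels > 0) & (labels != breast_lab)


def segment_breast(
    image: GreyscaleImage, config: PipelineConfig | None = None
) -> SegmentationOutcome:
    """Identify the breast area; report characterised failures as data.

    The candidate is rejected (``FAIL_BREAST_SEGMENTATION``) when it
    touches both vertical effective edges, touches three or more edges,
    touches no vertical edge, or occupies an implausible fraction of the
    image (outside ``[min_breast_frac, max_breast_frac]``).  Edge contact
    is assessed at the *effective* edges, i.e. just inside any stripped
    scanner border, so a breast running under the frame counts as touching
    that edge.  An empty or constant image fails with ``FAIL_EMPTY_IMAGE``.
    """
    cfg = config or PipelineConfig()
    px = image.pixels
    if px.size == 0 or px.min() == px.max():
        return SegmentationOutcome(status="failure", reason=FAIL_EMPTY_IMAGE)

    widths = detect_border(image, cfg)
    stripped = strip_border(image, cfg)
    spx = stripped.pixels
    if spx.min() == spx.max():
        return SegmentationOutcome(status="failure", reason=FAIL_EMPTY_IMAGE)

    labels, n = _foreground_labels(spx)
    if n == 0:
        return SegmentationOutcome(status="failure", reason=FAIL_EMPTY_IMAGE)

    breast_lab = _largest_component(labels, n, widths)
    candidate = ndimage.binary_fill_holes(labels == breast_lab)

    h, w = px.shape
    touches = {
        "left": bool(np.any(candidate[:, widths["left"]])),
        "right": bool(np.any(candidate[:, w - 1 - widths["right"]])),
        "top": bool(np.any(candidate[widths["top"], :])),
        "bottom": bool(np.any(candidate[h - 1 - widths["bottom"], :])),
    }
    n_vertical = touches["left"] + touches["right"]
    n_total = sum(touches.values())
    area_frac = candidate.sum() / (h * w)

    if n_vertical != 1 or n_total >= 3:
        log.info(
            "%s: breast candidate rejected (edge contacts %s)",
            image.source_id, touches,
        )
        return SegmentationOutcome(status="failure", reason=FAIL_BREAST_SEGMENTATION)
    if not (cfg.min_breast_frac <= area_frac <= cfg.max_breast_frac):
        log.info(
            "%s: breast candidate rejected (area fraction %.3f)",
            image.source_id, area_frac,
        )
        return SegmentationOutcome(status="failure", reason=FAIL_BREAST_SEGMENTATION)

    chest_edge = "left" if touches["left"] else "right"
    return SegmentationOutcome(
        status="success", mask=BreastMask(pixels=candidate, chest_edge=chest_edge)
    )
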