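"""Synthetic digitised-film mammogram phantoms and simulated screening cohorts.

The phantom generator emulates the gross structure of a scanned film
cranio-caudal mammogram: a bright half-elliptical breast attached to one
vertical image edge (the chest wall), dense sub-regions of controllable
area fraction and contrast, additive film-grain noise, and the background
clutter a film scanner introduces — a bright border frame and detached
high-intensity tag/nameplate blobs.  Ground-truth breast and dense masks
are returned alongside each image, so every stage of the measurement
pipeline can be validated without any image download.

The cohort generator draws simulated screening records: each woman gets a
latent population density percentile, categorical covariates, a pair of
correlated dense-area measures, and an outcome (small/large
screen-detected cancer, interval cancer, or no cancer) from a multinomial
logistic model whose per-density-group log-odds are the design parameters.
Cases are always retained; controls are subsampled at the per-round
sampling fractions (1.55% first round, 3.25% subsequent) and carry the
inverse fraction as analysis weight, mimicking a weighted case-control
sample from a screening programme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .image_io import GreyscaleImage
from .validation_stats import AGE_GROUPS, GROUP_LABELS, assign_group

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "PhantomGenerationError",
    "generate_phantom",
    "generate_cohort",
    "failure_spec",
]


class PhantomGenerationError(RuntimeError):
    """Raised when the dense-disc solver cannot hit the target fraction."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic mammogram.

    ``breast_axes`` are the horizontal and vertical semi-axes of the
    half-ellipse in pixels (defaults scale with the image).  Axes wider
    than the image deliberately produce a breast spanning both vertical
    edges — the characterised segmentation-failure geometry.
    """

    width: int = 256
    height: int = 256
    bit_depth: int = 8
    chest_edge: str = "left"  # which vertical edge the breast touches
    breast_axes: Optional[tuple[float, float]] = None
    dense_fraction: float = 0.25
    fatty_mean: float = 90.0
    dense_mean: float = 170.0
    noise_sd: float = 8.0
    border_width: int = 0
    tag: bool = False
    tag_size: tuple[int, int] = (20, 20)
    disc_radius_range: tuple[int, int] = (4, 16)
    dense_tolerance: float = 0.02  # |realised - target| bound on the fraction
    seed: int = 0

    def resolved_axes(self) -> tuple[float, float]:
        if self.breast_axes is not None:
            return self.breast_axes
        return 0.55 * self.width, 0.42 * self.height


def failure_spec(spec: PhantomSpec) -> PhantomSpec:
    """Variant of ``spec`` whose breast spans both vertical edges (under a
    scanner border), guaranteeing a breast-segmentation failure."""
    return replace(
        spec,
        breast_axes=(1.2 * spec.width, 0.48 * spec.height),
        border_width=max(spec.border_width, 6),
    )


def _breast_mask(spec: PhantomSpec) -> np.ndarray:
    a, b = spec.resolved_axes()
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    cy = spec.height / 2.0
    cx = 0.0 if spec.chest_edge == "left" else spec.width - 1.0
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def _place_dense_discs(
    spec: PhantomSpec, breast: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Non-overlapping random discs inside the breast, grown/shrunk until
    the realised dense fraction is within the tolerance of the target."""
    breast_area = int(breast.sum())
    target_px = spec.dense_fraction * breast_area
    tol_px = spec.dense_tolerance * breast_area
    if spec.dense_fraction == 0:
        return np.zeros_like(breast)

    dist = ndimage.distance_transform_edt(breast)
    r_min, r_max = spec.disc_radius_range
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]

    for attempt in range(100):
        dense = np.zeros_like(breast)
        cap = r_max
        while True:
            deficit = target_px - int(dense.sum())
            if deficit <= tol_px:
                return dense
            r = min(cap, max(2, int(math.sqrt(deficit / math.pi))))
            # centres keeping the disc inside the breast and off existing discs
            free = dist >= r + 1
            if dense.any():
                free &= ndimage.distance_transform_edt(~dense) > r
            idx = np.flatnonzero(free)
            if idx.size == 0:
                if r <= 2:
                    break  # jammed; retry from scratch
                cap = r - 1
                continue
            c = idx[rng.integers(idx.size)]
            cy, cx = divmod(int(c), spec.width)
            dense |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        realised = dense.sum() / breast_area
        if abs(realised - spec.dense_fraction) <= spec.dense_tolerance:
            return dense
    raise PhantomGenerationError(
        f"could not realise dense fraction {spec.dense_fraction:.2f} "
        f"within ±{spec.dense_tolerance:.2f} after 100 attempts"
    )


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[GreyscaleImage, np.ndarray, np.ndarray]:
    """Render one phantom; returns (image, true breast mask, true dense mask).

    Deterministic for a given spec (the seed is part of the spec).  Dense
    pixels are drawn at ``dense_mean`` and fatty ones at ``fatty_mean``,
    plus clipped Gaussian noise; the border frame and any tag are
    composited outside the breast at near-full intensity.
    """
    if spec.dense_mean <= spec.fatty_mean and spec.dense_fraction > 0:
        raise ValueError("dense_mean must exceed fatty_mean")
    if not 0 <= spec.dense_fraction <= 1:
        raise ValueError("dense_fraction must be in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    full = (1 << spec.bit_depth) - 1

    breast = _breast_mask(spec)
    dense = _place_dense_discs(spec, breast, rng)

    img = np.zeros((spec.height, spec.width), dtype=np.float64)
    img[breast] = spec.fatty_mean
    img[dense] = spec.dense_mean
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)

    if spec.tag:
        th, tw = spec.tag_size
        # top corner opposite the chest wall, clear of the breast
        y0 = 4
        x0 = spec.width - tw - 8 if spec.chest_edge == "left" else 8
        region = np.zeros_like(breast)
        region[y0 : y0 + th, x0 : x0 + tw] = True
        if np.any(region & ndimage.binary_dilation(breast, iterations=2)):
            raise PhantomGenerationError("tag position overlaps the breast")
        img[region] = 0.95 * full

    if spec.border_width > 0:
        w = spec.border_width
        img[:w, :] = full
        img[-w:, :] = full
        img[:, :w] = full
        img[:, -w:] = full

    img = np.clip(np.rint(img), 0, full)
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    image = GreyscaleImage(
        pixels=img.astype(dtype),
        bit_depth=spec.bit_depth,
        source_id=f"phantom_{spec.seed}",
    )
    return image, breast, dense


# ---------------------------------------------------------------------------
# simulated screening cohorts


def _default_group_logors() -> dict[str, tuple[float, ...]]:
    """Per-density-group log odds ratios (vs Q1) for each cancer outcome.

    Endpoints follow the graded associations an automated density measure
    shows against screening outcomes (highest-decile ORs about 2.2 for
    small screen-detected, 6.4 for large screen-detected and 4.7 for
    interval cancers); intermediate groups are interpolated monotonically.
    """
    return {
        "small_screen_detected": (0.0, 0.16, 0.32, 0.47, 0.63, math.log(2.2)),
        "large_screen_detected": (0.0, 0.37, 0.74, 1.11, 1.48, math.log(6.4)),
        "interval": (0.0, 0.31, 0.62, 0.93, 1.24, math.log(4.7)),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one simulated screening cohort.

    ``n_women`` is the size of the simulated screened population; the
    returned records are the analysis sample (all cases plus controls
    subsampled at the per-round sampling fractions, weighted by the
    inverse fraction).  ``q1_outcome_probs`` are per-screen outcome
    probabilities for a baseline-covariate woman in the lowest density
    quintile; their defaults give a Q1 programme sensitivity of 70%
    (interval odds 3/7 against screen-detected).  ``group_logors`` holds
    the designed per-group log-ORs for each cancer outcome.
    """

    n_women: int = 50_000
    sampling_fraction_round1: float = 0.0155
    sampling_fraction_subsequent: float = 0.0325
    p_first_round: float = 0.45
    age_group_probs: tuple[float, ...] = (0.09, 0.19, 0.20, 0.19, 0.19, 0.14)
    p_ht_use: float = 0.22
    p_family_history: float = 0.03
    p_symptoms: float = 0.06
    q1_outcome_probs: dict = field(
        default_factory=lambda: {
            "small_screen_detected": 0.005,
            "large_screen_detected": 0.0025,
            "interval": (3.0 / 7.0) * 0.0075,
        }
    )
    group_logors: dict = field(default_factory=_default_group_logors)
    covariate_logors: dict = field(
        default_factory=lambda: {
            "ht_use": math.log(1.3),
            "family_history": math.log(2.0),
            "symptoms": math.log(1.2),
            "subsequent_round": math.log(0.8),
        }
    )
    dense_area_median_a: float = 21_293.0
    dense_area_median_b: float = 18_400.0
    dense_area_log_sd: float = 0.9
    measure_correlation: float = 0.65  # latent-normal copula correlation
    p_microinvasive: float = 0.02
    seed: int = 0


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate one weighted case-control screening sample.

    Returns a DataFrame with the cohort CSV schema (woman_id, age_group,
    ht_use, family_history, symptoms, screening_round, outcome,
    tumour_size_mm, dense_area_px_a, dense_area_px_b, weight) plus a
    ``latent_percentile`` diagnostic column.  Covariate effects act
    equally on every cancer outcome, so the designed interval-versus-
    screen-detected odds per density group (and hence programme
    sensitivity) are untouched by the adjustment variables.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_women

    rounds = np.where(
        rng.random(n) < spec.p_first_round, "first", "subsequent"
    )
    age = rng.choice(AGE_GROUPS, size=n, p=np.asarray(spec.age_group_probs))
    ht = np.where(rng.random(n) < spec.p_ht_use, "yes", "no")
    fh = np.where(rng.random(n) < spec.p_family_history, "yes", "no")
    sym = np.where(rng.random(n) < spec.p_symptoms, "no-significant", "none")

    u = rng.uniform(0.0, 100.0, size=n)  # latent population percentile
    groups = assign_group(u)
    gidx = np.array([GROUP_LABELS.index(g) for g in groups])

    # linear predictor shared covariate part (equal across cancer outcomes)
    cov_lp = (
        (ht == "yes") * spec.covariate_logors["ht_use"]
        + (fh == "yes") * spec.covariate_logors["family_history"]
        + (sym != "none") * spec.covariate_logors["symptoms"]
        + (rounds == "subsequent") * spec.covariate_logors["subsequent_round"]
    )

    outcomes_order = ("small_screen_detected", "large_screen_detected", "interval")
    etas = np.empty((n, 3))
    for k, out in enumerate(outcomes_order):
        p0 = spec.q1_outcome_probs[out]
        p_ctrl0 = 1.0 - sum(spec.q1_outcome_probs.values())
        alpha = math.log(p0 / p_ctrl0)
        beta = np.asarray(spec.group_logors[out])[gidx]
        etas[:, k] = alpha + beta + cov_lp
    exp_eta = np.exp(etas)
    denom = 1.0 + exp_eta.sum(axis=1)
    probs = np.column_stack([exp_eta / denom[:, None], 1.0 / denom])
    cum = np.cumsum(probs, axis=1)
    draw = rng.random(n)
    choice = (draw[:, None] > cum).sum(axis=1)
    outcome = np.asarray(outcomes_order + ("control",), dtype=object)[choice]

    # correlated dense-area measures through a Gaussian copula
    z_a = stats.norm.ppf(np.clip(u / 100.0, 1e-12, 1 - 1e-12))
    rho = spec.measure_correlation
    z_b = rho * z_a + math.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    dense_a = np.exp(math.log(spec.dense_area_median_a) + spec.dense_area_log_sd * z_a)
    dense_b = np.exp(math.log(spec.dense_area_median_b) + spec.dense_area_log_sd * z_b)

    # tumour sizes consistent with the outcome labels
    size = np.full(n, np.nan)
    is_small = outcome == "small_screen_detected"
    is_large = outcome == "large_screen_detected"
    is_interval = outcome == "interval"
    size[is_small] = rng.uniform(1.0, 15.0, is_small.sum())
    size[is_large] = rng.uniform(15.1, 40.0, is_large.sum())
    size[is_interval] = rng.uniform(2.0, 40.0, is_interval.sum())
    micro = is_small & (rng.random(n) < spec.p_microinvasive)
    size[micro] = 0.1

    # retain all cases; subsample controls at the per-round fractions
    sf = np.where(
        rounds == "first",
        spec.sampling_fraction_round1,
        spec.sampling_fraction_subsequent,
    )
    is_control = outcome == "control"
    keep = ~is_control | (rng.random(n) < sf)
    weight = np.where(is_control, 1.0 / sf, 1.0)

    df = pd.DataFrame(
        {
            "woman_id": np.arange(n),
            "age_group": age,
            "ht_use": ht,
            "family_history": fh,
            "symptoms": sym,
            "screening_round": rounds,
            "outcome": outcome,
            "tumour_size_mm": size,
            "dense_area_px_a": dense_a,
            "dense_area_px_b": dense_b,
            "weight": weight,
            "latent_percentile": u,
        }
    )
    return df[keep].reset_index(drop=True)
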