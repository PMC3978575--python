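import numpy as np
import pytest
from dataclasses import replace

from mammodensity.breast_segmentation import BreastMask
from mammodensity.density_segmentation import (
    DensityFailure,
    compute_threshold,
    measure_density,
    process_image,
    segment_dense,
)
from mammodensity.image_io import GreyscaleImage
from mammodensity.phantom import PhantomSpec, failure_spec, generate_phantom


def _exhaustive_best_threshold(values, levels):
    """Independent oracle: scan every intensity level, computing the
    between-class variance of (<= t) vs (> t) directly from the pixels."""
    values = values.astype(np.float64)
    best_t, best_j = None, -1.0
    for t in range(levels):
        lo = values[values <= t]
        hi = values[values > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0 = lo.size / values.size
        w1 = hi.size / values.size
        j = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if j > best_j:
            best_j, best_t = j, t
    return best_t


def _full_mask(px):
    return np.ones_like(px, dtype=bool)


def test_two_level_breast_threshold_matches_exhaustive_scan():
    """60% of pixels at 50 and 40% at 200: any split between the levels is
    perfect; the returned threshold equals the exhaustive maximiser."""
    px = np.concatenate([np.full(60, 50), np.full(40, 200)]).astype(np.uint8)
    px = np.tile(px, (100, 1))
    img = GreyscaleImage(px, 8, "twolevel")
    t = compute_threshold(img, _full_mask(px))
    assert t == _exhaustive_best_threshold(px.ravel(), 256)
    assert 50 <= t < 200
    dense = segment_dense(img, _full_mask(px), t)
    assert dense.area_px == 40 * 100


def test_bimodal_gaussian_threshold_between_modes():
    rng = np.random.default_rng(5)
    vals = np.concatenate(
        [rng.normal(80, 10, 6000), rng.normal(180, 10, 4000)]
    )
    px = np.clip(np.rint(vals), 0, 255).astype(np.uint8).reshape(100, 100)
    img = GreyscaleImage(px, 8, "bimodal")
    t = compute_threshold(img, _full_mask(px))
    assert t == _exhaustive_best_threshold(px.ravel(), 256)
    assert 110 <= t <= 150


def test_constant_breast_is_degenerate_not_a_failure():
    px = np.full((80, 80), 100, dtype=np.uint8)
    img = GreyscaleImage(px, 8, "const")
    t = compute_threshold(img, _full_mask(px))
    assert t == 100
    assert segment_dense(img, _full_mask(px), t).area_px == 0


def test_segment_dense_strict_threshold_semantics(clean_phantom):
    image, breast, _ = clean_phantom
    vmax = int(image.pixels[breast].max())
    assert segment_dense(image, breast, vmax).area_px == 0
    assert segment_dense(image, breast, -1).area_px == breast.sum()


def test_measure_density_ratios():
    breast = BreastMask(np.zeros((50, 50), dtype=bool), "left")
    breast.pixels[:40, :25] = True  # 1000 px
    dense_px = np.zeros_like(breast.pixels)
    dense_px[:10, :25] = True  # 250 px
    from mammodensity.density_segmentation import DenseMask

    res = measure_density(breast, DenseMask(dense_px))
    assert res.percent_density == pytest.approx(25.0)
    res_full = measure_density(breast, DenseMask(breast.pixels.copy()))
    assert res_full.percent_density == 100.0
    bad = np.ones_like(breast.pixels)
    with pytest.raises(ValueError, match="subset"):
        measure_density(breast, DenseMask(bad))


def test_process_image_recovers_designed_density(clean_phantom, clean_spec):
    image, breast, dense = clean_phantom
    res = process_image(image)
    truth = 100.0 * dense.sum() / breast.sum()
    assert abs(res.percent_density - truth) <= 5.0
    assert 0 <= res.percent_density <= 100
    assert res.dense_area_px <= res.breast_area_px


def test_process_image_propagates_segmentation_failure(clean_spec):
    image, _, _ = generate_phantom(failure_spec(clean_spec))
    out = process_image(image)
    assert isinstance(out, DensityFailure)
    assert out.reason == "FAIL_BREAST_SEGMENTATION"


def test_process_image_is_deterministic(clean_phantom):
    image, _, _ = clean_phantom
    a = process_image(image)
    b = process_image(image)
    assert a == b


def test_threshold_independent_of_other_images(clean_spec):
    """Per-image independence: the threshold for one mammogram does not
    change when other images are processed before or after it."""
    image, _, _ = generate_phantom(clean_spec)
    alone = process_image(image)
    others = [generate_phantom(replace(clean_spec, seed=s))[0] for s in (21, 22)]
    batch = [process_image(im) for im in (others[0], image, others[1])]
    assert batch[1] == alone


def test_affine_intensity_remap_preserves_dense_set(clean_phantom):
    """Scaling breast intensities affinely rescales the threshold but
    selects the same dense-pixel set (the between-class-variance criterion
    is affine-equivariant)."""
    image, breast, _ = clean_phantom
    t = compute_threshold(image, breast)
    remapped = GreyscaleImage(
        (image.pixels.astype(np.uint16) * 2 + 7), bit_depth=16, source_id="remap"
    )
    t2 = compute_threshold(remapped, breast)
    d1 = segment_dense(image, breast, t)
    d2 = segment_dense(remapped, breast, t2)
    assert np.array_equal(d1.pixels, d2.pixels)
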