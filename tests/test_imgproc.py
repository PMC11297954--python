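"""Unit tests for the shared low-level image operations."""

import numpy as np
import pytest

from endoquant import (
    Image2D,
    binarize,
    gaussian_blur,
    isodata_threshold,
    project_stack,
    rolling_ball_subtract,
    sharpen,
    subtract_median_projection,
)
from endoquant.imgproc import rolling_ball_background

from conftest import make_stack


# ---------------------------------------------------------------------------
# oracles (independent implementations used only for comparison)


def naive_ball_opening(img: np.ndarray, r: int) -> np.ndarray:
    """Per-pixel min/max ball opening with replicate padding."""
    h, w = img.shape
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    fp = xx**2 + yy**2 <= r * r
    hei = np.zeros_like(xx, float)
    hei[fp] = np.sqrt(r * r - (xx**2 + yy**2)[fp]) - r
    pad = np.pad(img, r, mode="edge")
    ero = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            win = pad[i : i + 2 * r + 1, j : j + 2 * r + 1]
            ero[i, j] = np.min(win[fp] - hei[fp])
    pad2 = np.pad(ero, r, mode="edge")
    dil = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            win = pad2[i : i + 2 * r + 1, j : j + 2 * r + 1]
            dil[i, j] = np.max(win[fp] + hei[fp])
    return dil


def brute_force_isodata(pixels: np.ndarray) -> float:
    """Direct intermeans iteration on the raw pixel array (256 min-max bins)."""
    flat = np.asarray(pixels, float).ravel()
    lo, hi = flat.min(), flat.max()
    edges = np.linspace(lo, hi, 257)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # snap every pixel to its bin centre, as a histogram-based method sees it
    idx = np.clip(np.searchsorted(edges, flat, side="right") - 1, 0, 255)
    vals = centers[idx]
    t = flat.mean()
    for _ in range(500):
        below = vals[vals <= t]
        above = vals[vals > t]
        if len(below) == 0 or len(above) == 0:
            break
        t_new = 0.5 * (below.mean() + above.mean())
        if abs(t_new - t) < 1e-12:
            break
        t = t_new
    return t


def naive_convolve(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Nested-loop correlation with replicate padding (no clipping)."""
    kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    pad = np.pad(img, ((ph, ph), (pw, pw)), mode="edge")
    out = np.empty_like(img, float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = np.sum(pad[i : i + kh, j : j + kw] * kernel)
    return out


# ---------------------------------------------------------------------------
# projections


def test_project_single_slice_identity(rng):
    img = rng.uniform(0, 50, (8, 8))
    stack = make_stack([img])
    for method in ("average", "max", "sum", "median"):
        np.testing.assert_array_equal(project_stack(stack, method).pixels, img)


def test_project_average_arithmetic():
    stack = make_stack([[[0, 2], [4, 6]], [[2, 4], [0, 2]]])
    np.testing.assert_array_equal(
        project_stack(stack, "average").pixels, [[1, 3], [2, 4]]
    )


def test_project_max_constant():
    stack = make_stack([np.full((4, 4), 7.0)] * 5)
    np.testing.assert_array_equal(project_stack(stack, "max").pixels, np.full((4, 4), 7.0))


def test_project_average_times_n_equals_sum(rng):
    arrays = [rng.uniform(0, 10, (6, 6)) for _ in range(4)]
    stack = make_stack(arrays)
    np.testing.assert_allclose(
        project_stack(stack, "average").pixels * 4,
        project_stack(stack, "sum").pixels,
        rtol=0,
        atol=1e-12,
    )


def test_project_unknown_method_errors(rng):
    with pytest.raises(ValueError, match="projection method"):
        project_stack(make_stack([rng.uniform(0, 1, (4, 4))]), "geometric")


# ---------------------------------------------------------------------------
# rolling ball


def test_rolling_ball_flat_image_fully_removed():
    out = rolling_ball_subtract(Image2D(np.full((32, 32), 10.0)), 7)
    np.testing.assert_allclose(out.pixels, 0.0, atol=1e-9)


def test_rolling_ball_plateau_preserved_matches_oracle():
    img = np.full((64, 64), 10.0)
    img[30:33, 30:33] = 100.0
    bg = rolling_ball_background(Image2D(img), 50).pixels
    oracle = naive_ball_opening(img, 50)
    assert np.abs(bg - oracle).max() < 0.01 * img.max()
    out = rolling_ball_subtract(Image2D(img), 50)
    assert out.pixels[31, 31] > 85.0  # plateau retained
    assert out.pixels[5, 5] < 1.0  # flat background removed


def test_rolling_ball_ramp_removed():
    ramp = np.tile(np.linspace(0, 20, 96), (48, 1))
    r = 24
    out = rolling_ball_subtract(Image2D(ramp), r)
    # the ball hugs a plane exactly away from the replicate-padded border
    interior = out.pixels[:, r : 96 - r]
    assert interior.max() < 1e-6
    # and the full image agrees with the naive opening oracle everywhere
    oracle = np.clip(ramp - naive_ball_opening(ramp, r), 0, None)
    np.testing.assert_allclose(out.pixels, oracle, atol=1e-9)


@pytest.mark.parametrize("radius", [3, 9])
def test_rolling_ball_matches_naive_oracle_random(rng, radius):
    img = rng.uniform(0, 100, (32, 32))
    mine = rolling_ball_background(Image2D(img), radius).pixels
    oracle = naive_ball_opening(img, radius)
    np.testing.assert_allclose(mine, oracle, atol=1e-9)


def test_rolling_ball_bounds_property(rng):
    for _ in range(5):
        img = rng.uniform(0, 200, (24, 24))
        out = rolling_ball_subtract(Image2D(img), 5).pixels
        assert np.all(out >= 0)
        assert np.all(out <= img + 1e-9)


def test_rolling_ball_invalid_radius():
    with pytest.raises(ValueError, match="radius"):
        rolling_ball_subtract(Image2D(np.ones((4, 4))), 0)


# ---------------------------------------------------------------------------
# thresholding


def test_isodata_bimodal_example():
    img = np.concatenate([np.full(50, 10.0), np.full(50, 200.0)]).reshape(10, 10)
    mask = binarize(Image2D(img))
    assert mask.threshold == pytest.approx(105.0)
    assert mask.pixels.sum() == 50
    assert np.all(img[mask.pixels] == 200.0)


def test_binarize_fixed_extremes(rng):
    img = Image2D(rng.uniform(0, 100, (10, 10)))
    assert binarize(img, "fixed", img.pixels.max()).pixels.sum() == 0
    assert binarize(img, "fixed", -1.0).pixels.all()


def test_binarize_constant_image_warns_empty():
    with pytest.warns(UserWarning, match="constant"):
        mask = binarize(Image2D(np.full((6, 6), 3.0)))
    assert not mask.pixels.any()
    assert mask.threshold is None


def test_isodata_matches_brute_force_on_random_histograms(rng):
    for _ in range(200):
        n_modes = rng.integers(1, 4)
        parts = [
            rng.normal(rng.uniform(0, 255), rng.uniform(2, 40), rng.integers(50, 500))
            for _ in range(n_modes)
        ]
        pixels = np.clip(np.concatenate(parts), 0, 255)
        if pixels.max() == pixels.min():
            continue
        mine = isodata_threshold(pixels)
        oracle = brute_force_isodata(pixels)
        assert mine == pytest.approx(oracle, abs=1e-6)


def test_isodata_close_to_skimage_on_clean_bimodal(rng):
    from skimage.filters import threshold_isodata

    pixels = np.concatenate(
        [rng.normal(40, 5, 3000), rng.normal(200, 5, 3000)]
    ).clip(0, 255)
    mine = isodata_threshold(pixels)
    ref = threshold_isodata(pixels, nbins=256)
    bin_width = (pixels.max() - pixels.min()) / 256
    assert abs(mine - ref) < 3 * bin_width


def test_isodata_scale_invariant_mask(rng):
    img = Image2D(rng.uniform(0, 100, (20, 20)))
    doubled = img.with_pixels(img.pixels * 2)
    np.testing.assert_array_equal(
        binarize(img).pixels, binarize(doubled).pixels
    )


# ---------------------------------------------------------------------------
# convolution filters


def test_sharpen_preserves_constant():
    out = sharpen(Image2D(np.full((8, 8), 5.0)))
    np.testing.assert_allclose(out.pixels, 5.0, atol=1e-12)


def test_sharpen_impulse():
    img = np.zeros((7, 7))
    img[3, 3] = 1.0
    out = sharpen(Image2D(img)).pixels
    assert out[3, 3] == pytest.approx(3.0)
    assert out.sum() == pytest.approx(3.0)  # negative ring clipped away


def test_sharpen_matches_naive_convolution(rng):
    from endoquant.imgproc import SHARPEN_KERNEL
    from scipy import ndimage as ndi

    img = rng.uniform(0, 100, (16, 16))
    ours_preclip = ndi.correlate(img, SHARPEN_KERNEL, mode="nearest")
    oracle = naive_convolve(img, SHARPEN_KERNEL)
    np.testing.assert_allclose(ours_preclip, oracle, atol=1e-9)
    np.testing.assert_allclose(
        sharpen(Image2D(img)).pixels, np.clip(oracle, 0, None), atol=1e-9
    )


def test_gaussian_blur_constant_and_mass(rng):
    out = gaussian_blur(Image2D(np.full((10, 10), 4.0)), 2.0)
    np.testing.assert_allclose(out.pixels, 4.0, atol=1e-9)

    impulse = np.zeros((31, 31))
    impulse[15, 15] = 1.0
    blurred = gaussian_blur(Image2D(impulse), 2.0).pixels
    assert blurred.sum() == pytest.approx(1.0, abs=1e-6)

    blob = np.zeros((64, 64))
    blob[28:36, 28:36] = 50.0
    out = gaussian_blur(Image2D(blob), 3.0).pixels
    assert abs(out.sum() / blob.sum() - 1) < 1e-3


def test_gaussian_blur_bad_sigma():
    with pytest.raises(ValueError, match="sigma"):
        gaussian_blur(Image2D(np.ones((4, 4))), 0.0)


# ---------------------------------------------------------------------------
# temporal median subtraction


def test_median_projection_identical_frames_zero(rng):
    frame = rng.uniform(0, 50, (8, 8))
    stack = make_stack([frame] * 4, axis="time", frame_interval=10.0)
    out = subtract_median_projection(stack)
    for s in out.slices:
        np.testing.assert_allclose(s.pixels, 0.0, atol=1e-12)


def test_median_projection_values():
    stack = make_stack(
        [np.full((2, 2), v) for v in (1.0, 5.0, 9.0)], axis="time", frame_interval=1.0
    )
    out = subtract_median_projection(stack)
    residuals = [s.pixels[0, 0] for s in out.slices]
    assert residuals == [0.0, 0.0, 4.0]


def test_median_projection_moving_object_survives(rng):
    bg = rng.uniform(0, 10, (16, 16))
    frames = [bg.copy() for _ in range(5)]
    frames[2] = bg.copy()
    frames[2][8, 8] += 100.0
    stack = make_stack(frames, axis="time", frame_interval=1.0)
    out = subtract_median_projection(stack)
    assert out.slices[2].pixels[8, 8] == pytest.approx(100.0)
    assert out.slices[0].pixels.max() < 1e-9


def test_median_projection_single_frame_errors():
    stack = make_stack([np.ones((4, 4))], axis="time", frame_interval=1.0)
    with pytest.raises(ValueError, match="2 frames"):
        subtract_median_projection(stack)
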