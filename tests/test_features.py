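"""Morphometric features against independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import ndimage as ndi

from coccogate import make_coccolith, make_coccosphere
from coccogate.errors import FeatureUndefinedError
from coccogate.features import (
    aspect_ratio,
    circularity,
    equal_area_diameter,
    extract_feature_table,
    extract_features,
    gradient_rms,
    spot_count,
)
from coccogate.masking import BinaryMask, ObjectImage, object_tight_mask

from conftest import disk_mask


# --- independent oracles -------------------------------------------------

def flood_fill_count(grid: np.ndarray) -> int:
    """Hand-written 8-connected component count (stack-based flood fill)."""
    grid = grid.astype(bool)
    seen = np.zeros_like(grid)
    count = 0
    for start in zip(*np.nonzero(grid)):
        if seen[start]:
            continue
        count += 1
        stack = [start]
        seen[start] = True
        while stack:
            y, x = stack.pop()
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    ny, nx = y + dy, x + dx
                    if (
                        0 <= ny < grid.shape[0]
                        and 0 <= nx < grid.shape[1]
                        and grid[ny, nx]
                        and not seen[ny, nx]
                    ):
                        seen[ny, nx] = True
                        stack.append((ny, nx))
    return count


def boundary_distance_stats(mask: np.ndarray):
    """Brute-force boundary enumeration: mean/SD of distances to centroid."""
    coords = np.argwhere(mask)
    cy, cx = coords.mean(axis=0)
    dists = []
    for y, x in coords:
        for ny, nx in ((y - 1, x), (y + 1, x), (y, x - 1), (y, x + 1)):
            if (
                ny < 0 or nx < 0 or ny >= mask.shape[0] or nx >= mask.shape[1]
                or not mask[ny, nx]
            ):
                dists.append(math.hypot(y - cy, x - cx))
                break
    dists = np.asarray(dists)
    return dists.mean(), dists.std()


def moments_axis_ratio(mask: np.ndarray) -> float:
    """Aspect ratio from the eigenvalues of the pixel covariance matrix."""
    coords = np.argwhere(mask).astype(float)
    cov = np.cov(coords.T, bias=True) + np.eye(2) / 12.0  # pixel spread
    evals = np.sort(np.linalg.eigvalsh(cov))
    return math.sqrt(evals[0] / evals[1])


# --- equal-area diameter -------------------------------------------------

class TestEqualAreaDiameter:
    @pytest.mark.parametrize(
        "n_px,pixel_area,expected",
        [(100, 0.33, 2 * math.sqrt(33 / math.pi)), (1, 0.33, 2 * math.sqrt(0.33 / math.pi))],
    )
    def test_closed_form(self, n_px, pixel_area, expected):
        px = np.zeros((64, 64), bool)
        px.ravel()[:n_px] = True
        assert equal_area_diameter(BinaryMask(px.reshape(64, 64)), pixel_area) == pytest.approx(expected)

    def test_rotation_invariant(self, rng):
        px = rng.random((32, 32)) > 0.5
        m = BinaryMask(px)
        r = BinaryMask(np.rot90(px).copy())
        assert equal_area_diameter(m, 0.33) == equal_area_diameter(r, 0.33)

    def test_empty_mask_undefined(self):
        with pytest.raises(FeatureUndefinedError):
            equal_area_diameter(BinaryMask(np.zeros((4, 4), bool)), 0.33)

    def test_area_diameter_conservation(self, rng):
        for _ in range(20):
            px = rng.random((24, 24)) > 0.6
            if not px.any():
                continue
            d = equal_area_diameter(BinaryMask(px), 0.33)
            assert math.pi * (d / 2) ** 2 == pytest.approx(px.sum() * 0.33, rel=1e-9)


# --- circularity ---------------------------------------------------------

class TestCircularity:
    def test_rasterised_disk_scores_high(self):
        mask = disk_mask((64, 64), (32, 32), 20.0)
        assert circularity(mask) >= 10

    def test_square_matches_boundary_enumeration_oracle(self):
        px = np.zeros((31, 31), bool)
        px[5:26, 5:26] = True  # 21x21 solid square
        mean, sd = boundary_distance_stats(px)
        assert circularity(BinaryMask(px)) == pytest.approx(mean / sd)

    def test_random_blobs_match_oracle(self, rng):
        for _ in range(25):
            px = ndi.binary_dilation(rng.random((32, 32)) > 0.92, iterations=2)
            lbl, n = ndi.label(px)
            if n == 0:
                continue
            largest = lbl == np.argmax(np.bincount(lbl.ravel())[1:]) + 1
            mask = BinaryMask(largest)
            coords = np.argwhere(largest)
            if len(coords) < 12:
                continue
            mean, sd = boundary_distance_stats(largest)
            if sd == 0:
                continue
            assert circularity(mask) == pytest.approx(mean / sd)

    def test_degenerate_mask_undefined(self):
        px = np.zeros((4, 4), bool)
        px[1, 1:3] = True
        with pytest.raises(FeatureUndefinedError):
            circularity(BinaryMask(px))

    def test_decreases_with_radial_roughness(self, rng):
        """On a synthetic disk family, roughness monotonically lowers circularity."""
        values = []
        for rough in (0.0, 0.05, 0.12, 0.25):
            yy, xx = np.indices((64, 64), dtype=float)
            theta = np.arctan2(yy - 32, xx - 32)
            wobble = 1.0 + rough * np.cos(5 * theta)
            mask = BinaryMask(np.hypot(yy - 32, xx - 32) <= 18 * wobble)
            values.append(circularity(mask))
        assert all(a > b for a, b in zip(values, values[1:]))


# --- spot count ----------------------------------------------------------

class TestSpotCount:
    def test_seven_disjoint_blobs(self):
        px = np.zeros((40, 40), bool)
        for i in range(7):
            y, x = 5 + 5 * (i % 3), 5 + 10 * (i // 3)
            px[y : y + 2, x : x + 2] = True  # 4-px blobs, well separated
        assert spot_count(BinaryMask(px, "peak_range")) == 7

    def test_empty_mask_counts_zero(self):
        assert spot_count(BinaryMask(np.zeros((8, 8), bool), "peak_range")) == 0

    @given(st.integers(0, 2**31 - 1))
    def test_matches_flood_fill_oracle_on_random_grids(self, seed):
        grid = np.random.default_rng(seed).random((16, 16)) > 0.65
        assert spot_count(BinaryMask(grid, "peak_range")) == flood_fill_count(grid)


# --- gradient RMS --------------------------------------------------------

class TestGradientRMS:
    def test_uniform_image_scores_zero(self):
        mask = BinaryMask(np.ones((16, 16), bool))
        img = ObjectImage(np.full((16, 16), 80.0), 0.33)
        assert gradient_rms(img, mask) == 0.0

    def test_blur_strictly_lowers_score(self):
        img, _ = make_coccolith(5.0, seed=9)
        mask = object_tight_mask(img)
        sharp = gradient_rms(img, mask)
        prev = sharp
        for sigma in (1.0, 2.0, 4.0):
            blurred = ObjectImage(ndi.gaussian_filter(img.pixels, sigma), 0.33)
            score = gradient_rms(blurred, mask)
            assert score < prev
            prev = score

    def test_focus_threshold_separates_generator_classes(self):
        """In-focus objects score > 15; a sigma=4 blur drops below 15."""
        img, _ = make_coccolith(5.0, seed=2)
        mask = object_tight_mask(img)
        assert gradient_rms(img, mask) > 15
        blurred = ObjectImage(
            np.clip(np.round(ndi.gaussian_filter(img.pixels, 4.0)), 0, 255), 0.33
        )
        bmask = object_tight_mask(blurred)
        assert gradient_rms(blurred, bmask) <= 15

    def test_empty_mask_undefined(self, bright_disk):
        with pytest.raises(FeatureUndefinedError):
            gradient_rms(bright_disk, BinaryMask(np.zeros(bright_disk.shape, bool)))


# --- aspect ratio --------------------------------------------------------

class TestAspectRatio:
    def test_disk_is_round(self):
        assert aspect_ratio(disk_mask((64, 64), (32, 32), 20.0)) == pytest.approx(1.0, abs=0.02)

    def test_two_to_one_ellipse(self):
        yy, xx = np.indices((64, 64), dtype=float)
        px = ((xx - 32) / 24) ** 2 + ((yy - 32) / 12) ** 2 <= 1.0
        mask = BinaryMask(px)
        assert aspect_ratio(mask) == pytest.approx(0.5, abs=0.02)
        assert aspect_ratio(mask) == pytest.approx(moments_axis_ratio(px), abs=0.02)

    def test_tangent_doublet_fails_singlet_threshold(self):
        yy, xx = np.indices((64, 64), dtype=float)
        px = (np.hypot(yy - 32, xx - 22) <= 10) | (np.hypot(yy - 32, xx - 42) <= 10)
        ratio = aspect_ratio(BinaryMask(px))
        assert ratio < 0.75
        # closed form: per-disk variance r^2/4, plus r^2 center offset along
        # the axis -> sqrt((1/4) / (5/4)) = 0.447
        assert ratio == pytest.approx(math.sqrt(1 / 5), abs=0.02)
        assert ratio == pytest.approx(moments_axis_ratio(px), abs=0.02)

    def test_collinear_mask_returns_near_zero(self):
        px = np.zeros((8, 8), bool)
        px[3, 1:7] = True
        assert aspect_ratio(BinaryMask(px)) <= 0.05

    def test_single_pixel_undefined(self):
        px = np.zeros((4, 4), bool)
        px[1, 1] = True
        with pytest.raises(FeatureUndefinedError):
            aspect_ratio(BinaryMask(px))


# --- extract_features ----------------------------------------------------

class TestExtractFeatures:
    def test_coccosphere_record_matches_truth(self):
        img, truth = make_coccosphere(8.0, 12, seed=21)
        rec = extract_features(img)
        assert rec.detected
        assert rec.diameter_um == pytest.approx(truth.true_diameter_um, rel=0.10)
        assert rec.circularity >= 10
        assert rec.spot_count >= 5

    def test_all_dark_image_flagged_non_detected(self):
        rec = extract_features(ObjectImage(np.zeros((32, 32)), 0.33, "dark"))
        assert not rec.detected
        assert math.isnan(rec.diameter_um)
        assert rec.spot_count == 0

    def test_batch_preserves_ids_and_order(self):
        imgs = [make_coccolith(5.0, seed=s, object_id=f"o{s}")[0] for s in range(5)]
        table = extract_feature_table(imgs)
        assert list(table["object_id"]) == [f"o{s}" for s in range(5)]

    def test_translation_invariance(self):
        img, _ = make_coccolith(5.0, seed=4)
        shifted = ObjectImage(np.roll(img.pixels, (5, -7), axis=(0, 1)), 0.33)
        a, b = extract_features(img), extract_features(shifted)
        assert a.diameter_um == pytest.approx(b.diameter_um)
        assert a.spot_count == b.spot_count
        assert a.circularity == pytest.approx(b.circularity)
        assert a.aspect_ratio == pytest.approx(b.aspect_ratio)

    def test_rotation_invariance_of_scalar_features(self):
        img, _ = make_coccosphere(9.0, 12, seed=6)
        rotated = ObjectImage(np.rot90(img.pixels).copy(), 0.33)
        a, b = extract_features(img), extract_features(rotated)
        assert a.diameter_um == pytest.approx(b.diameter_um)
        assert a.area_um2 == pytest.approx(b.area_um2)
        assert a.spot_count == b.spot_count
        assert a.circularity == pytest.approx(b.circularity)
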