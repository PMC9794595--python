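"""Rasterisation against an independent geometric oracle, NLM behaviour,
and the deterministic largest-remainder dataset split."""

import json

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from rdaunet import imaging_io
from rdaunet.imaging_io import NlmParams, SplitSpec


def _shapely_scan(points, shape):
    """Brute-force oracle: pixel centre inside-or-on-boundary, via shapely."""
    poly = Polygon(points)
    H, W = shape
    mask = np.zeros((H, W), dtype=np.uint8)
    for y in range(H):
        for x in range(W):
            if poly.covers(Point(x, y)):
                mask[y, x] = 1
    return mask


def test_empty_shapes_gives_zero_mask():
    doc = {"version": "5.2.1", "shapes": []}
    assert imaging_io.labelme_to_mask(doc, (8, 8)).sum() == 0


def test_axis_aligned_square_matches_pixel_scan():
    pts = [(2, 2), (6, 2), (6, 6), (2, 6)]
    mask = imaging_io.polygon_to_mask(np.array(pts, float), (10, 10))
    oracle = _shapely_scan(pts, (10, 10))
    assert np.array_equal(mask, oracle)
    assert mask.sum() == 25      # boundary-inclusive 5x5 block


@pytest.mark.parametrize("seed", range(12))
def test_random_convex_polygons_match_shapely_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 13))
    # convex polygon: sorted angles around a centre
    angles = np.sort(rng.uniform(0, 2 * np.pi, size=n))
    radii = rng.uniform(3, 14, size=n)
    cx, cy = rng.uniform(15, 35, size=2)
    pts = np.stack([cx + radii * np.cos(angles),
                    cy + radii * np.sin(angles)], axis=1)
    mask = imaging_io.polygon_to_mask(pts.copy(), (50, 50))
    oracle = _shapely_scan(pts, (50, 50))
    assert np.array_equal(mask, oracle)


def test_two_overlapping_polygons_union_semantics():
    a = {"label": "x", "points": [[1, 1], [6, 1], [6, 6], [1, 6]],
         "shape_type": "polygon"}
    b = {"label": "x", "points": [[4, 4], [9, 4], [9, 9], [4, 9]],
         "shape_type": "polygon"}
    doc = {"shapes": [a, b]}
    union = imaging_io.labelme_to_mask(doc, (12, 12))
    ma = imaging_io.labelme_to_mask({"shapes": [a]}, (12, 12))
    mb = imaging_io.labelme_to_mask({"shapes": [b]}, (12, 12))
    assert np.array_equal(union, ma | mb)
    assert union.sum() <= ma.sum() + mb.sum()


def test_degenerate_polygon_skipped_with_warning():
    doc = {"shapes": [{"label": "x", "points": [[1, 1], [2, 2]],
                       "shape_type": "polygon"}]}
    with pytest.warns(UserWarning, match="degenerate"):
        mask = imaging_io.labelme_to_mask(doc, (5, 5))
    assert mask.sum() == 0


def test_malformed_json_raises():
    with pytest.raises(ValueError, match="malformed"):
        imaging_io.labelme_to_mask("{not json", (5, 5))


# ---------------------------------------------------------------------------
# non-local means

def test_nlm_constant_image_is_fixed_point():
    img = np.full((32, 32), 0.4)
    out = imaging_io.nlm_denoise(img, NlmParams(h=0.1, patch_size=5,
                                                search_window=11))
    assert out.shape == img.shape
    assert np.allclose(out, 0.4, atol=1e-12)


def test_nlm_small_h_approaches_identity(rng):
    img = rng.uniform(0.2, 0.8, size=(24, 24))
    out = imaging_io.nlm_denoise(img, NlmParams(h=1e-6, patch_size=3,
                                                search_window=7))
    assert np.abs(out - img).max() < 1e-3


def test_nlm_reduces_noise_variance(rng):
    img = 0.5 + rng.normal(0, 0.1, size=(64, 64))
    out = imaging_io.nlm_denoise(img, NlmParams(h=0.15, patch_size=5,
                                                search_window=15))
    assert out.shape == img.shape
    assert out.var() < img.var()
    assert out.min() >= img.min() - 1e-9 and out.max() <= img.max() + 1e-9


def test_nlm_rejects_bad_input(rng):
    with pytest.raises(ValueError, match="finite"):
        imaging_io.nlm_denoise(np.array([[np.nan, 1.0], [0.0, 0.5]]))
    with pytest.raises(ValueError):
        imaging_io.nlm_denoise(rng.random((4, 4, 3)))
    with pytest.raises(ValueError):
        NlmParams(patch_size=4)
    with pytest.raises(ValueError):
        NlmParams(search_window=5, patch_size=7)


# ---------------------------------------------------------------------------
# splitting

def test_split_200_items_at_14_3_3():
    train, val, test = imaging_io.split_dataset(list(range(200)),
                                                SplitSpec(seed=0))
    assert (len(train), len(val), len(test)) == (140, 30, 30)


def test_split_exact_division_and_partition():
    items = list(range(20))
    train, val, test = imaging_io.split_dataset(items, SplitSpec(seed=3))
    assert (len(train), len(val), len(test)) == (14, 3, 3)
    assert sorted(train + val + test) == items


@pytest.mark.parametrize("n", [1, 7, 53, 199])
def test_split_sizes_sum_and_largest_remainder(n):
    parts = imaging_io.split_dataset(list(range(n)), SplitSpec(seed=1))
    sizes = [len(p) for p in parts]
    assert sum(sizes) == n
    # largest-remainder apportionment never deviates by more than 1 from exact
    for s, r in zip(sizes, (14, 3, 3)):
        assert abs(s - n * r / 20) < 1


def test_split_deterministic_and_seed_sensitive():
    items = list(range(100))
    a = imaging_io.split_dataset(items, SplitSpec(seed=5))
    b = imaging_io.split_dataset(items, SplitSpec(seed=5))
    c = imaging_io.split_dataset(items, SplitSpec(seed=6))
    assert a == b
    assert a[0] != c[0]


from hypothesis import given, settings
from hypothesis import strategies as st


@given(n=st.integers(1, 400), seed=st.integers(0, 2 ** 31 - 1))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_split_partition_property(n, seed):
    """Any n and seed: disjoint exhaustive partition, sizes within one of
    the exact ratio apportionment."""
    parts = imaging_io.split_dataset(list(range(n)), SplitSpec(seed=seed))
    sizes = [len(p) for p in parts]
    assert sum(sizes) == n
    assert sorted(parts[0] + parts[1] + parts[2]) == list(range(n))
    for s, r in zip(sizes, (14, 3, 3)):
        exact = n * r / 20
        assert np.floor(exact) <= s <= np.ceil(exact)


def test_split_empty_raises():
    with pytest.raises(ValueError):
        imaging_io.split_dataset([], SplitSpec())


# ---------------------------------------------------------------------------
# files and tiling

def test_mask_png_round_trip(tmp_path, rng):
    mask = (rng.random((16, 16)) > 0.5).astype(np.uint8)
    path = tmp_path / "m.png"
    imaging_io.save_mask(mask, path)
    assert np.array_equal(imaging_io.load_mask(path), mask)


def test_annotated_image_invariants(rng):
    img = rng.random((8, 8))
    with pytest.raises(ValueError, match="shape"):
        imaging_io.AnnotatedImage(img, np.zeros((4, 4), np.uint8))
    with pytest.raises(ValueError, match="mask values"):
        imaging_io.AnnotatedImage(img, np.full((8, 8), 2, np.uint8))


def test_pad_tile_stitch_round_trip(rng):
    img = rng.random((70, 90))
    padded, orig = imaging_io.pad_to_multiple(img, 16)
    assert padded.shape == (80, 96) and orig == (70, 90)
    tiles = imaging_io.tile_image(img, tile=32, overlap=8)
    rebuilt = imaging_io.stitch_tiles(tiles, img.shape, overlap=8)
    assert np.allclose(rebuilt, img)
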