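"""Shape-descriptor extraction from binary drawings."""

import math

import numpy as np
import pytest
from scipy import ndimage
from skimage import draw, measure

from phossum.drawing import (
    Drawing,
    DrawingFormatError,
    Phosphene,
    ShapeDescriptors,
    extract_phosphenes,
    mean_image,
    raw_moment,
    shape_descriptors,
    validate_drawing,
)


def _random_mask(rng, shape=(5, 5), p=0.5):
    m = (rng.random(shape) < p).astype(np.uint8)
    if not m.any():
        m[shape[0] // 2, shape[1] // 2] = 1
    return m


def _brute_moment(mask, i, j):
    total = 0.0
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c]:
                total += (c**i) * (r**j)  # x = column, y = row
    return total


# ---------------------------------------------------------------------------
# raw moments
# ---------------------------------------------------------------------------

def test_raw_moment_single_pixel():
    m = np.zeros((10, 10), dtype=np.uint8)
    m[7, 3] = 1  # x=3, y=7
    d = Drawing(m)
    assert raw_moment(d, 0, 0) == 1
    assert raw_moment(d, 1, 0) == 3
    assert raw_moment(d, 0, 1) == 7


def test_raw_moment_block_and_errors():
    m = np.zeros((4, 4), dtype=np.uint8)
    m[0:2, 0:2] = 1
    assert raw_moment(Drawing(m), 0, 0) == 4
    with pytest.raises(ValueError):
        raw_moment(Drawing(m), -1, 0)


@pytest.mark.parametrize("seed", range(10))
def test_raw_moment_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    mask = _random_mask(rng)
    for i in range(3):
        for j in range(3):
            assert raw_moment(mask, i, j) == pytest.approx(
                _brute_moment(mask, i, j)
            )


# ---------------------------------------------------------------------------
# per-phosphene descriptors
# ---------------------------------------------------------------------------

def test_square_area_centroid():
    m = np.zeros((5, 5), dtype=np.uint8)
    m[1:4, 1:4] = 1
    p = Phosphene(*np.nonzero(m))
    area, _, _, _, centroid = shape_descriptors(p)
    assert area == 9
    assert centroid == (2.0, 2.0)


def test_horizontal_line_axis_lengths():
    # 1x9 line: zero vertical variance; Var(x) = 60/9
    m = np.zeros((3, 9), dtype=np.uint8)
    m[1, :] = 1
    p = Phosphene(*np.nonzero(m))
    assert p.minor_axis_length == pytest.approx(0.0)
    assert p.major_axis_length == pytest.approx(4.0 * math.sqrt(60.0 / 9.0))


@pytest.mark.parametrize("shape", [(3, 3), (2, 2), (4, 7), (5, 5), (2, 9)])
def test_perimeter_rectangles_closed_form(shape):
    # polyline through border-pixel centers of an m x n rectangle: 2(m+n) - 4
    m, n = shape
    a = np.zeros((m + 2, n + 2), dtype=np.uint8)
    a[1 : m + 1, 1 : n + 1] = 1
    p = Phosphene(*np.nonzero(a))
    assert p.perimeter == pytest.approx(2 * (m + n) - 4)


def test_perimeter_degenerate_single_pixel():
    p = Phosphene(np.array([3]), np.array([4]))
    assert p.perimeter == 0.0


@pytest.mark.parametrize("seed", range(8))
def test_descriptors_match_regionprops(seed):
    """Cross-library check of all descriptors on random blobs."""
    rng = np.random.default_rng(seed)
    mask = np.zeros((40, 40), dtype=np.uint8)
    for _ in range(3):
        r, c = rng.integers(8, 32, size=2)
        rad = rng.integers(2, 6)
        rr, cc = draw.disk((r, c), rad, shape=mask.shape)
        mask[rr, cc] = 1
    labels = measure.label(mask, connectivity=2)
    for region in measure.regionprops(labels):
        p = Phosphene(region.coords[:, 0], region.coords[:, 1])
        assert p.area == region.area
        assert p.centroid == pytest.approx(region.centroid[::-1])
        assert p.major_axis_length == pytest.approx(
            region.axis_major_length, abs=1e-9
        )
        assert p.minor_axis_length == pytest.approx(
            region.axis_minor_length, abs=1e-9
        )
        if region.area > 1:
            assert p.perimeter == pytest.approx(region.perimeter)


@pytest.mark.parametrize("seed", range(5))
def test_translation_invariance(seed):
    rng = np.random.default_rng(seed)
    mask = np.zeros((30, 30), dtype=np.uint8)
    mask[5:12, 4:14] = _random_mask(rng, (7, 10), 0.7)
    p0 = Phosphene(*np.nonzero(mask))
    shifted = np.roll(np.roll(mask, 9, axis=0), 7, axis=1)
    p1 = Phosphene(*np.nonzero(shifted))
    assert p1.area == p0.area
    assert p1.perimeter == pytest.approx(p0.perimeter)
    assert p1.major_axis_length == pytest.approx(p0.major_axis_length)
    assert p1.minor_axis_length == pytest.approx(p0.minor_axis_length)
    assert p1.centroid[0] == pytest.approx(p0.centroid[0] + 7)
    assert p1.centroid[1] == pytest.approx(p0.centroid[1] + 9)


@pytest.mark.parametrize("seed", range(5))
def test_rotation_90_preserves_axis_set(seed):
    rng = np.random.default_rng(seed)
    mask = _random_mask(rng, (8, 12), 0.6)
    p0 = Phosphene(*np.nonzero(mask))
    p1 = Phosphene(*np.nonzero(np.rot90(mask)))
    assert p1.area == p0.area
    assert p1.major_axis_length == pytest.approx(p0.major_axis_length)
    assert p1.minor_axis_length == pytest.approx(p0.minor_axis_length)


@pytest.mark.parametrize("seed", range(10))
def test_minor_never_exceeds_major(seed):
    rng = np.random.default_rng(100 + seed)
    p = Phosphene(*np.nonzero(_random_mask(rng, (9, 9), 0.4)))
    assert 0.0 <= p.minor_axis_length <= p.major_axis_length


def test_empty_phosphene_rejected():
    with pytest.raises(ValueError):
        Phosphene(np.array([]), np.array([]))


# ---------------------------------------------------------------------------
# drawing validation
# ---------------------------------------------------------------------------

def test_validate_solid_square_unchanged():
    m = np.zeros((9, 9), dtype=np.uint8)
    m[2:7, 2:7] = 1
    out = validate_drawing(m)
    assert np.array_equal(out.pixels, m)


def test_validate_empty_flagged():
    out = validate_drawing(np.zeros((5, 5)))
    assert out.is_empty
    assert not out.pixels.any()


def test_validate_closes_gapped_outline_flood_fill_oracle():
    """A 1-px circle outline with a 1-px gap becomes a filled disc whose
    area matches an independent background flood fill of the closed outline."""
    m = np.zeros((41, 41), dtype=np.uint8)
    rr, cc = draw.circle_perimeter(20, 20, 12)
    m[rr, cc] = 1
    m[20, 32] = 0  # knock a 1-px gap into the outline
    out = validate_drawing(m, close_radius=1)
    # oracle: close the gap by hand, then flood-fill the background from the
    # border; interior = everything the flood never reaches
    closed = m.copy()
    closed[20, 32] = 1
    from collections import deque

    bg = np.zeros_like(closed, dtype=bool)
    q = deque([(0, 0)])
    bg[0, 0] = True
    while q:
        r, c = q.popleft()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr_, cc_ = r + dr, c + dc
            if (0 <= rr_ < 41 and 0 <= cc_ < 41 and not bg[rr_, cc_]
                    and not closed[rr_, cc_]):
                bg[rr_, cc_] = True
                q.append((rr_, cc_))
    oracle_filled = (~bg).sum()
    # the morphological closing thickens the ring slightly relative to the
    # hand-closed outline, so the filled area may only exceed the oracle's
    assert out.pixels.sum() >= oracle_filled
    assert out.pixels.sum() <= oracle_filled + rr.size * 3
    # the interior pixel grid is now solid: no holes remain
    assert np.array_equal(
        out.pixels.astype(bool), ndimage.binary_fill_holes(out.pixels)
    )


def test_validate_binarizes_grayscale_and_rejects_out_of_range():
    gray = np.full((4, 4), 0.4)
    gray[1:3, 1:3] = 0.9
    out = validate_drawing(gray, close_radius=0)
    assert out.pixels.sum() == 4
    with pytest.raises(DrawingFormatError):
        validate_drawing(np.full((3, 3), 2.0))
    with pytest.raises(DrawingFormatError):
        Drawing(np.full((3, 3), 5, dtype=np.uint8))


# ---------------------------------------------------------------------------
# phosphene extraction and the small-region filter
# ---------------------------------------------------------------------------

def _drawing_with(regions):
    m = np.zeros((40, 80), dtype=np.uint8)
    for (r, c, h, w) in regions:
        m[r : r + h, c : c + w] = 1
    return Drawing(m)


def test_spec_filter_rare_small_region_dropped():
    big = (5, 5, 10, 10)          # 100 px
    spec = (25, 60, 1, 5)         # 5 px
    trial_set = [
        _drawing_with([big, spec] if t < 2 else [big]) for t in range(10)
    ]
    out = extract_phosphenes(trial_set)
    assert all(sd.number_of_phosphenes == 1 for _, sd in out)


def test_spec_filter_prevalent_small_region_kept():
    big = (5, 5, 10, 10)
    spec = (25, 60, 1, 5)
    trial_set = [_drawing_with([big, spec]) for _ in range(10)]
    out = extract_phosphenes(trial_set)
    assert all(sd.number_of_phosphenes == 2 for _, sd in out)


def test_two_large_regions_totals_sum():
    a = (5, 5, 10, 10)
    b = (25, 40, 10, 10)
    trial_set = [_drawing_with([a, b]) for _ in range(4)]
    out = extract_phosphenes(trial_set)
    for phosphenes, sd in out:
        assert sd.number_of_phosphenes == 2
        assert sd.area == sum(p.area for p in phosphenes) == 200
        assert sd.perimeter == sum(p.perimeter for p in phosphenes)


def test_spec_filter_idempotent():
    big = (5, 5, 10, 10)
    spec = (25, 60, 1, 5)
    trial_set = [
        _drawing_with([big, spec] if t < 3 else [big]) for t in range(10)
    ]
    out1 = extract_phosphenes(trial_set)
    rebuilt = []
    for (phosphenes, _), d in zip(out1, trial_set):
        m = np.zeros_like(d.pixels)
        for p in phosphenes:
            m[p.rows, p.cols] = 1
        rebuilt.append(Drawing(m))
    out2 = extract_phosphenes(rebuilt)
    for (_, sd1), (_, sd2) in zip(out1, out2):
        assert sd1 == sd2


def test_extract_requires_nonempty_trial_set():
    with pytest.raises(ValueError):
        extract_phosphenes([])


def test_descriptors_zero_iff_no_phosphenes():
    sd = ShapeDescriptors.from_phosphenes([])
    assert sd.number_of_phosphenes == 0
    assert sd.area == sd.perimeter == 0.0


# ---------------------------------------------------------------------------
# mean images
# ---------------------------------------------------------------------------

def test_mean_image_identical_drawings():
    d = _drawing_with([(5, 5, 8, 8)])
    out = mean_image([d] * 5)
    assert np.array_equal(out, d.pixels.astype(float))


def test_mean_image_alignment_removes_translation():
    base = np.zeros((40, 40), dtype=np.uint8)
    base[10:18, 10:18] = 1
    shifted = np.roll(np.roll(base, 5, axis=0), -3, axis=1)
    out = mean_image([Drawing(base), Drawing(shifted)])
    assert set(np.unique(out)) <= {0.0, 1.0}
    assert (out == 1.0).sum() == base.sum()


def test_mean_image_support_between_intersection_and_union(rng):
    base = np.zeros((60, 60), dtype=np.uint8)
    rr, cc = draw.disk((30, 30), 8)
    base[rr, cc] = 1
    drawings = []
    for _ in range(6):
        dr, dc = rng.integers(-4, 5, size=2)
        drawings.append(Drawing(np.roll(np.roll(base, dr, axis=0), dc, axis=1)))
    out = mean_image(drawings)
    support = (out > 0).sum()
    # aligned discs: support can't be smaller than one disc (intersection
    # of identical shapes after exact alignment) nor exceed the jitter union
    assert base.sum() * 0.8 <= support <= base.sum() * 3


def test_mean_image_all_empty_raises():
    with pytest.raises(ValueError):
        mean_image([Drawing(np.zeros((5, 5), dtype=np.uint8))])
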