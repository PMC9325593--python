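"""Binary morphology against brute-force set-definition oracles."""

import numpy as np
import pytest

from dermseg.morphology import (
    area_open,
    component_sizes,
    disk_element,
    fill_holes,
    largest_component,
    morph_close,
    morph_open,
    square_element,
)

# ---------------------------------------------------------------- oracles


def _offsets(footprint):
    r = footprint.shape[0] // 2
    return [tuple(o - r) for o in np.argwhere(footprint)]


def erode_oracle(mask, footprint):
    """x kept iff every SE offset lands on foreground (outside frame = 0)."""
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    offs = _offsets(footprint)
    for i in range(h):
        for j in range(w):
            ok = True
            for di, dj in offs:
                y, x = i + di, j + dj
                if not (0 <= y < h and 0 <= x < w and mask[y, x]):
                    ok = False
                    break
            out[i, j] = ok
    return out


def dilate_oracle(mask, footprint):
    """x set iff some reflected SE offset reaches foreground."""
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    offs = _offsets(footprint)
    for i in range(h):
        for j in range(w):
            for di, dj in offs:
                y, x = i - di, j - dj
                if 0 <= y < h and 0 <= x < w and mask[y, x]:
                    out[i, j] = True
                    break
    return out


def open_oracle(mask, footprint):
    return dilate_oracle(erode_oracle(mask, footprint), footprint)


def close_oracle(mask, footprint):
    # evaluate on a padded canvas so the infinite-plane closing is exact
    # on the image region, then crop back
    r = footprint.shape[0] // 2
    padded = np.pad(mask, r, constant_values=False)
    closed = erode_oracle(dilate_oracle(padded, footprint), footprint)
    return closed[r:-r, r:-r]


def fill_holes_oracle(mask):
    """Flood-fill background from the border with 4-connectivity."""
    h, w = mask.shape
    reach = np.zeros((h, w), dtype=bool)
    stack = [
        (i, j)
        for i in range(h)
        for j in range(w)
        if (i in (0, h - 1) or j in (0, w - 1)) and not mask[i, j]
    ]
    for p in stack:
        reach[p] = True
    while stack:
        i, j = stack.pop()
        for y, x in ((i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)):
            if 0 <= y < h and 0 <= x < w and not mask[y, x] and not reach[y, x]:
                reach[y, x] = True
                stack.append((y, x))
    return mask | ~reach


def area_open_oracle(mask, min_size):
    h, w = mask.shape
    seen = np.zeros((h, w), dtype=bool)
    out = np.zeros_like(mask, dtype=bool)
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                comp, stack = [], [(i, j)]
                seen[i, j] = True
                while stack:
                    y, x = stack.pop()
                    comp.append((y, x))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if (
                                0 <= yy < h and 0 <= xx < w
                                and mask[yy, xx] and not seen[yy, xx]
                            ):
                                seen[yy, xx] = True
                                stack.append((yy, xx))
                if len(comp) >= min_size:
                    for p in comp:
                        out[p] = True
    return out


def random_masks(rng, n, shape=(16, 16)):
    for _ in range(n):
        yield rng.random(shape) < rng.uniform(0.2, 0.7)


# ------------------------------------------------------------------ tests


class TestDiskElement:
    def test_radius_one_is_plus(self):
        fp = disk_element(1).footprint
        assert fp.sum() == 5
        np.testing.assert_array_equal(
            fp, [[0, 1, 0], [1, 1, 1], [0, 1, 0]]
        )

    def test_radius_two_lattice_count(self):
        fp = disk_element(2).footprint
        assert fp.shape == (5, 5)
        assert fp.sum() == 13  # lattice points with i^2+j^2 <= 4

    @pytest.mark.parametrize("radius", [1, 2, 3, 9])
    def test_rotation_symmetric(self, radius):
        fp = disk_element(radius).footprint
        np.testing.assert_array_equal(fp, np.rot90(fp))

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            disk_element(0)

    def test_square_element(self):
        assert square_element(3).footprint.sum() == 9
        with pytest.raises(ValueError):
            square_element(4)


class TestOpenClose:
    def test_isolated_pixel_vanishes_under_opening(self):
        m = np.zeros((9, 9), dtype=bool)
        m[4, 4] = True
        assert not morph_open(m, disk_element(1)).any()

    def test_large_square_opening_keeps_interior_shape(self):
        # only the four sharp corners are clipped by a disk opening
        m = np.zeros((31, 31), dtype=bool)
        m[5:26, 5:26] = True
        out = morph_open(m, disk_element(1))
        corners = {(5, 5), (5, 25), (25, 5), (25, 25)}
        assert set(map(tuple, np.argwhere(m & ~out))) == corners
        assert np.all(out <= m)

    def test_closing_fills_interior_hole(self):
        m = np.ones((11, 11), dtype=bool)
        m[5, 5] = False
        assert morph_close(m, disk_element(1)).all()

    def test_closing_empty_is_empty(self):
        m = np.zeros((8, 8), dtype=bool)
        assert not morph_close(m, disk_element(2)).any()

    @pytest.mark.parametrize("radius", [1, 2])
    def test_open_close_match_oracles(self, rng, radius):
        se = disk_element(radius)
        for m in random_masks(rng, 10):
            np.testing.assert_array_equal(
                morph_open(m, se), open_oracle(m, se.footprint)
            )
            np.testing.assert_array_equal(
                morph_close(m, se), close_oracle(m, se.footprint)
            )

    def test_extensivity_and_idempotence(self, rng):
        se = disk_element(2)
        for m in random_masks(rng, 5):
            opened = morph_open(m, se)
            closed = morph_close(m, se)
            assert np.all(opened <= m) and np.all(m <= closed)
            np.testing.assert_array_equal(morph_open(opened, se), opened)
            np.testing.assert_array_equal(morph_close(closed, se), closed)

    def test_duality_away_from_borders(self, rng):
        # opening of m == complement of closing of complement, checked on
        # the interior region unaffected by frame effects
        se = disk_element(1)
        for m in random_masks(rng, 5):
            a = morph_open(m, se)
            b = ~morph_close(~m, se)
            np.testing.assert_array_equal(a[2:-2, 2:-2], b[2:-2, 2:-2])


class TestAreaOpen:
    def test_small_component_pruned(self):
        m = np.zeros((40, 40), dtype=bool)
        m[1, 1:4] = True  # 3 px
        m[10:35, 10:30] = True  # 500 px
        out = area_open(m, 10)
        assert not out[1, 1] and out[10:35, 10:30].all()

    def test_min_size_one_is_identity(self, rng):
        m = rng.random((16, 16)) < 0.4
        np.testing.assert_array_equal(area_open(m, 1), m)

    def test_diagonal_pixels_are_one_component(self):
        m = np.zeros((6, 6), dtype=bool)
        m[2, 2] = m[3, 3] = True
        np.testing.assert_array_equal(area_open(m, 2), m)

    def test_matches_oracle(self, rng):
        for m in random_masks(rng, 10):
            np.testing.assert_array_equal(
                area_open(m, 5), area_open_oracle(m, 5)
            )

    def test_never_creates_foreground(self, rng):
        for m in random_masks(rng, 5):
            assert np.all(area_open(m, 7) <= m)


class TestFillHoles:
    def test_ring_becomes_solid(self):
        from conftest import make_disk_mask

        ring = make_disk_mask(10, 32) & ~make_disk_mask(6, 32)
        np.testing.assert_array_equal(fill_holes(ring), make_disk_mask(10, 32))

    def test_solid_blob_unchanged(self):
        from conftest import make_disk_mask

        m = make_disk_mask(10, 32)
        np.testing.assert_array_equal(fill_holes(m), m)

    def test_two_cavities_filled(self):
        m = np.zeros((20, 20), dtype=bool)
        m[2:18, 2:18] = True
        m[5, 5] = False  # 1-px cavity
        m[10:13, 10:13] = False  # 9-px cavity
        expect = fill_holes_oracle(m)
        out = fill_holes(m)
        np.testing.assert_array_equal(out, expect)
        assert out[5, 5] and out[11, 11]

    def test_matches_oracle(self, rng):
        for m in random_masks(rng, 10):
            np.testing.assert_array_equal(fill_holes(m), fill_holes_oracle(m))

    def test_never_removes_foreground(self, rng):
        for m in random_masks(rng, 5):
            assert np.all(m <= fill_holes(m))


class TestLargestComponent:
    def test_keeps_biggest(self):
        m = np.zeros((30, 60), dtype=bool)
        m[2:7, 2:10] = True  # 40 px
        m[10:30, 30:50] = True  # 400 px
        out = largest_component(m)
        assert out.sum() == 400 and not out[3, 3]

    def test_empty_in_empty_out(self):
        m = np.zeros((8, 8), dtype=bool)
        assert not largest_component(m).any()

    def test_tie_breaks_by_raster_order(self):
        m = np.zeros((10, 10), dtype=bool)
        m[1:3, 1:3] = True  # first in raster order
        m[6:8, 6:8] = True  # same size, later
        out = largest_component(m)
        assert out[1, 1] and not out[6, 6]

    def test_output_single_component(self, rng):
        from scipy import ndimage

        for m in random_masks(rng, 5):
            out = largest_component(m)
            if out.any():
                _, n = ndimage.label(out, structure=np.ones((3, 3)))
                assert n == 1

    def test_component_sizes_diagnostics(self):
        m = np.zeros((10, 10), dtype=bool)
        m[0, 0] = True
        m[5:7, 5:7] = True
        assert sorted(component_sizes(m)) == [1, 4]
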