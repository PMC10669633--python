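import numpy as np
import pytest
from scipy import ndimage

from chorosps import (
    BandCriteria,
    SuperpixelMap,
    auto_select_band,
    boundary_pixels,
    extract_boundary,
    region_properties,
    select_superpixels,
)


@pytest.fixture
def banded_map(banded_gray):
    """One label per band of the 30/200/60 three-band fixture."""
    labels = np.empty(banded_gray.shape, dtype=np.int64)
    labels[:20] = 1
    labels[20:40] = 2
    labels[40:] = 3
    return SuperpixelMap.from_labels(labels, banded_gray)


class TestSelectSuperpixels:
    def test_all_labels_covers_image(self, banded_map):
        mask = select_superpixels(banded_map, [1, 2, 3])
        assert mask.all()

    def test_single_label_popcount(self, random_gray):
        from chorosps import SuperpixelParams, slic_segment

        sp = slic_segment(random_gray, SuperpixelParams(n_superpixels=9, iterations=5))
        hist = np.bincount(sp.labels.ravel())
        mask = select_superpixels(sp, [2])
        assert mask.sum() == hist[2]

    def test_duplicate_ids_are_set_semantics(self, banded_map):
        a = select_superpixels(banded_map, [1, 3])
        b = select_superpixels(banded_map, [1, 3, 3, 1])
        assert np.array_equal(a, b)

    def test_union_respects_partition(self, banded_map):
        sizes = banded_map.label_sizes()
        mask = select_superpixels(banded_map, [1, 3])
        assert mask.sum() == sizes[1] + sizes[3]

    def test_empty_selection_rejected(self, banded_map):
        with pytest.raises(ValueError, match="no superpixels"):
            select_superpixels(banded_map, [])

    def test_unknown_id_lists_valid_range(self, banded_map):
        with pytest.raises(ValueError, match="1..3"):
            select_superpixels(banded_map, [4])


class TestAutoSelectBand:
    def test_vacuous_criteria_selects_everything(self, banded_map, banded_gray):
        crit = BandCriteria(intensity_range=(0, 255), depth_range=(0, 60))
        assert auto_select_band(banded_map, banded_gray, crit) == [1, 2, 3]

    def test_intensity_window_picks_choroid_band(self, banded_map, banded_gray):
        crit = BandCriteria(intensity_range=(50, 70), depth_range=(0, 60))
        assert auto_select_band(banded_map, banded_gray, crit) == [3]

    def test_no_match_returns_empty(self, banded_map, banded_gray):
        crit = BandCriteria(intensity_range=(80, 80), depth_range=(0, 60))
        assert auto_select_band(banded_map, banded_gray, crit) == []

    def test_depth_relative_to_anchor(self, banded_map, banded_gray):
        # anchor at the bright band's centroid row (29.5-ish); the 60-band
        # centroid (row 49.5) sits ~20 rows below it
        anchor = np.full(60, 29.5)
        crit = BandCriteria(intensity_range=(0, 255), depth_range=(10, 30), anchor=anchor)
        assert auto_select_band(banded_map, banded_gray, crit) == [3]

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            BandCriteria(intensity_range=(10, 5), depth_range=(0, 1))
        with pytest.raises(ValueError):
            BandCriteria(intensity_range=(0, 1), depth_range=(5, 2))


class TestRegionProperties:
    def test_rectangle_closed_form(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:15, 3:23] = True
        props = region_properties(mask)
        assert props.area == 200
        assert props.centroid == (9.5, 12.5)
        assert props.bounding_box == (5, 3, 10, 20)
        assert props.n_components == 1

    def test_two_islands(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[1, 1] = mask[8, 8] = True
        assert region_properties(mask).n_components == 2

    def test_area_is_popcount(self, rng):
        mask = rng.random((40, 40)) < 0.3
        mask[0, 0] = True
        count = sum(1 for r in range(40) for c in range(40) if mask[r, c])
        assert region_properties(mask).area == count

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            region_properties(np.zeros((5, 5), dtype=bool))


class TestExtractBoundary:
    def test_single_pixel(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        (contour,) = extract_boundary(mask)
        assert contour.tolist() == [[2, 2]]

    @pytest.mark.parametrize("h,w", [(2, 2), (3, 5), (6, 4)])
    def test_rectangle_contour_length(self, h, w):
        mask = np.zeros((h + 4, w + 4), dtype=bool)
        mask[2 : 2 + h, 2 : 2 + w] = True
        (contour,) = extract_boundary(mask)
        assert len(contour) == 2 * w + 2 * h - 4
        assert tuple(contour[0]) == (2, 2)  # starts at the top-left-most pixel

    def test_blob_contour_matches_neighbor_scan(self, rng):
        blob = ndimage.binary_fill_holes(
            ndimage.binary_dilation(rng.random((30, 30)) < 0.08, iterations=3)
        )
        comp, n = ndimage.label(blob, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
        sizes = np.bincount(comp.ravel())
        blob = comp == sizes[1:].argmax() + 1  # largest component, no holes
        (contour,) = extract_boundary(blob)
        got = {tuple(p) for p in contour}
        expected = {tuple(p) for p in np.argwhere(boundary_pixels(blob))}
        assert got == expected
        # boundary is inside the mask
        assert all(blob[p] for p in got)

    def test_filled_contour_reproduces_component(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[3:9, 2:10] = True
        (contour,) = extract_boundary(mask)
        canvas = np.zeros_like(mask)
        canvas[tuple(contour.T)] = True
        assert np.array_equal(ndimage.binary_fill_holes(canvas), mask)
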