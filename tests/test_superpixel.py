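import numpy as np
import pytest
from scipy import ndimage

from chorosps import (
    SuperpixelMap,
    SuperpixelParams,
    enforce_connectivity,
    overlay_labels,
    slic_segment,
)
from chorosps.superpixel import boundary_mask

from slic_oracle import brute_force_slic

FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def assert_partition(sp, shape):
    assert sp.labels.shape == shape
    sizes = sp.label_sizes()[1:]
    assert sizes.sum() == shape[0] * shape[1]
    assert (sizes > 0).all()
    assert sp.labels.min() == 1


class TestSlicSegment:
    def test_constant_image_spatial_kmeans(self):
        img = np.full((100, 100), 77, dtype=np.uint8)
        sp = slic_segment(img, SuperpixelParams(n_superpixels=4, iterations=10))
        sizes = sp.label_sizes()[1:]
        assert len(sizes) == 4
        assert (np.abs(sizes - 2500) <= 125).all()  # 2500 +/- 5%

    def test_single_cluster_covers_image(self, random_gray):
        sp = slic_segment(random_gray, SuperpixelParams(n_superpixels=1))
        assert sp.n_labels == 1
        assert (sp.labels == 1).all()

    def test_two_band_purity(self):
        img = np.empty((64, 64), dtype=np.uint8)
        img[:32] = 30
        img[32:] = 220
        sp = slic_segment(img, SuperpixelParams(n_superpixels=8, iterations=10))
        for lab in range(1, sp.n_labels + 1):
            rows = np.nonzero(sp.labels == lab)[0]
            assert rows.max() < 32 or rows.min() >= 32  # no label spans both bands

    def test_partition_over_seeds(self, rng):
        for _ in range(5):
            img = rng.integers(0, 256, size=(48, 40)).astype(np.uint8)
            sp = slic_segment(img, SuperpixelParams(n_superpixels=12, iterations=5))
            assert_partition(sp, img.shape)

    def test_deterministic(self, random_gray):
        p = SuperpixelParams(n_superpixels=16, iterations=5)
        a = slic_segment(random_gray, p)
        b = slic_segment(random_gray.copy(), p)
        assert np.array_equal(a.labels, b.labels)

    def test_too_many_superpixels_rejected(self):
        with pytest.raises(ValueError):
            slic_segment(np.zeros((4, 4), dtype=np.uint8), SuperpixelParams(n_superpixels=17))

    @pytest.mark.parametrize("shape,k", [((24, 24), 4), ((32, 32), 4), ((20, 28), 2)])
    def test_agrees_with_brute_force_oracle(self, shape, k, rng):
        img = rng.integers(0, 256, size=shape).astype(np.uint8)
        ours = slic_segment(img, SuperpixelParams(n_superpixels=k, iterations=100))
        oracle = brute_force_slic(img, n_superpixels=k, compactness=10.0)
        assert np.array_equal(ours.labels, oracle)

    def test_compactness_shortens_boundaries(self, rng):
        img = rng.integers(0, 256, size=(64, 64)).astype(np.uint8)
        lengths = []
        for m in (1.0, 10.0, 40.0):
            sp = slic_segment(img, SuperpixelParams(n_superpixels=16, iterations=10, compactness=m))
            lengths.append(int(boundary_mask(sp.labels).sum()))
        assert lengths[0] >= lengths[1] >= lengths[2]


class TestEnforceConnectivity:
    def test_connected_map_is_fixed_point_up_to_renumbering(self):
        labels = np.ones((20, 20), dtype=np.int64)
        labels[:, 10:] = 2
        sp = SuperpixelMap.from_labels(labels)
        out = enforce_connectivity(sp)
        assert np.array_equal(out.labels == out.labels[0, 0], labels == 1)

    def test_orphan_absorbed_into_surrounding_label(self):
        labels = np.ones((12, 12), dtype=np.int64)
        labels[6, 6] = 2  # single orphan pixel inside label 1
        sp = SuperpixelMap.from_labels(labels)
        out = enforce_connectivity(sp)
        assert out.n_labels == 1
        assert (out.labels == 1).all()

    def test_every_label_four_connected_after_enforcement(self, rng):
        for _ in range(10):
            img = rng.integers(0, 256, size=(48, 48)).astype(np.uint8)
            sp = slic_segment(img, SuperpixelParams(n_superpixels=12, iterations=3))
            out = enforce_connectivity(sp, img)
            assert_partition(out, img.shape)
            for lab in range(1, out.n_labels + 1):
                _, n = ndimage.label(out.labels == lab, structure=FOUR)
                assert n == 1


class TestOverlay:
    def test_single_label_draws_only_frame(self, random_gray):
        sp = slic_segment(random_gray, SuperpixelParams(n_superpixels=1))
        rgb = overlay_labels(random_gray, sp)
        interior = rgb[2:-2, 2:-2]
        yellow = (interior == [255, 255, 0]).all(axis=2)
        assert not yellow.any()

    def test_boundary_set_matches_neighbor_scan(self, random_gray):
        sp = enforce_connectivity(
            slic_segment(random_gray, SuperpixelParams(n_superpixels=9, iterations=5)),
            random_gray,
        )
        rgb = overlay_labels(random_gray, sp)
        lab = sp.labels
        expected = np.zeros(lab.shape, dtype=bool)
        h, w = lab.shape
        for r in range(h):
            for c in range(w):
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and lab[rr, cc] != lab[r, c]:
                        expected[r, c] = True
        yellow = (rgb == [255, 255, 0]).all(axis=2)
        # frame pixels are always drawn; compare away from frame and digits
        red = (rgb == [255, 32, 32]).all(axis=2)
        inner = np.zeros_like(expected)
        inner[1:-1, 1:-1] = True
        check = inner & ~red
        assert np.array_equal(yellow[check], expected[check])

    def test_byte_identical_across_runs(self, random_gray):
        p = SuperpixelParams(n_superpixels=9, iterations=5)
        a = overlay_labels(random_gray, slic_segment(random_gray, p))
        b = overlay_labels(random_gray, slic_segment(random_gray, p))
        assert np.array_equal(a, b)

    def test_shape_mismatch_rejected(self, random_gray):
        sp = slic_segment(random_gray, SuperpixelParams(n_superpixels=4))
        with pytest.raises(ValueError):
            overlay_labels(random_gray[:32], sp)
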