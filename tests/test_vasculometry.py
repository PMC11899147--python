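"""Segmentation, skeleton topology and VPD/VL/VAD/VT morphometry."""

import numpy as np
import pytest
from skimage.draw import disk

from oacd.vasculometry import (
    binarize_adaptive_region_growth,
    build_skeleton_graph,
    compute_metrics,
    detect_nodes,
    diameters_from_distance_transform,
    skeletonize,
)


def bar_image(shape=(100, 100), rows=(48, 53), cols=(10, 90)):
    img = np.zeros(shape, dtype=bool)
    img[rows[0]:rows[1], cols[0]:cols[1]] = True
    return img


def plus_image(size=60, arm=5):
    img = np.zeros((size, size), dtype=bool)
    c = size // 2
    img[c - arm // 2:c + arm // 2 + 1, 10:size - 10] = True
    img[10:size - 10, c - arm // 2:c + arm // 2 + 1] = True
    return img


def ring_image(size=60, r_out=20, r_in=14):
    img = np.zeros((size, size), dtype=bool)
    rr, cc = disk((size // 2, size // 2), r_out)
    img[rr, cc] = True
    rr, cc = disk((size // 2, size // 2), r_in)
    img[rr, cc] = False
    return img


class TestBinarization:
    def test_bright_tube_on_noise_iou(self):
        rng = np.random.default_rng(0)
        img = 1 + 0.1 * rng.standard_normal((80, 80))
        truth = bar_image((80, 80), (30, 37), (0, 80))
        img[truth] = 10.0
        mask = binarize_adaptive_region_growth(img)
        iou = (mask & truth).sum() / (mask | truth).sum()
        assert iou >= 0.9

    def test_uniform_image_yields_empty_mask(self):
        assert not binarize_adaptive_region_growth(np.ones((50, 50))).any()

    def test_dim_vessel_detected_alongside_bright_one(self):
        """The local criterion keeps weak vessels that a global threshold
        anchored to the bright vessel would discard."""
        rng = np.random.default_rng(1)
        img = 1 + 0.1 * rng.standard_normal((100, 100))
        bright = bar_image((100, 100), (10, 14), (0, 100))
        dim = bar_image((100, 100), (60, 66), (0, 100))
        img[bright] = 10.0
        img[dim] = 3.0
        mask = binarize_adaptive_region_growth(img)
        assert (mask & bright).sum() / bright.sum() > 0.9
        assert (mask & dim).sum() / dim.sum() > 0.9
        assert (mask & ~(bright | dim)).sum() < 0.05 * mask.sum()

    def test_non_finite_image_rejected(self):
        img = np.ones((20, 20))
        img[0, 0] = np.nan
        with pytest.raises(ValueError):
            binarize_adaptive_region_growth(img)


class TestSkeleton:
    def test_straight_bar_thins_to_single_straight_line(self):
        sk = skeletonize(bar_image())
        rows = np.nonzero(sk)[0]
        assert sk.sum() > 0
        assert len(set(rows)) == 1  # one-pixel-wide, perfectly straight
        # no 2x2 block fully set
        two_by_two = sk[:-1, :-1] & sk[1:, :-1] & sk[:-1, 1:] & sk[1:, 1:]
        assert not two_by_two.any()

    def test_solid_disk_collapses_to_point_cluster(self):
        img = np.zeros((50, 50), dtype=bool)
        rr, cc = disk((25, 25), 10)
        img[rr, cc] = True
        assert skeletonize(img).sum() <= 5

    def test_component_count_preserved(self):
        img = bar_image()
        img |= bar_image(rows=(10, 15), cols=(10, 90))
        from scipy import ndimage
        sk = skeletonize(img)
        assert ndimage.label(sk, np.ones((3, 3)))[1] == ndimage.label(img, np.ones((3, 3)))[1]


class TestDiameters:
    def test_bar_width_seven_recovered(self):
        img = bar_image(rows=(40, 47))
        g = build_skeleton_graph(img)
        interior = [d for (i, j), d in g.diameter_at.items() if 20 <= j <= 80]
        assert abs(np.median(interior) - 7) <= 1

    def test_disk_center_diameter(self):
        img = np.zeros((60, 60), dtype=bool)
        rr, cc = disk((30, 30), 12)
        img[rr, cc] = True
        sk = np.zeros_like(img)
        sk[30, 30] = True
        d = diameters_from_distance_transform(img, sk)
        assert d[(30, 30)] == pytest.approx(24, abs=2)

    def test_width_one_line_minimal_diameter(self):
        img = np.zeros((30, 30), dtype=bool)
        img[15, 5:25] = True
        d = diameters_from_distance_transform(img, img)
        vals = list(d.values())
        assert 1.0 <= np.median(vals) <= 2.0


class TestNodes:
    def test_straight_line_endpoints_only(self):
        sk = np.zeros((20, 20), dtype=bool)
        sk[10, 3:17] = True
        branch, ends, segs = detect_nodes(sk)
        assert branch == []
        assert len(ends) == 2
        assert len(segs) == 1 and not segs[0].cyclic

    def test_plus_sign_one_branch_four_endpoints(self):
        g = build_skeleton_graph(plus_image())
        assert len(g.branch_nodes) == 1
        assert len(g.endpoints) == 4

    def test_closed_ring_single_cyclic_segment(self):
        g = build_skeleton_graph(ring_image())
        assert g.branch_nodes == [] and g.endpoints == []
        cyclic = [s for s in g.segments if s.cyclic]
        assert len(cyclic) == 1


class TestMetrics:
    def test_straight_vessel_tortuosity_is_exactly_one(self):
        m = compute_metrics(bar_image())
        assert m.VT == 1.0
        assert m.n_branch == 0 and m.n_end == 2

    def test_right_angle_l_tortuosity_sqrt_two(self):
        img = np.zeros((60, 60), dtype=bool)
        img[10:41, 10:13] = True
        img[38:41, 10:41] = True
        m = compute_metrics(img)
        assert m.VT == pytest.approx(np.sqrt(2), rel=0.02)

    def test_vpd_is_area_ratio(self):
        img = np.zeros((100, 100), dtype=bool)
        img[:25, :] = True
        m = compute_metrics(img)
        assert m.VPD == 0.25

    def test_empty_mask_flagged(self):
        m = compute_metrics(np.zeros((50, 50), dtype=bool))
        assert m.VPD == 0.0 and m.VL == 0.0 and m.VT == 1.0
        assert m.flags.get("empty")

    def test_vt_at_least_one_for_noncyclic_networks(self):
        rng = np.random.default_rng(7)
        img = np.zeros((80, 80), dtype=bool)
        for _ in range(4):
            r0, c0 = rng.integers(5, 70, 2)
            img[r0:r0 + 3, c0:min(c0 + rng.integers(10, 30), 78)] = True
            img[r0:min(r0 + rng.integers(10, 30), 78), c0:c0 + 3] = True
        m = compute_metrics(img)
        assert m.VT >= 1.0 - 1e-9

    def test_vpd_and_vl_rotation_invariance(self):
        img = bar_image((160, 160), rows=(78, 83), cols=(5, 155))
        m0 = compute_metrics(img)
        m90 = compute_metrics(np.rot90(img))
        assert m90.VPD == m0.VPD
        assert m90.VL == pytest.approx(m0.VL, rel=0.02)

    def test_dilation_raises_vpd_and_vad_keeps_topology(self):
        from scipy import ndimage
        img = plus_image()
        dil = ndimage.binary_dilation(img)
        m0, m1 = compute_metrics(img), compute_metrics(dil)
        assert m1.VPD > m0.VPD
        assert m1.VAD > m0.VAD
        assert (m1.n_branch, m1.n_end) == (m0.n_branch, m0.n_end)


class TestPhantomRecovery:
    def test_vpd_recovered_within_ten_percent(self, single_vessel_phantom):
        """Binarized superficial en-face of a single-vessel phantom matches
        the ground-truth footprint area within +-10%."""
        import numpy as np
        from oacd.angiography import decorrelate, detect_surface, enface_project, split_slabs
        spec, vol, truth = single_vessel_phantom
        D = decorrelate(np.sqrt(vol.data))
        surface = detect_surface(vol.data)
        sup3, _ = split_slabs(D, surface, vol.delta)
        enface = enface_project(sup3).pixels
        mask = binarize_adaptive_region_growth(enface)
        assert mask.mean() == pytest.approx(truth.superficial_mask_2d.mean(), rel=0.10)
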