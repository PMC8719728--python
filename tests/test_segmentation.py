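"""Binarization, cleaning, border detection, overlap separation, counting."""

import numpy as np
import pytest
from scipy import ndimage

from wbcseg.hue_pca import ProjectionMap
from wbcseg.segmentation import (
    PRESETS,
    SegmentationConfig,
    binarize,
    count,
    counting_precision,
    detect_borders,
    remove_small,
    segment_and_count,
    separate_overlaps,
)

def _pmap(omega, phi_hat=None):
    return ProjectionMap(omega=np.asarray(omega, float), selected_axis=0,
                         phi_hat=phi_hat)


def _disc(shape, cy, cx, r):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2


class TestBinarize:
    def test_zero_map_gives_empty_mask(self):
        assert not binarize(_pmap(np.zeros((5, 5)))).any()

    def test_threshold_is_inclusive(self):
        omega = np.zeros((3, 3))
        omega[1, 1] = 1.0     # rescales to 255
        omega[0, 0] = 37 / 255
        mask = binarize(_pmap(omega), 37)
        assert mask[0, 0] and mask[1, 1]

    def test_threshold_near_zero_keeps_everything(self):
        m = binarize(_pmap(np.ones((4, 4))), 1e-9)
        assert m.all()

    def test_monotone_in_threshold(self, rng):
        omega = rng.random((30, 30))
        prev = None
        for d in (10, 37, 90, 200):
            m = binarize(_pmap(omega), d)
            if prev is not None:
                assert not (m & ~prev).any()
            prev = m


class TestRemoveSmall:
    def test_single_small_blob_deleted(self):
        mask = np.zeros((100, 100), bool)
        mask[:10, :10] = True                       # 100 px
        assert not remove_small(mask, 3500).any()

    def test_exact_cutoff_area_survives(self):
        mask = np.zeros((40, 40), bool)
        mask[:10, :10] = True                       # exactly 100 px
        assert remove_small(mask, 100).sum() == 100

    def test_mixed_areas(self):
        mask = np.zeros((200, 200), bool)
        mask[:80, :50] = True                       # 4000 px
        mask[150:160, 150:170] = True               # 200 px
        out = remove_small(mask, 3500)
        assert count(out) == 1 and out.sum() == 4000

    def test_idempotent(self, rng):
        mask = rng.random((64, 64)) > 0.7
        once = remove_small(mask, 10)
        assert np.array_equal(once, remove_small(once, 10))


class TestDetectBorders:
    def test_constant_fields_give_no_borders(self):
        phi = np.tile(np.array([0.6, 0.48, 0.64]), (20, 20, 1))
        b = detect_borders(_pmap(np.ones((20, 20)), phi))
        assert not b.any()

    def test_identical_neighbors_have_zero_angle(self):
        # angle condition alone must block border marking
        phi = np.tile(np.array([1.0, 0.0, 0.0]), (10, 10, 1))
        omega = np.zeros((10, 10))
        omega[:, 5:] = 1.0      # strong step, but no chromatic difference
        assert not detect_borders(_pmap(omega, phi)).any()

    def test_ideal_step_edge_needs_bidirectional_variation(self):
        # a perfect 1-px vertical hue step: the row-direction angle is zero
        # everywhere, so the conjunctive rule cannot mark it, while the
        # column-direction angle alone (OR) does
        h, w = 12, 12
        a = np.array([1.0, 0.0, 0.0])
        th = np.deg2rad(10)
        b_vec = np.array([np.cos(th), np.sin(th), 0.0])
        phi = np.empty((h, w, 3))
        phi[:, :6] = a
        phi[:, 6:] = b_vec
        omega = np.zeros((h, w))
        omega[:, 6:] = 0.5
        pm = _pmap(omega, phi)
        assert not detect_borders(pm, combine="and").any()
        assert detect_borders(pm, combine="or")[:, 5].all()

    def test_smooth_diagonal_transition_marks_border_band(self):
        # a 3-px smooth transition between two hue regions running
        # diagonally: both angular differences and the gradient exceed
        # their thresholds inside the band, producing a cutting border
        n = 40
        th = np.deg2rad(24)
        a = np.array([1.0, 0.0, 0.0])
        b_vec = np.array([np.cos(th), np.sin(th), 0.0])
        yy, xx = np.mgrid[0:n, 0:n]
        t = np.clip((xx + yy - n) / 6.0 + 0.5, 0, 1)    # 0 -> a, 1 -> b
        phi = a[None, None] * (1 - t[..., None]) + b_vec[None, None] * t[..., None]
        phi /= np.linalg.norm(phi, axis=-1, keepdims=True)
        omega = 0.9 * t
        borders = detect_borders(_pmap(omega, phi), delta_I=0.2,
                                 delta_theta_deg=2.5)
        # Prewitt/angle stencils extend one pixel beyond the band itself
        near = ndimage.binary_dilation((t > 0) & (t < 1), iterations=2)
        assert borders.any()
        assert borders[~near].sum() == 0
        # the marked band disconnects the two flat regions
        from skimage import measure
        lab = measure.label(~borders, connectivity=2)
        assert lab[0, 0] != lab[-1, -1]

    def test_or_combination_is_more_sensitive(self):
        phi = np.tile(np.array([1.0, 0.0, 0.0]), (10, 10, 1))
        omega = np.zeros((10, 10))
        omega[:, 5:] = 1.0
        assert not detect_borders(_pmap(omega, phi), combine="and").any()
        assert detect_borders(_pmap(omega, phi), combine="or").any()


class TestSeparateOverlaps:
    def _peanut(self):
        """Two discs fused into one blob with a known waist line."""
        mask = _disc((200, 260), 100, 90, 64) | _disc((200, 260), 100, 170, 64)
        borders = np.zeros_like(mask)
        borders[:, 128:133] = True      # cuts the waist
        return mask, borders

    def test_large_blob_split_in_two(self):
        mask, borders = self._peanut()
        assert count(mask) == 1 and mask.sum() > 21_000
        out = separate_overlaps(mask, borders, split_area_px=21_000)
        assert count(out) == 2

    def test_small_object_untouched(self):
        mask = _disc((150, 150), 75, 75, 56)        # ~10,000 px
        borders = np.zeros_like(mask)
        borders[:, 70:76] = True
        out = separate_overlaps(mask, borders, split_area_px=13_000)
        assert np.array_equal(out, mask)

    def test_empty_border_mask_is_identity(self):
        mask, _ = self._peanut()
        out = separate_overlaps(mask, np.zeros_like(mask), 21_000)
        assert np.array_equal(out, mask)

    def test_never_gains_area_never_loses_components(self, rng):
        for _ in range(20):
            mask = ndimage.binary_dilation(rng.random((64, 64)) > 0.95,
                                           iterations=3)
            borders = rng.random((64, 64)) > 0.8
            out = separate_overlaps(mask, borders, split_area_px=40)
            assert out.sum() <= mask.sum()
            assert count(out) >= count(mask)

    def test_skin_sliver_fragments_are_dropped(self):
        mask, _ = self._peanut()
        # waist cut plus a band grazing the blob top: shaves a thin sliver
        borders = np.zeros_like(mask)
        borders[:, 128:133] = True
        borders[40:43, :] = True
        out = separate_overlaps(mask, borders, split_area_px=21_000,
                                min_fragment_px=500)
        assert count(out) == 2


class TestCount:
    def test_empty(self):
        assert count(np.zeros((10, 10), bool)) == 0

    def test_three_disjoint_discs(self):
        mask = _disc((100, 100), 20, 20, 8) | _disc((100, 100), 20, 70, 8) \
            | _disc((100, 100), 70, 45, 8)
        assert count(mask) == 3

    def test_corner_touching_merges_under_8_connectivity(self):
        mask = np.zeros((10, 10), bool)
        mask[2:4, 2:4] = True
        mask[4:6, 4:6] = True       # touches corner-to-corner
        mask[7:9, 0:2] = True
        assert count(mask) == 2

    def test_matches_flood_fill_oracle_on_random_matrices(self, rng):
        s8 = np.ones((3, 3), int)
        for _ in range(300):
            mask = rng.random((64, 64)) > rng.uniform(0.4, 0.9)
            _, n = ndimage.label(mask, structure=s8)
            assert count(mask) == n


class TestCountingPrecision:
    def test_identical_masks_are_perfect(self):
        truth = _disc((80, 120), 40, 30, 10).astype(int)
        truth[_disc((80, 120), 40, 90, 10)] = 2
        cp, n, m = counting_precision(truth > 0, truth)
        assert (cp, n, m) == (100.0, 2, 2)

    def test_spurious_detection_lowers_precision(self):
        truth = np.zeros((100, 200), int)
        det = np.zeros((100, 200), int)
        for k, cx in enumerate((30, 80, 130), start=1):
            blob = _disc((100, 200), 50, cx, 10)
            truth[blob] = k
            det[blob] = k
        det[_disc((100, 200), 50, 180, 8)] = 4      # spurious
        cp, n, m = counting_precision(det, truth)
        assert (n, m) == (3, 4) and cp == pytest.approx(75.0)

    def test_fused_pair_counts_once(self):
        truth = np.zeros((120, 260), int)
        for k, cx in enumerate((30, 80, 130, 190, 215), start=1):
            truth[_disc((120, 260), 60, cx, 11)] = k
        det = np.zeros_like(truth)
        for k, cx in enumerate((30, 80, 130), start=1):
            det[_disc((120, 260), 60, cx, 11)] = k
        det[_disc((120, 260), 60, 190, 11) | _disc((120, 260), 60, 215, 11)] = 4
        cp, n, m = counting_precision(det, truth)
        assert (n, m) == (4, 4) and cp == 100.0

    def test_no_detection_is_undefined(self):
        truth = _disc((50, 50), 25, 25, 8)
        cp, n, m = counting_precision(np.zeros((50, 50), bool), truth)
        assert cp is None and m == 0


class TestPipeline:
    def test_counts_disjoint_cells(self, tiny_smear):
        img, truth, n = tiny_smear
        res = segment_and_count(img, SegmentationConfig(space="lab"))
        assert res.count == n
        cp, _, _ = counting_precision(res.labels, truth)
        assert cp == 100.0

    def test_blank_image_degenerate_or_empty(self):
        from wbcseg.hue_pca import DegenerateModelError
        img = np.full((60, 60, 3), 240, np.uint8)
        with pytest.raises(DegenerateModelError):
            segment_and_count(img, SegmentationConfig())

    def test_flip_equivariance(self, tiny_smear):
        img = tiny_smear[0]
        cfg = SegmentationConfig(space="lab")
        a = segment_and_count(img, cfg)
        b = segment_and_count(img[::-1].copy(), cfg)
        assert np.array_equal(a.binary[::-1], b.binary)
        assert a.count == b.count

    def test_presets_carry_reference_cutoffs(self):
        small = PRESETS["allidb-small"]
        large = PRESETS["allidb-large"]
        assert (small.min_area_px, small.split_area_px) == (3500, 13_000)
        assert (large.min_area_px, large.split_area_px) == (5000, 21_000)
        assert small.scaled_areas((1368, 1712)) == (3500, 13_000)

    def test_area_autoscaling_tracks_image_area(self):
        cfg = SegmentationConfig()
        half = cfg.scaled_areas((684, 1712))
        assert half == (1750, 6500)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SegmentationConfig(min_area_px=5000, split_area_px=4000)
        with pytest.raises(ValueError):
            SegmentationConfig(delta_omega=0)
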