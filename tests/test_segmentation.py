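"""Per-slice segmentation operators against direct oracles and invariants."""

import numpy as np
import pytest
from scipy import ndimage

from mtphen import segmentation as seg
from mtphen.segmentation import (
    SegmentationParams,
    enhance,
    generate_seeds,
    homogenize_lighting,
    morphological_opening,
    segment_slice,
    segment_stack,
    subtract_local_background,
)

P = SegmentationParams(kr=5)


def disc_image(shape, centers, radius, value=200.0, background=0.0):
    img = np.full(shape, background, dtype=float)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cy, cx in centers:
        img[np.hypot(yy - cy, xx - cx) <= radius] = value
    return img


class TestHomogenizeLighting:
    def test_constant_image_maps_to_zero(self):
        assert np.all(homogenize_lighting(np.full((80, 80), 37.0), 5) == 0)

    def test_definitional_identity_with_opening(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 100, (90, 90))
        out = homogenize_lighting(img, 5)
        assert np.array_equal(out, img - morphological_opening(img, 25))
        assert np.all(out >= 0)

    def test_ramp_removed_disk_preserved(self):
        yy, xx = np.mgrid[0:120, 0:120]
        ramp = 50.0 * xx / 119.0
        img = ramp + disc_image((120, 120), [(60, 60)], radius=P.kr, value=100.0)
        out = homogenize_lighting(img, P.kr)
        # background ramp suppressed, disk peak preserved within 5%
        assert out[60, 60] >= 0.95 * 100.0
        # interior background (away from the disk and from border effects
        # of the structuring element) is flattened
        interior = (np.hypot(yy - 60, xx - 60) > 30) & (
            (yy > 26) & (yy < 93) & (xx > 26) & (xx < 93)
        )
        assert np.percentile(out[interior], 99) < 5.0

    def test_rejects_non_2d(self):
        with pytest.raises(ValueError, match="2D"):
            homogenize_lighting(np.zeros((3, 4, 5)), 5)


class TestLocalBackground:
    def test_constant_image_zeroed(self):
        assert np.all(subtract_local_background(np.full((100, 100), 9.0), 5) == 0)

    def test_invariant_to_added_constant(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(10, 50, (100, 100))
        a = subtract_local_background(img, 5)
        b = subtract_local_background(img + 17.0, 5)
        assert np.allclose(a, b)

    def test_background_pixels_mostly_zeroed(self):
        rng = np.random.default_rng(2)
        img = np.abs(rng.normal(5, 2, (120, 120)))
        img += disc_image((120, 120), [(30, 30), (90, 80)], 8, value=150.0)
        out = subtract_local_background(img, 5)
        yy, xx = np.mgrid[0:120, 0:120]
        bg_mask = (np.hypot(yy - 30, xx - 30) > 12) & (np.hypot(yy - 90, xx - 80) > 12)
        assert (out[bg_mask] == 0).mean() >= 0.45  # local median zeroes half
        assert out[30, 30] > 100.0

    def test_oversized_window_warns_and_clips(self):
        with pytest.warns(UserWarning, match="clipped"):
            subtract_local_background(np.random.default_rng(0).uniform(0, 1, (20, 20)), 5)


class TestEnhance:
    def test_isolated_impulse_removed_by_median_stage(self):
        img = np.zeros((60, 60))
        img[30, 30] = 100.0
        out = enhance(img, P)
        assert out.max() < 10.0

    def test_solid_disk_retained_matches_direct_composition(self):
        from skimage.morphology import disk

        img = disc_image((120, 120), [(60, 60)], radius=3 * P.kr, value=100.0)
        out = enhance(img, P)
        oracle = ndimage.maximum_filter(
            ndimage.gaussian_filter(
                ndimage.median_filter(img, footprint=disk(P.kr)),
                sigma=P.kr / 2.0,
            ),
            footprint=disk(P.kr),
        )
        assert np.allclose(out, oracle)
        # the object survives; the halo ends within KR (max filter) plus
        # the Gaussian tail (~2 sigma = KR)
        yy, xx = np.mgrid[0:120, 0:120]
        r = np.hypot(yy - 60, xx - 60)
        assert out[60, 60] > 80.0
        assert np.all(out[r > 3 * P.kr + 2 * P.kr + 1] < 5.0)

    def test_stage_order_is_locked(self):
        # permuting the stages changes the output on the impulse fixture:
        # max->median kills the impulse entirely, median->max does not
        # resurrect it; a maximum-first chain keeps a large plateau
        img = np.zeros((40, 40))
        img[20, 20] = 100.0
        out = enhance(img, P)
        from skimage.morphology import disk

        permuted = ndimage.median_filter(
            ndimage.maximum_filter(img, footprint=disk(P.kr)),
            footprint=disk(P.kr),
        )
        assert not np.allclose(out, permuted)


class TestSeeds:
    def test_two_separated_discs_give_two_seeds_near_centers(self):
        centers = [(40, 40), (40, 40 + 2 * 4 * P.kr + 3 * P.kr)]
        img = disc_image((80, 160), centers, radius=4 * P.kr, value=100.0)
        seeds = generate_seeds(img, P)
        assert len(seeds) == 2
        found = sorted(map(tuple, seeds))
        for (sy, sx), (cy, cx) in zip(found, sorted(centers)):
            assert np.hypot(sy - cy, sx - cx) <= 2.0

    def test_blank_slice_has_no_seeds(self):
        assert generate_seeds(np.zeros((50, 50)), P).shape == (0, 2)

    def test_single_disc_seed_at_center(self):
        img = disc_image((90, 90), [(45, 45)], radius=12, value=80.0)
        seeds = generate_seeds(img, P)
        assert len(seeds) == 1
        assert np.hypot(seeds[0][0] - 45, seeds[0][1] - 45) <= 1.0


class TestSegmentSlice:
    def test_minimum_area_is_kr_squared(self):
        # a 24-px object is dropped with KR=5; a 25-px one is kept
        img = np.zeros((60, 60))
        img[10:14, 10:16] = 100.0  # 24 px
        img[40:45, 40:45] = 100.0  # 25 px
        seeds = generate_seeds(img, P)
        objs = segment_slice(img, seeds, P)
        assert len(objs) == 1
        assert objs[0].area >= 25
        assert abs(objs[0].centroid[0] - 42) < 1

    def test_touching_discs_split_equally_by_nearest_seed(self):
        img = disc_image((80, 120), [(40, 45), (40, 45 + 24)], radius=13, value=90.0)
        seeds = generate_seeds(img, P)
        assert len(seeds) == 2
        objs = segment_slice(img, seeds, P)
        assert len(objs) == 2
        a1, a2 = sorted(o.area for o in objs)
        assert a1 == pytest.approx(a2, rel=0.05)

    def test_oversize_object_split_into_floor_ratio_parts(self):
        # a single-seed object 2.4x the split threshold -> floor(2.4) = 2
        img = np.zeros((80, 200))
        img[30:50, 20:140] = 100.0  # 2400 px²
        params = SegmentationParams(kr=5, split_threshold=1000.0)
        objs = segment_slice(img, np.array([[40, 80]]), params)
        assert len(objs) == 2
        assert sum(o.area for o in objs) == 2400

    def test_no_seeds_emits_single_object_with_warning(self):
        img = disc_image((60, 60), [(30, 30)], radius=10, value=50.0)
        with pytest.warns(UserWarning, match="unseeded"):
            objs = segment_slice(img, np.empty((0, 2), dtype=int), P)
        assert len(objs) == 1

    def test_objects_disjoint_and_in_foreground(self, small_stack_segmented):
        _, _, per_slice, _ = small_stack_segmented
        for objs in per_slice[::8]:
            seen = set()
            for o in objs:
                px = set(zip(o.rows.tolist(), o.cols.tolist()))
                assert not (px & seen)
                seen |= px


class TestSegmentStack:
    def test_translation_equivariance(self):
        rng = np.random.default_rng(5)
        img = disc_image((100, 100), [(40, 40), (65, 70)], radius=10, value=120.0)
        img += rng.normal(0, 2, img.shape)
        shift = (7, 11)
        shifted = np.roll(img, shift, axis=(0, 1))
        p = SegmentationParams(kr=5)

        def centroids(im):
            chain = enhance(
                subtract_local_background(homogenize_lighting(im, 5), 5), p
            )
            objs = segment_slice(chain, generate_seeds(chain, p), p)
            return sorted((o.centroid[0], o.centroid[1]) for o in objs)

        c0 = centroids(img)
        c1 = centroids(shifted)
        assert len(c0) == len(c1) == 2
        for (y0, x0), (y1, x1) in zip(c0, c1):
            assert y1 - y0 == pytest.approx(shift[0], abs=0.5)
            assert x1 - x0 == pytest.approx(shift[1], abs=0.5)

    def test_rerun_is_identical(self, small_stack):
        _, stack, _ = small_stack
        p = SegmentationParams(kr=5)
        a = segment_stack(stack, "dapi", p)
        b = segment_stack(stack, "dapi", p)
        assert [len(x) for x in a] == [len(x) for x in b]
        for oa, ob in zip(a[20], b[20]):
            assert np.array_equal(oa.rows, ob.rows)

    def test_central_slice_recall_on_synthetic_stack(self, small_stack_segmented):
        stack, truth, per_slice, _ = small_stack_segmented
        hits = 0
        for row in truth.itertuples():
            z = int(round(row.center_z_um / stack.z_step_um))
            cy = row.center_y_um / stack.um_per_px
            cx = row.center_x_um / stack.um_per_px
            found = any(
                np.hypot(o.centroid[0] - cy, o.centroid[1] - cx)
                < row.a_um / stack.um_per_px
                for o in per_slice[z]
            )
            hits += found
        assert hits / len(truth) >= 0.95

    def test_empty_stack_gives_empty_result(self):
        from mtphen.stack import ImageStack

        stack = ImageStack(
            np.zeros((1, 4, 64, 64), dtype=np.uint8), 0.5, 1.0, ("dapi",)
        )
        result = segment_stack(stack, "dapi", P)
        assert all(len(objs) == 0 for objs in result)

    def test_bad_channel_fails(self, small_stack):
        _, stack, _ = small_stack
        with pytest.raises(KeyError):
            segment_stack(stack, "nope", P)


class TestParams:
    def test_split_threshold_must_exceed_kr_squared(self):
        with pytest.raises(ValueError, match="KR"):
            SegmentationParams(kr=5, split_threshold=20.0)
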