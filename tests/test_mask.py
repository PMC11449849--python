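import numpy as np
import pytest

from octaquant.mask import (
    adaptive_mask,
    decompose_segments,
    diameter_field,
    global_otsu,
    make_bam,
    skeletonize,
    ti_skeleton_map,
    vesselness,
)


def straight_tube(radius: int, shape=(21, 110), col_span=(5, 105)) -> np.ndarray:
    rows = np.abs(np.arange(shape[0]) - shape[0] // 2) <= radius
    mask = np.zeros(shape, dtype=np.uint8)
    mask[rows, col_span[0] : col_span[1]] = 1
    return mask


class TestGlobalOtsu:
    def test_bimodal_threshold_between_modes(self):
        img = np.concatenate([np.full(50, 10.0), np.full(50, 200.0)]).reshape(10, 10)
        assert 10.0 < global_otsu(img) < 200.0

    def test_achieves_exhaustive_maximum(self, rng):
        """The returned threshold attains the maximum between-class variance
        found by exhaustively scoring every 256-bin histogram cut."""
        img = rng.normal(100.0, 40.0, (40, 40)) + 80.0 * (rng.random((40, 40)) > 0.6)
        hist, edges = np.histogram(img, bins=256)
        centers = (edges[:-1] + edges[1:]) / 2

        def between_class_variance(k):
            # classes: bins [0, k] and [k+1, 255]
            w0, w1 = hist[: k + 1].sum(), hist[k + 1 :].sum()
            if w0 == 0 or w1 == 0:
                return 0.0
            m0 = (hist[: k + 1] * centers[: k + 1]).sum() / w0
            m1 = (hist[k + 1 :] * centers[k + 1 :]).sum() / w1
            return w0 * w1 * (m0 - m1) ** 2

        best = max(between_class_variance(k) for k in range(255))
        threshold = global_otsu(img)
        k_returned = int(np.argmin(np.abs(centers - threshold)))
        assert centers[k_returned] == pytest.approx(threshold)
        assert between_class_variance(k_returned) >= best * (1.0 - 1e-12)

    def test_constant_image_errors(self):
        with pytest.raises(ValueError, match="constant"):
            global_otsu(np.full((5, 5), 3.0))


class TestAdaptiveMask:
    def test_uniform_image_positive_offset_empty(self):
        out = adaptive_mask(np.full((20, 20), 5.0), window=5, offset=0.1)
        assert not out.mask.any()

    def test_bright_stripe_detected_matches_loop_oracle(self, rng):
        img = rng.normal(1.0, 0.05, (30, 30))
        img[:, 12:18] += 2.0
        window, offset = 7, 0.1
        out = adaptive_mask(img, window=window, offset=offset).mask.astype(bool)
        pad = window // 2
        padded = np.pad(img, pad, mode="edge")
        for r in range(30):
            for c in range(30):
                local = padded[r : r + window, c : c + window].mean()
                assert out[r, c] == (img[r, c] > local + offset)
        assert out[:, 14].all()

    def test_huge_window_equals_global_mean_threshold(self):
        img = np.zeros((9, 9))
        img[4, 4] = 9.0
        out = adaptive_mask(img, window=17, offset=0.0).mask.astype(bool)
        # window replicated past every border degenerates to the global mean
        assert out[4, 4]
        assert out.sum() == 1

    def test_window_validation(self):
        with pytest.raises(ValueError, match="odd"):
            adaptive_mask(np.zeros((10, 10)), window=4)
        with pytest.raises(ValueError, match="twice"):
            adaptive_mask(np.zeros((10, 10)), window=41)


class TestVesselness:
    def test_constant_image_zero(self):
        assert not vesselness(np.full((20, 20), 3.0)).data.any()

    def test_tube_response_on_axis(self):
        img = straight_tube(2).astype(float)
        resp = vesselness(img).data
        center = resp[10, 20:90]
        background = resp[2, 20:90]
        assert center.min() > 0.5
        assert background.max() < 0.1

    def test_tube_beats_equal_peak_blob(self):
        yy, xx = np.mgrid[0:41, 0:41].astype(float)
        blob = np.exp(-((yy - 20) ** 2 + (xx - 20) ** 2) / (2 * 3.0**2))
        tube = np.exp(-((yy - 20) ** 2) / (2 * 3.0**2))
        assert vesselness(tube).data[20, 20] > vesselness(blob).data[20, 20]

    def test_scale_validation(self):
        with pytest.raises(ValueError, match="scales"):
            vesselness(np.zeros((10, 10)), scales=())


class TestMakeBam:
    def test_noise_free_phantom_dice(self, enface_phantom):
        img, gt = enface_phantom
        bam = make_bam(img).mask.astype(bool)
        truth = gt["layer_masks"][1]
        dice = 2.0 * (bam & truth).sum() / (bam.sum() + truth.sum())
        assert dice >= 0.90

    def test_all_zero_image_empty_mask(self):
        assert not make_bam(np.zeros((64, 64))).mask.any()

    def test_output_strictly_binary(self, enface_phantom):
        img, _ = enface_phantom
        assert set(np.unique(make_bam(img).mask)) <= {0, 1}


class TestSkeletonize:
    def test_bar_gives_single_straight_chain(self):
        """A 100x5 bar thins to one chain whose length is 100 minus bounded
        end-of-bar retraction (at most the bar half-width per end)."""
        bar = np.zeros((21, 110), np.uint8)
        bar[8:13, 5:105] = 1
        segments = decompose_segments(skeletonize(bar))
        assert len(segments) == 1
        assert 100 - 5 <= segments[0].length_px <= 101

    def test_skeleton_subset_of_mask(self, enface_phantom):
        img, _ = enface_phantom
        bam = make_bam(img)
        skel = skeletonize(bam).skeleton
        assert not (skel.astype(bool) & ~bam.mask.astype(bool)).any()

    def test_empty_mask_empty_skeleton(self):
        assert not skeletonize(np.zeros((10, 10), np.uint8)).skeleton.any()

    def test_no_2x2_block(self, enface_phantom):
        img, _ = enface_phantom
        s = skeletonize(make_bam(img)).skeleton.astype(bool)
        blocks = s[:-1, :-1] & s[:-1, 1:] & s[1:, :-1] & s[1:, 1:]
        assert not blocks.any()


class TestDecomposeSegments:
    def test_y_shape_three_segments(self):
        skel = np.zeros((30, 30), np.uint8)
        skel[5:15, 15] = 1  # stem
        for i in range(10):  # two arms
            skel[15 + i, 15 - i] = 1
            skel[15 + i, 15 + i] = 1
        skel[15, 15] = 1
        segments = decompose_segments(skel, min_len_px=3)
        assert len(segments) == 3

    def test_single_open_curve_one_segment(self):
        skel = np.zeros((20, 40), np.uint8)
        cols = np.arange(2, 38)
        rows = (10 + 4 * np.sin(cols / 5.0)).astype(int)
        skel[rows, cols] = 1
        assert len(decompose_segments(skel)) == 1

    def test_diagonal_chain_length(self):
        skel = np.zeros((10, 10), np.uint8)
        for i in range(4):
            skel[i, i] = 1
        seg = decompose_segments(skel, min_len_px=1)[0]
        assert seg.length_px == pytest.approx(3 * np.sqrt(2.0))

    def test_closed_loop_cut_open(self):
        ring = np.zeros((20, 20), np.uint8)
        ring[5, 5:15] = 1
        ring[14, 5:15] = 1
        ring[5:15, 5] = 1
        ring[5:15, 14] = 1
        segments = decompose_segments(ring)
        assert len(segments) == 1
        assert segments[0].was_loop
        assert segments[0].chord_px > 0

    def test_branch_points_unassigned(self):
        skel = np.zeros((30, 30), np.uint8)
        skel[5:15, 15] = 1
        for i in range(10):
            skel[15 + i, 15 - i] = 1
            skel[15 + i, 15 + i] = 1
        skel[15, 15] = 1
        segments = decompose_segments(skel, min_len_px=3)
        covered = np.zeros_like(skel, dtype=bool)
        for seg in segments:
            covered[seg.pixels[:, 0], seg.pixels[:, 1]] = True
        assert not covered[15, 15]  # the junction belongs to no segment


class TestSkeletonPartition:
    def test_segments_and_junctions_account_for_skeleton(self, enface_phantom):
        """Segment pixels, junction pixels, and dropped short chains
        partition the skeleton with no overlap."""
        from octaquant.mask import _branch_points

        img, _ = enface_phantom
        skel = skeletonize(make_bam(img)).skeleton.astype(bool)
        segments = decompose_segments(skel.astype(np.uint8), min_len_px=0.0)
        covered = np.zeros_like(skel)
        for seg in segments:
            assert not covered[seg.pixels[:, 0], seg.pixels[:, 1]].any()  # disjoint
            covered[seg.pixels[:, 0], seg.pixels[:, 1]] = True
        junctions = _branch_points(skel)
        assert not (covered & junctions).any()
        accounted = covered | junctions
        assert not (accounted & ~skel).any()
        # only sub-2-px fragments may remain unaccounted
        assert (skel & ~accounted).sum() <= 2 * len(segments)


class TestDiameterField:
    @pytest.mark.parametrize("radius", [2, 3, 5, 8])
    def test_tube_centerline_diameter(self, radius):
        shape = (4 * radius + 9, 140)
        tube = straight_tube(radius, shape=shape, col_span=(5, 135))
        bvs = skeletonize(tube)
        values = diameter_field(tube, bvs).values
        on = values[values > 0]
        assert 2 * radius - 1.5 <= on.mean() <= 2 * radius + 1.5

    def test_edge_adjacent_pixel_bounded(self):
        mask = np.zeros((10, 10), np.uint8)
        mask[4:6, 2:8] = 1
        skel = np.zeros_like(mask)
        skel[4, 2] = 1  # adjacent to background
        values = diameter_field(mask, skel).values
        assert 0 < values[4, 2] <= 2 * np.sqrt(2.0)

    def test_support_equals_skeleton(self, enface_phantom):
        img, _ = enface_phantom
        bam = make_bam(img)
        bvs = skeletonize(bam)
        values = diameter_field(bam, bvs).values
        np.testing.assert_array_equal(values > 0, bvs.skeleton.astype(bool))

    def test_skeleton_outside_mask_rejected(self):
        mask = np.zeros((5, 5), np.uint8)
        mask[2, 2] = 1
        skel = np.zeros_like(mask)
        skel[0, 0] = 1
        with pytest.raises(ValueError, match="outside"):
            diameter_field(mask, skel)


class TestTISkeletonMap:
    def test_straight_segment_zero(self):
        skel = np.zeros((10, 40), np.uint8)
        skel[5, 2:38] = 1
        segments = decompose_segments(skel)
        out = ti_skeleton_map(segments, skel.shape).values
        assert out[5, 10] == 0.0

    def test_semicircle_value(self):
        from octaquant.phantom import CenterlineSpec, make_centerline, rasterize_tube

        spec = CenterlineSpec(
            "arc", {"center": (60, 60), "radius": 40, "theta0": -np.pi / 2, "theta1": np.pi / 2}
        )
        tube = rasterize_tube(make_centerline(spec), 3, (120, 120))
        segments = decompose_segments(skeletonize(tube.astype(np.uint8)))
        assert len(segments) == 1
        analytic = (np.pi / 2 - 1.0) * 100.0
        assert segments[0].ti == pytest.approx(analytic, rel=0.05)
        out = ti_skeleton_map(segments, tube.shape).values
        assert np.unique(out[out > 0]).size == 1

    def test_two_segments_two_values(self):
        skel = np.zeros((45, 45), np.uint8)
        skel[5, 2:38] = 1  # straight: TI 0
        # right angle with equal legs of 10: TI (sqrt2-1)*100
        skel[20:30, 10] = 1
        skel[30, 10:21] = 1
        segments = decompose_segments(skel)
        out = ti_skeleton_map(segments, skel.shape).values
        tis = sorted(np.unique(out[skel.astype(bool)]))
        assert tis == pytest.approx([0.0, (np.sqrt(2.0) - 1.0) * 100.0])


class TestRotationInvariance:
    def test_segment_tis_stable_under_90_degree_rotation(self):
        """Per-vessel TI changes by < 2% when the mask is rotated 90 degrees.

        Uses long, clearly tortuous tubes: thinning retracts chain ends by a
        few orientation-dependent pixels, an absolute TI jitter that the
        relative bound only absorbs away from straightness.
        """
        from octaquant.phantom import CenterlineSpec, make_centerline, rasterize_tube

        shape = (512, 512)
        mask = np.zeros(shape, np.uint8)
        for i, (amp, wav) in enumerate([(12.0, 70.0), (10.0, 60.0), (14.0, 80.0)]):
            curve = make_centerline(
                CenterlineSpec(
                    "sinusoid",
                    {
                        "row0": 4.0,
                        "row1": 507.0,
                        "col0": 100.0 + 150.0 * i,
                        "amplitude": amp,
                        "wavelength": wav,
                        "phase": 0.7 * i,
                    },
                )
            )
            mask |= rasterize_tube(curve, 2.5, shape)
        tis_a = sorted(s.ti for s in decompose_segments(skeletonize(mask)))
        tis_b = sorted(s.ti for s in decompose_segments(skeletonize(np.rot90(mask).copy())))
        assert len(tis_a) == len(tis_b) == 3
        for ta, tb in zip(tis_a, tis_b):
            assert tb == pytest.approx(ta, rel=0.02)
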