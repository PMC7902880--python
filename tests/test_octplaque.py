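"""Unfolding, A-line classification, region grouping, cap thickness,
segmentation metrics."""

import numpy as np
import pytest

from cardiossae import octplaque, synthgen
from cardiossae.octplaque import (
    ALINE_LEN,
    OCTAnalysisConfig,
    PlaqueRegion,
    PolarOCTImage,
    cap_thickness,
    classify_aline,
    generate_regions,
    seg_metrics,
    unfold,
)


def flat_image(n_depth=200, n_angle=20, border_row=10, value=0.5):
    img = np.full((n_depth, n_angle), value)
    return PolarOCTImage(img, np.full(n_angle, border_row))


class TestUnfold:
    def test_rows_taken_below_border(self):
        rng = np.random.default_rng(0)
        img = PolarOCTImage(rng.random((200, 4)), np.array([10, 20, 30, 40]))
        mat, pads = unfold(img)
        np.testing.assert_array_equal(mat[:, 0], img.intensity[11:111, 0])
        assert pads[0] == 0

    def test_bottom_zero_padding(self):
        img = PolarOCTImage(np.ones((60, 3)), np.full(3, 10))
        mat, pads = unfold(img)
        assert pads[0] == 51  # 49 real rows (11..59), 51 padded
        np.testing.assert_array_equal(mat[:49, 0], 1.0)
        np.testing.assert_array_equal(mat[49:, 0], 0.0)

    def test_constant_image_constant_alines(self):
        mat, pads = unfold(flat_image(value=0.7))
        np.testing.assert_array_equal(mat, 0.7)
        assert (pads == 0).all()

    def test_shape_always_100_by_n_angle(self):
        for border in (0, 100, 198):
            img = PolarOCTImage(np.ones((200, 5)), np.full(5, border))
            mat, pads = unfold(img)
            assert mat.shape == (ALINE_LEN, 5)
        # border at the last valid row -> fully padded, flagged by pad_count
        img = PolarOCTImage(np.ones((200, 5)), np.full(5, 199))
        mat, pads = unfold(img)
        assert (pads == 100).all() and np.all(mat == 0)


class TestClassifyAline:
    def test_all_zero_is_guidewire(self):
        assert classify_aline(np.zeros(ALINE_LEN), stack=None) == "GS"

    def test_untrained_stack_rejected_on_network_path(self):
        from cardiossae import sae

        with pytest.raises(sae.SAEError, match="untrained"):
            classify_aline(np.full(ALINE_LEN, 0.5), stack=None)


class TestGenerateRegions:
    def test_uniform_labels_single_full_region(self):
        regions = generate_regions(np.full(36, "F"))
        assert len(regions) == 1
        assert (regions[0].start_col, regions[0].end_col) == (0, 36)

    def test_single_column_blip_absorbed(self):
        labels = np.full(40, "F", dtype="<U3")
        labels[17] = "F-C"
        regions = generate_regions(labels)
        assert len(regions) == 1 and regions[0].tissue_class == "F"

    def test_gs_runs_excluded(self):
        labels = np.full(60, "F", dtype="<U3")
        labels[20:40] = "GS"
        regions = generate_regions(labels)
        assert all(r.tissue_class != "GS" for r in regions)
        covered = set()
        for r in regions:
            covered.update(int(c) for c in r.columns(60))
        assert covered == set(range(60)) - set(range(20, 40))

    def test_wrap_around_run_joined(self):
        labels = np.full(60, "F", dtype="<U3")
        labels[:10] = "F-L"
        labels[50:] = "F-L"
        regions = generate_regions(labels)
        fl = [r for r in regions if r.tissue_class == "F-L"]
        assert len(fl) == 1
        assert sorted(int(c) for c in fl[0].columns(60)) == list(range(10)) + list(range(50, 60))

    def test_region_spans_partition_non_gs_columns(self):
        rng = np.random.default_rng(1)
        labels = np.array(
            [("F", "F-C", "F-L", "GS")[i] for i in rng.integers(0, 4, size=90)], dtype="<U3"
        )
        regions = generate_regions(labels)
        seen = []
        for r in regions:
            seen.extend(int(c) for c in r.columns(90))
        assert len(seen) == len(set(seen))  # no double assignment

    def test_phantom_two_arcs_recovered(self):
        spec = synthgen.OCTPhantomSpec(
            n_angle=120,
            arcs=[(10, 45, "F-C", 80.0), (70, 110, "F-L", 90.0)],
            border_profile=np.full(120, 20),
        )
        _, labels, _ = synthgen.gen_oct_phantom(spec, seed=0)
        regions = generate_regions(labels)
        spans = {(r.start_col, r.end_col % 120, r.tissue_class) for r in regions}
        fc = next(r for r in regions if r.tissue_class == "F-C")
        fl = next(r for r in regions if r.tissue_class == "F-L")
        assert abs(fc.start_col - 10) <= 4 and abs(fc.end_col - 45) <= 4
        assert abs(fl.start_col - 70) <= 4 and abs(fl.end_col - 110) <= 4


class TestCapThickness:
    def test_constructed_profile_four_pixels(self):
        # cap of 4 pixels at 10 um pitch -> 40 um
        img = np.zeros((200, 3))
        border = 10
        prof = np.concatenate([[0.6] * 4, [0.1] * 96])
        for c in range(3):
            img[border + 1 : border + 101, c] = prof
        image = PolarOCTImage(img, np.full(3, border), pixel_pitch_um=10.0)
        thick, reg = cap_thickness(image, PlaqueRegion(0, 3, "F-L"))
        np.testing.assert_array_equal(thick, 40.0)
        assert reg.min_cap_thickness_um == 40.0

    def test_threshold_semantics(self):
        for cap_px, expect_vuln in ((4, True), (12, False)):
            img = np.zeros((200, 2))
            prof = np.concatenate([[0.6] * cap_px, [0.1] * (100 - cap_px)])
            img[11:111, :] = prof[:, None]
            image = PolarOCTImage(img, np.full(2, 10), pixel_pitch_um=10.0)
            _, reg = cap_thickness(image, PlaqueRegion(0, 2, "F-L"), thin_cap_um=65.0)
            assert reg.vulnerable is expect_vuln

    def test_no_drop_point_flagged_as_window_depth(self):
        image = flat_image(value=0.6)
        thick, reg = cap_thickness(image, PlaqueRegion(0, 5, "F-L"))
        np.testing.assert_array_equal(thick, ALINE_LEN * image.pixel_pitch_um)

    def test_monotone_cap_across_phantom_arc(self):
        # linearly varying programmed cap 30 -> 130 um across columns
        n = 40
        img = np.zeros((300, n))
        caps_um = np.linspace(30, 130, n)
        for c in range(n):
            cap_px = int(round(caps_um[c] / 10.0))
            prof = np.concatenate([[0.55] * cap_px, 0.22 * np.exp(-np.arange(100 - cap_px) / 12)])
            img[11:111, c] = prof
        image = PolarOCTImage(img, np.full(n, 10), pixel_pitch_um=10.0)
        thick, _ = cap_thickness(image, PlaqueRegion(0, n, "F-L"))
        assert all(b >= a for a, b in zip(thick, thick[1:]))

    def test_non_lipid_region_rejected(self):
        with pytest.raises(ValueError, match="F-L"):
            cap_thickness(flat_image(), PlaqueRegion(0, 5, "F"))


class TestSegMetrics:
    def test_identical_masks(self):
        m = np.zeros((10, 10), bool)
        m[2:5, 3:7] = True
        s = seg_metrics(m, m)
        assert (s.dice, s.jaccard, s.precision, s.recall) == (1.0, 1.0, 1.0, 1.0)
        assert s.hausdorff_px == 0.0

    def test_disjoint_masks(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[0, 0] = True
        b[9, 9] = True
        s = seg_metrics(a, b)
        assert s.dice == 0.0 and s.jaccard == 0.0

    def test_shifted_block_hand_enumeration(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[4:6, 4:6] = True
        b[4:6, 5:7] = True  # shifted 1 px: intersection 2 cells
        s = seg_metrics(a, b)
        assert s.dice == pytest.approx(0.5)
        assert s.jaccard == pytest.approx(1 / 3)
        assert s.hausdorff_px == pytest.approx(1.0)
        assert s.precision == pytest.approx(0.5) and s.recall == pytest.approx(0.5)

    def test_empty_conventions(self):
        e = np.zeros((8, 8), bool)
        both = seg_metrics(e, e)
        assert both.dice == both.jaccard == 1.0 and both.hausdorff_px == 0.0
        m = e.copy()
        m[2, 2] = True
        one = seg_metrics(e, m)
        assert one.dice == one.jaccard == 0.0
        assert one.hausdorff_px == pytest.approx(np.sqrt(2 * 49))

    def test_jaccard_never_exceeds_dice(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a = rng.random((6, 6)) < 0.4
            b = rng.random((6, 6)) < 0.4
            s = seg_metrics(a, b)
            assert s.jaccard <= s.dice + 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            seg_metrics(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


@pytest.fixture(scope="module")
def small_stack():
    from cardiossae import pipelines

    return pipelines.train_aline_classifier(n_train_phantoms=4, seed=3)


class TestAnalyzeImage:
    def test_no_lipid_arc_no_vulnerable_regions(self, small_stack):
        spec = synthgen.OCTPhantomSpec(
            n_angle=120, arcs=[(10, 50, "F", 80.0), (60, 100, "F-C", 80.0)]
        )
        image, _, _ = synthgen.gen_oct_phantom(spec, seed=1)
        rep = octplaque.analyze_image(image, small_stack)
        assert not rep.vulnerable_mask.any()
        assert all(not r.vulnerable for r in rep.regions)

    def test_deterministic(self, small_stack):
        spec = synthgen.OCTPhantomSpec(n_angle=90, arcs=[(10, 50, "F-L", 40.0)])
        image, _, _ = synthgen.gen_oct_phantom(spec, seed=2)
        r1 = octplaque.analyze_image(image, small_stack)
        r2 = octplaque.analyze_image(image, small_stack)
        np.testing.assert_array_equal(r1.vulnerable_mask, r2.vulnerable_mask)
        np.testing.assert_array_equal(r1.labels, r2.labels)

    def test_thin_cap_arc_flagged(self, small_stack):
        spec = synthgen.OCTPhantomSpec(
            n_angle=120, arcs=[(20, 70, "F-L", 40.0)], guidewire=(90, 110)
        )
        image, _, gt_vuln = synthgen.gen_oct_phantom(spec, seed=4)
        rep = octplaque.analyze_image(image, small_stack, gold_vulnerable_mask=gt_vuln)
        assert rep.metrics.dice >= 0.85
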