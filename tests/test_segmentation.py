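"""Bead detection: stable regions, circle fits, intensity model, filters."""

import math

import numpy as np
import pytest

from beadpcr import segmentation as seg
from beadpcr import synthetic as syn


def _match(valid_dets, truth, tol=2.0):
    """Count truth beads matched by a valid detection within tol px."""
    tx = truth.beads[["x_px", "y_px"]].to_numpy()
    if not valid_dets:
        return 0
    dc = np.array([d.center for d in valid_dets])
    return int(sum(np.hypot(*(dc - tb).T).min() < tol for tb in tx))


class TestDetectRegions:
    def test_constant_image_no_regions(self, seg_params):
        assert seg.detect_regions(np.full((64, 64), 7.0), seg_params) == []

    def test_high_contrast_beads_one_region_each(self, seg_params, noiseless_well):
        marker, _, truth = noiseless_well
        regions = seg.detect_regions(marker, seg_params)
        assert len(regions) == truth.n_beads

    def test_artifacts_add_candidate_regions(self, seg_params):
        pop = syn.BeadPopulationSpec(n_beads=40, mean_diameter_um=96, diameter_cv=0.0)
        spec = syn.ImageSpec(width=400, height=400, noise_sd=0.0, artifact_rate=0.2)
        marker, _, truth = syn.render_well_image(pop, spec, 0.5, seed=11)
        regions = seg.detect_regions(marker, seg_params)
        assert truth.n_artifacts > 0
        assert len(regions) >= truth.n_beads

    def test_deterministic(self, seg_params, noiseless_well):
        marker, _, _ = noiseless_well
        a = seg.detect_regions(marker, seg_params)
        b = seg.detect_regions(marker, seg_params)
        assert len(a) == len(b)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.pixels, rb.pixels)

    def test_rescaling_invariance(self, seg_params, noiseless_well):
        """Detection depends only on relative intensity structure."""
        marker, _, _ = noiseless_well
        scaled = (marker.astype(np.float64)) * 3.7 + 11.0
        a = seg.detect_beads(marker, seg_params)
        b = seg.detect_beads(scaled, seg_params)
        assert len(a) == len(b)
        ca = np.array(sorted(d.center for d in a))
        cb = np.array(sorted(d.center for d in b))
        assert np.allclose(ca, cb, atol=0.5)


class TestFitCircle:
    def test_rendered_disk_radius_recovered(self):
        img = syn.render_field(
            np.array([[32.0, 32.0]]), [10.0], [1000.0],
            width=64, height=64, background=0.0,
        )
        rows, cols = np.nonzero(img > 0)
        (cx, cy), r, degenerate = seg.fit_circle(np.c_[rows, cols])
        assert not degenerate
        assert r == pytest.approx(10.0, abs=0.5)
        assert (cx, cy) == pytest.approx((32.0, 32.0), abs=0.5)

    def test_single_pixel_convention(self):
        (cx, cy), r, degenerate = seg.fit_circle(np.array([[5, 9]]))
        assert (cx, cy) == (9.0, 5.0)
        assert r == 0.5
        assert degenerate

    def test_two_pixels_degenerate_flag(self):
        _, r, degenerate = seg.fit_circle(np.array([[0, 0], [0, 3]]))
        assert degenerate
        assert r >= 1.5

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            seg.fit_circle(np.empty((0, 2)))

    def test_covers_all_pixels(self):
        rng = np.random.default_rng(0)
        pts = rng.integers(0, 40, size=(60, 2))
        (cx, cy), r, _ = seg.fit_circle(pts)
        d = np.hypot(pts[:, 1] - cx, pts[:, 0] - cy)
        assert np.all(d <= r + 1e-6)


class TestRepresentativeIntensity:
    def test_noiseless_sphere_recovered_within_one_percent(self):
        img = syn.render_field(
            np.array([[40.0, 40.0]]), [10.0], [1000.0],
            width=80, height=80, background=100.0,
        ).astype(float)
        amp, bg, fallback = seg.representative_intensity(img, (40.0, 40.0), 10.0)
        assert not fallback
        assert amp == pytest.approx(1000.0, rel=0.01)
        assert bg == pytest.approx(100.0, abs=1.0)

    def test_flat_disk_biased_high(self):
        """A flat (non-spherical) disk of value V fits an amplitude
        above its mean-above-background: documented model mismatch."""
        img = np.full((80, 80), 100.0)
        yy, xx = np.mgrid[0:80, 0:80]
        img[np.hypot(xx - 40, yy - 40) < 10] = 1100.0
        amp, _, _ = seg.representative_intensity(img, (40.0, 40.0), 10.0)
        assert amp > 1000.0

    def test_zero_signal_circle(self):
        img = np.full((60, 60), 250.0)
        amp, _, _ = seg.representative_intensity(img, (30.0, 30.0), 8.0)
        assert amp == pytest.approx(0.0, abs=1e-9)

    def test_annulus_outside_image_falls_back(self):
        # every annulus pixel (d in [11, 15] from the center) lies
        # beyond this tiny image, so background must come from the
        # global median and be flagged
        img = np.full((12, 12), 50.0)
        _, _, fallback = seg.representative_intensity(img, (6.0, 6.0), 10.0)
        assert fallback


class TestValidityFilters:
    def test_small_radius_invalid_size(self, seg_params):
        d = seg.BeadDetection(center=(50.0, 50.0), radius=2.0, region_area=12)
        seg.apply_validity_filters([d], seg_params, (100, 100))
        assert not d.valid and d.reason == "size"

    def test_concentric_detections_resolved_by_overlap(self, seg_params):
        big = seg.BeadDetection(center=(50.0, 50.0), radius=8.0, region_area=200,
                                shape_score=1.0)
        small = seg.BeadDetection(center=(50.0, 50.0), radius=5.0, region_area=60,
                                  shape_score=1.0)
        seg.apply_validity_filters([big, small], seg_params, (100, 100))
        assert big.valid
        assert not small.valid and small.reason == "overlap"

    def test_edge_clipped_bead_flagged(self, seg_params):
        """A half-moon region from a bead at the border gets an edge
        invalidation, not a silent bad circle."""
        img = syn.render_field(
            np.array([[0.0, 50.0]]), [8.0], [1000.0],
            width=100, height=100, background=100.0,
        )
        dets = seg.detect_beads(img, seg_params)
        assert len(dets) == 1
        assert not dets[0].valid
        assert dets[0].reason in ("edge", "shape")

    def test_exactly_one_invalid_reason(self, seg_params):
        d = seg.BeadDetection(center=(0.5, 0.5), radius=1.0, region_area=2,
                              shape_score=0.1)
        seg.apply_validity_filters([d], seg_params, (100, 100))
        assert not d.valid
        assert d.reason == "size"  # precedence: first failing criterion only


class TestEndToEndDetection:
    def test_noiseless_recall_and_accuracy(self, seg_params, noiseless_well):
        marker, _, truth = noiseless_well
        dets = seg.detect_beads(marker, seg_params)
        valid = [d for d in dets if d.valid]
        assert len(valid) == truth.n_beads
        assert _match(valid, truth) == truth.n_beads
        tx = truth.beads[["x_px", "y_px"]].to_numpy()
        tr = truth.beads["radius_px"].to_numpy()
        for d in valid:
            i = int(np.hypot(*(tx - d.center).T).argmin())
            assert np.hypot(*(tx[i] - d.center)) <= 2.0
            assert abs(d.radius - tr[i]) / tr[i] <= 0.10

    def test_artifacts_invalidated_beads_kept(self, seg_params):
        pop = syn.BeadPopulationSpec(n_beads=80, mean_diameter_um=96, diameter_cv=0.07)
        spec = syn.ImageSpec(width=400, height=400, noise_sd=25.0, artifact_rate=0.05)
        lost = art_total = art_bad = 0
        for s in range(5):
            marker, _, truth = syn.render_well_image(pop, spec, 0.5, seed=300 + s)
            dets = seg.detect_beads(marker, seg_params)
            valid = [d for d in dets if d.valid]
            matched = _match(valid, truth)
            lost += truth.n_beads - matched
            art_total += truth.n_artifacts
            art_bad += max(len(valid) - matched, 0)  # accepted non-beads
        assert art_total > 0
        assert art_bad <= 0.05 * art_total
        assert lost <= 0.02 * 5 * 80

    def test_marker_then_detection_channel(self, seg_params, noiseless_well):
        marker, detect, truth = noiseless_well
        dets = seg.detect_beads(marker, seg_params, channel="marker")
        seg.measure_channel(dets, detect, "detect")
        tx = truth.beads[["x_px", "y_px"]].to_numpy()
        tpk = truth.beads["detect_peak"].to_numpy()
        for d in dets:
            if not d.valid:
                continue
            i = int(np.hypot(*(tx - d.center).T).argmin())
            assert d.intensities["detect"] == pytest.approx(tpk[i], rel=0.08, abs=60)


class TestCountBeads:
    def test_blank_image_counts_zero(self, seg_params):
        img = np.full((128, 128), 500, dtype=np.uint16)
        n, conc = seg.count_beads([img], seg_params, input_volume_ul=6.0)
        assert n == 0 and conc == 0.0

    def test_stock_concentration_consistency(self):
        """A 6 uL aliquot at 565 beads/uL holds 3,390 beads; counting a
        rendered monolayer recovers the stock concentration."""
        pop = syn.BeadPopulationSpec(n_beads=3390)
        spec = syn.ImageSpec(width=620, height=620, pixel_size_um=12.0, noise_sd=25.0)
        params = seg.SegmentationParams(min_radius_px=2.3, max_radius_px=6.5)
        marker, _, _ = syn.render_well_image(pop, spec, 0.0, seed=5)
        n, conc = seg.count_beads([marker], params, input_volume_ul=6.0)
        assert conc == pytest.approx(565.0, rel=0.02)

    def test_requires_images(self, seg_params):
        with pytest.raises(ValueError):
            seg.count_beads([], seg_params)
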