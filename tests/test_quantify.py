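"""Poisson statistics, mixture thresholding, and concentration math."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beadpcr.quantify import (
    StudyDesign,
    WellIntensitySet,
    concentration_beads,
    concentration_volume,
    detection_stats,
    find_threshold,
    lambda_confidence_interval,
    per_bead_loading,
    poisson_lambda,
    quantify_well,
    select_modality,
    sphere_volume,
)


class TestPoissonLambda:
    @pytest.mark.parametrize(
        "n_neg,n,expected",
        [
            (1000, 1000, 0.0),
            (500, 1000, math.log(2)),
            (3000, 3300, math.log(1.1)),
        ],
    )
    def test_closed_form(self, n_neg, n, expected):
        assert poisson_lambda(n_neg, n) == pytest.approx(expected, rel=1e-12)

    def test_all_positive_has_no_finite_estimate(self):
        assert math.isinf(poisson_lambda(0, 100))

    @pytest.mark.parametrize("n_neg,n", [(-1, 10), (11, 10), (0, 0)])
    def test_domain_errors(self, n_neg, n):
        with pytest.raises(ValueError):
            poisson_lambda(n_neg, n)

    @given(st.integers(1, 10_000), st.integers(1, 10_000))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_in_negative_count(self, a, b):
        n = max(a, b) + 1
        lo, hi = sorted((a, b))
        assert poisson_lambda(hi, n) <= poisson_lambda(lo, n)

    def test_recovers_simulated_truth_within_sampling_error(self):
        """Simulated Poisson partitioning, classified by truth, recovers
        lambda within 3x the standard digital-PCR sampling SD."""
        n = 5000
        for lam in (0.1, 0.7, 2.0):
            sd = math.sqrt((math.exp(lam) - 1) / n)
            for seed in range(5):
                counts = np.random.default_rng(seed).poisson(lam, n)
                est = poisson_lambda(int((counts == 0).sum()), n)
                assert abs(est - lam) < 3 * sd


class TestConcentrations:
    def test_bead_count_formula(self, design):
        assert concentration_beads(0.0, design) == 0.0
        c = concentration_beads(math.log(2), design)
        assert c == pytest.approx(3916, abs=1.0)

    def test_volume_formula(self, design):
        assert concentration_volume(20_000, 20_000, design) == 0.0
        c = concentration_volume(10_000, 20_000, design)
        assert c == pytest.approx(4082, abs=1.0)

    def test_volume_formula_units(self):
        d = StudyDesign(compartment_volume_nl=1.0, dilution_factor=1.0)
        n = 100_000
        n_neg = int(round(n * math.exp(-1.0)))
        lam = poisson_lambda(n_neg, n)
        assert concentration_volume(n_neg, n, d) == pytest.approx(lam * 1000, rel=1e-9)

    @given(
        st.floats(0.0, 10.0),
        st.integers(1_000, 200_000),
        st.floats(1.0, 500.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_linearity(self, lam, n_b, v_s):
        d = StudyDesign(n_beads_incubated=n_b, sample_volume_ul=v_s)
        base = concentration_beads(lam, d)
        assert concentration_beads(2 * lam, d) == pytest.approx(2 * base, rel=1e-9)
        d2 = StudyDesign(n_beads_incubated=2 * n_b, sample_volume_ul=v_s)
        assert concentration_beads(lam, d2) == pytest.approx(2 * base, rel=1e-9)
        d3 = StudyDesign(n_beads_incubated=n_b, sample_volume_ul=2 * v_s)
        assert concentration_beads(lam, d3) == pytest.approx(base / 2, rel=1e-9)

    def test_same_volume_equivalence(self):
        """When beads exactly tile the sample volume, the bead-count and
        compartment-volume formulas agree identically (D = 1)."""
        v_c_nl = 0.446
        n_b = 10_000
        d = StudyDesign(
            n_beads_incubated=n_b,
            sample_volume_ul=n_b * v_c_nl * 1e-3,
            compartment_volume_nl=v_c_nl,
            dilution_factor=1.0,
        )
        for n_neg in (9000, 5000, 1234):
            lam = poisson_lambda(n_neg, n_b)
            assert concentration_beads(lam, d) == pytest.approx(
                concentration_volume(n_neg, n_b, d), rel=1e-12
            )


class TestSphereVolume:
    @pytest.mark.parametrize(
        "diameter,expected,tol",
        [
            (94.8, 0.446, 0.001),
            (117.5, 0.849, 0.001),
            (124.07, 1.000, 0.001),
        ],
    )
    def test_values(self, diameter, expected, tol):
        assert sphere_volume(diameter) == pytest.approx(expected, abs=tol)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            sphere_volume(0.0)


class TestDetectionStats:
    def test_low_concentration_regime(self, design):
        expected, p = detection_stats(3.18, design, 3300)
        assert expected == pytest.approx(1.9, abs=0.05)
        assert p == pytest.approx(1 - math.exp(-expected), rel=1e-12)

    def test_unit_case(self):
        d = StudyDesign(n_beads_incubated=1000, sample_volume_ul=1.0)
        expected, p = detection_stats(1.0, d, 1000)
        assert expected == pytest.approx(1.0)
        assert p == pytest.approx(1 - math.exp(-1))

    def test_cannot_analyze_more_than_incubated(self, design):
        with pytest.raises(ValueError):
            detection_stats(1.0, design, design.n_beads_incubated + 1)


def test_per_bead_loading():
    assert per_bead_loading(171.0, 57_000) == pytest.approx(0.003, abs=1e-4)


class TestModality:
    def test_identical_intensities_unimodal(self):
        assert select_modality(np.full(100, 5.0)).modality == 1

    def test_too_few_beads_indeterminate(self):
        assert select_modality(np.arange(5.0)).modality == 0

    def test_bimodal_detected(self, bimodal_intensities):
        res = select_modality(bimodal_intensities)
        assert res.modality == 2
        assert res.bic_2 < res.bic_1
        assert res.means[0] < res.threshold < res.means[1]

    def test_unimodal_stable_across_seeds(self):
        wrong = 0
        for seed in range(25):
            x = np.random.default_rng(seed).normal(100, 10, 3000)
            wrong += select_modality(x).modality != 1
        assert wrong == 0

    def test_tiny_minority_demoted(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(100, 10, 2000), rng.normal(1000, 10, 2)])
        res = select_modality(x)
        assert res.modality == 1
        assert res.demoted


class TestThreshold:
    def test_separates_well_separated_modes(self, bimodal_intensities):
        res = select_modality(bimodal_intensities)
        thr = res.threshold
        assert 130 < thr < 850
        truth = np.arange(bimodal_intensities.size) >= 1500
        mis = (bimodal_intensities > thr) != truth
        assert mis.mean() <= 0.005

    def test_symmetric_mixture_threshold_at_midpoint(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(0, 1, 2000), rng.normal(10, 1, 2000)])
        res = select_modality(x)
        assert res.threshold == pytest.approx(5.0, abs=0.2)

    def test_requires_bimodal(self):
        res = select_modality(np.random.default_rng(0).normal(0, 1, 500))
        with pytest.raises(ValueError):
            find_threshold(np.zeros(10), res)


class TestQuantifyWell:
    def test_all_negative_well(self, design):
        rng = np.random.default_rng(0)
        well = WellIntensitySet(rng.normal(6000, 600, 1000))
        res = quantify_well(well, design, positive_control_intensity=11000)
        assert res.flags.get("all_negative")
        assert res.lam == 0.0
        assert res.concentration == 0.0

    def test_all_positive_well_above_range(self, design):
        rng = np.random.default_rng(0)
        well = WellIntensitySet(rng.normal(16000, 900, 1000))
        res = quantify_well(well, design, positive_control_intensity=11000)
        assert res.flags.get("all_positive")
        assert res.flags.get("above_range")
        assert math.isinf(res.lam)

    def test_unimodal_without_control_indeterminate(self, design):
        well = WellIntensitySet(np.random.default_rng(0).normal(6000, 600, 500))
        res = quantify_well(well, design)
        assert res.flags.get("indeterminate")

    def test_mixed_well_estimates_lambda(self, design):
        rng = np.random.default_rng(1)
        lam = 0.8
        pos = rng.poisson(lam, 3300) >= 1
        vals = np.where(pos, rng.normal(16000, 900, 3300), rng.normal(6000, 600, 3300))
        res = quantify_well(WellIntensitySet(vals), design)
        assert res.lam == pytest.approx(
            poisson_lambda(int((~pos).sum()), 3300), rel=1e-9
        )
        assert abs(res.lam - lam) < 3 * math.sqrt((math.exp(lam) - 1) / 3300)

    def test_wilson_ci_brackets_lambda(self):
        lo, hi = lambda_confidence_interval(500, 1000)
        assert lo < math.log(2) < hi
        lo, hi = lambda_confidence_interval(1000, 1000)
        assert lo == 0.0
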