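"""PDD/profile analysis: extraction, extrapolation, comparison statistics."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kvbeam import analysis, transport
from kvbeam.analysis import (ComparisonStats, DepthDoseCurve,
                             compare_to_reference, percent_difference_stats,
                             quadrature_uncertainty, surface_extrapolate)


def axial_result(depths, dose, ssd=15.0):
    tallies = tuple(transport.Tally((0.0, 0.0, ssd + d)) for d in depths)
    dose = np.asarray(dose, dtype=float)
    return transport.DoseResult(tallies=tallies, dose=dose,
                                stderr=np.zeros_like(dose), histories=1000,
                                seed=0, launched_energy=1.0,
                                deposited_energy=1.0, escaped_energy=0.0)


class TestExtractPdd:
    def test_constant_dose_gives_flat_curve_at_100(self):
        r = axial_result([1, 2, 3, 4, 5], np.ones(5))
        c = analysis.extract_pdd(r, ssd=15.0)
        assert np.allclose(c.dose, 100.0)

    def test_exponential_dose_surface_normalized_closed_form(self):
        d = np.arange(1.0, 11.0)
        r = axial_result(d, np.exp(-0.2 * d))
        # normalize at the exact surface value instead of the polynomial fit
        # to check the closed form: value at 5 cm is 100 e^-1
        c = analysis.extract_pdd(r, ssd=15.0, normalize="shallowest")
        ratio = c.dose[d == 5.0][0] / c.dose[0]
        assert 100 * ratio * np.exp(-0.2) == pytest.approx(100 * np.exp(-1.0),
                                                           rel=1e-12)

    def test_off_axis_tallies_rejected(self):
        t = (transport.Tally((1.0, 0.0, 16.0)), transport.Tally((0, 0, 17.0)))
        r = transport.DoseResult(tallies=t, dose=np.ones(2),
                                 stderr=np.zeros(2), histories=1000, seed=0,
                                 launched_energy=1, deposited_energy=1,
                                 escaped_energy=0)
        with pytest.raises(ValueError, match="central axis"):
            analysis.extract_pdd(r, ssd=15.0)


class TestSurfaceExtrapolation:
    def test_exact_on_cubic_data(self):
        coeffs = [0.02, -0.5, -2.0, 100.0]
        d = np.arange(1.0, 9.0)
        v = np.polyval(coeffs, d)
        assert surface_extrapolate(d, v, order=3, k=5) == \
            pytest.approx(100.0, abs=1e-9)

    def test_linear_two_points_closed_form(self):
        assert surface_extrapolate([1.0, 2.0], [90.0, 80.0],
                                   order=1, k=2) == pytest.approx(100.0)

    def test_unbiased_on_noisy_exponential(self):
        # 1% multiplicative noise, 20 repeats: recovered surface within 2%
        rng = np.random.Generator(np.random.Philox(77))
        d = np.arange(1.0, 11.0)
        truth = np.exp(-0.25 * d)
        estimates = [surface_extrapolate(
            d, truth * (1 + 0.01 * rng.standard_normal(len(d))))
            for _ in range(20)]
        assert np.mean(estimates) == pytest.approx(1.0, rel=0.02)

    def test_underdetermined_fit_rejected(self):
        with pytest.raises(ValueError, match="underdetermined"):
            surface_extrapolate([1.0, 2.0], [90.0, 80.0], order=3, k=2)


class TestPercentDifference:
    def test_identical_curves_all_zero(self):
        x = np.arange(1.0, 6.0)
        v = np.array([100, 80, 60, 45, 30.0])
        s = percent_difference_stats(x, v, x, v)
        assert s.min == s.max == s.mean_abs == s.sd_abs == 0.0

    def test_uniform_two_percent_offset(self):
        x = np.arange(1.0, 6.0)
        v = np.array([100, 80, 60, 45, 30.0])
        s = percent_difference_stats(x, 1.02 * v, x, v)
        assert np.allclose(s.signed, 2.0, rtol=1e-12)
        assert s.sd_abs == pytest.approx(0.0, abs=1e-12)

    def test_three_point_toy_by_hand(self):
        s = percent_difference_stats([1, 2, 3], [100, 50, 25],
                                     [1, 2, 3], [100, 48, 26])
        assert s.signed == pytest.approx([0.0, 100 * 2 / 48, -100 / 26],
                                         rel=1e-9)
        assert s.mean_abs == pytest.approx(
            (0 + 100 * 2 / 48 + 100 / 26) / 3, rel=1e-9)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_invariant_to_common_rescale(self, scale):
        x = np.arange(1.0, 6.0)
        a = np.array([100, 81, 62, 44, 31.0])
        b = np.array([100, 80, 60, 45, 30.0])
        s1 = percent_difference_stats(x, a, x, b)
        s2 = percent_difference_stats(x, scale * a, x, scale * b)
        assert np.allclose(s1.signed, s2.signed, rtol=1e-9)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="zero reference"):
            percent_difference_stats([1, 2], [1, 1], [1, 2], [1, 0])


class TestQuadrature:
    def test_setup_plus_reading_uncertainty(self):
        # 2.1% setup and 0.3% reading combine to 2.1% at one decimal
        assert quadrature_uncertainty([2.1, 0.3]) == 2.1

    def test_pythagorean_triple(self):
        assert quadrature_uncertainty([3.0, 4.0]) == 5.0

    def test_single_component_identity(self):
        assert quadrature_uncertainty([1.7]) == 1.7

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            quadrature_uncertainty([2.0, -1.0])


class TestReferenceComparison:
    def curve(self):
        d = np.arange(1.0, 11.0)
        return DepthDoseCurve(d, 100 * np.exp(-0.2 * (d - 1)))

    def test_equal_reference_gives_zero_stats(self):
        c = self.curve()
        s = compare_to_reference(c, c.depths, c.dose)
        assert s.mean_abs == 0.0

    def test_five_percent_shifted_reference(self):
        c = self.curve()
        s = compare_to_reference(c, c.depths, 1.05 * c.dose)
        assert np.allclose(s.signed, 100 * (1 / 1.05 - 1), rtol=1e-9)

    def test_technique_mismatch_is_explicit_refusal(self):
        c = self.curve()
        with pytest.raises(ValueError, match="technique mismatch on kvp"):
            compare_to_reference(c, c.depths, c.dose,
                                 ref_meta={"kvp": 100},
                                 curve_meta={"kvp": 120})

    def test_disjoint_depth_ranges_rejected(self):
        c = self.curve()
        with pytest.raises(ValueError, match="overlap"):
            compare_to_reference(c, c.depths + 100.0, c.dose)


class TestPrimaryKermaPdd:
    def test_monotone_decreasing_and_normalized(self, tuned120):
        d = np.arange(1.0, 11.0)
        c = analysis.primary_kerma_pdd(tuned120, d, ssd=15.0)
        assert np.all(np.diff(c.dose) < 0)
        assert c.dose[0] < 100.0  # surface normalization point is shallower

    def test_harder_beam_penetrates_more(self, spec120, tuned120):
        # tuned (harder) beam retains more dose at 10 cm than the nominal
        from kvbeam.spectra import air_kerma_hvl
        d = np.arange(1.0, 11.0)
        soft, hard = (spec120, tuned120) if air_kerma_hvl(spec120) < \
            air_kerma_hvl(tuned120) else (tuned120, spec120)
        c_soft = analysis.primary_kerma_pdd(soft, d, ssd=15.0)
        c_hard = analysis.primary_kerma_pdd(hard, d, ssd=15.0)
        assert c_hard.dose[-1] / c_hard.dose[0] > \
            c_soft.dose[-1] / c_soft.dose[0]
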