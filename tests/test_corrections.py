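"""Verification scaling, blank subtraction and concentration summaries."""

from math import sqrt

import pytest
from hypothesis import given, strategies as st

from canmp import corrections
from canmp.types import (
    BrandConcentration,
    CanObservation,
    CorrectionConstants,
)


def obs(code, counts, mass=50.0):
    return [
        CanObservation(code, i + 1, mass, c) for i, c in enumerate(counts)
    ]


class TestRates:
    @pytest.mark.parametrize(
        "analyzed, verified, expected",
        [(79, 64, 64 / 79), (10, 10, 1.0), (10, 0, 0.0)],
    )
    def test_verification_rate(self, analyzed, verified, expected):
        c = CorrectionConstants(n_analyzed=analyzed, n_verified=verified)
        assert corrections.verification_rate(c) == pytest.approx(expected)

    def test_survey_rate_displays_as_81_percent(self, constants):
        rate = corrections.verification_rate(constants)
        assert round(rate * 100) == 81
        assert rate == pytest.approx(0.810127, abs=1e-6)

    def test_zero_analyzed_is_an_error(self):
        c = CorrectionConstants(n_analyzed=0, n_verified=0)
        with pytest.raises(ZeroDivisionError):
            corrections.verification_rate(c)

    @pytest.mark.parametrize(
        "particles, units, expected",
        [(2, 3, 2 / 3), (0, 3, 0.0), (6, 4, 1.5)],
    )
    def test_blank_rate(self, particles, units, expected):
        c = CorrectionConstants(blank_particles=particles, blank_units=units)
        assert corrections.blank_rate(c) == pytest.approx(expected)

    def test_survey_blank_displays_as_0_67(self, constants):
        assert round(corrections.blank_rate(constants), 2) == 0.67


class TestBrandConcentration:
    def test_equal_counts_give_printed_raw_mean(self):
        brand = corrections.brand_concentration(obs("D-C-1", [5, 5, 5]))
        assert brand.raw_mean_per100g == pytest.approx(10.00)
        assert brand.std_error_per100g == pytest.approx(0.0)

    def test_all_zero_counts(self):
        brand = corrections.brand_concentration(obs("A-B-1", [0, 0, 0]))
        assert brand.raw_mean_per100g == 0.0
        assert brand.std_error_per100g == 0.0

    def test_hand_computed_mean_and_se(self):
        # per-replicate values 2, 4, 6 per 100 g: mean 4, SD 2, SE 2/sqrt(3)
        brand = corrections.brand_concentration(obs("A-B-1", [1, 2, 3]))
        assert brand.raw_mean_per100g == pytest.approx(4.00)
        assert brand.std_error_per100g == pytest.approx(2.0 / sqrt(3))

    def test_mixed_codes_rejected(self):
        rows = obs("A-B-1", [1]) + obs("A-B-2", [2])
        with pytest.raises(ValueError, match="multiple brands"):
            corrections.brand_concentration(rows)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            corrections.brand_concentration([])


class TestCorrectBrand:
    @pytest.mark.parametrize(
        "raw, expected",
        [(10.00, 8.10), (16.67, 13.50)],
        ids=["D-C-1", "D-D-3"],
    )
    def test_printed_corrected_means(self, raw, expected, constants):
        rate = corrections.verification_rate(constants)
        brand = corrections.correct_brand(
            BrandConcentration("x", raw), rate
        )
        assert brand.corrected_mean_per100g == pytest.approx(
            expected, abs=0.005
        )

    def test_rate_one_is_identity(self):
        brand = corrections.correct_brand(
            BrandConcentration("x", 7.5, std_error_per100g=1.2), 1.0
        )
        assert brand.corrected_mean_per100g == 7.5
        assert brand.std_error_per100g == 1.2

    def test_standard_error_scaled_with_the_mean(self, constants):
        rate = corrections.verification_rate(constants)
        brand = corrections.correct_brand(
            BrandConcentration("x", 10.0, std_error_per100g=1.0), rate
        )
        assert brand.std_error_per100g == pytest.approx(rate)

    def test_no_blank_subtraction_at_brand_level(self):
        # corrected equals raw*rate exactly, background untouched
        brand = corrections.correct_brand(BrandConcentration("x", 2.0), 0.5)
        assert brand.corrected_mean_per100g == pytest.approx(1.0)


class TestGrandMean:
    def test_two_brand_oracle(self):
        brands = [BrandConcentration("a", 10.0), BrandConcentration("b", 20.0)]
        grand = corrections.grand_mean(brands, rate=0.5, blank=1.0)
        assert grand.corrected_mean_per100g == pytest.approx(6.5)

    def test_blank_equal_to_signal_floors_at_zero(self):
        brands = [BrandConcentration("a", (2 / 3) * (79 / 64))]
        grand = corrections.grand_mean(brands, rate=64 / 79, blank=2 / 3)
        assert grand.corrected_mean_per100g == pytest.approx(0.0, abs=1e-12)

    def test_scale_then_subtract_order(self, reference_concentrations):
        # subtract-then-scale would give (5.93 - 0.67) * 0.81 = 4.26;
        # the implemented order gives 5.93 * 0.8101 - 0.67 = 4.14
        grand = corrections.grand_mean(
            reference_concentrations, rate=64 / 79, blank=2 / 3
        )
        assert grand.raw_mean_per100g == pytest.approx(5.93, abs=0.005)
        assert grand.corrected_mean_per100g == pytest.approx(4.137, abs=0.005)
        subtract_first = (grand.raw_mean_per100g - 2 / 3) * 64 / 79
        assert subtract_first == pytest.approx(4.26, abs=0.005)
        assert grand.corrected_mean_per100g != pytest.approx(
            subtract_first, abs=0.05
        )

    def test_unit_consistent_mode_subtracts_per_100g_rate(self):
        brands = [BrandConcentration("a", 10.0)]
        standard = corrections.grand_mean(brands, 1.0, 2 / 3)
        strict = corrections.grand_mean(
            brands, 1.0, 2 / 3, blank_mode="unit_consistent",
            subsample_mass_g=50.0,
        )
        assert standard.corrected_mean_per100g == pytest.approx(10 - 2 / 3)
        assert strict.corrected_mean_per100g == pytest.approx(10 - 4 / 3)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            corrections.grand_mean([], 1.0, 0.0)

    @given(
        raws=st.lists(
            st.floats(min_value=0, max_value=50), min_size=1, max_size=10
        ),
        rate=st.floats(min_value=0, max_value=1),
        blank=st.floats(min_value=0, max_value=5),
    )
    def test_identity_and_monotonicity_properties(self, raws, rate, blank):
        brands = [
            BrandConcentration(f"b{i}", r) for i, r in enumerate(raws)
        ]
        grand = corrections.grand_mean(brands, rate, blank)
        # with rate 1 and blank 0 the correction stage is the identity
        identity = corrections.grand_mean(brands, 1.0, 0.0)
        assert identity.corrected_mean_per100g == pytest.approx(
            identity.raw_mean_per100g
        )
        # corrected grand is non-decreasing in the rate
        larger = corrections.grand_mean(brands, min(rate + 0.1, 1.0), blank)
        assert larger.corrected_mean_per100g >= (
            grand.corrected_mean_per100g - 1e-12
        )
        # and non-decreasing when every raw mean grows
        shifted = [
            BrandConcentration(f"b{i}", r + 1.0) for i, r in enumerate(raws)
        ]
        bigger = corrections.grand_mean(shifted, rate, blank)
        assert bigger.corrected_mean_per100g >= (
            grand.corrected_mean_per100g - 1e-12
        )


class TestOverallFromCounts:
    def test_pooled_count_route_reproduces_printed_overall(self):
        value = corrections.overall_mean_from_counts(
            293, 99, 50.0, 0.81, 0.67
        )
        assert value == pytest.approx(4.12, abs=0.01)

    def test_floors_at_zero(self):
        assert corrections.overall_mean_from_counts(1, 3, 50.0, 0.5, 5.0) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            corrections.overall_mean_from_counts(10, 0, 50.0, 0.8, 0.0)
        with pytest.raises(ValueError):
            corrections.overall_mean_from_counts(10, 3, 0.0, 0.8, 0.0)
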