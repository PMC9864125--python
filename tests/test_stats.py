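"""Normality checks, one-way ANOVA and the weight correlation."""

import numpy as np
import pytest

from canmp import simulate, stats as cs
from canmp.survey import CannedFishSurvey
from canmp.types import ValidationError


class TestLogTransform:
    def test_zero_maps_to_zero(self):
        assert cs.log_transform([0.0])[0] == 0.0

    def test_closed_form_point(self):
        assert cs.log_transform([np.e - 1])[0] == pytest.approx(1.0)

    def test_monotone_input_stays_monotone(self):
        rng = np.random.default_rng(0)
        values = np.sort(rng.uniform(0, 20, size=50))
        out = cs.log_transform(values)
        assert np.all(np.diff(out) >= 0)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            cs.log_transform([-0.1])


class TestNormality:
    def test_normal_sample_not_flagged(self):
        rng = np.random.default_rng(314)
        result = cs.normality_tests(rng.normal(10, 2, size=1000))
        assert not result.non_normal

    def test_skewed_sample_flagged(self):
        rng = np.random.default_rng(314)
        result = cs.normality_tests(rng.exponential(1.0, size=1000))
        assert result.non_normal

    def test_constant_sample_rejected(self):
        with pytest.raises(ValidationError):
            cs.normality_tests([3.0, 3.0, 3.0, 3.0])

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValidationError):
            cs.normality_tests([1.0, 2.0])


def hand_anova(groups):
    """Independent textbook computation: between/within mean squares."""
    all_values = [v for g in groups for v in g]
    grand = sum(all_values) / len(all_values)
    ss_between = sum(
        len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups
    )
    ss_within = sum(
        (v - sum(g) / len(g)) ** 2 for g in groups for v in g
    )
    df_b = len(groups) - 1
    df_w = len(all_values) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


class TestAnova:
    def test_identical_groups_give_f_zero(self):
        grouped = cs.GroupedValues(
            "producer", {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}
        )
        result = cs.one_way_anova(grouped, transform=False)
        assert result.f_statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_computed_f(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0]}
        grouped = cs.GroupedValues("producer", groups)
        result = cs.one_way_anova(grouped, transform=False)
        assert result.f_statistic == pytest.approx(
            hand_anova(list(groups.values()))
        )
        assert result.df_between == 1
        assert result.df_within == 4

    def test_singleton_groups_dropped_with_warning(self):
        grouped = cs.GroupedValues(
            "species",
            {"a": [1.0, 2.0], "b": [2.0, 3.0], "lonely": [5.0]},
        )
        with pytest.warns(UserWarning, match="lonely"):
            result = cs.one_way_anova(grouped)
        assert result.n_groups_used == 2
        assert result.dropped_groups == ("lonely",)

    def test_fewer_than_two_usable_groups_rejected(self):
        grouped = cs.GroupedValues(
            "species", {"a": [1.0, 2.0], "b": [5.0]}
        )
        with pytest.warns(UserWarning):
            with pytest.raises(ValidationError):
                cs.one_way_anova(grouped)

    def test_f_invariant_under_shift_and_scale(self):
        rng = np.random.default_rng(5)
        groups = {
            label: list(rng.normal(loc, 1.0, size=6))
            for label, loc in (("a", 0.0), ("b", 1.0), ("c", 0.5))
        }
        base = cs.one_way_anova(
            cs.GroupedValues("producer", groups), transform=False
        )
        moved = {
            k: [3.0 + 2.5 * v for v in vs] for k, vs in groups.items()
        }
        shifted = cs.one_way_anova(
            cs.GroupedValues("producer", moved), transform=False
        )
        assert shifted.f_statistic == pytest.approx(base.f_statistic)

    def test_power_against_injected_producer_effect(self):
        """A producer effect at the generator's default size is detected
        in at least 80% of seeded surveys."""
        rejections = 0
        runs = 200
        for seed in range(runs):
            tables = simulate.generate_survey(
                simulate.GeneratorConfig(seed=seed)
            )
            results = CannedFishSurvey.from_tables(tables).fit()
            if results.anova("producer").pvalue < 0.05:
                rejections += 1
        assert rejections / runs >= 0.80

    def test_null_producer_effect_rejects_near_alpha(self):
        """With no injected effect the brand-level producer ANOVA rejects
        at ~5%. (Per-can values are clustered by brand, so exchangeability
        under the null only holds after aggregating to brand means.)"""
        rejections = 0
        runs = 200
        for seed in range(runs):
            tables = simulate.generate_survey(
                simulate.GeneratorConfig(seed=seed, producer_effect_sd=0.0)
            )
            results = CannedFishSurvey.from_tables(tables).fit()
            if results.anova("producer", level="brand").pvalue < 0.05:
                rejections += 1
        # 3 sigma above alpha at 200 runs, allowing mild non-normality
        assert rejections / runs <= 0.12


class TestPearson:
    def test_perfect_positive(self):
        r, _ = cs.pearson_weight_abundance([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        r, _ = cs.pearson_weight_abundance([1, 2, 3, 4], [8, 6, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_matches_hand_computed_r(self):
        w = np.array([80.0, 100.0, 120.0, 160.0, 185.0])
        a = np.array([10.0, 2.7, 6.0, 1.3, 6.7])
        r, p = cs.pearson_weight_abundance(w, a)
        wc, ac = w - w.mean(), a - a.mean()
        hand_r = (wc @ ac) / np.sqrt((wc @ wc) * (ac @ ac))
        assert r == pytest.approx(hand_r)
        assert 0.0 <= p <= 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            cs.pearson_weight_abundance([1, 1, 1], [1, 2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            cs.pearson_weight_abundance([1, 2], [1, 2, 3])
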