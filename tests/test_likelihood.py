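"""Scenario likelihoods, per-variant LRs and case combination."""

import math

import pytest

from twinlr import (
    CaseResult,
    PosteriorBeta,
    ReadCount,
    ScenarioConfig,
    VariantObservation,
    combine_case,
    is_discriminating,
    variant_likelihood,
    variant_lr,
)

SPERM = ScenarioConfig(scenario="sperm")
PATERNITY = ScenarioConfig(scenario="paternity")


def obs(vid, chrom, vA, wA, vB, wB, detected=True):
    return VariantObservation(vid, chrom, ReadCount(vA, wA), ReadCount(vB, wB), detected)


class TestVariantLikelihood:
    @pytest.mark.parametrize(
        "config, alpha, beta, expected, tol",
        [
            (SPERM, 0.5, 115.0, 6.01e-4, 5e-7),  # casework table
            (SPERM, 1.5, 80.0, 0.0414, 5e-5),  # casework table
            (PATERNITY, 1.5, 115.0, 0.01288, 5e-6),  # casework table
        ],
    )
    def test_detected_variant(self, config, alpha, beta, expected, tol):
        lik = variant_likelihood(PosteriorBeta(alpha, beta), config, detected=True)
        assert lik == pytest.approx(expected, abs=tol)

    def test_absent_variant_is_complement(self):
        post = PosteriorBeta(1.5, 80.0)
        detected = variant_likelihood(post, SPERM, detected=True)
        absent = variant_likelihood(post, SPERM, detected=False)
        assert detected + absent == pytest.approx(1.0, abs=1e-15)


class TestVariantLR:
    def test_headline_paternity_ratio(self):
        assert round(variant_lr(0.4372, 4.33e-3)) == 101

    def test_headline_sperm_odds(self):
        assert round(1 / variant_lr(0.0414, 0.9999)) == 24

    def test_equal_likelihoods_are_neutral(self):
        assert variant_lr(0.123, 0.123) == 1.0

    def test_zero_denominator_rejected_with_guidance(self):
        with pytest.raises(ValueError, match="beta model never yields 0"):
            variant_lr(0.5, 0.0)


class TestCombineCase:
    def test_single_variant_sperm_case(self):
        # carrier twin: v=25/w=50; other twin: v=0 with posterior Beta(0.5, 80)
        result = combine_case([obs("v1", "7", 25, 50, 0, 65)], SPERM)
        (variant,) = result.per_variant
        assert variant.lik_A > 0.9999
        assert variant.lik_B == pytest.approx(4.23e-3, abs=5e-6)
        assert result.combined_lr == pytest.approx(variant.lik_A / variant.lik_B)
        assert result.posterior_odds == result.combined_lr  # equal prior odds
        assert result.warnings == []

    def test_product_rule_for_identical_independent_variants(self):
        single = combine_case([obs("v1", "1", 25, 50, 0, 65)], SPERM).combined_lr
        double = combine_case(
            [obs("v1", "1", 25, 50, 0, 65), obs("v2", "2", 25, 50, 0, 65)], SPERM
        ).combined_lr
        assert double == pytest.approx(single**2, rel=1e-12)

    def test_combined_lr_equals_independent_remultiplication(self):
        observations = [
            obs("v1", "1", 25, 50, 0, 75),
            obs("v2", "2", 50, 50, 1, 75),
            obs("v3", "3", 25, 75, 1, 100),
        ]
        result = combine_case(observations, PATERNITY)
        manual = 1.0
        for o in observations:
            manual *= combine_case([o], PATERNITY).combined_lr
        assert result.combined_lr == pytest.approx(manual, rel=1e-12)
        assert result.combined_lr == pytest.approx(
            math.prod(v.lr for v in result.per_variant), rel=1e-9
        )

    def test_permutation_invariance(self):
        observations = [
            obs("v1", "1", 25, 50, 0, 75),
            obs("v2", "2", 50, 75, 1, 100),
            obs("v3", "3", 40, 60, 0, 90),
        ]
        forward = combine_case(observations, SPERM).combined_lr
        reverse = combine_case(observations[::-1], SPERM).combined_lr
        assert forward == pytest.approx(reverse, rel=1e-12)

    def test_twin_label_swap_inverts_lr(self):
        observations = [obs("v1", "1", 25, 50, 0, 75), obs("v2", "2", 50, 50, 1, 100)]
        forward = combine_case(observations, SPERM)
        swapped = combine_case([o.swapped() for o in observations], SPERM)
        assert swapped.combined_lr == pytest.approx(1.0 / forward.combined_lr, rel=1e-9)

    def test_neutral_variant_leaves_lr_unchanged(self):
        base = combine_case([obs("v1", "1", 25, 50, 0, 75)], SPERM).combined_lr
        padded = combine_case(
            [obs("v1", "1", 25, 50, 0, 75), obs("v2", "2", 30, 70, 30, 70)], SPERM
        ).combined_lr
        assert padded == base  # identical reads in both twins => lr exactly 1

    def test_shared_chromosome_warning(self):
        result = combine_case(
            [obs("v1", "4", 25, 50, 0, 75), obs("v2", "4", 50, 50, 1, 100)], SPERM
        )
        assert any("share chromosome" in w for w in result.warnings)
        assert result.combined_lr > 1  # still multiplied, only warned

    def test_undetected_variant_excluded_by_default(self):
        informative = combine_case([obs("v1", "1", 25, 50, 0, 75)], SPERM)
        with_absent = combine_case(
            [obs("v1", "1", 25, 50, 0, 75), obs("v2", "2", 30, 70, 0, 80, detected=False)],
            SPERM,
        )
        assert with_absent.combined_lr == pytest.approx(informative.combined_lr)
        assert any("not informative" in w for w in with_absent.warnings)
        absent_entry = with_absent.per_variant[1]
        assert not absent_entry.informative and absent_entry.lr == 1.0

    def test_use_absence_scores_complement(self):
        config = ScenarioConfig(scenario="sperm", use_absence=True)
        result = combine_case([obs("v1", "1", 30, 70, 0, 80, detected=False)], config)
        (variant,) = result.per_variant
        post_A = PosteriorBeta(0.5 + 30, 15.0 + 70)
        assert variant.lik_A == pytest.approx(
            1.0 - variant_likelihood(post_A, config, detected=True)
        )

    def test_empty_case_rejected(self):
        with pytest.raises(ValueError):
            combine_case([], SPERM)

    def test_carrier_likelihood_approaches_one_with_depth(self):
        # v/(v+w) fixed at 1/3, well above the 5% threshold
        liks = [
            combine_case([obs("v1", "1", n, 2 * n, 0, 75)], SPERM).per_variant[0].lik_A
            for n in (5, 25, 125, 625)
        ]
        assert all(a <= b for a, b in zip(liks, liks[1:]))  # ties only at float saturation
        assert liks[-1] > 1 - 1e-9

    def test_noncarrier_likelihood_decreases_with_wildtype_depth(self):
        liks = [
            combine_case([obs("v1", "1", 25, 50, 1, w)], SPERM).per_variant[0].lik_B
            for w in (50, 100, 200, 400)
        ]
        assert all(a > b for a, b in zip(liks, liks[1:]))


class TestConfigValidation:
    def test_bad_scenario(self):
        with pytest.raises(ValueError):
            ScenarioConfig(scenario="mixture")

    def test_bad_threshold_and_odds(self):
        with pytest.raises(ValueError):
            ScenarioConfig(detection_threshold=0.0)
        with pytest.raises(ValueError):
            ScenarioConfig(prior_odds=-1.0)

    def test_discriminating_classification(self):
        assert is_discriminating(obs("v1", "1", 25, 50, 1, 75))
        assert not is_discriminating(obs("v1", "1", 25, 50, 9, 75))
        assert not is_discriminating(obs("v1", "1", 25, 50, 0, 75, detected=False))
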