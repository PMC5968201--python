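"""Exact rank-sum testing, Bonferroni alphas and the three-way conjunction rule."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from combiscreen import (
    ArmSet,
    ExperimentDesign,
    MissingArmError,
    ValidationError,
    bonferroni_alpha,
    call_interaction,
    call_single_mirna_effect,
    rank_sum_p,
    run_interaction_family,
)
from combiscreen.plate_data import Assay, ViabilityRecord

from _rank_oracle import brute_force_p


class TestRankSumP:
    def test_fully_separated_three_vs_three(self):
        """x={1,2,3}, y={4,5,6}: one-sided 1/20, two-sided 0.1."""
        assert rank_sum_p([1, 2, 3], [4, 5, 6], "less") == pytest.approx(1 / 20)
        assert rank_sum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        assert rank_sum_p([1, 2, 5], [1, 2, 5]) == 1.0

    def test_empty_or_tiny_group_rejected(self):
        with pytest.raises(ValidationError):
            rank_sum_p([], [1, 2])
        with pytest.raises(ValidationError):
            rank_sum_p([1, 2], [3])

    @given(
        st.lists(st.integers(0, 5), min_size=2, max_size=5),
        st.lists(st.integers(0, 5), min_size=2, max_size=5),
    )
    def test_two_sided_symmetry(self, x, y):
        assert rank_sum_p(x, y) == pytest.approx(rank_sum_p(y, x))

    def test_exact_path_matches_scipy_on_untied_data(self, rng):
        """scipy's exact Mann-Whitney is an independent oracle when there are no ties."""
        for n, m in [(2, 2), (3, 4), (5, 5), (6, 6), (4, 8)]:
            x = rng.normal(size=n)
            y = rng.normal(0.5, size=m)
            for alt_ours, alt_scipy in [("less", "less"), ("greater", "greater"), ("two_sided", "two-sided")]:
                expected = mannwhitneyu(x, y, alternative=alt_scipy, method="exact").pvalue
                assert rank_sum_p(x, y, alt_ours) == pytest.approx(float(expected), abs=1e-12)

    def test_exact_path_matches_brute_force_with_ties(self, rng):
        for n, m in [(2, 3), (4, 4), (3, 6)]:
            x = list(rng.integers(0, 3, n).astype(float))
            y = list(rng.integers(0, 3, m).astype(float))
            for alt in ("less", "greater", "two_sided"):
                assert rank_sum_p(x, y, alt) == pytest.approx(brute_force_p(x, y, alt), abs=1e-12)

    def test_approximate_path_used_above_enumeration_cutoff(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(0.8, size=30)
        p = rank_sum_p(x, y)
        expected = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert 0 < p <= 1 and p == pytest.approx(float(expected), rel=1e-6)


class TestBonferroniAlpha:
    @pytest.mark.parametrize(
        "n,printed", [(10, 0.005), (7, 0.007), (3, 0.017), (2, 0.025), (1, 0.05)]
    )
    def test_printed_family_thresholds(self, n, printed):
        assert round(bonferroni_alpha(n), 3) == pytest.approx(printed)

    def test_full_precision_kept(self):
        assert bonferroni_alpha(7) == pytest.approx(0.05 / 7, rel=1e-15)

    def test_invalid_count_rejected(self):
        with pytest.raises(ValidationError):
            bonferroni_alpha(0)


def arm_set(untreated, mirna_only, drug_only, combination):
    return ArmSet("MCF7", "miR-126", "LEE011", tuple(untreated), tuple(mirna_only), tuple(drug_only), tuple(combination))


class TestCallInteraction:
    def test_identical_arms_yield_no_interaction(self):
        arm = (50.0, 51.0, 49.0, 50.0)
        call = call_interaction(arm_set(arm, arm, arm, arm), alpha=0.05)
        assert call.p_untreated_vs_comb == 1.0
        assert not call.is_true_interaction

    def test_fully_separated_arms_hit_exact_floor(self):
        """Complete separation at n=6 gives the minimum two-sided p 2/924 < 0.005."""
        call = call_interaction(
            arm_set(
                [100, 101, 99, 100, 102, 98],
                [80, 82, 79, 81, 80, 83],
                [70, 72, 71, 69, 70, 73],
                [40, 42, 41, 39, 40, 43],
            ),
            alpha=0.005,
        )
        for p in (call.p_mirna_vs_comb, call.p_drug_vs_comb, call.p_untreated_vs_comb):
            assert p == pytest.approx(2 / 924)
        assert call.direction_ok and call.is_true_interaction

    def test_direction_check_blocks_antagonism(self):
        """Combination below the drug arm but above the miRNA arm is not an interaction."""
        call = call_interaction(
            arm_set(
                [100, 101, 99, 100, 102, 98],
                [30, 32, 29, 31, 30, 33],
                [70, 72, 71, 69, 70, 73],
                [50, 52, 51, 49, 50, 53],
            ),
            alpha=0.05,
        )
        assert not call.direction_ok
        assert not call.is_true_interaction

    def test_conjunction_monotone_in_alpha(self):
        arms = arm_set(
            [100, 101, 99, 100, 102, 98],
            [80, 82, 79, 81, 80, 83],
            [70, 72, 71, 69, 70, 73],
            [40, 42, 41, 39, 40, 43],
        )
        for alpha_big, alpha_small in [(0.05, 0.005), (0.005, 0.001), (0.0025, 0.002)]:
            big = call_interaction(arms, alpha_big).is_true_interaction
            small = call_interaction(arms, alpha_small).is_true_interaction
            assert big or not small  # shrinking alpha never creates an interaction


class TestSingleMirnaEffect:
    def test_identical_arms_not_significant(self):
        p, sig = call_single_mirna_effect([1, 2, 3], [1, 2, 3], alpha=0.017)
        assert p == 1.0 and not sig

    def test_separated_six_vs_six_significant(self):
        p, sig = call_single_mirna_effect(
            [100, 101, 99, 100, 102, 98], [80, 82, 79, 81, 80, 83], alpha=0.017
        )
        assert p == pytest.approx(2 / 924) and sig

    def test_small_n_floor_blocks_significance(self):
        """At 2 vs 2 the smallest two-sided p is 2/6; no alpha below that can pass."""
        p, sig = call_single_mirna_effect([100, 101], [40, 41], alpha=0.017)
        assert p == pytest.approx(1 / 3) and not sig


def family_records(effects, wells_per_arm=6, seed=0, cell_line="MCF7"):
    """Build alamarBlue well records for a full (mirnas x drugs) family."""
    rng = np.random.default_rng(seed)
    records = []
    for (mirna, drug), effect in effects.items():
        for w in range(wells_per_arm):
            records.append(
                ViabilityRecord(
                    cell_line,
                    mirna,
                    drug,
                    1e-6 if drug else 0.0,
                    w // 2 + 1,
                    w % 2 + 1,
                    Assay.ALAMAR,
                    float(100 * effect * rng.lognormal(0, 0.05)),
                )
            )
    return records


class TestRunInteractionFamily:
    def design(self, n_drugs=2):
        return ExperimentDesign("MCF7", ("miR-126",), tuple(f"drug-{i}" for i in range(n_drugs)))

    def effects(self, n_drugs=2, combo=0.4):
        eff = {(None, None): 1.0, ("miR-126", None): 0.8}
        for i in range(n_drugs):
            eff[(None, f"drug-{i}")] = 0.8
            eff[("miR-126", f"drug-{i}")] = combo
        return eff

    def test_family_alpha_follows_drug_count(self):
        result = run_interaction_family(family_records(self.effects(2)), self.design(2))
        assert result.alpha_interaction == pytest.approx(0.025)
        assert np.allclose(result.interactions["alpha"], 0.025)
        assert result.alpha_single == pytest.approx(0.05)

    def test_planted_interactions_detected(self):
        result = run_interaction_family(family_records(self.effects(2)), self.design(2))
        assert result.interactions["is_true_interaction"].all()
        assert result.single_effects["significant"].all()

    def test_missing_arm_names_the_triple(self):
        effects = self.effects(2)
        del effects[("miR-126", "drug-1")]
        with pytest.raises(MissingArmError, match="drug-1"):
            run_interaction_family(family_records(effects), self.design(2))
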