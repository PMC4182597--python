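"""Net-arrow aggregation, the category-transition rule, and cohort summaries."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from shorebird_risk.assessment import (
    assess_all,
    category_distribution,
    concordance_r2,
    delta_histogram,
    factor_response_summary,
    net_arrows,
    revise_category,
    total_score,
)
from shorebird_risk.errors import ParameterError, ValidationError
from shorebird_risk.factor_model import FactorKind, level_from_arrows, score_to_arrows
from shorebird_risk.species_table import RiskCategory, SpeciesProfile


def _profile(arrows_by_kind, current=3):
    levels = {k: level_from_arrows(k, a) for k, a in zip(FactorKind, arrows_by_kind)}
    return SpeciesProfile(
        common_name="T", scientific_name=None, population_tag=None,
        current_category=current, levels=levels,
    )


def _by_name(profiles, name, tag=None):
    return next(p for p in profiles if p.key == (name, tag))


class TestNetArrows:
    @pytest.mark.parametrize(
        "name, expected",
        [("Semipalmated Sandpiper", 10), ("Bar-tailed Godwit", 11), ("Killdeer", 0)],
    )
    def test_published_row_sums(self, packaged_profiles, name, expected):
        assert net_arrows(_by_name(packaged_profiles, name)) == expected

    def test_up_and_down_arrows_cancel(self):
        # one up and one down arrow net to zero
        assert net_arrows(_profile([1, -1, 0, 0, 0, 0])) == 0

    def test_equals_sum_of_score_derived_arrows(self, packaged_profiles):
        for p in packaged_profiles:
            derived = sum(
                score_to_arrows(k, p.levels[k].score) for k in FactorKind
            )
            assert net_arrows(p) == derived


class TestTotalScore:
    def test_worked_example_narrative_scores_sum_to_24(self):
        # per-factor scores 3,5,3,5,4,4 (breeding..specialization)
        assert total_score([3, 5, 3, 5, 4, 4]) == 24

    def test_minimum_risk_and_maximum(self):
        # lowest legal row: neutral habitats/synchronicity/specialization, rank-1 distance
        assert total_score([0, 0, 0, 0, 1, 0]) == 1
        assert total_score([5, 5, 5, 5, 5, 5]) == 30

    def test_illegal_explicit_score_rejected(self):
        with pytest.raises(ValidationError):
            total_score([4, 0, 0, 0, 1, 0])  # 4 is not a breeding-habitat score


class TestReviseCategory:
    @pytest.mark.parametrize(
        "current, net, threshold, expected",
        [
            (3, 10, 4, 5),   # two full steps
            (5, 8, 4, 6),    # capped at Critical
            (4, 3, 4, 4),    # below threshold: unchanged
            (2, -8, 4, 1),   # downward revision, clamped at the bottom
            (3, 7, 7, 4),    # exactly one threshold
            (3, -3, 3, 2),   # downward single step
        ],
    )
    def test_transition_rule(self, current, net, threshold, expected):
        assert revise_category(current, net, threshold) == RiskCategory(expected)

    @pytest.mark.parametrize("bad", [0, -1, 0.5, "4"])
    def test_threshold_must_be_positive_integer(self, bad):
        with pytest.raises(ParameterError):
            revise_category(3, 4, bad)

    def test_clamped_to_scale_over_exhaustive_grid(self):
        for current in range(1, 7):
            for net in range(-12, 13):
                for threshold in range(1, 13):
                    revised = revise_category(current, net, threshold)
                    assert 1 <= int(revised) <= 6

    @given(
        current=st.integers(1, 6),
        threshold=st.integers(1, 12),
        net_a=st.integers(-12, 12),
        net_b=st.integers(-12, 12),
    )
    def test_monotone_in_net(self, current, threshold, net_a, net_b):
        lo, hi = sorted((net_a, net_b))
        assert revise_category(current, lo, threshold) <= revise_category(
            current, hi, threshold
        )

    @given(
        current=st.integers(1, 6),
        net=st.integers(0, 12),
        t_a=st.integers(1, 12),
        t_b=st.integers(1, 12),
    )
    def test_monotone_in_threshold_for_upward_nets(self, current, net, t_a, t_b):
        lo, hi = sorted((t_a, t_b))
        assert revise_category(current, net, hi) <= revise_category(current, net, lo)


class TestAssessAll:
    def test_reproduces_published_revised_column(self, packaged_profiles, packaged_reference):
        results = assess_all(packaged_profiles, 4)
        matches = sum(
            int(r.revised_category) == int(pub)
            for r, pub in zip(results, packaged_reference.published_revised)
        )
        assert matches == 52

    def test_order_preserving_and_delta_consistent(self, packaged_profiles):
        results = assess_all(packaged_profiles, 4)
        assert [r.common_name for r in results] == [p.common_name for p in packaged_profiles]
        for r in results:
            assert r.delta == int(r.revised_category) - int(r.current_category)

    def test_empty_input(self):
        assert assess_all([], 4) == []

    def test_threshold_above_max_net_changes_nothing(self, packaged_profiles):
        assert all(r.delta == 0 for r in assess_all(packaged_profiles, 12))


class TestCohortSummaries:
    def test_delta_histogram_45_taxa_increase(self, packaged_profiles):
        hist = delta_histogram(assess_all(packaged_profiles, 4))
        assert hist == {0: 7, 1: 33, 2: 12}

    def test_delta_histogram_degenerate_inputs(self):
        assert delta_histogram([]) == {}
        assert delta_histogram(assess_all([_profile([0] * 6)], 4)) == {0: 1}

    def test_factor_response_counts(self, packaged_profiles):
        summary = factor_response_summary(packaged_profiles)
        assert summary[FactorKind.BREEDING_HABITAT].increased == 38
        assert summary[FactorKind.WINTERING_HABITAT].increased == 36
        assert summary[FactorKind.MIGRATION_HABITAT].increased == 34
        assert summary[FactorKind.BREEDING_HABITAT].maximal == 24
        assert summary[FactorKind.WINTERING_HABITAT].maximal == 19
        assert summary[FactorKind.MIGRATION_HABITAT].maximal == 16
        for resp in summary.values():
            assert resp.increased + resp.none_or_positive == 52

    def test_factor_response_all_zero_cohort(self):
        profiles = [_profile([0] * 6) for _ in range(4)]
        for resp in factor_response_summary(profiles).values():
            assert (resp.increased, resp.none_or_positive) == (0, 4)

    def test_current_category_distribution(self, packaged_profiles):
        dist = category_distribution(p.current_category for p in packaged_profiles)
        assert dist.as_dict() == {1: 0, 2: 7, 3: 16, 4: 23, 5: 6, 6: 0}
        assert dist.total == 52

    def test_43_taxa_revised_to_high_concern_or_above(self, packaged_profiles):
        dist = category_distribution(
            r.revised_category for r in assess_all(packaged_profiles, 4)
        )
        assert dist.at_or_above(4) == 43

    def test_histogram_and_distribution_conserve_counts(self, packaged_profiles):
        results = assess_all(packaged_profiles, 4)
        assert sum(delta_histogram(results).values()) == 52
        assert category_distribution(r.revised_category for r in results).total == 52


class TestConcordance:
    def test_perfect_linearity(self):
        x = [0.0, 1.0, 2.0, 3.0]
        y = [2 * v + 1 for v in x]
        assert concordance_r2(x, y) == pytest.approx(1.0)

    def test_hand_computed_case(self):
        # r = cov/sd_x sd_y = 0.866..., r^2 = 3/4
        assert concordance_r2([0, 1, 2], [0, 0, 3]) == pytest.approx(0.75)

    def test_zero_variance_rejected(self):
        with pytest.raises(ParameterError, match="variance"):
            concordance_r2([1, 1, 1], [0, 1, 2])

    def test_too_short_rejected(self):
        with pytest.raises(ParameterError):
            concordance_r2([0, 1], [1, 0])

    def test_packaged_external_concordance_is_loose(self, packaged_profiles):
        # external State of the Birds scores agree only loosely with net arrows
        x = [p.external_score for p in packaged_profiles]
        y = [net_arrows(p) for p in packaged_profiles]
        r2 = concordance_r2(x, y)
        assert 0.0 < r2 < 0.6
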