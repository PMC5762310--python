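"""Filter cascade: stage semantics, funnel accounting, invariants."""

import pytest

from exoburden.filtration import (
    apply_consequence_filter,
    apply_dp_gq_filter,
    apply_site_filter,
    run_filtration,
)
from exoburden.types import CohortDesign, Consequence, FunctionalClass, SiteFilter

from conftest import exonic_site, make_matrix


def single_carrier_setup(depth, quality, dosage=1):
    sites = [exonic_site(100)]
    gm = make_matrix(
        ["CASE1", "CTRL1"],
        [sites[0].key],
        [[dosage], [0]],
        [[depth], [50]],
        [[quality], [90]],
    )
    design = CohortDesign(frozenset({"CASE1"}), frozenset({"CTRL1"}))
    return sites, gm, design


class TestSiteFilter:
    def test_keeps_exactly_pass_sites(self):
        sites = [
            exonic_site(1, site_filter=SiteFilter.PASS),
            exonic_site(2, site_filter=SiteFilter.TRANCHE_FAIL),
            exonic_site(3, site_filter=SiteFilter.OTHER_FAIL),
        ]
        assert [s.key.pos for s in apply_site_filter(sites)] == [1]

    def test_all_pass_input_is_identity(self):
        sites = [exonic_site(p) for p in (1, 2, 3)]
        assert apply_site_filter(sites) == sites


class TestDpGqFilter:
    @pytest.mark.parametrize(
        "depth,quality,kept",
        [
            (9, 30, False),   # DP below 10 drops the only carrier's support
            (10, 20, True),   # thresholds inclusive on the keep side
            (10, 19, False),
            (50, 90, True),
        ],
    )
    def test_supported_carrier_thresholds(self, depth, quality, kept):
        sites, gm, design = single_carrier_setup(depth, quality)
        out = apply_dp_gq_filter(sites, gm, design)
        assert (len(out) == 1) is kept

    def test_non_carrier_support_does_not_rescue_a_site(self):
        # the only well-supported genotype is homozygous reference
        sites, gm, design = single_carrier_setup(5, 5)
        assert apply_dp_gq_filter(sites, gm, design) == []

    def test_missing_carrier_genotype_gives_no_support(self):
        sites, gm, design = single_carrier_setup(50, 90, dosage=-1)
        assert apply_dp_gq_filter(sites, gm, design) == []

    def test_site_mean_mode_uses_cohort_averages(self):
        sites = [exonic_site(100)]
        gm = make_matrix(
            ["CASE1", "CTRL1"], [sites[0].key], [[1], [0]], [[4], [4]], [[90], [90]]
        )
        design = CohortDesign(frozenset({"CASE1"}), frozenset({"CTRL1"}))
        assert apply_dp_gq_filter(sites, gm, design, mode="site_mean") == []
        gm2 = make_matrix(
            ["CASE1", "CTRL1"], [sites[0].key], [[1], [0]], [[4], [40]], [[90], [90]]
        )
        assert len(apply_dp_gq_filter(sites, gm2, design, mode="site_mean")) == 1

    def test_relaxing_thresholds_never_shrinks_the_retained_set(self, filtration_fixture):
        sites, gm, design, _, _ = filtration_fixture
        strict = {s.key for s in apply_dp_gq_filter(sites, gm, design, 10, 20)}
        for min_dp, min_gq in [(0, 20), (10, 0), (0, 0), (5, 10)]:
            relaxed = {s.key for s in apply_dp_gq_filter(sites, gm, design, min_dp, min_gq)}
            assert strict <= relaxed


class TestConsequenceFilter:
    def test_class_rule_applies_before_consequence(self):
        site = exonic_site(1, functional_class=FunctionalClass.INTRONIC)
        assert apply_consequence_filter([site]) == []

    def test_exonic_synonymous_dropped(self):
        site = exonic_site(1, consequence=Consequence.SYNONYMOUS)
        assert apply_consequence_filter([site]) == []

    def test_damaging_consequence_classes_all_retained(self):
        sites = [
            exonic_site(1, consequence=Consequence.STOPGAIN),
            exonic_site(2, consequence=Consequence.STOPLOSS),
            exonic_site(3, consequence=Consequence.FRAMESHIFT_INDEL),
            exonic_site(4, consequence=Consequence.NONFRAMESHIFT_INDEL),
            exonic_site(5, functional_class=FunctionalClass.SPLICING,
                        consequence=Consequence.SPLICING),
        ]
        assert apply_consequence_filter(sites) == sites

    def test_unknown_consequence_within_exonic_is_retained(self):
        site = exonic_site(1, consequence=Consequence.UNKNOWN)
        assert apply_consequence_filter([site]) == [site]


class TestRunFiltration:
    def test_empty_input_gives_zero_counts(self):
        gm = make_matrix(["CASE1", "CTRL1"], [], [[], []])
        design = CohortDesign(frozenset({"CASE1"}), frozenset({"CTRL1"}))
        retained, report = run_filtration([], gm, design)
        assert retained == []
        assert all(c == 0 for c in report.counts.values())

    def test_designed_fixture_survivors_and_reasons(self, filtration_fixture):
        sites, gm, design, expected_retained, expected_reasons = filtration_fixture
        retained, report = run_filtration(sites, gm, design)
        assert {s.key for s in retained} == expected_retained
        assert report.drop_reasons == expected_reasons
        assert report.counts["input"] == 12
        assert report.counts["after_site_filter"] == 10
        assert report.counts["after_dp_gq"] == 7
        assert report.counts["after_functional_class"] == 5
        assert report.counts["after_synonymous_removal"] == 4

    def test_funnel_cross_foots(self, filtration_fixture):
        sites, gm, design, _, _ = filtration_fixture
        retained, report = run_filtration(sites, gm, design)
        assert report.counts["input"] == len(retained) + len(report.drop_reasons)
        report.check_consistency()

    def test_permuting_input_order_preserves_results(self, filtration_fixture):
        sites, gm, design, expected_retained, _ = filtration_fixture
        retained, report = run_filtration(list(reversed(sites)), gm, design)
        assert {s.key for s in retained} == expected_retained
        assert report.counts["after_synonymous_removal"] == 4

    def test_idempotence_on_own_output(self, filtration_fixture):
        sites, gm, design, _, _ = filtration_fixture
        once, _ = run_filtration(sites, gm, design)
        twice, report = run_filtration(once, gm, design)
        assert [s.key for s in twice] == [s.key for s in once]
        assert report.drop_reasons == {}
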