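"""Gene burden collapsing, the enrichment rule, homozygote scan, taxonomy."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from exoburden.burden import (
    Group,
    GeneAlleleSummary,
    Rule,
    STRATUM_COMMON,
    STRATUM_PATHOGENIC,
    STRATUM_RARE,
    assign_groups,
    duration_comparison,
    scan_homozygotes,
    summarize_gene,
    test_gene_enrichment,
)
from exoburden.classify import Basis, DeleteriousCall, FrequencyClass, Novelty
from exoburden.types import CohortDesign, ReferenceAFTable

from conftest import key, make_matrix
from oracles import burden_rule_oracle


def summary(ac_case=0, an_case=116, ac_ctrl=0, an_ctrl=132, ac_panel=0, an_panel=210,
            carriers=0, gene="G"):
    return GeneAlleleSummary(
        gene=gene, ac_cases=ac_case, an_cases=an_case, ac_controls=ac_ctrl,
        an_controls=an_ctrl, ac_panel=ac_panel, an_panel=an_panel,
        carrier_cases=carriers,
    )


def cohort(n_cases, n_controls, dosage_by_site, panel_af=None, panel_size=105):
    """Small cohort: dosage_by_site is {key: [case dosages..., control dosages...]}."""
    sample_ids = [f"CASE{i}" for i in range(n_cases)] + [f"CTRL{i}" for i in range(n_controls)]
    keys = list(dosage_by_site)
    dosage = np.array([dosage_by_site[k] for k in keys]).T
    gm = make_matrix(sample_ids, keys, dosage)
    design = CohortDesign(
        frozenset(sample_ids[:n_cases]), frozenset(sample_ids[n_cases:])
    )
    ref = ReferenceAFTable(af=panel_af or {}, panel_size=panel_size)
    return gm, design, ref


class TestSummarizeGene:
    def test_het_cases_sum_to_allele_count(self):
        # 4 het cases among 58, no missing: AC=4, AN=116
        dosages = [1] * 4 + [0] * 54 + [0] * 66
        gm, design, ref = cohort(58, 66, {key(100): dosages})
        s = summarize_gene("G", [key(100)], gm, design, ref)
        assert (s.ac_cases, s.an_cases) == (4, 116)
        assert s.af_cases == pytest.approx(4 / 116)
        assert s.carrier_cases == 4

    def test_homozygote_counts_two_alleles_one_carrier(self):
        dosages = [2] + [0] * 57 + [0] * 66
        gm, design, ref = cohort(58, 66, {key(100): dosages})
        s = summarize_gene("G", [key(100)], gm, design, ref)
        assert s.ac_cases == 2
        assert s.carrier_cases == 1

    def test_carrier_at_two_variants_counted_once(self):
        d1 = [1] + [0] * 57 + [0] * 66
        gm, design, ref = cohort(58, 66, {key(100): d1, key(200): list(d1)})
        s = summarize_gene("G", [key(100), key(200)], gm, design, ref)
        assert s.ac_cases == 2
        assert s.carrier_cases == 1

    def test_missing_genotypes_contribute_neither_ac_nor_an(self):
        dosages = [1, -1] + [0] * 56 + [0] * 66
        gm, design, ref = cohort(58, 66, {key(100): dosages})
        s = summarize_gene("G", [key(100)], gm, design, ref)
        assert (s.ac_cases, s.an_cases) == (1, 114)

    def test_panel_counts_emulated_from_per_variant_frequencies(self):
        gm, design, ref = cohort(
            2, 2, {key(100): [0, 0, 0, 0], key(200): [0, 0, 0, 0]},
            panel_af={key(100): 0.01, key(200): 0.02}, panel_size=105,
        )
        s = summarize_gene("G", [key(100), key(200)], gm, design, ref)
        # round(0.01*210)=2, round(0.02*210)=4; AN = 210 per variant
        assert (s.ac_panel, s.an_panel) == (6, 420)

    def test_gene_without_qualifying_variants_is_a_contract_violation(self):
        gm, design, ref = cohort(1, 1, {key(100): [0, 0]})
        with pytest.raises(ValueError):
            summarize_gene("G", [], gm, design, ref)


class TestEnrichmentRule:
    def test_three_carriers_and_zero_control_frequency_fires_zero_af_rule(self):
        # the SAA1 pattern: found in 3 cases, absent from both control groups
        res = test_gene_enrichment(summary(ac_case=3, carriers=3))
        assert res.enriched and res.rule == Rule.ZERO_AF

    def test_ratio_must_exceed_threshold_against_both_control_groups(self):
        res = test_gene_enrichment(
            summary(ac_case=7, an_case=116, ac_ctrl=4, an_ctrl=132,
                    ac_panel=11, an_panel=210, carriers=7)
        )
        # ratios 1.99 and 1.15: the panel side fails the 1.5-fold rule
        assert not res.enriched

    def test_two_carriers_below_min_cases_not_enriched(self):
        res = test_gene_enrichment(summary(ac_case=2, carriers=2))
        assert not res.enriched

    def test_mixed_zero_control_side_is_infinite_and_other_side_decides(self):
        res = test_gene_enrichment(
            summary(ac_case=6, an_case=116, ac_ctrl=0, an_ctrl=132,
                    ac_panel=2, an_panel=210, carriers=5)
        )
        assert res.ratio_vs_controls == math.inf
        assert res.enriched and res.rule == Rule.RATIO
        res2 = test_gene_enrichment(
            summary(ac_case=1, an_case=116, ac_ctrl=0, an_ctrl=132,
                    ac_panel=2, an_panel=210, carriers=1)
        )
        assert not res2.enriched  # case/panel ratio below 1.5

    def test_agreement_with_literal_rule_transcription_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(2000):
            ac = rng.integers(0, 11, size=3)
            an = rng.choice([20, 116, 132, 210], size=3)
            carriers = int(rng.integers(0, 6))
            s = summary(ac_case=int(ac[0]), an_case=int(an[0]),
                        ac_ctrl=int(ac[1]), an_ctrl=int(an[1]),
                        ac_panel=int(ac[2]), an_panel=int(an[2]), carriers=carriers)
            expected = burden_rule_oracle(
                int(ac[0]), int(an[0]), int(ac[1]), int(an[1]),
                int(ac[2]), int(an[2]), carriers,
            )
            assert test_gene_enrichment(s).enriched == expected

    @given(
        ac_ctrl=st.integers(0, 10), ac_panel=st.integers(0, 10),
        ac_case=st.integers(0, 9), carriers=st.integers(0, 5),
    )
    def test_increasing_case_alleles_never_flips_enriched_off(
        self, ac_ctrl, ac_panel, ac_case, carriers
    ):
        lo = test_gene_enrichment(
            summary(ac_case=ac_case, ac_ctrl=ac_ctrl, ac_panel=ac_panel,
                    carriers=carriers)
        )
        hi = test_gene_enrichment(
            summary(ac_case=ac_case + 1, ac_ctrl=ac_ctrl, ac_panel=ac_panel,
                    carriers=max(carriers, 1))
        )
        assert hi.enriched or not lo.enriched

    def test_swapping_case_and_control_inverts_finite_ratios(self):
        s = summary(ac_case=6, an_case=116, ac_ctrl=4, an_ctrl=132,
                    ac_panel=3, an_panel=210, carriers=6)
        swapped = summary(ac_case=4, an_case=132, ac_ctrl=6, an_ctrl=116,
                          ac_panel=3, an_panel=210, carriers=4)
        r = test_gene_enrichment(s)
        r_swapped = test_gene_enrichment(swapped)
        assert r_swapped.ratio_vs_controls == pytest.approx(1 / r.ratio_vs_controls)


class TestHomozygoteScan:
    def setup_cohort(self, case_dosages, ctrl_dosages, panel_af=None):
        return cohort(
            len(case_dosages), len(ctrl_dosages),
            {key(100): case_dosages + ctrl_dosages}, panel_af=panel_af,
        )

    def test_case_homozygote_absent_everywhere_else_is_reported(self):
        gm, design, ref = self.setup_cohort([2, 0, 0], [0, 0, 0])
        hits = scan_homozygotes("G", [key(100)], gm, design, ref)
        assert len(hits) == 1
        assert hits[0].case_ids == ["CASE0"]

    def test_control_het_excludes_the_variant(self):
        gm, design, ref = self.setup_cohort([2, 0, 0], [1, 0, 0])
        assert scan_homozygotes("G", [key(100)], gm, design, ref) == []

    def test_het_only_cases_are_not_reported(self):
        gm, design, ref = self.setup_cohort([1, 1, 0], [0, 0, 0])
        assert scan_homozygotes("G", [key(100)], gm, design, ref) == []

    def test_nonzero_panel_frequency_excludes_the_variant(self):
        gm, design, ref = self.setup_cohort([2, 0, 0], [0, 0, 0],
                                            panel_af={key(100): 0.004})
        assert scan_homozygotes("G", [key(100)], gm, design, ref) == []


def call(pos, gene, basis, novelty=Novelty.NOVEL, freq=FrequencyClass.RARE):
    return DeleteriousCall(key=key(pos), gene=gene, basis=basis,
                           novelty=novelty, frequency_class=freq)


def burden_results(enriched_by_stratum):
    """stratum -> {gene: enriched} mapped onto minimal GeneBurdenResult stubs."""
    out = {STRATUM_PATHOGENIC: {}, STRATUM_RARE: {}, STRATUM_COMMON: {}}
    for stratum, genes in enriched_by_stratum.items():
        for gene, flag in genes.items():
            s = summary(ac_case=3, carriers=3, gene=gene)
            res = test_gene_enrichment(s)  # zero-AF enriched template
            res.enriched = flag
            res.rule = Rule.ZERO_AF if flag else Rule.NONE
            out[stratum][gene] = res
    return out


class TestAssignGroups:
    def test_decision_tree_covers_the_six_groups(self):
        calls = [
            call(1, "KG1", Basis.CLINVAR_PATHOGENIC, novelty=Novelty.KNOWN_CANDIDATE),
            call(2, "KG2", Basis.LR_DAMAGING, novelty=Novelty.KNOWN_CANDIDATE),
            call(3, "NG2", Basis.CLINVAR_PATHOGENIC),
            call(4, "NG4", Basis.LR_DAMAGING),
            call(5, "NG5", Basis.LR_DAMAGING),
            call(6, "NG6", Basis.LR_DAMAGING, freq=FrequencyClass.COMMON),
            call(7, "NGX", Basis.NOT_DELETERIOUS, freq=FrequencyClass.UNCLASSIFIED),
        ]
        results = burden_results({
            STRATUM_PATHOGENIC: {"NG2": True},
            STRATUM_RARE: {"NG4": True, "NG5": True},
            STRATUM_COMMON: {"NG6": True},
        })
        from exoburden.burden import HomozygoteHit

        hits = [HomozygoteHit(key=key(5), gene="NG5", case_ids=["CASE0"])]
        groups = {a.key.pos: a.group for a in assign_groups(calls, results, hits)}
        assert groups == {
            1: Group.G1_KNOWN_CLINVAR,
            2: Group.G3_KNOWN_LR,
            3: Group.G2_NOVEL_CLINVAR_BURDEN,
            4: Group.G4_NOVEL_RARE_BURDEN,
            5: Group.G5_NOVEL_RARE_HOMOZYGOUS,
            6: Group.G6_NOVEL_COMMON_BURDEN,
            7: Group.UNASSIGNED,
        }

    def test_homozygote_takes_precedence_over_rare_burden(self):
        calls = [call(5, "NG", Basis.LR_DAMAGING)]
        results = burden_results({STRATUM_RARE: {"NG": True}})
        from exoburden.burden import HomozygoteHit

        hits = [HomozygoteHit(key=key(5), gene="NG", case_ids=["CASE0"])]
        [a] = assign_groups(calls, results, hits)
        assert a.group == Group.G5_NOVEL_RARE_HOMOZYGOUS

    def test_known_candidate_ignores_burden_entirely(self):
        calls = [call(2, "KNOWN", Basis.LR_DAMAGING, novelty=Novelty.KNOWN_CANDIDATE)]
        results = burden_results({STRATUM_RARE: {"KNOWN": False}})
        [a] = assign_groups(calls, results, [])
        assert a.group == Group.G3_KNOWN_LR

    def test_groups_partition_the_deleterious_calls(self, small_bundle):
        from exoburden.pipeline import analyze_cohort

        cc = analyze_cohort(
            small_bundle.sites, small_bundle.genotypes, small_bundle.design,
            small_bundle.ref_af, small_bundle.candidate_genes,
        )
        assert len(cc.assignments) == len(cc.calls)
        novel_groups = {
            Group.G2_NOVEL_CLINVAR_BURDEN, Group.G4_NOVEL_RARE_BURDEN,
            Group.G5_NOVEL_RARE_HOMOZYGOUS, Group.G6_NOVEL_COMMON_BURDEN,
        }
        novelty_by_key = {c.key: c.novelty for c in cc.calls}
        for a in cc.assignments:
            if a.group in novel_groups:
                assert novelty_by_key[a.key] == Novelty.NOVEL


class TestDurationComparison:
    def test_strata_sizes_match_the_design(self, small_bundle):
        long_ids, short_ids = small_bundle.design.duration_strata(3.0, 1.0)
        assert (len(long_ids), len(short_ids)) == (23, 26)

    def test_spiked_duration_gene_appears_only_in_the_unique_set(self, small_bundle):
        duration_genes, unique = duration_comparison(
            small_bundle.sites, small_bundle.genotypes, small_bundle.design,
            small_bundle.ref_af, candidate_genes=small_bundle.candidate_genes,
        )
        dur_spikes = [
            t.gene for t in small_bundle.manifest.spikes
            if t.mechanism == "duration_spike"
        ]
        assert dur_spikes
        for gene in dur_spikes:
            assert gene in duration_genes
            assert gene in unique

    def test_empty_stratum_is_a_configuration_error(self, small_bundle):
        with pytest.raises(ValueError, match="stratum"):
            duration_comparison(
                small_bundle.sites, small_bundle.genotypes, small_bundle.design,
                small_bundle.ref_af, long_years=99.0, short_years=1.0,
            )
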