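"""Gene burden test, homozygote scan, six-group taxonomy, duration comparison.

The burden statistic is a deterministic ratio rule, not a calibrated test:
qualifying deleterious variants are collapsed per gene, aggregate allele
frequencies are computed for cases, sequenced controls and the external
public panel, and a gene is called enriched when

* the case/control allele-frequency ratio exceeds 1.5-fold against BOTH
  control groups (ratio rule), or
* both control groups carry zero alleles and at least 3 distinct case
  samples carry the gene's deleterious alleles (zero-AF rule).

When exactly one control group has zero frequency, that side's ratio is
infinite; the other side decides, and at least one case carrier is required.

All available genotype calls at surviving sites contribute to allele counts,
regardless of their DP or GQ (quality gates discovery, not counting).  The
public panel contributes only per-variant frequencies; its allele counts are
emulated as round(af * 2 * panel_size) per variant so the gene-level panel
frequency stays a proper frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .classify import Basis, DeleteriousCall, FrequencyClass, Novelty
from .types import (
    CohortDesign,
    GenotypeMatrix,
    ReferenceAFTable,
    VariantKey,
)


class Rule(str, Enum):
    RATIO = "ratio_rule"
    ZERO_AF = "zero_af_rule"
    NONE = "none"


class Group(str, Enum):
    G1_KNOWN_CLINVAR = "g1_known_clinvar"
    G2_NOVEL_CLINVAR_BURDEN = "g2_novel_clinvar_burden"
    G3_KNOWN_LR = "g3_known_lr"
    G4_NOVEL_RARE_BURDEN = "g4_novel_rare_burden"
    G5_NOVEL_RARE_HOMOZYGOUS = "g5_novel_rare_homozygous"
    G6_NOVEL_COMMON_BURDEN = "g6_novel_common_burden"
    UNASSIGNED = "unassigned"


#: burden strata, mirroring the branch-then-burden order of the workflow
STRATUM_PATHOGENIC = "pathogenic"
STRATUM_RARE = "rare"
STRATUM_COMMON = "common"
STRATA = (STRATUM_PATHOGENIC, STRATUM_RARE, STRATUM_COMMON)


@dataclass
class GeneAlleleSummary:
    """Aggregated allele counts over one gene's qualifying variants."""

    gene: str
    ac_cases: int
    an_cases: int
    ac_controls: int
    an_controls: int
    ac_panel: int
    an_panel: int
    carrier_cases: int

    def __post_init__(self) -> None:
        for ac, an in ((self.ac_cases, self.an_cases),
                       (self.ac_controls, self.an_controls),
                       (self.ac_panel, self.an_panel)):
            if not (0 <= ac <= an):
                raise ValueError(f"invalid allele counts AC={ac}, AN={an} for {self.gene}")

    @staticmethod
    def _af(ac: int, an: int) -> float:
        return ac / an if an > 0 else 0.0

    @property
    def af_cases(self) -> float:
        return self._af(self.ac_cases, self.an_cases)

    @property
    def af_controls(self) -> float:
        return self._af(self.ac_controls, self.an_controls)

    @property
    def af_panel(self) -> float:
        return self._af(self.ac_panel, self.an_panel)


@dataclass
class GeneBurdenResult:
    gene: str
    summary: GeneAlleleSummary
    ratio_vs_controls: float  # +inf when the control AF is 0
    ratio_vs_panel: float
    rule: Rule
    enriched: bool


@dataclass
class GroupAssignment:
    key: VariantKey
    gene: str
    group: Group


@dataclass
class HomozygoteHit:
    key: VariantKey
    gene: str
    case_ids: list[str]


def summarize_gene(
    gene: str,
    qualifying_variants: list[VariantKey],
    genotypes: GenotypeMatrix,
    design: CohortDesign,
    ref_af_table: ReferenceAFTable,
) -> GeneAlleleSummary:
    """Collapse a gene's qualifying variants into per-group allele counts.

    AC sums dosages over non-missing genotypes; AN counts two alleles per
    non-missing genotype, summed over variants.  A case is a carrier when it
    holds at least one alternate allele anywhere in the gene.
    """
    if not qualifying_variants:
        raise ValueError(f"gene {gene!r} has no qualifying variants")
    cols = genotypes.site_cols(qualifying_variants)
    case_rows = genotypes.sample_rows(design.case_ids)
    ctrl_rows = genotypes.sample_rows(design.control_ids)

    def counts(rows: np.ndarray) -> tuple[int, int]:
        dos = genotypes.dosage[np.ix_(rows, cols)]
        present = dos >= 0
        return int(dos[present].sum()), int(2 * present.sum())

    ac_cases, an_cases = counts(case_rows)
    ac_controls, an_controls = counts(ctrl_rows)

    case_dos = genotypes.dosage[np.ix_(case_rows, cols)]
    carrier_cases = int(((case_dos >= 1).any(axis=1)).sum())

    two_n = 2 * ref_af_table.panel_size
    ac_panel = int(sum(round(ref_af_table.lookup(k) * two_n) for k in qualifying_variants))
    an_panel = two_n * len(qualifying_variants)

    return GeneAlleleSummary(
        gene=gene,
        ac_cases=ac_cases,
        an_cases=an_cases,
        ac_controls=ac_controls,
        an_controls=an_controls,
        ac_panel=ac_panel,
        an_panel=an_panel,
        carrier_cases=carrier_cases,
    )


def _ratio_exceeds(ac_num, an_num, ac_den, an_den, threshold) -> bool:
    """(ac_num/an_num) / (ac_den/an_den) > threshold, exactly on integer counts.

    Cross-multiplied so exact-boundary ratios (e.g. exactly 1.5-fold) never
    flip on floating-point rounding; requires an_num, an_den > 0.
    """
    return ac_num * an_den > threshold * (ac_den * an_num)


def test_gene_enrichment(
    summary: GeneAlleleSummary,
    ratio_threshold: float = 1.5,
    min_cases: int = 3,
) -> GeneBurdenResult:
    """Apply the two-sentence burden rule to one gene summary."""
    afc = summary.af_cases
    af_ctrl = summary.af_controls
    af_panel = summary.af_panel

    ratio_vs_controls = math.inf if af_ctrl == 0 else afc / af_ctrl
    ratio_vs_panel = math.inf if af_panel == 0 else afc / af_panel

    def exceeds_vs_controls() -> bool:
        return _ratio_exceeds(summary.ac_cases, summary.an_cases,
                              summary.ac_controls, summary.an_controls,
                              ratio_threshold)

    def exceeds_vs_panel() -> bool:
        return _ratio_exceeds(summary.ac_cases, summary.an_cases,
                              summary.ac_panel, summary.an_panel,
                              ratio_threshold)

    if af_ctrl == 0 and af_panel == 0:
        rule = Rule.ZERO_AF if summary.carrier_cases >= min_cases else Rule.NONE
    elif af_ctrl > 0 and af_panel > 0:
        rule = Rule.RATIO if exceeds_vs_controls() and exceeds_vs_panel() else Rule.NONE
    else:
        # exactly one control AF is zero: that side is infinitely enriched,
        # the positive side decides, and at least one case carrier is required
        positive = exceeds_vs_controls() if af_ctrl > 0 else exceeds_vs_panel()
        rule = Rule.RATIO if positive and summary.carrier_cases >= 1 else Rule.NONE

    return GeneBurdenResult(
        gene=summary.gene,
        summary=summary,
        ratio_vs_controls=ratio_vs_controls,
        ratio_vs_panel=ratio_vs_panel,
        rule=rule,
        enriched=rule != Rule.NONE,
    )


test_gene_enrichment.__test__ = False  # the name is the operation's, not a pytest test


def scan_homozygotes(
    gene: str,
    rare_novel_variants: list[VariantKey],
    genotypes: GenotypeMatrix,
    design: CohortDesign,
    ref_af_table: ReferenceAFTable,
) -> list[HomozygoteHit]:
    """Rare novel deleterious variants homozygous in a case, absent in all controls."""
    hits = []
    case_rows = genotypes.sample_rows(design.case_ids)
    ctrl_rows = genotypes.sample_rows(design.control_ids)
    case_ids = [genotypes.sample_ids[i] for i in case_rows]
    for key in rare_novel_variants:
        col = genotypes.column(key)
        case_dos = genotypes.dosage[case_rows, col]
        if not (case_dos == 2).any():
            continue
        ctrl_dos = genotypes.dosage[ctrl_rows, col]
        if (ctrl_dos >= 1).any():
            continue
        if ref_af_table.lookup(key) > 0:
            continue
        homozygotes = [sid for sid, d in zip(case_ids, case_dos) if d == 2]
        hits.append(HomozygoteHit(key=key, gene=gene, case_ids=homozygotes))
    return hits


def _stratum_variants(calls: list[DeleteriousCall]) -> dict[str, dict[str, list[VariantKey]]]:
    """Group novel qualifying variant keys by stratum then gene.

    Strata mirror the workflow's branch-then-burden order: the ClinVar-
    pathogenic stratum holds novel "pathogenic" variants of any frequency;
    the rare/common strata hold novel deleterious variants of that frequency
    class (so a rare ClinVar-pathogenic variant qualifies in both the
    pathogenic and the rare stratum).
    """
    strata: dict[str, dict[str, list[VariantKey]]] = {s: {} for s in STRATA}

    def add(stratum: str, call: DeleteriousCall) -> None:
        if call.gene:
            strata[stratum].setdefault(call.gene, []).append(call.key)

    for call in calls:
        if not call.deleterious or call.novelty != Novelty.NOVEL:
            continue
        if call.basis == Basis.CLINVAR_PATHOGENIC:
            add(STRATUM_PATHOGENIC, call)
        if call.frequency_class == FrequencyClass.RARE:
            add(STRATUM_RARE, call)
        elif call.frequency_class == FrequencyClass.COMMON:
            add(STRATUM_COMMON, call)
    return strata


def burden_scan(
    calls: list[DeleteriousCall],
    genotypes: GenotypeMatrix,
    design: CohortDesign,
    ref_af_table: ReferenceAFTable,
    ratio_threshold: float = 1.5,
    min_cases: int = 3,
) -> dict[str, dict[str, GeneBurdenResult]]:
    """Per-stratum, per-gene burden results over all novel deleterious variants."""
    results: dict[str, dict[str, GeneBurdenResult]] = {s: {} for s in STRATA}
    for stratum, by_gene in _stratum_variants(calls).items():
        for gene in sorted(by_gene):
            summary = summarize_gene(gene, by_gene[gene], genotypes, design, ref_af_table)
            results[stratum][gene] = test_gene_enrichment(summary, ratio_threshold, min_cases)
    return results


def homozygote_scan(
    calls: list[DeleteriousCall],
    genotypes: GenotypeMatrix,
    design: CohortDesign,
    ref_af_table: ReferenceAFTable,
) -> list[HomozygoteHit]:
    """Homozygote scan over every gene's rare novel deleterious variants."""
    by_gene: dict[str, list[VariantKey]] = {}
    for call in calls:
        if (
            call.deleterious
            and call.novelty == Novelty.NOVEL
            and call.frequency_class == FrequencyClass.RARE
            and call.gene
        ):
            by_gene.setdefault(call.gene, []).append(call.key)
    hits = []
    for gene in sorted(by_gene):
        hits.extend(scan_homozygotes(gene, by_gene[gene], genotypes, design, ref_af_table))
    return hits


def assign_groups(
    calls: list[DeleteriousCall],
    burden_results: dict[str, dict[str, GeneBurdenResult]],
    homozygote_hits: list[HomozygoteHit],
) -> list[GroupAssignment]:
    """Assign every deleterious variant to exactly one of the six groups.

    Decision tree: known candidates split by ClinVar vs LR basis (groups 1
    and 3); novel ClinVar-pathogenic variants in burden-enriched genes form
    group 2; novel rare variants are group 5 when they are homozygote hits
    (precedence over group 4) and group 4 when their gene is rare-stratum
    enriched; novel common variants in common-stratum enriched genes form
    group 6.  Everything else is unassigned.
    """
    homo_keys = {h.key for h in homozygote_hits}

    def enriched(stratum: str, gene: str) -> bool:
        res = burden_results[stratum].get(gene)
        return res is not None and res.enriched

    assignments = []
    for call in calls:
        if not call.deleterious:
            group = Group.UNASSIGNED
        elif call.novelty == Novelty.KNOWN_CANDIDATE:
            group = (
                Group.G1_KNOWN_CLINVAR
                if call.basis == Basis.CLINVAR_PATHOGENIC
                else Group.G3_KNOWN_LR
            )
        elif call.basis == Basis.CLINVAR_PATHOGENIC and enriched(STRATUM_PATHOGENIC, call.gene):
            group = Group.G2_NOVEL_CLINVAR_BURDEN
        elif call.frequency_class == FrequencyClass.RARE and call.key in homo_keys:
            group = Group.G5_NOVEL_RARE_HOMOZYGOUS
        elif call.frequency_class == FrequencyClass.RARE and enriched(STRATUM_RARE, call.gene):
            group = Group.G4_NOVEL_RARE_BURDEN
        elif call.frequency_class == FrequencyClass.COMMON and enriched(STRATUM_COMMON, call.gene):
            group = Group.G6_NOVEL_COMMON_BURDEN
        else:
            group = Group.UNASSIGNED
        assignments.append(GroupAssignment(key=call.key, gene=call.gene, group=group))
    return assignments


def gene_sets_by_group(assignments: list[GroupAssignment]) -> dict[Group, frozenset[str]]:
    out: dict[Group, set[str]] = {g: set() for g in Group}
    for a in assignments:
        if a.gene:
            out[a.group].add(a.gene)
    return {g: frozenset(s) for g, s in out.items()}


def candidate_gene_union(assignments: list[GroupAssignment]) -> frozenset[str]:
    """Union of the six groups' genes — the run's candidate gene list.

    Includes the known-candidate hits (groups 1/3) alongside the novel burden
    and homozygote groups, matching a headline union over all group tables.
    """
    per_group = gene_sets_by_group(assignments)
    union: set[str] = set()
    for g in Group:
        if g != Group.UNASSIGNED:
            union |= per_group[g]
    return frozenset(union)


def duration_comparison(
    sites,
    genotypes: GenotypeMatrix,
    design: CohortDesign,
    ref_af_table: ReferenceAFTable,
    candidate_genes: frozenset[str] = frozenset(),
    candidate_variants: frozenset[VariantKey] = frozenset(),
    config: dict | None = None,
    long_years: float = 3.0,
    short_years: float = 1.0,
) -> tuple[frozenset[str], frozenset[str]]:
    """Re-run the whole pipeline with long- vs short-duration cases.

    Cases with disease duration >= ``long_years`` play the case role, cases
    with duration <= ``short_years`` play the sequenced-control role; the
    public panel is unchanged.  Returns ``(duration_genes, unique_genes)``
    where ``unique_genes`` are duration genes absent from the case-control
    comparison's gene set.
    """
    from .pipeline import analyze_cohort  # deferred: pipeline imports this module

    long_ids, short_ids = design.duration_strata(long_years, short_years)
    if not long_ids or not short_ids:
        raise ValueError(
            f"empty duration stratum: {len(long_ids)} cases >= {long_years}y, "
            f"{len(short_ids)} cases <= {short_years}y"
        )
    duration_design = CohortDesign(
        case_ids=long_ids,
        control_ids=short_ids,
        duration_years={s: design.duration_years[s] for s in long_ids},
    )
    cc = analyze_cohort(
        sites, genotypes, design, ref_af_table, candidate_genes, candidate_variants, config
    )
    dur = analyze_cohort(
        sites, genotypes, duration_design, ref_af_table, candidate_genes,
        candidate_variants, config,
    )
    duration_genes = dur.gene_union
    unique_genes = frozenset(duration_genes - cc.gene_union)
    return duration_genes, unique_genes
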