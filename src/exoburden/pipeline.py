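"""End-to-end orchestration: filtration, classification, burden, taxonomy,
duration comparison, pathway enrichment, and the run report.

The core entry point is :func:`analyze_cohort`, which turns one annotated
cohort (sites + genotypes + design + reference panel) into a
:class:`CohortAnalysis`; :func:`run_pipeline` wraps it with file I/O, the
duration re-run, enrichment on the candidate gene union and on the
duration-unique genes, and a cross-footed :class:`RunReport`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from . import io as cio
from .burden import (
    Group,
    GroupAssignment,
    HomozygoteHit,
    assign_groups,
    burden_scan,
    candidate_gene_union,
    gene_sets_by_group,
    homozygote_scan,
)
from .classify import DeleteriousCall, classify_variants
from .config import DEFAULTS, load_config
from .enrichment import EnrichmentResult, enrich, results_table
from .filtration import FilterReport, run_filtration, write_filter_report
from .simulate import Bundle, SimConfig, simulate
from .types import (
    CohortDesign,
    GeneSetCollection,
    GenotypeMatrix,
    ReferenceAFTable,
    VariantKey,
    VariantSite,
)

logger = logging.getLogger(__name__)


@dataclass
class CohortAnalysis:
    """Everything one comparison (case-control or duration) produces."""

    preliminary: list[VariantSite]
    filter_report: FilterReport
    calls: list[DeleteriousCall]
    burden: dict[str, dict]  # stratum -> gene -> GeneBurdenResult
    homozygote_hits: list[HomozygoteHit]
    assignments: list[GroupAssignment]
    gene_union: frozenset[str]
    background_genes: frozenset[str]  # genes with >= 1 preliminary variant

    def group_genes(self) -> dict[Group, frozenset[str]]:
        return gene_sets_by_group(self.assignments)

    def group_variant_counts(self) -> dict[Group, int]:
        counts = {g: 0 for g in Group}
        for a in self.assignments:
            counts[a.group] += 1
        return counts


def analyze_cohort(
    sites: list[VariantSite],
    genotypes: GenotypeMatrix,
    design: CohortDesign,
    ref_af: ReferenceAFTable,
    candidate_genes: frozenset[str] = frozenset(),
    candidate_variants: frozenset[VariantKey] = frozenset(),
    config: dict | None = None,
) -> CohortAnalysis:
    """Run filtration -> classification -> burden -> taxonomy for one design."""
    cfg = dict(DEFAULTS)
    if config:
        cfg.update(config)

    preliminary, report = run_filtration(
        sites,
        genotypes,
        design,
        min_dp=cfg["filtration.min_dp"],
        min_gq=cfg["filtration.min_gq"],
        mode=cfg["filtration.mode"],
    )
    calls = classify_variants(
        preliminary,
        ref_af,
        candidate_genes=candidate_genes,
        candidate_variants=candidate_variants,
        rare_maf=cfg["classify.rare_maf"],
        fold_af=cfg["classify.fold_af"],
        novelty_match=cfg["novelty.match"],
    )
    burden = burden_scan(
        calls,
        genotypes,
        design,
        ref_af,
        ratio_threshold=cfg["burden.ratio_threshold"],
        min_cases=cfg["burden.min_cases"],
    )
    hits = homozygote_scan(calls, genotypes, design, ref_af)
    assignments = assign_groups(calls, burden, hits)
    return CohortAnalysis(
        preliminary=preliminary,
        filter_report=report,
        calls=calls,
        burden=burden,
        homozygote_hits=hits,
        assignments=assignments,
        gene_union=candidate_gene_union(assignments),
        background_genes=frozenset(s.gene for s in preliminary if s.gene),
    )


@dataclass
class RunReport:
    """Human-readable summary of one end-to-end run; cross-foots its tables."""

    funnel: dict[str, int]
    group_variant_counts: dict[str, int]
    group_gene_counts: dict[str, int]
    gene_union_count: int
    duration_gene_count: int
    duration_unique_count: int
    enrichment: list[dict]
    duration_enrichment: list[dict]
    homozygote_variants: list[str]
    config: dict
    seed: int | None
    version: str = __version__

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    case_control: CohortAnalysis
    duration: CohortAnalysis | None
    duration_genes: frozenset[str]
    duration_unique: frozenset[str]
    enrichment: list[EnrichmentResult]
    duration_enrichment: list[EnrichmentResult]
    report: RunReport


def _duration_design(design: CohortDesign, long_years: float, short_years: float) -> CohortDesign:
    long_ids, short_ids = design.duration_strata(long_years, short_years)
    if not long_ids or not short_ids:
        raise ValueError(
            f"empty duration stratum: {len(long_ids)} cases >= {long_years}y, "
            f"{len(short_ids)} cases <= {short_years}y"
        )
    return CohortDesign(
        case_ids=long_ids,
        control_ids=short_ids,
        duration_years={s: design.duration_years[s] for s in long_ids},
    )


def run_pipeline(
    sites: list[VariantSite],
    genotypes: GenotypeMatrix,
    design: CohortDesign,
    ref_af: ReferenceAFTable,
    candidate_genes: frozenset[str] = frozenset(),
    gene_sets: GeneSetCollection | None = None,
    config: dict | None = None,
    out_dir=None,
    seed: int | None = None,
) -> PipelineResult:
    """Full analysis: case-control, duration comparison, and enrichment.

    Enrichment runs twice, as in a two-panel pathway table: once on the
    union of the case-control group genes, once on the duration-unique
    genes.  The background universe is every gene carrying at least one
    preliminary variant in the case-control run.  With ``out_dir`` set,
    every intermediate table is persisted alongside ``report.json``.
    """
    cfg = dict(DEFAULTS)
    if config:
        cfg.update(config)
    for key in sorted(cfg):
        logger.info("config %s = %r", key, cfg[key])

    cc = analyze_cohort(sites, genotypes, design, ref_af, candidate_genes, config=cfg)

    duration: CohortAnalysis | None = None
    duration_genes: frozenset[str] = frozenset()
    duration_unique: frozenset[str] = frozenset()
    if design.duration_years:
        dur_design = _duration_design(
            design, cfg["duration.long_years"], cfg["duration.short_years"]
        )
        duration = analyze_cohort(
            sites, genotypes, dur_design, ref_af, candidate_genes, config=cfg
        )
        duration_genes = duration.gene_union
        duration_unique = frozenset(duration_genes - cc.gene_union)

    enrichment: list[EnrichmentResult] = []
    duration_enrichment: list[EnrichmentResult] = []
    if gene_sets is not None and len(gene_sets) and cc.background_genes:
        enrichment = enrich(
            cc.gene_union,
            gene_sets,
            cc.background_genes,
            alpha=cfg["enrich.alpha"],
            statistic=cfg["enrich.statistic"],
            fdr=cfg["enrich.fdr"],
        )
        if duration_unique:
            duration_enrichment = enrich(
                duration_unique,
                gene_sets,
                cc.background_genes,
                alpha=cfg["enrich.alpha"],
                statistic=cfg["enrich.statistic"],
                fdr=cfg["enrich.fdr"],
            )

    group_genes = cc.group_genes()
    report = RunReport(
        funnel=dict(cc.filter_report.counts),
        group_variant_counts={g.value: c for g, c in cc.group_variant_counts().items()},
        group_gene_counts={g.value: len(group_genes[g]) for g in Group},
        gene_union_count=len(cc.gene_union),
        duration_gene_count=len(duration_genes),
        duration_unique_count=len(duration_unique),
        enrichment=results_table(enrichment),
        duration_enrichment=results_table(duration_enrichment),
        homozygote_variants=[str(h.key) for h in cc.homozygote_hits],
        config={k: cfg[k] for k in sorted(cfg)},
        seed=seed,
    )
    _check_report(report, cc)

    result = PipelineResult(
        case_control=cc,
        duration=duration,
        duration_genes=duration_genes,
        duration_unique=duration_unique,
        enrichment=enrichment,
        duration_enrichment=duration_enrichment,
        report=report,
    )
    if out_dir is not None:
        write_results(result, out_dir)
    return result


def _check_report(report: RunReport, cc: CohortAnalysis) -> None:
    """Internal consistency: funnel cross-foots and group counts tile the calls."""
    cc.filter_report.check_consistency()
    n_calls = len(cc.calls)
    n_assigned = sum(report.group_variant_counts.values())
    if n_calls != n_assigned:
        raise AssertionError(
            f"group assignments ({n_assigned}) do not tile the classified "
            f"variants ({n_calls})"
        )


def _burden_rows(analysis: CohortAnalysis):
    for stratum, by_gene in analysis.burden.items():
        for gene, res in sorted(by_gene.items()):
            s = res.summary
            yield {
                "stratum": stratum,
                "gene": gene,
                "ac_cases": s.ac_cases,
                "an_cases": s.an_cases,
                "af_cases": s.af_cases,
                "ac_controls": s.ac_controls,
                "an_controls": s.an_controls,
                "af_controls": s.af_controls,
                "ac_panel": s.ac_panel,
                "an_panel": s.an_panel,
                "af_panel": s.af_panel,
                "carrier_cases": s.carrier_cases,
                "ratio_vs_controls": res.ratio_vs_controls,
                "ratio_vs_panel": res.ratio_vs_panel,
                "rule": res.rule.value,
                "enriched": res.enriched,
            }


def write_results(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cc = result.case_control
    write_filter_report(cc.filter_report, out / "filter_funnel.tsv", out / "filter_reasons.tsv")
    cio.write_table(list(_burden_rows(cc)), out / "gene_burden.tsv")
    cio.write_table(
        [
            {
                "chrom": a.key.chrom,
                "pos": a.key.pos,
                "ref": a.key.ref,
                "alt": a.key.alt,
                "gene": a.gene,
                "group": a.group.value,
            }
            for a in cc.assignments
        ],
        out / "variant_groups.tsv",
    )
    cio.write_table(
        [
            {"chrom": h.key.chrom, "pos": h.key.pos, "ref": h.key.ref, "alt": h.key.alt,
             "gene": h.gene, "case_ids": ",".join(h.case_ids)}
            for h in cc.homozygote_hits
        ],
        out / "homozygotes.tsv",
    )
    cio.write_table(
        [{"gene": g} for g in sorted(result.duration_genes)], out / "duration_genes.tsv"
    )
    cio.write_table(
        [{"gene": g} for g in sorted(result.duration_unique)], out / "duration_unique_genes.tsv"
    )
    cio.write_table(results_table(result.enrichment), out / "enrichment.tsv")
    cio.write_table(results_table(result.duration_enrichment), out / "duration_enrichment.tsv")
    (out / "report.json").write_text(
        json.dumps(result.report.to_dict(), indent=2, sort_keys=True) + "\n"
    )


def run_on_bundle(bundle: Bundle, config: dict | None = None, out_dir=None) -> PipelineResult:
    """Convenience: run the full pipeline on an in-memory simulated bundle."""
    return run_pipeline(
        bundle.sites,
        bundle.genotypes,
        bundle.design,
        bundle.ref_af,
        candidate_genes=bundle.candidate_genes,
        gene_sets=bundle.gene_sets,
        config=config,
        out_dir=out_dir,
        seed=bundle.config.seed,
    )


# ---------------------------------------------------------------------------
# Power study
# ---------------------------------------------------------------------------

def score_recovery(bundle: Bundle, result: PipelineResult) -> dict:
    """Compare a pipeline result against the bundle's truth manifest.

    Returns per-mechanism and overall detection counts, the homozygote
    recovery rate, and the false-call rate on unspiked genes.
    """
    group_genes = {g.value: genes for g, genes in result.case_control.group_genes().items()}
    detected, total = {}, {}
    for truth in bundle.manifest.spikes:
        total[truth.mechanism] = total.get(truth.mechanism, 0) + 1
        if truth.comparison == "duration_unique":
            hit = truth.gene in result.duration_unique
        else:
            hit = truth.gene in group_genes.get(truth.expected_group, frozenset())
        detected[truth.mechanism] = detected.get(truth.mechanism, 0) + int(hit)

    spiked = {t.gene for t in bundle.manifest.spikes}
    enriched_genes = {
        gene
        for by_gene in result.case_control.burden.values()
        for gene, res in by_gene.items()
        if res.enriched
    }
    null_genes = {s.gene for s in bundle.sites if s.gene} - spiked
    false_calls = len(enriched_genes - spiked)
    n_cc = sum(v for m, v in total.items() if m != "duration_spike")
    d_cc = sum(v for m, v in detected.items() if m != "duration_spike")
    return {
        "detected_by_mechanism": detected,
        "total_by_mechanism": total,
        "case_control_detection_rate": d_cc / n_cc if n_cc else float("nan"),
        "false_call_rate": false_calls / len(null_genes) if null_genes else 0.0,
        "n_null_genes": len(null_genes),
        "enriched_gene_fraction": len(enriched_genes) / bundle.config.n_genes,
    }


def run_power_study(
    effect_sizes=(1.0, 2.0, 3.0, 5.0),
    n_seeds: int = 5,
    base_seed: int = 0,
    n_genes: int = 500,
    base_af: float = 0.02,
    n_spikes: int = 5,
    config: dict | None = None,
):
    """Detection and false-call rates of the burden rule across effect sizes.

    For each effect size, ``n_seeds`` cohorts are simulated with
    ``n_spikes`` ratio-spiked genes; the detection rate over spiked genes
    and the false-call rate over null genes are averaged over seeds, with
    Monte-Carlo standard errors (binomial, over all spiked/null genes).
    Effect size 1 is the null: its "spikes" carry no signal.
    """
    import math

    from .simulate import Spike

    rows = []
    for effect in effect_sizes:
        det_num = det_den = 0
        false_num = false_den = 0
        for r in range(n_seeds):
            seed = base_seed + 1000 * r
            spikes = tuple(
                Spike(f"SPKPOW{i}", "ratio_spike", effect=effect, base_af=base_af)
                for i in range(1, n_spikes + 1)
            )
            sim_cfg = SimConfig(n_genes=n_genes, spikes=spikes, seed=seed)
            bundle = simulate(sim_cfg)
            result = run_on_bundle(bundle, config=config)
            score = score_recovery(bundle, result)
            det_num += score["detected_by_mechanism"].get("ratio_spike", 0)
            det_den += score["total_by_mechanism"].get("ratio_spike", 0)
            false_num += round(score["false_call_rate"] * score["n_null_genes"])
            false_den += score["n_null_genes"]
        p_det = det_num / det_den if det_den else float("nan")
        p_false = false_num / false_den if false_den else float("nan")
        rows.append(
            {
                "effect": effect,
                "n_seeds": n_seeds,
                "detection_rate": p_det,
                "detection_se": math.sqrt(max(p_det * (1 - p_det), 0) / det_den)
                if det_den
                else float("nan"),
                "false_call_rate": p_false,
                "false_call_se": math.sqrt(max(p_false * (1 - p_false), 0) / false_den)
                if false_den
                else float("nan"),
            }
        )
    return rows
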