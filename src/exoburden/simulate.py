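"""Synthetic exome cohort generator with known ground truth.

Emulates the study design the pipeline targets: 58 cases, 66 sequenced
controls, an external 105-sample public reference panel, a rare-heavy minor
allele frequency spectrum, annotation labels (consequence class, ClinVar,
LR metapredictor), genotype-quality noise, VQSR tranche failures, and a
configurable list of spiked genes with a truth manifest for recovery
scoring.

Genotypes are unlinked and samples unrelated (the burden rule only uses
marginal counts): under the null every dosage is an independent
binomial(2, af) draw at the variant's true panel frequency.  Spike
mechanisms:

``ratio_spike``
    case allele frequency = effect x base frequency; controls and panel at
    the base frequency.
``zero_af_spike``
    variants absent from sequenced controls and the panel; a fixed number
    of distinct heterozygous case carriers is planted per variant.
``homozygote_spike``
    a single variant absent from controls and panel with one case genotype
    set to dosage 2.
``common_spike``
    as ratio_spike but at a common (>= 2%) base frequency.
``duration_spike``
    long-duration cases at effect x base; short/mid-duration cases and the
    panel at base; sequenced controls at the blended overall-case frequency,
    so the signal shows in the duration comparison but the case-control
    ratio centres on 1 and the gene stays out of the case-control gene set.

Everything is driven by one integer seed; the same seed reproduces the
bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as cio
from .types import (
    MISSING,
    ClinvarStatus,
    CohortDesign,
    Consequence,
    FunctionalClass,
    GeneSet,
    GeneSetCollection,
    GenotypeMatrix,
    LrCall,
    ReferenceAFTable,
    SiteFilter,
    VariantKey,
    VariantSite,
)

MECHANISMS = ("ratio_spike", "zero_af_spike", "homozygote_spike", "common_spike",
              "duration_spike")

SPIKED_PATHWAY = "SPIKED_PATHWAY"


class SimulationConfigError(ValueError):
    """The simulation configuration is infeasible."""


@dataclass(frozen=True)
class Spike:
    gene: str
    mechanism: str
    effect: float = 5.0
    base_af: float = 0.02
    n_variants: int = 4
    clinvar: bool = False  # annotate variants ClinVar-pathogenic instead of LR-damaging
    min_carriers: int = 3  # planted het carriers per variant (zero_af_spike)

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise SimulationConfigError(f"unknown spike mechanism {self.mechanism!r}")
        if self.n_variants < 1:
            raise SimulationConfigError(f"spike {self.gene}: n_variants must be >= 1")


def default_spikes() -> tuple[Spike, ...]:
    """The default spiked-signal panel: five genes per case-control mechanism
    (zero-AF split between LR-damaging and ClinVar-pathogenic annotation so
    both the rare and the ClinVar burden branches are exercised) plus two
    duration-only genes."""
    spikes: list[Spike] = []
    for i in range(1, 6):
        spikes.append(Spike(f"SPKRATIO{i}", "ratio_spike", effect=5.0, base_af=0.02))
    for i in range(1, 6):
        spikes.append(
            Spike(f"SPKZERO{i}", "zero_af_spike", clinvar=(i > 3), min_carriers=3)
        )
    for i in range(1, 6):
        spikes.append(Spike(f"SPKHOMO{i}", "homozygote_spike", n_variants=1))
    for i in range(1, 6):
        spikes.append(Spike(f"SPKCOMMON{i}", "common_spike", effect=5.0, base_af=0.05))
    for i in range(1, 3):
        spikes.append(Spike(f"SPKDUR{i}", "duration_spike", effect=5.0, base_af=0.05))
    return tuple(spikes)


@dataclass
class SimConfig:
    """Study-design defaults: 58 cases / 66 controls / 105-sample panel,
    duration strata 23 long / 26 short / 9 mid."""

    n_cases: int = 58
    n_controls: int = 66
    panel_size: int = 105
    n_genes: int = 2000
    mean_extra_variants_per_gene: float = 2.5  # variants/gene = 1 + Poisson(mean)
    rare_fraction: float = 0.6
    common_af_range: tuple[float, float] = (0.02, 0.4)
    frac_synonymous: float = 0.40
    frac_tranche_fail: float = 0.05
    frac_other_fail: float = 0.01
    frac_low_dp_gq: float = 0.05
    frac_non_exonic: float = 0.10
    frac_clinvar_pathogenic: float = 0.002
    frac_lr_damaging: float = 0.30
    missing_rate: float = 0.02
    n_candidate_genes: int = 15
    n_gene_sets: int = 50
    genes_per_set: int = 20
    n_duration_long: int = 23
    n_duration_short: int = 26
    spikes: tuple[Spike, ...] = field(default_factory=default_spikes)
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "rare_fraction": self.rare_fraction,
            "frac_synonymous": self.frac_synonymous,
            "frac_tranche_fail": self.frac_tranche_fail,
            "frac_other_fail": self.frac_other_fail,
            "frac_low_dp_gq": self.frac_low_dp_gq,
            "frac_non_exonic": self.frac_non_exonic,
            "frac_clinvar_pathogenic": self.frac_clinvar_pathogenic,
            "frac_lr_damaging": self.frac_lr_damaging,
            "missing_rate": self.missing_rate,
        }
        for name, v in fracs.items():
            if not (0.0 <= v <= 1.0):
                raise SimulationConfigError(f"{name} must lie in [0,1], got {v}")
        genes = [s.gene for s in self.spikes]
        if len(genes) != len(set(genes)):
            raise SimulationConfigError("spiked genes must be distinct")
        if len(self.spikes) > self.n_genes:
            raise SimulationConfigError("more spikes than genes")
        if self.n_duration_long + self.n_duration_short > self.n_cases:
            raise SimulationConfigError("duration strata exceed the number of cases")
        for s in self.spikes:
            if s.mechanism == "zero_af_spike" and s.min_carriers > self.n_cases:
                raise SimulationConfigError(
                    f"spike {s.gene}: {s.min_carriers} carriers > {self.n_cases} cases"
                )
            if s.mechanism in ("ratio_spike", "common_spike", "duration_spike"):
                if s.effect * s.base_af > 0.95:
                    raise SimulationConfigError(
                        f"spike {s.gene}: case frequency {s.effect * s.base_af:.3f} "
                        f"is not a valid allele frequency"
                    )


@dataclass
class SpikeTruth:
    gene: str
    mechanism: str
    expected_group: str  # g2/g4/g5/g6
    comparison: str  # "case_control" | "duration_unique"


@dataclass
class TruthManifest:
    spikes: list[SpikeTruth]
    pathway_name: str
    pathway_genes: list[str]

    def __post_init__(self) -> None:
        genes = [s.gene for s in self.spikes]
        if len(genes) != len(set(genes)):
            raise ValueError("each spike must appear exactly once in the manifest")


@dataclass
class Bundle:
    """A complete in-memory input bundle plus its ground truth."""

    sites: list[VariantSite]
    genotypes: GenotypeMatrix
    design: CohortDesign
    ref_af: ReferenceAFTable
    candidate_genes: frozenset[str]
    gene_sets: GeneSetCollection
    manifest: TruthManifest
    config: SimConfig


def _expected_group(spike: Spike, rare_maf: float = 0.01) -> tuple[str, str]:
    if spike.mechanism == "homozygote_spike":
        return "g5_novel_rare_homozygous", "case_control"
    if spike.mechanism == "zero_af_spike":
        group = "g2_novel_clinvar_burden" if spike.clinvar else "g4_novel_rare_burden"
        return group, "case_control"
    maf = min(spike.base_af, 1.0 - spike.base_af)
    group = "g4_novel_rare_burden" if maf < rare_maf else "g6_novel_common_burden"
    if spike.clinvar:
        group = "g2_novel_clinvar_burden"
    comparison = "duration_unique" if spike.mechanism == "duration_spike" else "case_control"
    return group, comparison


def simulate(config: SimConfig) -> Bundle:
    """Draw a full input bundle under ``config``; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    n_cases, n_controls = config.n_cases, config.n_controls
    n_samples = n_cases + n_controls
    case_ids = [f"CASE{i:03d}" for i in range(1, n_cases + 1)]
    control_ids = [f"CTRL{i:03d}" for i in range(1, n_controls + 1)]
    sample_ids = case_ids + control_ids
    case_rows = np.arange(n_cases)
    ctrl_rows = np.arange(n_cases, n_samples)

    n_long, n_short = config.n_duration_long, config.n_duration_short
    long_rows = case_rows[:n_long]
    rest_rows = case_rows[n_long:]  # short + mid strata
    durations = {}
    for i, sid in enumerate(case_ids):
        if i < n_long:
            durations[sid] = float(3.0 + 9.0 * rng.random())
        elif i < n_long + n_short:
            durations[sid] = float(0.1 + 0.9 * rng.random())
        else:
            durations[sid] = float(1.5 + 1.0 * rng.random())
    design = CohortDesign(frozenset(case_ids), frozenset(control_ids), durations)

    # gene universe: nulls, then candidate-list genes (null behaviour), then spikes
    n_spiked = len(config.spikes)
    n_null = config.n_genes - n_spiked
    null_genes = [f"GENE{i:05d}" for i in range(1, n_null + 1)]
    candidate_genes = [f"KNOWN{i:03d}" for i in range(1, config.n_candidate_genes + 1)]
    spike_genes = [s.gene for s in config.spikes]
    all_genes = null_genes + candidate_genes + spike_genes

    sites: list[VariantSite] = []
    dosage_cols: list[np.ndarray] = []
    ref_af: dict[VariantKey, float] = {}
    low_dp_flags: list[bool] = []
    spiked_flags: list[bool] = []

    def new_key(gene_idx: int, var_idx: int) -> VariantKey:
        return VariantKey("chr1", gene_idx * 100_000 + var_idx * 10 + 1, "A", "G")

    # --- null + candidate-list genes -------------------------------------
    for gi, gene in enumerate(null_genes + candidate_genes):
        n_var = 1 + int(rng.poisson(config.mean_extra_variants_per_gene))
        for vi in range(n_var):
            key = new_key(gi, vi)
            if rng.random() < config.rare_fraction:
                af = float(rng.uniform(1.0 / (2 * config.panel_size), 0.01))
            else:
                af = float(rng.uniform(*config.common_af_range))
            ref_af[key] = af

            u = rng.random()
            if u < config.frac_non_exonic * 0.8:
                fclass = FunctionalClass.INTRONIC
            elif u < config.frac_non_exonic:
                fclass = FunctionalClass.UTR
            elif u < config.frac_non_exonic + 0.02:
                fclass = FunctionalClass.SPLICING
            else:
                fclass = FunctionalClass.EXONIC

            if fclass == FunctionalClass.SPLICING:
                cons = Consequence.SPLICING
            elif rng.random() < config.frac_synonymous:
                cons = Consequence.SYNONYMOUS
            else:
                u2 = rng.random()
                if u2 < 0.02:
                    cons = Consequence.STOPGAIN
                elif u2 < 0.04:
                    cons = Consequence.FRAMESHIFT_INDEL
                else:
                    cons = Consequence.NONSYNONYMOUS

            u3 = rng.random()
            if u3 < config.frac_tranche_fail:
                sfilter = SiteFilter.TRANCHE_FAIL
            elif u3 < config.frac_tranche_fail + config.frac_other_fail:
                sfilter = SiteFilter.OTHER_FAIL
            else:
                sfilter = SiteFilter.PASS

            clinvar = (
                ClinvarStatus.PATHOGENIC
                if rng.random() < config.frac_clinvar_pathogenic
                else ClinvarStatus.ABSENT
            )
            lr = LrCall.D if rng.random() < config.frac_lr_damaging else LrCall.T

            sites.append(
                VariantSite(
                    key=key,
                    site_filter=sfilter,
                    gene=gene,
                    functional_class=fclass,
                    consequence=cons,
                    clinvar=clinvar,
                    lr_call=lr,
                    ref_maf=min(af, 1.0 - af),
                )
            )
            dosage_cols.append(rng.binomial(2, af, size=n_samples).astype(np.int8))
            low_dp_flags.append(bool(rng.random() < config.frac_low_dp_gq))
            spiked_flags.append(False)

    # --- spiked genes -----------------------------------------------------
    for si, spike in enumerate(config.spikes):
        gi = n_null + config.n_candidate_genes + si
        for vi in range(spike.n_variants):
            key = new_key(gi, vi)
            dos = np.zeros(n_samples, dtype=np.int8)
            if spike.mechanism in ("ratio_spike", "common_spike"):
                case_af = spike.effect * spike.base_af
                dos[case_rows] = rng.binomial(2, case_af, size=n_cases)
                dos[ctrl_rows] = rng.binomial(2, spike.base_af, size=n_controls)
                ref_af[key] = spike.base_af
                panel_maf = min(spike.base_af, 1.0 - spike.base_af)
            elif spike.mechanism == "duration_spike":
                long_af = spike.effect * spike.base_af
                blended = (n_long * long_af + (n_cases - n_long) * spike.base_af) / n_cases
                dos[long_rows] = rng.binomial(2, long_af, size=len(long_rows))
                dos[rest_rows] = rng.binomial(2, spike.base_af, size=len(rest_rows))
                dos[ctrl_rows] = rng.binomial(2, blended, size=n_controls)
                ref_af[key] = spike.base_af
                panel_maf = min(spike.base_af, 1.0 - spike.base_af)
            elif spike.mechanism == "zero_af_spike":
                carriers = rng.choice(case_rows, size=spike.min_carriers, replace=False)
                dos[carriers] = 1
                panel_maf = 0.0  # absent from the panel table
            else:  # homozygote_spike
                homozygote = int(rng.choice(case_rows))
                dos[homozygote] = 2
                panel_maf = 0.0

            sites.append(
                VariantSite(
                    key=key,
                    site_filter=SiteFilter.PASS,
                    gene=spike.gene,
                    functional_class=FunctionalClass.EXONIC,
                    consequence=Consequence.NONSYNONYMOUS,
                    clinvar=ClinvarStatus.PATHOGENIC if spike.clinvar else ClinvarStatus.ABSENT,
                    lr_call=LrCall.T if spike.clinvar else LrCall.D,
                    ref_maf=panel_maf,
                )
            )
            dosage_cols.append(dos)
            low_dp_flags.append(False)  # spiked variants always well-supported
            spiked_flags.append(True)

    n_sites = len(sites)
    dosage = np.stack(dosage_cols, axis=1)

    # genotype-level missingness (null sites only; spikes stay deterministic)
    miss = rng.random((n_samples, n_sites)) < config.missing_rate
    miss[:, np.array(spiked_flags)] = False
    dosage[miss] = MISSING

    # read depth and genotype quality; designated low-support sites fail DP<10
    depth = rng.poisson(70, size=(n_samples, n_sites)).astype(np.int32)
    low = np.array(low_dp_flags)
    if low.any():
        depth[:, low] = rng.integers(0, 10, size=(n_samples, int(low.sum())))
    quality = np.clip(np.rint(rng.normal(80, 15, size=(n_samples, n_sites))), 0, 99).astype(
        np.int32
    )
    depth[miss] = MISSING
    quality[miss] = MISSING

    genotypes = GenotypeMatrix(
        sample_ids=sample_ids,
        keys=[s.key for s in sites],
        dosage=dosage,
        depth=depth,
        quality=quality,
    )

    # gene sets: random draws from the universe plus one pathway of spiked genes
    sets: dict[str, GeneSet] = {}
    for i in range(1, config.n_gene_sets + 1):
        members = rng.choice(all_genes, size=min(config.genes_per_set, len(all_genes)),
                             replace=False)
        name = f"SET{i:03d}"
        sets[name] = GeneSet(name, f"random gene set {i}", frozenset(map(str, members)))
    if spike_genes:
        sets[SPIKED_PATHWAY] = GeneSet(
            SPIKED_PATHWAY, "pathway holding every spiked gene", frozenset(spike_genes)
        )

    manifest = TruthManifest(
        spikes=[
            SpikeTruth(s.gene, s.mechanism, *_expected_group(s)) for s in config.spikes
        ],
        pathway_name=SPIKED_PATHWAY if spike_genes else "",
        pathway_genes=sorted(spike_genes),
    )

    return Bundle(
        sites=sites,
        genotypes=genotypes,
        design=design,
        ref_af=ReferenceAFTable(af=ref_af, panel_size=config.panel_size),
        candidate_genes=frozenset(candidate_genes),
        gene_sets=GeneSetCollection(sets=sets),
        manifest=manifest,
        config=config,
    )


def emit_bundle(bundle: Bundle, out_dir) -> dict[str, Path]:
    """Write the bundle as the pipeline's on-disk input formats plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "annotations": out / "annotations.tsv",
        "reference_af": out / "reference_af.tsv",
        "design": out / "design.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "candidate_genes": out / "candidate_genes.txt",
        "truth": out / "truth.json",
    }
    cio.write_vcf(bundle.sites, bundle.genotypes, paths["vcf"])
    cio.write_annotations(bundle.sites, paths["annotations"])
    cio.write_reference_af(bundle.ref_af, paths["reference_af"])
    cio.write_design(bundle.design, paths["design"], sample_order=bundle.genotypes.sample_ids)
    cio.write_gene_sets(bundle.gene_sets, paths["gene_sets"])
    cio.write_candidate_genes(bundle.candidate_genes, paths["candidate_genes"])
    truth = {
        "spikes": [dataclasses.asdict(s) for s in bundle.manifest.spikes],
        "pathway_name": bundle.manifest.pathway_name,
        "pathway_genes": bundle.manifest.pathway_genes,
        "seed": bundle.config.seed,
    }
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return paths


def load_bundle(in_dir) -> tuple[list[VariantSite], GenotypeMatrix, CohortDesign,
                                 ReferenceAFTable, frozenset[str], GeneSetCollection]:
    """Read an emitted bundle back through the standard readers."""
    d = Path(in_dir)
    sites, genotypes, design = cio.read_cohort(d / "cohort.vcf", d / "design.tsv")
    sites = cio.read_annotations(d / "annotations.tsv", sites)
    ref_af = cio.read_reference_af(d / "reference_af.tsv")
    candidates = cio.read_candidate_genes(d / "candidate_genes.txt")
    gene_sets = cio.read_gene_sets(d / "gene_sets.gmt")
    return sites, genotypes, design, ref_af, candidates, gene_sets
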