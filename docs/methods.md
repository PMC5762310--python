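# Methods

## The prioritization model

The pipeline implements a deterministic variant-prioritization scheme for
case–control exome cohorts. It is not a calibrated statistical test: genes
are flagged by fixed thresholds on aggregate allele-frequency ratios, so
its operating characteristics (false-call rate, detection power) are
empirical properties of the cohort sizes and frequency spectrum, which is
why the package ships a simulator and a power study rather than p-values
for the burden step.

### Filtration

Variants pass three gates in a fixed order; a dropped variant is attributed
to the first failing stage.

1. **Site filter** — only FILTER = PASS sites survive. Any FILTER value
   beginning `VQSRTranche` is recorded as a tranche failure (the site fell
   outside the variant-quality-score-recalibration truth-sensitivity
   tranche), anything else non-PASS as a generic failure.
2. **DP/GQ support** (`filtration.min_dp` = 10, `filtration.min_gq` = 20) —
   in the default `supported_carrier` mode a site survives iff at least one
   case or sequenced-control sample carries a non-missing, non-reference
   genotype with depth ≥ 10 *and* genotype quality ≥ 20. A genotype with
   missing DP or GQ never counts as support. The alternative `site_mean`
   mode gates on the cohort mean DP and GQ instead. The genotype matrix is
   never modified: quality gates variant *discovery*, while burden counting
   later uses every available call at surviving sites. This resolves the
   tension between removing low-DP/GQ variants and counting alleles
   "regardless of DP or GQ": the first is a site-discovery statement, the
   second a counting statement.
3. **Consequence** — keep functional class exonic/splicing, then drop
   synonymous variants. An exonic variant with unknown consequence is
   retained (it cannot be shown synonymous); this is logged.

### Deleteriousness and partitions

A variant is deleterious on the basis of a ClinVar "pathogenic" annotation,
or failing that a damaging (D) verdict from an ensemble logistic-regression
metapredictor consumed as a precomputed annotation (dbNSFP-style). ClinVar
precedence is explicit. The predictor is never retrained or re-derived
here.

Deleterious variants split at `classify.rare_maf` = 0.01 on the reference
panel **minor** allele frequency, folded as min(af, 1−af)
(`classify.fold_af` toggles folding off, for pipelines whose annotation
source reports alternate-allele frequency). A variant absent from the
panel has frequency 0 and is rare by definition — this is what makes the
zero-AF burden branch reachable.

Novelty is matched at gene level *or* exact variant level
(`novelty.match` = gene | variant | either): published candidate loci are
referenced both ways in practice, and the known/novel split gates the
group taxonomy, not the burden arithmetic.

### The burden rule

For one gene, qualifying deleterious variants are collapsed:
AC = Σ dosages over non-missing genotypes, AN = 2 × (number of non-missing
genotypes), summed over qualifying variants; AF = AC/AN (0 when AN = 0).
The public panel contributes only per-variant frequencies, so its counts
are emulated per variant as round(af × 2 × panel_size) with
AN = 2 × panel_size per variant, keeping the gene-level panel AF a proper
frequency. Rounding is Python's nearest-integer (banker's) round; its only
visible effect is on frequencies within 1/(4·panel_size) of a half-count.

A gene is enriched when either

* **ratio rule**: AF_case/AF_ctrl > 1.5 and AF_case/AF_panel > 1.5 with
  both denominators positive, or
* **zero-AF rule**: both control AFs are zero and the gene's deleterious
  alleles appear in ≥ `burden.min_cases` = 3 *distinct* case samples
  (carriers, not alleles — a single homozygote is one carrier).

When exactly one control AF is zero, that side's ratio is infinite; the
positive side decides at the same threshold and at least one case carrier
is required. This interpolates between the two stated rules, which are
silent on the mixed case.

Threshold comparisons are evaluated by cross-multiplication on integer
allele counts, so a ratio that is *exactly* 1.5 is decided exactly (not
enriched — the rule is a strict inequality) rather than by floating-point
rounding of the quotient.

Burden runs per frequency stratum, mirroring a branch-then-burden
workflow: the ClinVar-pathogenic stratum (novel "pathogenic" variants of
any frequency), the rare stratum, and the common stratum. A rare
ClinVar-pathogenic variant therefore qualifies in two strata; the group
taxonomy resolves each *variant* to exactly one group.

### Homozygote scan and group taxonomy

The scan reports rare novel deleterious variants with at least one case at
dosage 2, zero alternate alleles among sequenced controls, and zero panel
frequency. Group assignment is a decision tree over (novelty, basis,
frequency class, gene enrichment, homozygote hit); the homozygote group
takes precedence over the rare-burden group so the six groups plus
"unassigned" tile the deleterious variants. The exact published membership
rules for the known-candidate groups are not fully specified in the
source material; the tree here reconstructs them from the reported group
descriptions and should be read as a reconstruction.

### Duration comparison

The *entire* pipeline (filtration → classification → burden → taxonomy) is
re-run with long-duration cases (≥ `duration.long_years` = 3) in the case
role and short-duration cases (≤ `duration.short_years` = 1) in the
sequenced-control role; the public panel is unchanged. The duration gene
set is the same group-union statistic as the case–control run; the
duration-unique set is its set difference against the case–control union.

### Pathway over-representation

One-tailed Fisher exact p = P(X ≥ k) for X ~ Hypergeometric(N, K, n),
computed exactly in log space (scipy), and the EASE score — the same tail
at k−1 — as the primary statistic, since that is DAVID's "modified Fisher
exact". EASE is deliberately conservative: a singleton overlap can never
be significant. Significance is a raw `enrich.alpha` = 0.05 threshold by
default; Benjamini–Hochberg correction is available behind `enrich.fdr`.
The background universe is the set of genes bearing at least one
preliminary variant in the run — an explicit, reproducible choice, since
web-tool default backgrounds vary per submission and are not recoverable.

## The simulator

`exoburden.simulate` emulates the full input bundle at the study design:
58 cases (23 with disease duration ≥ 3 years, 26 with ≤ 1 year, 9
intermediate), 66 sequenced controls, a 105-sample external panel.
Defaults, chosen once to mirror a realistic exome funnel:

| parameter | default | rationale |
| --- | --- | --- |
| variants per gene | 1 + Poisson(2.5) | ≈ 3.6 variants/gene, a ~72k-variant exome over ~20k genes |
| LR-damaging fraction | 0.30 | ≈ 21.8k damaging calls among 72k exonic variants |
| ClinVar-pathogenic fraction | 0.002 | ≈ 135 pathogenic annotations among 72k |
| synonymous fraction | 0.40 | typical exonic synonymous share |
| tranche-fail / other-fail | 0.05 / 0.01 | modest VQSR failure rate |
| low-DP/GQ sites | 0.05 | sites whose genotypes all fail support |
| non-exonic fraction | 0.10 | intronic/UTR contamination of capture |
| genotype missingness | 0.02 | joint-genotyping no-calls |
| allele-frequency spectrum | 0.6 rare U[1/210, 0.01) + 0.4 common U[0.02, 0.4] | a post-discovery exome mix; the rare floor is one panel allele |

Null genotypes are independent binomial(2, af) draws per sample at the
variant's true panel frequency — no linkage, no relatedness, no population
structure, autosomes only. Spiked genes (4 variants each, one for
homozygote spikes; always exonic, deleterious, well-supported) implement
five mechanisms: case-frequency multiplication at a common base frequency
(ratio and common spikes, 5× on 2% and 5%), planted carriers at zero
control/panel frequency (≥ 3 distinct het cases per variant), a planted
case homozygote absent everywhere else, and duration spikes.

Duration spikes put the signal in the long-duration stratum
(af = 5 × 0.05), leave short/mid cases and the panel at base, and give
sequenced controls the blended overall-case frequency — so the duration
comparison sees a ~5-fold contrast against both of its control groups
while the case–control ratio against sequenced controls centres on 1 and
fails the "both > 1.5" requirement. The 5%/5× choice keeps the chance of
a duration gene leaking into the case–control set below ~1% per gene.

What passing simulation tests does **not** show: robustness to linkage
disequilibrium between qualifying variants, relatedness or ancestry
stratification, annotation error, differential missingness between cases
and controls, or chrX hemizygosity (male X genotypes would be counted as
diploid; the simulator stays autosomal for that reason).

## Numerical and design choices

* Multi-allelic VCF records are decomposed at read time, one alternate per
  variant, dosages recoded per alternate; every downstream rule is
  allele-level. Missing genotypes contribute neither allele count nor
  allele number.
* One gene symbol per variant (first listed wins, logged), symbols
  uppercased; a multi-consequence annotation collapses to the worst label
  (stopgain > frameshift > stoploss > splicing > nonsynonymous >
  non-frameshift > synonymous).
* Ratios against a zero-frequency control group are reported as +inf;
  0/0 is also reported as +inf and never drives a decision (the zero-AF
  branch is decided on carriers).
* The EASE shift k→k−1 can fall below the hypergeometric support floor;
  the tail is exactly 1 there and this is accepted rather than rejected.
* Result tables print reals to 12 significant digits and round-trip to
  that precision; strings and integers round-trip exactly.
* All randomness flows from one integer seed through one generator;
  re-running any step with the same seed and config reproduces every
  output file byte for byte.
* Test and acceptance problem sizes — 2000-gene cohorts, 10–20 replicate
  seeds, exhaustive rule grids up to background 60 — were chosen as the
  smallest sizes at which the measured rates stabilize.

## Known limitations

The burden rule's false-call rate on null genes is ~6–7% at the default
design: a fixed fold-change threshold at these cohort sizes is
anticonservative for rare variants (a single case allele can exceed 1.5×
a one-allele panel frequency). This matches the method's role as a
prioritization screen feeding downstream review, not a significance test.
The panel-count emulation assumes the panel was genotyped at every site
(absent means frequency 0, not missing). DAVID-specific behaviours other
than the EASE statistic (annotation clustering, fold enrichment, database
snapshots) are out of scope.
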