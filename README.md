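# exoburden

Case–control whole-exome variant prioritization with a deterministic
gene-burden ratio test, built for cohort studies that ask which genes carry
an excess of deleterious variation in patients — the setting is a rheumatoid
arthritis exome study with 58 cases, 66 sequenced healthy controls, and an
external public reference panel of 105 southern Han Chinese samples, but
every design parameter is configurable.

## What it does

Starting from a joint-genotyped multi-sample VCF, a variant annotation
table, a reference-panel allele-frequency table, a known-candidate gene
list, and gene sets in GMT format, the pipeline:

1. **Filters** variants: VQSR tranche failures removed; a site must have at
   least one carrier genotype supported by read depth DP ≥ 10 and genotype
   quality GQ ≥ 20; only exonic/splicing variants are kept and synonymous
   variants are removed. The survivors are the *preliminary variant list*.
2. **Classifies** each preliminary variant as deleterious when ClinVar calls
   it "pathogenic" or an ensemble logistic-regression metapredictor calls it
   damaging (D), splits deleterious variants into *rare* (panel minor allele
   frequency < 1%) and *common*, and marks variants in known candidate genes.
3. **Collapses** each gene's qualifying deleterious variants and applies the
   burden rule. With aggregate allele frequencies `p_case`, `p_ctrl`
   (sequenced controls) and `p_panel` (public panel), a gene is *enriched*
   when

   ```
   p_case / p_ctrl > 1.5  AND  p_case / p_panel > 1.5        (ratio rule)
   ```

   or, when both control frequencies are zero, when the gene's deleterious
   alleles are carried by ≥ 3 distinct cases (zero-AF rule). All available
   genotype calls contribute to the allele counts regardless of DP/GQ;
   quality gates discovery, not counting.
4. **Scans** for rare novel deleterious variants homozygous in a case and
   absent from both control groups, and assigns every deleterious variant to
   one of six groups: known candidates by ClinVar (g1) or metapredictor
   (g3); novel ClinVar-pathogenic in burden-enriched genes (g2); novel rare
   in enriched genes (g4); novel rare case-homozygotes (g5, takes precedence
   over g4); novel common in enriched genes (g6).
5. **Repeats** the whole analysis with long-disease-duration cases (≥ 3
   years) as cases and short-duration cases (≤ 1 year) as controls, and
   reports the genes unique to the duration comparison.
6. **Tests pathways** for over-representation with the one-tailed Fisher
   exact test and its conservative EASE variant (the Fisher tail after
   removing one gene from the overlap), against the background of all genes
   bearing a preliminary variant.

A synthetic cohort module simulates the complete input bundle — genotypes,
annotations, quality noise, tranche failures, panel frequencies, gene sets —
with spiked enriched/homozygous/duration-associated genes and a truth
manifest, so the whole pipeline can be validated end to end.

## Worked example

```
$ exoburden simulate --out demo/bundle --seed 1 --n-genes 500
wrote bundle with 1828 sites to demo/bundle
$ exoburden run --bundle demo/bundle --out demo/results
funnel: {'input': 1828, 'after_site_filter': 1727, 'after_dp_gq': 1488,
         'after_functional_class': 1346, 'after_synonymous_removal': 858}
gene union: 57 genes; duration-unique: 29
homozygous hits: 5
results written to demo/results
```

The funnel shows the filter cascade: 1828 simulated sites drop to 858
preliminary variants (site filters, then DP/GQ support, then
functional-class and synonymous removal). The run recovered all 22 spiked
genes: the 5 planted homozygotes appear as `homozygous hits`, and the gene
union of the six groups (57 genes) contains every case–control spike plus
the null genes the deterministic threshold rule picks up by chance (~6–7%
of genes; the rule is a screen, not a calibrated test). The enrichment
table ranks the pathway holding the spiked genes first:

```
$ head -2 demo/results/enrichment.tsv | cut -f1,2,4,6,7
set_name        p_ease            k   n    N
SPIKED_PATHWAY  1.24750814502e-15 20  57   430
```

i.e. 20 of the 57 query genes fall in the 22-member spiked pathway against
a 430-gene background, EASE p ≈ 1.2e-15. A power study across effect sizes:

```
$ exoburden power --out demo/power.tsv --effects 1,3,5 --n-seeds 3 --n-genes 200
effect  1.0: detection 0.067 +- 0.064, false calls 0.0698 +- 0.0102
effect  3.0: detection 0.933 +- 0.064, false calls 0.0698 +- 0.0102
effect  5.0: detection 1.000 +- 0.000, false calls 0.0698 +- 0.0102
```

At effect size 1 (no signal) the "detection" of spiked genes matches the
false-call rate on null genes, as it must; by a 5-fold case enrichment on a
2% base frequency the rule detects every spiked gene.

## Layout

| module | role |
| --- | --- |
| `exoburden.io` | VCF (via cyvcf2, multi-allelics decomposed), annotation/AF/design TSVs, GMT, result tables |
| `exoburden.filtration` | the filter cascade and its funnel report |
| `exoburden.classify` | deleteriousness basis, known/novel, rare/common |
| `exoburden.burden` | gene collapsing, burden rule, homozygote scan, six-group taxonomy, duration comparison |
| `exoburden.enrichment` | Fisher / EASE over-representation |
| `exoburden.simulate` | synthetic cohorts with spiked signal and truth manifest |
| `exoburden.pipeline` | end-to-end orchestration, run report, power study |
| `exoburden.cli` | `exoburden simulate / run / power / report` |

See `docs/methods.md` for the model, parameter defaults, and limitations.
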