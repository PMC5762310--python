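"""Quality/consequence filter cascade producing the preliminary variant list.

The cascade runs in a fixed order: VQSR site filter, then read-depth /
genotype-quality support, then functional class with synonymous removal.
A dropped variant is attributed to the first stage that fails it.

The DP/GQ stage gates variant *discovery* only: a site survives when at
least one case or sequenced-control sample carries a non-missing,
non-reference genotype backed by depth >= 10 and genotype quality >= 20
(the supported-carrier rule).  Genotype matrices are never modified —
burden counting downstream uses all available calls at surviving sites,
regardless of DP or GQ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import (
    CohortDesign,
    Consequence,
    FunctionalClass,
    GenotypeMatrix,
    SiteFilter,
    VariantKey,
    VariantSite,
)

STAGES = ("input", "after_site_filter", "after_dp_gq", "after_functional_class",
          "after_synonymous_removal")

REASON_VQSR = "vqsr"
REASON_OTHER_FILTER = "site_filter"
REASON_DP_GQ = "dp_gq"
REASON_FUNCTIONAL_CLASS = "functional_class"
REASON_SYNONYMOUS = "synonymous"


@dataclass
class FilterReport:
    """Funnel counts per stage plus one (first-failing) reason per dropped variant."""

    counts: dict[str, int] = field(default_factory=dict)
    drop_reasons: dict[VariantKey, str] = field(default_factory=dict)

    def reason_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.drop_reasons.values():
            out[r] = out.get(r, 0) + 1
        return out

    def check_consistency(self) -> None:
        stages = [self.counts[s] for s in STAGES]
        if any(a < b for a, b in zip(stages, stages[1:])):
            raise AssertionError(f"stage counts increase along the cascade: {self.counts}")
        if stages[0] != stages[-1] + len(self.drop_reasons):
            raise AssertionError(
                f"funnel does not cross-foot: input {stages[0]} != retained "
                f"{stages[-1]} + dropped {len(self.drop_reasons)}"
            )


def apply_site_filter(sites: list[VariantSite]) -> list[VariantSite]:
    """Keep exactly the sites whose FILTER outcome is PASS."""
    return [s for s in sites if s.site_filter == SiteFilter.PASS]


def _supported_carrier_mask(
    sites, genotypes: GenotypeMatrix, design: CohortDesign, min_dp: int, min_gq: int
) -> np.ndarray:
    """Boolean per site: some case/control carrier genotype has DP and GQ support.

    A genotype with missing DP or GQ never counts as support.
    """
    rows = genotypes.sample_rows(design.all_ids)
    cols = genotypes.site_cols([s.key for s in sites])
    if len(cols) == 0:
        return np.zeros(0, dtype=bool)
    dos = genotypes.dosage[np.ix_(rows, cols)]
    dp = genotypes.depth[np.ix_(rows, cols)]
    gq = genotypes.quality[np.ix_(rows, cols)]
    supported = (dos >= 1) & (dp >= min_dp) & (gq >= min_gq)
    return supported.any(axis=0)


def _site_mean_mask(
    sites, genotypes: GenotypeMatrix, design: CohortDesign, min_dp: int, min_gq: int
) -> np.ndarray:
    """Alternative per-site reading: mean DP and mean GQ over non-missing genotypes."""
    rows = genotypes.sample_rows(design.all_ids)
    cols = genotypes.site_cols([s.key for s in sites])
    if len(cols) == 0:
        return np.zeros(0, dtype=bool)
    dp = genotypes.depth[np.ix_(rows, cols)].astype(float)
    gq = genotypes.quality[np.ix_(rows, cols)].astype(float)
    dp[dp < 0] = np.nan
    gq[gq < 0] = np.nan
    with np.errstate(invalid="ignore"):
        mean_dp = np.nanmean(dp, axis=0)
        mean_gq = np.nanmean(gq, axis=0)
    return (mean_dp >= min_dp) & (mean_gq >= min_gq)


def apply_dp_gq_filter(
    sites: list[VariantSite],
    genotypes: GenotypeMatrix,
    design: CohortDesign,
    min_dp: int = 10,
    min_gq: int = 20,
    mode: str = "supported_carrier",
) -> list[VariantSite]:
    if mode == "supported_carrier":
        keep = _supported_carrier_mask(sites, genotypes, design, min_dp, min_gq)
    elif mode == "site_mean":
        keep = _site_mean_mask(sites, genotypes, design, min_dp, min_gq)
    else:
        raise ValueError(f"unknown filtration mode {mode!r}")
    return [s for s, k in zip(sites, keep) if k]


def apply_consequence_filter(sites: list[VariantSite]) -> list[VariantSite]:
    """Keep exonic/splicing sites, then remove synonymous ones.

    An exonic/splicing site with consequence ``unknown`` is retained
    (conservative: it cannot be shown synonymous).
    """
    keep_class = {FunctionalClass.EXONIC, FunctionalClass.SPLICING}
    return [
        s
        for s in sites
        if s.functional_class in keep_class and s.consequence != Consequence.SYNONYMOUS
    ]


def run_filtration(
    sites: list[VariantSite],
    genotypes: GenotypeMatrix,
    design: CohortDesign,
    min_dp: int = 10,
    min_gq: int = 20,
    mode: str = "supported_carrier",
) -> tuple[list[VariantSite], FilterReport]:
    """Run the full cascade and account for every dropped variant once."""
    report = FilterReport()
    report.counts["input"] = len(sites)

    stage1 = apply_site_filter(sites)
    kept1 = {s.key for s in stage1}
    for s in sites:
        if s.key not in kept1:
            report.drop_reasons[s.key] = (
                REASON_VQSR if s.site_filter == SiteFilter.TRANCHE_FAIL else REASON_OTHER_FILTER
            )
    report.counts["after_site_filter"] = len(stage1)

    stage2 = apply_dp_gq_filter(stage1, genotypes, design, min_dp, min_gq, mode)
    kept2 = {s.key for s in stage2}
    for s in stage1:
        if s.key not in kept2:
            report.drop_reasons[s.key] = REASON_DP_GQ
    report.counts["after_dp_gq"] = len(stage2)

    keep_class = {FunctionalClass.EXONIC, FunctionalClass.SPLICING}
    stage3 = [s for s in stage2 if s.functional_class in keep_class]
    kept3 = {s.key for s in stage3}
    for s in stage2:
        if s.key not in kept3:
            report.drop_reasons[s.key] = REASON_FUNCTIONAL_CLASS
    report.counts["after_functional_class"] = len(stage3)

    stage4 = [s for s in stage3 if s.consequence != Consequence.SYNONYMOUS]
    kept4 = {s.key for s in stage4}
    for s in stage3:
        if s.key not in kept4:
            report.drop_reasons[s.key] = REASON_SYNONYMOUS
    report.counts["after_synonymous_removal"] = len(stage4)

    report.check_consistency()
    return stage4, report


def write_filter_report(report: FilterReport, stage_path, reasons_path) -> None:
    from .io import write_table

    write_table(
        [{"stage": s, "count": report.counts[s]} for s in STAGES],
        stage_path,
    )
    write_table(
        [
            {"chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt, "reason": r}
            for k, r in sorted(report.drop_reasons.items())
        ],
        reasons_path,
    )
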