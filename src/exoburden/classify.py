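"""Deleteriousness classification and the known/novel, rare/common partitions.

A preliminary variant is deleterious when ClinVar annotates it "pathogenic",
or failing that when the ensemble logistic-regression metapredictor calls it
damaging (D).  ClinVar takes precedence when both hold.  Deleterious variants
are then split at minor allele frequency 1% in the external reference panel;
a variant absent from the panel has frequency 0 and is rare by definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .types import ClinvarStatus, LrCall, ReferenceAFTable, VariantKey, VariantSite


class Basis(str, Enum):
    CLINVAR_PATHOGENIC = "clinvar_pathogenic"
    LR_DAMAGING = "lr_damaging"
    NOT_DELETERIOUS = "not_deleterious"


class Novelty(str, Enum):
    KNOWN_CANDIDATE = "known_candidate"
    NOVEL = "novel"


class FrequencyClass(str, Enum):
    RARE = "rare"
    COMMON = "common"
    UNCLASSIFIED = "unclassified"


@dataclass
class DeleteriousCall:
    key: VariantKey
    gene: str
    basis: Basis
    novelty: Novelty = Novelty.NOVEL
    frequency_class: FrequencyClass = FrequencyClass.UNCLASSIFIED

    @property
    def deleterious(self) -> bool:
        return self.basis != Basis.NOT_DELETERIOUS


def call_deleterious(site: VariantSite) -> Basis:
    if site.clinvar == ClinvarStatus.PATHOGENIC:
        return Basis.CLINVAR_PATHOGENIC
    if site.lr_call == LrCall.D:
        return Basis.LR_DAMAGING
    return Basis.NOT_DELETERIOUS


def mark_novelty(
    site: VariantSite,
    candidate_genes: frozenset[str] = frozenset(),
    candidate_variants: frozenset[VariantKey] = frozenset(),
    match: str = "either",
) -> Novelty:
    """Known-candidate when the gene symbol or exact variant key is on the list.

    ``match`` restricts the comparison to gene level, variant level, or either.
    """
    gene_hit = site.gene.upper() in candidate_genes if site.gene else False
    variant_hit = site.key in candidate_variants
    if match == "gene":
        hit = gene_hit
    elif match == "variant":
        hit = variant_hit
    elif match == "either":
        hit = gene_hit or variant_hit
    else:
        raise ValueError(f"unknown novelty match mode {match!r}")
    return Novelty.KNOWN_CANDIDATE if hit else Novelty.NOVEL


def split_rare_common(
    site: VariantSite,
    ref_af_table: ReferenceAFTable,
    rare_maf: float = 0.01,
    fold_af: bool = True,
) -> FrequencyClass:
    """Rare iff the panel minor allele frequency is below ``rare_maf``.

    The alternate AF is folded to min(af, 1-af) by default; a variant absent
    from the panel folds to 0 and is therefore rare.
    """
    maf = ref_af_table.minor_af(site.key, fold=fold_af)
    return FrequencyClass.RARE if maf < rare_maf else FrequencyClass.COMMON


def classify_variants(
    sites: list[VariantSite],
    ref_af_table: ReferenceAFTable,
    candidate_genes: frozenset[str] = frozenset(),
    candidate_variants: frozenset[VariantKey] = frozenset(),
    rare_maf: float = 0.01,
    fold_af: bool = True,
    novelty_match: str = "either",
) -> list[DeleteriousCall]:
    """Classify every preliminary site; frequency class only for deleterious ones."""
    calls = []
    for site in sites:
        basis = call_deleterious(site)
        freq = (
            split_rare_common(site, ref_af_table, rare_maf, fold_af)
            if basis != Basis.NOT_DELETERIOUS
            else FrequencyClass.UNCLASSIFIED
        )
        calls.append(
            DeleteriousCall(
                key=site.key,
                gene=site.gene.upper(),
                basis=basis,
                novelty=mark_novelty(site, candidate_genes, candidate_variants, novelty_match),
                frequency_class=freq,
            )
        )
    return calls
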