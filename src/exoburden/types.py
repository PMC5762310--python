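"""Core domain containers shared across the pipeline.

Coordinates are 1-based and fully closed, exactly as written in VCF.
Multi-allelic records are decomposed at read time, so every container holds
one alternate allele per variant and every downstream rule (frequency,
deleteriousness, burden) is allele-level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

MISSING = -1  # sentinel in dosage/depth/quality matrices


class SiteFilter(str, Enum):
    PASS = "pass"
    TRANCHE_FAIL = "tranche_fail"
    OTHER_FAIL = "other_fail"


class FunctionalClass(str, Enum):
    EXONIC = "exonic"
    SPLICING = "splicing"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"
    UTR = "utr"
    OTHER = "other"


class Consequence(str, Enum):
    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    STOPGAIN = "stopgain"
    STOPLOSS = "stoploss"
    FRAMESHIFT_INDEL = "frameshift_indel"
    NONFRAMESHIFT_INDEL = "nonframeshift_indel"
    SPLICING = "splicing"
    UNKNOWN = "unknown"


#: worst first; used to collapse multi-consequence annotation rows to one label
CONSEQUENCE_SEVERITY: tuple[Consequence, ...] = (
    Consequence.STOPGAIN,
    Consequence.FRAMESHIFT_INDEL,
    Consequence.STOPLOSS,
    Consequence.SPLICING,
    Consequence.NONSYNONYMOUS,
    Consequence.NONFRAMESHIFT_INDEL,
    Consequence.SYNONYMOUS,
)


class ClinvarStatus(str, Enum):
    PATHOGENIC = "pathogenic"
    OTHER = "other"
    ABSENT = "absent"


class LrCall(str, Enum):
    """Verdict of the ensemble logistic-regression metapredictor.

    D = damaging (disease-related), T = tolerated (benign/neutral).  Consumed
    as a precomputed annotation, never recomputed here.
    """

    D = "D"
    T = "T"
    ABSENT = "absent"


@dataclass(frozen=True, order=True)
class VariantKey:
    """One biallelic variant: chromosome, 1-based position, ref and a single alt."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")
        if "," in self.alt:
            raise ValueError(
                f"alt must be a single allele, got {self.alt!r} "
                f"(decompose multi-allelic records first)"
            )

    def __str__(self) -> str:  # e.g. "chrX:49114808:C:T"
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class VariantSite:
    """One decomposed variant with its site filter status and annotations."""

    key: VariantKey
    site_filter: SiteFilter = SiteFilter.PASS
    gene: str = ""
    functional_class: FunctionalClass = FunctionalClass.OTHER
    consequence: Consequence = Consequence.UNKNOWN
    clinvar: ClinvarStatus = ClinvarStatus.ABSENT
    lr_call: LrCall = LrCall.ABSENT
    ref_maf: float | None = None  # folded minor AF in the reference panel

    def __post_init__(self) -> None:
        if self.ref_maf is not None and not (0.0 <= self.ref_maf <= 0.5):
            raise ValueError(f"ref_maf must lie in [0, 0.5], got {self.ref_maf}")


@dataclass
class GenotypeMatrix:
    """Per-sample allele dosages with per-genotype depth and genotype quality.

    Arrays are (n_samples, n_sites); ``MISSING`` (-1) marks an unavailable
    value.  A missing dosage contributes neither allele count nor allele
    number downstream.
    """

    sample_ids: list[str]
    keys: list[VariantKey]
    dosage: np.ndarray
    depth: np.ndarray
    quality: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.sample_ids), len(self.keys))
        for name in ("dosage", "depth", "quality"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        bad = (self.dosage < MISSING) | (self.dosage > 2)
        if bad.any():
            raise ValueError("dosage values must be in {0, 1, 2} or missing (-1)")
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}
        self._key_index = {k: j for j, k in enumerate(self.keys)}

    def sample_rows(self, ids) -> np.ndarray:
        """Row indices for an iterable of sample ids (sorted for determinism)."""
        return np.array(sorted(self._sample_index[s] for s in ids), dtype=np.intp)

    def site_cols(self, keys) -> np.ndarray:
        return np.array([self._key_index[k] for k in keys], dtype=np.intp)

    def column(self, key: VariantKey) -> int:
        return self._key_index[key]


@dataclass
class CohortDesign:
    """Sample roles plus per-case disease duration in years."""

    case_ids: frozenset[str]
    control_ids: frozenset[str]
    duration_years: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = self.case_ids & self.control_ids
        if overlap:
            raise ValueError(f"samples listed as both case and control: {sorted(overlap)}")
        stray = set(self.duration_years) - set(self.case_ids)
        if stray:
            raise ValueError(f"duration given for non-case samples: {sorted(stray)}")
        for s, d in self.duration_years.items():
            if d < 0:
                raise ValueError(f"negative disease duration for {s}: {d}")

    @property
    def all_ids(self) -> frozenset[str]:
        return self.case_ids | self.control_ids

    def duration_strata(self, long_years: float, short_years: float):
        """(long-duration case ids, short-duration case ids)."""
        long_ids = frozenset(
            s for s, d in self.duration_years.items() if d >= long_years
        )
        short_ids = frozenset(
            s for s, d in self.duration_years.items() if d <= short_years
        )
        return long_ids, short_ids


@dataclass
class ReferenceAFTable:
    """Alternate-allele frequencies in the external public panel.

    Variants absent from the table are treated as frequency 0 in the panel,
    which is what makes the zero-AF burden branch reachable.
    """

    af: dict[VariantKey, float]
    panel_size: int

    def __post_init__(self) -> None:
        if self.panel_size <= 0:
            raise ValueError(f"panel_size must be positive, got {self.panel_size}")
        for k, v in self.af.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"allele frequency out of [0,1] for {k}: {v}")

    def lookup(self, key: VariantKey) -> float:
        return self.af.get(key, 0.0)

    def minor_af(self, key: VariantKey, fold: bool = True) -> float:
        """Minor allele frequency; folds the alternate AF as min(af, 1-af)."""
        v = self.lookup(key)
        return min(v, 1.0 - v) if fold else v


@dataclass
class GeneSet:
    name: str
    description: str
    genes: frozenset[str]


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if not gs.genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())
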