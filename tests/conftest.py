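import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from exoburden.types import (
    MISSING,
    ClinvarStatus,
    CohortDesign,
    Consequence,
    FunctionalClass,
    GenotypeMatrix,
    LrCall,
    SiteFilter,
    VariantKey,
    VariantSite,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


def make_matrix(sample_ids, keys, dosage, depth=None, quality=None):
    """GenotypeMatrix from nested lists; depth/quality default to well-supported."""
    dosage = np.asarray(dosage, dtype=np.int8)
    if depth is None:
        depth = np.full(dosage.shape, 50, dtype=np.int32)
    else:
        depth = np.asarray(depth, dtype=np.int32)
    if quality is None:
        quality = np.full(dosage.shape, 90, dtype=np.int32)
    else:
        quality = np.asarray(quality, dtype=np.int32)
    depth = depth.copy()
    quality = quality.copy()
    depth[dosage == MISSING] = MISSING
    quality[dosage == MISSING] = MISSING
    return GenotypeMatrix(
        sample_ids=list(sample_ids), keys=list(keys),
        dosage=dosage, depth=depth, quality=quality,
    )


def key(pos, chrom="chr1", ref="A", alt="G"):
    return VariantKey(chrom, pos, ref, alt)


def exonic_site(pos, gene="GENEX", consequence=Consequence.NONSYNONYMOUS,
                site_filter=SiteFilter.PASS,
                functional_class=FunctionalClass.EXONIC,
                clinvar=ClinvarStatus.ABSENT, lr_call=LrCall.D, ref_maf=0.0):
    return VariantSite(
        key=key(pos), site_filter=site_filter, gene=gene,
        functional_class=functional_class, consequence=consequence,
        clinvar=clinvar, lr_call=lr_call, ref_maf=ref_maf,
    )


@pytest.fixture
def filtration_fixture():
    """Twelve constructed sites exercising every drop branch of the cascade.

    Two samples (one case, one control).  Designed fates:

    ====  ==========================  ==================  =========
    site  construction                first failing stage outcome
    ====  ==========================  ==================  =========
    s1    clean exonic nonsyn         -                   retained
    s2    VQSR tranche failure        site filter (vqsr)  dropped
    s3    other FILTER failure        site filter         dropped
    s4    only carrier has DP 9       dp_gq               dropped
    s5    only carrier has GQ 19      dp_gq               dropped
    s6    only carrier is missing     dp_gq               dropped
    s7    intronic                    functional class    dropped
    s8    UTR                         functional class    dropped
    s9    exonic synonymous           synonymous          dropped
    s10   splicing-class variant      -                   retained
    s11   exonic stopgain             -                   retained
    s12   carrier at DP 10 / GQ 20    -                   retained
    ====  ==========================  ==================  =========
    """
    sites = [
        exonic_site(100),
        exonic_site(200, site_filter=SiteFilter.TRANCHE_FAIL),
        exonic_site(300, site_filter=SiteFilter.OTHER_FAIL),
        exonic_site(400),
        exonic_site(500),
        exonic_site(600),
        exonic_site(700, functional_class=FunctionalClass.INTRONIC),
        exonic_site(800, functional_class=FunctionalClass.UTR),
        exonic_site(900, consequence=Consequence.SYNONYMOUS),
        exonic_site(1000, functional_class=FunctionalClass.SPLICING,
                    consequence=Consequence.SPLICING),
        exonic_site(1100, consequence=Consequence.STOPGAIN),
        exonic_site(1200),
    ]
    # rows: CASE1, CTRL1; columns follow the sites above
    dosage = [
        [1, 1, 1, 1, 1, MISSING, 1, 1, 1, 1, 1, 1],
        [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    ]
    depth = [
        [50, 50, 50, 9, 50, 50, 50, 50, 50, 50, 50, 10],
        [50, 50, 50, 50, 50, 50, 50, 50, 50, 50, 50, 50],
    ]
    quality = [
        [90, 90, 90, 30, 19, 90, 90, 90, 90, 90, 90, 20],
        [90, 90, 90, 90, 90, 90, 90, 90, 90, 90, 90, 90],
    ]
    genotypes = make_matrix(
        ["CASE1", "CTRL1"], [s.key for s in sites], dosage, depth, quality
    )
    design = CohortDesign(frozenset({"CASE1"}), frozenset({"CTRL1"}))
    retained = {sites[0].key, sites[9].key, sites[10].key, sites[11].key}
    reasons = {
        sites[1].key: "vqsr",
        sites[2].key: "site_filter",
        sites[3].key: "dp_gq",
        sites[4].key: "dp_gq",
        sites[5].key: "dp_gq",
        sites[6].key: "functional_class",
        sites[7].key: "functional_class",
        sites[8].key: "synonymous",
    }
    return sites, genotypes, design, retained, reasons


@pytest.fixture(scope="session")
def small_bundle():
    """A modest spiked cohort shared by pipeline-level tests."""
    from exoburden.simulate import SimConfig, simulate

    return simulate(SimConfig(n_genes=300, seed=11))
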