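"""Readers and writers for every external artifact the pipeline touches.

Formats (all plain text):

* multi-sample VCF v4.2 with per-genotype GT/DP/GQ; the FILTER column carries
  the VQSR outcome (any value beginning ``VQSRTranche`` means the site fell
  outside the chosen truth-sensitivity tranche),
* annotation TSV keyed by chrom/pos/ref/alt,
* reference-panel allele-frequency TSV with a ``#panel_size=<int>`` header,
* sample design TSV (role, optional disease duration),
* GMT gene sets, one-symbol-per-line candidate gene lists,
* generic result tables (TSV, round-trippable).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import (
    MISSING,
    ClinvarStatus,
    CohortDesign,
    Consequence,
    CONSEQUENCE_SEVERITY,
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

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A source file could not be parsed; the message names the location."""


class DesignError(ValueError):
    """The cohort design is inconsistent with the genotype data."""


# ---------------------------------------------------------------------------
# VCF + design
# ---------------------------------------------------------------------------

def read_design(path) -> CohortDesign:
    """Read the design TSV: sample_id, role (case|control), duration_years."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "role"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: design file needs columns {sorted(required)}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise DesignError(f"{path}: duplicated sample ids {sorted(set(dup))}")
    cases, controls, durations = set(), set(), {}
    for row in df.itertuples(index=False):
        role = str(row.role).strip().lower()
        if role == "case":
            cases.add(row.sample_id)
        elif role == "control":
            controls.add(row.sample_id)
        else:
            raise ParseError(f"{path}: unknown role {row.role!r} for {row.sample_id}")
        if "duration_years" in df.columns:
            d = getattr(row, "duration_years")
            if d is not None and not (isinstance(d, float) and math.isnan(d)):
                durations[row.sample_id] = float(d)
    return CohortDesign(frozenset(cases), frozenset(controls), durations)


def _site_filter_from_vcf(filter_field: str | None) -> SiteFilter:
    if filter_field is None or filter_field in ("PASS", "."):
        return SiteFilter.PASS
    if any(f.startswith("VQSRTranche") for f in filter_field.split(";")):
        return SiteFilter.TRANCHE_FAIL
    return SiteFilter.OTHER_FAIL


def _format_ints(variant, tag: str, n_samples: int) -> np.ndarray:
    """Per-sample integer FORMAT values, MISSING where absent."""
    out = np.full(n_samples, MISSING, dtype=np.int32)
    try:
        vals = variant.format(tag)
    except KeyError:
        return out
    if vals is None:
        return out
    vals = np.asarray(vals).reshape(n_samples, -1)[:, 0]
    ok = np.isfinite(vals.astype(float)) & (vals.astype(float) >= 0)
    out[ok] = vals[ok].astype(np.int32)
    return out


def read_cohort(vcf_path, design_path):
    """Read a joint-genotyped VCF plus its design file.

    Multi-allelic records are decomposed into one :class:`VariantSite` per
    alternate allele, with dosages recoded against that alternate (a genotype
    contributes to an alternate's dosage the number of allele calls equal to
    that alternate).  Genotypes with any no-call allele are missing.

    Returns ``(sites, genotypes, design)``.
    """
    design = read_design(design_path)
    try:
        vcf = VCF(str(vcf_path), gts012=False)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise ParseError(f"{vcf_path}: cannot open VCF ({exc})") from exc

    samples = list(vcf.samples)
    missing_from_vcf = design.all_ids - set(samples)
    extra_in_vcf = set(samples) - design.all_ids
    if missing_from_vcf or extra_in_vcf:
        raise DesignError(
            f"sample sets differ between design and VCF; "
            f"in design only: {sorted(missing_from_vcf)}, "
            f"in VCF only: {sorted(extra_in_vcf)}"
        )

    n = len(samples)
    sites: list[VariantSite] = []
    dosage_cols, depth_cols, qual_cols = [], [], []
    try:
        for variant in vcf:
            alts = variant.ALT
            if not alts:
                continue
            gts = variant.genotype.array()[:, :-1]  # allele codes, -1 = no-call
            dp = _format_ints(variant, "DP", n)
            gq = _format_ints(variant, "GQ", n)
            site_filter = _site_filter_from_vcf(variant.FILTER)
            any_missing = (gts < 0).any(axis=1)
            for ai, alt in enumerate(alts, start=1):
                key = VariantKey(variant.CHROM, variant.POS, variant.REF, alt)
                dos = (gts == ai).sum(axis=1).astype(np.int8)
                dos[any_missing] = MISSING
                sites.append(VariantSite(key=key, site_filter=site_filter))
                dosage_cols.append(dos)
                depth_cols.append(dp)
                qual_cols.append(gq)
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(f"{vcf_path}: malformed VCF record ({exc})") from exc

    if sites:
        dosage = np.stack(dosage_cols, axis=1)
        depth = np.stack(depth_cols, axis=1)
        quality = np.stack(qual_cols, axis=1)
    else:
        dosage = np.zeros((n, 0), dtype=np.int8)
        depth = np.zeros((n, 0), dtype=np.int32)
        quality = np.zeros((n, 0), dtype=np.int32)
    genotypes = GenotypeMatrix(
        sample_ids=samples,
        keys=[s.key for s in sites],
        dosage=dosage,
        depth=depth,
        quality=quality,
    )
    return sites, genotypes, design


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

_FUNCTIONAL = {fc.value: fc for fc in FunctionalClass}
_CONSEQUENCE = {c.value: c for c in Consequence}
_CLINVAR = {c.value: c for c in ClinvarStatus}

_ABSENT_TOKENS = {"", ".", "na", "nan", "none", "absent"}


def _parse_consequence(token: str) -> Consequence:
    """Collapse a possibly multi-valued consequence field to its worst label."""
    parts = [p.strip().lower() for p in str(token).replace("&", ";").replace(",", ";").split(";")]
    parts = [p for p in parts if p and p not in _ABSENT_TOKENS]
    if not parts:
        return Consequence.UNKNOWN
    found = []
    for p in parts:
        if p not in _CONSEQUENCE:
            raise ParseError(f"unparseable consequence token {p!r}")
        found.append(_CONSEQUENCE[p])
    for c in CONSEQUENCE_SEVERITY:  # worst-consequence rule
        if c in found:
            return c
    return found[0]  # only 'unknown' remains


def _parse_clinvar(token) -> ClinvarStatus:
    t = str(token).strip().lower()
    if t in _ABSENT_TOKENS:
        return ClinvarStatus.ABSENT
    if t not in _CLINVAR:
        raise ParseError(f"unparseable clinvar token {token!r}")
    return _CLINVAR[t]


def _parse_lr(token) -> LrCall:
    t = str(token).strip()
    if t.lower() in _ABSENT_TOKENS:
        return LrCall.ABSENT
    t = t.upper()
    if t not in ("D", "T"):
        raise ParseError(f"unparseable lr_call token {token!r}")
    return LrCall(t)


def read_annotations(path, sites: list[VariantSite]) -> list[VariantSite]:
    """Populate annotation fields of ``sites`` from the annotation TSV.

    Sites without a matching row keep their defaults (class ``other``,
    consequence ``unknown``, everything else absent).  Duplicate keys: the
    last row wins, with a logged warning.  One site carries one gene symbol;
    if the table lists several (comma-separated), the first wins, logged.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"chrom", "pos", "ref", "alt"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: annotation table needs columns {sorted(required)}")

    rows: dict[VariantKey, dict] = {}
    for rec in df.to_dict("records"):
        key = VariantKey(rec["chrom"], int(rec["pos"]), rec["ref"], rec["alt"])
        if key in rows:
            logger.warning("duplicate annotation rows for %s; last row wins", key)
        rows[key] = rec

    out = []
    for site in sites:
        rec = rows.get(site.key)
        if rec is None:
            out.append(site)
            continue
        gene = rec.get("gene", "").strip()
        if "," in gene:
            first = gene.split(",")[0].strip()
            logger.warning("site %s lists genes %r; keeping %s", site.key, gene, first)
            gene = first
        fc_token = rec.get("functional_class", "").strip().lower()
        if fc_token and fc_token not in _ABSENT_TOKENS and fc_token not in _FUNCTIONAL:
            raise ParseError(f"unparseable functional_class token {fc_token!r}")
        maf_token = rec.get("ref_maf", "").strip()
        ref_maf = None if maf_token.lower() in _ABSENT_TOKENS else float(maf_token)
        out.append(
            VariantSite(
                key=site.key,
                site_filter=site.site_filter,
                gene=gene.upper(),
                functional_class=_FUNCTIONAL.get(fc_token, FunctionalClass.OTHER),
                consequence=_parse_consequence(rec.get("consequence", "")),
                clinvar=_parse_clinvar(rec.get("clinvar", "")),
                lr_call=_parse_lr(rec.get("lr_call", "")),
                ref_maf=ref_maf,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Reference AF, gene sets, candidate genes
# ---------------------------------------------------------------------------

def read_reference_af(path) -> ReferenceAFTable:
    """Read the public-panel allele-frequency table.

    First line must be ``#panel_size=<int>``; then a TSV with columns
    chrom, pos, ref, alt, af.  Variants absent from the table are frequency 0.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#panel_size="):
            raise ParseError(f"{path}: first line must be '#panel_size=<int>'")
        panel_size = int(header.split("=", 1)[1])
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    af = {}
    for rec in df.itertuples(index=False):
        v = float(rec.af)
        if not (0.0 <= v <= 1.0):
            raise ParseError(f"{path}: allele frequency {v} outside [0,1] at {rec.chrom}:{rec.pos}")
        af[VariantKey(rec.chrom, int(rec.pos), rec.ref, rec.alt)] = v
    return ReferenceAFTable(af=af, panel_size=panel_size)


def read_gene_sets(gmt_path) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, then member genes."""
    sets: dict[str, GeneSet] = {}
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{gmt_path}:{lineno}: GMT line needs name, description and "
                    f"at least one member ({len(fields)} fields found)"
                )
            name, description = fields[0], fields[1]
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            sets[name] = GeneSet(name=name, description=description, genes=genes)
    return GeneSetCollection(sets=sets)


def read_candidate_genes(path) -> frozenset[str]:
    """Known-candidate gene list: one symbol per line, deduplicated, uppercased."""
    with open(path) as fh:
        return frozenset(
            line.strip().upper() for line in fh if line.strip() and not line.startswith("#")
        )


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_table(rows, path) -> None:
    """Write result rows (list of dicts or DataFrame) as TSV.

    Reals are printed with 12 significant digits so a read-back reproduces
    them to that precision; strings and integers round-trip bit-exactly.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Writers for the full input bundle (used by the simulator and round-trips)
# ---------------------------------------------------------------------------

def write_vcf(sites, genotypes: GenotypeMatrix, path) -> None:
    """Emit a minimal VCF v4.2 with GT:DP:GQ, one biallelic record per site."""
    gt_strings = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    filter_strings = {
        SiteFilter.PASS: "PASS",
        SiteFilter.TRANCHE_FAIL: "VQSRTrancheSNP99.00to99.90",
        SiteFilter.OTHER_FAIL: "LowQual",
    }
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FILTER=<ID=VQSRTrancheSNP99.00to99.90,Description="VQSR tranche 99.00-99.90">\n')
        fh.write('##FILTER=<ID=LowQual,Description="Low quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        for chrom in dict.fromkeys(s.key.chrom for s in sites):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        for j, site in enumerate(sites):
            cells = []
            for i in range(len(genotypes.sample_ids)):
                gt = gt_strings[int(genotypes.dosage[i, j])]
                dp = genotypes.depth[i, j]
                gq = genotypes.quality[i, j]
                dp_s = "." if dp == MISSING else str(int(dp))
                gq_s = "." if gq == MISSING else str(int(gq))
                cells.append(f"{gt}:{dp_s}:{gq_s}")
            k = site.key
            fh.write(
                f"{k.chrom}\t{k.pos}\t.\t{k.ref}\t{k.alt}\t100\t"
                f"{filter_strings[site.site_filter]}\t.\tGT:DP:GQ\t" + "\t".join(cells) + "\n"
            )


def write_annotations(sites, path) -> None:
    rows = [
        {
            "chrom": s.key.chrom,
            "pos": s.key.pos,
            "ref": s.key.ref,
            "alt": s.key.alt,
            "gene": s.gene,
            "functional_class": s.functional_class.value,
            "consequence": s.consequence.value,
            "clinvar": s.clinvar.value,
            "lr_call": s.lr_call.value if s.lr_call != LrCall.ABSENT else ".",
            "ref_maf": "." if s.ref_maf is None else f"{s.ref_maf:.12g}",
        }
        for s in sites
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_reference_af(table: ReferenceAFTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#panel_size={table.panel_size}\n")
        fh.write("chrom\tpos\tref\talt\taf\n")
        for key in sorted(table.af):
            fh.write(f"{key.chrom}\t{key.pos}\t{key.ref}\t{key.alt}\t{table.af[key]:.12g}\n")


def write_design(design: CohortDesign, path, sample_order=None) -> None:
    ids = sample_order if sample_order is not None else sorted(design.all_ids)
    with open(path, "w") as fh:
        fh.write("sample_id\trole\tduration_years\n")
        for s in ids:
            role = "case" if s in design.case_ids else "control"
            d = design.duration_years.get(s)
            fh.write(f"{s}\t{role}\t{'' if d is None else f'{d:.12g}'}\n")


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.genes)]) + "\n")


def write_candidate_genes(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")
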