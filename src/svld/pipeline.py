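"""End-to-end SV-SNP LD scan: load, match, pair, estimate, filter, write.

Stages mirror the scan funnel: read both genotype panels, intersect their
samples, read and significance-filter the association table, join
associations to genotyped SNPs by position, enumerate candidate pairs
within the flanking window, tabulate the nine double genotypes per pair,
estimate g^2 with its chi-square LD p-value, and retain pairs at or above
the tag-SNP threshold (g^2 >= 0.80 by default).  The scan is fully
deterministic: identical inputs give a byte-identical catalog.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from svld import gwas as gwas_mod
from svld import pairing as pairing_mod
from svld.errors import SvldError
from svld.ld import g_squared, tabulate_double_genotypes
from svld.variants import GenotypePanel, intersect_samples, sv_span
from svld.vcf_io import read_genotype_vcf

logger = logging.getLogger(__name__)

DEFAULT_MIN_G2 = 0.80

CATALOG_COLUMNS = [
    "sv_id", "sv_chrom", "sv_start", "sv_end", "sv_length",
    "snp_rsid", "snp_pos", "snp_ref", "snp_alt",
    "g_squared", "ld_p_value", "n_samples", "distance_bp",
    "trait", "gwas_p_value", "pubmed_id",
]


@dataclass(frozen=True)
class ScanConfig:
    """All knobs of one scan run.

    The scan itself is deterministic; ``seed`` is carried only for
    downstream consumers that subsample or simulate from the catalog.
    """

    sv_vcf: str
    snp_vcf: str
    gwas_tsv: str
    flank: int = pairing_mod.DEFAULT_FLANK
    min_g2: float = DEFAULT_MIN_G2
    gwas_p_threshold: float = gwas_mod.GENOME_WIDE_SIGNIFICANCE
    include_snps_inside_sv: bool = True
    output: Optional[str] = None
    collapse: bool = False
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_g2 <= 1.0):
            raise ValueError("min_g2 must lie in [0, 1]")
        if not (0.0 < self.gwas_p_threshold <= 1.0):
            raise ValueError("gwas_p_threshold must lie in (0, 1]")
        if self.flank < 0:
            raise ValueError("flank must be non-negative")


@dataclass(frozen=True)
class CatalogEntry:
    """One catalog row: an SV, a genotyped SNP, one trait association, and LD."""

    sv_id: str
    sv_chrom: str
    sv_start: int
    sv_end: int
    sv_length: Optional[int]
    snp_rsid: str
    snp_pos: int
    snp_ref: str
    snp_alt: str
    g_squared: float
    ld_p_value: float
    n_samples: int
    distance_bp: int
    trait: str
    gwas_p_value: float
    pubmed_id: str


@dataclass
class ScanSummary:
    """Stage-by-stage attrition counts of one scan run."""

    svs_read: int = 0
    snps_read: int = 0
    shared_samples: int = 0
    associations_read: int = 0
    significant_associations: int = 0
    matched_snps: int = 0
    unmatched_associations: int = 0
    candidate_pairs: int = 0
    degenerate_pairs: int = 0
    pairs_passing: int = 0
    catalog_rows: int = 0
    unique_svs: int = 0
    unique_snps: int = 0
    unique_traits: int = 0


def run_scan(config: ScanConfig) -> tuple[list[CatalogEntry], ScanSummary]:
    """Execute the full scan and return the catalog plus stage counts."""
    summary = ScanSummary()

    logger.info("stage 1/6: reading genotype panels")
    sv_panel, _ = _stage("read SV VCF", read_genotype_vcf, config.sv_vcf, "SV")
    snp_panel, _ = _stage("read SNP VCF", read_genotype_vcf, config.snp_vcf, "SNP")
    summary.svs_read = sv_panel.n_variants
    summary.snps_read = snp_panel.n_variants

    logger.info("stage 2/6: intersecting samples")
    sv_panel, snp_panel = _stage("intersect samples", intersect_samples, sv_panel, snp_panel)
    summary.shared_samples = sv_panel.n_samples
    logger.info("shared samples: %d", summary.shared_samples)

    logger.info("stage 3/6: reading and filtering associations")
    associations, _ = _stage("read associations", gwas_mod.read_associations, config.gwas_tsv)
    summary.associations_read = len(associations)
    significant = gwas_mod.filter_significant(associations, config.gwas_p_threshold)
    summary.significant_associations = len(significant)
    logger.info(
        "associations: %d read, %d significant at p < %g",
        len(associations), len(significant), config.gwas_p_threshold,
    )

    logger.info("stage 4/6: matching associations to genotyped SNPs")
    matches, unmatched = gwas_mod.attach_genotyped_snp(significant, snp_panel)
    summary.matched_snps = len({m.variant.variant_id for m in matches})
    summary.unmatched_associations = unmatched
    logger.info("matched %d unique SNPs (%d associations unmatched)", summary.matched_snps, unmatched)

    logger.info("stage 5/6: enumerating candidate pairs within +/-%d bp", config.flank)
    pairs = pairing_mod.candidate_pairs(
        sv_panel.variants, matches, config.flank, config.include_snps_inside_sv
    )
    summary.candidate_pairs = len(pairs)
    logger.info("candidate pairs: %d", len(pairs))

    # trait rows per unique SNP, for the final per-trait expansion
    traits_by_snp: dict[str, list[gwas_mod.GwasAssociation]] = {}
    for m in matches:
        traits_by_snp.setdefault(m.variant.variant_id, []).append(m.association)

    logger.info("stage 6/6: estimating g^2 and applying the %g threshold", config.min_g2)
    sv_col = {v.variant_id: j for j, v in enumerate(sv_panel.variants)}
    catalog: list[CatalogEntry] = []
    passing_pairs = 0
    for sv, match in pairs:
        table = tabulate_double_genotypes(
            sv_panel.genotypes_for(sv_col[sv.variant_id]),
            snp_panel.genotypes_for(match.panel_index),
        )
        result = g_squared(table)
        if result.degenerate:
            summary.degenerate_pairs += 1
            logger.debug("degenerate pair %s-%s skipped", sv.variant_id, match.variant.variant_id)
            continue
        if result.g_squared < config.min_g2:
            continue
        passing_pairs += 1
        _, sv_start, sv_end = sv_span(sv)
        distance = pairing_mod.snp_distance_to_sv(sv, match.variant.pos)
        for assoc in traits_by_snp[match.variant.variant_id]:
            catalog.append(
                CatalogEntry(
                    sv_id=sv.variant_id,
                    sv_chrom=sv.chrom,
                    sv_start=sv_start,
                    sv_end=sv_end,
                    sv_length=sv.sv_length,
                    snp_rsid=match.variant.variant_id,
                    snp_pos=match.variant.pos,
                    snp_ref=match.variant.ref_allele,
                    snp_alt=match.variant.alt_allele,
                    g_squared=result.g_squared,
                    ld_p_value=result.p_value,
                    n_samples=int(result.n_samples),
                    distance_bp=distance,
                    trait=assoc.trait,
                    gwas_p_value=assoc.p_value,
                    pubmed_id=assoc.pubmed_id,
                )
            )
    summary.pairs_passing = passing_pairs

    catalog.sort(key=lambda e: (e.sv_chrom, e.sv_start, e.snp_pos, e.trait, e.pubmed_id))
    summary.catalog_rows = len(catalog)
    summary.unique_svs = len({e.sv_id for e in catalog})
    summary.unique_snps = len({e.snp_rsid for e in catalog})
    summary.unique_traits = len({e.trait for e in catalog})
    logger.info(
        "catalog: %d rows, %d pairs passing, %d unique SVs, %d unique SNPs, %d traits",
        summary.catalog_rows, summary.pairs_passing,
        summary.unique_svs, summary.unique_snps, summary.unique_traits,
    )
    if not catalog:
        logger.warning("empty catalog: no pair passed all filters")
    return catalog, summary


def _stage(name, fn, *args):
    try:
        return fn(*args)
    except SvldError as exc:
        raise type(exc)(f"[stage: {name}] {exc}") from exc


def _fmt(value) -> str:
    if value is None:
        return "."
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_catalog(catalog: list[CatalogEntry], path: str, collapse: bool = False) -> None:
    """Write the catalog TSV (fixed header, canonical order, 6 significant digits).

    With ``collapse``, one row per unique (SV, SNP) pair with traits and
    publications concatenated by '|'.
    """
    with open(path, "w") as fh:
        if not collapse:
            fh.write("\t".join(CATALOG_COLUMNS) + "\n")
            for e in catalog:
                fh.write("\t".join(_fmt(getattr(e, c)) for c in CATALOG_COLUMNS) + "\n")
            return
        fh.write("\t".join(CATALOG_COLUMNS[:13] + ["traits", "gwas_p_values", "pubmed_ids"]) + "\n")
        grouped: dict[tuple[str, str], list[CatalogEntry]] = {}
        for e in catalog:
            grouped.setdefault((e.sv_id, e.snp_rsid), []).append(e)
        for entries in grouped.values():
            first = entries[0]
            row = [_fmt(getattr(first, c)) for c in CATALOG_COLUMNS[:13]]
            row.append("|".join(e.trait for e in entries))
            row.append("|".join(_fmt(e.gwas_p_value) for e in entries))
            row.append("|".join(e.pubmed_id for e in entries))
            fh.write("\t".join(row) + "\n")


def read_catalog(path: str) -> list[CatalogEntry]:
    """Read back a (non-collapsed) catalog TSV written by :func:`write_catalog`."""
    entries: list[CatalogEntry] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != CATALOG_COLUMNS:
            raise SvldError(f"unexpected catalog header in {path}")
        for line in fh:
            raw = dict(zip(CATALOG_COLUMNS, line.rstrip("\n").split("\t")))
            entries.append(
                CatalogEntry(
                    sv_id=raw["sv_id"],
                    sv_chrom=raw["sv_chrom"],
                    sv_start=int(raw["sv_start"]),
                    sv_end=int(raw["sv_end"]),
                    sv_length=None if raw["sv_length"] == "." else int(raw["sv_length"]),
                    snp_rsid=raw["snp_rsid"],
                    snp_pos=int(raw["snp_pos"]),
                    snp_ref=raw["snp_ref"],
                    snp_alt=raw["snp_alt"],
                    g_squared=float(raw["g_squared"]),
                    ld_p_value=float(raw["ld_p_value"]),
                    n_samples=int(raw["n_samples"]),
                    distance_bp=int(raw["distance_bp"]),
                    trait=raw["trait"],
                    gwas_p_value=float(raw["gwas_p_value"]),
                    pubmed_id=raw["pubmed_id"],
                )
            )
    return entries
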