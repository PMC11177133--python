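"""GWAS-catalog-style association tables and the genome-wide-significance filter.

Two dialects are recognised by header inspection: the GWAS Catalog
association download (SNPS / CHR_ID / CHR_POS / P-VALUE / DISEASE.TRAIT /
PUBMEDID) and a minimal generic six-column TSV (rsid / chrom / pos /
p_value / trait / pubmed_id, any order).  Rows with unparseable positions
or p-values, and multi-SNP haplotype rows, are dropped and counted.
"""

from __future__ import annotations

import logging
import math
import re
import sys
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from svld.errors import FormatError
from svld.variants import GenotypePanel, VariantRecord

logger = logging.getLogger(__name__)

GENOME_WIDE_SIGNIFICANCE = 5e-8

# column aliases, lower-cased, checked in order
_COLUMN_ALIASES = {
    "rsid": ["snps", "rsid", "snp", "variant_id"],
    "chrom": ["chr_id", "chrom", "chr", "chromosome"],
    "pos": ["chr_pos", "pos", "position", "bp"],
    "p_value": ["p-value", "p_value", "pvalue", "p"],
    "trait": ["disease/trait", "disease.trait", "trait", "phenotype"],
    "pubmed_id": ["pubmedid", "pubmed_id", "pmid", "study"],
    "risk_allele": ["strongest snp-risk allele", "risk_allele"],
}


@dataclass(frozen=True)
class GwasAssociation:
    """One catalog row: a SNP-trait association from one publication."""

    rsid: str
    chrom: str
    pos: int
    p_value: float
    trait: str
    pubmed_id: str
    risk_allele: Optional[str] = None
    p_value_underflow: bool = False


@dataclass
class ParseStats:
    parsed: int = 0
    dropped_bad_position: int = 0
    dropped_bad_pvalue: int = 0
    dropped_multi_snp: int = 0


@dataclass(frozen=True)
class SnpMatch:
    """A GWAS association joined to a genotyped panel SNP by chrom+position."""

    association: GwasAssociation
    variant: VariantRecord
    panel_index: int
    rsid_conflict: bool = False


def normalize_chrom(chrom: str) -> str:
    """Map 'chr10' and '10' to one convention (bare name, no 'chr' prefix)."""
    chrom = str(chrom).strip()
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def _parse_pvalue(raw: object) -> tuple[Optional[float], bool]:
    """Parse a p-value string, flagging subnormal/zero underflow.

    Extreme catalog values like "2E-246" are representable; anything that
    underflows to zero is clamped to the smallest positive normal float and
    flagged.
    """
    try:
        value = float(str(raw).strip())
    except (TypeError, ValueError):
        return None, False
    if math.isnan(value) or value < 0 or value > 1:
        return None, False
    if value == 0.0:
        return sys.float_info.min, True
    return value, False


def _resolve_columns(columns: list[str]) -> dict[str, str]:
    lowered = {c.lower().strip(): c for c in columns}
    resolved = {}
    for canonical, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lowered:
                resolved[canonical] = lowered[alias]
                break
    required = {"rsid", "chrom", "pos", "p_value", "trait", "pubmed_id"}
    missing = required - resolved.keys()
    if missing:
        raise FormatError(
            f"association table is missing required columns: {sorted(missing)}; "
            f"found {columns}"
        )
    return resolved


def read_associations(path: str) -> tuple[list[GwasAssociation], ParseStats]:
    """Parse a GWAS association TSV into typed rows, dropping malformed ones."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = _resolve_columns(list(df.columns))
    stats = ParseStats()
    out: list[GwasAssociation] = []
    for row in df.itertuples(index=False):
        rec = dict(zip(df.columns, row))
        rsid = str(rec[cols["rsid"]]).strip()
        # haplotype rows list several rsIDs joined by 'x' or ';'
        if re.search(r"\s+x\s+|;|,", rsid):
            stats.dropped_multi_snp += 1
            continue
        try:
            pos = int(float(rec[cols["pos"]]))
            if pos < 1:
                raise ValueError
        except (TypeError, ValueError):
            stats.dropped_bad_position += 1
            continue
        p_value, underflow = _parse_pvalue(rec[cols["p_value"]])
        if p_value is None:
            stats.dropped_bad_pvalue += 1
            continue
        out.append(
            GwasAssociation(
                rsid=rsid,
                chrom=normalize_chrom(rec[cols["chrom"]]),
                pos=pos,
                p_value=p_value,
                trait=str(rec[cols["trait"]]).strip(),
                pubmed_id=str(rec[cols["pubmed_id"]]).strip(),
                risk_allele=rec.get(cols.get("risk_allele", ""), None) or None,
                p_value_underflow=underflow,
            )
        )
        stats.parsed += 1
    logger.info(
        "%s: parsed %d associations (dropped %d bad position, %d bad p-value, "
        "%d multi-SNP)",
        path, stats.parsed, stats.dropped_bad_position,
        stats.dropped_bad_pvalue, stats.dropped_multi_snp,
    )
    return out, stats


def filter_significant(
    associations: list[GwasAssociation],
    threshold: float = GENOME_WIDE_SIGNIFICANCE,
) -> list[GwasAssociation]:
    """Retain genome-wide significant rows: p strictly below the threshold."""
    return [a for a in associations if a.p_value < threshold]


def attach_genotyped_snp(
    associations: list[GwasAssociation], panel: GenotypePanel
) -> tuple[list[SnpMatch], int]:
    """Join associations to panel SNPs on (chromosome, 1-based position).

    rsID disagreement between catalog and panel keeps the match but flags
    it.  Returns the matches and the count of unmatched associations.
    """
    index: dict[tuple[str, int], int] = {}
    for j, var in enumerate(panel.variants):
        index[(normalize_chrom(var.chrom), var.pos)] = j
    matches: list[SnpMatch] = []
    unmatched = 0
    for assoc in associations:
        j = index.get((normalize_chrom(assoc.chrom), assoc.pos))
        if j is None:
            unmatched += 1
            continue
        var = panel.variants[j]
        conflict = (
            bool(var.variant_id)
            and var.variant_id.startswith("rs")
            and assoc.rsid.startswith("rs")
            and var.variant_id != assoc.rsid
        )
        matches.append(SnpMatch(assoc, var, j, rsid_conflict=conflict))
    return matches, unmatched
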