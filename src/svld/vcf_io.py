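"""Reading and writing genotype panels as VCF, with biallelic filtering.

Accepts generic VCF 4.2+ with either explicit REF/ALT sequences or symbolic
SV alleles (``<DEL>``, ``<INS>``) plus END/SVLEN INFO annotations — both
dialects seen in long-read SV call sets.  Multi-allelic records are dropped
(and counted); positions are VCF 1-based throughout.  Backed by pysam.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pysam

from svld.errors import FormatError
from svld.variants import (
    GenotypePanel,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    VariantRecord,
)

logger = logging.getLogger(__name__)

# placeholder contig length for writer headers; only ordering matters downstream
_CONTIG_LENGTH = 300_000_000


@dataclass
class ReadStats:
    """Per-file record accounting: retained + dropped categories = scanned."""

    scanned: int = 0
    retained: int = 0
    dropped_multiallelic: int = 0
    dropped_non_diploid: int = 0
    dropped_non_pass: int = 0


def _encode_call(gt: tuple) -> Optional[int]:
    """pysam GT tuple -> genotype code, or None for non-diploid/non-biallelic."""
    if len(gt) != 2:
        return None
    if gt[0] is None or gt[1] is None:
        return MISSING
    if gt[0] > 1 or gt[1] > 1:
        return None
    return int(gt[0]) + int(gt[1])


def read_genotype_vcf(
    path: str,
    kind: Literal["SV", "SNP"],
    region: Optional[tuple[str, int, int]] = None,
    require_pass: bool = False,
) -> tuple[GenotypePanel, ReadStats]:
    """Load a biallelic genotype panel from a VCF file.

    Parameters
    ----------
    path
        Plain or bgzip VCF; an index is required only for ``region`` queries.
    kind
        "SV" extracts span metadata (END / SVLEN INFO keys); "SNP" does not.
    region
        Optional (chrom, start, end) restriction, 1-based inclusive.
    require_pass
        Drop records whose FILTER is set and not PASS (default: retain).
    """
    vcf = pysam.VariantFile(path)
    samples = list(vcf.header.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no sample columns (GT data required)")

    stats = ReadStats()
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []

    if region is not None:
        chrom, start, end = region
        iterator = vcf.fetch(chrom, start - 1, end)
    else:
        iterator = vcf.fetch() if vcf.index is not None else vcf

    for rec in iterator:
        stats.scanned += 1
        if rec.alts is None or len(rec.alts) != 1:
            stats.dropped_multiallelic += 1
            continue
        if require_pass and rec.filter.keys() not in ([], ["PASS"]):
            stats.dropped_non_pass += 1
            continue

        col = np.full(len(samples), MISSING, dtype=np.int8)
        ok = True
        for i, sample in enumerate(samples):
            gt = rec.samples[sample].get("GT")
            if gt is None:
                col[i] = MISSING
                continue
            code = _encode_call(tuple(gt))
            if code is None:
                ok = False
                break
            col[i] = code
        if not ok:
            stats.dropped_non_diploid += 1
            logger.warning("skipping non-diploid/non-biallelic call at %s:%d", rec.chrom, rec.pos)
            continue

        span_end = None
        sv_length = None
        if kind == "SV":
            info = dict(rec.info)
            if "SVLEN" in info:
                raw = info["SVLEN"]
                sv_length = int(raw[0] if isinstance(raw, tuple) else raw)
            # pysam folds INFO/END (and explicit REF length) into rec.stop,
            # 0-based exclusive == 1-based inclusive end
            if rec.stop > rec.pos:
                span_end = rec.stop
        variants.append(
            VariantRecord(
                variant_id=rec.id or f"{rec.chrom}:{rec.pos}",
                chrom=rec.chrom,
                pos=rec.pos,
                ref_allele=rec.ref,
                alt_allele=rec.alts[0],
                kind=kind,
                span_end=span_end,
                sv_length=sv_length,
            )
        )
        columns.append(col)
        stats.retained += 1

    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    logger.info(
        "%s: scanned %d records, retained %d (dropped %d multi-allelic, "
        "%d non-diploid, %d non-PASS)",
        path,
        stats.scanned,
        stats.retained,
        stats.dropped_multiallelic,
        stats.dropped_non_diploid,
        stats.dropped_non_pass,
    )
    return GenotypePanel(samples, variants, calls), stats


def write_genotype_vcf(panel: GenotypePanel, path: str) -> None:
    """Write a panel as a minimal standard-compliant VCF (round-trip safe)."""
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(v.chrom for v in panel.variants):
        header.contigs.add(chrom, length=_CONTIG_LENGTH)
    header.add_line(
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">'
    )
    header.add_line(
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed SV length">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for sample in panel.sample_ids:
        header.add_sample(sample)

    _GT = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(path, "w", header=header) as out:
        for j, var in enumerate(panel.variants):
            rec = out.new_record(
                contig=var.chrom,
                start=var.pos - 1,
                stop=var.span_end if var.span_end is not None else var.pos,
                alleles=(var.ref_allele, var.alt_allele),
                id=var.variant_id,
            )
            if var.span_end is not None:
                rec.stop = var.span_end  # pysam emits INFO/END from this
            if var.sv_length is not None:
                rec.info["SVLEN"] = var.sv_length
            for i, sample in enumerate(panel.sample_ids):
                rec.samples[sample]["GT"] = _GT[int(panel.calls[i, j])]
            out.write(rec)
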