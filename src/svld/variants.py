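"""Biallelic variant sites and per-sample unphased genotype panels.

Genotype calls are stored as small integer codes: ``HOM_REF`` (0), ``HET``
(1), ``HOM_ALT`` (2) and ``MISSING`` (-1).  The code + 1 is the 1/2/3
numeric coding used by the LD estimator, so the two conventions differ by
an affine shift that leaves any correlation unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np

from svld.errors import MalformedRecordError, NoCommonSamplesError

logger = logging.getLogger(__name__)

HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

_CODE_NAMES = {HOM_REF: "hom-ref", HET: "het", HOM_ALT: "hom-alt", MISSING: "missing"}


class NonDiploidError(MalformedRecordError):
    """A genotype call is not diploid (haploid or higher ploidy)."""


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic site (SV or SNP).

    Coordinates are 1-based; ``span_end`` is the 1-based inclusive end of
    the affected reference interval (SVs only).  ``sv_length`` is signed:
    insertions positive, deletions negative.
    """

    variant_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    kind: Literal["SV", "SNP"]
    span_end: Optional[int] = None
    sv_length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: position must be >= 1, got {self.pos}")
        if self.kind == "SV" and self.span_end is not None and self.span_end < self.pos:
            raise ValueError(
                f"{self.variant_id}: span_end {self.span_end} precedes pos {self.pos}"
            )


@dataclass
class GenotypePanel:
    """An ordered sample list, variant list, and samples x variants call matrix."""

    sample_ids: list[str]
    variants: list[VariantRecord]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        expected = (len(self.sample_ids), len(self.variants))
        if self.calls.shape != expected:
            raise ValueError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.calls, [HOM_REF, HET, HOM_ALT, MISSING])
        if bad.any():
            raise ValueError("call matrix contains codes outside {0,1,2,-1}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def genotypes_for(self, variant_index: int) -> np.ndarray:
        """Per-sample genotype codes for one variant (a column view)."""
        return self.calls[:, variant_index]


def encode_genotype(gt_field: str) -> int:
    """Map a diploid VCF GT string to a genotype code.

    Phase separators ``/`` and ``|`` are treated identically (the analysis
    is unphased).  Any missing allele yields MISSING.  Allele indices above
    1 (non-biallelic) and non-diploid calls raise.
    """
    sep = "|" if "|" in gt_field else "/"
    alleles = gt_field.split(sep)
    if len(alleles) != 2:
        raise NonDiploidError(f"non-diploid GT field {gt_field!r}")
    if "." in alleles:
        return MISSING
    try:
        a, b = (int(x) for x in alleles)
    except ValueError as exc:
        raise MalformedRecordError(f"unparseable GT field {gt_field!r}") from exc
    if a > 1 or b > 1 or a < 0 or b < 0:
        raise MalformedRecordError(f"allele index beyond biallelic in GT {gt_field!r}")
    return a + b


def decode_genotype(code: int) -> str:
    """Inverse of :func:`encode_genotype` up to phase: a canonical GT string."""
    return {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}[code]


def sv_span(record: VariantRecord) -> tuple[str, int, int]:
    """The (chrom, start, end) reference interval an SV affects, 1-based inclusive.

    Deletions: end = explicit END annotation if present, else pos + |sv_length|.
    Insertions: a zero-length reference footprint, end = pos.
    """
    if record.kind != "SV":
        raise ValueError(f"{record.variant_id} is not an SV")
    if record.sv_length is not None and record.sv_length > 0:
        # insertion: inserted sequence has no reference footprint
        return (record.chrom, record.pos, record.pos)
    if record.span_end is not None:
        return (record.chrom, record.pos, record.span_end)
    if record.sv_length is not None:
        return (record.chrom, record.pos, record.pos + abs(record.sv_length))
    raise MalformedRecordError(
        f"{record.variant_id}: SV carries neither END nor length information"
    )


def intersect_samples(
    panel_a: GenotypePanel, panel_b: GenotypePanel
) -> tuple[GenotypePanel, GenotypePanel]:
    """Restrict both panels to their shared samples, lexicographically ordered.

    The canonical (sorted) sample order makes downstream output byte-stable
    regardless of input file ordering.
    """
    shared = sorted(set(panel_a.sample_ids) & set(panel_b.sample_ids))
    if not shared:
        raise NoCommonSamplesError("the two panels share no sample IDs")
    if len(shared) < 20:
        logger.warning(
            "only %d shared samples; LD estimates will be noisy", len(shared)
        )

    def subset(panel: GenotypePanel) -> GenotypePanel:
        idx = [panel.sample_ids.index(s) for s in shared]
        return GenotypePanel(
            sample_ids=list(shared),
            variants=list(panel.variants),
            calls=panel.calls[idx, :].copy(),
        )

    return subset(panel_a), subset(panel_b)
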