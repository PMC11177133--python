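"""Physical windows around SV endpoints and candidate SV-SNP pair enumeration.

The window for an SV spanning [start, end] with flank f is the closed
1-based interval [max(1, start - f), end + f]; the default flank of
100 kbp approximates the physical distance over which r^2 around a causal
site typically decays below ~0.2 in large human populations.  SNPs inside
the SV body itself are inside the window (optionally excludable, since LD
with a SNP removed by a deletion can be an artefact).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from svld.gwas import SnpMatch, normalize_chrom
from svld.variants import VariantRecord, sv_span

DEFAULT_FLANK = 100_000


@dataclass(frozen=True)
class WindowSpec:
    """A closed 1-based interval around one SV's endpoints."""

    chrom: str
    start: int
    end: int
    flank: int

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ValueError("flank must be non-negative")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid window [{self.start}, {self.end}]")

    def contains(self, chrom: str, pos: int) -> bool:
        return (
            normalize_chrom(chrom) == normalize_chrom(self.chrom)
            and self.start <= pos <= self.end
        )


def sv_window(record: VariantRecord, flank: int = DEFAULT_FLANK) -> WindowSpec:
    """The closed interval [max(1, span_start - flank), span_end + flank]."""
    chrom, start, end = sv_span(record)
    return WindowSpec(chrom=chrom, start=max(1, start - flank), end=end + flank, flank=flank)


def candidate_pairs(
    svs: Iterable[VariantRecord],
    snps: Iterable[SnpMatch],
    flank: int = DEFAULT_FLANK,
    include_snps_inside_sv: bool = True,
) -> list[tuple[VariantRecord, SnpMatch]]:
    """Enumerate (SV, SNP) pairs with the SNP inside the SV's window.

    Each unique (SV id, SNP id) pair appears once regardless of how many
    trait rows the SNP carries.  Implemented as a per-chromosome sorted
    sweep (binary search on SNP positions), sub-quadratic in the input
    sizes; output order is canonical (chrom, SV position, SNP position)
    and independent of input ordering.
    """
    # one representative SnpMatch per unique panel SNP
    snp_by_id: dict[str, SnpMatch] = {}
    for m in sorted(snps, key=lambda m: (m.variant.chrom, m.variant.pos, m.variant.variant_id)):
        snp_by_id.setdefault(m.variant.variant_id, m)

    by_chrom: dict[str, list[SnpMatch]] = {}
    for m in snp_by_id.values():
        by_chrom.setdefault(normalize_chrom(m.variant.chrom), []).append(m)
    positions: dict[str, np.ndarray] = {}
    for chrom, ms in by_chrom.items():
        ms.sort(key=lambda m: (m.variant.pos, m.variant.variant_id))
        positions[chrom] = np.array([m.variant.pos for m in ms], dtype=np.int64)

    pairs: list[tuple[VariantRecord, SnpMatch]] = []
    for sv in sorted(svs, key=lambda v: (normalize_chrom(v.chrom), v.pos, v.variant_id)):
        window = sv_window(sv, flank)
        chrom = normalize_chrom(window.chrom)
        if chrom not in positions:
            continue
        pos = positions[chrom]
        lo = int(np.searchsorted(pos, window.start, side="left"))
        hi = int(np.searchsorted(pos, window.end, side="right"))
        _, body_start, body_end = sv_span(sv)
        for m in by_chrom[chrom][lo:hi]:
            if not include_snps_inside_sv and body_start <= m.variant.pos <= body_end:
                continue
            pairs.append((sv, m))
    return pairs


def snp_distance_to_sv(sv: VariantRecord, snp_pos: int) -> int:
    """Distance (bp) from a SNP to the nearest SV endpoint; 0 inside the SV body."""
    _, start, end = sv_span(sv)
    if start <= snp_pos <= end:
        return 0
    return start - snp_pos if snp_pos < start else snp_pos - end


def windows_to_bed(svs: Iterable[VariantRecord], flank: int, path: str) -> None:
    """Export SV windows as BED (0-based half-open conversion at this boundary)."""
    with open(path, "w") as fh:
        for sv in svs:
            w = sv_window(sv, flank)
            fh.write(f"{w.chrom}\t{w.start - 1}\t{w.end}\t{sv.variant_id}\n")
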