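"""Synthetic fixtures: diploid panels with controlled two-locus LD.

Emulates the study conditions of a small long-read SV panel: a diploid
panel of 32 individuals (the HGSVC sample scale) genotyped at SV and SNP
sites, with planted SV-SNP pairs at a chosen haplotype r^2, plus a
GWAS-catalog-style association table mixing genome-wide-significant and
sub-threshold rows.  Haplotypes are drawn by random union of gametes, so
the panel is in Hardy-Weinberg equilibrium in expectation and the sampled
genotypic g^2 is a consistent estimator of the planted r^2.

Truth labels in the fixture's truth table are computed from the realized
genotypes, not the intended parameters, so end-to-end comparisons are
exact even for sampled pairs.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from svld.errors import FeasibilityError, FixtureError
from svld.gwas import GENOME_WIDE_SIGNIFICANCE
from svld.ld import (
    GenotypeCountTable,
    HaplotypeFrequencies,
    g_squared,
    tabulate_double_genotypes,
)
from svld.pairing import DEFAULT_FLANK, snp_distance_to_sv, sv_window
from svld.pipeline import DEFAULT_MIN_G2
from svld.variants import GenotypePanel, VariantRecord
from svld.vcf_io import write_genotype_vcf

DEFAULT_N_DIPLOID = 32

TRUTH_COLUMNS = ["sv_id", "snp_rsid", "in_catalog", "excluded_by", "realized_g2"]

# Integer double-genotype table whose exact rational g^2 is 4/5: the family
# (4,0,0,1,k,1,0,0,4) has g^2 = 4/5 for every k >= 0; k=22 gives N=32.
_BOUNDARY_FLAT = (4, 0, 0, 1, 22, 1, 0, 0, 4)


def boundary_table(n_diploid: int = DEFAULT_N_DIPLOID) -> GenotypeCountTable:
    """An integer table with g^2 exactly at the 0.80 tag-SNP threshold."""
    k = n_diploid - 10
    if k < 0:
        raise FeasibilityError("boundary table needs at least 10 diploids")
    flat = list(_BOUNDARY_FLAT)
    flat[4] = k
    return GenotypeCountTable.from_flat(flat)


def freqs_from_target(p: float, q: float, r2: float) -> HaplotypeFrequencies:
    """Haplotype frequencies with given allele frequencies and (positive-D) r^2.

    Solves |D| = r * sqrt(p(1-p)q(1-q)) with r = +sqrt(r2) and h11 = p*q + D,
    preferring positive coupling (D > 0) and falling back to negative D when
    only that sign is feasible for (p, q).  Raises
    :class:`FeasibilityError`, naming the admissible r^2 range, when neither
    sign fits.
    """
    if not (0 < p < 1 and 0 < q < 1):
        raise FeasibilityError(f"allele frequencies must be in (0,1), got p={p}, q={q}")
    if not (0 <= r2 <= 1):
        raise FeasibilityError(f"r2 must be in [0,1], got {r2}")
    d = math.sqrt(r2) * math.sqrt(p * (1 - p) * q * (1 - q))
    d_pos_max = min(p * (1 - q), (1 - p) * q)
    d_neg_max = min(p * q, (1 - p) * (1 - q))
    if d <= d_pos_max + 1e-12:
        d = min(d, d_pos_max)
    elif d <= d_neg_max + 1e-12:
        d = -min(d, d_neg_max)
    else:
        var = p * (1 - p) * q * (1 - q)
        r2_max = max(d_pos_max, d_neg_max) ** 2 / var
        raise FeasibilityError(
            f"r2={r2} infeasible for p={p}, q={q}; "
            f"admissible r2 range is [0, {r2_max:.6g}]"
        )
    # clamp float dust so the frequencies form a valid probability vector
    h = np.array([p * q + d, p * (1 - q) - d, (1 - p) * q - d, (1 - p) * (1 - q) + d])
    h = np.clip(h, 0.0, 1.0)
    h = h / h.sum()
    return HaplotypeFrequencies(*h)


def flip_coupling(freqs: HaplotypeFrequencies) -> HaplotypeFrequencies:
    """Swap the SNP allele labels (B1 <-> B2), negating D; r^2 is unchanged."""
    return HaplotypeFrequencies(freqs.h12, freqs.h11, freqs.h22, freqs.h21)


def simulate_panel(
    freqs: HaplotypeFrequencies, n_diploid: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw two aligned unphased genotype vectors for ``n_diploid`` samples.

    2*n haplotypes are drawn i.i.d. from the four-haplotype distribution and
    paired consecutively into diploids (random union of gametes, hence HWE);
    the unphased genotype at each site is the count of alternate alleles.
    """
    if n_diploid < 2:
        raise ValueError("need at least two diploids")
    haps = rng.choice(4, size=2 * n_diploid, p=freqs.as_array())
    # haplotype k carries SV allele k//2 and SNP allele k%2 (0 = reference)
    sv_alleles = (haps // 2).reshape(n_diploid, 2).sum(axis=1)
    snp_alleles = (haps % 2).reshape(n_diploid, 2).sum(axis=1)
    return sv_alleles.astype(np.int8), snp_alleles.astype(np.int8)


def genotypes_from_table(
    table: GenotypeCountTable, rng: Optional[np.random.Generator] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Expand an integer count table into aligned genotype vectors.

    Sample order is shuffled when an rng is given; order never affects any
    LD statistic.
    """
    c = np.round(table.counts).astype(int)
    sv = np.repeat(np.repeat([0, 1, 2], 3), c.ravel())
    snp = np.repeat(np.tile([0, 1, 2], 3), c.ravel())
    if rng is not None:
        perm = rng.permutation(sv.size)
        sv, snp = sv[perm], snp[perm]
    return sv.astype(np.int8), snp.astype(np.int8)


@dataclass(frozen=True)
class PlantedPair:
    """Specification of one planted SV-SNP pair in a fixture.

    ``offset_bp`` is the SNP's distance beyond the SV endpoint (may exceed
    the flank to plant a window negative); ``gwas_p`` may exceed the
    significance threshold to plant a filter negative.  ``exact_g2`` routes
    the pair through a deterministic expected-count genotype table (only
    0.0, 0.8 and 1.0 are constructible exactly); otherwise genotypes are
    sampled at ``target_r2``.  ``monomorphic`` plants a degenerate SV.
    """

    sv_id: str
    chrom: str
    sv_pos: int
    sv_length: int  # signed: insertions positive, deletions negative
    snp_rsid: str
    offset_bp: int
    target_r2: float = 0.9
    p: float = 0.5
    q: float = 0.5
    gwas_p: float = 1e-12
    trait: str = "synthetic trait"
    pubmed_id: str = "00000000"
    exact_g2: Optional[float] = None
    monomorphic: bool = False
    negative_coupling: bool = False

    @property
    def sv_type(self) -> Literal["DEL", "INS"]:
        return "INS" if self.sv_length > 0 else "DEL"

    @property
    def sv_end(self) -> int:
        return self.sv_pos if self.sv_length > 0 else self.sv_pos + abs(self.sv_length)

    @property
    def snp_pos(self) -> int:
        return self.sv_end + self.offset_bp


def _exact_table(pair: PlantedPair, n: int) -> GenotypeCountTable:
    if pair.exact_g2 == 0.8:
        return boundary_table(n)
    if pair.exact_g2 == 1.0:
        half = n // 2
        return GenotypeCountTable.from_flat((half, 0, 0, 0, 0, 0, 0, 0, n - half))
    if pair.exact_g2 == 0.0:
        if n % 16:
            raise FixtureError("exact independence table needs n divisible by 16")
        u = n // 16
        return GenotypeCountTable.from_flat((u, 2 * u, u, 2 * u, 4 * u, 2 * u, u, 2 * u, u))
    raise FixtureError(f"no exact construction for g^2 = {pair.exact_g2}")


def _pair_genotypes(
    pair: PlantedPair, n_diploid: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    if pair.monomorphic:
        sv = np.zeros(n_diploid, dtype=np.int8)
        freqs = freqs_from_target(pair.p, pair.q, 0.0)
        _, snp = simulate_panel(freqs, n_diploid, rng)
        return sv, snp
    if pair.exact_g2 is not None:
        return genotypes_from_table(_exact_table(pair, n_diploid), rng)
    freqs = freqs_from_target(pair.p, pair.q, pair.target_r2)
    if pair.negative_coupling:
        freqs = flip_coupling(freqs)
    return simulate_panel(freqs, n_diploid, rng)


def build_fixture(
    pairs: list[PlantedPair],
    out_dir: str,
    n_diploid: int = DEFAULT_N_DIPLOID,
    seed: int = 0,
    flank: int = DEFAULT_FLANK,
    min_g2: float = DEFAULT_MIN_G2,
    gwas_p_threshold: float = GENOME_WIDE_SIGNIFICANCE,
) -> dict[str, str]:
    """Write a self-contained fixture: SV VCF, SNP VCF, GWAS TSV, truth TSV.

    The truth table lists, for every planted pair, whether it belongs in
    the scan catalog and otherwise the first filter that excludes it
    (window / gwas-p / degenerate / g2), judged from the realized genotypes
    at the stated flank, significance and g^2 thresholds.  Returns the four
    file paths keyed by role.
    """
    seen: dict[str, list[tuple[int, int]]] = {}
    for pair in pairs:
        spans = seen.setdefault(pair.chrom, [])
        w = (pair.sv_pos - flank - 1, max(pair.sv_end, pair.snp_pos) + flank + 1)
        if any(not (w[1] < a or b < w[0]) for a, b in spans):
            raise FixtureError(
                f"{pair.sv_id}: planted coordinates collide on {pair.chrom} "
                "(windows must be disjoint per chromosome)"
            )
        spans.append(w)

    rng = np.random.default_rng(seed)
    samples = [f"NA{20000 + i:05d}" for i in range(n_diploid)]
    sv_records: list[VariantRecord] = []
    snp_records: list[VariantRecord] = []
    sv_cols: list[np.ndarray] = []
    snp_cols: list[np.ndarray] = []
    gwas_rows: list[dict] = []
    truth_rows: list[dict] = []

    for pair in pairs:
        sv_gt, snp_gt = _pair_genotypes(pair, n_diploid, rng)
        if pair.sv_type == "DEL":
            sv_rec = VariantRecord(
                pair.sv_id, pair.chrom, pair.sv_pos, "N", "<DEL>", "SV",
                span_end=pair.sv_end, sv_length=pair.sv_length,
            )
        else:
            sv_rec = VariantRecord(
                pair.sv_id, pair.chrom, pair.sv_pos, "N", "<INS>", "SV",
                sv_length=pair.sv_length,
            )
        snp_rec = VariantRecord(
            pair.snp_rsid, pair.chrom, pair.snp_pos, "A", "G", "SNP"
        )
        sv_records.append(sv_rec)
        snp_records.append(snp_rec)
        sv_cols.append(sv_gt)
        snp_cols.append(snp_gt)
        gwas_rows.append(
            {
                "rsid": pair.snp_rsid,
                "chrom": pair.chrom,
                "pos": pair.snp_pos,
                "p_value": f"{pair.gwas_p:G}",
                "trait": pair.trait,
                "pubmed_id": pair.pubmed_id,
            }
        )

        # truth from realized genotypes, first failing filter wins
        in_window = sv_window(sv_rec, flank).contains(pair.chrom, pair.snp_pos)
        result = g_squared(tabulate_double_genotypes(sv_gt, snp_gt))
        if not in_window:
            verdict, label = False, "window"
        elif not (pair.gwas_p < gwas_p_threshold):
            verdict, label = False, "gwas-p"
        elif result.degenerate:
            verdict, label = False, "degenerate"
        elif result.g_squared < min_g2:
            verdict, label = False, "g2"
        else:
            verdict, label = True, "."
        truth_rows.append(
            {
                "sv_id": pair.sv_id,
                "snp_rsid": pair.snp_rsid,
                "in_catalog": "1" if verdict else "0",
                "excluded_by": label,
                "realized_g2": "." if result.degenerate else f"{result.g_squared:.6g}",
            }
        )

    order = sorted(range(len(pairs)), key=lambda i: (pairs[i].chrom, pairs[i].sv_pos))
    sv_panel = GenotypePanel(
        samples, [sv_records[i] for i in order],
        np.stack([sv_cols[i] for i in order], axis=1),
    )
    snp_panel = GenotypePanel(
        samples, [snp_records[i] for i in order],
        np.stack([snp_cols[i] for i in order], axis=1),
    )

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "sv_vcf": os.path.join(out_dir, "svs.vcf"),
        "snp_vcf": os.path.join(out_dir, "snps.vcf"),
        "gwas_tsv": os.path.join(out_dir, "gwas.tsv"),
        "truth_tsv": os.path.join(out_dir, "truth.tsv"),
    }
    write_genotype_vcf(sv_panel, paths["sv_vcf"])
    write_genotype_vcf(snp_panel, paths["snp_vcf"])
    with open(paths["gwas_tsv"], "w") as fh:
        fh.write("rsid\tchrom\tpos\tp_value\ttrait\tpubmed_id\n")
        for row in sorted(gwas_rows, key=lambda r: (r["chrom"], r["pos"])):
            fh.write(
                f"{row['rsid']}\t{row['chrom']}\t{row['pos']}\t{row['p_value']}\t"
                f"{row['trait']}\t{row['pubmed_id']}\n"
            )
    with open(paths["truth_tsv"], "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for i in order:
            row = truth_rows[i]
            fh.write("\t".join(row[c] for c in TRUTH_COLUMNS) + "\n")
    return paths


def default_planted_pairs() -> list[PlantedPair]:
    """A standard fixture exercising every filter of the scan funnel.

    Positives and negatives across the window, significance and g^2
    filters, one degenerate (monomorphic) SV, one exact tag-SNP-threshold
    boundary pair, one perfect-LD pair, and one negatively coupled pair.
    Chromosomal layout keeps every planted window disjoint.
    """
    pairs: list[PlantedPair] = []
    # clear positives: strong LD, significant, inside window
    for i in range(4):
        pairs.append(
            PlantedPair(
                sv_id=f"SV{100 + i}", chrom="1", sv_pos=1_000_000 + i * 600_000,
                sv_length=-5_000 if i % 2 == 0 else 384,
                snp_rsid=f"rs{1000 + i}", offset_bp=40_000 + 5_000 * i,
                target_r2=1.0, gwas_p=1e-12,
                trait=f"trait {i % 3}", pubmed_id=f"3000000{i}",
            )
        )
    # exact boundary: g^2 exactly at the 0.80 threshold -> included
    pairs.append(
        PlantedPair(
            sv_id="SV200", chrom="2", sv_pos=2_000_000, sv_length=-1_000,
            snp_rsid="rs2000", offset_bp=10_000, exact_g2=0.8, gwas_p=4e-14,
            trait="rheumatoid arthritis-like trait", pubmed_id="30000010",
        )
    )
    # negative coupling positive (allele-relabel invariance end to end)
    pairs.append(
        PlantedPair(
            sv_id="SV201", chrom="2", sv_pos=3_200_000, sv_length=207,
            snp_rsid="rs2001", offset_bp=25_000, target_r2=1.0,
            negative_coupling=True, gwas_p=2e-36,
            trait="multiple sclerosis-like trait", pubmed_id="30000011",
        )
    )
    # window negatives: SNP beyond the flank
    pairs.append(
        PlantedPair(
            sv_id="SV300", chrom="3", sv_pos=1_500_000, sv_length=-2_000,
            snp_rsid="rs3000", offset_bp=150_000, target_r2=1.0, gwas_p=1e-12,
        )
    )
    # significance negative: sub-threshold p (suggestive association)
    pairs.append(
        PlantedPair(
            sv_id="SV301", chrom="3", sv_pos=3_000_000, sv_length=-2_000,
            snp_rsid="rs3001", offset_bp=20_000, target_r2=1.0, gwas_p=9.13e-7,
            trait="cognitive function-like trait",
        )
    )
    # boundary significance negative: p exactly at 5e-8 (strict '<' excludes)
    pairs.append(
        PlantedPair(
            sv_id="SV302", chrom="3", sv_pos=4_500_000, sv_length=-2_000,
            snp_rsid="rs3002", offset_bp=20_000, target_r2=1.0, gwas_p=5e-8,
        )
    )
    # low-LD negative: exact independence table
    pairs.append(
        PlantedPair(
            sv_id="SV400", chrom="4", sv_pos=1_000_000, sv_length=-3_000,
            snp_rsid="rs4000", offset_bp=30_000, exact_g2=0.0, gwas_p=1e-12,
        )
    )
    # degenerate: monomorphic SV
    pairs.append(
        PlantedPair(
            sv_id="SV401", chrom="4", sv_pos=2_500_000, sv_length=-800,
            snp_rsid="rs4001", offset_bp=15_000, monomorphic=True, gwas_p=1e-12,
        )
    )
    return pairs
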