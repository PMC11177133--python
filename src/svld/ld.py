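"""Genotypic linkage disequilibrium (g^2) from unphased two-site genotype data.

For two biallelic loci — an SV with alleles A1/A2 and a SNP with alleles
B1/B2 — each diploid individual falls into one of nine double-genotype
categories.  Coding the three genotypes at each locus numerically
(A1A1=1, A1A2=2, A2A2=3 and likewise for B), the genotypic squared
correlation

    g^2 = [mu_XY - mu_X*mu_Y]^2 / ([mu_X2 - mu_X^2] * [mu_Y2 - mu_Y^2])

is the squared Pearson correlation of the coded genotypes.  It is computed
directly on unphased data — no gametic phasing step — and equals the
standard haplotype-level r^2 under Hardy-Weinberg equilibrium, which this
module also provides as an independent reference quantity.

Internally g^2 is evaluated through the N-scaled sum identity

    (N*S_XY - S_X*S_Y)^2 / ((N*S_X2 - S_X^2) * (N*S_Y2 - S_Y^2))

where S_* are the unnormalised weighted sums over the nine cells.  For
integer count tables every term is an exactly representable integer, so the
result is a single correctly rounded division — tables whose exact rational
g^2 equals e.g. 4/5 evaluate to the float 0.8 exactly, which keeps threshold
comparisons at the tag-SNP cutoff free of rounding artefacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from svld.errors import (
    AlignmentError,
    DegenerateError,
    InternalConsistencyError,
    NoDataError,
)
from svld.variants import HET, HOM_ALT, HOM_REF, MISSING

# numeric genotype coding: hom-ref=1, het=2, hom-alt=3
_DOSAGE = np.array([1.0, 2.0, 3.0])

# clamping band: excursions beyond [0,1] by at most this much are floating error
_CLAMP_TOL = 1e-12


@dataclass(frozen=True)
class GenotypeCountTable:
    """The 3x3 table of the nine double-genotype counts for one SV-SNP pair.

    ``counts[i, j]`` is the number of individuals with SV genotype ``i``
    (0=A1A1, 1=A1A2, 2=A2A2) and SNP genotype ``j`` (0=B1B1, 1=B1B2,
    2=B2B2); in the flat x1..x9 convention, x1=counts[0,0], x2=counts[0,1],
    ..., x9=counts[2,2].  Real-valued (expected) tables are permitted: all
    moment formulas are linear in the cells.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=float)
        if arr.shape != (3, 3):
            raise ValueError(f"count table must be 3x3, got shape {arr.shape}")
        if np.any(arr < 0):
            raise ValueError("double-genotype counts must be non-negative")
        object.__setattr__(self, "counts", arr)

    @classmethod
    def from_flat(cls, x: "list[float] | tuple | np.ndarray") -> "GenotypeCountTable":
        """Build from the flat (x1, ..., x9) row-major vector."""
        x = np.asarray(x, dtype=float)
        if x.shape != (9,):
            raise ValueError("flat table must have exactly nine cells")
        return cls(x.reshape(3, 3))

    @property
    def n_total(self) -> float:
        """N = sum of the nine cells."""
        return float(self.counts.sum())

    @property
    def sv_marginals(self) -> np.ndarray:
        """Counts of the three SV genotypes (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def snp_marginals(self) -> np.ndarray:
        """Counts of the three SNP genotypes (column sums)."""
        return self.counts.sum(axis=0)

    def transpose(self) -> "GenotypeCountTable":
        """Swap the SV and SNP roles."""
        return GenotypeCountTable(self.counts.T.copy())


@dataclass(frozen=True)
class DosageMoments:
    """Sample moments of the 1/2/3-coded genotypes (X = SV, Y = SNP)."""

    mu_XY: float
    mu_X: float
    mu_Y: float
    mu_X2: float
    mu_Y2: float


@dataclass(frozen=True)
class LDResult:
    """g^2, sample count, LD p-value and degeneracy status for one pair.

    ``g_squared`` and ``p_value`` are NaN when ``degenerate`` is set (either
    site monomorphic among the counted samples).
    """

    g_squared: float
    n_samples: float
    p_value: float
    degenerate: bool


@dataclass(frozen=True)
class HaplotypeFrequencies:
    """Frequencies of the four two-locus haplotypes A1B1/A1B2/A2B1/A2B2.

    ``p`` and ``q`` are the A1 and B1 allele frequencies; ``D`` the gametic
    disequilibrium coefficient h11*h22 - h12*h21.
    """

    h11: float
    h12: float
    h21: float
    h22: float

    def __post_init__(self) -> None:
        hs = (self.h11, self.h12, self.h21, self.h22)
        if any(h < -1e-12 or h > 1 + 1e-12 for h in hs):
            raise ValueError(f"haplotype frequencies outside [0,1]: {hs}")
        if abs(sum(hs) - 1.0) >= 1e-12:
            raise ValueError(f"haplotype frequencies must sum to 1, got {sum(hs)}")

    @property
    def p(self) -> float:
        return self.h11 + self.h12

    @property
    def q(self) -> float:
        return self.h11 + self.h21

    @property
    def D(self) -> float:
        return self.h11 * self.h22 - self.h12 * self.h21

    def as_array(self) -> np.ndarray:
        return np.array([self.h11, self.h12, self.h21, self.h22])


def tabulate_double_genotypes(
    sv_genotypes: np.ndarray, snp_genotypes: np.ndarray
) -> GenotypeCountTable:
    """Count the nine double genotypes over samples non-missing at both sites.

    Parameters
    ----------
    sv_genotypes, snp_genotypes
        Aligned per-sample genotype codes (HOM_REF/HET/HOM_ALT/MISSING),
        identical length and sample order.

    Raises
    ------
    AlignmentError
        if the two vectors differ in length.
    NoDataError
        if no sample is called at both sites.
    """
    a = np.asarray(sv_genotypes)
    b = np.asarray(snp_genotypes)
    if a.shape != b.shape or a.ndim != 1:
        raise AlignmentError(
            f"genotype vectors must be aligned 1-D arrays, got {a.shape} vs {b.shape}"
        )
    keep = (a != MISSING) & (b != MISSING)
    a, b = a[keep], b[keep]
    if a.size == 0:
        raise NoDataError("no sample is genotyped at both sites")
    counts = np.zeros((3, 3))
    np.add.at(counts, (a.astype(int), b.astype(int)), 1.0)
    return GenotypeCountTable(counts)


def _weighted_sums(table: GenotypeCountTable) -> tuple[float, ...]:
    """Unnormalised sums (N, S_X, S_Y, S_XY, S_X2, S_Y2) over the nine cells."""
    c = table.counts
    n = c.sum()
    s_x = float(c.sum(axis=1) @ _DOSAGE)
    s_y = float(c.sum(axis=0) @ _DOSAGE)
    s_xy = float(_DOSAGE @ c @ _DOSAGE)
    s_x2 = float(c.sum(axis=1) @ _DOSAGE**2)
    s_y2 = float(c.sum(axis=0) @ _DOSAGE**2)
    return float(n), s_x, s_y, s_xy, s_x2, s_y2


def dosage_moments(table: GenotypeCountTable) -> DosageMoments:
    """The five sample moments mu_XY, mu_X, mu_Y, mu_X2, mu_Y2 of the coded genotypes."""
    n, s_x, s_y, s_xy, s_x2, s_y2 = _weighted_sums(table)
    if n == 0:
        raise NoDataError("cannot compute moments of an empty table")
    return DosageMoments(
        mu_XY=s_xy / n, mu_X=s_x / n, mu_Y=s_y / n, mu_X2=s_x2 / n, mu_Y2=s_y2 / n
    )


def g_squared(table: GenotypeCountTable) -> LDResult:
    """Genotypic squared correlation g^2 with its chi-square LD p-value.

    Monomorphic sites (zero dosage variance) yield a degenerate result with
    NaN g^2/p-value rather than an exception, so a scan can skip the pair.
    Values escaping [0,1] by at most 1e-12 are clamped; larger excursions
    raise :class:`InternalConsistencyError`.
    """
    n, s_x, s_y, s_xy, s_x2, s_y2 = _weighted_sums(table)
    if n == 0:
        raise NoDataError("cannot estimate LD from an empty table")
    var_x = n * s_x2 - s_x * s_x
    var_y = n * s_y2 - s_y * s_y
    if var_x <= 0 or var_y <= 0:
        return LDResult(math.nan, n, math.nan, degenerate=True)
    cov = n * s_xy - s_x * s_y
    g2 = (cov * cov) / (var_x * var_y)
    if g2 > 1.0:
        if g2 > 1.0 + _CLAMP_TOL:
            raise InternalConsistencyError(f"g^2 = {g2} exceeds 1 beyond tolerance")
        g2 = 1.0
    return LDResult(g2, n, ld_pvalue_from(g2, n), degenerate=False)


def ld_pvalue(result: LDResult) -> float:
    """P-value for the null g^2 = 0: N*g^2 referred to chi-square with 1 df."""
    if result.degenerate:
        return math.nan
    return ld_pvalue_from(result.g_squared, result.n_samples)


def ld_pvalue_from(g2: float, n: float) -> float:
    """Chi-square(1 df) upper-tail probability of the statistic N*g^2."""
    return float(stats.chi2.sf(n * g2, df=1))


def haplotype_r_squared(freqs: HaplotypeFrequencies) -> float:
    """Standard haplotype-level r^2 = D^2 / (p(1-p) q(1-q))."""
    p, q = freqs.p, freqs.q
    denom = p * (1 - p) * q * (1 - q)
    if denom <= 0:
        raise DegenerateError(f"monomorphic locus (p={p}, q={q}): r^2 undefined")
    r2 = freqs.D**2 / denom
    return min(r2, 1.0) if r2 <= 1.0 + _CLAMP_TOL else r2


def hwe_expected_table(freqs: HaplotypeFrequencies, n: float) -> GenotypeCountTable:
    """Expected double-genotype counts under random union of gametes.

    Each diploid is the union of two independent haplotype draws, so the
    probability of double genotype (i, j) aggregates the ordered haplotype
    pairs whose allele sums give SV genotype i and SNP genotype j, e.g.
    P(A1A2, B1B2) = 2*(h11*h22 + h12*h21).
    """
    h = freqs.as_array()
    # haplotype k carries SV allele k//2 (0=A1) and SNP allele k%2 (0=B1)
    pair = np.outer(h, h)
    probs = np.zeros((3, 3))
    for k in range(4):
        for m in range(4):
            i = (k // 2) + (m // 2)  # count of A2 alleles -> genotype index
            j = (k % 2) + (m % 2)
            probs[i, j] += pair[k, m]
    return GenotypeCountTable(n * probs)


def dosage_pearson_oracle(table: GenotypeCountTable) -> float:
    """Brute-force reference for g^2: expand to per-individual dosage pairs.

    Expands the table to N explicit (X, Y) pairs (integer tables only),
    computes the textbook Pearson correlation sum formula and squares it.
    Kept deliberately independent of :func:`g_squared`'s code path.
    """
    c = table.counts
    if not np.allclose(c, np.round(c)):
        raise ValueError("oracle expansion requires an integer count table")
    xs: list[float] = []
    ys: list[float] = []
    for i in range(3):
        for j in range(3):
            xs.extend([i + 1.0] * int(round(c[i, j])))
            ys.extend([j + 1.0] * int(round(c[i, j])))
    n = len(xs)
    if n < 2:
        raise NoDataError("oracle needs at least two individuals")
    x = np.array(xs)
    y = np.array(ys)
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    den = (n * sxx - sx * sx) * (n * syy - sy * sy)
    if den <= 0:
        raise DegenerateError("monomorphic site: correlation undefined")
    r = (n * sxy - sx * sy) / math.sqrt(den)
    return r * r
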