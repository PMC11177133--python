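# Methods

## Model and estimator

`svld` estimates pairwise linkage disequilibrium between a structural
variant (SV) and a SNP from **unphased** diploid genotypes. Both sites must
be biallelic. Each individual contributes one of nine double genotypes;
with genotypes coded 1/2/3 (hom-ref/het/hom-alt) at each site, the
genotypic squared correlation g² is the squared Pearson correlation of the
coded genotypes. Working on genotypes rather than inferred haplotypes
avoids propagating phasing/imputation error into the LD estimate; the cost
is that g² is a genotypic correlation, which coincides with the gametic
r² = D²/(p(1−p)q(1−q)) exactly when genotype frequencies follow
Hardy–Weinberg proportions (random union of gametes). The package carries
both quantities — `g_squared` on count tables and `haplotype_r_squared` on
haplotype frequencies — and the test suite checks the identity
g²(HWE-expected table) = r² to 1e-10 across random frequency vectors.

The 1/2/3 coding is an affine shift of the usual 0/1/2 alternate-allele
dosage; Pearson correlation is affine-invariant, so both conventions give
identical g². Tests assert the related invariances directly: table
transposition (swapping SV/SNP roles) and allele relabeling at either locus
(reversing the 3×3 table's rows or columns) leave g² unchanged.

### Numerical evaluation

g² is evaluated through the N-scaled sum identity

    g² = (N·S_XY − S_X·S_Y)² / ((N·S_X² − S_X²)(N·S_Y² − S_Y²))

with S the unnormalised weighted cell sums. This is algebraically the
moment formula multiplied through by N⁴, but for integer tables every term
is an exactly representable integer, so the only rounding is one final
correctly rounded division. Consequence: a table whose exact rational g²
is 4/5 evaluates to the float `0.8` bit-for-bit, and the inclusive
`g² ≥ 0.80` catalog comparison behaves exactly at the boundary. Values that
exceed 1 by at most 1e-12 (possible for real-valued expected tables) are
clamped to 1; larger excursions raise an internal-consistency error.

### Degenerate and missing data

* Missing genotypes are handled pairwise-complete: a sample is dropped from
  a pair's table iff it is missing at either of the two sites, so N is
  pair-specific.
* If either site is monomorphic among the counted samples (zero dosage
  variance), g² is undefined; the result is flagged degenerate and the scan
  skips the pair. No 0/0 division is ever attempted.
* Non-diploid calls (e.g. male chrX) are rejected per record with a
  warning — the nine-cell estimator is defined only for diploid genotypes.

### LD p-value

The p-value for the null hypothesis g² = 0 refers the statistic N·g² to a
chi-square distribution with 1 degree of freedom (the dosage analogue of
the allelic trend LD test). It is strictly decreasing in g² at fixed N and
in N at fixed g² > 0. No small-sample bias correction is applied to g²
itself.

## Scan pipeline

Stages, in order: read SV and SNP VCF panels (pysam; multi-allelic records
dropped and counted) → intersect samples (lexicographic canonical order,
making output byte-stable under input reordering) → parse the association
TSV (GWAS-catalog or generic dialect) and keep rows with p strictly below
5×10⁻⁸ → join associations to genotyped SNPs on normalized chromosome +
1-based position (rsID conflicts are flagged, never dropped; alleles are
not strand-matched since g² depends only on the genotype panel) →
enumerate candidate pairs → tabulate, estimate, filter → write the catalog
TSV sorted by (chrom, SV start, SNP pos, trait) with floats at 6
significant digits.

### Windows

An SV spanning [start, end] gets the closed 1-based window
[max(1, start − flank), end + flank], default flank 100,000 bp — roughly
the physical scale over which r² around a causal site decays below ~0.2 in
large human populations. Design choices where conventions genuinely vary:

* **Interval closure**: closed at both ends; a SNP exactly `flank` bp from
  an endpoint is inside.
* **Insertions** occupy a single reference coordinate (their window is
  pos ± flank); window arithmetic is reference-based, not allele-based.
* **Deletion end**: an explicit END annotation wins over pos + |SVLEN|.
* **SNPs inside the SV body** are included by default
  (`--exclude-snps-inside-sv` disables this, since LD with a SNP deleted by
  the SV may be an artefact).
* **Threshold comparisons**: the catalog keeps g² ≥ 0.80 (inclusive) and
  association p < 5×10⁻⁸ (strict); both are configurable.

Candidate enumeration is a per-chromosome sorted sweep (binary search over
SNP positions), verified against an all-pairs brute-force oracle on
randomized instances.

## Synthetic data generator

The generator emulates the scan's study conditions: a diploid panel of
**32 samples** (the long-read panel scale the default mirrors), biallelic
SV and SNP sites, and an association table mixing significant and
sub-threshold rows. For a planted pair with target haplotype r² and allele
frequencies (p, q), it solves |D| = r·√(p(1−p)q(1−q)) for the four
haplotype frequencies (positive coupling preferred, negative-D fallback
when only that sign is feasible, and a flag to force negative coupling),
then draws 2N haplotypes i.i.d. and pairs them — random union of gametes,
hence HWE in expectation, hence sampled g² is a consistent estimator of the
planted r². At N = 32 and r² = 0.85 the mean sampled g² lands within 0.05
of the target across 2,000 panels.

Pairs that must sit exactly at a threshold use deterministic integer
tables instead of sampling: the family (4, 0, 0, 1, k, 1, 0, 0, 4) has
exact rational g² = 4/5 for every k ≥ 0 (k = 22 gives N = 32), and exact
g² = 1 and g² = 0 tables are the coupled-diagonal and
outer-product-of-margins constructions.

Truth labels in a fixture's truth table are computed **from the realized
genotypes**, not the intended parameters, so end-to-end comparisons are
exact even when sampling noise moves a pair across a threshold. Planted
windows are required to be disjoint per chromosome so no unplanned
cross-pair can appear.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real panels: population structure and HWE departure
(real genotypic g² can diverge from gametic r²), recombination-map
heterogeneity (windows in cM rather than bp), genotyping error, multi-SNP
LD structure beyond two loci, and reference-bias in SV genotyping.

## Problem sizes

Default verification scales were chosen to make properties sharp while
keeping runs quick: 1,000 random tables for oracle agreement, 200
frequency vectors × three panel sizes for the HWE identity, 500 tables for
the symmetry suite, 100 random windowing instances, and 2,000 simulated
panels for parameter recovery. The planted end-to-end fixture has 11 pairs
covering every filter (window, significance, g², degeneracy) plus both
threshold boundaries.

## Known limitations

* g² is undefined (not zero) for monomorphic sites; catalogs from small
  panels will silently lose rare variants to degeneracy — the summary's
  `degenerate_pairs` counter exposes how many.
* The χ²(1) p-value is asymptotic; at N = 32 it is approximate and is not
  used as a filter, only reported.
* Associations are matched by position only; allele/rsID discrepancies are
  flagged but the catalog does not verify strand or allele identity.
* Breakend (BND) notation, multi-allelic records and genotype likelihoods
  are out of scope; records are used only through their hard GT calls.
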