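# svld

Linkage-disequilibrium scanning between structural variants (SVs) and
GWAS-significant SNPs on unphased genotype data.

## The problem

Long-read sequencing panels (such as the 32-genome HGSVC panel) reveal tens
of thousands of structural variants invisible to short-read GWAS genotyping.
When such an SV is in strong linkage disequilibrium with a SNP that carries
a genome-wide-significant trait association, the SV becomes a concrete
causal-variant hypothesis for that association signal. `svld` builds that
evidence: it pairs each biallelic SV with the GWAS-significant SNPs inside
a physical window around the SV's endpoints, estimates LD directly from
unphased diploid genotypes, and emits a filtered SV–SNP–trait catalog.

## The statistic

For two biallelic sites, code each individual's genotype numerically
(hom-ref = 1, het = 2, hom-alt = 3) at both sites, giving per-individual
dosage pairs (X, Y). From the nine double-genotype counts x₁…x₉ (N = Σxᵢ)
the genotypic squared correlation is the squared Pearson correlation of the
coded genotypes:

    g² = [μ_XY − μ_X μ_Y]² / ([μ_X² − (μ_X)²][μ_Y² − (μ_Y)²])

where the μ are the sample moments of X and Y. No phasing or
haplotype-frequency estimation is involved, yet under Hardy–Weinberg
equilibrium g² equals the standard haplotype-level r² = D²/(p(1−p)q(1−q)) —
an identity the test suite verifies to 1e-10. A p-value for the null
g² = 0 uses N·g² referred to a χ²(1) distribution.

The scan keeps an SV–SNP pair when

* the SNP lies within ±100 kbp (configurable) of the SV's endpoints
  (closed interval, SNPs inside the SV body included by default),
* the SNP has a trait association with p < 5×10⁻⁸ (strict), and
* g² ≥ 0.80 (inclusive; the consensus tag-SNP threshold).

## Worked example

The built-in generator plants SV–SNP pairs with known haplotype-level LD
and writes the three scan inputs (SV VCF, SNP VCF, association TSV) plus a
truth table:

```python
from svld.simulate import build_fixture, default_planted_pairs
from svld.pipeline import ScanConfig, run_scan, write_catalog

paths = build_fixture(default_planted_pairs(), "demo", n_diploid=32, seed=7)
config = ScanConfig(sv_vcf=paths["sv_vcf"], snp_vcf=paths["snp_vcf"],
                    gwas_tsv=paths["gwas_tsv"], output="demo/catalog.tsv")
catalog, summary = run_scan(config)
write_catalog(catalog, config.output)
for e in catalog:
    print(e.sv_id, e.snp_rsid, round(e.g_squared, 4), e.distance_bp)
```

prints

```
SV100 rs1000 1.0 40000
SV101 rs1001 1.0 45000
SV102 rs1002 1.0 50000
SV103 rs1003 1.0 55000
SV200 rs2000 0.8 10000
SV201 rs2001 1.0 25000
```

Six of the eleven planted pairs survive: four perfect-LD positives, one
pair constructed to sit exactly at the inclusive g² = 0.80 boundary, and
one negatively coupled perfect-LD pair. The excluded five are planted
negatives — a SNP beyond the 100 kbp flank, a suggestive association
(p = 9.13×10⁻⁷), an association exactly at 5×10⁻⁸ (strict `<` excludes
it), an independence (g² = 0) pair, and a monomorphic SV the estimator
flags as degenerate and skips. `summary` carries the stage-by-stage funnel
counts (candidate pairs, degenerate pairs, unique SVs/SNPs/traits).

The same scan is available from the shell:

```
svld scan --sv-vcf demo/svs.vcf --snp-vcf demo/snps.vcf \
          --gwas demo/gwas.tsv --out demo/catalog.tsv
```

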