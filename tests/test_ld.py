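"""Unit and property tests for the genotypic g^2 estimator and its oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svld.errors import AlignmentError, DegenerateError, NoDataError
from svld.ld import (
    GenotypeCountTable,
    HaplotypeFrequencies,
    dosage_moments,
    dosage_pearson_oracle,
    g_squared,
    haplotype_r_squared,
    hwe_expected_table,
    ld_pvalue_from,
    tabulate_double_genotypes,
)
from svld.variants import HET, HOM_ALT, HOM_REF, MISSING

from conftest import random_nondegenerate_tables

# the spec'd worked example: 60 individuals, exact rational g^2 = 27/80
EXAMPLE_TABLE = (10, 5, 1, 4, 20, 4, 1, 5, 10)
EXAMPLE_G2 = 0.3375


class TestTabulation:
    def test_identity_pairing(self):
        t = tabulate_double_genotypes(
            np.array([HOM_REF, HET, HOM_ALT]), np.array([HOM_REF, HET, HOM_ALT])
        )
        assert t.counts[0, 0] == 1 and t.counts[1, 1] == 1 and t.counts[2, 2] == 1
        assert t.n_total == 3

    def test_missing_at_either_site_excludes_sample(self):
        t = tabulate_double_genotypes(
            np.array([HOM_REF, MISSING]), np.array([HOM_REF, HOM_REF])
        )
        assert t.n_total == 1 and t.counts[0, 0] == 1

    def test_matches_per_sample_loop_oracle(self, rng):
        a = rng.integers(-1, 3, size=200)
        b = rng.integers(-1, 3, size=200)
        expected = np.zeros((3, 3))
        for x, y in zip(a, b):  # naive per-sample loop
            if x >= 0 and y >= 0:
                expected[x, y] += 1
        t = tabulate_double_genotypes(a, b)
        assert np.array_equal(t.counts, expected)

    def test_length_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            tabulate_double_genotypes(np.array([0, 1]), np.array([0]))

    def test_all_missing_raises(self):
        with pytest.raises(NoDataError):
            tabulate_double_genotypes(np.array([MISSING]), np.array([HOM_REF]))


class TestMoments:
    @pytest.mark.parametrize(
        "flat, expected",
        [
            # all (A1A1, B1B1): every moment is 1
            ((4, 0, 0, 0, 0, 0, 0, 0, 0), (1, 1, 1, 1, 1)),
            # all double-het: X=Y=2 so XY=4, squares=4
            ((0, 0, 0, 0, 7, 0, 0, 0, 0), (4, 2, 2, 4, 4)),
        ],
    )
    def test_single_cell_tables(self, flat, expected):
        m = dosage_moments(GenotypeCountTable.from_flat(flat))
        assert (m.mu_XY, m.mu_X, m.mu_Y, m.mu_X2, m.mu_Y2) == expected

    def test_moments_match_expansion_average(self):
        m = dosage_moments(GenotypeCountTable.from_flat(EXAMPLE_TABLE))
        # oracle: expand to 60 explicit dosage pairs and average
        xs, ys = [], []
        for idx, c in enumerate(EXAMPLE_TABLE):
            xs += [idx // 3 + 1] * c
            ys += [idx % 3 + 1] * c
        n = len(xs)
        assert m.mu_XY == pytest.approx(sum(x * y for x, y in zip(xs, ys)) / n)
        assert m.mu_X == pytest.approx(sum(xs) / n)
        assert m.mu_Y == pytest.approx(sum(ys) / n)
        assert m.mu_X2 == pytest.approx(sum(x * x for x in xs) / n)
        assert m.mu_Y2 == pytest.approx(sum(y * y for y in ys) / n)


class TestGSquared:
    def test_perfect_coupling(self):
        r = g_squared(GenotypeCountTable.from_flat((2, 0, 0, 0, 0, 0, 0, 0, 2)))
        assert r.g_squared == 1.0 and not r.degenerate

    def test_independence_factorization(self):
        r = g_squared(GenotypeCountTable.from_flat((1, 2, 1, 2, 4, 2, 1, 2, 1)))
        assert abs(r.g_squared) < 1e-12

    def test_example_table_regression(self):
        r = g_squared(GenotypeCountTable.from_flat(EXAMPLE_TABLE))
        assert r.g_squared == pytest.approx(EXAMPLE_G2, abs=1e-12)
        oracle = dosage_pearson_oracle(GenotypeCountTable.from_flat(EXAMPLE_TABLE))
        assert abs(r.g_squared - oracle) < 1e-12

    def test_monomorphic_flags_degenerate(self):
        r = g_squared(GenotypeCountTable.from_flat((3, 2, 1, 0, 0, 0, 0, 0, 0)))
        assert r.degenerate and math.isnan(r.g_squared) and math.isnan(r.p_value)

    def test_empty_table_raises(self):
        with pytest.raises(NoDataError):
            g_squared(GenotypeCountTable.from_flat((0,) * 9))

    def test_oracle_equivalence_on_random_tables(self, rng):
        for table in random_nondegenerate_tables(1000, rng):
            assert abs(g_squared(table).g_squared - dosage_pearson_oracle(table)) < 1e-10

    def test_bounds_on_random_tables(self, rng):
        for table in random_nondegenerate_tables(300, rng):
            g2 = g_squared(table).g_squared
            assert -1e-12 <= g2 <= 1.0

    def test_transpose_symmetry(self, rng):
        for table in random_nondegenerate_tables(250, rng):
            assert abs(
                g_squared(table).g_squared - g_squared(table.transpose()).g_squared
            ) <= 1e-12

    def test_allele_relabel_invariance(self, rng):
        # reversing rows (A1<->A2) or columns (B1<->B2) is an affine dosage
        # flip 1<->3 and must leave the squared correlation unchanged
        for table in random_nondegenerate_tables(250, rng):
            base = g_squared(table).g_squared
            flipped_rows = GenotypeCountTable(table.counts[::-1, :].copy())
            flipped_cols = GenotypeCountTable(table.counts[:, ::-1].copy())
            assert abs(base - g_squared(flipped_rows).g_squared) <= 1e-12
            assert abs(base - g_squared(flipped_cols).g_squared) <= 1e-12

    def test_moment_formula_agrees_with_sum_formula(self, rng):
        # the published moment form and the N-scaled sum identity coincide
        for table in random_nondegenerate_tables(100, rng):
            m = dosage_moments(table)
            cov = m.mu_XY - m.mu_X * m.mu_Y
            var_x = m.mu_X2 - m.mu_X**2
            var_y = m.mu_Y2 - m.mu_Y**2
            assert g_squared(table).g_squared == pytest.approx(
                cov**2 / (var_x * var_y), abs=1e-10
            )


class TestLDPValue:
    def test_null_value(self):
        assert ld_pvalue_from(0.0, 32) == 1.0

    def test_perfect_ld_at_n32_matches_erfc_identity(self):
        # chi-square(1 df) upper tail at x equals erfc(sqrt(x/2))
        assert ld_pvalue_from(1.0, 32) == pytest.approx(math.erfc(math.sqrt(16.0)), rel=1e-12)

    def test_monotone_decreasing_in_g2_and_n(self):
        assert ld_pvalue_from(0.5, 64) < ld_pvalue_from(0.5, 32)
        assert ld_pvalue_from(0.8, 32) < ld_pvalue_from(0.5, 32)


class TestHaplotypeR2:
    @pytest.mark.parametrize(
        "h, expected",
        [
            ((0.5, 0.0, 0.0, 0.5), 1.0),  # complete coupling
            ((0.25, 0.25, 0.25, 0.25), 0.0),  # linkage equilibrium
            ((0.4, 0.1, 0.1, 0.4), 0.36),  # (0.16-0.01)^2 / 0.5^4
        ],
    )
    def test_hand_checked_values(self, h, expected):
        assert haplotype_r_squared(HaplotypeFrequencies(*h)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_monomorphic_locus_raises(self):
        with pytest.raises(DegenerateError):
            haplotype_r_squared(HaplotypeFrequencies(0.5, 0.5, 0.0, 0.0))


class TestHWEExpectedTable:
    def test_fixed_haplotype_puts_all_mass_in_x1(self):
        t = hwe_expected_table(HaplotypeFrequencies(1.0, 0.0, 0.0, 0.0), 8)
        assert t.counts[0, 0] == 8 and t.n_total == pytest.approx(8)

    def test_equilibrium_factorizes_into_margin_outer_product(self):
        t = hwe_expected_table(HaplotypeFrequencies(0.25, 0.25, 0.25, 0.25), 16)
        margins = np.array([1, 2, 1]) / 4
        assert np.allclose(t.counts, 16 * np.outer(margins, margins))

    def test_cell_probabilities_match_ordered_pair_enumeration(self, rng):
        for _ in range(50):
            h = rng.dirichlet(np.ones(4))
            freqs = HaplotypeFrequencies(*(h / h.sum()))
            t = hwe_expected_table(freqs, 1.0)
            # oracle: enumerate the 16 ordered haplotype pairs
            expected = np.zeros((3, 3))
            hv = freqs.as_array()
            for k in range(4):
                for m in range(4):
                    expected[k // 2 + m // 2, k % 2 + m % 2] += hv[k] * hv[m]
            assert np.allclose(t.counts, expected, atol=1e-14)

    def test_hwe_identity_g2_equals_r2(self, rng):
        """g^2 of the HWE-expected table equals haplotype r^2, for any n."""
        checked = 0
        while checked < 200:
            p, q = rng.uniform(0.05, 0.95, size=2)
            d_lo = -min(p * q, (1 - p) * (1 - q))
            d_hi = min(p * (1 - q), (1 - p) * q)
            d = rng.uniform(d_lo, d_hi)
            freqs = HaplotypeFrequencies(
                p * q + d, p * (1 - q) - d, (1 - p) * q - d, (1 - p) * (1 - q) + d
            )
            r2 = haplotype_r_squared(freqs)
            for n in (10, 32, 1000):
                g2 = g_squared(hwe_expected_table(freqs, n)).g_squared
                assert abs(g2 - r2) < 1e-10
            checked += 1


class TestDosagePearsonOracle:
    def test_degenerate_table_raises(self):
        with pytest.raises(DegenerateError):
            dosage_pearson_oracle(GenotypeCountTable.from_flat((5, 3, 2, 0, 0, 0, 0, 0, 0)))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 50), min_size=9, max_size=9))
def test_g2_oracle_agreement_property(flat):
    """For every non-degenerate integer table, g^2 equals the expansion oracle."""
    table = GenotypeCountTable.from_flat(flat)
    n = table.n_total
    if n < 2 or max(table.sv_marginals) == n or max(table.snp_marginals) == n:
        return
    assert abs(g_squared(table).g_squared - dosage_pearson_oracle(table)) < 1e-10
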