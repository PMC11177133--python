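"""SV windows and candidate-pair enumeration against the all-pairs oracle."""

import numpy as np
import pytest

from svld.gwas import GwasAssociation, SnpMatch, normalize_chrom
from svld.pairing import candidate_pairs, snp_distance_to_sv, sv_window, windows_to_bed
from svld.variants import VariantRecord, sv_span


def _sv(vid, chrom, pos, end):
    return VariantRecord(vid, chrom, pos, "N", "<DEL>", "SV", span_end=end, sv_length=-(end - pos))


def _snp_match(rsid, chrom, pos):
    var = VariantRecord(rsid, chrom, pos, "A", "G", "SNP")
    assoc = GwasAssociation(rsid, normalize_chrom(chrom), pos, 1e-12, "t", "p")
    return SnpMatch(assoc, var, 0)


class TestSvWindow:
    def test_flank_arithmetic(self):
        w = sv_window(_sv("s", "1", 200_000, 205_000), 100_000)
        assert (w.start, w.end) == (100_000, 305_000)

    def test_left_clamp_at_chromosome_start(self):
        w = sv_window(_sv("s", "1", 50_000, 60_000), 100_000)
        assert (w.start, w.end) == (1, 160_000)

    def test_closed_right_boundary(self):
        w = sv_window(_sv("s", "1", 200_000, 205_000), 100_000)
        assert w.contains("1", 305_000)
        assert not w.contains("1", 305_001)


class TestCandidatePairs:
    def test_boundary_enumeration(self):
        svs = [_sv("sv", "1", 200_000, 205_000)]
        snps = [_snp_match(f"rs{p}", "1", p) for p in (99_999, 100_000, 305_001)]
        pairs = candidate_pairs(svs, snps, 100_000)
        assert [(s.variant_id, m.variant.variant_id) for s, m in pairs] == [("sv", "rs100000")]

    def test_chromosome_separation(self):
        pairs = candidate_pairs(
            [_sv("sv", "2", 200_000, 205_000)], [_snp_match("rs", "3", 210_000)], 100_000
        )
        assert pairs == []

    def test_duplicate_trait_rows_give_one_pair(self):
        svs = [_sv("sv", "1", 200_000, 205_000)]
        snps = [_snp_match("rs1", "1", 210_000), _snp_match("rs1", "1", 210_000)]
        assert len(candidate_pairs(svs, snps, 100_000)) == 1

    def test_exclude_snps_inside_sv_body(self):
        svs = [_sv("sv", "1", 200_000, 205_000)]
        snps = [_snp_match("inside", "1", 202_000), _snp_match("outside", "1", 250_000)]
        kept = candidate_pairs(svs, snps, 100_000, include_snps_inside_sv=False)
        assert [m.variant.variant_id for _, m in kept] == ["outside"]

    def _random_instance(self, rng):
        chroms = ["1", "2", "X"]
        svs = []
        for i in range(rng.integers(1, 200)):
            pos = int(rng.integers(1, 5_000_000))
            svs.append(_sv(f"sv{i}", str(rng.choice(chroms)), pos, pos + int(rng.integers(1, 20_000))))
        snps = [
            _snp_match(f"rs{j}", str(rng.choice(chroms)), int(rng.integers(1, 5_100_000)))
            for j in range(rng.integers(1, 500))
        ]
        return svs, snps

    def test_matches_all_pairs_oracle_on_random_instances(self, rng):
        for _ in range(100):
            svs, snps = self._random_instance(rng)
            flank = int(rng.choice([0, 1_000, 100_000]))
            got = {
                (s.variant_id, m.variant.variant_id)
                for s, m in candidate_pairs(svs, snps, flank)
            }
            expected = set()
            for sv in svs:  # brute-force double loop
                for m in snps:
                    if sv_window(sv, flank).contains(m.variant.chrom, m.variant.pos):
                        expected.add((sv.variant_id, m.variant.variant_id))
            assert got == expected

    def test_order_invariance_and_flank_monotonicity(self, rng):
        svs, snps = self._random_instance(rng)
        base = candidate_pairs(svs, snps, 50_000)
        perm_sv = [svs[i] for i in rng.permutation(len(svs))]
        perm_snp = [snps[i] for i in rng.permutation(len(snps))]
        assert [
            (s.variant_id, m.variant.variant_id) for s, m in candidate_pairs(perm_sv, perm_snp, 50_000)
        ] == [(s.variant_id, m.variant.variant_id) for s, m in base]
        small = {(s.variant_id, m.variant.variant_id) for s, m in base}
        large = {
            (s.variant_id, m.variant.variant_id) for s, m in candidate_pairs(svs, snps, 120_000)
        }
        assert small <= large


class TestDistances:
    def test_distance_zero_inside_body(self):
        sv = _sv("sv", "1", 200_000, 205_000)
        assert snp_distance_to_sv(sv, 202_000) == 0
        assert snp_distance_to_sv(sv, 205_100) == 100
        assert snp_distance_to_sv(sv, 199_000) == 1_000


def test_bed_export_is_zero_based_half_open(tmp_path):
    path = str(tmp_path / "w.bed")
    windows_to_bed([_sv("sv", "1", 200_000, 205_000)], 100_000, path)
    chrom, start, end, name = open(path).read().split()
    assert (chrom, int(start), int(end), name) == ("1", 99_999, 305_000, "sv")
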