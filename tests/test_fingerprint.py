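"""LD-space partitioning, binning, density fingerprints and census counts."""

import math

import numpy as np
import pytest

import ldfingerprint as ld
from ldfingerprint import fingerprint as fp_mod

from conftest import random_fingerprint
from test_summary import proteome_from_pairs

TABLE_LN_EDGES = [4.6, 4.9, 5.2, 5.5, 5.8, 6.1, 6.4, 6.7, 7.0]


class TestDefaultPartition:
    def test_10x10_reproduces_standard_edges(self):
        part = ld.default_partition(10, 10)
        assert part.ln_edges[0] == 0.0 and math.isinf(part.ln_edges[-1])
        assert np.allclose(part.ln_edges[1:-1], TABLE_LN_EDGES)
        assert np.allclose(part.id_edges, np.arange(11) / 10)

    def test_n2_halves_id_axis(self):
        part = ld.default_partition(10, 2)
        assert np.allclose(part.id_edges, [0.0, 0.5, 1.0])

    def test_too_small_rejected(self):
        with pytest.raises(ld.ValidationError):
            ld.default_partition(1, 10)

    @pytest.mark.parametrize(
        "edge,expected",
        [(4.6, 100), (4.9, 135), (5.2, 182), (5.5, 245), (5.8, 331),
         (6.1, 446), (6.4, 602), (6.7, 813), (7.0, 1097)],
    )
    def test_integer_length_bounds_ceil_exp(self, edge, expected):
        """Smallest integer length at or above each ln edge."""
        assert ld.integer_length_bound(edge) == expected
        assert math.ceil(math.exp(edge)) == expected  # independent closed form

    def test_edges_strictly_ascending_for_various_sizes(self):
        for M, N in [(2, 2), (5, 5), (10, 10), (13, 7)]:
            part = ld.default_partition(M, N)
            assert part.M == M and part.N == N
            assert np.all(np.diff(part.ln_edges) > 0)
            assert np.all(np.diff(part.id_edges) > 0)


class TestBinProtein:
    def test_boundary_just_above_first_edge(self):
        part = ld.default_partition(10, 10)
        # ln(100) = 4.605 >= 4.6, so bin 2
        assert ld.bin_protein(100, 0.05, part)[0] == 2
        assert ld.bin_protein(99, 0.05, part)[0] == 1

    def test_top_id_edge_closed(self):
        part = ld.default_partition(10, 10)
        assert ld.bin_protein(50, 1.0, part)[1] == 10

    def test_id_zero_in_first_bin(self):
        part = ld.default_partition(10, 10)
        assert ld.bin_protein(50, 0.0, part)[1] == 1

    def test_partition_is_exhaustive_and_disjoint(self):
        """Every (L, id) lattice point maps to exactly one block."""
        part = ld.default_partition(10, 10)
        for L in [1, 5, 74, 99, 100, 101, 446, 1096, 1097, 30000]:
            for idf in np.linspace(0, 1, 21):
                i, j = ld.bin_protein(int(L), float(idf), part)
                assert 1 <= i <= 10 and 1 <= j <= 10
                lo, hi = part.ln_edges[i - 1], part.ln_edges[i]
                assert lo <= math.log(L) < hi or (i == 10 and math.log(L) >= lo)
                lo_j, hi_j = part.id_edges[j - 1], part.id_edges[j]
                assert lo_j <= idf < hi_j or (j == 10 and idf == 1.0)

    def test_grid_totals_match_naive_scan(self, rng):
        part = ld.default_partition(10, 10)
        lengths = rng.integers(5, 5000, size=10_000)
        ids = rng.random(10_000)
        fp = ld.fingerprint_from_pairs("t", lengths, ids, part)

        oracle = np.zeros((10, 10), dtype=int)
        for L, f in zip(lengths, ids):
            i, j = ld.bin_protein(int(L), float(f), part)
            oracle[i - 1, j - 1] += 1
        assert np.array_equal(fp.counts, oracle)


class TestComputeFingerprint:
    def test_single_protein_single_block(self):
        prot = proteome_from_pairs("t", [150], [0.25])
        fp = ld.compute_fingerprint(prot, ld.default_partition(10, 10))
        assert fp.n_tot == 1
        assert fp.density.sum() == 1.0
        assert np.count_nonzero(fp.counts) == 1

    def test_record_order_invariance(self, rng):
        lengths = rng.integers(5, 3000, size=300).tolist()
        ids = rng.random(300).tolist()
        part = ld.default_partition(10, 10)
        a = ld.compute_fingerprint(proteome_from_pairs("a", lengths, ids), part)
        perm = rng.permutation(300)
        b = ld.compute_fingerprint(
            proteome_from_pairs("b", [lengths[i] for i in perm], [ids[i] for i in perm]),
            part,
        )
        assert np.array_equal(a.counts, b.counts)

    def test_density_equals_counts_over_n_tot(self, rng):
        part = ld.default_partition(10, 10)
        lengths = rng.integers(5, 4000, size=2000)
        ids = rng.random(2000)
        fp = ld.fingerprint_from_pairs("t", lengths, ids, part)
        assert np.array_equal(fp.density, fp.counts / 2000)
        assert abs(fp.density.sum() - 1.0) < 1e-12
        assert fp.counts.sum() == fp.n_tot == 2000

    def test_empty_view_rejected(self):
        prot = ld.Proteome(name="e", records=[])
        with pytest.raises(ld.ValidationError):
            ld.compute_fingerprint(prot, ld.default_partition(10, 10))

    def test_merged_proteome_is_weighted_mixture(self, rng):
        part = ld.default_partition(10, 10)
        for _ in range(10):
            n1, n2 = int(rng.integers(50, 300)), int(rng.integers(50, 300))
            l1, i1 = rng.integers(5, 3000, n1), rng.random(n1)
            l2, i2 = rng.integers(5, 3000, n2), rng.random(n2)
            f1 = ld.fingerprint_from_pairs("a", l1, i1, part)
            f2 = ld.fingerprint_from_pairs("b", l2, i2, part)
            merged = ld.fingerprint_from_pairs(
                "ab", np.concatenate([l1, l2]), np.concatenate([i1, i2]), part
            )
            mixture = (n1 * f1.density + n2 * f2.density) / (n1 + n2)
            assert np.allclose(merged.density, mixture, atol=1e-12)

    def test_coarsening_by_summing_nested_blocks(self, rng):
        """A 5x5 grid from merged 10x10 edges equals summed adjacent blocks."""
        fine = ld.default_partition(10, 10)
        coarse = ld.LDPartition(
            ln_edges=fine.ln_edges[::2], id_edges=fine.id_edges[::2]
        )
        lengths = rng.integers(5, 4000, size=3000)
        ids = rng.random(3000)
        f_fine = ld.fingerprint_from_pairs("t", lengths, ids, fine)
        f_coarse = ld.fingerprint_from_pairs("t", lengths, ids, coarse)
        summed = f_fine.counts.reshape(5, 2, 5, 2).sum(axis=(1, 3))
        assert np.array_equal(f_coarse.counts, summed)


class TestDifferential:
    def test_self_difference_zero(self, rng):
        part = ld.default_partition(10, 10)
        f = random_fingerprint(rng, "a", part)
        assert np.all(ld.differential(f, f) == 0.0)

    def test_antisymmetry_and_zero_sum(self, rng):
        part = ld.default_partition(10, 10)
        a = random_fingerprint(rng, "a", part)
        b = random_fingerprint(rng, "b", part)
        d = ld.differential(a, b)
        assert np.allclose(d, -ld.differential(b, a))
        assert abs(d.sum()) < 1e-12

    def test_partition_mismatch_rejected(self, rng):
        a = random_fingerprint(rng, "a", ld.default_partition(10, 10))
        b = random_fingerprint(rng, "b", ld.default_partition(5, 5))
        with pytest.raises(ld.ValidationError):
            ld.differential(a, b)

    def test_constructed_shift_localized(self):
        part = ld.default_partition(10, 10)
        # both proteomes identical except extra mass in one block of `a`
        base_l, base_i = [150] * 50, [0.25] * 50
        a = ld.fingerprint_from_pairs("a", base_l + [2000] * 50, base_i + [0.85] * 50, part)
        b = ld.fingerprint_from_pairs("b", base_l + [150] * 50, base_i + [0.25] * 50, part)
        d = ld.differential(a, b)
        nz = np.nonzero(d)
        assert set(zip(*nz)) == {
            tuple(x - 1 for x in ld.bin_protein(150, 0.25, part)),
            tuple(x - 1 for x in ld.bin_protein(2000, 0.85, part)),
        }


class TestCountCategory:
    def test_empty_proteome_counts_zero(self):
        prot = ld.Proteome(name="e", records=[])
        assert ld.count_category(prot, ld.short_rule(), ld.disordered_strict) == 0

    def test_all_short_disordered(self):
        prot = proteome_from_pairs("t", [50] * 7, [0.9] * 7)
        assert ld.count_category(prot, ld.short_rule(), ld.disordered_strict) == 7

    def test_strict_vs_inclusive_threshold(self):
        prot = proteome_from_pairs("t", [10], [0.5])  # id_pep exactly 0.5
        assert ld.count_category(prot, ld.short_rule(), ld.disordered_ge) == 1
        assert ld.count_category(prot, ld.short_rule(), ld.disordered_strict) == 0

    def test_planted_short_disordered_count(self, rng):
        """37 planted short-disordered proteins among background proteins."""
        lengths = [int(rng.integers(40, 99)) for _ in range(37)]
        ids = [0.8] * 37
        lengths += [int(rng.integers(200, 900)) for _ in range(100)]
        ids += [0.2] * 100
        prot = proteome_from_pairs("t", lengths, ids)
        assert ld.count_category(prot, ld.short_rule(100), ld.disordered_strict) == 37
        assert ld.count_category(prot, ld.long_rule(1000), ld.disordered_strict) == 0


class TestSerialization:
    def test_fingerprint_tsv_roundtrip_values(self, tmp_path, rng):
        part = ld.default_partition(10, 10)
        fp = random_fingerprint(rng, "x", part)
        path = tmp_path / "fp.tsv"
        fp_mod.write_fingerprint(fp, path)
        text = path.read_text()
        assert text.startswith("# fingerprint\tx\n")
        import pandas as pd

        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        assert np.allclose(df.values, fp.density, atol=1e-9)
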