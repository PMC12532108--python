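import numpy as np
import pytest

import chromarch as ca
from chromarch.contacts import ExpectedProfile


def write_lines(path, rows):
    path.write_text("\n".join("\t".join(map(str, r)) for r in rows) + "\n")


@pytest.fixture()
def small_bins(small_genome):
    return ca.make_bins(small_genome)


class TestCooIO:
    def test_single_record(self, tmp_path, small_bins):
        p = tmp_path / "m.tsv"
        write_lines(p, [(0, 1, 5)])
        mat = ca.read_coo(p, small_bins)
        assert mat.raw[0, 1] == 5 and mat.raw[1, 0] == 5

    def test_duplicates_summed(self, tmp_path, small_bins):
        p = tmp_path / "m.tsv"
        write_lines(p, [(2, 3, 1), (2, 3, 2)])
        mat = ca.read_coo(p, small_bins)
        assert mat.raw[2, 3] == 3

    def test_round_trip_bitwise(self, tmp_path, genome, bins, truth):
        from chromarch import simulate as sim
        mat = sim.simulate_contact_map(genome, bins, truth,
                                       sim.preset("null", seed=3, total_contacts=1e5))
        p = tmp_path / "rt.tsv"
        ca.write_coo(mat, p)
        back = ca.read_coo(p, bins)
        np.testing.assert_array_equal(mat.raw, back.raw)
        p2 = tmp_path / "rt2.tsv"
        ca.write_coo(back, p2)
        assert p.read_bytes() == p2.read_bytes()

    def test_out_of_range_index_names_line(self, tmp_path, small_bins):
        p = tmp_path / "bad.tsv"
        write_lines(p, [(0, 1, 2), (0, 99, 1)])
        with pytest.raises(ValueError, match="line 2"):
            ca.read_coo(p, small_bins)

    def test_negative_count_rejected(self, tmp_path, small_bins):
        p = tmp_path / "neg.tsv"
        write_lines(p, [(0, 1, -4)])
        with pytest.raises(ValueError, match="negative"):
            ca.read_coo(p, small_bins)


class TestMaskLowCoverage:
    def test_equal_marginals_only_zero_masked(self, small_bins):
        raw = np.ones((8, 8))
        raw[5, :] = 0
        raw[:, 5] = 0
        mat = ca.ContactMatrix(bins=small_bins, raw=raw)
        mask = ca.mask_low_coverage(mat, 0.0)
        assert not mask[5] and mask.sum() == 7

    def test_quantile_rule_masks_lowest_decile(self):
        g = ca.GenomeSpec(chrom_names=("c1",), chrom_lengths=(10_000_000,),
                          centromeres=((4_900_000, 5_100_000),), bin_size=100_000)
        bins = ca.make_bins(g)
        # diagonal matrix puts marginal i at value i+1 -> marginals 1..100
        raw = np.diag(np.arange(1.0, 101.0))
        mat = ca.ContactMatrix(bins=bins, raw=raw)
        mask = ca.mask_low_coverage(mat, 0.1)
        assert (~mask).sum() == 10
        assert not mask[:10].any() and mask[10:].all()


class TestIceBalance:
    def test_equal_marginals_fixed_point(self, small_bins):
        raw = np.ones((8, 8))
        mat = ca.ContactMatrix(bins=small_bins, raw=raw)
        ca.ice_balance(mat)
        assert mat.converged
        np.testing.assert_allclose(mat.balanced, raw, atol=1e-12)
        np.testing.assert_allclose(mat.bias, 1.0, atol=1e-12)

    def test_two_by_two_antidiagonal(self):
        # any positive symmetric matrix with zero diagonal and equal
        # off-diagonals balances immediately with equal marginals
        g = ca.GenomeSpec(chrom_names=("c1",), chrom_lengths=(600_000,),
                          centromeres=((250_000, 350_000),), bin_size=100_000)
        bins = ca.make_bins(g)
        raw = np.zeros((6, 6))
        raw[0, 1] = raw[1, 0] = 4.0
        mat = ca.ContactMatrix(bins=bins, raw=raw)
        ca.mask_low_coverage(mat, 0.0)
        ca.ice_balance(mat)
        sub = mat.balanced[:2, :2]
        assert mat.converged
        assert sub[0, 1] == sub[1, 0] > 0

    def test_matches_independent_sinkhorn(self, small_bins):
        rng = np.random.default_rng(5)
        n = 8
        w = rng.uniform(0.5, 2.0, (n, n))
        w = w + w.T
        mat = ca.ContactMatrix(bins=small_bins, raw=w)
        ca.ice_balance(mat, max_iter=10_000, tol=1e-10)
        assert mat.converged
        marg = mat.balanced.sum(axis=1)
        np.testing.assert_allclose(marg, marg.mean(), rtol=1e-8)
        # independent oracle: classic alternating Sinkhorn-Knopp row/column
        # scaling toward doubly stochastic, then gauge-normalized
        x = np.ones(n)
        for _ in range(100_000):
            x = 1.0 / (w @ x)
            x = np.sqrt(x * 1.0 / (w @ x))
            if np.abs((w * np.outer(x, x)).sum(1) - 1).max() < 1e-12:
                break
        oracle_bias = 1.0 / x
        ice_bias = mat.bias
        gauge = lambda b: b / np.exp(np.mean(np.log(b)))
        np.testing.assert_allclose(gauge(ice_bias), gauge(oracle_bias), atol=1e-4)

    def test_sinkhorn_agreement_50_bins(self):
        g = ca.GenomeSpec(chrom_names=("c1",), chrom_lengths=(5_000_000,),
                          centromeres=((2_400_000, 2_600_000),), bin_size=100_000)
        bins = ca.make_bins(g)
        rng = np.random.default_rng(12)
        w = rng.uniform(0.1, 1.0, (50, 50))
        w = w + w.T
        mat = ca.ContactMatrix(bins=bins, raw=w)
        ca.ice_balance(mat, max_iter=20_000, tol=1e-10)
        x = np.ones(50)
        for _ in range(200_000):
            x_new = np.sqrt(x / (w @ x))
            if np.allclose(x_new, x, rtol=1e-14):
                break
            x = x_new
        gauge = lambda b: b / np.exp(np.mean(np.log(b)))
        np.testing.assert_allclose(gauge(mat.bias), gauge(1.0 / x), atol=1e-4)

    def test_disconnected_block_reports_failure(self, small_bins):
        raw = np.zeros((8, 8))
        raw[0, 1] = raw[1, 0] = 3.0   # bins 2..7 unmasked but all-zero rows
        mat = ca.ContactMatrix(bins=small_bins, raw=raw)
        mat.valid_mask = np.ones(8, dtype=bool)
        ca.ice_balance(mat)
        assert mat.converged is False


class TestExpectedAndOE:
    def test_constant_matrix_expected_one(self, genome, bins):
        raw = np.ones((len(bins), len(bins)))
        mat = ca.ContactMatrix(bins=bins, raw=raw)
        ca.mask_low_coverage(mat, 0.0)
        ca.ice_balance(mat)
        exp = ca.expected_profile(mat)
        np.testing.assert_allclose(exp.cis[~np.isnan(exp.cis)], 1.0, atol=1e-9)
        assert all(abs(v - 1.0) < 1e-9 for v in exp.trans.values())

    def test_distance_valued_matrix(self):
        g = ca.GenomeSpec(chrom_names=("c1",), chrom_lengths=(1_000_000,),
                          centromeres=((450_000, 550_000),), bin_size=100_000)
        bins = ca.make_bins(g)
        idx = np.arange(10)
        raw = np.abs(idx[:, None] - idx[None, :]).astype(float)
        mat = ca.ContactMatrix(bins=bins, raw=raw)
        mat.balanced = raw.copy()    # bypass balancing: test the mean rule
        exp = ca.expected_profile(mat)
        np.testing.assert_allclose(exp.cis, np.arange(10.0), atol=1e-12)

    def test_masked_bin_excluded_from_diagonal_means(self):
        g = ca.GenomeSpec(chrom_names=("c1",), chrom_lengths=(1_000_000,),
                          centromeres=((450_000, 550_000),), bin_size=100_000)
        bins = ca.make_bins(g)
        raw = np.ones((10, 10))
        raw[0, :] = raw[:, 0] = 100.0   # outlier bin, to be masked
        raw[0, 0] = 0.0
        mat = ca.ContactMatrix(bins=bins, raw=raw)
        mat.valid_mask = np.ones(10, dtype=bool)
        mat.valid_mask[0] = False
        ca.ice_balance(mat)
        exp = ca.expected_profile(mat)
        finite = exp.cis[~np.isnan(exp.cis)]
        np.testing.assert_allclose(finite, finite[0], rtol=1e-6)

    def test_oe_of_entries_equal_to_expected_is_one(self, null_matrix):
        # pooled cis diagonal means and trans block means are 1 by
        # construction (the decay curve is shared across chromosomes)
        bins = null_matrix.bins
        for k in range(1, 5):
            d = np.concatenate([
                np.diagonal(null_matrix.oe[bins.chrom_slice(c),
                                           bins.chrom_slice(c)], offset=k)
                for c in bins.genome.chrom_names
            ])
            assert abs(np.nanmean(d) - 1.0) < 1e-9
        a, b = bins.chrom_slice("chr1"), bins.chrom_slice("chr2")
        assert abs(np.nanmean(null_matrix.oe[a, b]) - 1.0) < 1e-9

    def test_scale_invariance_of_oe(self, null_matrix, bins):
        mat7 = ca.ContactMatrix(bins=bins, raw=null_matrix.raw * 7.0)
        ca.normalize(mat7)
        np.testing.assert_allclose(mat7.oe, null_matrix.oe, rtol=1e-9,
                                   equal_nan=True)

    def test_null_oe_calibrated_on_aggregate(self, null_matrix):
        # under the structure-free model pooled O/E sits tightly around 1
        agg = ca.aggregate(null_matrix)
        for layer in (agg.cis, agg.trans):
            vals = layer[np.isfinite(layer)]
            assert vals.min() > 0.8 and vals.max() < 1.25
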