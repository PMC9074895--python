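"""TE computation, range statistics, codon correlates, periodicity."""

import numpy as np
import pandas as pd
import pytest

from tailscape import tequant

from _oracles import rank_then_pearson


class TestComputeTE:
    def test_log2_ratio_arithmetic(self):
        rpf = pd.Series({"g": 20})
        rna = pd.Series({"g": 10})
        out = tequant.compute_te(rpf, rna, rpf_library_size=1e6, rna_library_size=1e6)
        assert out.loc["g", "te"] == pytest.approx(1.0)

    def test_rna_rpm_cutoff_is_strict(self):
        rna = pd.Series({"lo": 99, "hi": 100})  # 9.9 vs 10.0 RPM at 10M reads
        rpf = pd.Series({"lo": 500, "hi": 500})
        out = tequant.compute_te(rpf, rna, rpf_library_size=1e7, rna_library_size=1e7)
        assert "lo" not in out.index and "hi" in out.index

    def test_equal_rpm_gives_zero_te(self):
        rpf = pd.Series({"g": 300})
        rna = pd.Series({"g": 300})
        out = tequant.compute_te(rpf, rna, rpf_library_size=1e6, rna_library_size=1e6)
        assert out.loc["g", "te"] == 0.0

    def test_zero_rpf_dropped_with_warning(self):
        rpf = pd.Series({"a": 0, "b": 100})
        rna = pd.Series({"a": 100, "b": 100})
        with pytest.warns(UserWarning, match="no RPF"):
            out = tequant.compute_te(rpf, rna, rpf_library_size=1e6, rna_library_size=1e6)
        assert list(out.index) == ["b"]

    def test_rpm_normalization_conserves_totals(self, rng):
        counts = pd.Series(rng.integers(0, 5000, 200), index=[f"g{i}" for i in range(200)])
        lib = 1e7
        rpm = counts * 1e6 / lib
        assert rpm.sum() * lib / 1e6 == pytest.approx(counts.sum())


class TestPercentileRange:
    def test_constant_te_is_one_fold(self):
        assert tequant.percentile_range(np.zeros(200)) == pytest.approx(1.0)

    def test_constructed_four_log2_units_is_sixteen_fold(self):
        # symmetric values whose 1st/99th percentiles sit exactly 4 apart
        values = np.concatenate([np.full(50, -2.0), np.zeros(100), np.full(50, 2.0)])
        assert tequant.percentile_range(values) == pytest.approx(16.0, rel=0.01)

    def test_invariant_to_global_scaling(self, rng):
        te = rng.normal(0, 1.2, 5000)
        assert tequant.percentile_range(te + 3.7) == pytest.approx(
            tequant.percentile_range(te), rel=1e-9
        )

    def test_small_tables_rejected(self):
        with pytest.raises(ValueError, match="100"):
            tequant.percentile_range(np.zeros(99))


@pytest.fixture(scope="module")
def codon_freqs():
    rng = np.random.default_rng(21)
    n = 400
    freqs = rng.dirichlet(np.ones(61), size=n)
    return pd.DataFrame(freqs, columns=list(tequant.SENSE_CODONS),
                        index=[f"g{i}" for i in range(n)])


class TestCodonCorrelation:

    def test_planted_codon_has_top_mean_r(self, codon_freqs):
        rng = np.random.default_rng(22)
        te = pd.DataFrame(
            {
                s: 2.0 * codon_freqs["GCC"] + rng.normal(0, 0.01, len(codon_freqs))
                for s in ("s1", "s2", "s3")
            }
        )
        out = tequant.codon_te_correlation(codon_freqs, te)
        assert out.index[0] == "GCC"

    def test_noise_te_gives_small_correlations(self, codon_freqs):
        rng = np.random.default_rng(23)
        te = pd.DataFrame({"s1": rng.normal(0, 1, len(codon_freqs))},
                          index=codon_freqs.index)
        out = tequant.codon_te_correlation(codon_freqs, te)
        assert out["mean_r"].abs().max() < 0.25

    def test_amino_acid_variant_pools_synonymous(self, codon_freqs):
        rng = np.random.default_rng(24)
        te = pd.DataFrame({"s1": rng.normal(0, 1, len(codon_freqs))},
                          index=codon_freqs.index)
        out = tequant.codon_te_correlation(codon_freqs, te, by_amino_acid=True)
        assert len(out) == 20  # amino acids, stops excluded

    def test_cds_codon_frequency_example(self):
        freqs = tequant.codon_frequencies({"g": "ATGGCCGCCTAA"})
        assert freqs.loc["g", "GCC"] == pytest.approx(2 / 3)
        assert freqs.loc["g"].sum() == pytest.approx(1.0)


class TestAsite:
    def _uniform_reads(self, cds, n, rng, dwell=None):
        starts = np.arange(0, len(cds) - 33, 3)
        if dwell is None:
            probs = np.ones(len(starts))
        else:
            probs = np.array([dwell.get(cds[s + 15 : s + 18], 1.0) for s in starts])
        picks = rng.choice(starts, size=n, p=probs / probs.sum())
        return pd.DataFrame({"gene": "g", "five_prime": picks, "read_length": 30})

    def test_uniform_positions_give_unit_enrichment(self, rng):
        cds = "ATG" + "GCCAAAGATTGC" * 50 + "TAA"
        reads = self._uniform_reads(cds, 6000, rng)
        enr = tequant.asite_occupancy(reads, {"g": cds})
        present = enr[np.isfinite(enr) & (enr > 0)]
        assert present.max() == pytest.approx(1.0, abs=0.35)

    def test_planted_dwell_enrichment(self, rng):
        # one AGA per 8 codons; a 3x dwell at AGA inflates its A-site share
        # from f to 3f / (3f + (1 - f)), so enrichment = 3 / (1 + 2f)
        unit = "AGA" + "GCAGATTGCCATGAATTC" + "TTG"
        cds = "ATG" + unit * 60 + "TAA"
        f = 1 / 8
        reads = self._uniform_reads(cds, 30000, rng, dwell={"AGA": 3.0})
        enr = tequant.asite_occupancy(reads, {"g": cds})
        assert enr["AGA"] == pytest.approx(3.0 / (1 + 2 * f), rel=0.1)

    def test_insufficient_reads_error(self):
        reads = pd.DataFrame({"gene": ["g"], "five_prime": [0], "read_length": [30]})
        with pytest.raises(ValueError, match="in-frame"):
            tequant.asite_occupancy(reads, {"g": "ATG" + "GCC" * 40 + "TAA"})

    def test_occupancy_te_regression_recovers_link(self, rng):
        enr = pd.Series(rng.uniform(0.5, 2.0, 61), index=list(tequant.SENSE_CODONS))
        corr = -0.3 * enr + rng.normal(0, 0.01, 61)
        assert tequant.occupancy_te_regression(corr, enr) > 0.95


class TestPeriodicity:
    def test_all_frame_zero(self):
        reads = pd.DataFrame({"five_prime": np.zeros(2000, dtype=int)})
        assert np.allclose(tequant.rpf_periodicity(reads), [1, 0, 0])

    def test_planted_frame_mix_recovered(self, rng):
        frames = rng.choice(3, p=[0.7, 0.2, 0.1], size=30_000)
        reads = pd.DataFrame({"five_prime": frames + 3 * rng.integers(0, 100, len(frames))})
        got = tequant.rpf_periodicity(reads)
        assert np.allclose(got, [0.7, 0.2, 0.1], atol=0.02)
        assert got.sum() == pytest.approx(1.0)


class TestTailTECorrelation:
    def test_monotone_relation_gives_unit_rs(self):
        tail = pd.Series(np.arange(50, 150), index=[f"g{i}" for i in range(100)])
        te = pd.Series(np.linspace(-2, 2, 100) ** 3, index=tail.index)
        r, p = tequant.tail_te_correlation(tail, te)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_gaussian_copula_matches_closed_form(self, rng):
        rho = 0.2
        n = 5000
        cov = [[1, rho], [rho, 1]]
        x, y = rng.multivariate_normal([0, 0], cov, size=n).T
        idx = [f"g{i}" for i in range(n)]
        r, _ = tequant.tail_te_correlation(pd.Series(x, idx), pd.Series(y, idx))
        expected = 6 / np.pi * np.arcsin(rho / 2)
        assert r == pytest.approx(expected, abs=0.04)

    def test_spearman_equals_rank_then_pearson(self, rng):
        x = rng.normal(0, 1, 200)
        y = rng.normal(0, 1, 200)
        idx = [f"g{i}" for i in range(200)]
        r, _ = tequant.tail_te_correlation(pd.Series(x, idx), pd.Series(y, idx))
        assert r == pytest.approx(rank_then_pearson(x, y), abs=1e-12)

    def test_too_few_genes_rejected(self):
        s = pd.Series([1.0] * 5)
        with pytest.raises(ValueError, match=">= 10"):
            tequant.tail_te_correlation(s, s)


@pytest.fixture(scope="module")
def coupled_table():
    rng = np.random.default_rng(31)
    n = 600
    idx = pd.Index([f"g{i}" for i in range(n)])
    tail = pd.Series(rng.normal(90, 20, n), idx)
    te = pd.Series(0.02 * tail + rng.normal(0, 1.0, n), idx)
    return tail, te


class TestSubsetPermutation:

    def test_random_subset_not_significant(self, coupled_table):
        tail, te = coupled_table
        rng = np.random.default_rng(32)
        subset = rng.choice(tail.index, 100, replace=False)
        _, p, _ = tequant.subset_correlation_test(tail, te, subset, n_perm=200, seed=0)
        assert p > 0.01

    def test_most_coupled_subset_is_significant(self, coupled_table):
        tail, te = coupled_table
        # hand-pick the genes where tail and TE ranks agree most
        resid = (te - te.mean()) / te.std() - (tail - tail.mean()) / tail.std()
        subset = resid.abs().nsmallest(100).index
        obs, p, _ = tequant.subset_correlation_test(tail, te, subset, n_perm=200, seed=0)
        assert p == pytest.approx(1 / 201, abs=1e-9)

    def test_zero_permutations_rejected(self, coupled_table):
        tail, te = coupled_table
        with pytest.raises(ValueError, match="n_perm"):
            tequant.subset_correlation_test(tail, te, tail.index[:60], n_perm=0)
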