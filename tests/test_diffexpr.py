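import numpy as np
import pytest
from scipy import stats as sps
from scipy.integrate import quad

from epistate.diffexpr import (
    DECallConfig,
    ExpressionMatrix,
    call_de,
    call_state_transition,
    chromosome_enrichment,
    estimate_dispersion,
    fisher_combine,
    nb_tail_test,
    rpkm,
    size_factors,
)
from epistate.synthetic_data import SimulationConfig, simulate_expression, simulate_genome


class TestSizeFactors:
    def test_identical_samples(self):
        c = np.array([[10, 10], [200, 200], [5, 5]])
        assert size_factors(c) == pytest.approx([1.0, 1.0])

    def test_doubled_sample(self):
        c = np.array([[10, 20], [100, 200], [7, 14]])
        assert size_factors(c) == pytest.approx([1 / np.sqrt(2), np.sqrt(2)])

    def test_toy_matrix_against_hand_computation(self):
        c = np.array([[4, 16, 1], [100, 100, 100], [9, 1, 3], [50, 200, 12]])
        refs = np.exp(np.mean(np.log(c), axis=1))
        want = np.exp(np.median(np.log(c / refs[:, None]), axis=0))
        want /= np.exp(np.mean(np.log(want)))
        assert size_factors(c) == pytest.approx(want)

    def test_all_zero_gene_rows_error(self):
        with pytest.raises(ValueError):
            size_factors(np.array([[0, 5], [3, 0]]))


class TestRPKM:
    def test_unit_example(self):
        c = np.array([[1000], [999_000]])
        v = rpkm(c, np.array([1.0]), np.array([1000.0, 1000.0]))
        assert v[0, 0] == pytest.approx(1000.0)

    def test_doubling_length_halves_value(self):
        c = np.array([[100], [900]])
        v1 = rpkm(c, np.array([1.0]), np.array([1000.0, 1000.0]))
        v2 = rpkm(c, np.array([1.0]), np.array([2000.0, 1000.0]))
        assert v2[0, 0] == pytest.approx(v1[0, 0] / 2)

    def test_invariant_under_common_library_rescaling(self):
        c = np.array([[40, 80], [400, 800], [4, 8]])
        v1 = rpkm(c, size_factors(c), np.array([1e3, 2e3, 5e2]))
        v2 = rpkm(3 * c, size_factors(3 * c), np.array([1e3, 2e3, 5e2]))
        assert v2 == pytest.approx(v1)


class TestNBTailTest:
    def test_mode_gives_p_one(self):
        assert nb_tail_test(10, 10.0, 0.0) == pytest.approx(1.0)

    def test_poisson_limit_matches_direct_summation(self):
        # independent oracle: brute-force mass-ordering sum over Poisson pmf
        mu, obs = 10.0, 25
        pmf = sps.poisson(mu).pmf(np.arange(0, 200))
        want = pmf[pmf <= pmf[obs] * (1 + 1e-12)].sum()
        assert nb_tail_test(obs, mu, 0.0) == pytest.approx(want, rel=1e-9)

    def test_nb_mode_gives_p_one(self):
        # NB(mean 100, disp 0.1) has its mode at 89
        assert nb_tail_test(89, 100.0, 0.1) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("mu,disp,obs", [(50.0, 0.2, 150),
                                             (100.0, 0.1, 100)])
    def test_nb_matches_direct_summation(self, mu, disp, obs):
        r = 1 / disp
        pmf = sps.nbinom(r, r / (r + mu)).pmf(np.arange(0, 5000))
        want = pmf[pmf <= pmf[obs] * (1 + 1e-12)].sum()
        assert nb_tail_test(obs, mu, disp) == pytest.approx(want, rel=1e-9)


class TestFisherCombine:
    def test_all_ones_combine_to_one(self):
        assert fisher_combine([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_single_p_identity(self):
        for p in (0.5, 0.01, 1e-8):
            assert fisher_combine([p]) == pytest.approx(p, rel=1e-12)

    def test_three_p05_against_quadrature_oracle(self):
        x = -2 * np.log(0.05) * 3
        want, _ = quad(lambda t: sps.chi2.pdf(t, 6), x, np.inf)
        assert fisher_combine([0.05] * 3) == pytest.approx(want, abs=1e-10)
        assert x == pytest.approx(17.97, abs=0.01)

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.5])


def _planted_matrix(seed, n_null=600, n_up=40, log2fc=3.0, mean=100.0,
                    disp=0.1, n_ctrl=4, n_ko=4):
    cfg = SimulationConfig(
        seed=seed, n_genes=n_null + n_up, frac_de=n_up / (n_null + n_up),
        planted_de_log2fc=log2fc, baseline_mean=mean, baseline_log2_sd=0.0,
        nb_dispersion=disp, n_ctrl_embryos=n_ctrl, n_ko_embryos=n_ko,
        de_chrx_bias=0.0, de_from_marked_frac=0.0,
        n_chroms=5, chrom_len_bp=12_000_000,
    )
    ann, truth = simulate_genome(cfg)
    return simulate_expression(ann, truth, cfg), truth


class TestCallDE:
    def test_all_zero_gene_unchanged(self):
        counts = np.array([[0] * 8, [100] * 8, [120] * 8])
        m = ExpressionMatrix(counts, ["g0", "g1", "g2"],
                             np.array([1e3] * 3),
                             ["control"] * 4 + ["ko"] * 4)
        res = call_de(m)
        assert res.loc[res.gene_id == "g0", "status"].item() == "unchanged"

    def test_planted_up_genes_recovered(self):
        matrix, truth = _planted_matrix(seed=5)
        res = call_de(matrix)
        up = set(res.loc[res.status == "up", "gene_id"])
        true_up = set(truth.de_genes)
        assert len(up & true_up) / len(true_up) >= 0.8
        null = set(matrix.gene_ids) - true_up
        assert len(up & null) / len(null) <= 0.01

    def test_rpkm_filter_blocks_low_expression(self):
        # clear fold change and p, but KO expression below Log2(RPKM) = 1
        rng = np.random.default_rng(0)
        n = 400
        counts = rng.poisson(1000.0, size=(n, 8))
        counts[0] = [2, 2, 2, 2, 30, 30, 30, 30]  # strong FC, tiny RPKM
        lengths = np.full(n, 1e4)
        lengths[0] = 2e5  # long transcript keeps its RPKM below the filter
        m = ExpressionMatrix(counts, [f"g{i}" for i in range(n)],
                             lengths, ["control"] * 4 + ["ko"] * 4)
        res = call_de(m)
        row = res.iloc[0]
        assert row["combined_p"] < 0.05
        assert row["mean_log2rpkm_ko"] <= 1.0
        assert row["status"] == "unchanged"

    def test_status_invariant_under_common_library_rescaling(self):
        matrix, _ = _planted_matrix(seed=9, n_null=200, n_up=20)
        res1 = call_de(matrix)
        scaled = ExpressionMatrix(matrix.counts * 2, matrix.gene_ids,
                                  matrix.gene_lengths, matrix.sample_labels,
                                  matrix.sample_names)
        res2 = call_de(scaled)
        assert (res1.status == res2.status).mean() > 0.99


class TestStateTransition:
    def test_swap_symmetry_exact(self):
        matrix, _ = _planted_matrix(seed=11, n_null=150, n_up=15)
        labels = ["ICM"] * 4 + ["epiblast"] * 4
        m = ExpressionMatrix(matrix.counts, matrix.gene_ids,
                             matrix.gene_lengths, labels)
        act_ab, rep_ab = call_state_transition(m, "ICM", "epiblast")
        act_ba, rep_ba = call_state_transition(m, "epiblast", "ICM")
        assert rep_ab == act_ba and act_ab == rep_ba

    def test_planted_activation_recovered_and_constant_genes_excluded(self):
        # planted genes are lowly expressed at stage A (Log2 RPKM < 4) and
        # jump 8-fold at stage B; abundant constant genes must not be called
        rng = np.random.default_rng(13)
        n_null, n_up = 300, 25
        n = n_null + n_up
        counts = rng.poisson(1000.0, size=(n, 8))
        counts[n_null:, :4] = rng.poisson(5.0, size=(n_up, 4))
        counts[n_null:, 4:] = rng.poisson(40.0, size=(n_up, 4))
        m = ExpressionMatrix(counts, [f"g{i}" for i in range(n)],
                             np.full(n, 6e3), ["ICM"] * 4 + ["epiblast"] * 4)
        activated, _ = call_state_transition(m, "ICM", "epiblast")
        true_up = {f"g{i}" for i in range(n_null, n)}
        assert len(activated & true_up) / n_up >= 0.7
        assert len(activated - true_up) / n_null <= 0.02


class TestChromosomeEnrichment:
    def test_matches_direct_hypergeometric_summation(self):
        chroms = {f"g{i}": ("chrX" if i < 50 else "chr1") for i in range(1000)}
        de = [f"g{i}" for i in range(5)] + [f"g{i}" for i in range(500, 505)]
        frac, p = chromosome_enrichment(de, chroms)
        # oracle: exhaustive sum over the hypergeometric pmf upper tail
        want = sum(sps.hypergeom.pmf(k, 1000, 50, 10) for k in range(5, 11))
        assert frac == 0.5
        assert p == pytest.approx(want, rel=1e-9)

    def test_no_enrichment_when_fraction_matches_genome(self):
        chroms = {f"g{i}": ("chrX" if i % 10 == 0 else "chr1")
                  for i in range(1000)}
        de = [f"g{i}" for i in range(0, 100)]  # 10 of 100 on chrX
        _, p = chromosome_enrichment(de, chroms)
        assert p >= 0.5

    def test_empty_de_set(self):
        frac, p = chromosome_enrichment([], {"g0": "chr1"})
        assert frac == 0.0 and p == 1.0
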