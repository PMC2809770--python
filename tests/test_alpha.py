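import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dfemk.alpha import (
    alpha_bias_relation,
    alpha_fww,
    alpha_model_based,
    contrast_alpha,
    expected_deleterious_divergence,
    expected_relative_rate,
    mk_table,
    relative_fixation_rate,
)
from dfemk.simulate.wright_fisher import exact_absorption_probabilities


class TestRelativeFixationRate:
    def test_neutral_limit(self):
        assert relative_fixation_rate(0.0) == pytest.approx(1.0)
        assert relative_fixation_rate(1e-12) == pytest.approx(1.0, abs=1e-9)

    def test_minus_ten(self):
        assert relative_fixation_rate(-10.0) == pytest.approx(4.540e-4, rel=1e-3)

    def test_overflow_guard(self):
        assert relative_fixation_rate(-1000.0) == 0.0
        assert relative_fixation_rate(1000.0) == pytest.approx(1000.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            relative_fixation_rate(float("nan"))

    @pytest.mark.parametrize("S", [-10.0, -5.0, -1.0, 2.0])
    def test_matches_exact_chain_in_diffusion_limit(self, S):
        """R(S) vs 2N u from the fundamental matrix, S = 2N s.

        The discrete chain approaches the diffusion value with O(1/N)
        error (a few percent at 2N = 100 for |S| = 10), so the comparison
        Richardson-extrapolates two grid sizes to the limit.
        """
        vals = []
        for two_n in (500, 1000):
            s = -S / two_n  # deleterious S < 0 maps to s > 0 in the matrix
            u = exact_absorption_probabilities(two_n, s)[1]
            vals.append(two_n * u)
        extrapolated = 2 * vals[1] - vals[0]
        assert extrapolated == pytest.approx(relative_fixation_rate(S), rel=0.01)

    def test_chain_error_shrinks_with_population_size(self):
        S = -5.0
        errs = []
        for two_n in (100, 400):
            u = exact_absorption_probabilities(two_n, -S / two_n)[1]
            errs.append(abs(two_n * u - relative_fixation_rate(S)))
        assert errs[1] < errs[0]


class TestExpectedRate:
    def test_mean_zero(self):
        assert expected_relative_rate(0.3, 0.0) == 1.0

    def test_matches_brute_force_quantile_average(self):
        shape, mean = 0.31, 1e4
        val = expected_relative_rate(shape, mean)
        from scipy import stats as sp_stats

        u = (np.arange(2_000_000) + 0.5) / 2_000_000
        x = sp_stats.gamma.ppf(u, a=shape, scale=mean / shape)
        r = np.where(x < 700, x / np.expm1(np.clip(x, 1e-12, 700)), 0.0)
        brute = r.mean()
        assert val == pytest.approx(brute, abs=1e-5)

    def test_monotone_decreasing_in_mean(self):
        vals = [expected_relative_rate(0.3, m) for m in (1.0, 10.0, 100.0)]
        assert vals[0] > vals[1] > vals[2]


class TestExpectedDeleteriousDivergence:
    def test_mean_zero_reproduces_neutral(self, monkeypatch):
        class FakeFit:
            class dfe:
                shape = 0.5
                mean_S = 0.0
        assert expected_deleterious_divergence(FakeFit, 0.03) == 0.03

    def test_all_lethal_gives_zero(self):
        class FakeFit:
            class dfe:
                shape = 5.0
                mean_S = 1e9
        assert expected_deleterious_divergence(FakeFit, 0.03) < 1e-6


class TestAlphaModelBased:
    def test_equal_gives_zero(self):
        assert alpha_model_based(0.01, 0.01) == 0.0

    def test_double_gives_half(self):
        assert alpha_model_based(0.02, 0.01) == 0.5

    def test_zero_divergence_undefined(self):
        with pytest.raises(ValueError):
            alpha_model_based(0.0, 0.01)

    def test_negative_alpha_reported(self):
        assert alpha_model_based(0.01, 0.02) == -1.0


class TestAlphaFWW:
    def test_strict_neutrality(self):
        t = pd.DataFrame({"D_N": [10], "D_S": [10], "P_N": [5], "P_S": [5]})
        assert alpha_fww(t) == 0.0

    def test_formula_value(self):
        t = pd.DataFrame({"D_N": [10], "D_S": [10], "P_N": [5], "P_S": [10]})
        assert alpha_fww(t) == pytest.approx(0.5)

    def test_zero_denominator(self):
        t = pd.DataFrame({"D_N": [10], "D_S": [1], "P_N": [5], "P_S": [0]})
        with pytest.raises(ValueError):
            alpha_fww(t)

    def test_summation_over_genes(self):
        t = pd.DataFrame({"D_N": [5, 5], "D_S": [5, 5], "P_N": [3, 2],
                          "P_S": [6, 4]})
        assert alpha_fww(t) == pytest.approx(1 - (10 * 5) / (10 * 10))


class TestBiasRelation:
    def test_paper_worked_values_inversion(self):
        assert alpha_bias_relation(1 / 5, 0.2, alpha_est=0.1) == pytest.approx(
            0.35, abs=0.005)
        assert alpha_bias_relation(1 / 10, 0.2, alpha_est=0.1) == pytest.approx(
            0.43, abs=0.005)
        assert alpha_bias_relation(5.0, 0.31, alpha_est=0.57) == pytest.approx(
            0.29, abs=0.005)
        assert alpha_bias_relation(10.0, 0.31, alpha_est=0.57) == pytest.approx(
            0.12, abs=0.005)

    def test_lambda_one_identity(self):
        for b in (0.1, 0.5, 2.0):
            assert alpha_bias_relation(1.0, b, alpha_true=0.4) == pytest.approx(0.4)

    def test_contraction_underestimates(self):
        est = alpha_bias_relation(0.2, 0.3, alpha_true=0.5)
        assert est < 0.5
        est = alpha_bias_relation(5.0, 0.3, alpha_true=0.5)
        assert est > 0.5

    @given(st.floats(0.0, 0.95), st.floats(0.05, 2.0), st.floats(0.1, 10.0))
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, a_true, b, lam):
        est = alpha_bias_relation(lam, b, alpha_true=a_true)
        back = alpha_bias_relation(lam, b, alpha_est=est)
        assert back == pytest.approx(a_true, abs=1e-12)

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            alpha_bias_relation(0.0, 0.3, alpha_true=0.5)
        with pytest.raises(ValueError):
            alpha_bias_relation(1.0, 0.3)
        with pytest.raises(ValueError):
            alpha_bias_relation(1.0, 0.3, alpha_true=0.1, alpha_est=0.1)


class TestMKTable:
    def test_columns_and_reproducibility(self, clean_loci):
        t1 = mk_table(clean_loci, seed=3)
        t2 = mk_table(clean_loci, seed=3)
        assert list(t1.columns) == ["locus", "D_N", "P_N", "L_N",
                                    "D_S", "P_S", "L_S"]
        pd.testing.assert_frame_equal(t1, t2)

    def test_threshold_reduces_polymorphism_counts(self, dfe_loci):
        t0 = mk_table(dfe_loci, freq_threshold=0.0, seed=1)
        t10 = mk_table(dfe_loci, freq_threshold=0.10, seed=1)
        assert t10["P_N"].sum() <= t0["P_N"].sum()
        assert t10["P_S"].sum() <= t0["P_S"].sum()
        assert (t10["D_N"] == t0["D_N"]).all()

    def test_fww_threshold_direction_on_dfe_data(self):
        """Removing rare variants raises alpha_FWW when deleterious
        mutations segregate (tendency over seeds)."""
        from dfemk.annotate import annotate_loci
        from dfemk.simulate import SimulationConfig, generate_locus_set

        wins = 0
        total = 0
        for seed in range(8):
            cfg = SimulationConfig(n_loci=40, exon_len=498, intron_len=200,
                                   dfe_shape=0.3, dfe_mean_S=1000.0,
                                   missing_rate=0.0, alpha_true=0.3,
                                   seed=400 + seed)
            loci = annotate_loci(generate_locus_set(cfg).loci)
            try:
                a0 = alpha_fww(mk_table(loci, freq_threshold=0.0, seed=seed))
                a10 = alpha_fww(mk_table(loci, freq_threshold=0.10, seed=seed))
            except ValueError:
                continue
            total += 1
            wins += a10 > a0
        assert total >= 5
        assert wins / total > 0.6


class TestContrastAlpha:
    def test_identical_datasets(self):
        rng = np.random.default_rng(3)
        boot = rng.normal(0.5, 0.1, 400)
        assert contrast_alpha(boot, boot.copy()[::-1]) > 0.5

    def test_reproducible(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0.6, 0.1, 300), rng.normal(0.1, 0.1, 300)
        assert contrast_alpha(a, b) == contrast_alpha(a, b)
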