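import math

import numpy as np
import pytest
from scipy import stats as sp_stats

from dfemk.dfe.likelihood import f0_adjust, grouped_sfs_loglik, multinomial_loglik
from dfemk.dfe.transition import (
    Demography,
    SelectionGrid,
    expected_folded_sfs_neutral,
    expected_folded_sfs_selected,
    integrate_over_dfe,
    population_density,
)
from dfemk.dfe.fit import (
    DemographicModel,
    GammaDFE,
    bootstrap_contrast_pvalue,
    nes_class_proportions,
    weighted_recent_n,
)
from dfemk.sfs import fold_vector


class TestNeutralExpectation:
    def test_equilibrium_proportional_to_folded_one_over_i(self):
        d = Demography(100, 100, 0)
        # population density itself is proportional to 1/j in the interior
        two_n, v = population_density(d, 0.0)
        scaled = v * np.arange(1, two_n)
        inner = scaled[2:80]
        assert np.allclose(inner, inner.mean(), rtol=0.02)
        # the folded sample spectrum tracks folded 1/i (small discrete-grid
        # edge effects at the largest counts)
        n = 20
        sfs = expected_folded_sfs_neutral(d, n)
        unfolded = 1.0 / np.arange(1, n)
        expected = fold_vector(np.concatenate([[0.0], unfolded, [0.0]]))
        seg = sfs[1:] / sfs[1:].sum()
        exp_seg = expected[1:] / expected[1:].sum()
        assert np.allclose(seg, exp_seg, rtol=0.07)

    def test_t_zero_equals_any_second_size(self):
        a = expected_folded_sfs_neutral(Demography(80, 80, 0), 20)
        b = expected_folded_sfs_neutral(Demography(80, 400, 0), 20)
        assert np.allclose(a, b)

    def test_expansion_increases_singleton_excess(self):
        eq = expected_folded_sfs_neutral(Demography(100, 100, 0), 20)
        exp = expected_folded_sfs_neutral(Demography(100, 300, 60), 20)
        assert (exp[1] / exp[1:].sum()) > (eq[1] / eq[1:].sum())

    def test_sums_to_one_nonnegative(self):
        for d in (Demography(60, 60, 0), Demography(60, 120, 30)):
            v = expected_folded_sfs_neutral(d, 15)
            assert (v >= 0).all()
            assert v.sum() == pytest.approx(1.0, abs=1e-9)


class TestSelectedExpectation:
    def test_s_zero_equals_neutral(self):
        d = Demography(80, 160, 40)
        a = expected_folded_sfs_selected(d, 0.0, 20)
        b = expected_folded_sfs_neutral(d, 20)
        assert np.allclose(a, b)

    def test_strong_selection_concentrates_on_singletons(self):
        d = Demography(100, 100, 0)
        v = expected_folded_sfs_selected(d, 20.0, 20)
        seg = v[1:] / v[1:].sum()
        assert seg[0] > 0.75
        assert v[1:].sum() < expected_folded_sfs_neutral(d, 20)[1:].sum()

    def test_lethal_is_all_monomorphic(self):
        d = Demography(60, 60, 0)
        v = expected_folded_sfs_selected(d, 1e9, 12)
        assert v[0] == pytest.approx(1.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            expected_folded_sfs_selected(Demography(60, 60, 0), float("inf"), 12)

    def test_grid_size_guard(self):
        with pytest.raises(ValueError):
            Demography(100, 4000, 10)


class TestOracleAgreement:
    """Transition-matrix expectations vs the independently coded exact chain."""

    @pytest.mark.parametrize("s", [0.0, 0.05, 0.2])
    def test_population_density_matches_oracle(self, s):
        from dfemk.simulate.wright_fisher import demographic_sojourn_density

        for demog in (Demography(100, 100, 0), Demography(100, 200, 50)):
            two_n_a, va = population_density(demog, s)
            two_n_b, vb = demographic_sojourn_density(
                demog.two_n1, demog.two_n2, demog.t, s)
            assert two_n_a == two_n_b
            assert np.allclose(va, vb, rtol=1e-8, atol=1e-10)

    def test_matches_forward_monte_carlo_sojourn(self):
        """Expected sample SFS at 2N=100 vs brute-force forward simulation.

        The forward engine accumulates the sojourn histogram of new
        mutations over their whole lifetime; binomial sampling of that
        histogram is the Monte-Carlo analogue of the expected sample SFS.
        """
        from scipy import stats as sps

        from dfemk.simulate.wright_fisher import forward_wf_simulate

        two_n, n = 100, 10
        demog = Demography(two_n, two_n, 0)
        expected = expected_folded_sfs_neutral(demog, n)
        seg_expected = expected[1:] / expected[1:].sum()

        hist = np.zeros(two_n - 1)
        reps_per_batch = 10_000
        for batch in range(4):
            res = forward_wf_simulate(
                two_n, 0.0, 2500, seed=1000 + batch,
                n_replicates=reps_per_batch, record_trajectories=True)
            traj = res.trajectories
            transient = traj[(traj > 0) & (traj < two_n)]
            hist += np.bincount(transient - 1, minlength=two_n - 1)[: two_n - 1]
        freqs = np.arange(1, two_n) / two_n
        pmf = sps.binom.pmf(np.arange(n + 1)[None, :], n, freqs[:, None])
        seg_mc = fold_vector(hist @ pmf)[1:]
        seg_mc = seg_mc / seg_mc.sum()
        assert np.allclose(seg_mc, seg_expected, atol=0.01)


class TestDFEIntegration:
    def test_point_mass_limit(self):
        d = Demography(80, 80, 0)
        grid = SelectionGrid(d, [16], n_grid=64)
        # very large shape concentrates the gamma at its mean
        v_mix = grid.expected_sfs(200.0, 5.0, 16)
        v_point = expected_folded_sfs_selected(d, 5.0, 16)
        seg_mix = v_mix[1:] / v_mix[1:].sum()
        seg_point = v_point[1:] / v_point[1:].sum()
        assert np.allclose(seg_mix, seg_point, rtol=0.05)

    def test_mean_zero_is_neutral(self):
        d = Demography(80, 80, 0)
        v = integrate_over_dfe(d, 0.5, 0.0, 16)
        assert np.allclose(v, expected_folded_sfs_neutral(d, 16))

    def test_quadrature_self_convergence(self):
        d = Demography(80, 80, 0)
        a = integrate_over_dfe(d, 0.3, 50.0, 16, n_quadrature=64)
        b = integrate_over_dfe(d, 0.3, 50.0, 16, n_quadrature=128)
        assert np.abs(a - b).max() < 1e-4

    def test_quadrature_minimum(self):
        with pytest.raises(ValueError):
            integrate_over_dfe(Demography(80, 80, 0), 0.3, 50.0, 16,
                               n_quadrature=8)


class TestLikelihood:
    def test_hand_evaluated_toy(self):
        ll = multinomial_loglik(np.array([10.0, 5.0]), np.array([2 / 3, 1 / 3]))
        assert ll == pytest.approx(-9.548, abs=1e-3)
        assert ll == pytest.approx(10 * math.log(2 / 3) + 5 * math.log(1 / 3))

    def test_empty_spectrum_zero(self):
        assert multinomial_loglik(np.zeros(4), np.full(4, 0.25)) == 0.0

    def test_additivity_over_groups(self):
        obs = {20: np.array([50.0, 5.0, 3.0] + [0.0] * 8)}
        fn = lambda n: f0_adjust(
            expected_folded_sfs_neutral(Demography(60, 60, 0), n), 0.0)
        one = grouped_sfs_loglik(obs, lambda n: expected_folded_sfs_neutral(
            Demography(60, 60, 0), n), 0.3)
        both = grouped_sfs_loglik(
            {20: obs[20], 18: np.zeros(10)},
            lambda n: expected_folded_sfs_neutral(Demography(60, 60, 0), n), 0.3)
        assert both == pytest.approx(one)

    def test_zero_probability_flagged(self):
        assert multinomial_loglik(np.array([1.0, 1.0]),
                                  np.array([1.0, 0.0])) == -math.inf

    def test_f0_adjust_bounds(self):
        with pytest.raises(ValueError):
            f0_adjust(np.array([0.5, 0.5]), 1.5)


class TestWeightedN:
    def test_t_zero_gives_n1(self):
        assert weighted_recent_n(DemographicModel(100, 200, 0)) == 100

    def test_large_t_gives_n2(self):
        nw = weighted_recent_n(DemographicModel(100, 200, 100_000))
        assert nw == pytest.approx(200, rel=1e-6)

    def test_closed_form_value(self):
        nw = weighted_recent_n(DemographicModel(100, 200, 100))
        assert nw == pytest.approx(100 * math.exp(-0.25)
                                   + 200 * (1 - math.exp(-0.25)), rel=1e-12)
        assert nw == pytest.approx(122.1, abs=0.05)


class TestNesClassProportions:
    def test_strong_selection_limit(self):
        p = nes_class_proportions(GammaDFE(2.0, 1e9))
        assert p[2] == pytest.approx(1.0, abs=1e-6)

    def test_weak_selection_limit(self):
        p = nes_class_proportions(GammaDFE(2.0, 1e-9))
        assert p[0] == pytest.approx(1.0, abs=1e-6)

    def test_matches_independent_cdf_oracle(self):
        shape, mean = 0.31, 1e4
        p = nes_class_proportions(GammaDFE(shape, mean))
        # oracle: numerical integration of the gamma density; the x^(a-1)
        # endpoint singularity is handled with an algebraic quadrature weight
        from math import gamma as gamma_func

        from scipy import integrate

        scale = mean / shape
        const = 1.0 / (gamma_func(shape) * scale**shape)
        p0, _ = integrate.quad(lambda x: const * np.exp(-x / scale), 0, 1,
                               weight="alg", wvar=(shape - 1, 0))
        p1, _ = integrate.quad(
            lambda x: sp_stats.gamma.pdf(x, a=shape, scale=scale), 1, 10)
        assert p[0] == pytest.approx(p0, abs=1e-6)
        assert p[1] == pytest.approx(p1, abs=1e-6)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)


class TestContrast:
    def test_identical_distributions_give_large_p(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 500)
        b = rng.normal(0, 1, 500)
        assert bootstrap_contrast_pvalue(a, b) > 0.2

    def test_separated_distributions_give_small_p(self):
        rng = np.random.default_rng(2)
        a = rng.normal(3, 0.5, 500)
        b = rng.normal(0, 0.5, 500)
        assert bootstrap_contrast_pvalue(a, b) < 0.01

    def test_few_replicates_warn(self):
        with pytest.warns(UserWarning):
            bootstrap_contrast_pvalue(np.ones(10), np.zeros(10))
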