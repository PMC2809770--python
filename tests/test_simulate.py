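import numpy as np
import pytest
from scipy import stats as sp_stats

from dfemk.annotate import annotate_loci
from dfemk.simulate import (
    SimulationConfig,
    WFState,
    exact_absorption_probabilities,
    exact_sojourn_times,
    forward_wf_simulate,
    generate_locus_set,
    simulate_population_sfs,
)
from dfemk.simulate.wright_fisher import demographic_sojourn_density
from dfemk import stats as pg_stats


class TestConfig:
    def test_defaults_valid(self):
        SimulationConfig()

    @pytest.mark.parametrize("kwargs", [
        {"missing_rate": 1.5},
        {"alpha_true": 1.0},
        {"dfe_shape": 0.0},
        {"dfe_mean_S": -1.0},
        {"div_neutral_far": 0.8},
        {"exon_len": 100},
        {"demog": (1.0, -2.0, 10)},
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        cfg = SimulationConfig(n_loci=3, seed=9)
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        assert SimulationConfig.from_yaml(str(path)) == cfg


class TestWFState:
    def test_bounds(self):
        WFState(pop_size_2N=10, allele_count=10)
        with pytest.raises(ValueError):
            WFState(pop_size_2N=10, allele_count=11)


class TestForwardEngine:
    def test_invalid_args(self):
        with pytest.raises(ValueError):
            forward_wf_simulate(100, float("nan"), 10, seed=0)
        with pytest.raises(ValueError):
            forward_wf_simulate(2, 0.0, 10, seed=0)

    def test_fixed_state_is_absorbing(self):
        res = forward_wf_simulate(50, -0.1, 100, seed=1, n_replicates=20,
                                  initial_count=50)
        assert res.fixed.all()

    def test_neutral_fixation_fraction(self):
        two_n = 50
        res = forward_wf_simulate(two_n, 0.0, 3000, seed=2, n_replicates=60_000)
        assert res.fixed.sum() + res.lost.sum() == 60_000
        p = res.fixation_fraction
        se = np.sqrt((1 / two_n) * (1 - 1 / two_n) / 60_000)
        assert abs(p - 1 / two_n) < 4 * se

    def test_heterozygosity_decay(self):
        """Replicate-mean 2p(1-p) declines by (1 - 1/2N) per generation."""
        two_n, gens, reps = 40, 30, 40_000
        res = forward_wf_simulate(two_n, 0.0, gens, seed=3, n_replicates=reps,
                                  initial_count=two_n // 2,
                                  record_trajectories=True)
        p = res.trajectories / two_n
        het = (2 * p * (1 - p) * two_n / (two_n - 1)).mean(axis=0)
        expected = het[0] * (1 - 1 / two_n) ** np.arange(gens + 1)
        assert np.allclose(het, expected, rtol=0.02)

    def test_reproducible_under_seed(self):
        a = forward_wf_simulate(60, -0.05, 200, seed=11, n_replicates=100)
        b = forward_wf_simulate(60, -0.05, 200, seed=11, n_replicates=100)
        assert (a.final_counts == b.final_counts).all()

    def test_size_change_epoch(self):
        res = forward_wf_simulate(
            20, 0.0, 0, seed=4, n_replicates=500, initial_count=10,
            epochs=[(20, 5), (40, 5)],
        )
        assert res.pop_size_2N == 40
        assert (res.final_counts <= 40).all()


class TestExactChain:
    @pytest.mark.parametrize("two_n,S", [(50, 5.0), (50, -5.0), (100, 20.0),
                                         (100, -20.0), (100, 0.0)])
    def test_forward_matches_fundamental_matrix(self, two_n, S):
        s = S / two_n
        exact = exact_absorption_probabilities(two_n, s)[1]
        reps = 40_000
        res = forward_wf_simulate(two_n, s, 60 * two_n, seed=int(abs(S)) + two_n,
                                  n_replicates=reps)
        assert (res.fixed | res.lost).all()
        mc = res.fixation_fraction
        se = np.sqrt(max(exact * (1 - exact), 1e-9) / reps)
        assert abs(mc - exact) < 4 * se + 1e-6

    def test_sojourn_matches_forward_histogram(self):
        two_n, s, reps = 30, -0.1, 30_000
        expected = exact_sojourn_times(two_n, s)
        res = forward_wf_simulate(two_n, s, 40 * two_n, seed=5,
                                  n_replicates=reps, record_trajectories=True)
        traj = res.trajectories
        hist = np.zeros(two_n - 1)
        for j in range(1, two_n):
            hist[j - 1] = (traj[:, 1:] == j).sum() / reps
        # entry generation: trajectories start at count 1 before reproduction
        hist[0] += 1.0
        assert np.allclose(hist, expected, rtol=0.08, atol=0.02)


class TestPopulationSFS:
    def test_t_zero_ignores_second_size(self):
        base = SimulationConfig(seed=1, demog=(1.0, 1.0, 0), missing_rate=0.0)
        alt = SimulationConfig(seed=1, demog=(1.0, 3.0, 0), missing_rate=0.0)
        a = simulate_population_sfs(base, n_sites={"4fold": 5000}, classes=("4fold",))
        b = simulate_population_sfs(alt, n_sites={"4fold": 5000}, classes=("4fold",))
        assert (a["4fold"].spectra[30] == b["4fold"].spectra[30]).all()

    def test_neutral_equilibrium_one_over_i(self):
        """Unfolded expectation proportional to 1/i before folding."""
        two_n, v = demographic_sojourn_density(100, 100, 0, 0.0)
        j = np.arange(1, two_n)
        ratio = v * j
        inner = ratio[2:60]
        assert np.allclose(inner, inner.mean(), rtol=0.03)

    def test_no_selection_matches_neutral_class(self):
        cfg = SimulationConfig(seed=8, dfe_mean_S=0.0, missing_rate=0.0,
                               demog=(1.0, 1.0, 0))
        sfs = simulate_population_sfs(
            cfg, n_sites={"0fold": 40_000, "4fold": 40_000},
            classes=("0fold", "4fold"))
        a = sfs["0fold"].spectra[30]
        b = sfs["4fold"].spectra[30]
        obs = np.vstack([a[1:], b[1:]])
        keep = obs.sum(axis=0) >= 5
        chi2, p, *_ = sp_stats.chi2_contingency(obs[:, keep])
        assert p > 0.01

    def test_strong_dfe_suppresses_diversity(self):
        """0-fold/4-fold diversity ratio matches the sojourn-integral oracle."""
        cfg = SimulationConfig(seed=9, dfe_shape=0.3, dfe_mean_S=1000.0,
                               missing_rate=0.0, demog=(1.0, 1.0, 0))
        sfs = simulate_population_sfs(
            cfg, n_sites={"0fold": 300_000, "4fold": 300_000},
            classes=("0fold", "4fold"))

        def pi_of(g):
            total = 0.0
            for n, vec in g.spectra.items():
                k = np.arange(len(vec))
                total += float((vec * 2 * k * (n - k) / (n * (n - 1))).sum())
            return total / g.total_sites

        ratio = pi_of(sfs["0fold"]) / pi_of(sfs["4fold"])
        assert ratio < 0.5
        # oracle: expected heterozygosity ratio by integrating the sojourn
        # density over the equal-mass gamma discretisation
        n_w = cfg.weighted_n()
        u = (np.arange(200) + 0.5) / 200
        s_vals = sp_stats.gamma.ppf(u, a=0.3, scale=1000.0 / 0.3) / n_w
        het_neutral = het_sel = 0.0
        two_n, v0 = demographic_sojourn_density(cfg.two_n1, cfg.two_n2, 0, 0.0)
        x = np.arange(1, two_n) / two_n
        het_neutral = float(v0 @ (2 * x * (1 - x)))
        for s in s_vals:
            if s >= 0.99:
                continue
            _, v = demographic_sojourn_density(cfg.two_n1, cfg.two_n2, 0, float(s))
            het_sel += float(v @ (2 * x * (1 - x))) / 200
        expected_ratio = het_sel / het_neutral
        assert ratio == pytest.approx(expected_ratio, rel=0.15)

    def test_reproducible(self):
        cfg = SimulationConfig(seed=10)
        a = simulate_population_sfs(cfg, n_sites={"4fold": 2000}, classes=("4fold",))
        b = simulate_population_sfs(cfg, n_sites={"4fold": 2000}, classes=("4fold",))
        assert (a["4fold"].spectra[30] == b["4fold"].spectra[30]).all()


class TestLocusSet:
    def test_full_coverage_without_missing(self, clean_loci):
        for locus in clean_loci:
            assert (locus.coverage == 30).all()

    def test_close_outgroup_identical_when_divergence_zero(self):
        cfg = SimulationConfig(n_loci=4, exon_len=300, intron_len=100,
                               div_neutral_close=0.0, theta_neutral=0.0,
                               missing_rate=0.0, seed=3)
        ls = generate_locus_set(cfg)
        for raw in ls.loci:
            assert raw.outgroup_close == raw.alleles[0]

    def test_far_divergence_matches_target(self):
        cfg = SimulationConfig(n_loci=60, exon_len=300, intron_len=300,
                               missing_rate=0.0, seed=17)
        loci = annotate_loci(generate_locus_set(cfg).loci)
        n_diff, n_valid = pg_stats.divergence_counts(loci, "4fold", "far")
        d = pg_stats.jc_correct(n_diff / n_valid)
        # binomial CI on the raw proportion, propagated through the JC curve
        p_target = 0.75 * (1 - np.exp(-4 * cfg.div_neutral_far / 3))
        se = np.sqrt(p_target * (1 - p_target) / n_valid)
        lo = pg_stats.jc_correct(p_target - 4 * se)
        hi = pg_stats.jc_correct(p_target + 4 * se)
        assert lo < d < hi

    def test_exon_len_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(exon_len=301)

    def test_bit_reproducible(self):
        cfg = SimulationConfig(n_loci=3, exon_len=150, intron_len=100, seed=77,
                               missing_rate=0.05, inbreeding_F=0.3)
        a = generate_locus_set(cfg)
        b = generate_locus_set(cfg)
        for la, lb in zip(a.loci, b.loci):
            assert la.alleles == lb.alleles
            assert la.outgroup_far == lb.outgroup_far

    def test_write_read_round_trip(self, tmp_path, clean_locus_set):
        from dfemk.simulate import read_locus_set, write_locus_set

        out = tmp_path / "data"
        write_locus_set(clean_locus_set, str(out))
        back = read_locus_set(str(out))
        assert len(back.loci) == len(clean_locus_set.loci)
        for la, lb in zip(clean_locus_set.loci, back.loci):
            assert la.reference == lb.reference
            assert la.alleles == lb.alleles
            assert la.features == lb.features
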