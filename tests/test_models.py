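"""The model zoo: Eldon-Wakeley, bottlenecks, PD-power, the exponential model."""

import math

import numpy as np
import pytest
from scipy import special, stats

import asymcoal as ac
from asymcoal.models import (
    _TruncatedYSampler,
    exp_model_timescale_constants,
    pd_timescale_ell,
    stick_breaking_K,
    upsilon_constant,
)
from asymcoal.partitions import Partition
from asymcoal.rates import BOLTHAUSEN_SZNITMAN, LambdaMeasure


class TestEldonWakeley:
    def test_deterministic_half_sweep_offspring_vector(self, rng):
        params = ac.EldonWakeleyParams(LambdaMeasure.point_mass(0.5), 0.3, 10)
        xi = ac.eldon_wakeley_offspring(params, rng)
        assert sorted(xi.tolist(), reverse=True) == [5, 1, 1, 1, 1, 1, 0, 0, 0, 0]
        assert xi.sum() == 10

    def test_pair_coalescence_matches_floor_formula(self):
        params = ac.EldonWakeleyParams(LambdaMeasure.point_mass(0.5), 0.3, 10)
        c, se = ac.pair_coalescence_probability(ac.EldonWakeleyOffspring(params))
        assert se == 0.0 and c == pytest.approx(20 / 90)

    def test_full_sweep_forces_mrca_in_one_generation(self):
        params = ac.EldonWakeleyParams(LambdaMeasure.point_mass(1.0), 0.5, 20)
        trace = ac.simulate_genealogy(ac.EldonWakeleyOffspring(params), 5, seed=3)
        assert trace.mrca_reached and trace.times[-1] == 1.0

    def test_zero_mass_above_cutoff_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            ac.EldonWakeleyOffspring(
                ac.EldonWakeleyParams(LambdaMeasure.point_mass(0.5), 0.5, 10)
            )

    def test_sampler_moments_match_quadrature(self, rng):
        # beta(1,1): truncated law y^{-2} dy on (c, 1]; E[Y^b] has closed form
        c = 0.1
        sampler = _TruncatedYSampler(BOLTHAUSEN_SZNITMAN, c)
        y = sampler.sample(rng, 50_000)
        for b in (2, 3):
            closed = {
                2: (1 - c) / (1 / c - 1),
                3: (1 - c**2) / 2 / (1 / c - 1),
            }[b]
            assert sampler.moment(b) == pytest.approx(closed, rel=1e-6)
            se = np.std(y**b, ddof=1) / math.sqrt(len(y))
            assert abs(np.mean(y**b) - closed) < 4 * se

    def test_moment_ratio_tends_to_bs_limit_across_N(self):
        # E[Y^3]/E[Y^2] -> lambda_{3,3}/lambda_{2,2} = 1/2 as the cutoff vanishes
        ratios = [
            ac.EldonWakeleyOffspring(
                ac.EldonWakeleyParams(BOLTHAUSEN_SZNITMAN, 0.5, N)
            ).y_moment(3)
            / ac.EldonWakeleyOffspring(
                ac.EldonWakeleyParams(BOLTHAUSEN_SZNITMAN, 0.5, N)
            ).y_moment(2)
            for N in (100, 1000, 10_000)
        ]
        assert ratios[0] > ratios[1] > ratios[2] > 0.5

    def test_frequency_version_scales_offspring(self, rng):
        params = ac.EldonWakeleyParams(LambdaMeasure.point_mass(0.5), 0.3, 10)
        eta = ac.EldonWakeleyFrequency(params).sample(rng)
        assert eta.sum() == pytest.approx(1.0)
        assert eta.max() == pytest.approx(0.5)


class TestBottleneck:
    def _params(self, nu=None, F=None):
        return ac.BottleneckParams(
            F=F or {2: 1.0},
            a_N=lambda n: n**0.5,
            b_N=lambda n: max(2, int(round(n**0.25))),
            nu_bar=nu or ac.SymmetricBottleneckLaw(),
        )

    def test_zero_F_reduces_to_hat_model(self, rng):
        params = self._params(F={2: 0.0})
        eta = ac.bottleneck_frequencies(params, 100, rng)
        assert np.allclose(eta, 1 / 100)

    def test_symmetric_law_conditional_pair_merge(self):
        nu = ac.SymmetricBottleneckLaw()
        for k in (2, 5, 10):
            assert nu.pair_merge_probability(k) == pytest.approx(1 / k)

    def test_bottleneck_probability_validated(self):
        params = self._params(F={2: 50.0})
        with pytest.raises(ValueError):
            params.bottleneck_probability(100)  # 50/10 > 1

    def test_limit_rates_symmetric_pair(self):
        # F = delta_2 weight w, nu_2 = (1/2,1/2), n = 2: Q_bar(merge) = w/2
        params = self._params(F={2: 0.8})
        Q, report = ac.bottleneck_limit_rates(params, 2)
        assert Q.rate(Partition(2, [[1, 2]])) == pytest.approx(0.4)
        assert report["regime"] == "bottleneck-dominated"

    def test_limit_rates_n3_paintbox_values(self):
        params = self._params()
        Q, _ = ac.bottleneck_limit_rates(params, 3)
        # paint-box of (1/2, 1/2) on [3]: each labeled pair 1/4, triple 1/4
        assert Q.rate(Partition(3, [[1, 2], [3]])) == pytest.approx(0.25)
        assert Q.rate(Partition(3, [[1, 2, 3]])) == pytest.approx(0.25)

    def test_dirichlet_law_rates_close_to_mc_pair_probability(self, rng):
        nu = ac.NormalizedWeightsBottleneckLaw()
        params = self._params(nu=nu, F={3: 1.0})
        Q, _ = ac.bottleneck_limit_rates(params, 2, rng=rng, mc_atoms=512)
        # E[sum (W_i/S)^2] for k=3 exponential weights (Dirichlet(1,1,1)): 1/2
        assert Q.rate(Partition(2, [[1, 2]])) == pytest.approx(0.5, abs=0.02)

    def test_forward_pair_merge_probability(self, rng):
        # (F(2)/a_N) * 1/2 + (1 - F(2)/a_N) * 1/N, checked by simulation
        N = 2500
        params = self._params()
        model = ac.BottleneckFrequency(params, N)
        draws = 20_000
        merged = sum(
            len(ac.awf_increment(model.sample(rng), 2, rng)) == 1 for _ in range(draws)
        )
        target = 0.5 / N**0.5 + (1 - 1 / N**0.5) / N
        se = math.sqrt(target * (1 - target) / draws)
        assert abs(merged / draws - target) < 3 * se


class TestPDStickBreaking:
    def test_first_stick_mean(self, rng):
        # E[V_1] = (1 - alpha)/(1 + theta)
        alpha, theta = 0.6, 0.8
        V, _ = ac.pd_stick_breaking(alpha, theta, 1, rng)
        draws = np.array(
            [ac.pd_stick_breaking(alpha, theta, 1, rng)[0][0] for _ in range(20_000)]
        )
        se = draws.std(ddof=1) / math.sqrt(len(draws))
        assert abs(draws.mean() - (1 - alpha) / (1 + theta)) < 3 * se

    def test_partial_sums_below_one_and_increasing(self, rng):
        V, Y = ac.pd_stick_breaking(0.5, 0.0, 200, rng)
        s = np.cumsum(V)
        assert np.all(np.diff(s) > 0) and s[-1] < 1.0
        assert np.all((Y > 0) & (Y < 1))

    def test_invalid_domain_rejected(self, rng):
        with pytest.raises(ValueError):
            ac.pd_stick_breaking(1.2, 0.0, 5, rng)
        with pytest.raises(ValueError):
            ac.pd_stick_breaking(0.5, -0.6, 5, rng)

    def test_change_of_parameters_property(self, rng):
        # removing V_1 and renormalizing turns PD(a, th) into PD(a, th + a):
        # V_2/(1 - V_1) must be Beta(1-a, th+2a) like a fresh first stick
        alpha, theta = 0.55, 0.2
        draws = 10_000
        first = np.empty(draws)
        for k in range(draws):
            V, _ = ac.pd_stick_breaking(alpha, theta, 2, rng)
            first[k] = V[1] / (1 - V[0])
        fresh = rng.beta(1 - alpha, theta + 2 * alpha, size=draws)
        ks = stats.ks_2samp(first, fresh)
        assert ks.pvalue > 0.01


class TestPDPowerFrequencies:
    def test_gamma_zero_is_uniform(self, rng):
        m = ac.PDPowerFrequency(ac.PDPowerParams(0.5, 0.0, 0.0, 40))
        assert np.allclose(m.sample(rng), 1 / 40)

    def test_rows_are_probability_vectors(self, rng):
        m = ac.PDPowerFrequency(ac.PDPowerParams(0.7, 0.2, 0.6, 100))
        batch = m.sample_batch(rng, 50)
        assert np.allclose(batch.sum(axis=1), 1.0)
        assert np.all(batch > 0)

    def test_gamma_one_is_renormalized_pd_prefix(self, rng):
        m = ac.PDPowerFrequency(ac.PDPowerParams(0.9, 0.0, 0.9, 30))
        r1 = np.random.default_rng(4)
        eta = m.sample(r1)
        r2 = np.random.default_rng(4)
        V, _ = ac.pd_stick_breaking(0.9, 0.0, 30, r2)
        assert np.allclose(eta, V**0.9 / np.sum(V**0.9))

    def test_out_of_regime_gamma_warns(self):
        with pytest.warns(UserWarning):
            ac.PDPowerParams(0.5, 0.0, 0.1, 10)


class TestPDConstants:
    def test_harmonic_u_N(self):
        consts = ac.pd_constants(0.5, 0.0, 0.5, 10)
        assert consts.u_N == pytest.approx(2.9289682539682538, abs=1e-12)

    def test_upsilon_matches_partial_sums(self):
        for a in (0.0, 0.4, 2.5):
            M = 2_000_000
            partial = np.sum(1.0 / (a + np.arange(1, M + 1))) - math.log(M)
            assert upsilon_constant(a) == pytest.approx(partial, abs=1e-5)
        assert upsilon_constant(0.0) == pytest.approx(np.euler_gamma, abs=1e-12)

    def test_K_matches_mu_N_expansion(self):
        # e^{mu_N} ~ K N^{(1-alpha)/alpha} / alpha  (numerical check at N = 1e6)
        alpha, theta, N = 0.7, 0.2, 1_000_000
        i = np.arange(1, N + 1)
        mu = float(
            np.sum(special.digamma(theta + (i - 1) * alpha + 1)
                   - special.digamma(theta + i * alpha))
        )
        approx = stick_breaking_K(alpha, theta) * N ** ((1 - alpha) / alpha) / alpha
        assert math.exp(mu) == pytest.approx(approx, rel=1e-4)

    def test_K_makes_martingale_moment_formula_true(self, rng):
        # E[e^{g S_inf}] = K^g Gamma(th+1)/Gamma(th+g+1) *
        #                  Gamma((th+g)/a + 1)/Gamma(th/a + 1)
        alpha, theta, g = 0.5, 0.5, -0.375
        N, reps = 100_000, 400
        i = np.arange(1, N + 1)
        mu = float(
            np.sum(special.digamma(theta + (i - 1) * alpha + 1)
                   - special.digamma(theta + i * alpha))
        )
        vals = np.empty(reps)
        for k in range(reps):
            Y = rng.beta(1 - alpha, theta + alpha * i)
            vals[k] = math.exp(g * (mu + np.log1p(-Y).sum()))
        K = stick_breaking_K(alpha, theta)
        formula = (
            K**g
            * math.gamma(theta + 1) / math.gamma(theta + g + 1)
            * math.gamma((theta + g) / alpha + 1) / math.gamma(theta / alpha + 1)
        )
        se = vals.std(ddof=1) / math.sqrt(reps)
        assert abs(vals.mean() - formula) < 4 * se

    def test_theta_zero_ell_simplification(self):
        # ell^{-1} = (a/g) Gamma(2 - g/a) / (Gamma(1+g-a) Gamma(1+a-g)) at theta=0,
        # from term-by-term simplification of the general display
        for alpha, gamma in [(0.5, 0.5), (0.5, 0.375), (0.7, 0.6)]:
            simplified = (
                (alpha / gamma)
                * math.gamma(2 - gamma / alpha)
                / (math.gamma(1 + gamma - alpha) * math.gamma(1 + alpha - gamma))
            )
            assert 1 / pd_timescale_ell(alpha, 0.0, gamma) == pytest.approx(
                simplified, rel=1e-12
            )

    def test_predicted_c_N_only_in_beta_regime(self):
        assert ac.pd_constants(0.5, 0.0, 0.5, 100).c_N_predicted is not None
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert ac.pd_constants(0.5, 0.8, 0.5, 100).c_N_predicted is None


class TestZetaLimit:
    def test_pathwise_convergence_to_constant(self, rng):
        # r_N = zeta/(u_N e^{gamma S_N}) converges a.s.; at N = 1e7 all paths
        # sit within 10% of Gamma(1+g-a)/Gamma(1-a) K^{-g}
        rep = ac.zeta_limit_check(0.7, 0.2, 0.6, [10**6, 10**7], rng, paths=3)
        assert max(rep["relative_deviation_at_N_max"]) < 0.10

    def test_median_sticks_smoke(self):
        # replacing Y_i by their medians keeps the ratio finite and stable
        alpha, theta, gamma = 0.7, 0.2, 0.6
        N = 10_000
        i = np.arange(1, N + 1)
        Y = stats.beta.median(1 - alpha, theta + alpha * i)
        V = Y * np.concatenate([[1.0], np.cumprod(1 - Y)[:-1]])
        zeta = np.cumsum(V**gamma)
        u = np.cumsum(i ** (-gamma / alpha))
        mu = np.cumsum(
            special.digamma(theta + (i - 1) * alpha + 1)
            - special.digamma(theta + i * alpha)
        )
        S = mu + np.cumsum(np.log1p(-Y))
        r = zeta / (u * np.exp(gamma * S))
        tail = r[len(r) // 2 :]
        assert np.all(np.isfinite(tail)) and tail.std() / tail.mean() < 0.05

    def test_gamma_above_alpha_zeta_converges(self, rng):
        # for gamma > alpha, zeta_N has an a.s. finite limit
        alpha, theta, gamma = 0.5, 0.0, 0.8
        V, _ = ac.pd_stick_breaking(alpha, theta, 20_000, rng)
        zeta = np.cumsum(V**gamma)
        assert zeta[-1] - zeta[len(zeta) // 2] < 1e-2 * zeta[-1]

    def test_domain_validated(self, rng):
        with pytest.raises(ValueError):
            ac.zeta_limit_check(0.5, 0.0, 0.2, [100], rng)


class TestExponentialModel:
    def test_parameter_domain(self):
        with pytest.raises(ValueError):
            ac.ExpModelParams(N=10, beta=1.0, kappa=1.0)
        with pytest.raises(ValueError):
            ac.ExpModelParams(N=10, beta=2.0, kappa=1.0, K_atoms=5).resolved_K()

    def test_equal_positions_give_uniform_parent_choice(self, rng):
        params = ac.ExpModelParams(N=50, beta=2.0, kappa=1.0)
        _, parents = ac.exp_model_step(params, np.zeros(50), rng)
        assert parents.min() >= 0 and parents.max() < 50
        # uniformity: chi-square over many steps
        counts = np.zeros(50)
        for _ in range(200):
            _, parents = ac.exp_model_step(params, np.zeros(50), rng)
            counts += np.bincount(parents, minlength=50)
        assert stats.chisquare(counts).pvalue > 0.01

    def test_dominant_parent_takes_all_children(self, rng):
        params = ac.ExpModelParams(N=5, beta=2.0, kappa=1.0)
        positions = np.array([100.0, 0.0, 0.0, 0.0, 0.0])
        _, parents = ac.exp_model_step(params, positions, rng)
        assert np.all(parents == 0)

    def test_reduction_parameters(self):
        red = ac.exp_model_reduction(ac.ExpModelParams(N=10, beta=2.0, kappa=1.0))
        p = red.params
        assert (p.alpha, p.theta, p.gamma) == (0.5, 0.0, 0.5)

    def test_family_frequency_law_matches_reduction(self, rng):
        # two-sample KS on the largest family frequency (the Prop-5.2 identity)
        N = 100
        params = ac.ExpModelParams(N=N, beta=2.0, kappa=1.0)
        em = ac.ExpModelFrequency(params)
        red = ac.exp_model_reduction(params)
        reps = 1000
        mx_em = np.array([em.sample(rng).max() for _ in range(reps)])
        mx_rd = red.sample_batch(rng, reps).max(axis=1)
        assert stats.ks_2samp(mx_em, mx_rd).pvalue > 0.01

    def test_increment_laws_agree_between_constructions(self, rng):
        # chi-square on partition-of-[3] profiles, explicit step vs reduction
        N = 50
        params = ac.ExpModelParams(N=N, beta=2.0, kappa=1.0)
        em = ac.ExpModelFrequency(params)
        red = ac.exp_model_reduction(params)
        draws = 4000
        cats = [(1, 1, 1), (2, 1), (3,)]
        obs = {c: 0 for c in cats}
        exp_counts = {c: 0 for c in cats}
        for _ in range(draws):
            obs[ac.awf_increment(em.sample(rng), 3, rng).profile()] += 1
            exp_counts[ac.awf_increment(red.sample(rng), 3, rng).profile()] += 1
        chi2 = stats.chisquare(
            [obs[c] for c in cats],
            f_exp=np.array([exp_counts[c] for c in cats])
            * draws / sum(exp_counts.values()),
        )
        assert chi2.pvalue > 0.005

    def test_timescale_candidates_coincide_at_kappa_one(self):
        consts = exp_model_timescale_constants(2.0, 1.0)
        assert consts["direct"] == pytest.approx(consts["printed"], abs=1e-12)
        consts75 = exp_model_timescale_constants(2.0, 0.75)
        assert consts75["direct"] != pytest.approx(consts75["printed"], abs=1e-3)
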