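"""Expression-model layer: densities, samplers, MLE fitters, nonparametrics."""

import numpy as np
import pytest
from scipy import integrate, stats

from retinaquant import models
from retinaquant.params import (
    GammaParams,
    NormalMixtureParams,
    ParameterError,
    TwoStateParams,
)
from retinaquant.reference import (
    RH6_R8_MIXTURE,
    TWO_STATE_FITS,
    WILDTYPE_GAMMA_FITS,
)


class TestDensities:
    def test_exponential_special_case(self):
        p = GammaParams(1.0, 2.0, 0.0)
        assert models.shifted_gamma_pdf(0.0, p) == pytest.approx(0.5)

    def test_wildtype_rh3_mode(self):
        # mode of a shifted gamma: shift + (alpha - 1) * beta
        p = WILDTYPE_GAMMA_FITS["Rh3"]
        assert p.mode == pytest.approx(1.57 + 4.6 * 0.17)
        assert p.mode == pytest.approx(2.352)
        grid = np.linspace(1.0, 5.0, 20001)
        dens = models.shifted_gamma_pdf(grid, p)
        assert grid[np.argmax(dens)] == pytest.approx(p.mode, abs=1e-3)

    @pytest.mark.parametrize("key", ["Rh3@0wk", "Rh5@0wk", "Rh3@4wk", "Rh6@4wk"])
    def test_two_state_pdf_normalized(self, key):
        p = TWO_STATE_FITS[key]
        # the on component diverges (integrably) at its shift when alpha_on < 1;
        # give the quadrature the breakpoints
        val, _ = integrate.quad(
            lambda x: models.two_state_pdf(x, p),
            0.0,
            500.0,
            points=[p.shift, p.shift_on],
            limit=800,
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_two_state_degenerate_mixtures(self):
        p = TWO_STATE_FITS["Rh3@0wk"]
        x = np.linspace(0, 20, 301)
        p0 = TwoStateParams(p.alpha_off, p.beta_off, p.alpha_on, p.beta_on, 0.0, p.shift)
        p1 = TwoStateParams(p.alpha_off, p.beta_off, p.alpha_on, p.beta_on, 1.0, p.shift)
        np.testing.assert_allclose(
            models.two_state_pdf(x, p0), models.shifted_gamma_pdf(x, p0.off)
        )
        np.testing.assert_allclose(
            models.two_state_pdf(x, p1), models.shifted_gamma_pdf(x, p1.on)
        )

    def test_on_shift_rules(self):
        # alpha_off > 1: on component sits at the off mode; else at the shift
        p = TwoStateParams(2.0, 0.5, 1.0, 1.0, 0.3, shift=1.0)
        assert p.shift_on == pytest.approx(1.5)
        p = TwoStateParams(0.8, 0.5, 1.0, 1.0, 0.3, shift=1.0)
        assert p.shift_on == pytest.approx(1.0)

    def test_invalid_params_raise(self):
        with pytest.raises(ParameterError):
            GammaParams(-1.0, 1.0)
        with pytest.raises(ParameterError):
            TwoStateParams(1.0, 1.0, 1.0, 1.0, 1.5)
        with pytest.raises(ParameterError):
            NormalMixtureParams(2.0, 1.0, 1.0, 1.0, 0.5)  # unordered means


class TestSampling:
    def test_p_on_zero_all_off(self):
        p = TwoStateParams(2.0, 0.5, 1.0, 1.0, 0.0, shift=1.0)
        levels, states = models.sample_two_state(p, 500, seed=0)
        assert not states.any()
        assert (levels >= p.shift).all()

    def test_mixture_mean_matches_closed_form(self):
        # closed-form mean of the mixture as oracle, 3 SE tolerance
        p = TWO_STATE_FITS["Rh5@0wk"]
        n = 100_000
        levels, _ = models.sample_two_state(p, n, seed=7)
        se = np.sqrt(p.var / n)
        assert abs(levels.mean() - p.mean) < 3 * se

    def test_state_fraction_binomial_ci(self):
        p = TWO_STATE_FITS["Rh3@0wk"]
        n = 100_000
        _, states = models.sample_two_state(p, n, seed=11)
        se = np.sqrt(p.p_on * (1 - p.p_on) / n)
        assert abs(states.mean() - p.p_on) < 4 * se

    def test_deterministic_given_seed(self):
        p = TWO_STATE_FITS["Rh6@1wk"]
        a = models.sample_two_state(p, 1000, seed=42)
        b = models.sample_two_state(p, 1000, seed=42)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestShiftedGammaFit:
    def test_recovers_wildtype_alpha_large_n(self):
        p = WILDTYPE_GAMMA_FITS["Rh3"]
        x = models.sample_shifted_gamma(p, 100_000, seed=5)
        est = models.ShiftedGamma().fit(x)
        assert abs(est.alpha_ - p.alpha) / p.alpha < 0.03

    def test_degenerate_sample_raises(self):
        with pytest.raises(ValueError):
            models.ShiftedGamma().fit(np.full(100, 3.0))

    def test_bias_at_published_sample_size(self):
        # Monte-Carlo recovery bias of alpha at n = 672 stays below 5 %
        p = WILDTYPE_GAMMA_FITS["Rh3"]
        alphas = []
        for rep in range(200):
            x = models.sample_shifted_gamma(p, 672, seed=1000 + rep)
            alphas.append(models.ShiftedGamma().fit(x).alpha_)
        bias = abs(np.mean(alphas) - p.alpha) / p.alpha
        assert bias < 0.05


class TestTwoStateFit:
    def test_recovers_p_on(self):
        p = TWO_STATE_FITS["Rh5@2wk"]
        levels, _ = models.sample_two_state(p, p.n, seed=3)
        est = models.TwoStateGammaMixture(random_state=0).fit(levels)
        assert abs(est.p_on_ - p.p_on) < 0.05

    def test_pure_off_data_gives_small_p_on(self):
        off = TwoStateParams(2.0, 0.17, 1.0, 1.0, 0.0, shift=1.62)
        levels, _ = models.sample_two_state(off, 2000, seed=9)
        est = models.TwoStateGammaMixture(random_state=0).fit(levels)
        assert est.p_on_ < 0.05

    def test_two_state_nests_single_gamma(self):
        # with p_on fixed to 0 the two-state likelihood equals the single
        # gamma's, and the free fit can only do better, on genuine mixture data
        p = TWO_STATE_FITS["Rh6@1wk"]
        levels, _ = models.sample_two_state(p, 1500, seed=21)
        shift = float(levels.min()) - 1e-4 * float(levels.std())
        single = models.ShiftedGamma(shift=shift).fit(levels)
        constrained = models.TwoStateGammaMixture(
            shift=shift, fix_p_on=0.0, random_state=0
        ).fit(levels)
        free = models.TwoStateGammaMixture(shift=shift, random_state=0).fit(levels)
        assert constrained.loglik_ == pytest.approx(single.loglik_, abs=1e-3)
        assert free.loglik_ >= single.loglik_ - 1e-6

    def test_predict_separates_clear_states(self):
        p = TWO_STATE_FITS["Rh5@0wk"]  # widely separated components
        levels, states = models.sample_two_state(p, p.n, seed=2)
        est = models.TwoStateGammaMixture(random_state=0).fit(levels)
        pred = est.predict(levels)
        agreement = np.mean(pred == states)
        assert agreement > 0.97


class TestNormalMixture:
    def test_bimodal_rh6_recovery(self):
        x = models.sample_normal_mixture(RH6_R8_MIXTURE, 5000, seed=42)
        est = models.TwoNormalMixture(random_state=0).fit(x)
        assert abs(est.weight_on_ - 0.80) < 0.03
        assert abs(est.mu_off_ - 1.9) < 0.1

    def test_separable_point_masses(self):
        x = np.concatenate([np.zeros(500), np.full(1500, 10.0)])
        x = x + np.random.default_rng(0).normal(0, 1e-3, x.size)
        est = models.TwoNormalMixture(random_state=0).fit(x)
        assert est.weight_on_ == pytest.approx(0.75, abs=0.01)

    def test_component_ordering_contract(self):
        x = models.sample_normal_mixture(RH6_R8_MIXTURE, 2000, seed=1)
        est = models.TwoNormalMixture(random_state=0).fit(x)
        assert est.mu_off_ < est.mu_on_

    def test_refit_weight_recovery(self):
        fixed = RH6_R8_MIXTURE
        target = NormalMixtureParams(
            fixed.mu_off, fixed.sigma_off, fixed.mu_on, fixed.sigma_on, 0.6
        )
        x = models.sample_normal_mixture(target, 2000, seed=8)
        w = models.refit_mixture_weight(x, fixed)
        assert abs(w - 0.6) < 0.03

    def test_refit_weight_all_on(self):
        x = np.random.default_rng(0).normal(11.0, 5.1, 1000)
        x = np.clip(x, 5.0, None)  # keep clear of the off component
        w = models.refit_mixture_weight(x, RH6_R8_MIXTURE)
        assert w > 0.95

    def test_refit_weight_matches_grid_scan(self):
        x = models.sample_normal_mixture(RH6_R8_MIXTURE, 800, seed=4)
        w = models.refit_mixture_weight(x, RH6_R8_MIXTURE)
        grid = np.linspace(0.01, 0.99, 981)
        f_off = stats.norm.pdf(x[:, None], RH6_R8_MIXTURE.mu_off, RH6_R8_MIXTURE.sigma_off)
        f_on = stats.norm.pdf(x[:, None], RH6_R8_MIXTURE.mu_on, RH6_R8_MIXTURE.sigma_on)
        ll = np.sum(np.log((1 - grid) * f_off + grid * f_on), axis=0)
        assert abs(w - grid[np.argmax(ll)]) < 2e-3


class TestNonparametrics:
    def test_ks_one_sample_brute_force(self, rng):
        x = rng.normal(size=15)
        cdf = stats.norm.cdf
        d, _ = models.ks_one_sample(x, cdf)
        xs = np.sort(x)
        n = len(xs)
        d_brute = max(
            max((i + 1) / n - cdf(xs[i]), cdf(xs[i]) - i / n) for i in range(n)
        )
        assert d == pytest.approx(d_brute, abs=1e-12)

    def test_ks_one_sample_calibrated_under_null(self):
        pvals = []
        for rep in range(60):
            x = np.random.default_rng(rep).normal(size=1000)
            _, p = models.ks_one_sample(x, stats.norm.cdf)
            pvals.append(p)
        _, p_uniform = stats.kstest(pvals, "uniform")
        assert p_uniform > 0.05

    def test_ks_one_sample_shifted_d_to_one(self, rng):
        x = rng.normal(size=200) + 100.0
        d, p = models.ks_one_sample(x, stats.norm.cdf)
        assert d > 0.999 and p < 1e-10

    def test_ks_two_sample_identical(self, rng):
        a = rng.normal(size=50)
        d, _ = models.ks_two_sample_one_sided(a, a.copy())
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_ks_two_sample_stochastically_smaller(self, rng):
        a = rng.uniform(0, 1, 100)
        b = rng.uniform(1, 2, 100)
        d, p = models.ks_two_sample_one_sided(a, b)
        assert d == pytest.approx(1.0)
        assert p < 1e-10

    @pytest.mark.parametrize("seed", range(8))
    def test_ks_two_sample_brute_force_small(self, seed):
        g = np.random.default_rng(seed)
        a = g.normal(size=g.integers(3, 21))
        b = g.normal(0.3, 1.1, size=g.integers(3, 21))
        d, _ = models.ks_two_sample_one_sided(a, b)
        pooled = np.concatenate([a, b])
        d_brute = max(
            np.mean(a <= t) - np.mean(b <= t) for t in pooled
        )
        assert d == pytest.approx(max(d_brute, 0.0), abs=1e-12)

    def test_spearman_monotone(self, rng):
        x = rng.normal(size=30)
        rho, _ = models.spearman_correlation(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        rho, _ = models.spearman_correlation(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_spearman_manual_oracle(self):
        g = np.random.default_rng(5)
        x = g.normal(size=10)
        y = g.normal(size=10)
        rho, _ = models.spearman_correlation(x, y)
        # rank formula computed by hand: Pearson correlation of the ranks
        rx = np.argsort(np.argsort(x)).astype(float)
        ry = np.argsort(np.argsort(y)).astype(float)
        manual = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(manual, abs=1e-12)

    def test_spearman_constant_raises(self):
        with pytest.raises(ValueError):
            models.spearman_correlation(np.ones(10), np.arange(10.0))


class TestRepressionComparisons:
    def test_detects_programmed_repression(self, rng):
        # R3 cells programmed stochastically lower than the rest
        import pandas as pd

        rows = []
        for pr in ["R1", "R2", "R3", "R4", "R5", "R6"]:
            shift = -1.0 if pr == "R3" else 0.0
            for v in rng.normal(3.0 + shift, 0.5, 80):
                rows.append({"pr_label": pr, "channel": "Rh3", "i_l": v})
        df = pd.DataFrame(rows)
        table = models.repression_comparisons(df)
        by = table.set_index("comparison")
        assert by.loc["R3_vs_rest", "p"] < 1e-6  # R3 more repressed
        assert by.loc["rest_vs_R3", "p"] > 0.5
        assert by.loc["R3R4_vs_R2R5", "p"] < 1e-3  # the R3/R4 pair inherits it
        assert {"D_plus", "neg_log10_p", "n_a", "n_b"} <= set(table.columns)


class TestSmoothedDensity:
    def test_single_sample_is_the_kernel(self):
        sd = models.smoothed_density([0.0], w=0.3, grid=np.linspace(-2, 2, 401))
        np.testing.assert_allclose(
            sd.density, stats.norm.pdf(sd.grid, 0.0, 0.3), atol=1e-12
        )

    def test_integrates_to_one(self, rng):
        sd = models.smoothed_density(rng.normal(size=200), w=0.5)
        assert sd.integral() == pytest.approx(1.0, abs=1e-3)

    def test_matches_double_loop(self, rng):
        x = rng.normal(size=50)
        grid = np.linspace(-4, 4, 101)
        sd = models.smoothed_density(x, w=0.3, grid=grid)
        w = 0.3
        brute = np.array(
            [
                sum(
                    np.exp(-((g - xi) ** 2) / (2 * w**2)) / (w * np.sqrt(2 * np.pi))
                    for xi in x
                )
                / len(x)
                for g in grid
            ]
        )
        np.testing.assert_allclose(sd.density, brute, atol=1e-12)


class TestRatesAndConversions:
    def test_burst_relations(self):
        kr = models.kinetic_rates_from_gamma(5.6, 0.17, gamma_p=1.0, gamma_m=10.0)
        assert kr.lambda_m == pytest.approx(5.6)
        assert kr.alpha == pytest.approx(5.6)
        assert kr.beta == pytest.approx(0.17)
        assert kr.equilibration_time == pytest.approx(1.0)

    def test_round_trip(self):
        kr = models.kinetic_rates_from_gamma(2.2, 0.17, gamma_p=0.5, gamma_m=4.0)
        kr2 = models.kinetic_rates_from_gamma(kr.alpha, kr.beta, kr.gamma_p, kr.gamma_m)
        assert kr2 == kr

    def test_molecule_conversion_reference_point(self):
        # 2.5e5 molecules/um^3 at the mean on level 11.0 -> ~2.3e4 per unit
        factor = models.intensity_to_molecules(1.0, mean_on=11.0)
        assert float(f"{float(factor):.2g}") == pytest.approx(2.3e4)
        assert models.intensity_to_molecules(0.0, mean_on=11.0) == 0.0
        assert models.intensity_to_molecules(1.0, mean_on=1.0) == pytest.approx(2.5e5)

    def test_half_life_to_rate(self):
        assert models.half_life_to_rate(1.0) == pytest.approx(np.log(2))
        assert models.half_life_to_rate(2.0) == pytest.approx(0.3466, abs=2e-4)
        assert models.half_life_to_rate(4.0) == pytest.approx(
            models.half_life_to_rate(2.0) / 2
        )

    def test_switching_bound(self):
        assert models.switching_rate_upper_bound(1.0) == pytest.approx(1.0)
        with pytest.raises(ParameterError):
            models.switching_rate_upper_bound(0.0)
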