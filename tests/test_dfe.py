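"""DFE machinery: diffusion weights, expected spectra, likelihood, fitting."""

import numpy as np
import pytest
from scipy.stats import binom

from dfescan import dfe
from dfescan.spectra import SpectrumSet


class TestSojournWeight:
    def test_neutral_limit_is_reciprocal(self):
        x = np.array([0.01, 0.3, 0.9])
        assert dfe.sojourn_weight(x, 0.0) == pytest.approx(list(1 / x))

    def test_closed_form_value(self):
        assert dfe.sojourn_weight(0.5, 1.0) == pytest.approx(2.4899, abs=1e-4)

    def test_strong_purifying_limit(self):
        assert dfe.sojourn_weight(0.5, -1e4) == pytest.approx(0.0, abs=1e-300)

    def test_domain_check(self):
        with pytest.raises(ValueError):
            dfe.sojourn_weight(0.0, 1.0)
        with pytest.raises(ValueError):
            dfe.sojourn_weight(1.0, 1.0)

    def test_stable_at_extreme_s(self):
        for S in (-1e4, -1e3, 1e3, 1e4):
            v = dfe.sojourn_weight(np.array([1e-4, 0.5, 1 - 1e-4]), S)
            assert np.all(np.isfinite(v)) and np.all(v >= 0)


class TestFixationRatio:
    def test_neutral_limit(self):
        assert dfe.fixation_ratio(0.0) == 1.0

    def test_closed_form_value(self):
        assert dfe.fixation_ratio(2.0) == pytest.approx(2.3130, abs=1e-4)

    def test_asymptotics(self):
        assert dfe.fixation_ratio(-1e4) == pytest.approx(0.0, abs=1e-300)
        assert dfe.fixation_ratio(1e4) == pytest.approx(1e4)


class TestSfsWeight:
    def test_neutral_closed_form(self):
        for n in (4, 10, 20):
            i = np.arange(1, n)
            assert dfe.sfs_weight(0.0, i, n) == pytest.approx(list(1 / i))

    def test_deleterious_mass_at_low_frequency(self):
        assert dfe.sfs_weight(-50, 9, 10) < dfe.sfs_weight(-50, 1, 10)

    def test_quadrature_against_midpoint_oracle(self):
        # brute-force midpoint integration on a coarse S grid
        m = 10_000
        xs = (np.arange(m) + 0.5) / m
        for S in (-10.0, -1.0, 1.0, 10.0):
            for i in (1, 5, 9):
                oracle = float(np.mean(binom.pmf(i, 10, xs)
                                       * dfe.sojourn_weight(xs, S)))
                assert dfe.sfs_weight(S, i, 10) == pytest.approx(
                    oracle, rel=1e-4)

    def test_class_bounds(self):
        with pytest.raises(ValueError):
            dfe.sfs_weight(1.0, 0, 10)
        with pytest.raises(ValueError):
            dfe.sfs_weight(1.0, 10, 10)


class TestExpectedSpectrum:
    def test_neutral_closed_form(self):
        for n in (4, 10, 20):
            p = dfe.DFEParams("Neutral", theta=0.01)
            exp = dfe.expected_spectrum(p, n, Ls=1000.0, Ln=3000.0)
            i = np.arange(1, n)
            assert np.allclose(exp.sfs_syn, 10.0 / i, rtol=1e-12)
            assert np.allclose(exp.sfs_nonsyn, 30.0 / i, rtol=1e-12)

    def test_gammaexpo_nests_gamma(self):
        ge = dfe.DFEParams("GammaExpo", theta=0.01, shape=0.4, mean_del=500.0,
                           p_b=0.0, mean_ben=10.0)
        g = dfe.DFEParams("Gamma", theta=0.01, shape=0.4, mean_del=500.0)
        a = dfe.expected_spectrum(ge, 10, 100.0, 300.0)
        b = dfe.expected_spectrum(g, 10, 100.0, 300.0)
        assert np.allclose(a.sfs_nonsyn, b.sfs_nonsyn)

    def test_purifying_selection_skews_ratio_downward(self):
        # nonsyn/syn ratio decreases with derived-allele class under a
        # deleterious DFE
        p = dfe.DFEParams("Gamma", theta=0.01, shape=0.3, mean_del=1000.0)
        exp = dfe.expected_spectrum(p, 12, 1000.0, 1000.0)
        ratio = exp.sfs_nonsyn / exp.sfs_syn
        assert np.all(np.diff(ratio) < 0)

    def test_misidentification_mixes_mirror_classes(self):
        p = dfe.DFEParams("Neutral", theta=0.01, eps=0.1)
        exp = dfe.expected_spectrum(p, 6, 100.0, 0.0)
        i = np.arange(1, 6)
        direct = 1.0 / i
        assert np.allclose(exp.sfs_syn,
                           0.01 * 100 * (0.9 * direct + 0.1 * direct[::-1]))

    def test_folded_expectation_pools_mirror_classes(self):
        p = dfe.DFEParams("Neutral", theta=0.01)
        unf = dfe.expected_spectrum(p, 6, 100.0, 0.0)
        fol = dfe.expected_spectrum(p, 6, 100.0, 0.0, folded=True)
        assert fol.sfs_syn[0] == pytest.approx(unf.sfs_syn[0] + unf.sfs_syn[4])
        assert fol.sfs_syn[2] == pytest.approx(unf.sfs_syn[2])


class TestPoissonLoglik:
    def test_hand_computed_single_class(self):
        # one class (n=2), observed 2, expected 2: 2 ln2 - 2 - ln(2!)
        p = dfe.DFEParams("Neutral", theta=2.0)
        obs = SpectrumSet(n=2, Ls=1.0, Ln=0.0, sfs_syn=[2.0], sfs_nonsyn=[0.0])
        assert dfe.poisson_loglik(p, obs) == pytest.approx(
            2 * np.log(2) - 2 - np.log(2), abs=1e-10)

    def test_zero_expected_positive_observed_is_minus_inf(self):
        p = dfe.DFEParams("Neutral", theta=2.0)
        obs = SpectrumSet(n=2, Ls=0.0, Ln=1.0, sfs_syn=[0.0], sfs_nonsyn=[3.0])
        # Ln > 0 but theta*Ls = 0 for the syn class with positive counts
        obs2 = SpectrumSet(n=2, Ls=0.0, Ln=1.0, sfs_syn=[3.0], sfs_nonsyn=[0.0])
        assert dfe.poisson_loglik(p, obs2) == -np.inf

    def test_theta_mle_maximizes_at_observed_rate(self):
        obs = SpectrumSet(n=5, Ls=100.0, Ln=0.0,
                          sfs_syn=[10, 5, 3, 2], sfs_nonsyn=[0, 0, 0, 0])
        # profile MLE theta matches the analytic optimum over a scan
        fit = dfe.fit_model(
            SpectrumSet(n=5, Ls=100.0, Ln=100.0, sfs_syn=[10, 5, 3, 2],
                        sfs_nonsyn=[10, 5, 3, 2]),
            family="Neutral")
        thetas = np.linspace(0.5, 1.5, 41) * fit.params.theta
        lls = []
        for t in thetas:
            p = dfe.DFEParams("Neutral", theta=t)
            lls.append(dfe.poisson_loglik(
                p, SpectrumSet(n=5, Ls=100.0, Ln=100.0,
                               sfs_syn=[10, 5, 3, 2],
                               sfs_nonsyn=[10, 5, 3, 2])))
        assert np.argmax(lls) == 20  # the central (profiled) value


class TestAlphaDecompose:
    def test_printed_identities(self):
        p = dfe.DFEParams("Gamma", theta=0.01, shape=0.3, mean_del=1e12)
        obs = SpectrumSet(n=4, Ls=100.0, Ln=100.0, sfs_syn=[1, 0, 0],
                          sfs_nonsyn=[1, 0, 0], Ds=10.0, Dn=2.0)
        omega, w_na, w_a, alpha = dfe.alpha_decompose(p, obs)
        assert omega == pytest.approx(0.2)
        assert w_a == pytest.approx(omega - w_na)
        assert alpha == pytest.approx(w_a / omega)

    def test_neutral_family_alpha(self):
        p = dfe.DFEParams("Neutral", theta=0.01)
        obs = SpectrumSet(n=4, Ls=100.0, Ln=100.0, sfs_syn=[1, 0, 0],
                          sfs_nonsyn=[1, 0, 0], Ds=10.0, Dn=5.0)
        omega, w_na, w_a, alpha = dfe.alpha_decompose(p, obs)
        assert w_na == 1.0
        assert alpha == pytest.approx(1 - 1 / omega)

    def test_strong_selection_limit(self):
        p = dfe.DFEParams("Gamma", theta=0.01, shape=2.0, mean_del=1e9)
        assert dfe.omega_na_expected(p) < 1e-3

    def test_no_divergence_is_an_error(self):
        p = dfe.DFEParams("Neutral", theta=0.01)
        obs = SpectrumSet(n=4, Ls=100.0, Ln=100.0, sfs_syn=[1, 0, 0],
                          sfs_nonsyn=[1, 0, 0], Ds=0.0, Dn=5.0)
        with pytest.raises(ValueError, match="Ds=0"):
            dfe.alpha_decompose(p, obs)


class TestFitting:
    def test_neutral_theta_recovery(self):
        rng = np.random.default_rng(3)
        n, Ls, Ln, theta = 10, 1e5, 3e5, 0.01
        i = np.arange(1, n)
        obs = SpectrumSet(n=n, Ls=Ls, Ln=Ln,
                          sfs_syn=rng.poisson(theta * Ls / i),
                          sfs_nonsyn=rng.poisson(theta * Ln / i))
        fit = dfe.fit_model(obs, family="Neutral")
        se = theta / np.sqrt(obs.total_polymorphisms())
        assert abs(fit.params.theta - theta) < 3 * se

    def test_likelihood_nesting(self, big_spectrum):
        fits = {f.params.family: f
                for f in dfe.compare_models(big_spectrum, seed=0)}
        assert fits["GammaExpo"].loglik >= fits["Gamma"].loglik - 1e-6
        assert fits["Gamma"].loglik >= fits["Neutral"].loglik - 1e-6

    def test_aic_formula_and_ranking(self, big_spectrum):
        fits = dfe.compare_models(big_spectrum, seed=0)
        for f in fits:
            assert f.aic == pytest.approx(2 * f.n_params - 2 * f.loglik)
        aics = [f.aic for f in fits]
        assert aics == sorted(aics)

    def test_fit_is_deterministic(self, big_spectrum):
        f1 = dfe.fit_model(big_spectrum, "GammaExpo", seed=7)
        f2 = dfe.fit_model(big_spectrum, "GammaExpo", seed=7)
        assert f1.loglik == f2.loglik
        assert f1.params.shape == f2.params.shape

    def test_empty_class_rejected(self):
        obs = SpectrumSet(n=4, Ls=10.0, Ln=10.0, sfs_syn=[0, 0, 0],
                          sfs_nonsyn=[1, 0, 0])
        with pytest.raises(ValueError, match="polymorphic site"):
            dfe.fit_model(obs)

    def test_nuisance_r_profiles_exactly(self, big_spectrum):
        fit = dfe.fit_model(big_spectrum, "Gamma", seed=0, use_r=True)
        assert fit.params.r is not None
        assert fit.params.r[0] == pytest.approx(1.0)
        assert fit.n_params == 3 + (big_spectrum.n - 2)

    def test_folded_fit_runs(self, big_spectrum):
        from dfescan.spectra import fold_spectrum

        folded = fold_spectrum(big_spectrum)
        fit = dfe.fit_model(folded, "Gamma", seed=0)
        assert np.isfinite(fit.loglik)
        assert 0.0 < fit.omega_na < 1.0
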