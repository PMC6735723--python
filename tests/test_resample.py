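"""Bootstrap machinery, trimming, trend/pairwise tests, FDR, ANCOVA."""

import numpy as np
import pandas as pd
import pytest

from dfescan import dfe
from dfescan.resample import (
    BootstrapResult,
    bootstrap_categories,
    ancova_partition,
    fdr_adjust,
    kendall_trend,
    pairwise_bootstrap_test,
    significance_code,
    summarize,
    trim_replicates,
)
from dfescan.spectra import SpectrumSet


def fake_fit(mean_del, shape, omega_a=0.1):
    p = dfe.DFEParams("Gamma", theta=0.01, shape=shape, mean_del=mean_del)
    return dfe.FitResult(params=p, loglik=-10.0, n_params=3, aic=26.0,
                         omega=0.2, omega_na=0.2 - omega_a, omega_a=omega_a,
                         alpha=omega_a / 0.2)


def boot_result(reps, label="c", B=None):
    return BootstrapResult(scheme_name="s", labels=[label],
                           replicates={label: reps},
                           point={label: reps[0]}, B=B or len(reps))


class TestTrimming:
    def test_distinct_extremes_on_distinct_replicates(self):
        # means 1..100; shapes permuted so extreme shapes sit on other
        # replicates than extreme means: 2 dropped per parameter -> 96
        means = np.arange(1.0, 101.0)
        shapes = np.roll(means, 50) / 100.0
        reps = [fake_fit(m, s) for m, s in zip(means, shapes)]
        trimmed = trim_replicates(boot_result(reps))
        assert trimmed.retained["c"] == 96

    def test_overlapping_extremes(self):
        # extremes of mean and shape on the same two replicates -> 98 kept
        means = np.arange(1.0, 101.0)
        shapes = means / 100.0
        reps = [fake_fit(m, s) for m, s in zip(means, shapes)]
        trimmed = trim_replicates(boot_result(reps))
        assert trimmed.retained["c"] == 98

    def test_identical_replicates_all_kept(self):
        reps = [fake_fit(10.0, 0.3) for _ in range(100)]
        trimmed = trim_replicates(boot_result(reps))
        assert trimmed.retained["c"] == 100

    def test_failed_replicates_always_dropped(self):
        reps = [fake_fit(10.0, 0.3) for _ in range(50)] + [None] * 10
        trimmed = trim_replicates(boot_result(reps, B=60))
        assert trimmed.retained["c"] == 50

    def test_low_retention_warns(self):
        reps = [fake_fit(10.0, 0.3)] * 20 + [None] * 80
        with pytest.warns(UserWarning, match="fewer than 50%"):
            trim_replicates(boot_result(reps, B=100))


class TestSummarize:
    def test_constant_replicates(self):
        reps = [fake_fit(10.0, 0.3, omega_a=0.07) for _ in range(20)]
        df = summarize(boot_result(reps))
        row = df[df.metric == "omega_a"].iloc[0]
        assert row["mean"] == pytest.approx(0.07)
        assert row["ci_low"] == pytest.approx(0.07)
        assert row["ci_high"] == pytest.approx(0.07)

    def test_percentile_interval_convention(self):
        reps = [fake_fit(10.0, 0.3, omega_a=v) for v in
                np.arange(1.0, 101.0)]
        df = summarize(boot_result(reps))
        row = df[df.metric == "omega_a"].iloc[0]
        assert row["mean"] == pytest.approx(50.5)
        assert row["ci_low"] == pytest.approx(3.475)
        assert row["ci_high"] == pytest.approx(97.525)
        assert row["ci_low"] <= row["ci_high"]


class TestKendallTrend:
    def test_strictly_increasing(self):
        t = kendall_trend([1.0, 2.0, 3.0, 4.0])
        assert t.statistic == 1.0
        assert t.p_value < 0.1

    def test_one_discordant_pair(self):
        t = kendall_trend([1.0, 3.0, 2.0])
        assert t.statistic == pytest.approx(1 / 3)

    def test_reversal_negates_tau(self):
        means = [0.3, 0.1, 0.8, 0.5, 0.9]
        assert kendall_trend(means).statistic == pytest.approx(
            -kendall_trend(means[::-1]).statistic)

    def test_zero_variance_undefined(self):
        t = kendall_trend([2.0, 2.0, 2.0])
        assert np.isnan(t.statistic) and "undefined" in t.comparison

    def test_too_few_categories(self):
        with pytest.raises(ValueError):
            kendall_trend([1.0, 2.0])


class TestPairwiseBootstrapTest:
    def test_fully_separated_distributions(self):
        a = np.arange(100.0) + 1000.0
        b = np.arange(100.0)
        t = pairwise_bootstrap_test(a, b, seed=0)
        assert t.statistic == 0
        assert t.p_value == pytest.approx(1 / 101)

    def test_printed_formula_k10(self):
        # construct exactly 10 sign reversals with index pairing
        a = np.ones(100)
        b = np.zeros(100)
        b[:10] = 2.0  # d < 0 for ten pairs
        t = pairwise_bootstrap_test(a, b, pairing="index")
        assert t.statistic == 10
        assert t.p_value == pytest.approx(21 / 101)

    def test_maximal_overlap(self):
        a = np.ones(100)
        b = np.ones(100)
        b[::2] = 2.0
        b[1::2] = 0.0  # 50 positive, 50 negative differences
        t = pairwise_bootstrap_test(a, b, pairing="index")
        assert t.statistic == 50
        assert t.p_value == 1.0

    def test_zeros_split_evenly(self):
        a = np.ones(20)
        t = pairwise_bootstrap_test(a, a, pairing="index")
        assert t.statistic == 10
        assert t.p_value == 1.0

    def test_padding_shorter_side(self):
        a = np.arange(50.0) + 100.0
        b = np.arange(100.0)
        t = pairwise_bootstrap_test(a, b, seed=1)
        assert t.p_value == pytest.approx(1 / 101)

    def test_needs_ten_replicates(self):
        with pytest.raises(ValueError):
            pairwise_bootstrap_test(np.ones(5), np.ones(100))


class TestFDR:
    def test_hand_applied_bh(self):
        assert fdr_adjust([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.03, 0.03])

    def test_two_values(self):
        assert fdr_adjust([0.04, 0.5]) == pytest.approx([0.08, 0.5])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.2]) == pytest.approx([0.2])

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(0)
        p = rng.random(30)
        adj = fdr_adjust(p)
        assert np.all(adj >= p - 1e-12)

    def test_domain(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.0, 0.5])


class TestSignificanceCodes:
    def test_codes(self):
        assert significance_code(0.0005) == "***"
        assert significance_code(0.005) == "**"
        assert significance_code(0.03) == "*"
        assert significance_code(0.07) == "."
        assert significance_code(0.5) == ""


class TestAncova:
    def test_rsa_dominates_when_response_is_rsa(self):
        rng = np.random.default_rng(0)
        rsa = np.linspace(0, 1, 40)
        disorder = rng.random(40)  # orthogonal noise covariate
        y = 2.0 * rsa + 0.01 * rng.standard_normal(40)
        df = pd.DataFrame({"omega_a": y, "rsa": rsa, "disorder": disorder})
        out = ancova_partition(df)
        assert out.loc["rsa", "fraction"] > 0.95
        assert out.loc["rsa", "PR(>F)"] < 1e-6

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"omega_a": rng.random(30),
                           "rsa": rng.random(30),
                           "disorder": rng.random(30)})
        out = ancova_partition(df)
        assert out["fraction"].sum() == pytest.approx(1.0, abs=1e-10)

    def test_null_fractions_small(self):
        rng = np.random.default_rng(2)
        fracs = []
        for _ in range(30):
            df = pd.DataFrame({"omega_a": rng.standard_normal(50),
                               "rsa": rng.random(50),
                               "disorder": rng.random(50)})
            out = ancova_partition(df)
            fracs.append(out.loc["rsa", "fraction"])
        # under the null each 1-df term explains ~1/(n-1) on average
        assert np.mean(fracs) < 0.08

    def test_collinear_covariates_rejected(self):
        rsa = np.linspace(0, 1, 20)
        df = pd.DataFrame({"omega_a": rsa, "rsa": rsa, "disorder": rsa})
        with pytest.raises(ValueError, match="collinear"):
            ancova_partition(df)


class TestBootstrapCategories:
    def unit_spectra(self, n_units=30, seed=0):
        rng = np.random.default_rng(seed)
        n, i = 8, np.arange(1, 8)
        return {
            f"u{j}": SpectrumSet(
                n=n, Ls=250.0, Ln=750.0,
                sfs_syn=rng.poisson(2.5 * 250 / 100 / i),
                sfs_nonsyn=rng.poisson(2.5 * 750 / 100 / i * 0.3),
                Ds=float(rng.poisson(25)), Dn=float(rng.poisson(20)))
            for j in range(n_units)
        }

    def test_identity_mode_equals_point(self):
        sp = self.unit_spectra()
        boot = bootstrap_categories({"all": list(sp)}, sp, B=1,
                                    identity=True, estimator="omega")
        rep = boot.replicates["all"][0]
        assert rep.omega == pytest.approx(boot.point["all"].omega)

    def test_determinism(self):
        sp = self.unit_spectra()
        b1 = bootstrap_categories({"all": list(sp)}, sp, B=8, seed=5,
                                  estimator="omega")
        b2 = bootstrap_categories({"all": list(sp)}, sp, B=8, seed=5,
                                  estimator="omega")
        assert np.array_equal(b1.values("all", "omega"),
                              b2.values("all", "omega"))

    def test_identical_unit_sets_indistinguishable(self):
        from scipy.stats import ks_2samp

        sp = self.unit_spectra()
        units = {"a": list(sp), "b": list(sp)}
        boot = bootstrap_categories(units, sp, B=100, seed=3,
                                    estimator="omega")
        ks = ks_2samp(boot.values("a", "omega"), boot.values("b", "omega"))
        assert ks.pvalue > 0.01

    def test_small_category_rejected(self):
        sp = self.unit_spectra(n_units=1)
        with pytest.raises(ValueError, match="fewer than 2"):
            bootstrap_categories({"a": ["u0"]}, sp, B=2)
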