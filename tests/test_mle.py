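import math

import numpy as np
import pytest

from pffcens import (
    IWDParams,
    PFFSample,
    ci_lognormal,
    ci_normal,
    entropy,
    entropy_variance,
    fit_mle,
    ks_pvalue,
    ks_statistic,
    load_dataset,
    log_likelihood,
    observed_info,
    parse_scheme,
    score,
    simulate_pff,
)
from pffcens.distribution import log_pdf
from pffcens.mle_inference import FitError, ordering_constant


def _random_instance(rng):
    n = int(rng.integers(15, 40))
    m = int(rng.integers(5, n))
    R = np.zeros(m, int)
    R[rng.integers(0, m)] = n - m
    k = int(rng.integers(1, 4))
    scheme = parse_scheme(",".join(map(str, R)), k=k, n=n)
    p_true = IWDParams(rng.uniform(0.7, 3), rng.uniform(0.3, 5))
    s = simulate_pff(scheme, p_true, seed=int(rng.integers(1 << 30)))
    p_eval = IWDParams(rng.uniform(0.7, 3), rng.uniform(0.3, 5))
    return s, p_eval


class TestLogLikelihood:
    def test_guinea_neg_loglik(self, guinea_complete_sample):
        # printed -lnL at the printed MLE
        val = log_likelihood(guinea_complete_sample, IWDParams(1.415, 283.837))
        assert -val == pytest.approx(395.649, abs=5e-3)

    def test_single_observation_is_log_pdf(self):
        sch = parse_scheme("(0)", k=1, n=1)
        s = PFFSample(sch, np.array([3.7]))
        p = IWDParams(1.3, 2.1)
        assert log_likelihood(s, p) == pytest.approx(float(log_pdf(3.7, p)), abs=1e-12)

    def test_constant_flag(self, guinea_r1_sample):
        p = IWDParams(1.2, 100.0)
        base = log_likelihood(guinea_r1_sample, p)
        full = log_likelihood(guinea_r1_sample, p, include_constant=True)
        assert full - base == pytest.approx(ordering_constant(guinea_r1_sample), abs=1e-10)
        # constant itself: log P + m log k with P = n(n-1-R1)...(n-m+1-sum R)
        n, m, k = 36, 18, 2
        logP = math.log(n) + sum(math.log(n - i - 18) for i in range(1, m))
        assert ordering_constant(guinea_r1_sample) == pytest.approx(
            logP + m * math.log(k), abs=1e-10
        )

    def test_gradient_matches_score(self, sim_sample_n50_m40):
        p = IWDParams(2.0, 1.0)
        h = 1e-6
        fd = np.array([
            (log_likelihood(sim_sample_n50_m40, IWDParams(2 + h, 1))
             - log_likelihood(sim_sample_n50_m40, IWDParams(2 - h, 1))) / (2 * h),
            (log_likelihood(sim_sample_n50_m40, IWDParams(2, 1 + h))
             - log_likelihood(sim_sample_n50_m40, IWDParams(2, 1 - h))) / (2 * h),
        ])
        assert score(sim_sample_n50_m40, p) == pytest.approx(fd, abs=1e-5)


class TestScore:
    def test_vanishes_at_mle(self, guinea_r1_sample, fit_r1):
        assert np.max(np.abs(score(guinea_r1_sample, fit_r1.params_hat))) < 1e-6

    def test_matches_finite_differences_random(self):
        rng = np.random.default_rng(20)
        for _ in range(20):
            s, p = _random_instance(rng)
            h = 1e-6
            fd = np.array([
                (log_likelihood(s, IWDParams(p.alpha + h, p.lam))
                 - log_likelihood(s, IWDParams(p.alpha - h, p.lam))) / (2 * h),
                (log_likelihood(s, IWDParams(p.alpha, p.lam + h))
                 - log_likelihood(s, IWDParams(p.alpha, p.lam - h))) / (2 * h),
            ])
            sc = score(s, p)
            assert sc == pytest.approx(fd, rel=1e-4, abs=1e-4)

    def test_complete_sample_censoring_terms_vanish(self, guinea_complete_sample):
        # k=1, R=0 makes every exponent k(R+1)-1 zero: the score must equal
        # the score of the plain i.i.d. log-likelihood sum(log pdf)
        p = IWDParams(1.5, 250.0)
        x = guinea_complete_sample.times
        h = 1e-6

        def iid_ll(a, l):
            return float(np.sum(log_pdf(x, IWDParams(a, l))))

        fd = np.array([
            (iid_ll(p.alpha + h, p.lam) - iid_ll(p.alpha - h, p.lam)) / (2 * h),
            (iid_ll(p.alpha, p.lam + h * 100) - iid_ll(p.alpha, p.lam - h * 100)) / (2 * h * 100),
        ])
        assert score(guinea_complete_sample, p) == pytest.approx(fd, rel=1e-5)


class TestObservedInfo:
    def test_matches_numeric_hessian_random(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            s, p = _random_instance(rng)
            h_a = 1e-5 * max(p.alpha, 1)
            h_l = 1e-5 * max(p.lam, 1)

            def sc(a, l):
                return score(s, IWDParams(a, l))

            num = np.column_stack([
                (sc(p.alpha + h_a, p.lam) - sc(p.alpha - h_a, p.lam)) / (2 * h_a),
                (sc(p.alpha, p.lam + h_l) - sc(p.alpha, p.lam - h_l)) / (2 * h_l),
            ])
            ana = -observed_info(s, p)
            scale = np.maximum(np.abs(num), 1.0)
            assert np.max(np.abs(ana - num) / scale) < 1e-5

    def test_positive_definite_at_guinea_mle(self, guinea_complete_sample):
        f = fit_mle(guinea_complete_sample)
        info = observed_info(guinea_complete_sample, f.params_hat)
        assert np.all(np.linalg.eigvalsh(info) > 0)

    def test_complete_sample_l02_closed_form(self, guinea_complete_sample):
        p = IWDParams(1.4, 280.0)
        info = observed_info(guinea_complete_sample, p)
        m = guinea_complete_sample.m
        assert info[1, 1] == pytest.approx(m / p.lam**2, rel=1e-12)


class TestFitMle:
    def test_guinea_complete(self, guinea_complete_sample):
        f = fit_mle(guinea_complete_sample)
        assert f.converged
        assert f.alpha_hat == pytest.approx(1.415, abs=5e-4)
        assert f.lam_hat == pytest.approx(283.837, abs=1e-2)
        assert -f.loglik == pytest.approx(395.649, abs=5e-4)

    def test_table13_r1(self, fit_r1):
        assert fit_r1.alpha_hat == pytest.approx(1.17, abs=5e-3)
        assert fit_r1.lam_hat == pytest.approx(123.79, abs=1.1e-2)
        assert fit_r1.entropy_hat == pytest.approx(6.01, abs=5e-3)

    def test_entropy_invariance(self, fit_r1):
        assert fit_r1.entropy_hat == entropy(fit_r1.params_hat)

    def test_score_zero_and_tau_pd(self, fit_n50_m40, sim_sample_n50_m40):
        assert np.max(np.abs(score(sim_sample_n50_m40, fit_n50_m40.params_hat))) < 1e-6
        assert np.all(np.linalg.eigvalsh(fit_n50_m40.tau) > 0)

    def test_degenerate_sample_rejected(self):
        sch = parse_scheme("(0*4)", k=1, n=4)
        with pytest.raises(FitError):
            fit_mle(PFFSample(sch, np.full(4, 2.0)))

    def test_consistency_trend(self, std_params):
        # mean |alpha_hat - 2| decreases with n at fixed 50% censoring
        # (scaled to 300 reps per n)
        errs = []
        for n in (50, 70, 100):
            m = n // 2
            sch = parse_scheme(f"({n - m},0*{m - 1})", k=1, n=n)
            vals = []
            for r in range(300):
                s = simulate_pff(sch, std_params, seed=(9, n, r))
                vals.append(abs(fit_mle(s).alpha_hat - 2.0))
            errs.append(np.mean(vals))
        assert errs[0] > errs[1] > errs[2]


class TestEntropyVariance:
    def test_zero_tau(self, fit_r1):
        from dataclasses import replace

        f0 = replace(fit_r1, tau=np.zeros((2, 2)))
        assert entropy_variance(f0) == 0.0

    def test_positive_on_r1(self, fit_r1):
        assert entropy_variance(fit_r1) > 0

    def test_matches_parametric_bootstrap(self, std_params):
        # scaled: 600 refits (spec sketch uses 2000), 25% tolerance
        sch = parse_scheme("(10,0*59)", k=1, n=70)
        s = simulate_pff(sch, std_params, seed=17)
        f = fit_mle(s)
        var = entropy_variance(f)
        ents = []
        for r in range(600):
            sb = simulate_pff(sch, f.params_hat, seed=(1000, r))
            ents.append(fit_mle(sb).entropy_hat)
        boot = np.var(ents, ddof=1)
        assert var == pytest.approx(boot, rel=0.25)


class TestIntervals:
    def test_normal_symmetric_and_z(self, fit_r1):
        iv = ci_normal(fit_r1, "alpha", 0.95)
        mid = (iv.lower + iv.upper) / 2
        assert mid == pytest.approx(fit_r1.alpha_hat, abs=1e-12)
        half = (iv.upper - iv.lower) / 2
        assert half / math.sqrt(fit_r1.tau[0, 0]) == pytest.approx(1.959964, abs=1e-6)

    def test_lognormal_table13_r1(self, fit_r1):
        iva = ci_lognormal(fit_r1, "alpha", 0.95)
        assert (iva.lower, iva.upper) == pytest.approx((0.87, 1.59), abs=6e-3)
        ivl = ci_lognormal(fit_r1, "lambda", 0.95)
        assert (ivl.lower, ivl.upper) == pytest.approx((33.88, 452.35), abs=1.1e-2)
        ivh = ci_lognormal(fit_r1, "entropy", 0.95)
        assert (ivh.lower, ivh.upper) == pytest.approx((5.36, 6.75), abs=6e-3)

    def test_lognormal_geometric_symmetry(self, fit_n50_m40):
        for target, point in (
            ("alpha", fit_n50_m40.alpha_hat),
            ("lambda", fit_n50_m40.lam_hat),
            ("entropy", fit_n50_m40.entropy_hat),
        ):
            iv = ci_lognormal(fit_n50_m40, target)
            assert iv.lower * iv.upper == pytest.approx(point**2, rel=1e-10)
            assert iv.lower > 0

    def test_families_converge_large_n(self, std_params):
        sch = parse_scheme("(0*500)", k=1, n=500)
        s = simulate_pff(sch, std_params, seed=4)
        f = fit_mle(s)
        for target in ("alpha", "lambda", "entropy"):
            a = ci_normal(f, target)
            b = ci_lognormal(f, target)
            assert a.lower == pytest.approx(b.lower, abs=0.02)
            assert a.upper == pytest.approx(b.upper, abs=0.02)


class TestKS:
    def test_guinea_value(self, guinea_complete):
        d = ks_statistic(guinea_complete.times, IWDParams(1.415, 283.837))
        assert d == pytest.approx(0.152, abs=5e-4)

    def test_brute_force_double_loop(self, std_params):
        from pffcens import cdf, quantile

        n = 25
        data = quantile(np.arange(1, n + 1) / (n + 1), std_params)
        # definitional sup over both one-sided gaps
        xs = np.sort(data)
        brute = 0.0
        for i in range(1, n + 1):
            F = float(cdf(xs[i - 1], std_params))
            brute = max(brute, i / n - F, F - (i - 1) / n)
        assert ks_statistic(data, std_params) == pytest.approx(brute, abs=1e-15)
        assert brute < 2.0 / (n + 1)

    def test_single_observation_at_median(self, std_params):
        from pffcens import quantile

        x = quantile(0.5, std_params)
        assert ks_statistic([x], std_params) == pytest.approx(0.5, abs=1e-12)

    def test_pvalue_scale(self):
        assert ks_pvalue(0.152, 72) == pytest.approx(0.072, abs=5e-3)

    def test_errors(self, std_params):
        with pytest.raises(ValueError):
            ks_statistic([], std_params)
        with pytest.raises(ValueError):
            ks_statistic([-1.0, 2.0], std_params)
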