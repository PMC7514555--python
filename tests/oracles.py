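"""Independent numerical oracles shared across test modules."""

import numpy as np

from pffcens import EULER_GAMMA, fit_mle


def quadrature_posterior_means(s, prior, n_grid=501):
    """Exact posterior means of alpha, lambda, entropy by 2-D tensor quadrature.

    Evaluates the unnormalized log-posterior on a tensor grid spanning
    +-8 asymptotic SDs around the MLE and integrates by the trapezoid rule;
    independent of the Lindley and importance-sampling code paths.
    """
    f = fit_mle(s)
    sa = np.sqrt(f.tau[0, 0])
    sl = np.sqrt(f.tau[1, 1])
    als = np.linspace(max(f.alpha_hat - 8 * sa, 1e-3), f.alpha_hat + 8 * sa, n_grid)
    lms = np.linspace(max(f.lam_hat - 8 * sl, 1e-4), f.lam_hat + 8 * sl, n_grid)
    x = s.times
    m = s.m
    R = np.asarray(s.scheme.R)
    c = s.scheme.k * (R + 1) - 1
    lp = np.empty((len(als), len(lms)))
    for i, al in enumerate(als):
        t = x ** (-al)
        u = np.outer(t, lms)
        S = -np.expm1(-u)
        lp[i] = (
            m * np.log(al)
            + m * np.log(lms)
            - u.sum(0)
            - (al + 1) * np.log(x).sum()
            + (c[:, None] * np.log(S)).sum(0)
            - np.log(al)
            + (prior.a - 1) * np.log(lms)
            - prior.b * lms
        )
    w = np.exp(lp - lp.max())
    A, L = np.meshgrid(als, lms, indexing="ij")
    Z = np.trapezoid(np.trapezoid(w, lms, axis=1), als)

    def mean(g):
        return float(np.trapezoid(np.trapezoid(g * w, lms, axis=1), als) / Z)

    H = (A + 1) / A * (EULER_GAMMA + np.log(L)) + 1 - np.log(A * L)
    return {"alpha": mean(A), "lambda": mean(L), "entropy": mean(H)}
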