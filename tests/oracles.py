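"""Independent reference implementations used only to check the package.

These are deliberately naive (explicit loops, scipy distribution calls) so
they share no code path with the vectorised implementations they verify.
"""

import numpy as np
from scipy.stats import norm, poisson


def brute_force_loglik(S, e, centroids, C, sigma2, R, A, beta_e,
                       effort_scale_factor=10.0):
    """Naive triple-loop Poisson log-likelihood over (individual, bin, year)."""
    I, L, T = S.shape
    e_scaled = effort_scale_factor * e / e.max()
    total = 0.0
    for i in range(I):
        for l in range(L):
            for t in range(T):
                if e[l, t] == 0:
                    continue
                d = abs(centroids[l] - C[i, t])
                gamma = A[i, t] * np.exp(R[i, t] + beta_e * e_scaled[l, t])
                lam = gamma * np.exp(-d ** 2 / (2.0 * sigma2[i, t]))
                if lam == 0.0:
                    if S[i, l, t] > 0:
                        return -np.inf
                    continue
                total += poisson.logpmf(S[i, l, t], lam)
    return total


def grid_posterior_C(S_bins, e_scaled, centroids, edges, sigma2, R, beta_e,
                     n_grid=4000):
    """Dense grid evaluation of the posterior of a single activity center.

    All other parameters fixed; C has a uniform prior over [edges[0],
    edges[-1]]. Returns (grid_points, normalised posterior weights) where the
    weights integrate to 1 by the midpoint rule.
    """
    lo, hi = edges[0], edges[-1]
    cs = np.linspace(lo, hi, n_grid, endpoint=False) + (hi - lo) / (2 * n_grid)
    logp = np.zeros(n_grid)
    for j, c in enumerate(cs):
        lam = np.exp(R + beta_e * e_scaled) * np.exp(
            -(centroids - c) ** 2 / (2.0 * sigma2))
        logp[j] = np.sum(S_bins * np.log(lam) - lam)
    logp -= logp.max()
    w = np.exp(logp)
    w /= w.sum()
    return cs, w


def normal_mass(edges, C, sigma):
    """Per-bin normal probability mass via scipy's CDF, loop form."""
    out = np.empty(len(edges) - 1)
    for l in range(len(edges) - 1):
        out[l] = norm.cdf(edges[l + 1], C, sigma) - norm.cdf(edges[l], C, sigma)
    return out
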