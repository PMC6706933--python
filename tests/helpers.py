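"""Independent oracles used by the tests.

Each oracle is a brute-force or closed-form computation kept deliberately
separate from the package's own code paths.
"""

from __future__ import annotations

import math

import numpy as np


def bh_oracle(pvals: np.ndarray) -> np.ndarray:
    """O(m^2) brute-force Benjamini-Hochberg step-up adjustment.

    adj_i = min over j with p_j >= p_i of (m * p_j / rank_j), capped at 1,
    where rank_j counts p-values <= p_j.
    """
    p = np.asarray(pvals, float)
    m = len(p)
    adj = np.empty(m)
    for i in range(m):
        best = 1.0
        for j in range(m):
            if p[j] >= p[i]:
                rank_j = int((p <= p[j]).sum())
                best = min(best, m * p[j] / rank_j)
        adj[i] = best
    return adj


def eb_std_oracle(fc, control_norm, window_size, monotone, guide_ids):
    """Brute-force windowed RMS (about zero) down the control-count ranking."""
    g = len(fc)
    order = sorted(range(g), key=lambda i: (-control_norm[i], guide_ids[i]))
    n = min(window_size, g)
    half = window_size // 2
    raw = []
    for r in range(g):
        start = min(max(r - half, 0), g - n)
        window = [fc[order[j]] ** 2 for j in range(start, start + n)]
        raw.append(math.sqrt(sum(window) / n))
    if monotone:
        for r in range(1, g):
            raw[r] = max(raw[r], raw[r - 1])
    out = [0.0] * g
    for r, i in enumerate(order):
        out[i] = raw[r]
    return np.array(out)


def ng_posterior_mean(y, mu_prior, tau_prior, a_prior, b_prior) -> float:
    """Posterior mean of mu under the semi-conjugate Normal model.

    Data y_i ~ Normal(mu, 1/tau) with independent priors
    mu ~ Normal(mu_prior, 1/tau_prior), tau ~ Gamma(a_prior, rate b_prior).
    Integrating mu out analytically leaves a one-dimensional marginal in
    tau, evaluated here by quadrature on a log-spaced grid — fully
    independent of any Gibbs chain.
    """
    y = np.asarray(y, float)
    n = len(y)
    ybar = y.mean()
    ss = ((y - ybar) ** 2).sum()
    tau = np.logspace(-8, 6, 40001)
    logw = (
        (a_prior - 1 + n / 2) * np.log(tau)
        - b_prior * tau
        - 0.5 * np.log(n * tau + tau_prior)
        - 0.5 * tau * ss
        - 0.5 * (n * tau * tau_prior / (n * tau + tau_prior))
        * (ybar - mu_prior) ** 2
    )
    w = np.exp(logw - logw.max())
    mu_of_tau = (n * ybar * tau + mu_prior * tau_prior) / (n * tau + tau_prior)
    return float(np.trapezoid(w * mu_of_tau, tau) / np.trapezoid(w, tau))


def batch_mcse(draws: np.ndarray, n_batches: int = 25) -> float:
    """Monte-Carlo standard error of a chain mean by batch means."""
    n = len(draws) // n_batches
    bm = draws[: n * n_batches].reshape(n_batches, n).mean(axis=1)
    return float(bm.std(ddof=1) / math.sqrt(n_batches))
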