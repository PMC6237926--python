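"""Independent brute-force oracles used by the test suite.

These deliberately avoid the recursions they are checking: the
state-space oracle builds the full joint Gaussian of states and
observations and conditions it directly; the clustering oracle runs
average linkage from its definition in O(n^3).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

F = np.array([[1.0, 1.0], [0.0, 1.0]])
H = np.array([1.0, 0.0])


def joint_gaussian_moments(T, params, m0, P0):
    """Mean and covariance of the stacked states (Z_1 .. Z_T).

    Z_1 ~ N(m0, P0); Z_t = F Z_{t-1} + w_t with w ~ N(0, Q).
    """
    Q = np.diag([params.sigma2_a, params.sigma2_b])
    mu = np.zeros(2 * T)
    mu[0:2] = m0
    for t in range(1, T):
        mu[2 * t: 2 * t + 2] = F @ mu[2 * (t - 1): 2 * t]
    S = np.zeros((2 * T, 2 * T))
    S[0:2, 0:2] = P0
    for t in range(1, T):
        for s in range(t):
            blk = F @ S[2 * (t - 1): 2 * t, 2 * s: 2 * s + 2]
            S[2 * t: 2 * t + 2, 2 * s: 2 * s + 2] = blk
            S[2 * s: 2 * s + 2, 2 * t: 2 * t + 2] = blk.T
        S[2 * t: 2 * t + 2, 2 * t: 2 * t + 2] = (
            F @ S[2 * (t - 1): 2 * t, 2 * (t - 1): 2 * t] @ F.T + Q
        )
    return mu, S


def _obs_matrix(T, obs_idx):
    Hbig = np.zeros((len(obs_idx), 2 * T))
    for r, t in enumerate(obs_idx):
        Hbig[r, 2 * t] = 1.0
    return Hbig


def conditioned_states(y, params, init_var=1e7, upto=None):
    """Condition every state on the observed data by direct linear
    algebra.

    ``upto=None`` gives smoothed moments (all data); ``upto=t`` gives
    the moments given observations up to and including index t
    (filtered, when evaluated at state t).  Returns per-state means
    (T, 2) and covariances (T, 2, 2).
    """
    y = np.asarray(y, float)
    T = len(y)
    obs = np.flatnonzero(~np.isnan(y))
    m0 = np.array([y[obs[0]], 0.0])
    P0 = np.diag([init_var, init_var])
    mu, S = joint_gaussian_moments(T, params, m0, P0)
    use = obs if upto is None else obs[obs <= upto]
    if len(use) == 0:
        means = mu.reshape(T, 2).copy()
        covs = np.array([S[2 * t: 2 * t + 2, 2 * t: 2 * t + 2] for t in range(T)])
        return means, covs
    Hbig = _obs_matrix(T, use)
    R = params.sigma2_eps * np.eye(len(use))
    Syy = Hbig @ S @ Hbig.T + R
    Szy = S @ Hbig.T
    K = Szy @ np.linalg.inv(Syy)
    mu_c = mu + K @ (y[use] - Hbig @ mu)
    S_c = S - K @ Szy.T
    means = mu_c.reshape(T, 2)
    covs = np.array([S_c[2 * t: 2 * t + 2, 2 * t: 2 * t + 2] for t in range(T)])
    return means, covs


def marginal_loglik(y, params, init_var=1e7):
    """Log density of the observed vector under the implied
    multivariate normal."""
    y = np.asarray(y, float)
    T = len(y)
    obs = np.flatnonzero(~np.isnan(y))
    m0 = np.array([y[obs[0]], 0.0])
    P0 = np.diag([init_var, init_var])
    mu, S = joint_gaussian_moments(T, params, m0, P0)
    Hbig = _obs_matrix(T, obs)
    mean = Hbig @ mu
    cov = Hbig @ S @ Hbig.T + params.sigma2_eps * np.eye(len(obs))
    return float(stats.multivariate_normal(mean, cov).logpdf(y[obs]))


def naive_average_linkage(values):
    """Average-linkage agglomeration from the definition, O(n^3).

    Returns the list of partitions (as sets of frozensets of indices)
    for every cluster count n .. 1, plus the merge heights.
    """
    clusters = [[i] for i in range(len(values))]
    partitions = {len(clusters): {frozenset(c) for c in clusters}}
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = float(np.mean([
                    abs(values[i] - values[j])
                    for i in clusters[a] for j in clusters[b]
                ]))
                key = (d, min(clusters[a] + clusters[b]))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, _), a, b = best
        heights.append(d)
        merged = sorted(clusters[a] + clusters[b])
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
        partitions[len(clusters)] = {frozenset(c) for c in clusters}
    return partitions, heights
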