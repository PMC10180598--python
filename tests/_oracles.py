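"""Independent oracles used by the test suite.

Everything here deliberately avoids the package's computational paths:
dense matrix likelihoods from first principles, Monte-Carlo gene
dropping, and generic derivative-free optimisation.
"""

import numpy as np
from scipy.optimize import minimize


def dense_restricted_loglik(y, X, V):
    """REML log-likelihood from the dense covariance (constant omitted)."""
    n, p = X.shape
    Vi = np.linalg.inv(V)
    K = X.T @ Vi @ X
    beta = np.linalg.solve(K, X.T @ Vi @ y)
    r = y - X @ beta
    return -0.5 * (
        np.linalg.slogdet(V)[1] + np.linalg.slogdet(K)[1] + float(r @ Vi @ r)
    )


def dense_V(theta, terms, residual_builder):
    """Assemble V = sum gamma_k * M_k + R directly from dense pieces.

    ``terms`` is a list of dense unit-variance covariance matrices M_k;
    ``residual_builder(theta_res)`` returns R for the trailing residual
    parameters.
    """
    k = len(terms)
    V = residual_builder(theta[k:]).copy()
    for gamma, M in zip(theta[:k], terms):
        V += gamma * M
    return V


def brute_force_reml(y, X, terms, residual_builder, n_res, starts, bounds):
    """Maximise the dense REML likelihood with Nelder-Mead multistart.

    Returns (best_llf, best_theta).  ``bounds`` is a list of (lo, hi)
    used to clip candidate parameters inside the objective.
    """

    def objective(theta):
        th = np.array(
            [np.clip(v, lo, hi) for v, (lo, hi) in zip(theta, bounds)]
        )
        try:
            V = dense_V(th, terms, residual_builder)
            return -dense_restricted_loglik(y, X, V)
        except np.linalg.LinAlgError:
            return np.inf

    best = (-np.inf, None)
    for s in starts:
        out = minimize(
            objective,
            np.asarray(s, dtype=float),
            method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
        )
        if -out.fun > best[0]:
            best = (-out.fun, out.x)
    return best


def gene_dropping_A(ped_ids, dams, sires, n_drops=200_000, seed=0):
    """Monte-Carlo numerator relationships by gene dropping.

    Simulates biallelic gamete descent ``n_drops`` times; every unknown
    parent contributes fresh unrelated founder alleles.  Returns the
    estimated A matrix and the Monte-Carlo standard error matrix.
    """
    rng = np.random.default_rng(seed)
    n = len(ped_ids)
    index = {v: i for i, v in enumerate(ped_ids)}
    a1 = np.zeros((n_drops, n), dtype=np.int64)
    a2 = np.zeros((n_drops, n), dtype=np.int64)
    next_allele = 0
    for j in range(n):
        for slot, (parent, store) in enumerate(((dams[j], a1), (sires[j], a2))):
            if parent is None:
                store[:, j] = np.arange(
                    next_allele, next_allele + n_drops
                ) * n * 2 + (2 * j + slot)
                next_allele += 1
            else:
                pi = index[parent]
                pick = rng.integers(0, 2, n_drops, dtype=np.int64)
                store[:, j] = np.where(pick == 0, a1[:, pi], a2[:, pi])
    A_hat = np.zeros((n, n))
    se = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            share = 0.5 * (
                (a1[:, i] == a1[:, j]).astype(float)
                + (a1[:, i] == a2[:, j])
                + (a2[:, i] == a1[:, j])
                + (a2[:, i] == a2[:, j])
            )
            A_hat[i, j] = A_hat[j, i] = share.mean()
            se[i, j] = se[j, i] = share.std(ddof=1) / np.sqrt(n_drops)
    return A_hat, se
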