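"""Independent oracles used by the test suite.

These deliberately avoid the analytic determinant/trace identities of the
implementation: the Monte-Carlo estimator integrates the defining
expectations of matched/mismatched decoding by sampling, and the complex
oracle is a naive all-subset-pairs double loop.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from phistress.iit_core import LaggedGaussianModel, _factorized_decoder


def stationary_var_model(A, Q, tau=1, nodes=None, n_samples=10**6) -> LaggedGaussianModel:
    """Exact lagged Gaussian model of a stationary VAR(1)."""
    A = np.asarray(A, dtype=float)
    Q = np.asarray(Q, dtype=float)
    sigma = solve_discrete_lyapunov(A, Q)
    sigma = 0.5 * (sigma + sigma.T)
    cross = sigma @ np.linalg.matrix_power(A, tau).T
    n = A.shape[0]
    nodes = tuple(nodes) if nodes is not None else tuple(f"n{i}" for i in range(n))
    return LaggedGaussianModel(nodes, tau, sigma.copy(), sigma.copy(), cross, n_samples)


def random_stable_var(rng, n, radius=0.7, noise_corr=0.3):
    """A random stable transition matrix and SPD innovation covariance."""
    A = rng.standard_normal((n, n))
    A *= radius / max(np.abs(np.linalg.eigvals(A)))
    W = rng.standard_normal((n, n)) * noise_corr
    Q = W @ W.T + np.eye(n)
    return A, Q


def _logsumexp_rows(mat):
    """Row-wise stable log-sum-exp (faster than the scipy wrapper here)."""
    mx = mat.max(axis=1)
    np.subtract(mat, mx[:, None], out=mat)
    np.exp(mat, out=mat)
    return np.log(mat.sum(axis=1)) + mx


def mc_information(model, partition, betas, n_outer, n_inner, rng):
    """Monte-Carlo matched and mismatched decoding information.

    Returns ``(mi, i_tilde)`` with ``i_tilde[j] = I~(betas[j])``; the matched
    information is estimated with the same machinery at beta = 1 using the
    full (uncut) regression decoder, so the difference shares sampling noise
    with the mismatched estimates.

    Everything is an expectation over samples of the true joint: the outer
    average of beta * ln q(y|x) minus the outer average of
    ln E_{x'}[q(y|x')^beta] with the inner expectation itself sampled.
    """
    n = model.n_nodes
    joint = model.joint_covariance()
    Lj = np.linalg.cholesky(joint)
    z = rng.standard_normal((n_outer, 2 * n)) @ Lj.T
    x, y = z[:, :n], z[:, n:]
    Lx = np.linalg.cholesky(model.cov_past)
    xp = rng.standard_normal((n_inner, n)) @ Lx.T  # fresh draws from p(x)

    def decoder_terms(a_mat, g_mat, beta_list):
        gi = np.linalg.inv(g_mat)
        _, ldg = np.linalg.slogdet(g_mat)
        const = -0.5 * n * np.log(2 * np.pi) - 0.5 * ldg
        resid = y - x @ a_mat.T
        ln_q_pair = const - 0.5 * np.einsum("ij,jk,ik->i", resid, gi, resid)
        mu = xp @ a_mat.T
        ygy = np.einsum("ij,jk,ik->i", y, gi, y)
        mgm = np.einsum("kj,jl,kl->k", mu, gi, mu)
        ln_z = np.zeros((len(beta_list), n_outer))
        gmu = gi @ mu.T
        for s in range(0, n_outer, 4096):
            yb = y[s : s + 4096]
            lnq = const - 0.5 * (
                ygy[s : s + 4096, None] - 2.0 * yb @ gmu + mgm[None, :]
            )
            for j, beta in enumerate(beta_list):
                ln_z[j, s : s + 4096] = _logsumexp_rows(beta * lnq) - np.log(
                    n_inner
                )
        return np.array(
            [b * ln_q_pair.mean() - ln_z[j].mean() for j, b in enumerate(beta_list)]
        )

    # matched decoder: full regression of present on past
    a_full = np.linalg.solve(model.cov_past, model.cov_cross).T
    g_full = model.cov_present - a_full @ model.cov_cross
    mi = float(decoder_terms(a_full, 0.5 * (g_full + g_full.T), [1.0])[0])

    a_blk, g_blk = _factorized_decoder(model, partition)
    i_tilde = decoder_terms(a_blk, g_blk, list(betas))
    return mi, i_tilde


def mc_phi_star(model, partition, rng, n_outer=40000, n_inner=2500, betas=None):
    """Monte-Carlo Phi* = I_mc - max_beta I~_mc(beta) over a beta grid."""
    if betas is None:
        betas = np.arange(0.2, 2.61, 0.2)
    mi, i_tilde = mc_information(model, partition, betas, n_outer, n_inner, rng)
    return mi - i_tilde.max(), mi, i_tilde


# ---------------------------------------------------------------------------
# brute-force complex / main-complex oracle
# ---------------------------------------------------------------------------


def oracle_complexes(phi: dict, nodes) -> set:
    """Naive all-subset-pairs definition of a complex."""
    out = set()
    for cand, p in phi.items():
        if all(
            p > phi[other]
            for other in phi
            if cand < other
        ):
            out.add(cand)
    return out


def oracle_main_complexes(phi: dict, nodes) -> set:
    comps = oracle_complexes(phi, nodes)
    out = set()
    for cand in comps:
        if all(p_o < phi[cand] for other, p_o in phi.items() if other < cand):
            out.add(cand)
    return out


def random_phi_map(rng, nodes, min_size=2) -> dict:
    subsets = []
    labels = sorted(nodes)
    for r in range(min_size, len(labels) + 1):
        subsets.extend(itertools.combinations(labels, r))
    return {frozenset(s): float(rng.uniform(0, 1)) for s in subsets}
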