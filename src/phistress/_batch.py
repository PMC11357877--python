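"""Batched Phi_MIP evaluation across windows.

Numerically identical to the scalar routines in :mod:`iit_core` (the grid
refinement, clamping and tie-breaking are the same algorithm), but stacks
the per-window covariance matrices and pushes every linear-algebra step
through numpy's batched interfaces, so the per-window Python overhead is
amortized over a whole recording.  A batched failure (singular matrix
anywhere in the stack) falls back to the scalar path window by window, so
degeneracy is still diagnosed per window.
"""

from __future__ import annotations

import numpy as np
from numpy.linalg import LinAlgError

from .complex_search import enumerate_subsystems
from .exceptions import DegenerateModelError, NumericalError
from .iit_core import (
    Bipartition,
    LaggedGaussianModel,
    enumerate_bipartitions,
    find_mip,
)

_ZOOM_SCHEDULE = (64, 32, 32, 32, 32)  # mirrors iit_core.optimize_beta


def _batched_logdet(mats: np.ndarray) -> np.ndarray:
    """log det of a (B, k, k) stack of SPD matrices; raises on any failure."""
    L = np.linalg.cholesky(mats)
    d = np.diagonal(L, axis1=-2, axis2=-1)
    return 2.0 * np.log(d).sum(axis=-1)


def _sub(mats: np.ndarray, idx: np.ndarray) -> np.ndarray:
    return mats[:, idx[:, None], idx[None, :]]


def _batched_phi_partition(sx, sy, c, idx_parts, beta_max: float):
    """Phi* ingredients for one partition over a (B, k, k) model stack.

    Returns ``i_star`` (B,), the maximized mismatched information.
    """
    b_n, k, _ = sx.shape
    a_blk = np.zeros_like(sx)
    g_blk = np.zeros_like(sx)
    for idx in idx_parts:
        sxp = _sub(sx, idx)
        cpp = _sub(c, idx)
        np.linalg.cholesky(sxp)  # PD check
        a_p = np.linalg.solve(sxp, cpp).transpose(0, 2, 1)
        g_p = _sub(sy, idx) - a_p @ cpp
        g_p = 0.5 * (g_p + g_p.transpose(0, 2, 1))
        a_blk[:, idx[:, None], idx[None, :]] = a_p
        g_blk[:, idx[:, None], idx[None, :]] = g_p
    np.linalg.cholesky(g_blk)  # PD check
    g_inv = np.linalg.inv(g_blk)
    L = np.linalg.cholesky(sx)
    Lt = L.transpose(0, 2, 1)
    ac = a_blk @ c
    r = sy - ac - ac.transpose(0, 2, 1) + a_blk @ sx @ a_blk.transpose(0, 2, 1)
    t_r = np.einsum("bij,bji->b", g_inv, r)
    t_y = np.einsum("bij,bji->b", g_inv, sy)
    b_mat = a_blk.transpose(0, 2, 1) @ g_inv @ a_blk
    m = Lt @ b_mat @ L
    m = 0.5 * (m + m.transpose(0, 2, 1))
    lam, u = np.linalg.eigh(m)
    lam = np.clip(lam, 0.0, None)
    w_mat = a_blk.transpose(0, 2, 1) @ g_inv @ sy @ g_inv @ a_blk
    wm = Lt @ w_mat @ L
    w = np.einsum("bij,bij->bj", u, wm @ u)

    # vectorized grid-with-refinement beta search (same schedule as scalar)
    lo = np.zeros(b_n)
    hi = np.full(b_n, float(beta_max))
    best_v = np.zeros(b_n)
    for n_pts in _ZOOM_SCHEDULE:
        frac = np.linspace(0.0, 1.0, n_pts)
        grid = lo[:, None] + (hi - lo)[:, None] * frac[None, :]
        denom = 1.0 + grid[:, :, None] * lam[:, None, :]
        vals = (
            -0.5 * grid * t_r[:, None]
            + 0.5 * np.log(denom).sum(axis=-1)
            + 0.5 * grid * t_y[:, None]
            - 0.5 * grid**2 * (w[:, None, :] / denom).sum(axis=-1)
        )
        if not np.all(np.isfinite(vals)):
            raise NumericalError("non-finite I~(beta) in batched search")
        k_idx = np.argmax(vals, axis=1)
        v = np.take_along_axis(vals, k_idx[:, None], axis=1)[:, 0]
        b_best = np.take_along_axis(grid, k_idx[:, None], axis=1)[:, 0]
        best_v = np.maximum(best_v, v)
        step = (hi - lo) / (n_pts - 1)
        lo = np.clip(b_best - step, 0.0, None)
        hi = np.minimum(b_best + step, float(beta_max))
    return best_v


def phi_subset_table(
    models: list[LaggedGaussianModel],
    min_size: int = 2,
    beta_max: float = 10.0,
):
    """Phi_MIP for every subsystem of every model in one batched sweep.

    All models must share node set and tau (windows of one recording).
    Returns ``(subsets, phi, mips)`` where ``subsets`` is the canonical
    subset list, ``phi`` is a (n_models, n_subsets) array (NaN where
    degenerate) and ``mips`` maps (model index, subset index) to the winning
    :class:`Bipartition` (None where degenerate).
    """
    if not models:
        raise ValueError("no models to evaluate")
    nodes = models[0].nodes
    if any(m.nodes != nodes for m in models):
        raise ValueError("all models must share the node set")
    n_m = len(models)
    sx_full = np.stack([m.cov_past for m in models])
    sy_full = np.stack([m.cov_present for m in models])
    c_full = np.stack([m.cov_cross for m in models])

    subsets = enumerate_subsystems(nodes, min_size)
    phi = np.full((n_m, len(subsets)), np.nan)
    mips: dict[tuple[int, int], Bipartition | None] = {}
    pos = {lab: i for i, lab in enumerate(nodes)}
    tie_tol_rel = 1e-9

    for s_i, subset in enumerate(subsets):
        idx = np.array([pos[lab] for lab in subset])
        sx = _sub(sx_full, idx)
        sy = _sub(sy_full, idx)
        c = _sub(c_full, idx)
        parts = enumerate_bipartitions(subset)
        local = {lab: i for i, lab in enumerate(subset)}
        try:
            ld_x = _batched_logdet(sx)
            ld_y = _batched_logdet(sy)
            joint = np.block([[sx, c], [c.transpose(0, 2, 1), sy]])
            ld_j = _batched_logdet(joint)
            mi = 0.5 * (ld_x + ld_y - ld_j)
            phis = np.empty((n_m, len(parts)))
            for p_i, part in enumerate(parts):
                idx_parts = [
                    np.array([local[lab] for lab in part.part_a]),
                    np.array([local[lab] for lab in part.part_b]),
                ]
                i_star = _batched_phi_partition(sx, sy, c, idx_parts, beta_max)
                phis[:, p_i] = mi - i_star
            tol = tie_tol_rel * np.maximum(np.abs(mi), 1.0)
            bad = phis < -tol[:, None]
            phis = np.clip(phis, 0.0, None)
            pmin = phis.min(axis=1)
            near = phis <= (pmin + np.maximum(1e-9 * np.abs(pmin), 1e-9 * 1.0))[:, None]
            win = np.argmax(near, axis=1)  # first partition within tie tolerance
            for m_i in range(n_m):
                if bad[m_i].any():
                    mips[(m_i, s_i)] = None  # numerically unusable
                    continue
                phi[m_i, s_i] = pmin[m_i]
                mips[(m_i, s_i)] = parts[win[m_i]]
        except (LinAlgError, NumericalError):
            # something singular in the stack: diagnose window by window
            for m_i, model in enumerate(models):
                try:
                    res = find_mip(model.restrict(subset), beta_max=beta_max)
                    phi[m_i, s_i] = res.phi_mip
                    mips[(m_i, s_i)] = res.mip
                except (DegenerateModelError, NumericalError):
                    mips[(m_i, s_i)] = None
    return subsets, phi, mips
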