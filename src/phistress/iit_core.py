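"""Integrated information (Phi*) for lagged Gaussian models.

The system at time t is a Gaussian vector X(t) coupled to its own lagged past
X(t - tau).  Integrated information is measured through mismatched decoding:

    Phi* = I(X(t-tau); X(t)) - I*,      I* = max_{beta >= 0} I~(beta)

where I~(beta) is the information transmitted when the past is decoded from
the present using a *partitioned* model -- a decoder that wrongly assumes the
parts of a bipartition evolve independently -- raised to a decoding exponent
beta.  Phi* is zero exactly when the bipartition separates truly independent
blocks, and positive otherwise; the minimum information partition (MIP) is the
bipartition that minimizes Phi*.

All quantities are in nats.  For a factorized decoder q(y|x) built from the
part-restricted linear regressions, I~(beta) has the Gaussian closed form

    I~(beta) = -(beta/2) tr(G^-1 R) + (1/2) ln det(Sx) + (1/2) ln det(P)
               + (1/2) tr(Q Sy)

with Sx, Sy the past/present covariances, A' the block regression matrix,
G the block conditional covariance, R = E[(y - A'x)(y - A'x)^T],
P = Sx^-1 + beta A'^T G^-1 A' and
Q = beta G^-1 - beta^2 G^-1 A' P^-1 A'^T G^-1.
At the matched decoder (no cut) and beta = 1 this reduces to the mutual
information, and at beta = 0 it vanishes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from numpy.linalg import LinAlgError

from .exceptions import DegenerateModelError, NumericalError, SegmentLengthError

__all__ = [
    "LaggedGaussianModel",
    "Bipartition",
    "PhiResult",
    "MipResult",
    "estimate_lagged_gaussian",
    "gaussian_mutual_information",
    "mismatched_information",
    "optimize_beta",
    "phi_star",
    "enumerate_bipartitions",
    "find_mip",
]

#: default upper end of the beta search interval
BETA_MAX = 10.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Bipartition:
    """An unordered cut of a node set into two nonempty parts.

    Canonical form: both parts are sorted lexicographically and ``part_a``
    contains the lexicographically smallest node, so each unordered cut has
    exactly one representation.
    """

    part_a: tuple[str, ...]
    part_b: tuple[str, ...]

    @classmethod
    def of(cls, part_a, part_b) -> "Bipartition":
        a = tuple(sorted(part_a))
        b = tuple(sorted(part_b))
        if not a or not b:
            raise ValueError("both parts must be nonempty")
        if set(a) & set(b):
            raise ValueError("parts must be disjoint")
        if min(b) < min(a):
            a, b = b, a
        return cls(a, b)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.part_a) | frozenset(self.part_b)

    @property
    def cut_label(self) -> str:
        """Label of the smaller part (the paper's '{ECG}-cut' style);
        size ties go to ``part_a``."""
        small = self.part_a if len(self.part_a) <= len(self.part_b) else self.part_b
        return "+".join(small)

    def __str__(self) -> str:  # e.g. "Cz,Pz|ECG,EDA,Fz"
        return ",".join(self.part_a) + "|" + ",".join(self.part_b)


@dataclass(frozen=True)
class LaggedGaussianModel:
    """Second-order statistics of (X(t - tau), X(t)) for a set of nodes.

    ``cov_cross[i, j] = Cov(X_i(t - tau), X_j(t))`` -- past rows, present
    columns; for a stationary VAR(1) X(t) = A X(t-1) + e this equals
    ``Sigma @ A.T`` at tau = 1, with Sigma the stationary covariance.
    """

    nodes: tuple[str, ...]
    tau: int
    cov_present: np.ndarray
    cov_past: np.ndarray
    cov_cross: np.ndarray
    n_samples: int

    def __post_init__(self):
        n = len(self.nodes)
        if len(set(self.nodes)) != n:
            raise ValueError("duplicate node labels")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        for name in ("cov_present", "cov_past", "cov_cross"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}, got {m.shape}")
            object.__setattr__(self, name, m)
        for name in ("cov_present", "cov_past"):
            m = getattr(self, name)
            if not np.allclose(m, m.T, atol=1e-8 * (1.0 + np.abs(m).max())):
                raise ValueError(f"{name} must be symmetric")
            object.__setattr__(self, name, 0.5 * (m + m.T))
        if self.n_samples < n + 1:
            raise ValueError("n_samples must be at least node count + 1")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def indices(self, labels) -> np.ndarray:
        pos = {lab: i for i, lab in enumerate(self.nodes)}
        return np.array([pos[lab] for lab in labels], dtype=int)

    def restrict(self, subset) -> "LaggedGaussianModel":
        """Model of a sub-system: restriction of all covariances to ``subset``
        (kept in this model's node order)."""
        labels = tuple(lab for lab in self.nodes if lab in set(subset))
        if len(labels) != len(set(subset)):
            raise KeyError(f"unknown nodes: {set(subset) - set(self.nodes)}")
        ix = self.indices(labels)
        g = np.ix_(ix, ix)
        return LaggedGaussianModel(
            nodes=labels,
            tau=self.tau,
            cov_present=self.cov_present[g],
            cov_past=self.cov_past[g],
            cov_cross=self.cov_cross[g],
            n_samples=self.n_samples,
        )

    def joint_covariance(self) -> np.ndarray:
        """Covariance of the stacked vector (X(t - tau), X(t))."""
        return np.block(
            [[self.cov_past, self.cov_cross], [self.cov_cross.T, self.cov_present]]
        )


@dataclass(frozen=True)
class PhiResult:
    """Information quantities attached to one bipartition (all in nats)."""

    partition: Bipartition
    mutual_info: float
    mismatched_info: float
    beta_star: float
    phi: float


@dataclass(frozen=True)
class MipResult:
    """The minimum information partition and every candidate it beat."""

    mip: Bipartition
    phi_mip: float
    all_results: tuple[PhiResult, ...] = field(repr=False)


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------


def estimate_lagged_gaussian(segment, tau: int, ridge: float = 0.0, nodes=None) -> LaggedGaussianModel:
    """Estimate a :class:`LaggedGaussianModel` from a frames x channels segment.

    Covariances are empirical, mean-removed over all (t - tau, t) frame pairs.
    When ``ridge > 0``, ``ridge * mean(diag)`` is added to the diagonals of the
    present and past covariances (a small stabilizer for near-singular
    windows).  A singular covariance after ridging raises
    :class:`DegenerateModelError`, signalling an unusable window.
    """
    if hasattr(segment, "columns"):  # DataFrame
        if nodes is None:
            nodes = tuple(str(c) for c in segment.columns)
        segment = segment.to_numpy(dtype=float)
    x = np.asarray(segment, dtype=float)
    if x.ndim != 2:
        raise ValueError("segment must be 2-D (frames x channels)")
    t_len, n = x.shape
    if nodes is None:
        nodes = tuple(f"ch{i}" for i in range(n))
    nodes = tuple(nodes)
    if len(nodes) != n:
        raise ValueError("node labels do not match channel count")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if not np.all(np.isfinite(x)):
        raise ValueError("segment contains non-finite values")
    if t_len <= tau + n:
        raise SegmentLengthError(
            f"segment length {t_len} too short for tau={tau} with {n} channels"
        )
    m = t_len - tau
    if m < n + 1:
        raise SegmentLengthError(f"only {m} frame pairs for {n} channels")

    past = x[: t_len - tau] if tau > 0 else x
    pres = x[tau:]
    past = past - past.mean(axis=0)
    pres = pres - pres.mean(axis=0)
    denom = m - 1
    cov_past = past.T @ past / denom
    cov_present = pres.T @ pres / denom
    cov_cross = past.T @ pres / denom

    if ridge > 0.0:
        lam = ridge * 0.5 * (np.trace(cov_present) + np.trace(cov_past)) / n
        cov_present = cov_present + lam * np.eye(n)
        cov_past = cov_past + lam * np.eye(n)

    for name, c in (("present", cov_present), ("past", cov_past)):
        try:
            np.linalg.cholesky(c)
        except LinAlgError:
            raise DegenerateModelError(
                f"{name}-state covariance is singular (after ridge={ridge})"
            ) from None
        # round-off can leave an exactly-constant channel with a tiny positive
        # variance that Cholesky accepts; gate on conditioning as well
        eigs = np.linalg.eigvalsh(c)
        if eigs[0] <= 1e-12 * max(eigs[-1], np.finfo(float).tiny):
            raise DegenerateModelError(
                f"{name}-state covariance is numerically singular "
                f"(condition number > 1e12; ridge={ridge})"
            )

    return LaggedGaussianModel(
        nodes=nodes,
        tau=int(tau),
        cov_present=cov_present,
        cov_past=cov_past,
        cov_cross=cov_cross,
        n_samples=m,
    )


# ---------------------------------------------------------------------------
# information quantities
# ---------------------------------------------------------------------------


def _chol(mat: np.ndarray, what: str) -> np.ndarray:
    try:
        return np.linalg.cholesky(mat)
    except LinAlgError:
        raise DegenerateModelError(f"{what} is singular or indefinite") from None


def _logdet_pd(mat: np.ndarray, what: str) -> float:
    L = _chol(mat, what)
    return 2.0 * float(np.sum(np.log(np.diag(L))))


def gaussian_mutual_information(model: LaggedGaussianModel) -> float:
    """I(X(t - tau); X(t)) in nats.

    Computed as (1/2) [ln det Sx + ln det Sy - ln det S_joint]; equivalently
    (1/2) ln det(Sy) / det(Sy|x).  Raises :class:`DegenerateModelError` when
    the joint covariance is singular (e.g. a channel whose present value is a
    deterministic copy of its past).
    """
    ld_x = _logdet_pd(model.cov_past, "past covariance")
    ld_y = _logdet_pd(model.cov_present, "present covariance")
    ld_j = _logdet_pd(model.joint_covariance(), "joint (past, present) covariance")
    mi = 0.5 * (ld_x + ld_y - ld_j)
    return float(mi)


def _partition_index_blocks(model: LaggedGaussianModel, partition: Bipartition):
    if partition.nodes != frozenset(model.nodes):
        raise ValueError("partition does not cover the model's node set")
    return [model.indices(partition.part_a), model.indices(partition.part_b)]


def _factorized_decoder(model: LaggedGaussianModel, partition: Bipartition):
    """Block regression matrix A' and block conditional covariance G of the
    partition-factorized decoder q(y|x) = prod_parts N(y_p; A_p x_p, G_p)."""
    n = model.n_nodes
    sx, c = model.cov_past, model.cov_cross
    sy = model.cov_present
    a_blk = np.zeros((n, n))
    g_blk = np.zeros((n, n))
    for ix in _partition_index_blocks(model, partition):
        g = np.ix_(ix, ix)
        sx_p = sx[g]
        c_pp = c[g]  # E[x_p y_p^T]
        _chol(sx_p, "part-restricted past covariance")
        # A_p = Syx_p Sx_p^-1  (regression of part-present on part-past)
        a_p = np.linalg.solve(sx_p, c_pp).T
        g_p = sy[g] - a_p @ c_pp
        g_p = 0.5 * (g_p + g_p.T)
        a_blk[g] = a_p
        g_blk[g] = g_p
    _chol(g_blk, "factorized conditional covariance")
    return a_blk, g_blk


def mismatched_information(
    model: LaggedGaussianModel, partition: Bipartition, beta: float
) -> float:
    """I~(beta): information under the partition-factorized decoder, nats.

    Direct matrix-form evaluation of the closed form in the module docstring;
    the fast path used by :func:`optimize_beta` is the spectrally reduced
    version of the same expression, and the two are kept in exact agreement
    (property-tested).
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if beta == 0.0:
        return 0.0
    a_blk, g_blk = _factorized_decoder(model, partition)
    sx, sy, c = model.cov_past, model.cov_present, model.cov_cross
    g_inv = np.linalg.inv(g_blk)
    ac = a_blk @ c  # E[(A'x) y^T]
    r = sy - ac - ac.T + a_blk @ sx @ a_blk.T
    p = np.linalg.inv(sx) + beta * a_blk.T @ g_inv @ a_blk
    sign, ld_p = np.linalg.slogdet(p)
    if sign <= 0:
        raise DegenerateModelError("decoder precision matrix not positive definite")
    ld_x = _logdet_pd(sx, "past covariance")
    gia = g_inv @ a_blk
    q = beta * g_inv - beta**2 * gia @ np.linalg.solve(p, gia.T)
    val = (
        -0.5 * beta * float(np.trace(g_inv @ r))
        + 0.5 * ld_x
        + 0.5 * ld_p
        + 0.5 * float(np.trace(q @ sy))
    )
    return float(val)


class _SpectralMismatch:
    """Spectral reduction of I~(beta) for one (model, partition).

    After an O(n^3) precomputation, each evaluation is O(n):

        I~(beta) = -(beta/2) tR + (1/2) sum_i ln(1 + beta l_i)
                   + (beta/2) tY - (beta^2/2) sum_i w_i / (1 + beta l_i)

    with l_i the eigenvalues of L^T (A'^T G^-1 A') L (Sx = L L^T) and w_i the
    matching diagonal loadings of A'^T G^-1 Sy G^-1 A'.
    """

    def __init__(self, model: LaggedGaussianModel, partition: Bipartition):
        a_blk, g_blk = _factorized_decoder(model, partition)
        sx, sy, c = model.cov_past, model.cov_present, model.cov_cross
        L = _chol(sx, "past covariance")
        g_inv = np.linalg.inv(g_blk)
        ac = a_blk @ c
        r = sy - ac - ac.T + a_blk @ sx @ a_blk.T
        self.t_r = float(np.trace(g_inv @ r))
        self.t_y = float(np.trace(g_inv @ sy))
        b = a_blk.T @ g_inv @ a_blk
        m = L.T @ b @ L
        m = 0.5 * (m + m.T)
        lam, u = np.linalg.eigh(m)
        lam = np.clip(lam, 0.0, None)
        w_mat = a_blk.T @ g_inv @ sy @ g_inv @ a_blk
        wm = L.T @ w_mat @ L
        self.lam = lam
        self.w = np.einsum("ij,ij->j", u, wm @ u)  # diag(U^T W U)

    def __call__(self, beta):
        beta = np.asarray(beta, dtype=float)
        b = beta[..., None]
        denom = 1.0 + b * self.lam
        out = (
            -0.5 * beta * self.t_r
            + 0.5 * np.log(denom).sum(axis=-1)
            + 0.5 * beta * self.t_y
            - 0.5 * beta**2 * (self.w / denom).sum(axis=-1)
        )
        return out if out.ndim else float(out)


def optimize_beta(
    model: LaggedGaussianModel,
    partition: Bipartition,
    beta_max: float = BETA_MAX,
    tol: float = 1e-6,
) -> tuple[float, float]:
    """Maximize I~(beta) over beta in [0, beta_max].

    Returns ``(beta_star, i_star)``.  Uses a vectorized grid search with two
    refinement passes (final resolution well below ``tol``), which is robust
    to the occasional non-unimodal profile.  ``i_star`` never exceeds the
    mutual information (up to round-off), since mismatched decoding can only
    lose information.
    """
    f = _SpectralMismatch(model, partition)
    lo, hi = 0.0, float(beta_max)
    best_b, best_v = 0.0, 0.0
    n_pts = 64
    for _ in range(5):
        grid = np.linspace(lo, hi, n_pts)
        vals = f(grid)
        if not np.all(np.isfinite(vals)):
            raise NumericalError("non-finite I~(beta) during beta search")
        k = int(np.argmax(vals))
        if vals[k] > best_v:
            best_b, best_v = float(grid[k]), float(vals[k])
        step = grid[1] - grid[0]
        lo = max(0.0, grid[k] - step)
        hi = min(float(beta_max), grid[k] + step)
        n_pts = 32
        if step < tol:
            break
    return best_b, best_v


def phi_star(
    model: LaggedGaussianModel,
    partition: Bipartition,
    beta_max: float = BETA_MAX,
    _mi: float | None = None,
) -> PhiResult:
    """Integrated information Phi* = I - I* across one bipartition.

    Small negative values within round-off of zero are clamped to 0 (Phi* is
    analytically nonnegative); values more negative than the tolerance raise
    :class:`NumericalError`.  ``_mi`` lets an exhaustive search reuse the
    partition-independent mutual information.
    """
    mi = gaussian_mutual_information(model) if _mi is None else _mi
    beta_star, i_star = optimize_beta(model, partition, beta_max=beta_max)
    phi = mi - i_star
    tol = 1e-9 * max(abs(mi), 1.0)
    if phi < -tol:
        raise NumericalError(
            f"Phi* = {phi:.3e} below -tolerance ({-tol:.1e}); "
            "model is likely ill-conditioned"
        )
    if phi < 0.0:
        phi = 0.0
    return PhiResult(
        partition=partition,
        mutual_info=mi,
        mismatched_info=i_star,
        beta_star=beta_star,
        phi=float(phi),
    )


# ---------------------------------------------------------------------------
# partition enumeration and MIP search
# ---------------------------------------------------------------------------


def enumerate_bipartitions(nodes) -> list[Bipartition]:
    """All 2^(n-1) - 1 unordered bipartitions of ``nodes``, canonical order.

    The lexicographically smallest node is anchored in ``part_a``; the
    remaining nodes joining it are enumerated by increasing part size, then
    lexicographically.
    """
    labels = sorted(str(n) for n in nodes)
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate node labels")
    if len(labels) < 2:
        raise ValueError("need at least 2 nodes to bipartition")
    anchor, rest = labels[0], labels[1:]
    out = []
    for r in range(0, len(rest)):
        for combo in itertools.combinations(rest, r):
            part_a = (anchor,) + combo
            part_b = tuple(x for x in rest if x not in combo)
            out.append(Bipartition(part_a, part_b))
    return out


def find_mip(
    model: LaggedGaussianModel,
    beta_max: float = BETA_MAX,
    tie_tol: float = 1e-9,
) -> MipResult:
    """Exhaustive minimum-information-partition search.

    Evaluates Phi* for every bipartition of the model's nodes and returns the
    minimizer.  Ties within ``tie_tol`` (relative) are broken canonically --
    the first partition in :func:`enumerate_bipartitions` order wins -- so the
    result is deterministic for exchangeable systems.  Partitions that are
    degenerate (singular part covariance) are skipped; if every partition is
    degenerate a :class:`DegenerateModelError` is raised.
    """
    mi = gaussian_mutual_information(model)  # partition-independent
    results = []
    for part in enumerate_bipartitions(model.nodes):
        try:
            results.append(phi_star(model, part, beta_max=beta_max, _mi=mi))
        except DegenerateModelError:
            continue
    if not results:
        raise DegenerateModelError("every bipartition of the model is degenerate")
    phis = np.array([r.phi for r in results])
    min_phi = float(phis.min())
    tol = tie_tol * max(1.0, abs(min_phi))
    winner = next(r for r, p in zip(results, phis) if p <= min_phi + tol)
    return MipResult(mip=winner.partition, phi_mip=min_phi, all_results=tuple(results))
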