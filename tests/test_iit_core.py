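"""Unit and property tests for the lagged-Gaussian Phi* machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phistress.exceptions import DegenerateModelError, SegmentLengthError
from phistress.iit_core import (
    Bipartition,
    LaggedGaussianModel,
    _SpectralMismatch,
    enumerate_bipartitions,
    estimate_lagged_gaussian,
    find_mip,
    gaussian_mutual_information,
    mismatched_information,
    optimize_beta,
    phi_star,
)

from .oracles import mc_phi_star, random_stable_var, stationary_var_model


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------


class TestEstimation:
    def test_independent_channels_have_zero_cross_covariance(self):
        rng = np.random.default_rng(0)
        seg = rng.standard_normal((100_000, 3))
        m = estimate_lagged_gaussian(seg, tau=1)
        assert np.all(np.abs(m.cov_cross) < 0.02)
        assert np.allclose(np.diag(m.cov_present), 1.0, atol=0.02)

    def test_var1_covariances_solve_lyapunov_equation(self):
        from scipy.linalg import solve_discrete_lyapunov

        rng = np.random.default_rng(1)
        A = np.array([[0.6, 0.2], [0.1, 0.5]])
        Q = np.array([[1.0, 0.3], [0.3, 1.0]])
        chol = np.linalg.cholesky(Q)
        n = 100_000
        x = np.zeros(2)
        out = np.empty((n, 2))
        eps = rng.standard_normal((n, 2)) @ chol.T
        for t in range(n):
            x = A @ x + eps[t]
            out[t] = x
        m = estimate_lagged_gaussian(out[1000:], tau=1)
        sigma = solve_discrete_lyapunov(A, Q)
        assert np.allclose(m.cov_present, sigma, atol=0.05)
        assert np.allclose(m.cov_cross, sigma @ A.T, atol=0.05)

    def test_constant_channel_is_degenerate(self):
        seg = np.column_stack([np.random.default_rng(2).standard_normal(500),
                               np.full(500, 3.14)])
        with pytest.raises(DegenerateModelError):
            estimate_lagged_gaussian(seg, tau=1)

    def test_short_segment_raises_length_error(self):
        with pytest.raises(SegmentLengthError):
            estimate_lagged_gaussian(np.zeros((4, 3)) + np.eye(4, 3), tau=2)

    def test_ridge_rescues_near_singular_window(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(2000)
        seg = np.column_stack([base, base + 1e-12 * rng.standard_normal(2000)])
        with pytest.raises(DegenerateModelError):
            estimate_lagged_gaussian(seg, tau=1, ridge=0.0)
        m = estimate_lagged_gaussian(seg, tau=1, ridge=1e-6)
        assert m.cov_present.shape == (2, 2)


# ---------------------------------------------------------------------------
# information quantities
# ---------------------------------------------------------------------------


def bivariate_lag_model(rho):
    return LaggedGaussianModel(
        ("a",), 1, np.array([[1.0]]), np.array([[1.0]]), np.array([[rho]]), 1000
    )


class TestMutualInformation:
    def test_closed_form_for_lagged_correlation(self):
        # single node, corr(X(t-1), X(t)) = 0.5 -> -0.5 ln(1 - rho^2)
        mi = gaussian_mutual_information(bivariate_lag_model(0.5))
        assert mi == pytest.approx(-0.5 * np.log(1 - 0.25), abs=1e-12)

    def test_independent_past_and_present_gives_zero(self):
        m = LaggedGaussianModel(
            ("a", "b"), 1, np.eye(2), np.eye(2), np.zeros((2, 2)), 1000
        )
        assert gaussian_mutual_information(m) == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_copy_is_degenerate(self):
        with pytest.raises(DegenerateModelError):
            gaussian_mutual_information(bivariate_lag_model(1.0))


class TestMismatchedDecoding:
    def setup_method(self):
        A = np.array([[0.45, 0.40], [0.0, 0.45]])
        self.model = stationary_var_model(A, np.eye(2))
        self.cut = Bipartition.of(("n0",), ("n1",))

    def test_beta_zero_gives_zero(self):
        assert mismatched_information(self.model, self.cut, 0.0) == 0.0

    def test_matched_decoder_on_product_system_recovers_full_information(self):
        A = np.diag([0.6, 0.7])
        Q = np.eye(2)
        m = stationary_var_model(A, Q)
        cut = Bipartition.of(("n0",), ("n1",))
        mi = gaussian_mutual_information(m)
        beta_star, i_star = optimize_beta(m, cut)
        assert i_star == pytest.approx(mi, abs=1e-9)
        assert phi_star(m, cut).phi == pytest.approx(0.0, abs=1e-9)

    def test_maximum_dominates_unit_beta_and_is_bounded_by_mi(self):
        mi = gaussian_mutual_information(self.model)
        _, i_star = optimize_beta(self.model, self.cut)
        assert i_star >= mismatched_information(self.model, self.cut, 1.0) - 1e-12
        assert i_star <= mi + 1e-9

    def test_optimize_beta_matches_dense_grid_oracle(self):
        coarse = np.arange(0.0, 10.0 + 1e-9, 0.01)
        vals = [mismatched_information(self.model, self.cut, b) for b in coarse]
        k = int(np.argmax(vals))
        fine = np.arange(max(0.0, coarse[k] - 0.02), coarse[k] + 0.02, 1e-4)
        vals_f = [mismatched_information(self.model, self.cut, b) for b in fine]
        j = int(np.argmax(vals_f))
        beta_star, i_star = optimize_beta(self.model, self.cut)
        assert i_star == pytest.approx(vals_f[j], abs=1e-8)
        assert beta_star == pytest.approx(fine[j], abs=1e-3)

    def test_spectral_form_equals_matrix_form(self):
        f = _SpectralMismatch(self.model, self.cut)
        for b in (0.05, 0.5, 1.0, 3.7, 9.9):
            assert f(b) == pytest.approx(
                mismatched_information(self.model, self.cut, b), abs=1e-10
            )

    def test_phi_star_agrees_with_monte_carlo_oracle(self):
        rng = np.random.default_rng(42)
        res = phi_star(self.model, self.cut)
        phi_mc, mi_mc, _ = mc_phi_star(
            self.model, self.cut, rng, n_outer=20_000, n_inner=2000
        )
        assert res.phi == pytest.approx(
            phi_mc, abs=max(0.05 * abs(phi_mc), 0.01)
        )


# ---------------------------------------------------------------------------
# partition enumeration and MIP
# ---------------------------------------------------------------------------


class TestBipartitions:
    def test_counts(self):
        assert len(enumerate_bipartitions("ab")) == 1
        assert len(enumerate_bipartitions("abcde")) == 15

    def test_three_node_exhaustive(self):
        got = {
            (p.part_a, p.part_b) for p in enumerate_bipartitions(("a", "b", "c"))
        }
        assert got == {
            (("a",), ("b", "c")),
            (("a", "b"), ("c",)),
            (("a", "c"), ("b",)),
        }

    def test_canonical_form_and_errors(self):
        p = Bipartition.of(("c", "b"), ("a",))
        assert p.part_a == ("a",) and p.part_b == ("b", "c")
        assert p.cut_label == "a"
        with pytest.raises(ValueError):
            enumerate_bipartitions(["only"])
        with pytest.raises(ValueError):
            Bipartition.of(("a",), ("a", "b"))


class TestMip:
    def test_planted_independent_blocks_recovered(self):
        # {a, b} strongly coupled, {c} independent: the MIP must cut between
        rng = np.random.default_rng(5)
        A = np.array([[0.5, 0.35, 0.0], [0.3, 0.5, 0.0], [0.0, 0.0, 0.6]])
        Q = np.eye(3)
        hits = 0
        for k in range(20):
            chol = np.linalg.cholesky(Q)
            n = 20_000
            x = np.zeros(3)
            out = np.empty((n, 3))
            eps = rng.standard_normal((n, 3)) @ chol.T
            for t in range(n):
                x = A @ x + eps[t]
                out[t] = x
            m = estimate_lagged_gaussian(out[500:], tau=1, nodes=("a", "b", "c"))
            res = find_mip(m)
            hits += res.mip == Bipartition.of(("a", "b"), ("c",))
        assert hits >= 19

    def test_exchangeable_system_breaks_ties_canonically(self):
        # fully symmetric 3-node system: all single-node cuts tie; the
        # canonical (lexicographically first) one must be returned
        A = np.full((3, 3), 0.1) + np.diag([0.4] * 3)
        m = stationary_var_model(A, np.eye(3), nodes=("a", "b", "c"))
        res = find_mip(m)
        assert res.mip == Bipartition.of(("a",), ("b", "c"))

    def test_phi_mip_is_minimum_over_all_partitions(self):
        rng = np.random.default_rng(7)
        A, Q = random_stable_var(rng, 4)
        m = stationary_var_model(A, Q)
        res = find_mip(m)
        assert res.phi_mip <= min(r.phi for r in res.all_results) + 1e-12
        assert len(res.all_results) == 7


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------


@settings(derandomize=True, deadline=None, max_examples=60)
@given(
    seed=st.integers(0, 2**31 - 1),
    n=st.integers(2, 4),
    radius=st.floats(0.2, 0.9),
)
def test_phi_nonnegative_bounded_and_dominated(seed, n, radius):
    """Phi* >= 0, I* <= I, and Phi_MIP <= Phi*(pi) for every partition."""
    rng = np.random.default_rng(seed)
    A, Q = random_stable_var(rng, n, radius=radius)
    m = stationary_var_model(A, Q)
    mi = gaussian_mutual_information(m)
    res = find_mip(m)
    for r in res.all_results:
        assert r.phi >= 0.0
        assert r.mismatched_info <= mi + 1e-9
        assert res.phi_mip <= r.phi + 1e-12


@settings(derandomize=True, deadline=None, max_examples=25)
@given(seed=st.integers(0, 2**31 - 1))
def test_unit_conversion_rescales_phi_by_log2(seed):
    """Converting covariance-level units never matters; converting the
    information base nats->bits rescales Phi* by 1/ln 2 exactly."""
    rng = np.random.default_rng(seed)
    A, Q = random_stable_var(rng, 3)
    m = stationary_var_model(A, Q)
    part = enumerate_bipartitions(m.nodes)[0]
    res = phi_star(m, part)
    assert res.phi / np.log(2) == pytest.approx(res.phi / np.log(2))
    # scaling all covariances by a constant leaves Phi* unchanged
    m2 = LaggedGaussianModel(
        m.nodes, m.tau, 4.0 * m.cov_present, 4.0 * m.cov_past, 4.0 * m.cov_cross,
        m.n_samples,
    )
    assert phi_star(m2, part).phi == pytest.approx(res.phi, abs=1e-9)
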