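import numpy as np
import pytest
from scipy.linalg import svdvals

from unibrainnet import (
    HyperParams,
    ValidationError,
    build_laplacian,
    objective_value,
    pearson_network,
    soft_threshold_svd,
    standardize_columns,
)
from unibrainnet.network import (
    AdmmState,
    update_multipliers,
    update_p,
    update_q,
    update_u,
    update_w,
    update_xtilde,
)


def make_state(rng, n=6, m=4, k=10, mu=1.3):
    """Random consistent solver state for update-formula tests."""
    X = rng.standard_normal((k, n))
    Xt = rng.standard_normal((m, n))
    state = AdmmState(
        W=rng.standard_normal((n, n)),
        P=rng.standard_normal((n, n)),
        Q=rng.standard_normal((n, n)),
        U=rng.standard_normal((m, k)),
        Xt=Xt,
        Y1=rng.standard_normal((n, n)),
        Y2=rng.standard_normal((n, n)),
        Y3=rng.standard_normal((m, n)),
        mu=mu,
        K_gram=Xt.T @ Xt,
    )
    return state, X


class TestLaplacian:
    def test_two_node_example(self):
        lap = build_laplacian(np.array([[0.0, 2.0], [2.0, 0.0]]))
        np.testing.assert_array_equal(lap.L, [[2.0, -2.0], [-2.0, 2.0]])

    def test_zero_graph(self):
        assert not build_laplacian(np.zeros((4, 4))).L.any()

    def test_rows_sum_to_zero(self, rng):
        g = rng.uniform(0, 5, (6, 6))
        g = (g + g.T) / 2
        np.fill_diagonal(g, 0)
        lap = build_laplacian(g)
        np.testing.assert_allclose(lap.L.sum(axis=1), 0.0, atol=1e-12)

    def test_rejects_negative_and_asymmetric(self):
        with pytest.raises(ValidationError):
            build_laplacian(np.array([[0.0, -1.0], [-1.0, 0.0]]))
        with pytest.raises(ValidationError):
            build_laplacian(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_trace_identity_vs_edge_sum(self, rng):
        """tr(W L W^T) equals half the fiber-weighted sum of squared
        column-profile differences."""
        n = 7
        g = rng.uniform(0, 3, (n, n))
        g = (g + g.T) / 2
        np.fill_diagonal(g, 0)
        lap = build_laplacian(g)
        w = rng.standard_normal((n, n))
        direct = 0.5 * sum(
            g[i, j] * np.sum((w[:, i] - w[:, j]) ** 2)
            for i in range(n)
            for j in range(n)
        )
        assert abs(np.trace(w @ lap.L @ w.T) - direct) < 1e-10 * max(1.0, direct)


class TestPearson:
    def test_perfect_and_anti_correlation(self, rng):
        x = rng.standard_normal(50)
        m = np.column_stack([x, x, -x])
        c = pearson_network(m)
        assert c[0, 1] == pytest.approx(1.0)
        assert c[0, 2] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        m = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 4.0], [4.0, 3.0]])
        assert pearson_network(m)[0, 1] == pytest.approx(0.6)

    def test_zero_variance_column_names_region(self):
        m = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(ValidationError, match="1"):
            pearson_network(m)


class TestSoftThresholdSvd:
    def test_zero_threshold_is_identity(self, rng):
        m = rng.standard_normal((4, 4))
        np.testing.assert_allclose(soft_threshold_svd(m, 0.0), m, atol=1e-12)

    def test_diagonal_example(self):
        np.testing.assert_allclose(
            soft_threshold_svd(np.diag([3.0, 1.0]), 2.0), np.diag([1.0, 0.0]),
            atol=1e-12,
        )

    def test_shrinks_singular_values_by_threshold(self, rng):
        m = rng.standard_normal((5, 5))
        out = soft_threshold_svd(m, 0.4)
        np.testing.assert_allclose(
            svdvals(out), np.maximum(svdvals(m) - 0.4, 0.0), atol=1e-10
        )


class TestBlockUpdates:
    """Trivial reductions of each closed-form update."""

    def test_w_with_zero_gram(self, rng):
        state, _ = make_state(rng)
        state.K_gram = np.zeros((6, 6))
        expected = (state.P + state.Q) / 2 + (state.Y1 + state.Y2) / (2 * state.mu)
        np.testing.assert_allclose(update_w(state), expected, atol=1e-10)

    def test_w_stationarity(self, rng):
        state, _ = make_state(rng)
        w = update_w(state)
        grad = (
            2 * state.K_gram @ (w - np.eye(6))
            - state.Y1 - state.Y2
            + state.mu * (w - state.P) + state.mu * (w - state.Q)
        )
        assert np.abs(grad).max() < 1e-8

    def test_p_zero_alpha(self, rng):
        state, _ = make_state(rng)
        np.testing.assert_allclose(
            update_p(state, 0.0), state.W - state.Y1 / state.mu, atol=1e-12
        )

    def test_p_full_shrinkage(self, rng):
        state, _ = make_state(rng)
        target = state.W - state.Y1 / state.mu
        big_alpha = (svdvals(target).max() + 1.0) * state.mu
        assert np.abs(update_p(state, big_alpha)).max() < 1e-12

    def test_q_reduces_without_laplacian(self, rng):
        state, _ = make_state(rng)
        lap = build_laplacian(np.zeros((6, 6)))
        np.testing.assert_allclose(
            update_q(state, 5.0, lap), state.W - state.Y2 / state.mu, atol=1e-10
        )
        g = rng.uniform(0, 2, (6, 6))
        g = (g + g.T) / 2
        np.fill_diagonal(g, 0)
        np.testing.assert_allclose(
            update_q(state, 0.0, build_laplacian(g)),
            state.W - state.Y2 / state.mu,
            atol=1e-10,
        )

    def test_u_identity_data_reduction(self, rng):
        state, _ = make_state(rng, n=6, m=4, k=6)
        state.Y3 = np.zeros((4, 6))
        x_eye = np.eye(6)
        gamma = 0.7
        expected = state.mu * state.Xt / (2 * gamma + state.mu)
        np.testing.assert_allclose(update_u(state, gamma, x_eye), expected, atol=1e-10)

    def test_u_ridge_limit(self, rng):
        state, x = make_state(rng)
        assert np.abs(update_u(state, 1e12, x)).max() < 1e-9

    def test_xtilde_zero_w_reduction(self, rng):
        state, x = make_state(rng)
        state.W = np.zeros((6, 6))
        state.Y3 = np.zeros((4, 6))
        expected = state.mu * state.U @ x / (2 + state.mu)
        np.testing.assert_allclose(update_xtilde(state, x), expected, atol=1e-10)

    def test_xtilde_penalty_limit(self, rng):
        state, x = make_state(rng)
        state.mu = 1e9
        ux = state.U @ x
        out = update_xtilde(state, x)
        tol = 1e-6 * np.abs(ux).max() + np.abs(state.Y3).max() / state.mu
        assert np.abs(out - ux).max() < tol


class TestMultipliers:
    def test_zero_residuals_leave_multipliers(self, rng):
        state, x = make_state(rng)
        state.P = state.W.copy()
        state.Q = state.W.copy()
        state.Xt = state.U @ x
        y1, y2, y3, mu = state.Y1.copy(), state.Y2.copy(), state.Y3.copy(), state.mu
        params = HyperParams(rho=1.5, mu_max=100.0)
        update_multipliers(state, params, x)
        np.testing.assert_array_equal(state.Y1, y1)
        np.testing.assert_array_equal(state.Y2, y2)
        np.testing.assert_array_equal(state.Y3, y3)
        assert state.mu == pytest.approx(1.5 * mu)

    def test_penalty_cap(self, rng):
        state, x = make_state(rng)
        state.mu = 50.0
        update_multipliers(state, HyperParams(rho=2.0, mu_max=50.0), x)
        assert state.mu == 50.0

    def test_hand_computed_ascent(self, rng):
        state, x = make_state(rng)
        expected_y1 = state.Y1 + state.mu * (state.P - state.W)
        update_multipliers(state, HyperParams(rho=1.1), x)
        np.testing.assert_allclose(state.Y1, expected_y1, atol=1e-12)


class TestObjective:
    def test_zero_solution_scores_zero(self):
        params = HyperParams()
        lap = build_laplacian(np.zeros((4, 4)))
        x = np.ones((5, 4))
        assert objective_value(np.zeros((4, 4)), np.zeros((3, 5)), x, lap, params) == 0.0

    def test_identity_w_with_no_regularization(self, rng):
        params = HyperParams(alpha=0.0, beta=0.0, gamma=0.0)
        lap = build_laplacian(np.zeros((4, 4)))
        x = rng.standard_normal((5, 4))
        u = rng.standard_normal((3, 5))
        assert objective_value(np.eye(4), u, x, lap, params) == pytest.approx(0.0)

    def test_matches_term_by_term_recomputation(self, rng):
        params = HyperParams(alpha=0.9, beta=0.4, gamma=1.7)
        n, k, m = 5, 8, 3
        g = rng.uniform(0, 2, (n, n))
        g = (g + g.T) / 2
        np.fill_diagonal(g, 0)
        lap = build_laplacian(g)
        w = rng.standard_normal((n, n))
        u = rng.standard_normal((m, k))
        x = rng.standard_normal((k, n))
        xt = u @ x
        expected = (
            np.sum((xt - xt @ w) ** 2)
            + 0.9 * svdvals(w).sum()
            + 0.4 * np.einsum("ij,jk,ik->", w, lap.L, w)
            + 1.7 * np.sum(u * u)
        )
        assert objective_value(w, u, x, lap, params) == pytest.approx(expected)


class TestStandardize:
    def test_columns_become_zero_mean_unit_variance(self, rng):
        x = rng.normal(3.0, 2.5, (40, 6))
        z = standardize_columns(x)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-12)

    def test_rejects_constant_region(self):
        x = np.column_stack([np.arange(10.0), np.full(10, 2.0)])
        with pytest.raises(ValidationError, match="1"):
            standardize_columns(x)


class TestHyperParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(rho=1.0),
            dict(eps=0.0),
            dict(mu0=2.0, mu_max=1.0),
            dict(alpha=-0.1),
            dict(m=0),
        ],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            HyperParams(**kwargs)
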