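"""dynEMA coefficient fitting, greedy mode selection, reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dynem
from dynem.dynema import fit_pema


def series(X, dt=3.0):
    return dynem.FluxTimeSeries(np.asarray(X, float), dt * np.arange(len(X)))


class TestFitCoefficients:
    def test_single_mode_ratio_exact(self, toy_net, toy_ems):
        """With one mode the coefficient is the unique ratio X/p on the support."""
        fts = dynem.generate_dynamic_experiment(toy_net, 0, J=4, ems=toy_ems)
        p = toy_ems.modes[:, [0]]
        coeffs, F = dynem.fit_coefficients(fts, p)
        np.testing.assert_allclose(F, 0.0, atol=1e-12)
        sup = sorted(toy_ems.support(0))
        expect = fts.fluxes[:, sup] / p[sup, 0]
        np.testing.assert_allclose(coeffs.alpha[0][:, sup], expect)

    def test_zero_input_zero_coefficients(self, toy_ems):
        coeffs, F = dynem.fit_coefficients(np.zeros((3, 8)), toy_ems.modes)
        assert np.all(coeffs.alpha == 0) and np.all(F == 0)

    def test_shared_reaction_minimum_norm_split(self):
        """Two modes sharing a unit-weight reaction split its flux equally."""
        P = np.array([[1.0, 1.0]])  # K=1, two modes both using the reaction at 1
        coeffs, F = dynem.fit_coefficients(np.array([[2.0]]), P)
        np.testing.assert_allclose(coeffs.alpha[:, 0, 0], [1.0, 1.0])
        np.testing.assert_allclose(F, 0.0, atol=1e-15)

    def test_proportional_split_weighted(self):
        # weights 2 and 1: minimum-norm split is proportional to the weights
        P = np.array([[2.0, 1.0]])
        coeffs, _ = dynem.fit_coefficients(np.array([[5.0]]), P)
        np.testing.assert_allclose(coeffs.alpha[:, 0, 0], [2.0, 1.0])

    def test_zero_mode_column_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            dynem.fit_coefficients(np.ones((2, 2)), np.array([[1.0, 0.0], [1.0, 0.0]]))

    def test_dimension_mismatch(self, toy_ems):
        with pytest.raises(ValueError, match="reactions"):
            dynem.fit_coefficients(np.ones((2, 5)), toy_ems.modes)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_nonnegativity_and_support_respect(self, seed):
        """alpha >= 0 always; alpha = 0 wherever the mode is zero."""
        rng = np.random.default_rng(seed)
        J, K, E = rng.integers(1, 5), rng.integers(2, 6), rng.integers(1, 4)
        P = rng.uniform(0, 1, (K, E)) * (rng.uniform(size=(K, E)) > 0.4)
        P[rng.integers(0, K), :] = rng.uniform(0.5, 1, E)  # no zero column
        X = rng.uniform(0, 2, (J, K))
        coeffs, F = dynem.fit_coefficients(X, P)
        assert np.all(coeffs.alpha >= 0)
        assert np.all(coeffs.alpha[:, :, :][np.broadcast_to(P.T[:, None, :] == 0, coeffs.alpha.shape)] == 0)
        # reconstruction + residual == input identically
        recon = np.einsum("ejk,ke->jk", coeffs.alpha, P)
        np.testing.assert_allclose(recon + F, X, atol=1e-12)

    def test_unfolded_view_shape_and_order(self, toy_ems):
        X = np.ones((3, 8))
        coeffs, _ = dynem.fit_coefficients(X, toy_ems.modes[:, :2])
        unf = coeffs.unfolded
        assert unf.shape == (2 * 3, 8)
        # time-major: rows (e within j)
        np.testing.assert_allclose(unf[0], coeffs.alpha[0, 0])
        np.testing.assert_allclose(unf[1], coeffs.alpha[1, 0])
        np.testing.assert_allclose(unf[2], coeffs.alpha[0, 1])


class TestFitDynEMA:
    def test_single_source_recovery(self, toy_net, toy_ems):
        fts = dynem.generate_dynamic_experiment(toy_net, 0, J=6, ems=toy_ems)
        model = dynem.fit_dynema(fts, toy_ems, n_modes=1)
        assert model.selected_ems == (0,)
        assert model.explained_variance[0] == pytest.approx(1.0)

    def test_two_mode_steady_state_exact(self, toy_net, toy_ems):
        """Flux on reactions 1-6 only is exactly a two-mode combination."""
        x = dynem.generate_steady_fluxes(toy_net, [2, 1, 0], ems=toy_ems)
        assert np.all(x.fluxes[0, 6:] == 0)  # reactions 7-8 carry no flux
        model = dynem.fit_dynema(x, toy_ems, n_modes=2)
        assert set(model.selected_ems) == {0, 1}
        np.testing.assert_allclose(model.residual, 0.0, atol=1e-12)
        # the steady-state baseline with one weight per mode is exact too
        lam, F = fit_pema(x.fluxes, toy_ems.modes[:, list(model.selected_ems)])
        np.testing.assert_allclose(F, 0.0, atol=1e-10)

    def test_greedy_matches_exhaustive_first_step_and_noise(self, toy_net, toy_ems):
        """Greedy selection under flux noise: first pick matches exhaustive
        search and the residual is at the noise level."""
        rng = np.random.default_rng(42)
        base = (
            2.0 * dynem.generate_dynamic_experiment(toy_net, 0, J=8, ems=toy_ems).fluxes
            + dynem.generate_dynamic_experiment(toy_net, 1, J=8, ems=toy_ems).fluxes
        )
        noisy = np.maximum(base + 0.01 * rng.standard_normal(base.shape), 0.0)
        fts = series(noisy)
        model = dynem.fit_dynema(fts, toy_ems, n_modes=2)
        assert set(model.selected_ems) == {0, 1}
        # exhaustive single-mode search agrees with the greedy first step
        evs = []
        for z in range(toy_ems.n_modes):
            _, F = dynem.fit_coefficients(noisy, toy_ems.modes[:, [z]])
            evs.append(dynem.explained_variance(noisy, noisy - F))
        assert model.selected_ems[0] == int(np.argmax(evs))
        # residual at the injected noise level (within a factor 2)
        noise_norm = np.linalg.norm(noisy - base)
        assert np.linalg.norm(model.residual) <= 2 * noise_norm

    def test_monotone_explained_variance(self, toy_net, toy_ems):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (5, 8))
        model = dynem.fit_dynema(series(X), toy_ems, n_modes=3)
        assert list(model.explained_variance) == sorted(model.explained_variance)

    def test_variance_target_stop(self, toy_net, toy_ems):
        fts = dynem.generate_dynamic_experiment(toy_net, 0, J=4, ems=toy_ems)
        model = dynem.fit_dynema(fts, toy_ems, variance_target=0.95)
        assert len(model.selected_ems) == 1  # one mode fully explains it

    def test_empty_mode_matrix_rejected(self, toy_net):
        empty = dynem.ElementaryModeMatrix(np.zeros((8, 0)), ())
        with pytest.raises(ValueError, match="empty"):
            dynem.fit_dynema(series(np.ones((2, 8))), empty)

    def test_pema_limit_equivalence(self, toy_net, toy_ems):
        """Constant coefficients reduce dynEMA to the one-weight-per-mode
        steady-state model: identical reconstructions on steady input."""
        x = dynem.generate_steady_fluxes(toy_net, [1.5, 0.5, 0.25], ems=toy_ems)
        X = np.repeat(x.fluxes, 4, axis=0)  # steady series
        model = dynem.fit_dynema(series(X), toy_ems, n_modes=3)
        lam, F_pema = fit_pema(X, model.em_matrix)
        recon_dyn = dynem.reconstruct(model)
        np.testing.assert_allclose(recon_dyn, X - F_pema, atol=1e-9)
        # and the fitted coefficients are constant over time
        assert np.allclose(np.ptp(model.coefficients.alpha, axis=1), 0, atol=1e-9)


class TestReconstruct:
    def test_identity_with_residual(self, toy_net, toy_ems):
        rng = np.random.default_rng(11)
        X = rng.uniform(0, 2, (6, 8))
        model = dynem.fit_dynema(series(X), toy_ems, n_modes=2)
        np.testing.assert_array_less(
            np.abs(dynem.reconstruct(model) + model.residual - X).max(), 1e-10
        )

    def test_kronecker_bookkeeping(self):
        """alpha of ones with an all-ones single mode reproduces ones(J, K);
        matches the literal (I_J (x) 1_E')[A o (1_J (x) P')] evaluation."""
        J, K = 2, 2
        alpha = np.ones((1, J, K))
        P = np.ones((K, 1))
        model = dynem.DynEMAModel((0,), P, dynem.DynEMACoefficients(alpha), np.zeros((J, K)), (1.0,))
        np.testing.assert_allclose(dynem.reconstruct(model), np.ones((J, K)))
        A_unf = dynem.DynEMACoefficients(alpha).unfolded  # (E*J, K)
        literal = np.kron(np.eye(J), np.ones((1, 1))) @ (A_unf * np.kron(np.ones((J, 1)), P.T))
        np.testing.assert_allclose(dynem.reconstruct(model), literal)


class TestExplainedVariance:
    @pytest.mark.parametrize(
        "X, Xhat, expected",
        [
            ([[1.0, 0.0], [0.0, 1.0]], [[1.0, 0.0], [0.0, 1.0]], 1.0),
            ([[1.0, 0.0], [0.0, 1.0]], [[0.0, 0.0], [0.0, 0.0]], 0.0),
            ([[1.0, 0.0], [0.0, 1.0]], [[1.0, 0.0], [0.0, 0.0]], 0.5),
        ],
    )
    def test_values(self, X, Xhat, expected):
        assert dynem.explained_variance(np.array(X), np.array(Xhat)) == pytest.approx(expected)

    def test_zero_input_conventions(self):
        assert dynem.explained_variance(np.zeros((2, 2)), np.zeros((2, 2))) == 1.0
        with pytest.raises(ValueError):
            dynem.explained_variance(np.zeros((2, 2)), np.ones((2, 2)))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dynem.explained_variance(np.zeros((2, 2)), np.zeros((3, 2)))
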