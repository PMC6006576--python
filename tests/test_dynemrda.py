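"""dynEMR-DA screening, inactivity filter, greedy discriminant selection."""

import numpy as np
import pytest

import dynem
from dynem.dynemrda import fit_em_coefficients, minimal_components


def planted_set(toy_net, toy_ems, seed=0, n=8, J=10, effect=2.0, noise=0.2):
    cfg = dynem.SimulationConfig(
        seed=seed, n_experiments_per_class=n, n_timepoints=J,
        noise_fraction=noise, class_effect=effect,
    )
    return dynem.generate_two_class_set(cfg, toy_net, 0, toy_ems)


class TestScreening:
    def test_planted_mode_ranks_first_and_discriminates(self, toy_net, toy_ems):
        """The mode whose usage is scaled x2 in the high class tops the
        ranking and its reconstruction separates the classes perfectly."""
        X, y = planted_set(toy_net, toy_ems)
        res = dynem.screen_dynems(X, y, toy_ems)
        assert res.ranking[0] == 0
        rec = res.record_for(0)
        assert rec.active
        # every candidate was screened (exhaustive over the mode set)
        assert {r.em_index for r in res.records} == {0, 1, 2}
        _, Xhat = fit_em_coefficients(X, toy_ems, (0,))
        model = dynem.fit_npls1(Xhat, y, min(X.data.shape[0] - 1, 8))
        assert minimal_components(model, Xhat, y) is not None

    def test_ranking_invariant_under_relabeling(self, toy_net, toy_ems):
        X, y = planted_set(toy_net, toy_ems)
        res_a = dynem.screen_dynems(X, y, toy_ems)
        res_b = dynem.screen_dynems(X, 1 - y, toy_ems)
        assert res_a.ranking == res_b.ranking
        for ra, rb in zip(res_a.records, res_b.records):
            assert ra.y_variance == pytest.approx(rb.y_variance, abs=1e-9)

    def test_screening_order_independent(self, toy_net, toy_ems):
        """Permuting the candidate columns permutes the records, nothing else."""
        X, y = planted_set(toy_net, toy_ems)
        perm = [2, 0, 1]
        ems_p = dynem.ElementaryModeMatrix(
            toy_ems.modes[:, perm], tuple(toy_ems.em_ids[i] for i in perm)
        )
        res = dynem.screen_dynems(X, y, toy_ems)
        res_p = dynem.screen_dynems(X, y, ems_p)
        by_id = {r.em_id: r for r in res.records}
        for r in res_p.records:
            assert r.y_variance == pytest.approx(by_id[r.em_id].y_variance, abs=1e-9)
            assert r.active == by_id[r.em_id].active

    def test_disjoint_support_candidate_recorded_not_fatal(self, toy_ems):
        """A candidate using only flux-free reactions reconstructs nothing;
        the failure is recorded and the candidate is ranked below active ones."""
        rng = np.random.default_rng(4)
        N, K, J = 8, 8, 5
        X = np.zeros((N, K, J))
        X[:, 2:4, :] = rng.uniform(1, 2, (N, 2, J))  # flux on r3, r4 only
        X[4:, 2:4, :] *= 2.0
        y = np.array([0] * 4 + [1] * 4)
        res = dynem.screen_dynems(dynem.ThreeWayFluxArray(X), y, toy_ems)
        rec2 = res.record_for(1)  # support {r1, r2, r5, r6}: all flux-free
        assert (rec2.error is not None) or rec2.y_variance <= res.record_for(0).y_variance
        assert not rec2.active

    def test_reconstruction_confined_to_support(self, toy_net, toy_ems):
        X, _ = planted_set(toy_net, toy_ems)
        for z in range(toy_ems.n_modes):
            _, Xhat = fit_em_coefficients(X, toy_ems, (z,))
            outside = sorted(set(range(8)) - toy_ems.support(z))
            assert np.all(Xhat.data[:, outside, :] == 0)


class TestFilterInactive:
    def test_fully_used_mode_passes(self):
        alpha = np.ones((3, 4, 8))
        assert dynem.filter_inactive({0, 1, 2, 3}, alpha)

    def test_never_used_reaction_fails(self):
        alpha = np.ones((3, 4, 8))
        alpha[1, :, 3] = 0.0  # r4 unused at every time point of experiment 2
        assert not dynem.filter_inactive({0, 1, 2, 3}, alpha)

    def test_tolerance_boundary(self):
        alpha = np.ones((1, 4, 8))
        alpha[0, :, 2] = 1e-11  # below the 1e-10 activity threshold
        assert not dynem.filter_inactive({0, 1, 2}, alpha)
        alpha[0, :, 2] = 1e-9
        assert dynem.filter_inactive({0, 1, 2}, alpha)


class TestSelectDiscriminant:
    def test_separable_case_selects_exactly_one(self, toy_net, toy_ems):
        X, y = planted_set(toy_net, toy_ems)
        res = dynem.select_discriminant(X, y, toy_ems)
        assert res.selected == (0,)
        assert res.discriminates

    def test_permuted_labels_rarely_discriminate(self, toy_net, toy_ems):
        """Permutation null: with labels shuffled, held-out discrimination
        should almost never be perfect."""
        X, y = planted_set(toy_net, toy_ems, n=8)
        rng = np.random.default_rng(2024)
        n_perfect = 0
        for _ in range(20):
            yp = rng.permutation(y)
            fit_idx = list(range(0, 16, 2))
            eval_idx = list(range(1, 16, 2))
            Xf = dynem.ThreeWayFluxArray(X.data[fit_idx])
            Xe = dynem.ThreeWayFluxArray(X.data[eval_idx])
            yf, ye = yp[fit_idx], yp[eval_idx]
            if np.unique(yf).size < 2 or np.unique(ye).size < 2:
                continue
            res = dynem.select_discriminant(Xf, yf, toy_ems, Xe, ye)
            n_perfect += int(res.discriminates)
        assert n_perfect <= 4

    def test_two_independent_signals_need_two_modes(self, toy_ems):
        """Class defined by agreement of two signals living on different
        mode supports: no single mode separates, so the greedy loop
        continues to a second mode (and, the joint problem being an
        exclusive-or, never reaches perfect discrimination)."""
        rng = np.random.default_rng(77)
        K, J = 8, 6
        combos = [(1, 1, 1), (2, 2, 1), (1, 2, 0), (2, 1, 0)]  # (u, v, class)
        slabs, ys = [], []
        for rep in range(8):
            for u, v, cls in combos:
                X = np.zeros((K, J))
                X[0] = X[1] = u + v  # shared chain r1, r2
                X[2] = X[3] = u      # EM1-only branch
                X[4] = X[5] = v      # EM2-only branch
                X *= 1.0 + 0.05 * rng.standard_normal((K, J))
                slabs.append(np.maximum(X, 0))
                ys.append(cls)
        X3 = dynem.ThreeWayFluxArray(np.stack(slabs))
        y = np.array(ys)
        fit_idx, eval_idx = list(range(16)), list(range(16, 32))
        res = dynem.select_discriminant(
            dynem.ThreeWayFluxArray(X3.data[fit_idx]), y[fit_idx], toy_ems,
            dynem.ThreeWayFluxArray(X3.data[eval_idx]), y[eval_idx],
        )
        assert len(res.selected) >= 2
        assert not res.discriminates
        # exhaustive check: no single active mode classifies the held-out half
        for z in range(toy_ems.n_modes):
            _, Xf_hat = fit_em_coefficients(
                dynem.ThreeWayFluxArray(X3.data[fit_idx]), toy_ems, (z,)
            )
            _, Xe_hat = fit_em_coefficients(
                dynem.ThreeWayFluxArray(X3.data[eval_idx]), toy_ems, (z,)
            )
            try:
                model = dynem.fit_npls1(Xf_hat, y[fit_idx], 8)
            except ValueError:
                continue
            assert minimal_components(model, Xe_hat, y[eval_idx]) is None

    def test_nothing_active_returns_empty(self, toy_ems):
        rng = np.random.default_rng(9)
        X = np.zeros((8, 8, 4))
        X[:, 0, :] = rng.uniform(1, 2, (8, 4))  # r1 only: no mode fully active
        y = np.array([0] * 4 + [1] * 4)
        res = dynem.select_discriminant(dynem.ThreeWayFluxArray(X), y, toy_ems)
        assert res.selected == ()
        assert not res.discriminates
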