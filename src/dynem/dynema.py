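"""Dynamic elementary-mode analysis (dynEMA).

A steady-state flux vector decomposes as a positive combination of
elementary modes, ``x = sum_e lambda_e p_e``, with one weight per mode
(the PEMA model).  Away from steady state the same pathways still carry
the flux, but not uniformly: each reaction of a mode gets its own
non-negative coefficient at each time point,

    x_j = sum_e  alpha_{e,j} o p_e          (o = Hadamard product)

so a J x K flux time series ``X`` is modelled as

    X = (I_J (x) 1_E^T) [ A o (1_J (x) P^T) ] + F

with ``A`` the (E*J) x K coefficient matrix (a reaction-wise unfolded
E x J x K array), ``P`` the K x E matrix of selected modes and ``F`` the
residual.  The model is fitted greedily: every candidate mode is trialled
jointly with the already-selected set, and the one explaining most
variance is appended, until a mode count or an explained-variance target
is reached.

Because the model decouples into scalar equations
``X[j,k] = sum_e alpha[e,j,k] P[k,e]``, the non-negative least-squares
solution is exact but non-unique for E >= 2; this module takes the
minimum-L2-norm non-negative solution, which distributes the flux of a
shared reaction proportionally to the modes' stoichiometric weights
(``alpha[e,j,k] = X[j,k] P[k,e] / sum_e' P[k,e']^2``).  It is
deterministic, symmetric in the modes, and reduces to the plain NNLS
ratio ``X[j,k]/P[k,1]`` for a single mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .network import ElementaryModeMatrix, ZERO_TOL


@dataclass(frozen=True)
class FluxTimeSeries:
    """Non-negative fluxes of one experiment at J time points.

    ``fluxes`` is a ``(J, K)`` matrix in flux units (e.g. mMol/l/s);
    ``time_s`` holds the strictly increasing timestamps in seconds.
    """

    fluxes: np.ndarray
    time_s: np.ndarray
    experiment_id: str = ""

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.fluxes, dtype=float))
        t = np.atleast_1d(np.asarray(self.time_s, dtype=float))
        object.__setattr__(self, "fluxes", X)
        object.__setattr__(self, "time_s", t)
        if X.shape[0] != t.shape[0]:
            raise ValueError("one timestamp per flux row required")
        if X.shape[0] < 1:
            raise ValueError("at least one time point required")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(X < -1e-12):
            raise ValueError("fluxes must be non-negative (irreversible convention)")

    @property
    def n_timepoints(self) -> int:
        return self.fluxes.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.fluxes.shape[1]


@dataclass(frozen=True)
class DynEMACoefficients:
    """Non-negative coefficient array ``alpha`` of shape (E, J, K).

    ``alpha[e, j, k]`` scales reaction ``k`` of mode ``e`` at time point
    ``j``; it is zero wherever the mode does not use the reaction.
    """

    alpha: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float)
        if a.ndim != 3:
            raise ValueError("alpha must be a 3-way (E, J, K) array")
        if np.any(a < -1e-12):
            raise ValueError("coefficients must be non-negative")
        object.__setattr__(self, "alpha", a)

    @property
    def unfolded(self) -> np.ndarray:
        """Reaction-wise unfolding to (E*J, K), time-major (modes within time)."""
        E, J, K = self.alpha.shape
        return np.transpose(self.alpha, (1, 0, 2)).reshape(E * J, K)


@dataclass(frozen=True)
class DynEMAModel:
    """Fitted dynEMA decomposition of one flux time series."""

    selected_ems: tuple[int, ...]
    em_matrix: np.ndarray  # K x E, the selected modes (columns)
    coefficients: DynEMACoefficients
    residual: np.ndarray  # J x K
    explained_variance: tuple[float, ...]  # cumulative, one entry per step


def fit_coefficients(
    X: FluxTimeSeries | np.ndarray, P: np.ndarray
) -> tuple[DynEMACoefficients, np.ndarray]:
    """Fit the non-negative per-reaction, per-time coefficients.

    Solves ``X[j,k] = sum_e alpha[e,j,k] P[k,e]`` for ``alpha >= 0`` at
    every (j, k), taking the minimum-norm non-negative solution (see the
    module docstring).  Returns the coefficients and the residual
    ``F = X - Xhat``; the residual is non-zero only on reactions used by
    no selected mode.
    """
    Xm = X.fluxes if isinstance(X, FluxTimeSeries) else np.atleast_2d(np.asarray(X, float))
    P = np.atleast_2d(np.asarray(P, dtype=float))
    if P.ndim != 2:
        raise ValueError("P must be a K x E matrix")
    K, E = P.shape
    if Xm.shape[1] != K:
        raise ValueError(f"X has {Xm.shape[1]} reactions but P has {K}")
    col_norm = np.sum(P * P, axis=0)
    if np.any(col_norm <= ZERO_TOL**2):
        raise ValueError("P contains an all-zero mode column")
    J = Xm.shape[0]
    denom = np.sum(P * P, axis=1)  # per reaction: sum_e P[k,e]^2
    with np.errstate(divide="ignore", invalid="ignore"):
        share = np.where(denom[:, None] > 0, P / np.where(denom[:, None] > 0, denom[:, None], 1.0), 0.0)
    # alpha[e, j, k] = X[j, k] * P[k, e] / denom[k]
    alpha = np.einsum("jk,ke->ejk", Xm, share)
    alpha[alpha < 0] = 0.0
    recon = np.einsum("ejk,ke->jk", alpha, P)
    F = Xm - recon
    return DynEMACoefficients(alpha), F


def reconstruct(model: DynEMAModel) -> np.ndarray:
    """Reconstruction ``(I_J (x) 1_E^T)[A o (1_J (x) P^T)]`` as a J x K matrix."""
    return np.einsum("ejk,ke->jk", model.coefficients.alpha, model.em_matrix)


def explained_variance(X: np.ndarray, Xhat: np.ndarray) -> float:
    """Uncentered explained-variance fraction ``1 - ||X-Xhat||_F^2 / ||X||_F^2``.

    An all-zero ``X`` is perfectly explained by an all-zero ``Xhat``
    (returns 1.0) and inexplicable by anything else (raises).
    """
    X = np.asarray(X, dtype=float)
    Xhat = np.asarray(Xhat, dtype=float)
    if X.shape != Xhat.shape:
        raise ValueError("shape mismatch")
    total = float(np.sum(X * X))
    if total == 0.0:
        if np.allclose(Xhat, 0.0):
            return 1.0
        raise ValueError("explained variance undefined: X is zero but Xhat is not")
    return min(1.0, 1.0 - float(np.sum((X - Xhat) ** 2)) / total)


def fit_dynema(
    X: FluxTimeSeries,
    ems: ElementaryModeMatrix,
    n_modes: int | None = None,
    variance_target: float | None = None,
) -> DynEMAModel:
    """Greedy forward selection of dynamic elementary modes.

    At each step every unselected candidate is trialled jointly with the
    already-selected set (coefficients refitted for all modes), and the
    candidate maximising explained variance is appended.  Selection stops
    at ``n_modes`` modes or once ``variance_target`` (default 0.95 when
    neither is given) is reached.  Ties within 1e-12 go to the lower
    column index.
    """
    if ems.n_modes == 0:
        raise ValueError("empty elementary-mode matrix")
    if n_modes is None and variance_target is None:
        variance_target = 0.95
    if n_modes is not None and not (1 <= n_modes <= ems.n_modes):
        raise ValueError(f"n_modes must be in [1, {ems.n_modes}]")
    if variance_target is not None and not (0.0 < variance_target <= 1.0):
        raise ValueError("variance target must be in (0, 1]")

    Xm = X.fluxes
    selected: list[int] = []
    ev_path: list[float] = []
    max_steps = n_modes if n_modes is not None else ems.n_modes
    while len(selected) < max_steps:
        best_idx, best_ev = None, -np.inf
        for z in range(ems.n_modes):
            if z in selected:
                continue
            P_try = ems.modes[:, selected + [z]]
            _, F = fit_coefficients(Xm, P_try)
            ev = explained_variance(Xm, Xm - F)
            if ev > best_ev + 1e-12:
                best_idx, best_ev = z, ev
        if best_idx is None:
            break
        selected.append(best_idx)
        ev_path.append(best_ev)
        if variance_target is not None and best_ev >= variance_target:
            break

    P_sel = ems.modes[:, selected]
    coeffs, F = fit_coefficients(Xm, P_sel)
    return DynEMAModel(
        selected_ems=tuple(selected),
        em_matrix=P_sel,
        coefficients=coeffs,
        residual=F,
        explained_variance=tuple(ev_path),
    )


def fit_pema(X: np.ndarray, P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state baseline: one non-negative weight per mode and row.

    Fits ``X = Lambda P^T + F`` with ``Lambda >= 0`` by row-wise NNLS
    (rows are experiments, or time points when a single experiment's
    series is fitted).  Returns ``(Lambda, F)``.  This is the model the
    per-reaction dynEMA coefficients collapse to when
    ``alpha[e, j, k] = lambda_e`` for all (j, k).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    P = np.atleast_2d(np.asarray(P, dtype=float))
    N = X.shape[0]
    E = P.shape[1]
    Lam = np.zeros((N, E))
    for i in range(N):
        Lam[i], _ = nnls(P, X[i])
    F = X - Lam @ P.T
    return Lam, F
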