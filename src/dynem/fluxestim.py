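"""Flux estimation from concentration time series.

Fluxes are not measured directly; they are inferred from the change of
metabolite concentrations between consecutive sampling points.  With
``C`` the (T, M) concentration matrix and ``S`` the (M, K)
stoichiometric matrix, the (J, K) flux matrix ``X`` (J = T - 1) solves
the quadratic program

    min_X   sum_{j<J} sum_k (x_{j+1,k} - x_{j,k})^2  +  sum_j sum_k x_{j,k}^2
    s.t.    S X^T = dC^T/dt,      X >= 0

i.e. fluxes are kept smooth along time and small, subject to the
stoichiometric mass balances.  Derivatives are forward differences of
consecutive concentration rows divided by the actual time step (with a
uniform grid this differs from an index-based derivative only by a
constant factor absorbed into the flux units).  Both objective terms
carry unit weight.

The solver is fully deterministic: the equality constraints are
eliminated through an SVD nullspace parametrisation (LSE), the
remaining bound-constrained least-squares problem (LSI) is reduced to a
least-distance program (LDP), and the LDP is solved by the classical
Lawson--Hanson reduction to non-negative least squares.  When the
equality system is infeasible under the sign constraints — as noisy
data can make it — the solver falls back to a penalty formulation
(weight 1e6 on the squared mass-balance residual) and logs the
constraint violation.

The initial guess of the original formulation, the time-point-wise
non-negative least-squares solution of ``S x = dC/dt``, is exposed as
:func:`initial_guess`; the direct solver does not need a starting point
but the guess doubles as the feasibility probe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .dynema import FluxTimeSeries
from .network import MetabolicNetwork

logger = logging.getLogger(__name__)

#: mass-balance feasibility tolerance (flux units)
FEAS_TOL = 1e-6

#: penalty weight on the squared mass-balance residual in the fallback
PENALTY_WEIGHT = 1e6


class InfeasibleConstraintsError(RuntimeError):
    """Raised when the mass balances admit no non-negative flux at all
    and the penalty fallback is disabled."""

    def __init__(self, msg: str, per_timepoint_residual: np.ndarray):
        super().__init__(msg)
        self.per_timepoint_residual = per_timepoint_residual


@dataclass(frozen=True)
class ConcentrationTimeSeries:
    """Metabolite concentrations (mMol/l) of one experiment.

    ``conc`` is (T, M) with T >= 2 strictly increasing timestamps.
    """

    conc: np.ndarray
    time_s: np.ndarray
    experiment_id: str = ""

    def __post_init__(self) -> None:
        C = np.atleast_2d(np.asarray(self.conc, dtype=float))
        t = np.atleast_1d(np.asarray(self.time_s, dtype=float))
        object.__setattr__(self, "conc", C)
        object.__setattr__(self, "time_s", t)
        if C.shape[0] != t.shape[0]:
            raise ValueError("one timestamp per concentration row required")
        if C.shape[0] < 2:
            raise ValueError("at least two time points required to form derivatives")
        if not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(C < -1e-12):
            raise ValueError("concentrations must be non-negative")

    @property
    def n_timepoints(self) -> int:
        return self.conc.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.conc.shape[1]


def concentration_derivatives(C: ConcentrationTimeSeries) -> np.ndarray:
    """Forward-difference derivatives, (J, M) with J = T - 1."""
    dt = np.diff(C.time_s)[:, None]
    return np.diff(C.conc, axis=0) / dt


def initial_guess(C: ConcentrationTimeSeries, net: MetabolicNetwork) -> FluxTimeSeries:
    """Time-point-wise NNLS solution of ``S x = dC/dt``.

    Solves each time point independently; always returns (NNLS residuals
    are simply carried when the balances are not exactly satisfiable).
    """
    S = net.stoich
    if C.n_metabolites != S.shape[0]:
        raise ValueError(
            f"concentration columns ({C.n_metabolites}) do not match metabolites ({S.shape[0]})"
        )
    D = concentration_derivatives(C)
    J, K = D.shape[0], S.shape[1]
    X0 = np.zeros((J, K))
    for j in range(J):
        X0[j], _ = nnls(S, D[j], maxiter=max(30 * K, 300))
    return FluxTimeSeries(np.maximum(X0, 0.0), C.time_s[:-1], C.experiment_id)


# ---------------------------------------------------------------------------
# Lawson--Hanson reductions
# ---------------------------------------------------------------------------

def _ldp(G: np.ndarray, h: np.ndarray) -> np.ndarray | None:
    """Least-distance program: min ||w||  s.t.  G w >= h.

    Lawson--Hanson reduction to NNLS.  Returns None when infeasible.
    """
    m, n = G.shape
    E = np.vstack([G.T, h[None, :]])  # (n + 1, m)
    f = np.zeros(n + 1)
    f[-1] = 1.0
    u, _ = nnls(E, f, maxiter=max(30 * m, 300))
    r = E @ u - f
    if np.linalg.norm(r) < 1e-12:
        return None
    return -r[:n] / r[n]


def _lsi(E: np.ndarray, f: np.ndarray, G: np.ndarray, h: np.ndarray) -> np.ndarray | None:
    """Inequality-constrained least squares: min ||E z - f||  s.t.  G z >= h.

    E must have full column rank.  Returns None when infeasible.
    """
    U, s, Vt = np.linalg.svd(E, full_matrices=False)
    if s[-1] < 1e-12 * s[0]:
        raise np.linalg.LinAlgError("LSI design matrix is rank deficient")
    K1 = Vt.T / s[None, :]  # V Sigma^{-1}
    u1f = U.T @ f
    Gt = G @ K1
    ht = h - Gt @ u1f
    q = _ldp(Gt, ht)
    if q is None:
        return None
    return K1 @ (q + u1f)


def _objective_matrix(J: int, K: int) -> np.ndarray:
    """Stacked smoothness + magnitude operator on vec(X) (time-major)."""
    n = J * K
    rows = []
    L_smooth = np.zeros(((J - 1) * K, n))
    for j in range(J - 1):
        for k in range(K):
            r = j * K + k
            L_smooth[r, (j + 1) * K + k] = 1.0
            L_smooth[r, j * K + k] = -1.0
    rows.append(L_smooth)
    rows.append(np.eye(n))
    return np.vstack(rows)


def objective_value(X: np.ndarray) -> float:
    """Smoothness-plus-magnitude objective of a (J, K) flux matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return float(np.sum(np.diff(X, axis=0) ** 2) + np.sum(X**2))


def estimate_fluxes(
    C: ConcentrationTimeSeries,
    net: MetabolicNetwork,
    allow_penalty_fallback: bool = True,
) -> FluxTimeSeries:
    """Solve the smooth-and-small flux QP for one experiment.

    Returns a (T - 1)-point flux series satisfying the mass balances to
    :data:`FEAS_TOL` (hard-constrained path) or, when the balances are
    infeasible under ``X >= 0`` and the fallback is allowed, minimising
    the penalised residual instead (logged).
    """
    S = net.stoich
    M, K = S.shape
    if C.n_metabolites != M:
        raise ValueError(
            f"concentration columns ({C.n_metabolites}) do not match metabolites ({M})"
        )
    D = concentration_derivatives(C)  # (J, M)
    J = D.shape[0]
    n = J * K
    b = D.ravel()  # time-major

    # feasibility probe: per-time-point NNLS residuals
    X0 = initial_guess(C, net)
    probe = S @ X0.fluxes.T - D.T
    per_tp = np.linalg.norm(probe, axis=0)
    feasible = bool(np.max(per_tp) <= FEAS_TOL * max(1.0, float(np.max(np.abs(D)))))

    L = _objective_matrix(J, K)
    A_eq = np.kron(np.eye(J), S)  # (J*M, n), acts on time-major vec(X)

    x: np.ndarray | None = None
    if feasible:
        # eliminate the equalities: x = x_p + N z with A_eq N = 0
        U, s, Vt = np.linalg.svd(A_eq)
        rank = int(np.sum(s > 1e-10 * s[0])) if s.size else 0
        x_p, *_ = np.linalg.lstsq(A_eq, b, rcond=None)
        if rank == n:
            x = x_p
            if np.min(x) < -FEAS_TOL:
                feasible = False
                x = None
            else:
                x = np.maximum(x, 0.0)
        else:
            N = Vt[rank:].T  # (n, n - rank), orthonormal nullspace basis
            z = _lsi(L @ N, -L @ x_p, N, -x_p)
            if z is None:
                feasible = False
            else:
                x = np.maximum(x_p + N @ z, 0.0)

    if x is None:
        if not allow_penalty_fallback:
            raise InfeasibleConstraintsError(
                "mass balances infeasible under non-negativity", per_tp
            )
        logger.warning(
            "mass balances infeasible under X >= 0 (max per-time-point residual "
            "%.3g); solving the penalty formulation instead",
            float(np.max(per_tp)),
        )
        w = np.sqrt(PENALTY_WEIGHT)
        A_stack = np.vstack([L, w * A_eq])
        b_stack = np.concatenate([np.zeros(L.shape[0]), w * b])
        x, _ = nnls(A_stack, b_stack, maxiter=max(30 * n, 1000))

    X = x.reshape(J, K)
    return FluxTimeSeries(X, C.time_s[:-1], C.experiment_id)


def kkt_residual(X: np.ndarray, C: ConcentrationTimeSeries, net: MetabolicNetwork) -> float:
    """First-order optimality residual of a candidate QP solution.

    Checks stationarity ``g = A_eq' nu + mu`` with ``mu >= 0`` and
    ``mu_i x_i = 0`` (complementarity), plus primal feasibility.  The
    returned scalar is the max of: the stationarity residual on free
    coordinates, the negative part of the bound multipliers on active
    coordinates, the mass-balance residual, and the bound violation.
    """
    S = net.stoich
    D = concentration_derivatives(C)
    J, K = D.shape[0], S.shape[1]
    X = np.asarray(X, dtype=float).reshape(J, K)
    x = X.ravel()
    L = _objective_matrix(J, K)
    A_eq = np.kron(np.eye(J), S)
    b = D.ravel()

    g = 2.0 * (L.T @ (L @ x))
    scale = max(1.0, float(np.max(np.abs(g))))
    active = x <= 1e-9
    free = ~active
    # multipliers nu from the free-coordinate stationarity equations
    A_free = A_eq[:, free].T  # rows: free coords
    nu, *_ = np.linalg.lstsq(A_free, g[free], rcond=None)
    stat_free = float(np.max(np.abs(A_free @ nu - g[free]))) if np.any(free) else 0.0
    mu = g - A_eq.T @ nu
    mult_neg = float(max(0.0, -np.min(mu[active]))) if np.any(active) else 0.0
    feas = float(np.max(np.abs(A_eq @ x - b))) / max(1.0, float(np.max(np.abs(b))))
    bound = float(max(0.0, -np.min(x)))
    return max(stat_free / scale, mult_neg / scale, feas, bound)
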