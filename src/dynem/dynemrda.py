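"""Dynamic elementary-mode regression discriminant analysis (dynEMR-DA).

Given a two-class set of flux time series, the procedure asks which
elementary modes are used differently between the classes.  For each
candidate mode the experiment set is unfolded reaction-wise, dynEMA
coefficients against that single mode are fitted (an exact non-negative
least-squares step that masks the data to the mode's support), the data
are reconstructed and refolded, and a trilinear PLS discriminant model
is fitted between the reconstruction and the class vector.  Candidates
are ranked by how much class variance their reconstruction explains;
modes with an unused reaction (a support reaction whose coefficient is
zero at every time point of some experiment) do not represent a pathway
that actually carried flux and are filtered out before ranking.

Selection is greedy: the best-ranked candidate is adopted and, if it
does not already discriminate the evaluation split perfectly, the
screen is repeated jointly with the adopted modes, mirroring the
coefficient recalculation rule of dynEMA.  In practice a single mode
usually suffices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dynema import fit_coefficients
from .network import ElementaryModeMatrix
from .npls import NPLSModel, ThreeWayFluxArray, fit_npls1, predict

logger = logging.getLogger(__name__)

#: coefficients below this are treated as "reaction not used"
INACTIVE_TOL = 1e-10


@dataclass(frozen=True)
class EMScreenRecord:
    """Screening outcome for one candidate elementary mode."""

    em_index: int
    em_id: str
    y_variance: float
    n_components: int
    active: bool
    error: str | None = None


@dataclass(frozen=True)
class DynEMRDAResult:
    """Ranked screening records plus the selected discriminant modes."""

    records: tuple[EMScreenRecord, ...]
    ranking: tuple[int, ...]  # em indices, active ones first, by y-variance
    selected: tuple[int, ...] = ()
    discriminates: bool = False

    def record_for(self, em_index: int) -> EMScreenRecord:
        for r in self.records:
            if r.em_index == em_index:
                return r
        raise KeyError(em_index)


def fit_em_coefficients(
    X: ThreeWayFluxArray, ems: ElementaryModeMatrix, em_indices: tuple[int, ...] | list[int]
) -> tuple[np.ndarray, ThreeWayFluxArray]:
    """Fit dynEMA coefficients of every experiment against a mode subset.

    Unfolds the (N, K, J) array reaction-wise, solves the per-(j, k)
    non-negative least-squares problem for the selected modes jointly,
    and refolds.  Returns ``(alpha, Xhat)`` with ``alpha`` of shape
    (E, N, J, K) and ``Xhat`` the reconstructed three-way array (zero
    outside the union of the modes' supports).
    """
    idx = list(em_indices)
    if not idx:
        raise ValueError("at least one mode index required")
    P = ems.modes[:, idx]
    N, K, J = X.data.shape
    unfolded = X.unfold_reactionwise()  # (J*N, K), experiments stacked
    coeffs, F = fit_coefficients(unfolded, P)
    E = len(idx)
    alpha = coeffs.alpha.reshape(E, N, J, K)
    recon = (unfolded - F).reshape(N, J, K).transpose(0, 2, 1)
    return alpha, ThreeWayFluxArray(recon, X.experiment_ids)


def filter_inactive(
    em_support: frozenset[int] | set[int], alpha: np.ndarray, tol: float = INACTIVE_TOL
) -> bool:
    """Activity check for one candidate mode.

    ``alpha`` has shape (N, J, K) (the candidate's coefficient slab per
    experiment).  The mode *fails* — returns ``False`` — iff some
    support reaction carries a coefficient below ``tol`` at every time
    point of at least one experiment: the flux then never traverses the
    whole pathway and the mode is not a real metabolic route.
    """
    a = np.asarray(alpha, dtype=float)
    if a.ndim == 2:  # single experiment (J, K)
        a = a[None, :, :]
    for k in sorted(em_support):
        per_exp_max = np.max(a[:, :, k], axis=1)  # max over time, per experiment
        if np.any(per_exp_max <= tol):
            return False
    return True


def screen_dynems(
    X: ThreeWayFluxArray,
    y: np.ndarray,
    ems: ElementaryModeMatrix,
    n_components: int | None = None,
    base_ems: tuple[int, ...] = (),
) -> DynEMRDAResult:
    """Screen every candidate mode for class-discriminating usage.

    Each candidate (outside ``base_ems``) is fitted jointly with the
    already-selected base set, the reconstruction is refolded, and an
    NPLS-DA model with ``n_components`` components (default: the maximum
    permitted, capped at K) is fitted against ``y``.  Records carry the
    explained class variance, the activity flag, and any per-candidate
    failure (recorded, not raised).  Ranking lists active candidates
    first, ordered by explained class variance.
    """
    y = np.asarray(y, dtype=float).ravel()
    N, K, J = X.data.shape
    if y.shape[0] != N:
        raise ValueError("one class label per experiment required")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    a_cap = min(N - 1, K)
    A = a_cap if n_components is None else min(n_components, a_cap)

    records: list[EMScreenRecord] = []
    for z in range(ems.n_modes):
        if z in base_ems:
            continue
        try:
            alpha, Xhat = fit_em_coefficients(X, ems, tuple(base_ems) + (z,))
            active = filter_inactive(ems.support(z), alpha[-1])
            model = fit_npls1(Xhat, y, A)
            r2y = model.r2y[-1]
            records.append(EMScreenRecord(z, ems.em_ids[z], float(r2y), model.n_components, active))
        except (ValueError, np.linalg.LinAlgError) as exc:  # recorded, not fatal
            logger.warning("candidate %s failed screening: %s", ems.em_ids[z], exc)
            records.append(EMScreenRecord(z, ems.em_ids[z], float("-inf"), 0, False, str(exc)))

    ranking = sorted(
        (r for r in records if r.error is None),
        key=lambda r: (not r.active, -r.y_variance, r.em_index),
    )
    return DynEMRDAResult(tuple(records), tuple(r.em_index for r in ranking))


def _perfect(model: NPLSModel, Xev: ThreeWayFluxArray, yev: np.ndarray, A: int) -> bool:
    _, labels = predict(model, Xev, A)
    return bool(np.array_equal(labels, np.asarray(yev, dtype=int)))


def minimal_components(
    model: NPLSModel, Xev: ThreeWayFluxArray, yev: np.ndarray
) -> int | None:
    """Smallest component count classifying the evaluation split perfectly."""
    for a in range(1, model.n_components + 1):
        if _perfect(model, Xev, yev, a):
            return a
    return None


def select_discriminant(
    X: ThreeWayFluxArray,
    y: np.ndarray,
    ems: ElementaryModeMatrix,
    X_eval: ThreeWayFluxArray | None = None,
    y_eval: np.ndarray | None = None,
    n_components: int | None = None,
    max_modes: int | None = None,
) -> DynEMRDAResult:
    """Greedy selection of discriminant dynamic elementary modes.

    Repeats the screen, each round adopting the best-ranked *active*
    candidate jointly with those already adopted, until the joint model
    classifies the evaluation split perfectly (``X_eval``/``y_eval``,
    defaulting to the fitting data) or candidates are exhausted.  The
    component count used for the perfection test is the smallest one
    that classifies the evaluation split, per candidate.

    Returns the last screening result augmented with the adopted modes
    and whether perfect discrimination was reached; ``selected`` is
    empty when no active candidate exists at the first round.
    """
    if X_eval is None:
        X_eval, y_eval = X, y
    y_eval = np.asarray(y_eval, dtype=int).ravel()
    cap = ems.n_modes if max_modes is None else max_modes

    selected: list[int] = []
    last: DynEMRDAResult | None = None
    perfect = False
    while len(selected) < cap:
        res = screen_dynems(X, y, ems, n_components, tuple(selected))
        last = res
        best = next((i for i in res.ranking if res.record_for(i).active), None)
        if best is None:
            logger.warning("no active candidate mode discriminates; stopping")
            break
        selected.append(best)
        _, Xhat = fit_em_coefficients(X, ems, tuple(selected))
        _, Xhat_eval = fit_em_coefficients(X_eval, ems, tuple(selected))
        N, K, _ = X.data.shape
        a_cap = min(N - 1, K) if n_components is None else min(n_components, min(N - 1, K))
        model = fit_npls1(Xhat, y, a_cap)
        if minimal_components(model, Xhat_eval, y_eval) is not None:
            perfect = True
            break
    if last is None:
        last = screen_dynems(X, y, ems, n_components)
    if not perfect and not selected:
        return DynEMRDAResult(last.records, last.ranking, (), False)
    return DynEMRDAResult(last.records, last.ranking, tuple(selected), perfect)
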