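"""Trilinear partial least squares with a single response (tri-PLS1).

The discriminant engine behind dynEMR-DA.  A three-way flux array
(experiments x reactions x time points) is regressed on a response
vector; with a 0/1 class coding this is NPLS-DA.  Per component the
algorithm finds a unit reaction-weight ``w_k`` and unit time-weight
``w_j`` maximising the covariance between the projected array and the
current response residual — obtained in closed form as the leading
singular pair of the K x J matrix ``Z = sum_n y_n X_n`` — then scores
``t_n = w_k' X_n w_j``, regresses the response jointly on all scores,
and deflates both array and response.

Centering follows the usual N-way convention: the array is centered
across experiments (mode A) and the response is mean-centered; no
scaling is applied.  Weight signs are fixed so the largest-magnitude
reaction weight is positive, making the decomposition deterministic.
With a single time slab (J = 1) the model degenerates to two-way PLS1
and its predictions coincide with the classical NIPALS algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ThreeWayFluxArray:
    """N experiments x K reactions x J time points, no missing values.

    All experiments must share the same time grid and reaction set.
    """

    data: np.ndarray
    experiment_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        X = np.asarray(self.data, dtype=float)
        if X.ndim != 3:
            raise ValueError("expected a 3-way (N, K, J) array")
        if not np.all(np.isfinite(X)):
            raise ValueError("missing or non-finite values are not supported")
        ids = tuple(self.experiment_ids) or tuple(f"exp{i + 1}" for i in range(X.shape[0]))
        if len(ids) != X.shape[0]:
            raise ValueError("one experiment id per slab required")
        object.__setattr__(self, "data", X)
        object.__setattr__(self, "experiment_ids", ids)

    @property
    def n_experiments(self) -> int:
        return self.data.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.data.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[2]

    def unfold_reactionwise(self) -> np.ndarray:
        """Stack experiments' (J, K) slabs into a (J*N, K) matrix."""
        return np.transpose(self.data, (0, 2, 1)).reshape(-1, self.data.shape[1])


@dataclass(frozen=True)
class NPLSModel:
    """Fitted tri-PLS1 model.

    ``w_reaction`` (K x A) and ``w_time`` (J x A) hold the unit-norm
    weight vectors, ``scores`` the N x A training scores, ``coef`` the
    joint regression of the centered response on the scores, and the
    ``r2y``/``r2x`` tuples the cumulative explained-variance fractions.
    """

    n_components: int
    w_reaction: np.ndarray
    w_time: np.ndarray
    scores: np.ndarray
    coef: np.ndarray
    x_mean: np.ndarray  # K x J centering offsets
    y_mean: float
    y_centered: np.ndarray  # centered training response (for truncated refits)
    r2y: tuple[float, ...]
    r2x: tuple[float, ...]
    threshold: float = 0.5


def fit_npls1(
    X: ThreeWayFluxArray | np.ndarray,
    y: np.ndarray,
    n_components: int,
    threshold: float = 0.5,
) -> NPLSModel:
    """Fit a tri-PLS1 model of ``y`` on the three-way array ``X``.

    ``y`` is typically a 0/1 class vector (NPLS-DA) but any real
    response is accepted; for a binary response both classes must be
    present.  ``n_components`` must not exceed ``min(N - 1, K * J)``.
    Extraction stops early if the covariance matrix vanishes (response
    fully explained); the model then carries fewer components.
    """
    Xd = X.data if isinstance(X, ThreeWayFluxArray) else np.asarray(X, dtype=float)
    if Xd.ndim != 3:
        raise ValueError("expected a 3-way (N, K, J) array")
    y = np.asarray(y, dtype=float).ravel()
    N, K, J = Xd.shape
    if y.shape[0] != N:
        raise ValueError("one response value per experiment required")
    if N < 2:
        raise ValueError("at least two experiments required")
    uniq = np.unique(y)
    if set(uniq.tolist()) <= {0.0, 1.0} and uniq.size < 2:
        raise ValueError("single-class response: discrimination undefined")
    a_max = min(N - 1, K * J)
    if not (1 <= n_components <= a_max):
        raise ValueError(f"n_components must be in [1, {a_max}]")

    x_mean = Xd.mean(axis=0)  # K x J
    Ex = Xd - x_mean[None, :, :]
    y_mean = float(y.mean())
    yc = y - y_mean
    ssy = float(np.sum(yc * yc))
    ssx = float(np.sum(Ex * Ex))
    ey = yc.copy()

    Wk = np.zeros((K, n_components))
    Wj = np.zeros((J, n_components))
    T = np.zeros((N, n_components))
    r2y: list[float] = []
    r2x: list[float] = []
    n_used = 0
    for a in range(n_components):
        Z = np.einsum("n,nkj->kj", ey, Ex)
        if np.linalg.norm(Z) < 1e-14:
            break
        U, _, Vt = np.linalg.svd(Z, full_matrices=False)
        wk, wj = U[:, 0], Vt[0, :]
        if wk[int(np.argmax(np.abs(wk)))] < 0:
            wk, wj = -wk, -wj
        t = np.einsum("nkj,k,j->n", Ex, wk, wj)
        Wk[:, a], Wj[:, a], T[:, a] = wk, wj, t
        n_used = a + 1
        coef, *_ = np.linalg.lstsq(T[:, :n_used], yc, rcond=None)
        ey = yc - T[:, :n_used] @ coef
        Ex = Ex - np.einsum("n,k,j->nkj", t, wk, wj)
        r2y.append(1.0 - float(np.sum(ey * ey)) / ssy if ssy > 0 else 1.0)
        r2x.append(1.0 - float(np.sum(Ex * Ex)) / ssx if ssx > 0 else 1.0)

    if n_used == 0:
        raise ValueError("response has no covariance with the array")
    coef, *_ = np.linalg.lstsq(T[:, :n_used], yc, rcond=None)
    return NPLSModel(
        n_components=n_used,
        w_reaction=Wk[:, :n_used],
        w_time=Wj[:, :n_used],
        scores=T[:, :n_used],
        coef=coef,
        x_mean=x_mean,
        y_mean=y_mean,
        y_centered=yc,
        r2y=tuple(r2y),
        r2x=tuple(r2x),
        threshold=threshold,
    )


def transform(
    model: NPLSModel, X: ThreeWayFluxArray | np.ndarray, n_components: int | None = None
) -> np.ndarray:
    """Scores of new experiments under the fitted sequential deflation."""
    Xd = X.data if isinstance(X, ThreeWayFluxArray) else np.asarray(X, dtype=float)
    if Xd.ndim != 3:
        raise ValueError("expected a 3-way (N, K, J) array")
    A = model.n_components if n_components is None else n_components
    if not (1 <= A <= model.n_components):
        raise ValueError(f"n_components must be in [1, {model.n_components}]")
    if Xd.shape[1:] != model.x_mean.shape:
        raise ValueError(
            f"array shape {Xd.shape[1:]} does not match the fitted (K, J) {model.x_mean.shape}"
        )
    E = Xd - model.x_mean[None, :, :]
    T = np.zeros((Xd.shape[0], A))
    for a in range(A):
        wk, wj = model.w_reaction[:, a], model.w_time[:, a]
        t = np.einsum("nkj,k,j->n", E, wk, wj)
        T[:, a] = t
        E = E - np.einsum("n,k,j->nkj", t, wk, wj)
    return T


def predict(
    model: NPLSModel, X: ThreeWayFluxArray | np.ndarray, n_components: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous responses and hard class labels for new experiments.

    With a truncated ``n_components`` the response regression is refitted
    on the leading training scores, so prediction at A components equals
    a model originally fitted with A components.  Labels are 1 where the
    continuous prediction exceeds the threshold (default 0.5 for 0/1
    class coding), else 0.
    """
    A = model.n_components if n_components is None else n_components
    T = transform(model, X, A)
    if A == model.n_components:
        coef = model.coef
    else:
        # refit on the truncated training scores; the leading training
        # scores are identical to a model fitted with A components
        coef, *_ = np.linalg.lstsq(model.scores[:, :A], model.y_centered, rcond=None)
    yhat = model.y_mean + T @ coef
    labels = (yhat > model.threshold).astype(int)
    return yhat, labels
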