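"""Cross-validation protocols for dynEMR-DA.

Discriminant models on few experiments with many flux-by-time features
can separate classes by chance, so mode selection must be validated on
data that never influenced fitting, component choice, or ranking.  The
triple cross-validation (3CV) scheme divides the experiments into four
stratified groups — calibration, test, selection, validation — and
rotates the first three through the roles fit / choose-components /
score (calibration-test-selection, test-selection-calibration,
selection-calibration-test).  A candidate mode advances only if it
classifies the selection group perfectly in all three rotations; the
advancing modes are then scored once on the untouched validation group
by substituting it for the selection group in the three fitted models.

For small experiment sets where four stratified groups are impossible
(fewer than four experiments per class), a single-CV fallback leaves
out one experiment per class per fold, fitting and choosing components
on the remainder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dynemrda import fit_em_coefficients, filter_inactive, minimal_components
from .network import ElementaryModeMatrix
from .npls import ThreeWayFluxArray, fit_npls1, predict

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVPlan:
    """Four disjoint stratified experiment groups plus the role rotation."""

    calibration: tuple[int, ...]
    test: tuple[int, ...]
    selection: tuple[int, ...]
    validation: tuple[int, ...]
    seed: int

    def __post_init__(self) -> None:
        groups = [self.calibration, self.test, self.selection, self.validation]
        flat = [i for g in groups for i in g]
        if len(flat) != len(set(flat)):
            raise ValueError("cross-validation groups must be disjoint")

    @property
    def rotations(self) -> tuple[tuple[tuple[int, ...], tuple[int, ...], tuple[int, ...]], ...]:
        """(fit, tune, score) index triples for the three role rotations."""
        c, t, s = self.calibration, self.test, self.selection
        return ((c, t, s), (t, s, c), (s, c, t))


@dataclass(frozen=True)
class EMValidationRecord:
    """Validated verdict for one candidate elementary mode."""

    em_index: int
    em_id: str
    active: bool
    components_per_rotation: tuple[int | None, ...]
    selection_perfect: tuple[bool, ...]
    advanced: bool
    validation_accuracy: float | None  # mean over rotations; None if not advanced
    validation_all_correct: bool


def make_3cv_plan(
    y: np.ndarray, fractions: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
) -> CVPlan:
    """Stratified random split into calibration/test/selection/validation.

    Each class is shuffled with the seeded generator and divided
    according to ``fractions`` (default four quarters).  Every group
    must receive at least one experiment of each class, which requires
    at least four experiments per class.
    """
    y = np.asarray(y, dtype=int).ravel()
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    groups: list[list[int]] = [[], [], [], []]
    for cls in np.unique(y):
        idx = np.where(y == cls)[0]
        if idx.size < 4:
            raise ValueError(
                f"class {cls} has only {idx.size} experiments; four stratified "
                "groups need >= 4 per class — use run_single_cv instead"
            )
        idx = idx[rng.permutation(idx.size)]
        bounds = np.cumsum([round(f * idx.size) for f in fractions[:3]])
        parts = np.split(idx, bounds)
        # guarantee non-empty parts even under adverse rounding
        for g in range(4):
            if parts[g].size == 0:
                donor = int(np.argmax([p.size for p in parts]))
                parts[g] = parts[donor][-1:]
                parts[donor] = parts[donor][:-1]
        for g in range(4):
            groups[g].extend(int(i) for i in parts[g])
    return CVPlan(*(tuple(sorted(g)) for g in groups), seed=seed)


def _take(X: ThreeWayFluxArray, idx: tuple[int, ...]) -> ThreeWayFluxArray:
    return ThreeWayFluxArray(X.data[list(idx)], tuple(X.experiment_ids[i] for i in idx))


def run_3cv(
    X: ThreeWayFluxArray,
    y: np.ndarray,
    ems: ElementaryModeMatrix,
    plan: CVPlan,
    max_components: int | None = None,
) -> tuple[EMValidationRecord, ...]:
    """Run the full 3CV protocol; one validated record per candidate mode.

    Per rotation and candidate: dynEMA coefficients and the NPLS-DA
    model are fitted on the fit group (candidates failing the
    inactive-reaction filter there are dropped); the smallest component
    count classifying the tune group perfectly is chosen; the score
    group is then classified at that count.  Candidates perfect on the
    score group in all three rotations advance and are finally scored
    on the validation group using the three already-fitted models —
    validation experiments never touch fitting, component choice or
    ranking.
    """
    y = np.asarray(y, dtype=int).ravel()
    Xv = _take(X, plan.validation)
    yv = y[list(plan.validation)]
    K = X.n_reactions

    records: list[EMValidationRecord] = []
    for z in range(ems.n_modes):
        comps: list[int | None] = []
        sel_perfect: list[bool] = []
        active_all = True
        rotation_models = []  # (model, A) per rotation, for validation scoring
        for fit_idx, tune_idx, score_idx in plan.rotations:
            Xf, yf = _take(X, fit_idx), y[list(fit_idx)]
            alpha, Xf_hat = fit_em_coefficients(Xf, ems, (z,))
            if not filter_inactive(ems.support(z), alpha[0]):
                active_all = False
                comps.append(None)
                sel_perfect.append(False)
                rotation_models.append(None)
                continue
            a_cap = min(len(fit_idx) - 1, K)
            if max_components is not None:
                a_cap = min(a_cap, max_components)
            try:
                model = fit_npls1(Xf_hat, yf, a_cap)
            except ValueError as exc:
                logger.warning("mode %s rotation fit failed: %s", ems.em_ids[z], exc)
                comps.append(None)
                sel_perfect.append(False)
                rotation_models.append(None)
                continue
            _, Xt_hat = fit_em_coefficients(_take(X, tune_idx), ems, (z,))
            A = minimal_components(model, Xt_hat, y[list(tune_idx)])
            comps.append(A)
            if A is None:
                sel_perfect.append(False)
                rotation_models.append(None)
                continue
            _, Xs_hat = fit_em_coefficients(_take(X, score_idx), ems, (z,))
            _, labels = predict(model, Xs_hat, A)
            sel_perfect.append(bool(np.array_equal(labels, y[list(score_idx)])))
            rotation_models.append((model, A))

        advanced = active_all and all(sel_perfect)
        val_acc: float | None = None
        val_all = False
        if advanced:
            _, Xv_hat = fit_em_coefficients(Xv, ems, (z,))
            correct = 0
            total = 0
            for entry in rotation_models:
                model, A = entry
                _, labels = predict(model, Xv_hat, A)
                correct += int(np.sum(labels == yv))
                total += yv.size
            val_acc = correct / total
            val_all = correct == total
        records.append(
            EMValidationRecord(
                em_index=z,
                em_id=ems.em_ids[z],
                active=active_all,
                components_per_rotation=tuple(comps),
                selection_perfect=tuple(sel_perfect),
                advanced=advanced,
                validation_accuracy=val_acc,
                validation_all_correct=val_all,
            )
        )
    return tuple(records)


def run_single_cv(
    X: ThreeWayFluxArray,
    y: np.ndarray,
    ems: ElementaryModeMatrix,
    max_components: int | None = None,
) -> tuple[EMValidationRecord, ...]:
    """Leave-one-pair-out fallback for small experiment sets.

    Folds leave out one experiment per class (in file order; the
    smaller class is cycled when classes are unbalanced, which is
    logged).  Model building and component selection use the remaining
    experiments; a mode's verdict is positive when the left-out pair is
    classified correctly in every fold and the mode passes the activity
    filter in every fold.
    """
    y = np.asarray(y, dtype=int).ravel()
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("single CV requires exactly two classes")
    idx0 = np.where(y == classes[0])[0]
    idx1 = np.where(y == classes[1])[0]
    if min(idx0.size, idx1.size) < 2:
        raise ValueError(
            "need at least two experiments per class: leaving one pair out "
            "must still allow fitting on a two-class remainder"
        )
    n_folds = int(max(idx0.size, idx1.size))
    if idx0.size != idx1.size:
        logger.info(
            "unbalanced classes (%d vs %d): cycling the smaller class over %d folds",
            idx0.size, idx1.size, n_folds,
        )
    pairs = [(int(idx0[i % idx0.size]), int(idx1[i % idx1.size])) for i in range(n_folds)]
    K = X.n_reactions

    records: list[EMValidationRecord] = []
    for z in range(ems.n_modes):
        comps: list[int | None] = []
        fold_correct: list[bool] = []
        active_all = True
        for a0, a1 in pairs:
            train = tuple(i for i in range(y.size) if i not in (a0, a1))
            Xf, yf = _take(X, train), y[list(train)]
            alpha, Xf_hat = fit_em_coefficients(Xf, ems, (z,))
            if not filter_inactive(ems.support(z), alpha[0]):
                active_all = False
                comps.append(None)
                fold_correct.append(False)
                continue
            a_cap = min(len(train) - 1, K)
            if max_components is not None:
                a_cap = min(a_cap, max_components)
            try:
                model = fit_npls1(Xf_hat, yf, a_cap)
            except ValueError as exc:
                logger.warning("mode %s fold fit failed: %s", ems.em_ids[z], exc)
                comps.append(None)
                fold_correct.append(False)
                continue
            A = minimal_components(model, Xf_hat, yf)  # component choice on the 3+3
            comps.append(A)
            if A is None:
                fold_correct.append(False)
                continue
            _, Xp_hat = fit_em_coefficients(_take(X, (a0, a1)), ems, (z,))
            _, labels = predict(model, Xp_hat, A)
            fold_correct.append(bool(np.array_equal(labels, y[[a0, a1]])))
        n_ok = sum(fold_correct)
        records.append(
            EMValidationRecord(
                em_index=z,
                em_id=ems.em_ids[z],
                active=active_all,
                components_per_rotation=tuple(comps),
                selection_perfect=tuple(fold_correct),
                advanced=active_all and all(fold_correct),
                validation_accuracy=n_ok / len(fold_correct) if fold_correct else None,
                validation_all_correct=bool(fold_correct) and all(fold_correct),
            )
        )
    return records and tuple(records) or tuple()
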