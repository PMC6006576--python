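"""Stoichiometric network representation and elementary-mode enumeration.

A metabolic network is described by its stoichiometric matrix ``S`` (M
metabolites x K reactions) together with per-reaction reversibility
flags.  An elementary mode (EM) is a support-minimal flux vector ``p``
with ``S @ p = 0`` that respects irreversibility; EMs are the simplest
steady-state pathways connecting substrates to end-products and form
the candidate set for dynamic elementary-mode analysis.

Enumeration uses the classical nullspace tableau algorithm: reversible
reactions are split into forward/backward non-negative pairs, metabolite
balances are eliminated one at a time by combining rows of opposite
sign, and non-support-minimal rows are pruned after every elimination.
Exact rational arithmetic is used whenever the stoichiometric
coefficients are integral, so the printed 0/1 modes of small textbook
networks come out exact.  The algorithm is quadratic-to-combinatorial in
the number of modes and is therefore guarded by a reaction-count cap; it
targets networks with at most a few dozen reactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

#: absolute threshold below which a floating-point tableau entry is zero
ZERO_TOL = 1e-9

#: tolerance for the steady-state test  ||S p||_inf  of a candidate mode
STEADY_TOL = 1e-9


class NetworkValidationError(ValueError):
    """Raised when a network violates a structural invariant."""


class CombinatorialLimitError(RuntimeError):
    """Raised when enumeration is refused because K exceeds the cap."""


@dataclass(frozen=True)
class MetabolicNetwork:
    """Stoichiometric matrix with reaction/metabolite labels.

    Parameters
    ----------
    stoich:
        ``(M, K)`` array of net stoichiometric coefficients; column ``k``
        is the mass-balance signature of reaction ``k``.
    reaction_ids, metabolite_ids:
        Unique string labels for the K columns / M rows.
    reversible:
        Length-K boolean flags; irreversible reactions carry flux >= 0.
    """

    stoich: np.ndarray
    reaction_ids: tuple[str, ...]
    metabolite_ids: tuple[str, ...]
    reversible: np.ndarray

    def __post_init__(self) -> None:
        S = np.atleast_2d(np.asarray(self.stoich, dtype=float))
        object.__setattr__(self, "stoich", S)
        object.__setattr__(self, "reaction_ids", tuple(self.reaction_ids))
        object.__setattr__(self, "metabolite_ids", tuple(self.metabolite_ids))
        rev = np.asarray(self.reversible, dtype=bool)
        object.__setattr__(self, "reversible", rev)
        M, K = S.shape
        if M < 1 or K < 1:
            raise NetworkValidationError("network needs at least one metabolite and one reaction")
        if len(self.reaction_ids) != K:
            raise NetworkValidationError(f"expected {K} reaction ids, got {len(self.reaction_ids)}")
        if len(self.metabolite_ids) != M:
            raise NetworkValidationError(f"expected {M} metabolite ids, got {len(self.metabolite_ids)}")
        if rev.shape != (K,):
            raise NetworkValidationError("reversible flags must be one per reaction")
        if len(set(self.reaction_ids)) != K:
            raise NetworkValidationError("duplicate reaction id")
        if len(set(self.metabolite_ids)) != M:
            raise NetworkValidationError("duplicate metabolite id")
        zero_cols = np.where(~np.any(np.abs(S) > ZERO_TOL, axis=0))[0]
        if zero_cols.size:
            bad = ", ".join(self.reaction_ids[k] for k in zero_cols)
            raise NetworkValidationError(f"all-zero stoichiometry for reaction(s): {bad}")

    @property
    def n_metabolites(self) -> int:
        return self.stoich.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.stoich.shape[1]


@dataclass(frozen=True)
class ElementaryModeMatrix:
    """Elementary modes as columns of a ``(K, Z)`` matrix.

    Each column is normalised so its largest-magnitude entry is 1 and
    satisfies ``S @ p = 0`` within :data:`STEADY_TOL`.  Columns are
    ordered lexicographically by support, then by value, so mode indices
    are deterministic across runs.
    """

    modes: np.ndarray
    em_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        P = np.atleast_2d(np.asarray(self.modes, dtype=float))
        object.__setattr__(self, "modes", P)
        object.__setattr__(self, "em_ids", tuple(self.em_ids))
        if P.shape[1] != len(self.em_ids):
            raise ValueError("one id per mode required")
        if len(set(self.em_ids)) != len(self.em_ids):
            raise ValueError("duplicate elementary-mode id")

    @property
    def n_reactions(self) -> int:
        return self.modes.shape[0]

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def support(self, e: int) -> frozenset[int]:
        """0-based reaction indices used by mode ``e``."""
        return frozenset(np.where(np.abs(self.modes[:, e]) > ZERO_TOL)[0].tolist())


# ---------------------------------------------------------------------------
# tableau enumeration
# ---------------------------------------------------------------------------

def _is_integral(S: np.ndarray) -> bool:
    return bool(np.all(np.abs(S - np.round(S)) < 1e-12))


def _prune_non_minimal(rows: list[tuple[list, list]], nz) -> list[tuple[list, list]]:
    """Keep rows whose reaction support is minimal; dedupe equal supports."""
    sups = [frozenset(i for i, v in enumerate(r[1]) if nz(v)) for r in rows]
    keep: list[tuple[list, list]] = []
    seen: list[frozenset] = []
    order = sorted(range(len(rows)), key=lambda i: len(sups[i]))
    for i in order:
        s = sups[i]
        if not s:
            continue
        if any(t <= s for t in seen):  # strict subset or duplicate support
            continue
        seen.append(s)
        keep.append(rows[i])
    return keep


def enumerate_elementary_modes(
    net: MetabolicNetwork, max_reactions: int = 64
) -> ElementaryModeMatrix:
    """Enumerate all elementary modes of a (small) network.

    Reversible reactions are split into non-negative forward/backward
    pairs, the split cone's extreme rays are computed by the tableau
    algorithm, two-cycle artifacts of the splitting are discarded and
    the directions are recombined.  Each mode is scaled so that its
    largest-magnitude entry is 1.

    Raises
    ------
    CombinatorialLimitError
        If the network has more than ``max_reactions`` reactions.
    """
    K = net.n_reactions
    if K > max_reactions:
        raise CombinatorialLimitError(
            f"refusing to enumerate modes for K={K} > cap {max_reactions}: "
            "elementary-mode counts grow combinatorially; raise max_reactions "
            "explicitly if you accept the cost"
        )
    M = net.n_metabolites
    S = net.stoich
    exact = _is_integral(S)

    # split reversible reactions into forward/backward columns
    cols: list[np.ndarray] = []
    colmap: list[tuple[int, int]] = []  # (original reaction, direction)
    for k in range(K):
        cols.append(S[:, k])
        colmap.append((k, +1))
        if net.reversible[k]:
            cols.append(-S[:, k])
            colmap.append((k, -1))
    Ks = len(cols)

    if exact:
        def conv(x: float) -> Fraction:
            return Fraction(int(round(x)))

        zero_v = Fraction(0)
        one_v = Fraction(1)

        def nz(v: Fraction) -> bool:
            return v != 0
    else:
        def conv(x: float) -> float:
            return float(x)

        zero_v = 0.0
        one_v = 1.0

        def nz(v: float) -> bool:
            return abs(v) > ZERO_TOL

    # rows: (metabolite part of length M, reaction part of length Ks)
    rows: list[tuple[list, list]] = []
    for i in range(Ks):
        a = [conv(cols[i][m]) for m in range(M)]
        v = [zero_v] * Ks
        v[i] = one_v
        rows.append((a, v))

    for m in range(M):
        kept = [r for r in rows if not nz(r[0][m])]
        pos = [r for r in rows if nz(r[0][m]) and r[0][m] > 0]
        neg = [r for r in rows if nz(r[0][m]) and r[0][m] < 0]
        new: list[tuple[list, list]] = []
        for rp in pos:
            cp = rp[0][m]
            for rn in neg:
                cn = -rn[0][m]
                a = [cn * x + cp * y for x, y in zip(rp[0], rn[0])]
                v = [cn * x + cp * y for x, y in zip(rp[1], rn[1])]
                if not exact:
                    scale = max(abs(x) for x in v)
                    if scale > 0:
                        a = [x / scale for x in a]
                        v = [x / scale for x in v]
                new.append((a, v))
        rows = _prune_non_minimal(kept + new, nz)

    # recombine split directions; drop futile two-cycles
    modes: list[np.ndarray] = []
    for _, v in rows:
        used = {}
        twocycle = False
        for i, val in enumerate(v):
            if nz(val):
                k, d = colmap[i]
                if k in used and used[k] != d:
                    twocycle = True
                    break
                used[k] = d
        if twocycle:
            continue
        p = np.zeros(K)
        for i, val in enumerate(v):
            if nz(val):
                k, d = colmap[i]
                p[k] += d * float(val)
        scale = np.max(np.abs(p))
        if scale <= ZERO_TOL:
            continue
        modes.append(p / scale)

    # deterministic order: support first, then values; dedupe
    def sort_key(p: np.ndarray):
        sup = tuple(np.where(np.abs(p) > ZERO_TOL)[0].tolist())
        return (len(sup), sup, tuple(np.round(p, 10)))

    modes.sort(key=sort_key)
    unique: list[np.ndarray] = []
    for p in modes:
        if not any(np.allclose(p, q, atol=1e-9) for q in unique):
            unique.append(p)

    P = np.column_stack(unique) if unique else np.zeros((K, 0))
    ids = tuple(f"EM{i + 1}" for i in range(P.shape[1]))
    return ElementaryModeMatrix(P, ids)


def validate_em(
    net: MetabolicNetwork,
    p: Sequence[float],
    ems: ElementaryModeMatrix | None = None,
    tol: float = STEADY_TOL,
) -> tuple[bool, dict]:
    """Check whether ``p`` is an admissible elementary mode of ``net``.

    Returns ``(ok, diagnostics)`` where the diagnostics record the
    steady-state residual, the support, and which check failed.  A valid
    mode must balance every metabolite, respect irreversibility, have a
    non-empty support, and be support-minimal with respect to the
    enumerated mode set (``ems`` is enumerated on demand if omitted).
    """
    p = np.asarray(p, dtype=float)
    K = net.n_reactions
    if p.shape != (K,):
        raise ValueError(f"expected length-{K} vector, got shape {p.shape}")
    diag: dict = {}
    scale = max(1.0, float(np.max(np.abs(p))))
    resid = float(np.max(np.abs(net.stoich @ p))) if p.size else 0.0
    diag["steady_state_residual"] = resid
    diag["steady_state"] = resid <= tol * scale
    support = frozenset(np.where(np.abs(p) > ZERO_TOL)[0].tolist())
    diag["support"] = sorted(support)
    diag["nonempty"] = bool(support)
    irrev_ok = bool(np.all(p[~net.reversible] >= -ZERO_TOL))
    diag["irreversibility"] = irrev_ok
    minimal = True
    if diag["nonempty"]:
        if ems is None:
            ems = enumerate_elementary_modes(net)
        for e in range(ems.n_modes):
            s = ems.support(e)
            if s < support:  # strict subset -> p is decomposable
                minimal = False
                diag["violating_mode"] = ems.em_ids[e]
                break
    diag["support_minimal"] = minimal
    ok = diag["steady_state"] and diag["nonempty"] and irrev_ok and minimal
    return ok, diag
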