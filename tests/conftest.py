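"""Shared fixtures and independent oracles."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest
from scipy.linalg import null_space

import dynem


@pytest.fixture(scope="session")
def toy_net():
    return dynem.toy_network()


@pytest.fixture(scope="session")
def toy_net_boundary():
    return dynem.toy_network(boundary=True)


@pytest.fixture(scope="session")
def toy_ems(toy_net):
    return dynem.enumerate_elementary_modes(toy_net)


def brute_force_ems(S: np.ndarray) -> list[tuple[frozenset, np.ndarray]]:
    """Independent elementary-mode oracle for small irreversible networks.

    Enumerates every reaction subset (K <= 10), keeps subsets whose
    restricted stoichiometry has a one-dimensional nullspace spanned by
    a strictly sign-definite full-support vector, and filters the
    resulting candidates to support-minimal ones.  Completely
    independent of the tableau algorithm under test.
    """
    S = np.asarray(S, dtype=float)
    K = S.shape[1]
    assert K <= 10, "oracle is exponential; keep K small"
    cands: list[tuple[frozenset, np.ndarray]] = []
    for r in range(1, K + 1):
        for sub in combinations(range(K), r):
            ns = null_space(S[:, sub])
            if ns.shape[1] != 1:
                continue
            v = ns[:, 0]
            if np.any(np.abs(v) < 1e-8):
                continue  # not full support on the subset
            if np.all(v < 0):
                v = -v
            if np.any(v < 0):
                continue  # mixed signs: violates irreversibility
            p = np.zeros(K)
            p[list(sub)] = v
            cands.append((frozenset(sub), p / np.max(p)))
    sups = [s for s, _ in cands]
    return [(s, p) for s, p in cands if not any(t < s for t in sups)]


def random_irreversible_network(rng: np.random.Generator, M: int = 4, K: int = 6):
    """Random small integer stoichiometry without all-zero columns."""
    while True:
        S = rng.integers(-2, 3, size=(M, K)).astype(float)
        if np.all(np.any(S != 0, axis=0)):
            return dynem.MetabolicNetwork(
                S,
                tuple(f"r{k}" for k in range(K)),
                tuple(f"m{m}" for m in range(M)),
                np.zeros(K, dtype=bool),
            )


def mode_set(ems: dynem.ElementaryModeMatrix) -> set[tuple]:
    """Canonical comparable form: supports with max-1-normalised values."""
    out = set()
    for e in range(ems.n_modes):
        p = ems.modes[:, e]
        p = p / np.max(np.abs(p))
        out.add(tuple(np.round(p, 8)))
    return out
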