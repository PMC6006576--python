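"""Synthetic data generators.

Everything the test-bench needs is generated here: the small branched
toy network (5 internal metabolites, 8 irreversible reactions, exactly
3 elementary modes), steady-state fluxes as positive mode combinations,
non-steady-state experiments where the per-reaction usage of a mode
travels from upstream to downstream over time, two-class experiment
sets with multiplicative noise ``(1 + 0.2 eps)``, and concentration
series obtained by forward-integrating a flux path through the
stoichiometry.

Defaults mirror the simulated study design the framework targets:
32 experiments per class, 20 flux time points on a 3-second grid,
20% multiplicative Gaussian noise, and a class effect that scales the
coefficient usage of one planted mode by a factor 2 in the high class —
the high-substrate condition drives more flux through the same pathway
rather than a different pathway.  The noise enters the fluxes directly;
a kinetic simulator (where noise would enter via initial
concentrations) is deliberately out of scope, so the flux-level noise
is a stated surrogate, not a claim of kinetic equivalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dynema import FluxTimeSeries
from .fluxestim import ConcentrationTimeSeries
from .network import ElementaryModeMatrix, MetabolicNetwork, enumerate_elementary_modes
from .npls import ThreeWayFluxArray

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for two-class flux simulations.

    ``noise_fraction`` is the multiplicative noise level (0.2 means
    fluxes are scaled by ``1 + 0.2 eps`` with standard-normal ``eps``);
    ``class_effect`` multiplies the planted mode's coefficients in the
    high class.  The seed is mandatory: every generated byte is a
    deterministic function of it.
    """

    seed: int
    n_experiments_per_class: int = 32
    n_timepoints: int = 20
    dt_s: float = 3.0
    noise_fraction: float = 0.2
    class_effect: float = 2.0
    profile_amplitude: float = 0.8
    alpha_profile: str = "front"

    def __post_init__(self) -> None:
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")
        if self.n_timepoints < 2:
            raise ValueError("at least two time points required")
        if self.n_experiments_per_class < 1:
            raise ValueError("at least one experiment per class required")
        if not 0 <= self.profile_amplitude < 1:
            raise ValueError("profile amplitude must be in [0, 1) to keep usage positive")
        if self.alpha_profile not in ("front", "constant"):
            raise ValueError("alpha_profile must be 'front' or 'constant'")


def toy_network(boundary: bool = False) -> MetabolicNetwork:
    """The branched toy network: r1→r2 into a branch point, one branch
    r3→r4, the other r5 splitting into r6 and r7→r8.

    With ``boundary=False`` (default) only the 5 internal metabolites
    appear and the matrix is 5 x 8; its elementary modes are exactly
    the three vectors with supports {r1..r4}, {r1,r2,r5,r6} and
    {r1,r2,r5,r7,r8}.  With ``boundary=True`` the substrate and the
    three end-products are added as measured rows (9 x 8), which makes
    every flux identifiable from concentration changes — the form
    needed for flux-estimation round trips.
    """
    reactions = tuple(f"r{k}" for k in range(1, 9))
    internal = ("M1", "M2", "M3", "M4", "M5")
    S_int = np.array(
        [
            # r1  r2  r3  r4  r5  r6  r7  r8
            [1, -1, 0, 0, 0, 0, 0, 0],  # M1
            [0, 1, -1, 0, -1, 0, 0, 0],  # M2
            [0, 0, 1, -1, 0, 0, 0, 0],  # M3
            [0, 0, 0, 0, 1, -1, -1, 0],  # M4
            [0, 0, 0, 0, 0, 0, 1, -1],  # M5
        ],
        dtype=float,
    )
    if not boundary:
        return MetabolicNetwork(S_int, reactions, internal, np.zeros(8, dtype=bool))
    ext = ("S0", "P1", "P2", "P3")
    S_ext = np.array(
        [
            [-1, 0, 0, 0, 0, 0, 0, 0],  # S0 consumed by r1
            [0, 0, 0, 1, 0, 0, 0, 0],  # P1 produced by r4
            [0, 0, 0, 0, 0, 1, 0, 0],  # P2 produced by r6
            [0, 0, 0, 0, 0, 0, 0, 1],  # P3 produced by r8
        ],
        dtype=float,
    )
    return MetabolicNetwork(
        np.vstack([S_int, S_ext]), reactions, internal + ext, np.zeros(8, dtype=bool)
    )


def generate_steady_fluxes(
    net: MetabolicNetwork,
    weights: np.ndarray,
    noise: float = 0.0,
    seed: int | None = None,
    ems: ElementaryModeMatrix | None = None,
) -> FluxTimeSeries:
    """Steady-state flux vector as a positive mode combination (J = 1).

    ``x = sum_e lambda_e p_e`` with optional multiplicative noise
    ``(1 + noise * eps)`` applied elementwise.
    """
    weights = np.asarray(weights, dtype=float).ravel()
    if np.any(weights < 0):
        raise ValueError("mode weights must be non-negative")
    if ems is None:
        ems = enumerate_elementary_modes(net)
    if weights.shape[0] != ems.n_modes:
        raise ValueError(f"expected {ems.n_modes} weights, got {weights.shape[0]}")
    x = ems.modes @ weights
    if noise > 0:
        rng = np.random.default_rng(seed)
        x = np.maximum(x * (1.0 + noise * rng.standard_normal(x.shape)), 0.0)
    return FluxTimeSeries(x[None, :], np.array([0.0]), "steady")


def front_profile(
    J: int, support: list[int] | np.ndarray, K: int, amplitude: float = 0.8
) -> np.ndarray:
    """Travelling-front usage profile, (J, K), equal to 1 outside the support.

    Reactions early in the pathway (low index within the support) start
    above 1 and decay; late reactions start below 1 and rise; all
    converge to 1 at the final time point — the series ends at steady
    state.  Monotone in time for every reaction.
    """
    support = sorted(int(k) for k in support)
    prof = np.ones((J, K))
    n = len(support)
    for pos, k in enumerate(support):
        depth = pos / (n - 1) if n > 1 else 0.5
        relax = (J - 1 - np.arange(J)) / (J - 1)  # 1 at j=0 → 0 at j=J-1
        prof[:, k] = 1.0 + amplitude * (1.0 - 2.0 * depth) * relax
    return prof


def generate_dynamic_experiment(
    net: MetabolicNetwork,
    em_index: int,
    J: int,
    alpha_profile: np.ndarray | str = "front",
    dt_s: float = 3.0,
    amplitude: float = 0.8,
    ems: ElementaryModeMatrix | None = None,
    experiment_id: str = "",
) -> FluxTimeSeries:
    """Non-steady-state series with time-varying usage of one mode.

    ``X[j, k] = profile[j, k] * p[k]`` where the default profile is the
    travelling front above; pass an explicit (J, K) array or
    ``"constant"`` for a steady series.
    """
    if ems is None:
        ems = enumerate_elementary_modes(net)
    p = ems.modes[:, em_index]
    K = p.shape[0]
    if isinstance(alpha_profile, str):
        if alpha_profile == "front":
            prof = front_profile(J, sorted(ems.support(em_index)), K, amplitude)
        elif alpha_profile == "constant":
            prof = np.ones((J, K))
        else:
            raise ValueError(f"unknown profile {alpha_profile!r}")
    else:
        prof = np.asarray(alpha_profile, dtype=float)
        if prof.shape != (J, K):
            raise ValueError(f"profile must have shape ({J}, {K})")
        if np.any(prof < 0):
            raise ValueError("profile values must be non-negative")
    X = prof * p[None, :]
    t = dt_s * np.arange(J)
    return FluxTimeSeries(X, t, experiment_id)


def generate_two_class_set(
    config: SimulationConfig,
    net: MetabolicNetwork,
    em_index: int = 0,
    ems: ElementaryModeMatrix | None = None,
) -> tuple[ThreeWayFluxArray, np.ndarray]:
    """Balanced two-class experiment set with one planted mode.

    Every experiment uses the planted mode with the travelling-front
    usage profile; class-1 (high) experiments carry ``class_effect``
    times the coefficients of class 0.  Multiplicative noise
    ``(1 + noise_fraction * eps)`` is applied elementwise per
    experiment and negative values are clipped at zero.  Returns the
    (N, K, J) array (class 0 first) and the 0/1 label vector.
    """
    if ems is None:
        ems = enumerate_elementary_modes(net)
    rng = np.random.default_rng(config.seed)
    J = config.n_timepoints
    base = generate_dynamic_experiment(
        net, em_index, J,
        alpha_profile=config.alpha_profile,
        dt_s=config.dt_s,
        amplitude=config.profile_amplitude,
        ems=ems,
    ).fluxes  # (J, K)
    n = config.n_experiments_per_class
    slabs = []
    ids = []
    y = np.array([0] * n + [1] * n)
    for i, cls in enumerate(y):
        scale = config.class_effect if cls == 1 else 1.0
        eps = rng.standard_normal(base.shape)
        X = np.maximum(scale * base * (1.0 + config.noise_fraction * eps), 0.0)
        slabs.append(X.T)  # (K, J)
        ids.append(f"exp{i + 1:03d}")
    return ThreeWayFluxArray(np.stack(slabs), tuple(ids)), y


def fluxes_to_concentrations(
    X: FluxTimeSeries,
    net: MetabolicNetwork,
    c0: np.ndarray,
    dt_s: float | None = None,
) -> ConcentrationTimeSeries:
    """Forward-Euler accumulation ``C[t+1] = C[t] + dt * S @ X[t]``.

    The inverse of the mass-balance constraint used in flux estimation;
    returns J + 1 concentration rows.  Concentrations that would go
    negative are clipped at zero with a warning (the flux path is then
    not mass-consistent with ``c0``).
    """
    c0 = np.asarray(c0, dtype=float).ravel()
    M, K = net.stoich.shape
    if c0.shape[0] != M:
        raise ValueError(f"expected {M} initial concentrations, got {c0.shape[0]}")
    if np.any(c0 < 0):
        raise ValueError("initial concentrations must be non-negative")
    J = X.n_timepoints
    if dt_s is None:
        dt = np.diff(X.time_s) if J > 1 else np.array([1.0])
        dt = np.append(dt, dt[-1] if dt.size else 1.0)
    else:
        dt = np.full(J, float(dt_s))
    C = np.zeros((J + 1, M))
    C[0] = c0
    clipped = False
    for j in range(J):
        nxt = C[j] + dt[j] * (net.stoich @ X.fluxes[j])
        if np.any(nxt < -1e-12):
            clipped = True
        C[j + 1] = np.maximum(nxt, 0.0)
    if clipped:
        logger.warning(
            "concentration clipped at zero during integration; the flux path "
            "is not mass-consistent with the supplied initial concentrations"
        )
    t = np.append(X.time_s, X.time_s[-1] + dt[-1]) if J > 1 else np.array([0.0, dt[0]])
    return ConcentrationTimeSeries(C, t, X.experiment_id)
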