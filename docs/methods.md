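# Methods

## Model

A metabolic network is a stoichiometric matrix **S** (M × K) with
per-reaction reversibility flags.  An elementary mode (EM) is a
support-minimal vector **p** with **S p** = 0 that respects
irreversibility; after splitting reversible reactions into
forward/backward pairs every mode is non-negative.  A steady-state flux
vector is a positive combination of modes, `x = Σₑ λₑ pₑ`; the
steady-state baseline with one weight per mode and experiment
(`fit_pema`) is kept as the degenerate case of the dynamic model.

The dynamic model gives each reaction of each selected mode its own
non-negative coefficient at each time point:

    X = (I_J ⊗ 1ᵀ_E) [ A ∘ (1_J ⊗ Pᵀ) ] + F

with **A** the reaction-wise unfolded E × J × K coefficient array.  The
model decouples into scalar equations `X[j,k] = Σₑ α[e,j,k] P[k,e]`,
so the non-negative least-squares fit is exact on the union of the
selected supports and the residual lives entirely on unused reactions.
For E ≥ 2 the scalar problems are underdetermined; we take the
minimum-L2-norm non-negative solution, which distributes a shared
reaction's flux proportionally to the modes' weights
(`α[e,j,k] = X[j,k]·P[k,e] / Σₑ' P[k,e']²`).  This is deterministic,
symmetric in the modes, and reduces to the plain ratio for E = 1.  A
consequence worth knowing: model selection, not coefficient fitting,
carries all the statistical content of dynEMA — projecting onto a mode
set is exactly masking the data to its support union.

Explained variance is the uncentered sum-of-squares ratio
`1 − ‖X − X̂‖²_F / ‖X‖²_F`: fluxes are decomposed through the origin,
matching steady-state practice.  Greedy selection adds at each step the
candidate that maximises this quantity jointly with the modes already
selected; ties within 1e-12 go to the lower column index; the default
stop is 95% explained variance when no mode count is given.

## Elementary-mode enumeration

The classical nullspace tableau: start from `[Sᵀ | I]`, eliminate one
metabolite per pass by combining rows of opposite sign, and prune rows
whose reaction support strictly contains another row's support after
every pass.  Reversible reactions are split first; modes using both
directions of one reaction (two-cycle artifacts) are discarded before
recombination.  Exact rational arithmetic (`fractions.Fraction`) is
used when all coefficients are integral, otherwise floating point with
a 1e-9 zero threshold and per-pass row rescaling.  Modes are scaled so
the largest-magnitude entry is 1 (any fixed convention works — the
coefficients absorb scale — and this one makes 0/1 textbook modes
exact) and ordered lexicographically by support, then values, so mode
indices are reproducible.  Enumeration refuses networks above a
configurable cap (default 64 reactions): mode counts grow
combinatorially, and this implementation targets the tens-of-modes
scale, not genome scale.

## Discriminant screening (dynEMR-DA)

For each candidate mode: unfold the N × K × J experiment array
reaction-wise to (J·N) × K, fit the coefficients against the candidate
(jointly with any already-adopted modes), reconstruct, refold, and fit
a trilinear PLS1 model against the 0/1 class vector.  Candidates whose
pathway is not actually used — some support reaction's coefficient
below 1e-10 at every time point of at least one experiment — are
filtered out before ranking; the remaining candidates are ranked by
explained class variance.  Filtering before ranking is a choice; the
alternative (rank first, then drop) gives the same survivors and only
reorders the rejected tail of the report.

The trilinear PLS1 engine extracts, per component, the unit reaction-
and time-weights maximising covariance with the response residual (the
leading singular pair of `Z = Σₙ yₙ Xₙ`), scores each experiment,
regresses the response jointly on all scores, and deflates both array
and response.  The array is centered across experiments and the
response mean-centered; no scaling.  Weight signs are fixed so the
largest-magnitude reaction weight is positive.  With J = 1 the model
is two-way PLS1 and its predictions coincide with NIPALS to machine
precision (asserted in the tests against an independent
implementation).  Class assignment thresholds the continuous
prediction at 0.5 under 0/1 coding.

"Discriminates perfectly" always means 100% correct assignment on the
split the protocol designates (3CV selection set, single-CV left-out
pair, or a caller-supplied evaluation set) — not on training data:
with K·J features and a handful of experiments a training fit is
nearly always perfect, which is exactly the chance-discrimination trap
the validation design exists to avoid.  The number of components per
candidate is the smallest one achieving perfect classification of the
designated split, capped at K.

## Flux estimation

Fluxes are inferred from concentrations by

    min  Σ_{j<J} Σ_k (x_{j+1,k} − x_{j,k})² + Σ_j Σ_k x_{j,k}²
    s.t. S Xᵀ = dCᵀ/dt,   X ≥ 0

with forward-difference derivatives over the actual Δt and unit weight
on both terms.  For a general T-point series the smoothness sum runs
over j = 1..J−1 and the magnitude sum over j = 1..J (J = T−1).  The
solver chain is deterministic: equality constraints are eliminated via
an SVD nullspace parametrisation, the bound-constrained least-squares
problem is reduced to a least-distance program, and that is solved by
the Lawson–Hanson NNLS reduction.  Feasibility is probed by the
time-point-wise NNLS solution of `S x = dC/dt` (which is also the
classical initial guess, exposed as `initial_guess`); if the balances
admit no non-negative flux the solver falls back to a penalty
formulation with weight 1e6 on the squared balance residual and logs
the violation.  First-order optimality is checkable via
`kkt_residual` (stationarity on free coordinates, sign of the bound
multipliers, primal feasibility); the tests hold it below 1e-6 and it
typically sits at solver precision (~1e-15).

Identifiability caveat: flux components lying in the EM nullspace of
the *internal* stoichiometry leave concentrations unchanged, so with
only internal metabolites measured the regulariser silently shrinks
pathway throughput toward the smallest feasible value (a steady series
estimates as zero flux).  Quantitative recovery requires measured
boundary/exchange species; the toy network's `boundary=True` variant
(9 × 8, substrate plus three products) makes all eight fluxes
identifiable and is what the round-trip checks use.

## Validation protocols

3CV splits the experiments into four stratified groups (default
quarters; at least four experiments per class).  Rotations
calibration-test-selection, test-selection-calibration,
selection-calibration-test each fit the per-mode model on the first
group, pick the minimal component count on the second, and score the
third.  A mode advances only with perfect selection-group
classification in all three rotations (and activity in all three fit
groups); advancing modes are finally scored on the validation group by
the three already-fitted models.  The minimal component count is
chosen per candidate mode, not globally — each candidate's
reconstruction is a different feature space, so a global count would
be meaningless.  For small studies, `run_single_cv` leaves out one
experiment per class per fold (file order; the smaller class is cycled
when unbalanced, which is logged), fits and chooses components on the
remainder, and requires every fold's pair to classify correctly.

## Synthetic data

The generators define the study conditions the tests and the
acceptance script measure under:

- toy network: the branched 5 × 8 irreversible network whose three
  modes have supports {r1..r4}, {r1,r2,r5,r6}, {r1,r2,r5,r7,r8};
- travelling-front usage profile: a reaction at relative pathway depth
  d starts at `1 + a(1 − 2d)` (a = 0.8) and relaxes linearly to 1 at
  the last time point — upstream reactions start high and decay,
  downstream ones start low and rise, and the series ends at steady
  state;
- two-class sets: 32 experiments per class, 20 time points on a
  3-second grid, the high class scaling the planted mode's
  coefficients by 2.0, and elementwise multiplicative noise
  `(1 + 0.2 ε)`, ε ~ N(0, 1), clipped at zero.

What these data do *not* emulate: kinetics.  In a real study the noise
enters the initial concentrations of an ODE system and propagates
through saturating rate laws; here it is applied to fluxes directly,
and the class effect is a clean multiplicative scale on one mode's
usage.  Passing tests therefore demonstrate that the pipeline recovers
a planted dynamic pathway signal under multiplicative measurement
noise and rejects permuted labels — not that it tolerates kinetic
model mismatch, correlated noise, or overlapping active pathways,
which real data will add.  The problem sizes used throughout (8
reactions, 3 modes, 64 experiments, 20 seeds) keep the full suite in
the seconds range and are stated alongside each reported number.

## Numerical choices and degenerate inputs

- zero flux matrix: coefficients and residual are zero; explained
  variance of a zero matrix is defined as 1 against a zero
  reconstruction and an error otherwise;
- NPLS component extraction stops early when the covariance matrix
  vanishes (response fully explained); the model then carries fewer
  components than requested;
- candidate modes whose reconstruction is identically zero (support
  disjoint from all flux) fail the NPLS fit; screening records the
  failure instead of aborting and ranks such candidates last;
- the activity threshold is 1e-10 on coefficients, the steady-state
  tolerance 1e-9 on `‖S p‖∞`, the mass-balance feasibility tolerance
  1e-6 (relative to the derivative scale);
- all generator randomness flows from a single mandatory seed; the CLI
  writes a manifest (parameters, seed, input SHA-256 hashes) and equal
  seeds reproduce outputs byte-for-byte.

## Known limitations

- Mode enumeration is for small networks (tens of reactions/modes);
  no extreme-pathway computation, no SBML input.
- The minimum-norm coefficient split is one defensible resolution of
  the per-reaction underdetermination; other conventions (e.g. winner
  takes all) would change coefficient values but not reconstructions,
  residuals, or any selection decision.
- Flux estimation assumes the measured metabolite set makes fluxes
  identifiable (see the caveat above); it reports, rather than
  resolves, infeasibility from noisy derivatives.
- Single-response discriminant analysis only (two classes); no
  multi-response NPLS2, no confidence intervals on coefficients, no
  smoothing of coefficients over time.
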