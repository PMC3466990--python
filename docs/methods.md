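# Methods

## Model

A decision chain is a sequence of two-choice decision events indexed by
position on a road (1D) or lattice (2D).  Each cell is LIGHT or DARK.
In a LIGHT cell the locally dominant mechanism is deliberation, with
probability `p_r` of a correct forward move; in a DARK cell it is the
primary-emotion system, with probability `p_e1`.  A wrong decision —
whether an error of commission or an excess of caution — is folded into
a single *retreat* move, so each state has exactly one forward and one
backward transition.  For a long road with a repeating cell pattern of
period *n* (default `LLD`, so the light fraction is α = 2/3) the walk is
modelled as a cyclic birth–death chain on one period: state *i* advances
to *i*+1 (mod *n*) with forward probability `q_i` and retreats to *i*−1
(mod *n*) otherwise.  This cyclic reduction is what makes the worked
example exactly solvable: it reproduces the 13/47/40% occupancies and
the effective ability 0.52 for `p_r = 0.8`, `p_e1 = 0.1`.

Predictive ability has two readings, both implemented:

- **linear** (independent events): `α·p_r + (1−α)·p_e1`, and with
  markers `β·p_e2 + (1−β)·(α·p_r + (1−α)·p_e1)`;
- **non-linear** (chain): `Σ_i π_i q_i`, where π is the stationary
  distribution of the ring.

A confusion-matrix view (`a, b, c, d` counts; ability = `a* + d*`) is
provided for connecting the probabilities to frequency data; the
coin-flip baseline corresponds to `a* + d* = 1/2`.

## Somatic markers

Markers override the local mechanism with frequency β (default 1/2, the
value used throughout the analyses for tractability).  Two encodings:

- **mixture** (default): per decision, `q_i = (1−β)·p_local + β·p_e2`.
- **subcell**: each cell is split spatially into a local half-cell
  followed by a marker half-cell, doubling the ring; this realizes the
  override as alternating territory and therefore requires β = 1/2.

The two encodings agree in the homogeneous limit but differ in general;
"mixture" is the default because it is the simpler mechanism and
exhibits the coupling phenomenon the package exists to study.  The
marker ability `p_e2` is exogenous: no learning or acquisition model is
included, and the interesting regime is deliberately `p_e2 < 1/2`.

## Numerical choices

- **Stationary solve.**  `(Tᵀ − I)π = 0` with one row replaced by the
  normalization `Σπ = 1`, solved exactly (`numpy.linalg.solve`; a
  stacked batched variant powers the parameter sweeps).  No iterative
  ambiguity; residual `‖πT − π‖∞` is asserted below 1e−10 in tests.
- **Degeneracy.**  Any `q_i ∈ {0, 1}` makes the ring reducible, so the
  solver raises instead of returning a possibly non-unique vector.
  Probabilities are validated to [0, 1] at construction — errors, not
  clamps.  Minimum ring size is 3 (with 2 states forward and backward
  neighbors coincide).
- **Periodicity.**  A ±1 walk on an *even* ring is 2-periodic;
  uniqueness of π needs only irreducibility, so the direct solve is
  unaffected, but the test oracle iterates the lazy chain (I+T)/2,
  which has the same stationary vector and always converges.
- **Benefit conditions.**  Strict inequalities throughout: the linear
  benefit condition is `p_e2 > α·p_r + (1−α)·p_e1`, "above baseline" is
  `P_X > 1/2`; ties count as no benefit.
- **Region maps.**  Default grid step 0.01 in both `p_r` and `p_e1`,
  recorded in the output metadata; degenerate grid points carry NaN and
  are never flagged paradoxical.
- **Sensitivity derivative.**  Central differences at interior points,
  one-sided at the ends, at the curve's own sampling step (default
  0.025).
- **1D advantage boundary.**  The gain `P_X(with) − P_X(without)` is
  scanned densely (step 1e−3) to certify a single sign change, then the
  crossing is refined by Brent's method to 1e−6.  When `p_e1 = p_r` the
  gain is exactly `β(p_e2 − p_r)` and the boundary is `p_r`.

## Monte-Carlo simulators

All simulators draw from `numpy.random.Generator`s seeded through
`SeedSequence([seed, …offsets])`: identical configurations are
bit-identical, and sub-seeding is hierarchical — each road run *k* uses
`SeedSequence([seed, k])` and is reproducible in isolation; the 2D
simulator is vectorized across runs for speed, so there the sub-seed
offsets index simulation calls within a scan (one child generator per
`(p_r, p_e2)` point), not individual runs.

- **Ring** (`simulate_ring`): one long trajectory; occupancy estimated
  after a burn-in (defaults in the CLI: 10⁶ steps, 10⁴ burn-in).  At
  10⁶ steps the empirical occupancies sit within 0.01 per state of the
  exact π for the worked example.
- **Finite road** (`simulate_finite_road`): pattern repeated to length
  *L*; position 0 reflects, the goal absorbs; per-run forward-move
  fractions converge to the stationary-weighted ability on long roads
  (L = 300 suffices for ±0.02 agreement with 0.52).
- **2D grid** (`simulate_grid_2d`): rectangular lattice, corner start
  and goal.  A correct move goes to a uniformly chosen neighbor that
  reduces Manhattan distance to the goal; failures follow `move_mode`:

  - `retreat` (default): return to the previously occupied cell (stay
    in place before any move).  This reads the 1D "step back" rule
    agent-centrically: the walker backtracks its own path.
  - `away`: step to a uniformly chosen in-bounds distance-increasing
    neighbor (stay if none exists).  This is the environment-centric
    (spatial) reading, and it reduces *exactly* to the finite road on a
    1-row world — the dimensional-consistency tests use it.
  - `wrong-move`: failures split evenly between a uniformly chosen
    non-improving neighbor and the previous cell; a sensitivity
    variant that keeps an explicit "wrong forward" branch.

  The two readings of "move back" coincide along an unbroken forward
  march and diverge only after a retreat.  The package defaults to the
  agent-centric rule; under it the 2D marker-advantage boundary lies
  below the 1D analytic boundary for `p_r ≥ 0.6` (the coupling effect
  strengthens with dimension), whereas the spatial rule weakens the
  effect at low `p_r`.  Both are exposed precisely because the choice
  matters.

- **2D layout.**  `striped` darkens every k-th column
  (k = round(1/dark_fraction)), with the stripe placed mid-period so
  that neither the corner start nor the corner goal falls inside a dark
  column: an absorbing goal inside a dark stripe would force a
  consecutive run of dark decisions with no counterpart in the 1D road,
  where dark cells are crossed singly.  `random` darkens cells i.i.d.
  with the given fraction (seeded).
- **2D estimate.**  The effective ability is the fraction of correct
  moves pooled over every step of every run; the standard error is the
  cluster (per-run) ratio-estimator SE.  Runs are capped at
  `max_steps_per_run` and truncated runs still contribute their moves;
  boundary scans use a cap of a few hundred steps, which biases the
  estimate toward the transient only in regimes far below the crossing
  and leaves the located boundary unchanged at the reported precision.
- **2D boundary** (`boundary_curve_2d`): the no-marker ability is
  estimated once per `p_r`; the marker ability is scanned over `p_e2`
  at step 0.025; the boundary interpolates the first sign change of the
  gain, with an SE propagated through the local slope.  Scans with
  multiple sign changes at the given noise level are flagged uncertain.

## Default study conditions

Pattern `LLD` (α = 2/3), β = 1/2, worked-example abilities
`p_r = 0.8`, `p_e1 = 0.1`; region maps at `p_e2 ∈ {0.40, 0.425, 0.45,
0.475}`; 2D runs on a 9×9 striped grid.  Headline Monte-Carlo sizes
follow the analysis defaults of 50,000 runs for ability curves and
10,000 runs for boundary curves; the test suite uses 10,000 runs per
boundary point and 10⁶ ring steps, which keep every stochastic check
inside its stated tolerance at a few seconds of runtime.

## What the generators do and do not emulate

The synthetic worlds are exactly the model's own idealizations: binary
cell kinds, mechanism dominance fully determined by illumination,
constant abilities along the chain, no lethal outcomes (every mistake
is recoverable by construction), and no learning (all abilities fixed
over a trajectory).  Passing tests therefore validate the mathematics
of the chain model and its simulators — not the psychological claim
that real agents are described by it.  Real decision chains would add
heterogeneous and history-dependent abilities, correlated cell
structure, and asymmetric costs, none of which are represented here;
the cyclic reduction also assumes the road is long enough for the
stationary regime to dominate end effects.

## Known limitations

- The two marker encodings ("mixture" and "subcell") are distinct
  models that agree only in the homogeneous limit; neither is canonical,
  and quantitative marker results should state which encoding produced
  them.
- The 2D failure rule and light/dark layout are genuine modelling
  choices (see above); conclusions about the 2D boundary are reported
  for the default rule with the alternatives one flag away.
- `sm_advantage_boundary` assumes a single sign change of the gain in
  `p_e2`; this is certified numerically per call, not proved.
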