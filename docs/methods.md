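# Methods

This note records the models implemented in `superplan`, the conventions and
numerical choices behind them, and what the synthetic benchmarks do and do
not show.

## Discretization and constraints

The patient volume is a regular voxel grid (0-based linear indices,
x-fastest: `i = ix + nx*(iy + ny*iz)`); the fluence is a vector of `m`
nonnegative beamlet intensities; dose is the sparse product `d = Ax`.  Per
volume of interest (VOI), the prescription assigns a dose slab
`[l_q, u_q]` to every contained voxel.  Organs at risk carry `l = 0`
(positive lower bounds make no sense there), and a missing upper bound is
`+inf`.  Voxels whose slab is the trivial `[0, inf)`, and voxels whose
matrix row is all zero (no beamlet reaches them), are excluded from the
*active set*: they are neither visited by projections nor scored by the
proximity measures.  Overlapping structures are resolved once into an
exclusive partition: each voxel belongs to its highest-priority containing
structure, and both the constraints and the objectives are evaluated on
that partition, so a voxel is never pulled toward two different
prescriptions.  Per-voxel projection weights are the VOI's relative
prescription weight rescaled by the maximum weight, so the top-priority VOI
gets exactly 1.0 and the weights lie in (0, 1].

## The AMS sweep

One sweep visits every active voxel once, in the order given by the control
sequence (`cyclic` ascending index, `random` reshuffled every sweep from a
seeded generator, or stable sorts by ascending/descending weight).  At each
voxel the upper half-space is handled first, then the lower one, each with
the relaxed projection step using effective weight
`lambda * weight_scale * nu_i`; with effective weight 1 the violated
residual is closed exactly, and for `lambda in (0, 2]` every step is
nonexpansive toward any feasible point (Fejér monotonicity — asserted in
the tests against construction witnesses).  With effective weight at most 1
and `l <= u`, the two half-space steps of one voxel cannot both fire in a
single visit; for larger relaxation the lower step sees the post-upper-step
dose.  Nonnegativity is enforced once per sweep, by clamping after the full
pass — not after each projection.  The sweep is a pure function: it copies
its input.

Proximity is scored as
`V(x) = mean over active voxels of [ (l - <a_i,x>)_+^2 + (<a_i,x> - u)_+^2 ] / ||a_i||^2`.
Normalizing by the active-voxel count (rather than all `n` voxels) keeps
`V` comparable across prescriptions; bounds are simply undefined for
unassigned voxels.  `max_violation` is the infinity norm of the same
residuals, in Gy.

## Objectives

All objectives operate on the dose restricted to one structure and are
normalized by the structure size, so values are comparable across
structures and runs (but not across other software with different
normalization).  Kinds: squared deviation, one-sided squared
overdose/underdose, mean dose, and the two DVH penalties.  The DVH quantile
`d_V` (dose received by the hottest V-fraction) uses the nearest-rank
convention on a descending stable sort: 1-based rank
`max(1, round(V * |S|))` with round-half-up.  `max_dvh` penalizes
`(d_i - dref)^2 / |S|` over voxels with `dref < d_i <= d_V` — the hot
voxels that can be cooled without changing the DVH at the prescribed
volume; `min_dvh` mirrors this over `d_V <= d_i < dref`.  During
differentiation `d_V` is treated as locally constant (the selection set
changes discontinuously; this is the conventional subgradient-style
choice), so the gradient is nonzero only on the penalized set.  The
composite objective computes the dose once per evaluation and chains the
per-voxel gradients back to intensity space through `A^T`.

## The superiorized loop

Iteration `k`: a perturbation phase, then one AMS sweep with weight scale
`eta^k`, then `k` increments; one history record (f, V, max violation, s,
k, elapsed) per full iteration.  Each of the `N` perturbations records the
phase-start value `f_start = f(x)` and proposes `z = x + beta * v` where
`v` is the normalized negative gradient (normalization makes
`beta = alpha^s` the actual step length, the standard superiorization
practice) and `s` grows after every proposal, accepted or not, so the step
sizes form a summable geometric series.  A proposal is accepted as soon as
`f(z) <= f_start`.  A zero gradient skips the perturbation.  The warm
start adds its increment (default 25) after the run's very first proposal:
that proposal still uses `beta = alpha^s0`, and all later exponents start
from `s0 + 25` — this matches the exact proposal sequence the acceptance
examples pin down, and keeps the whole-run bound
`sum(beta) <= alpha^s0 / (1 - alpha)` valid (exponents are distinct and
nondecreasing).  A safety cap of 10^4 proposals per perturbation guards
against pathological objectives; for the smooth objectives here a
sufficiently small step is always accepted long before that.

Stopping: both the relative change of `f` and of `V`, each measured as
`|x_{k+1} - x_k| / max(1, x_k)`, must stay below their tolerances
(defaults 1e-4 and 1e-3) for 3 consecutive iterations.  A negative
tolerance disables that part; if both parts are disabled, early stopping is
off entirely and the run ends on the iteration cap (default 500) or the
wall-time cap (default 3000 s).  Bare feasibility-seeking uses the same
machinery with the `f` part disabled and weight scale fixed at 1; with
`N = 0` or an all-zero-weight objective the superiorized iterate sequence
is bitwise identical to it under the same control sequence.

Defaults `alpha = 0.99`, `N = 5`, `lambda = 1`, `eta = 1` are the package's
own choices for desk-scale problems (stable and well inside the admissible
ranges); all are exposed in `SuperiorizationConfig`.  The default start is
the zero fluence — nonnegative and objective-neutral.

## Synthetic data

**Toy problems** draw a sparse nonnegative matrix (every row gets at least
one nonzero; entries uniform in [0.5, 1.5]) and a strictly positive witness
`x*`; slabs are `[<a_i,x*> - slack, <a_i,x*> + slack]` clipped at zero, so
feasibility is certified by construction.  Default conditions used by the
convergence studies: n = 200 voxels, m = 30 beamlets, 10% density, 0.5 Gy
slack.  Infeasible instances duplicate one row onto another and give the
pair disjoint slabs — unsatisfiable for any `x`, no external certificate
needed (the tests additionally confirm infeasibility with an LP).  When the
paired bare-vs-superiorized studies need an objective on these structureless
systems, they use the total mean dose over all voxels — the natural
"irradiate no more than needed" surrogate when no anatomy distinguishes the
voxels.

**The phantom** is a 64x64x1 grid at 2.5 mm spacing: C-shaped annular
target (radii 15–35 mm, 90-degree opening), central core disc (10 mm),
elliptical body (65 x 55 mm).  These dimensions are this package's
defaults, chosen to look like the classic commissioning geometry, not
claimed to match any published phantom's exact measurements.  Five
equidistant fields are discretized into 2.5 mm beamlets spanning the
target's projection plus margin (144 beamlets total); each beamlet
deposits `scale * exp(-mu * depth) * Gaussian(lateral; sigma)` inside the
body, with depth measured from the beamlet's body entry, `mu = 0.005/mm`,
`sigma = 3 mm`, and entries below 1e-4 of the beamlet maximum dropped.
This analytic kernel reproduces the *structure* of a pencil-beam dose
matrix (nonnegative, sparse, attenuated, laterally smeared) but none of
the physics of a validated engine — no scatter, heterogeneity, or beam
spectrum — so passing benchmarks on it demonstrates algorithmic behavior,
not clinical dosimetry.

**The packaged benchmark problem** keeps the prescription shape
(target slab around 60 Gy, core and body upper bounds, weights
1000/100/30) but derives the actual bounds from an explicitly constructed
witness: a nonnegative least-squares fluence pushing 60 Gy into the target
(with lightly weighted zero-dose rows for core and body), rescaled to a
60 Gy mean target dose, with each VOI's slab widened just enough (2%
margin) to contain the witness dose.  The problem is therefore feasible by
construction and runs against it measure convergence, not prescription
attainability under a crude dose model.

## Numerical choices and degenerate inputs

- Row norms are cached at matrix construction; zero rows are flagged,
  skipped by projections with a warning, and excluded from `V`.
- Serialization uses MatrixMarket coordinate format (1-based on disk) with
  17 significant digits and round-trip float parsing, so problems reload
  bitwise-identically.
- Empty structures are rejected by objectives and DVH computations;
  a slab with `l > u` or weights outside (0, 1] are rejected at
  construction with the offending voxel/VOI named.
- DVH curves use the ">= threshold" convention; the default dose grid is
  200 points from 0 to 1.1 times the maximum dose.
- Problem sizes in the tests and the acceptance script (toy systems of
  200x30, the 64x64 phantom with 144 beamlets, 500-sweep budgets) are the
  package's study conditions for desk-scale verification.

## Known limitations

- Linear per-voxel dose bounds only: no DVH *constraints*, no nonlinear
  constraint sets, no EUD/NTCP-type objectives.
- AMS is the only basic algorithm; simultaneous/block-iterative and
  string-averaging variants are out of scope.
- The dose model is analytic and 2D-slab by default (full 3D grids run
  through the same code path, just slower).
- On infeasible problems the iterates approach a limit cycle; `V`
  plateaus at a positive value but the approach can be from below with
  increments of order 1e-7 and shrinking — the stagnation rule, not strict
  monotonicity, is the reliable detector.
- No DICOM/CT import, no clinical dose engines, no deliverability checks.
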