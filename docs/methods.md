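# Methods

`cpmix` simulates a confluent epithelial monolayer of two cell
populations — motile and non-motile — competing for space on a 2-D
lattice, using a cellular Potts model (CPM) with a polarization–velocity
feedback, a Hill-saturated motile force, and stochastic division/death
with extrusion.

## Model

### Lattice and energy

Each cell is a set of pixels sharing an integer id; every pixel holds
exactly one id (no medium sites — the layer is confluent).  Boundary
dynamics are Metropolis-accepted id-copy attempts against the effective
energy

```
E = λ_area Σ_α (A_α − A0)²  +  λ_cont Σ_α L_α²  +  Σ_bonds φ(τ_i, τ_j)
```

with `A_α` the cell area (pixels), `L_α` its perimeter, and the adhesion
sum running over unordered 4-neighbor pixel pairs belonging to different
cells.  The perimeter is defined as the count of 4-neighbor bonds from a
cell pixel to a pixel of any other cell — wall pixels and the domain edge
count as "other".  This makes `L` an integer, makes the incremental
update of a copy attempt exact, and fixes a quantity the continuum
description leaves open.  Wall cells carry no area or perimeter terms.

An elementary step picks a uniformly random non-frozen site and a
uniformly random source pixel from its Moore (8-)neighborhood; if the
source id differs, the copy is accepted with probability
`min(1, exp(−ΔE/T))` (ΔE = 0 counts as the unconditional branch,
consistent with `exp(0) = 1`).  One Monte Carlo step (MCS) — the unit of
time — makes as many attempts as there are non-frozen sites.  Copy
attempts *from* frozen pixels are rejected, so wall ids can never leak
into the tissue.  Site draws are independent with replacement rather than
a shuffled raster, which avoids directional sweep artifacts.  Adhesion
and perimeter use the von Neumann (4-)neighborhood; both neighborhoods
are configurable.

Defaults (soft regime): `λ_area = 70`, `λ_cont = 0.5` (7 in the hard
regime), `φ = −10` between cells and `0` against the wall, `T = 50`,
`A0 = 100` pixels.

No connectivity constraint is enforced: the energy favors compact cells
but nothing forbids fragmentation, which matches the minimal model
definition; `fragmented_cells()` reports fragmented ids so the effect is
observable rather than silently ignored.

### Polarization and motile force

Each motile cell carries a polarization vector ρ with

```
dρ/dt = ζ v − γ ρ,        F = F_M (ρ/|ρ|) |ρ|^μ / (|ρ|^μ + β^μ)
```

where `v` is the center-of-mass velocity.  Defaults: `ζ = 1`,
`γ = 0.1 /MCS` (persistence time 10 MCS), `β = 1` (half-saturation:
`|ρ| = β` produces exactly `F_M/2`), `μ = 10` (a sharp on/off switch
between stationary and migrating states), `F_M` variable (1000 in the
headline runs).  `ρ = 0` is mapped to zero force, the continuous limit of
the Hill factor.

The ODE is integrated by one forward-Euler step per MCS after the copy
sweep (operator splitting), with `v` estimated as the com displacement
over the last MCS, unsmoothed — the simplest estimator consistent with
"velocity of the cell's center of mass".  Both the step `dt` and the
estimator are parameters.  Division and death reset ρ to zero; dead and
non-motile cells are pinned at ρ = 0.

### The motile work term

The force enters the dynamics as the work a candidate copy performs.
Two conventions are implemented (`MotilityParams.work_mode`):

* `"pixel"` (default): `ΔE_mot = −F · ŝ` with `ŝ` the unit step from the
  source pixel to the target pixel, summed over the (at most two) motile
  alive cells involved.  This is the convention CPM motility/external-
  potential plugins apply per copy attempt: every accepted boundary move
  along F is rewarded with a fixed energy, independent of cell size.
* `"com"`: `ΔE_mot = −F · Δr_com`, the literal differential of an
  `F · r_com` energy term.  Because `|Δr_com| ≈ r/A ≈ 0.05` pixels for an
  `A = 100` cell, this convention is weaker by a factor of order the cell
  area.

The default matters.  Under `"com"`, a cell pushed at `F_M = 1000`
drifts at only ~0.02 px/MCS, so the polarization fixed point
`ζ v/γ ≈ 0.2` lies far below the Hill half-saturation `β = 1`: the
migrating state cannot self-sustain and neither spontaneous polarization,
mixing, nor motility-driven invasion occurs anywhere near the standard
parameter set.  Under `"pixel"`, the same parameters produce the expected
phenomenology — spontaneous polarization (mean `|ρ| ≈ 3` ≫ β) and
streaming at `F_M = 1000` in the soft regime, no polarization at
`F_M = 0`, and polarized-but-confined cells at `F_M = 400` against hard
neighbors.  The sign convention (motion along F lowers the energy) is
fixed by the force's role of driving the cell in its direction;
`work_sign` can flip it for sensitivity checks.

Spontaneous polarization is a genuine collective instability here: with
ρ = 0 the force vanishes, so polarization must bootstrap from
boundary-fluctuation-driven com motion amplified by the ζv feedback and,
cooperatively, by neighbors dragging each other.  On the reduced domain
it ignites stochastically around 3000–8000 MCS; runs that classify
mixing therefore use the full 25000-MCS horizon.

### Division, death, extrusion

Per MCS, after the copy sweep and in this order:

1. **Division** — every alive cell with `A ≥ A0` divides with
   probability `B` (per type).  The pixel set is split by a line through
   the com perpendicular to the principal axis (from the exact second
   moments, maintained incrementally); pixels are ordered by signed
   distance along the axis and split at the median, so daughters get
   ⌊A/2⌋ and ⌈A/2⌉ pixels.  Daughters keep `A0`, start at ρ = 0, and
   regrow under the area term.  Degenerate splits retry with a random
   orientation.
2. **Death** — every alive cell dies with probability `M` (per type),
   independent of size; cells that divided this MCS are exempt (division
   and death are mutually exclusive within one MCS).  A dead cell gets
   `φ = 0, λ_cont = 0, A0 = 0` and `λ_area = 500`, so it is compressed
   out by its neighbors.
3. **Extrusion** — dead cells whose area has reached the threshold
   (default 0 pixels: fully shrunk) leave the registry; with a positive
   threshold the remaining pixels go to the neighbor sharing the longest
   boundary.
4. **Polarization update** (above).

A dead cell surrounded by a single, already-oversized neighbor can stall
at a few pixels, because the neighbor's quadratic area penalty grows
faster than the dead-area relief shrinks — in tissue context division
spreads the reclaimed space over many cells and extrusion completes in
tens of MCS (stationary dead fraction ~1% at `B = 0.1, M = 0.001`).

## Scenarios

The standard domain is a 302×150-pixel interior (the full-scale layout:
two 150×150 halves plus a 2-pixel frozen barrier column, which is exactly
450 cells of 100 pixels) wrapped in a 1-pixel frozen wall frame with
`φ(wall, ·) = 0`.  Each half is tiled with near-square seeds: rows of
equal-height bands, each band split evenly, giving seed areas within
~20% of A0 for non-divisible geometries and exact 10×10 squares for the
standard one.

Schedule: (1) `relax_mcs = 400` with motility off and no turnover;
(2) `polarize_mcs = 1600` with motility on behind the barrier — in
invasion runs turnover is already on here, so both sides reach their
equilibrium density before contact; (3) barrier removal at MCS 2000: each
barrier pixel joins the bordering cell with the longest shared boundary
(ties to the lowest id), restoring confluence instantly; (4) main run to
`total_mcs` (default 25000).  MIXING runs force `B = M = 0`, so per-type
counts are conserved exactly.  Invasion runs stop early once one type is
eliminated unless told otherwise.

All randomness flows from one `numpy` Generator consumed in a fixed
order (sweep arrays, division draws, death draws), so a config plus a
seed reproduces a run bit-exactly; the manifest records the resolved
configuration and output checksums.

## Analysis

* **Crossing count** Ñ(t): alive cells whose *every* pixel lies strictly
  on the opposite side of the midline from their type's initial side
  (the two barrier columns split evenly between the sides); a com-based
  variant is available as a sensitivity flag.  Dead cells are excluded.
* **Mixing class**: WELL_MIXED if `max_t Ñ_m(t) ≥ N_m/2`; NONE if the
  maximum is 0; PARTIAL otherwise.
* **Polarity loss**: first time after which the mean `|ρ|` of motile
  cells stays below `0.1 β` for the rest of the run and for at least
  5000 MCS (both parameters exposed); brief dips do not count.
* **Invasion speed**: `v = (ΔN/Δt) · L/ρ0` with `L = 1` the domain
  length, `ΔN/Δt` the least-squares slope of the winner's count from
  barrier removal until it first holds 75% of all cells (the "initial
  stage" of the invasion), and `ρ0` the time-averaged alive count of the
  invader filling the whole domain alone with its own turnover rates
  (second half of a single-type run).
* **Outcome**: a type wins when the other type's alive count reaches
  zero; COEXIST requires both occupancy fractions to stay inside
  [0.05, 0.95] throughout the final third of the run; anything else is
  UNDECIDED (run too short to call).
* **Phase sweeps** run a config grid with replicate seeds (spawned from
  one SeedSequence) and report per-run outcomes plus a per-point
  majority vote with a unanimity flag.

## Problem sizes and what the tests show

Full-scale phase diagrams are long runs (10⁴–10⁵ MCS on 302×150); the
statistical test suite reproduces the regime structure on a
geometrically similar 152×76 domain with 56 cells per type (same A0 and
density, five fixed seeds per condition): well-mixing at `F_M = 1000`
soft vs restricted mixing at `F_M = 400` against hard neighbors;
motile elimination of the non-motile type under identical turnover; and
the invasion reversal (initial motile advance, then collapse) when the
non-motile side has `B = 0.8, M = 0.003` against `B = 0.1, M = 0.005`.
The relaxation-phase and dead-fraction summaries run on the full domain
and the reduced domain respectively (see `scripts/acceptance.py`).

These runs share every mechanism with the full-scale system but not its
aspect ratio of timescales: crossing a 76-pixel half-domain is ~2× faster
than crossing 151 pixels, and 56-cell populations fluctuate relatively
more than 225-cell ones, so classification thresholds are exercised
closer to their boundaries than at full scale.  Passing them shows the
implemented mechanisms generate the right regimes and orderings, not
that any real epithelium behaves this way: the model has no chemotaxis,
no contact inhibition of locomotion, no explicit polarity signaling, and
its parameters are in lattice units without physical calibration.

## Numerical notes

* Integer bookkeeping: areas, perimeters, coordinate sums and second
  moments are int64 and updated exactly per accepted copy; a full
  recomputation reproduces the caches bit-for-bit (audited in tests).
* The initialization metric: cells are seeded at (or within ~2% of) the
  target area, and `λ_area = 70` against `T = 50` pins areas to ±1 pixel,
  so the mean relative area deviation sits below 1–2% from the start of
  the relax phase; shape equilibration is visible in the mean perimeter,
  which plateaus within a few hundred MCS.
* A cell whose last pixel is copied away keeps its registry entry with
  `A = 0` (alive cells essentially never reach this under the default
  stiffness; fully shrunk dead cells are extruded).
* Division on a 1-pixel cell is skipped; ties in the median split are
  resolved by stable coordinate order, making splits deterministic.
* Barrier pixels with no adjacent cell (interior of the 2-wide column)
  are assigned iteratively after their neighbors have been handed over.
* `minmax_x`/crossing scans run on sampling steps only (default every
  50 MCS).

## Limitations

* The motile work convention is a genuine model choice (see above); the
  com-based literal reading is retained as an option but does not
  produce motility-driven phenomenology at the standard parameters.
* Boundaries are solid walls; no periodic variant.
* Two types only; no parameter heterogeneity within a type.
* The velocity estimator at `dt = 1` MCS is noisy; smoothing would shift
  the spontaneous-polarization threshold.
* Spontaneous polarization ignition is a rare-event process on small
  domains; its timing varies by thousands of MCS between seeds.
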