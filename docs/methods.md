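# Methods

This note records the models, algorithms and numerical choices behind
microER, and what its synthetic benchmarks do and do not demonstrate.

## Scope and coordinate conventions

Everything lives in an orthogonal P1 cell; fractionalization is division
by the three cell edges.  Structures are minimal fixed-format PDB (read
and written through gemmi), with the secondary-structure assignment
carried as input metadata in the segment column (or a sidecar mapping, or
defaulted to one element per chain) — it is never computed from geometry,
because the hierarchical partitions are a modelling choice, not a derived
property.  Reflection data are plain delimited tables
(`h k l fobs sigma free`).

## TLS mathematics

A TLS group (translation T in Å², libration L in rad², screw S in Å·rad,
origin at the group centroid) gives an atom at offset r from the origin
the anisotropic displacement parameter

    U(r) = T + A L Aᵀ + A S + Sᵀ Aᵀ,     A w = w × r,

which is the covariance of u = t + w × r for zero-mean translation
t ~ T, rotation vector w ~ L and cross-moment S = E[w tᵀ].  The isotropic
equivalent is B = (8π²/3)·tr U.  T and L are symmetric PSD; S is stored
trace-free (U is invariant under S → S + cI, so the trace is a gauge).
The implementation is validated against brute-force rigid-body ensembles
(sampling the joint 6×6 covariance and accumulating displacement
covariances) to better than 5% relative error at 10⁵ samples.

## The pTLS baseline

Per chain: take the marker atoms (default: atoms named CA), keep the
fraction p with the smallest B (ties broken by atom order), fit one TLS
group to those isotropic B values, and evaluate it for *every* atom of
the chain.  The extrapolation is the point: on structures whose disorder
is dominated by sub-chain motions the single quadratic surface exceeds
the true B of the least-disordered atoms.  Fits parameterize tr T = a²
and L = CCᵀ (Cholesky factors as free parameters) so PSD-ness holds by
construction; a B-profile target cannot identify more than tr T, so the
returned T is isotropic, and S is fixed at zero (only the antisymmetric
part of S would enter tr U, and a profile fit cannot constrain the joint
PSD-ness that makes a screw moment physical).  Degenerate groups (≤3
atoms, or rank-deficient geometry) freeze L at zero.

## The hierarchical disorder fit

One TLS group per hierarchy node at each level (chain /
secondary-structure / residue), fitted jointly to the per-atom isotropic
B profile:

1. **Penalized joint fit.**  Objective = Σ_atoms (B_target − Σ_levels
   B_level)² + l1·Σ_g w_g·amp_g + l2·Σ_g w_g·amp_g² + hinge, where amp_g
   is group g's mean B over its own atoms (non-negative, so the l1 term
   is smooth) and w_g weights each group by its atom fraction with a 5%
   extra cost per level of depth.  The weighting makes every level pay
   the same price for explaining the same per-atom B — without it, a
   coarse group can carry the lower envelope of a finer level's profile
   at a fraction of the cost and the decomposition collapses toward the
   chain level.  The hinge term max(0, Σ − B_target − tol)² (weight
   escalated ×10 until satisfied) enforces the physical bound.
2. **Backward level pruning.**  Finest level first, each level is
   tentatively clamped to zero and the survivors refit; the level is
   dropped if it explained less than 8% of the profile variance beyond
   the others (or if the remaining misfit is below 0.5% of Σ B².)  Flat
   or shared components are genuinely expressible at any level of an
   isotropic profile; pruning assigns them to the coarsest level that
   carries them exactly, which is the parsimony the hierarchy is for.
3. **Debiased refit.**  Surviving levels are refit without the
   elastic-net terms (relaxed-lasso style), so the returned amplitudes
   are not shrunk by the selection machinery.
4. **Hard bound projection.**  Any residual per-atom excess over
   B_target + 0.01 Å² is removed by scaling down the touching groups
   (parameters scale as √factor since B is quadratic in them).

Level contributions are non-negative by construction (the libration
design matrix |r|²I − rrᵀ is PSD), exactly additive across levels, and
bounded by the total B at every atom.  On single-layer synthetic
fixtures (500 conformers) the fit returns the generative layer within
10% with no leakage; this identifiability depends on the toy structure's
geometry being non-degenerate (see below).

## Structure factors and the time-averaged target

Direct summation with constant per-element form factors (electron
counts); B in the Debye–Waller exponent is the atomic B plus, when a
disorder model is supplied, its per-atom contribution.  Ensembles are
scored with the mean of member structure factors (exact for uniform
weights).  The X-ray residual is a least-squares amplitude target on the
work reflections with a fitted overall scale k,

    T = WX · Σ_work (|F_obs| − k|F̄_eff|)² / Σ_work |F_obs|²,

with F̄_eff = ρF̄ + (1−ρ)F_calc(x).  Only the instantaneous term is
differentiated; because k sits at its least-squares optimum its implicit
x-dependence contributes nothing (envelope theorem), so the analytic
gradient matches finite differences of the full expression to 1e-5.
Free reflections never enter the target, the gradient, or the scale.
R factors are Σ||F_obs| − k|F_model|| / Σ|F_obs| per set, with k fitted
on the work set only.  No bulk solvent, no anisotropic scaling, no
likelihood weighting: the restraint machinery, not the likelihood, is
under study, and the least-squares form keeps every gradient testable
against finite differences.

## DEN restraints

A seeded random subset (default one per atom) of atom pairs within 8 Å
and at least 2 residues apart, each restrained harmonically to an
adaptive reference distance: E = weight·Σ(d − d_ref)².  Per triggered
update, d_ref moves by κ·[γ(d_now − d_ref) + (1−γ)(d_init − d_ref)]
(defaults γ=1, κ=0.1: fully adaptive, slow drift).  Every
`reselect_interval` macrocycles (default 500) a random 20% of the pairs
is replaced by fresh candidates so the initial pair choice cannot bias
the sampling; the reselection draw is seeded by (seed, macrocycle), so
histories are reproducible.

## The ensemble-refinement engine

One macrocycle = 40 BAOAB Langevin steps (2 fs-equivalent timestep, in
kcal/mol–Å–ps–amu units).  At each macrocycle boundary the engine
accumulates F_calc into the rolling average, scores R_work/R_free from
the scaled |F̄|, and runs the DEN update/reselection schedule; within a
macrocycle all forces (geometry, DEN, X-ray) are re-evaluated each step
and applied velocity-Verlet-consistently.  An earlier variant that held
the X-ray force constant across a step integrated that component
explicit-Euler style and pumped energy through the F̄ lag until the
structure melted — the per-step refresh is load-bearing.  Because |F| is
invariant under rigid translation, centre-of-mass motion is removed each
step (standard MD practice); rotation is restrained by the data itself.
The simulated structure carries zero atomic B: all modelled disorder
enters through the input disorder model, and the rest must be sampled —
exactly the division of labour the disorder-model choice controls.

The toy force field is intra-residue bond cliques (every within-residue
pair, k = 300 kcal mol⁻¹ Å⁻²) plus the 4 closest cross-pair links
between consecutive residues and a soft-core repulsion below 2.2 Å,
with ideal values taken from the input structure.  Residues are
therefore semi-rigid and the chain hinge-flexible — a deliberately
minimal stand-in whose unrestrained minimum is the starting model.
Snapshots are collected after a 20% burn-in; the final score uses the
ensemble-averaged F over snapshots, uniformly weighted.  RMSF is the
per-atom RMS deviation from the snapshot mean (no superposition — COM
removal already holds the frame), and B_equiv = 8π²·rmsf²/3.

Default operating point: T = 5 K (reduced units), friction 10 ps⁻¹,
`xray_energy_scale` 5000 kcal/mol per unit of the normalized target at
WX = 1, TX = 8 macrocycles.  The scale converts the dimensionless
least-squares target into the engine's energy unit — the bridge for the
open question of what units WX carries — and was set, together with
temperature and friction, so that the restrained dynamics *equilibrates*:
too strong a coupling (or too little damping) turns the F̄ lag into a
positive feedback that stirs the structure instead of holding it.  With
this operating point the sampled fluctuations match the disorder missing
from the input model, which is the regime the method is meant to work in.

## The synthetic-crystal generator

The toy polymer is an L-shaped fold: secondary-structure segments of
twisted residues whose axes alternate between +z and +y, with atoms at
fixed offsets of varied radius *and* varied axial/equatorial direction.
Both irregularities are essential for identifiability: with atoms
equidistant from the residue centre, residue libration produces a flat
per-residue profile indistinguishable from translation; with all offsets
sharing one axial fraction, a group-level libration about the segment
axis reproduces the intra-residue pattern exactly; and with straight,
mutually-translated segments the chain- and SS-level quadratics become
linearly dependent.  The L-shape keeps the chain centroid away from
every segment middle, so each level's isotropic B signature is distinct.

Disorder layers are applied per conformer in order: residue libration,
SS rotation, chain rotation + translation, atomic jitter.  Rotations
draw a uniform axis and an angle ~ N(0, σ) (σ capped at 0.3 rad with a
warning; the small-angle covariance σ²(|r|²I − rrᵀ)/3 underlies the
analytic truth decomposition, B_rot = (16π²/9)σ²|r|²).  Reflections are
|mean F| over the conformers to d_min = 2.3 Å with optional
multiplicative noise and seeded free flags.  The "classically refined
input model" is emulated by the base coordinates carrying
variance-derived B factors — refinement itself is out of scope, which
means the input-model B factors are noiseless-in-expectation and carry
only Monte-Carlo error, a kindness real refinement does not offer.

Standard conditions: σ_chain_trans = 0.10 Å, σ_chain_rot = 0.03 rad,
σ_ss_rot = 0.15 rad, σ_res_lib = 0.25 rad, σ_atom = 0.10 Å, 300
conformers, 2% amplitude noise, 10% free set.  Fine-scale layers
dominate (mean B ≈ 13 Å², range ≈ 3–27 Å²), which is the regime where a
single chain-level TLS surface must overestimate the core — the
pathology under study.  With chain-dominated disorder the pTLS model is
close to correct and the methods hardly differ; that regime is exercised
by the single-layer fixtures instead.

## What the benchmarks show — and what they do not

Passing tests show that the machinery behaves as designed on crystals
whose disorder is exactly layered rigid motion, whose geometry is known,
and whose data are near-noiseless amplitudes from the true ensemble.
They do not show performance under real force-field error, model
incompleteness, solvent, experimental-noise models, space-group
symmetry, or anisotropic scaling — all deliberately out of scope.  The
R_free gap between the hierarchical and pTLS models (≈ 0.02–0.03 here)
is a toy-scale analogue of the marginal differences reported for real
structures, not a quantitative prediction.

## Numerical choices and degenerate inputs

* Bound tolerance 0.01 Å²; elastic-net weights (1e-3, 1e-5) of the data
  scale; hinge escalation ×10 up to 6 rounds; L-BFGS-B with analytic
  gradients throughout (the Cholesky saddle at C = 0 is avoided by
  seeding the factors at 0.02).
* pTLS subset ties break by atom order; all-equal-B targets return the
  pure-translation solution.
* Zero-disorder targets return all-zero amplitudes without optimization.
* Empty DEN candidate sets yield a valid inert network; reselection
  shrinks the network if candidates run out.
* Integration guards abort on |force| > 1e5 kcal mol⁻¹ Å⁻¹ or
  |velocity| > 1e4 Å ps⁻¹, naming the macrocycle.
* Sweep ties break toward smaller TX, then smaller WX; failed runs are
  recorded and excluded from the argmin.
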