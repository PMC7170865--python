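# Methods

`partikin` simulates cell-signalling reaction networks as individual
molecules (agents) undergoing Brownian motion and proximity-triggered
reactions in a reflective box, and pairs every such model with an
automatically generated deterministic mass-action ODE twin so the two
descriptions can be compared quantitatively.

## Particle dynamics

Each agent moves by a Gaussian random walk: per substep of length
Δt_diff, each coordinate receives an independent Normal(0, σ²) increment
with σ = √(2 D_T Δt_diff), where D_T is the species' translational
diffusion coefficient (m² s⁻¹). Soluble species move in 3D; membrane
species are pinned to the z = 0 face of the box and move in-plane (their
z-step is identically zero). All six box faces are reflective: a
proposed coordinate is folded back into [0, L] by the triangular-wave
map x → |((x mod 2L) − L)| mirrored about L, which is exact for steps of
any length, including steps longer than the box.

The engine's default normal sampler is NumPy's `Generator.standard_normal`
(ziggurat); a polar Box–Muller implementation is included and tested as
the reference sampler. The step contract is distributional, so any exact
standard-normal sampler is admissible.

**MSD accounting.** For diffusion validation the engine accumulates each
agent's *pre-reflection* squared step displacements. The time-normalised
cumulative sum Σ(Δx² + Δy² + Δz²)/t converges to λD with λ = 2·dim
(6 in 3D, 4 in-plane), and dividing by λ recovers D. Pre-reflection
accounting is a deliberate choice: the per-step sum of *reflected*
displacements inside a 3 μm box would saturate at the confinement scale
over minutes-long runs, whereas the free-walk sum is unbiased for D at
all times. The boundary treatment therefore does not influence the MSD
estimate, only the positions used by the reaction kernels.

## Reaction kernels

One reaction step (Δt_rxn, an exact integer multiple of Δt_diff,
default 0.05 s vs 1e-4 s) applies, in this fixed order:

1. **Second-order reactions** on end-of-step positions. A pair reacts
   when separated by less than an interaction distance d_i chosen so the
   swept interaction volume (or area) reproduces the mass-action rate:

   * soluble–soluble (spherical V_i):
     d_i = (3 k_f Δt / (4π·10³·N_A))^{1/3}
   * membrane–soluble (hemispherical V_i above the membrane; distances
     measured in 3D, the soluble partner is always in the upper
     half-space): d_i = (3 k_f Δt / (2π·10³·N_A))^{1/3}
   * membrane–membrane (disc A_i, in-plane distances): with k_f in
     M⁻¹ s⁻¹ the constant is first scaled by the surface-to-volume
     ratio, k_f′ = k_f·A_C/V_C, giving
     d_i = (k_f·A_C·Δt / (π·10³·V_C·N_A))^{1/2}. A density mode with
     k_f in m² s⁻¹, d_i = (k_f Δt / (π·10³·N_A))^{1/2}, is available
     behind an explicit `density` flag; its 10³·N_A factor is
     dimensionally questionable, so molar mode is the default.

   When several candidate pairs compete, proximity decides: candidates
   from *all* second-order reactions are accepted greedily in ascending
   distance (ties: lower agent id, then reaction order), each agent in
   at most one pair per step. This is implemented with k-d trees and is
   tested for exact equivalence against an O(N²) search. A+A reactions
   are supported with unordered pair counting.

2. **First-order reactions** (degradation, dissociation, catalysis, and
   the reverse leg of reversible reactions) on agents not consumed this
   step, each firing with the exact per-step probability
   P = 1 − e^{−k Δt_rxn}. Reactions draw in model order; with several
   channels on one species the combined per-step conversion
   1 − Π(1 − P_i) matches the additive rates of the ODE twin to first
   order, and all defaults keep k·Δt ≪ 1.

**Product placement.** Association products appear at the first-listed
reactant's position (for membrane–soluble reactions the membrane
reactant is canonically first, so membrane complexes stay at z = 0);
unimolecular conversions preserve position; two-reactant/two-product
conversions map product i to reactant i's position. On dissociation the
first product keeps the complex position and the second is displaced by
the unbinding distance d_u = 4 d_i of the corresponding association
reaction (d_u = 0 when none exists), in a uniformly random direction on
the admissible manifold — in-plane for membrane products, upper
hemisphere when leaving a membrane species, full sphere otherwise —
then reflected into the box. The enforced separation d_u > d_i prevents
immediate re-association of the fragments (geminate recombination).

Each agent participates in at most one event per reaction step, and
agents created within a step first react in the next step.

## Concentrations and initial states

All concentrations, including those of membrane species, are referred
to the fixed box volume V_C. Initial counts are
round(c0 · 10³ · V_C · N_A) — deterministic round-to-nearest rather than
stochastic rounding, since reproducibility outweighs the sub-molecule
bias at the counts used (≈1626 agents per 100 nM in the default
3 μm × 3 μm × 3 μm box). Soluble agents start uniform in the box,
membrane agents uniform on the z = 0 face. A single PCG64 generator
drives placement, diffusion and reaction draws, so one seed reproduces
a run bit for bit.

Model building warns (never errors) when d_i exceeds 10% of the
smallest box edge or when the expected number of partners per agent per
step, c·10³·N_A·V_i, exceeds 1 — both signs that Δt_rxn should be
reduced for the requested kinetics.

## ODE twin

`build_ode_system` expands the same network into mass-action channels
(k[X] for first-order, k_f[A][B] for second-order, both legs for
reversible) with net stoichiometry, and integrates with LSODA at
rtol 1e-8 on exactly the ABM record grid. Membrane reactions use the
molar k_f directly on volume-referenced concentrations; the k_f′
surface scaling exists only inside the particle engine's
membrane–membrane d_i, so both models live in the same concentration
space.

## Validation metrics

* **MSD diffusion recovery** — as above; tested to recover
  1.00/4.99/9.99 μm² s⁻¹ for inputs 1/5/10 μm² s⁻¹ over 5 simulated
  minutes at Δt = 1e-4 s.
* **ABM:ODE score** — the mean over sampled times of the ratio of
  product concentrations ABM/ODE (ideal value 1), sampled every 0.05 s
  for 5 min or until reaction completion. Two stabilising parameters
  are package choices with explicit defaults: completion is the first
  time the ODE limiting reactant falls below 0.5% of its initial value,
  and points where the ODE product is below one molecule-equivalent
  (1/(10³·N_A·V_C) M) are excluded so the earliest ratios stay finite.
* **R²** — 1 − SS_res/SS_tot with the ODE series as reference (the
  denominator is the ODE variance), matching the "agreement with the
  ODE" semantics.
* **Parallel-scaling arithmetic** — theoretical runtime(N) =
  runtime(1)/N, speed-up = runtime(1)/runtime, efficiency =
  speed-up/N·100%. These are pure formulas over user-supplied runtimes;
  the package itself runs single-process, and distributed execution is
  out of scope.

## The apoptosis execution fixture

The packaged model covers post-MOMP apoptosis execution: the
apoptosome (Apop) reversibly binds pro-caspase-9 (PC9) and activates it
to C9; C9 — and its C3-cleaved form C9P, which XIAP cannot inhibit —
convert PC3 to C3; C3 cleaves C9 to C9P (positive feedback) and cleaves
a FRET-substrate proxy; XIAP reversibly binds C3 and C9 and degrades
the bound caspase; SMAC binds XIAP and breaks up both caspase–XIAP
complexes; every signalling protein turns over slowly. That is
14 species and 23 reactions (4 reversible bindings, 1 activation,
3 catalytic conversions, 2 XIAP-mediated degradations, 2 SMAC-mediated
breakups, 1 substrate cleavage, 10 basal degradations), enforced as
structural invariants, with per-species monomer composition maps used
by mass-balance tests.

The rate constants and concentrations shipped in
`src/partikin/data/` are *representative literature-scale values*, not
a published parameter set: nanomolar-affinity bindings at
1e6–7e6 M⁻¹ s⁻¹, catalytic conversions at 1e6–3e6 M⁻¹ s⁻¹, complex
turnover at ~1e-3 s⁻¹, basal degradation at 5.7e-5 s⁻¹ (half-life
≈ 3.4 h), and initial concentrations Apop 100 nM, PC9 20 nM, PC3
200 nM, XIAP 300 nM, SMAC 400 nM, substrate 500 nM, giving 24,715
agents in the 3 μm box. The files are plain text precisely so measured
values can be substituted verbatim. The ABM-vs-ODE agreement this
package tests is parameterisation-independent: it checks that the
particle kernels reproduce whatever mass-action kinetics the network
defines, not a particular published trajectory.

## Problem sizes and numerical choices

* Benchmark runs use the 3 μm box with reflective walls, membrane on
  the bottom face, Δt_diff = 1e-4 s, Δt_rxn = 0.05 s, 5 simulated
  minutes, soluble D = 30 μm² s⁻¹, membrane D = 0.3 μm² s⁻¹.
* The bimolecular score benchmark in the test suite and acceptance
  script coarsens Δt_diff to 1e-3 s (rms substep ≈ 0.25 μm still mixes
  the box well between reaction steps); the apoptosis run coarsens it
  to 0.05 s (rms step ≈ 1.7 μm, of order the box, i.e. near-perfect
  mixing per reaction step). Both choices keep a full run in the
  minutes range on one core without touching the reaction time base.
* ODE integration: LSODA, rtol 1e-8, atol 1e-10·max(c0); solutions are
  clipped at zero (solver noise can undershoot by less than atol).
* Ties in pair matching are broken on (distance, lower agent id,
  higher agent id, reaction index); candidate separation uses a strict
  `< d_i`.
* Degenerate inputs: zero rate constants give P = 0 and d_i = 0 (no
  events); zero-agent models warn and produce an empty initial state;
  duration 0 records only the initial counts row.

## What the synthetic scenarios do and do not show

The benchmark generators emulate the idealised, well-mixed conditions
under which mass-action kinetics are the ground truth: uniform initial
distributions, simple box geometry, dilute point particles. Passing
tests therefore demonstrate that the kernels reproduce mass-action
kinetics and the targeted statistics under those conditions. They do
not probe crowding, excluded volume, diffusion-limited or
compartmentalised regimes, anomalous diffusion, or membrane curvature —
all explicitly out of scope (the proximity kernels are known to need
smaller time steps or collision-rate corrections in such regimes).
Wall-clock parallel performance is likewise out of scope; only the
scaling arithmetic is implemented.

## Known limitations

* First-order channels on a shared species are drawn sequentially in
  model order rather than as competing exponentials; the bias is
  O((kΔt)²) and negligible at the shipped parameters.
* Second-order kinetics carry a forward-Euler-like discretisation error
  of order k_f·c·Δt_rxn per step (≤ 0.14 at the fastest shipped
  binding); reduce Δt_rxn for faster reactions.
* Membrane species never unbind from the membrane, and no reaction may
  move mass through the membrane plane.
* The spatial index rebuilds per reaction per step; models with very
  many dense second-order reactions pay that cost linearly.
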