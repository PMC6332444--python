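# Methods

`sasmd` is a desk-scale simulator for self-adaptive steered molecular
dynamics (SA-SMD): constant-velocity harmonic pulling of a ligand whose
pulling direction is periodically re-optimized by minimizing the windowed
average pulling force. The all-atom machinery that the method was designed
for (explicit solvent, force fields, counterions) is replaced by a
surrogate: a point ligand on a closed-form anisotropic binding-funnel
energy surface, propagated with overdamped Langevin dynamics. The
surrogate preserves exactly what the control algorithm consumes — energies,
gradients, forces, and a separation coordinate — so the method itself (the
steering potential, the trigger, the direction optimizer, and the entropy
genetic algorithm) runs unmodified at full fidelity while each pull costs
seconds instead of CPU-days.

## The steering model

The ligand at position R(t) is coupled to a constraint point moving at
speed v along the unit direction n through the potential

    U_s = 1/2 k [ v t − (R(t) − R(0)) · n ]²

giving the force k·x·n with scalar extension
x = v (t − t_start) + x_offset − (R − R_ref)·n. The logged "pulling
force" is the signed scalar k·x (projection on the current direction), so
overtaking events carry a sign. When the direction switches, the new
segment resets R_ref and the segment clock to the switch point and carries
the accumulated extension in x_offset, which makes |force| exactly
continuous across switches; without this, artificial spikes would corrupt
both the trigger and the optimizer's objective. Force averages are taken
over non-overlapping windows of length T = 1 ps aligned to each segment's
start (trailing partial windows dropped); the **rupture force** of a run is
the maximum windowed average, ties resolved to the earliest window.

Defaults follow the standard protocol for this class of experiment:
k = 200 kJ·mol⁻¹·nm⁻², v = 0.002 nm/ps, dt = 0.002 ps (2 fs), T = 1 ps,
trigger interval t₀ = 5 ps, trigger force f₀ = 250 pN, termination when
the ligand separates 0.6 nm beyond the binding-site envelope. Internal
units are kJ/mol, nm, ps; forces convert to pN via
1 kJ·mol⁻¹·nm⁻¹ = 1.66054 pN.

## Direction optimization

A candidate direction is parameterized by nutation θ ∈ [0, π/2] and
precession φ ∈ [−π, π] about the *initial* direction n₀ (the hemisphere
around n₀; the φ = 0 axis is the component of the world x-axis orthogonal
to n₀, for reproducibility). An optimization fires at time t when both
(t − t_last) > t₀ and the trailing 1-ps mean force exceeds f₀. The
objective of a candidate is the mean scalar pulling force over a trial
segment of length T simulated forward from a checkpoint of the running
state. Three reproducibility rules:

- **Common random numbers.** Every trial restores the checkpoint's
  generator state, so all candidates are scored on the identical noise
  realization; candidates are propagated as one batched integration
  sharing one noise draw per step, which is equivalent and fast.
- **Re-simulation.** Trial trajectories are discarded; after the winning
  direction is adopted the main trajectory continues from the checkpoint
  on the main stream (which, by construction, replays the winner's noise
  during the first T).
- **Reference candidates.** n₀ itself (θ = 0) and the current direction
  are always evaluated besides the GA's candidates, so the adopted
  direction is never worse than keeping course, and the reported
  objective always equals the trial force of the chosen direction.

With f₀ = ∞ the trigger never fires and an SA-SMD run is bit-identical to
the conventional (fixed-direction) run at the same seed — the C-SMD driver
is literally the same loop with the trigger disabled.

A consequence of the 1-ps horizon worth knowing: the objective rewards
*compliance*, so from a stuck state the first switch typically points into
the azimuth of the easiest exit but at a larger nutation than the exit
channel itself, and several trigger/switch cycles complete the escape.
This is what produces the longer, more tortuous dissociation pathways of
the adaptive runs. It also means the measured rupture force can never
stay far above f₀ when *any* compliant direction exists: the rupture
force "pegs" at roughly f₀ plus the ramp overshoot, which is exactly why
the cut-off-force sweep flattens at low f₀.

## The entropy genetic algorithm

The optimizer is a real-coded multi-population GA: m = 16 populations
share the design box; after each generation the per-population best
fitnesses F_j are mapped to occurrence probabilities p_j (softmax of
negated, per-generation standardized fitnesses at temperature 0.25 —
shift-invariant, uniform for ties, concentrating on the best in the
large-gap limit; a pure rank rule is available), and each population's box
contracts around its best member:

    E(K) = (1 − p_j) E(K−1)
    lower = max(best − 0.5 (1 − p_j) E(K), initial lower)
    upper = min(best + 0.5 (1 − p_j) E(K), initial upper)

so no bound ever leaves the initial design space and members falling
outside are re-drawn uniformly inside. The coupled problem
{min Σ p_j F_j, min H = −Σ p_j ln p_j} has the same optimum as
min_j F_j; its weighted scalarization w₁ Σ p F + w₂ H (defaults 1.0, 0.1)
is recorded per generation as a convergence diagnostic. Both entropy
objectives are minimized; this sign choice is what preserves the
equivalence with the direct minimum. Genetic operators are standard
(tournament of 2, blend crossover, Gaussian mutation with σ = 0.1 × the
current per-variable extent, elitism of one); standalone defaults are
pop_size 20 and 25 generations with early stopping, while the embedded
optimizer inside a pulling run uses pop_size 4 × 3 generations ≈ 192 trial
segments per optimization.

## The dynamics engine

Overdamped (inertialess) Euler–Maruyama:

    Δr = (f_ext − ∇U) Δt / γ + sqrt(2 k_B T_K Δt / γ) ξ

with one standard-normal 3-vector ξ per step. Defaults γ = 50
kJ·mol⁻¹·nm⁻²·ps and T_K = 300 K, giving a well relaxation time γ/k_well
of a fraction of a picosecond — far below t₀ = 5 ps, so the ligand is
diffusively equilibrated between direction updates. The engine is
validated against closed forms: equipartition variance k_B T/κ within
10 %, and a Kolmogorov–Smirnov test of 10⁵ thinned harmonic-well samples
against the exact Gaussian. Checkpoints capture position, time and the
full generator state and restore bit-exactly (property-tested over random
step counts, including a JSON round trip to disk). The hot loops are
numba kernels; the generic `step()` uses the same update for any
landscape object.

## The synthetic landscape

For displacement w = r − c, d = |w|:

    U = −D exp(−d²/2 s_w²)                        binding well
      + B(u) S(d)                                 barrier shell
      + A G(d) Π_{i open} (1 − g_i(u))            guide wall

with angular channel factors g_i(u) = exp(κ_i (cos a_i − 1)), barrier
modulation B(u) = B_bg − Σ (B_bg − B_i) g_i(u), a Gaussian radial shell
S(d) at radius d_b (regularized to vanish at the centre so the minimum
sits exactly at c), and a guide-wall profile G(d) spanning the cleft
(radii ~0.25–1.1 nm). Everything is analytic; gradients are exact
(finite-difference checked at relative 10⁻⁴).

The guide wall is the design element the surrogate needs that a naive
"well + modulated shell" lacks. The 1-D spring constrains only the
pulling projection, so the ligand diffuses freely in the two lateral
directions; any angular soft spot visible from the bound state is then
found *passively* by a fixed-direction pull within tens of picoseconds,
and direction optimization would have nothing to add. The wall models the
steric confinement of a real binding cleft: it holds the ligand on the
approach channel (flagged `guide_open`) at all radii, while an easy exit
that is *not* flagged open is cryptic — its depressed shell barrier hides
behind the wall, unreachable by thermal drift but reachable by a
re-directed pull that pushes over the wall's edge. Constraint to respect
when designing landscapes: guide_amp + B_cryptic < B_open, so the cryptic
route is still the cheaper exit overall.

Three reference systems ship with the package:

- **standard**: approach channel along +z (barrier 70 kJ/mol, width 0.3
  rad, open), cryptic channel 45° off (+x half-plane, barrier 8, width
  0.2), background 100, wall 35, well 30 × 0.3 nm, shell at 0.8 × 0.15 nm.
  Conventional pulls rupture near 360 pN through the axial barrier;
  adaptive pulls escape through the cryptic notch near 250 pN.
- **family**: one open axial channel (barrier 10, width 0.4), background
  60, wall 20, narrow well (0.10 nm) of depth 20–60 kJ/mol across members
  (reference energy = −depth), small seeded jitter (0.03 rad / 3 %) on the
  shared geometry. The narrow well makes well escape the dominant,
  depth-graded rupture contribution, so mean rupture force ranks members
  by depth (Pearson |r| ≈ 0.95–0.99 over 8 members × 4 repeats).
- **rate-study**: a family-style funnel (depth 45) with friction
  γ = 2000. At γ = 50 the surrogate is quasi-static at both standard
  pulling speeds and rupture is measurably v-independent; real solvated
  systems at these speeds are not. The higher friction puts the pulled
  transport in the drag-sensitive regime, where 0.005 nm/ps yields a
  mean rupture force ~10 pN above 0.002 nm/ps with small seed-to-seed
  scatter.

"Separation" — the termination coordinate standing in for the minimum
receptor–ligand atom distance — is the distance beyond a spherical
binding-site envelope (default radius = the shell radius); a point ligand
has no atoms.

## What the surrogate does and does not show

Passing experiments on these landscapes demonstrate that the *control
algorithm* behaves as designed: the trigger fires exactly when specified,
the optimizer reliably finds more compliant directions under common random
numbers, adaptive pulls rupture at lower force and take longer paths when
a cheaper exit exists off-axis and do nothing harmful when the easy exit
is already aligned, switch counts and rupture forces respond to f₀ in the
expected directions, and rupture force ranks binding depth within a
family. They do not validate force-field accuracy, solvent effects,
ligand flexibility or rotational degrees of freedom, absolute force
scales, or transferability of the rupture-force/affinity correlation
across families — the slope of that correlation is protocol-dependent
here just as it is in the all-atom setting.

## Numerical choices and edge cases

- Seeds: every run derives independent engine and GA streams from one
  integer via `SeedSequence`; experiments derive per-run seeds from the
  experiment seed and run indices. Everything re-runs byte-identically.
- Windows: T must be an integer multiple of dt; the trigger's trailing
  window is a running mean of the last T/dt raw samples, updated every
  step, and is part of the checkpoint bookkeeping so re-simulated
  segments see consistent history.
- Ties: rupture force takes the earliest maximal window; probability
  updates average ranks over exact fitness ties.
- Non-finite GA fitness values are replaced by the generation's worst
  finite value and counted in the history.
- Degenerate narrowing (p_j = 1) collapses a population's box onto its
  best member, clamped to the initial space.
- Runs that reach max_time (default 6000 ps of pulling) without
  separating are flagged `unbound = False`; their rupture force is still
  the profile maximum. At low f₀ the adaptive controller can wander
  (myopic evasion), so a few timeouts per sweep are expected.
- The hemisphere is anchored at the fixed initial n₀ by default;
  `recenter_hemisphere=True` re-centres it on the current direction at
  each optimization instead.

## Problem sizes

The shipped experiments are sized for interactive use: 5 seeds per
condition in the mode comparison and sweeps, 8-member families with 4
repeats, ≈ 190 trial segments per direction optimization, pulls of
0.5–6 ns of simulated time. All analyses recompute from scratch in
minutes on one CPU core.
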