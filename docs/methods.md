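# Methods

`ringseg` simulates the segregation of two circular chromosomes confined in
a spherical vesicle, as a minimal physical model of nucleoid individualization
in a dividing *Sulfolobus*-like cell.  This note records the model, its
parameters, the numerical choices, and what the desk-scale defaults do and
do not represent.

## Model

Each chromosome is a ring of `N` beads (diameter σ, the length unit) joined
by harmonic springs, moving by overdamped Brownian dynamics inside a rigid
sphere of radius `R`.  Energies are in units of kT, friction γ = 1, so the
time unit is τ = γσ²/kT.  `R` is set from the DNA volume fraction φ by
counting bead volume as (π/6)σ³: `R = σ (n_total / 8φ)^{1/3}`.

Interactions (all bounded and C¹, so forces are finite everywhere):

* **Soft-core repulsion** `U_rep(r) = E_cross (1 + cos πr/σ)` for `r < σ`.
  The finite barrier (2·`E_cross` at contact) lets two DNA strands pass
  through one another at an activated rate — a coarse stand-in for
  topoisomerase-II strand passage.  Default `E_cross = 5 kT`: crossings are
  rare but not forbidden; a driven bead passes a blocker only when pushed
  harder than the force cap π·`E_cross`/σ.
* **Compaction attraction**: a plateau-bottomed cosine well, depth ε(t),
  range `r_att = 1.5σ`, flat at −ε below σ (continuity with the soft core).
  ε(t) ramps linearly from 0 to `eps_max = 1 kT` during the compaction
  phase.  1 kT per contact with ~10 contact neighbors in a collapsed blob
  gives a cohesion of order 10 kT per bead — deep enough to collapse a ring,
  shallow enough to stay liquid.
* **Bonds**: harmonic, `k_bond = 100 kT/σ²`, rest length σ.
* **Wall**: harmonic radial push, `k_wall = 100 kT/σ²`, outside `R`.
* **Membrane adhesion**: cosine well of depth `eps_mem = 1 kT` in the shell
  `[R − r_mem, R]` (`r_mem = 1σ`), switched on late in the protocol.

Bonded neighbors are excluded from the nonbonded terms.

## Protocol

A run reproduces the choreography seen in dividing cells:

1. **Mobile / entropic phase** `[0, t_relax)`: the two rings start compact
   and intermixed (the generator grows two closed random walks, superposes
   their centers of mass inside a ball of radius R/2, and briefly relaxes
   them with crossings allowed; initial segregation efficiency < 0.3) and
   then expand and demix under conformational entropy alone.
2. **Compaction** from `t_relax`: the attraction ramps up over `t_ramp`.
   "Fast" and "slow" differ only in the ramp duration.  In the global
   modes the attraction is suppressed for bead pairs straddling the
   **inhibition plane** — the plane through the midpoint of the two chain
   centers of mass, normal along their axis: the model's proxy for the
   aligned division machinery.  The plane is recomputed while the
   simulation runs (cadence `plane_update_interval`): it marks the
   boundary between the two nucleoids, and that boundary moves with them.
   Setting the interval to ∞ freezes the plane at compaction onset; in
   desk-scale runs a frozen plane goes stale within a few hundred τ, the
   inhibition then no longer falls at the inter-nucleoid boundary, and the
   two compacted masses re-fuse — so tracking is the default.
3. **In-cis spreading** (mode `spreading`): instead of the global
   attraction, a compaction signal starts at one origin bead per ring (by
   default the bead farthest from the inhibition plane) and spreads along
   the contour at `spreading_speed` beads/τ in both directions; only
   same-chain bead pairs that the front has passed attract.  This mimics a
   loop-forming machine acting strictly in cis.
4. **Membrane re-association** from `t_membrane_on` (default: the end of
   the compaction ramp): every bead feels the adhesion well, letting the
   compacted nucleoids re-attach to the vesicle wall as they do late in
   division.

Metrics are evaluated on every stored snapshot: the **segregation
efficiency** (a two-class Fisher discriminant on the labeled 3-D bead
coordinates; pooled within-class covariance with 1e-8 diagonal
regularization; threshold at the midpoint of the projected class means;
points on the threshold count ½ to each side; efficiency =
max(0, 2·balanced accuracy − 1), so chance → 0, perfect separation → 1)
and the **COM distance** between the chains normalized by `R`.  The
efficiency describes a configuration, not a predictor, so it is evaluated
on the configuration itself with no train/test split.

## Numerical choices

* Integrator: first-order Euler–Maruyama, `dt = 0.0025 τ`.  Two
  constraints set this: the displacement per step at the soft-core force
  cap must stay below 0.1σ (gives dt < 0.0064 at `E_cross` = 5), and the
  stiffest mode — the bond's relative coordinate, rate 2·`k_bond`·dt —
  must stay well inside the stability region (0.5 at the default).  At
  this rate the sampled bond-length distribution is ~7% wider than
  Boltzmann (first-order discretization bias); the equilibrium check in
  the test suite therefore runs at dt = 5·10⁻⁴, where the bias is
  negligible, and verifies KS distance < 0.05 against the exact density
  ∝ r² exp(−βk(r−r₀)²/2).
* Ring topology is monitored, not constrained: a run aborts if any bond
  reaches 2σ.  At `k_bond = 100` that is an 8.7-sigma excursion,
  probability ~10⁻¹⁸ per sample — soft enough to never trigger
  spuriously, tight enough to catch integration blow-ups.
* Pair search: Verlet list with a 2σ skin (1σ in the dense compacted
  phase) rebuilt through a linked-cell grid whenever any bead has moved
  half a skin.  During phases with ε = 0 only overlapping pairs (r < σ)
  interact, so the list cutoff drops to σ there.
* The compiled kernel evaluates the pair and membrane forces by linear
  interpolation from 4096-bin tables of the analytic expressions
  (interpolation error ~10⁻⁶ kT/σ, far below the thermal force scale);
  compiler fast-math shortcuts are disabled so the arithmetic is plain
  IEEE and a trajectory is reproducible bit-for-bit from its seed on a
  given machine.
* Thermal noise is drawn from a seeded PCG64 stream in chunks; the stream
  is consumed sequentially, so a trajectory is bit-reproducible for a
  given seed no matter how the run is chunked.
* Degenerate inputs: coincident class means give a zero discriminant
  direction; every point then lies on the threshold, balanced accuracy is
  0.5 and the efficiency is exactly 0 with no special-casing.  Coincident
  chain centers of mass make the inhibition-plane normal default to +z.

## Desk-scale defaults and what they represent

The published system runs at a scale (bead count, phase durations of order
10⁵ τ) that is far beyond a laptop-class CPU budget, so the package's
defaults define a *desk-scale* replica of the same protocol: rings of
N = 200 beads (tests and the mode/φ comparisons use N = 100), phase
durations anchored at `t_relax` = 1000 τ for N = 200 — where the entropic
efficiency curve of that system plateaus — and scaled with the ring Rouse
time (∝ N²) for other sizes.  Fast ramp: 50 τ; slow ramp: 1600 τ,
deliberately still unfinished when the run ends — slow compaction models a
cell whose compaction has not completed by division (the fast/slow
contrast, not either absolute number, is the modeled quantity); total run
1600 τ, by which point the fast-compaction efficiency curve has plateaued;
snapshots and plane updates every 25 τ (all at the N = 200 anchor).
The spreading front covers a half-ring in ~200 τ.  Replica ensembles
default to n = 10 at desk scale with seeds `base_seed + i`; the different
compaction modes are compared on common initial states (same seeds).

What the desk scale reproduces: partial entropic segregation in a
sphere; its rescue by rapid plane-inhibited compaction; the
fast > slow > none ordering; the clear superiority of in-cis spreading
compaction over global compaction.  The dependence of entropic
segregation on the volume fraction is *not* resolved at this scale: with
two 100-bead rings the entropic plateau fluctuates replica-to-replica
with a standard deviation of ~0.25, while the φ = 5/10/20% contrast in
the ensemble mean is of order 0.05 — ten replicas cannot order it
reliably, and repeated calibrations gave orderings in both directions.

What it does not: with only 100–200 beads per ring, the chains are short
enough that, once the two nucleoids are compacted, chain tension and the
tracked inhibition plane keep extracting mis-sorted beads, and the
efficiency creeps toward 1 over a few hundred τ instead of stalling at the
partial value a genome-scale system exhibits.  Final-time desk-scale
efficiencies for the compaction modes are therefore upper bounds on, not
estimates of, the full-scale values; the orderings and the entropic
baseline are the transferable results.  Real chromosomes also carry twist,
supercoiling, sequence-specific organization and a deformable membrane,
none of which are modeled.
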