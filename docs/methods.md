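# Methods

`polyadsorb` simulates a single coarse-grained semiflexible polymer near an
attractive planar wall with dynamic (single-monomer-move) Metropolis Monte
Carlo, and analyses the adsorption transition and the shape of the adsorbed
chain. This note records the model, the algorithmic choices, the defaults
and their rationale, and what the synthetic fixtures and scaled-down runs
do and do not demonstrate.

## Model

The chain is `N + 1` spherical beads at positions `r_0 ... r_N`, the wall
is the plane `z = 0`, and all beads are confined to `z >= 0`. Energies are
in units of `k_B T`, lengths in units of the maximum bond extension
`l_max = 1`. Four terms make up the total energy:

* **FENE bonds.** Each bond of length `l` contributes
  `U_FENE(l) = -(k r0^2 / 2) ln(1 - ((l - l0)/r0)^2)`
  with `l0 = 0.7`, `r0 = 0.3`, `k = 20`, so `l` is confined to
  `(l_min, l_max) = (0.4, 1.0)`. In the harmonic limit the curvature at
  `l0` is `k`. A bond at or beyond either limit carries the
  infinite-energy sentinel (`inf`), never a large finite number, so such
  trial moves are always rejected.
* **Excluded volume.** Non-bonded pairs (`|i - j| > 1`) interact through a
  Morse potential `eps (e^{-2a(r - r_m)} - 2 e^{-a(r - r_m)})` with
  `a = 24`, `r_m = 0.8`, `eps = 1`. The steep core prevents chain
  crossing; the shallow `-1 kT` minimum gives the chain a weak
  self-attraction, which is what lets stiff chains condense into toroids.
* **Bending.** Each interior joint pays `b (1 - cos phi)` where `phi` is
  the angle between successive bond vectors (`phi = 0` when straight).
  Equivalently `b (1 + cos theta)` in terms of the interior bead angle
  `theta` (straight chain: `theta = pi`). `b` is the stiffness control
  parameter; the persistence length is roughly `b * l0` at large `b`.
* **Wall attraction.** Every bead at height `z` contributes a Morse term
  of depth `eps_a` with the same steepness and minimum position
  (`a_s = 24`, `z_m = 0.8`) as the pair potential; the steep core doubles
  as a soft wall. `eps_a` is the adsorption control parameter.

**Pair cutoff.** The Morse pair interaction is treated as exactly zero
beyond `r = 1.0`, where its magnitude is `|U| = 0.0164 eps`; the cutoff is
applied identically in the full energy, the incremental single-move
energy, and the compiled kernel, so the three paths agree to rounding.
The wall term has no tail cutoff: it is one term per bead and costs
nothing to evaluate exactly.

**Slit option.** `ModelParams.z_max` (default `+inf`) optionally adds a
reflecting ceiling. A free chain above an attractive wall in an unbounded
half-space has no normalizable equilibrium (it eventually desorbs and
diffuses away), so exact-equilibrium tests of the wall-bound chain are run
in a slit, where the Boltzmann distribution exists and can be computed by
quadrature. Production runs use the unbounded half-space plus the
escape-restart rule below.

## Dynamics

One Monte Carlo step (MCS) is `N + 1` trial moves. A trial move displaces
one uniformly chosen bead by a uniform increment in
`[-0.15, +0.15]^3` and is accepted with probability `min(1, e^{-dU})`.
Moves placing a bead below the wall (or above the ceiling) or stretching a
bond out of its FENE range are rejected as infinite-energy moves —
statistically identical to letting the potentials diverge. Only
single-monomer displacements are used: collective moves (pivot, regrowth)
would equilibrate faster but change the kinetics, and the adsorption
pathway (train/loop/tail evolution, loop closure into a toroid) is part of
what the simulation describes.

The incremental energy of a move touches only the `<= 2` bonds, `<= 3`
angles, the bead's wall term and its non-bonded pairs, so a trial costs
`O(N)`; the compiled (numba) kernel reaches ~3e6 trials/s on one core.
A pure-python `metropolis_step`/`delta_energy` path implements the same
arithmetic and is cross-checked against full recomputation (to 1e-8
relative) and against the kernel through the running-energy drift check
(accumulated `dU` vs. fresh recomputation at every sampling point, re-synced
after each check; observed drift < 1e-6 relative).

**Replicas and restarts.** A replica grows a self-avoiding initial chain
with bending-biased joint angles (`p(cos phi) ~ e^{b cos phi}`, bonds at
`l0`), translates it so its lowest bead sits at the wall-potential minimum
`z = 0.8` (the chain starts "within attractive range"), equilibrates, then
samples every `sampling_interval_mcs`. If at an interval boundary the
lowest bead exceeds `escape_threshold = 5.0` — five times the interaction
range, far beyond any attraction — the chain has diffused away and the
replica restarts from a fresh initial conformation, discarding its
samples; a replica exceeding `restart_limit` restarts is marked failed and
reported, never silently dropped. Escape is checked at interval boundaries
(cheap, cannot clip adsorbed states) rather than continuously.

**Equilibration.** The burn-in is a fixed budget (default ten sampling
intervals) followed by a diagnostic: the wall energy is averaged over the
last two three-segment blocks of the burn-in, and a warning is logged if
the block means differ by more than one standard error (with a 0.5 kT
floor so near-zero wall energies stay quiet). The check warns; it never
silently extends the run.

**Reproducibility.** Each replica draws from
`SeedSequence([seed, replica_id])`; kernel blocks are seeded from that
stream in a fixed order, and the kernel draws per trial in a documented
order (bead, dx, dy, dz, acceptance). A (seed, replica) pair therefore
maps to a bit-identical trajectory on a given platform.

## Observables

* **Height distribution.** Bead distances to the wall are binned into
  unit-width bins `[D - 0.5, D + 0.5)` centred on integers
  `D = 0, 1, 2, ...`, so the adsorbed well (`z ~ 0.8`) falls in the
  `D = 1` bin. `N_m` are counts, `P(D)` proportions.
* **Adsorbed fraction.** Fraction of beads with `z <= 1.0`, the distance
  beyond which the wall attraction is negligible. A mean adsorbed
  fraction `>= 0.99` labels a state point *fully adsorbed* (a 301-bead
  chain with a dozen beads off the wall is still *partially adsorbed*);
  desorbed and partially adsorbed states share one label.
* **Spatial correlation G(m).** For one snapshot, with
  `c[i, j] = u_i . u_j` the direction cosines of unit bond vectors, each
  interior reference bond `i` contributes the lag-`m` autocorrelation of
  its sequence `{c[i, j]}_j` normalized by that sequence's variance, and
  `G(m)` averages over `i`. Zero-variance reference bonds are skipped; if
  all are skipped the lag is NaN. A sustained oscillation of period `p`
  means the bond direction completes a turn every `p` bonds.
* **Tangent correlation C(s).** Ensemble covariance
  `<(u(s) - <u(s)>) . (u(0) - <u(0)>)>` of unit bond vectors against the
  chain end, averaged over the two chain orientations because the ends
  are indistinguishable. Reported raw and normalized by `C(0)`; the
  normalized variant is used for period counting. The printed definition
  is read as a scalar covariance (dot product of centred vectors).
* **Wall-energy fluctuation.** `<U_s^2> - <U_s>^2` of the total wall
  attraction energy, pooled over replicas, with a bootstrap standard
  error over replicas (1000 seeded resamples). As a specific-heat
  analogue its peak along `eps_a` locates the adsorption transition; the
  reported critical `eps_a` is the grid argmax (no interpolation), with
  flags for boundary maxima and for peaks within one SE of the runner-up.
* **Toroid classifier.** A film-like toroid must be essentially fully
  adsorbed (fraction >= 0.9), flat (height extent <= 1.0) and
  periodically wound: the zero-padded discrete spectrum of its `G(m)`
  curve must have a dominant peak at least 4x the median power
  (`periodicity_score`). The turn count is
  `N_t = round(n_bonds / period)` from the dominant period. All
  thresholds are keyword-configurable; the defaults classify all
  constructed 1-5-turn spirals as toroids and none of 100 random coils.
  The toroid probability of a state point is the fraction of replicas
  whose final sample classifies toroidal.

## Sweep pipeline

`run_sweep` runs the replica schedule at every grid point, reduces samples
to a `PhasePoint`, and persists each point as JSON keyed by a content hash
of its parameters and schedule, so interrupted sweeps resume exactly and
re-runs are byte-identical. `phase_diagram` locates transitions per `b`,
fits the least-squares boundary line, and *reports* monotonicity
violations instead of hiding them. `turns_vs_parameters` aggregates
classifier output (points with fewer than three toroidal finals are
excluded and logged) and tests trend directions with Kendall's tau. The
reference `eps_a` grid step is 0.25 — the finest grid on which the
production-scale transition values (2.0, 2.75, 3.5, 4.25, 5.0 for
`b` = 100...500) are expressible.

## Problem sizes and what the tests show

Three profiles share one schema: `smoke` (N = 32, 4 replicas, 1e4-MCS
intervals), `desk` (N = 64, 8 replicas, 1e5-MCS intervals), `full`
(N = 300, 100 replicas, 100 samples at 1e6-MCS intervals — the production
schedule, 1e4 samples per state point, a multi-day single-CPU run).

The test suite validates correctness at sizes where exact statements
exist:

* Boltzmann sampling is checked on 2- and 3-bead systems against numeric
  quadrature of the exact marginals (bond length; joint angle including
  the 1-3 excluded-volume coupling; wall height in a slit), KS distance
  < 0.02 at 1e5 samples. This validates the move rule and energy
  arithmetic exactly, but says nothing about equilibration *times* of
  long chains.
* The desk-scale sweep (N = 64, equilibration 2.5e5 MCS, two samples per
  replica at 1e5-MCS intervals) reproduces the *trends*: adsorbed
  fraction monotone in `eps_a` and full adsorption requiring stronger
  attraction for `b = 300` than for `b = 50`. At this size and schedule
  the stiff chain is still partly kinetics-limited (its fractions keep
  rising with `eps_a` without reaching 1), which is also the regime the
  escape-restart dynamics describes; quantitative critical values at
  N = 64 are not comparable to the production-scale ones.
* The production-scale quantities (transition points per `b`, the height
  distribution plateaus, toroid probability > 80%) are wired into the
  `full` profile and its validation gate (`validate_full_results`,
  tolerances: one grid step for transitions, 0.05 for proportions); the
  gate's logic is tested, and producing the data is an explicit
  multi-day `run_sweep(profile="full")` campaign.

**Fixtures.** The constructed geometries (rod, regular polygon, flat
archimedean spiral, helix, self-avoiding coil) have exactly equal bond
lengths and known analytic shape; spirals emulate the film-like toroid
with one `gap >= 0.8` between windings. They exercise the observable
stack exactly but are noise-free: they validate the analysis, not the
simulation. An archimedean spiral is slightly chirped (inner windings
carry fewer bonds), so spectral turn counting is exact when windings are
reasonably wide (~64 bonds per turn is used in tests, matching simulated
toroid radii); an independent winding-angle oracle cross-checks the
counts in the suite.

## Numerical choices and limitations

* FENE validity is decided on the bond length against `(l_min, l_max)`
  directly (not on the rounded ratio), so boundary lengths map to the
  sentinel, never to a huge finite energy.
* `G(m)` period estimation zero-pads the spectrum 8x and requires peak
  power >= 4x the median; degenerate (zero-variance) curves score 0 and
  never classify as toroids.
* The bootstrap SE of the fluctuation resamples whole replicas, not
  samples, so within-replica correlation does not bias it low.
* Escape checking at interval boundaries means a chain that desorbs and
  re-adsorbs within one interval is never restarted; at production
  intervals (1e6 MCS) this is the intended "diffused far away" criterion.
* No solvent, no hydrodynamics, single chain, flat substrate only;
  dynamics is Metropolis kinetics, not Brownian dynamics — time is
  measured in MCS, and only relative kinetic statements are meaningful.
* Single-threaded by design (replicas are trivially independent; run
  several processes for throughput).
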