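# Methods

## Model

A single polymer is represented as a touching-bead bead–spring chain of
N beads in reduced Lennard-Jones units (σ = ε = m = 1; time unit
τ = σ√(m/ε); k_BT = 1 at the reference temperature). The potential
energy is the sum of four terms:

* **WCA pairs.** Every bead pair interacts through the purely repulsive
  Weeks–Chandler–Andersen potential, cut and shifted at 2^{1/6} σ.
  Bonded neighbors are included in this sum exactly once (their total
  bond interaction is FENE + WCA).
* **FENE bonds.** κ = 30 εσ⁻², R_o = 1.5 σ. Together with the WCA term
  this produces an equilibrium effective bond length ⟨l⟩ ≈ 0.97 σ and an
  effective bead size w ≈ 0.9 σ. A bond reaching R_o is a fatal
  integration error (it signals a broken configuration or an excessive
  timestep), not a recoverable state.
* **Bending.** The discretized wormlike-chain energy per consecutive
  bond pair, b·k_BT(1 − uᵢ·uᵢ₊₁), evaluated from bond unit vectors so no
  angle extraction is needed. b = 0 gives the flexible chain; b = 20
  the semiflexible chain, whose nominal persistence length is
  b·⟨l⟩ = 19.4 σ. Circular topology closes the bond ring and wraps the
  bending sum.
* **Bead–post.** Posts are infinite, x-aligned cylinders of bare
  diameter D_p on a square yz lattice of spacing S_p. A bead interacts
  with a post through the WCA form evaluated at the surface distance
  r − D_p/2; the force is structurally confined to the yz plane. Since
  S_p always exceeds the interaction range, only the four posts at the
  vertices of the bead's interstitial cell can interact with it; a
  brute-force scan over a wide post neighborhood backs this up in the
  test suite. Posts are an ideal infinite lattice and are never
  instantiated as objects.

The effective post diameter is d_p = D_p + w with w = 0.9 σ by default
(this makes the tabulated effective diameters correspond to round bare
diameters; w is a configuration parameter because the touching-bead
model admits w ≈ l ≈ 0.97 as an equally defensible convention).
Derived geometry: passage width w_p = S_p − d_p, quasi-channel diameter
d_c = √2·S_p − d_p, post volume fraction F = π d_p²/(4 S_p²). The yz
plane is tiled by half-open squares with post centers at their vertices
(floor convention: boundary points belong to the lower-index cell);
these cells define the occupation number, and a bead in a passage
aperture counts toward the cell containing it.

## Dynamics

Leap-frog integration with dt = 0.005 τ. Thermostats:

* **Nosé–Hoover** (default, relaxation time 0.1 τ): the friction
  variable is advanced with the full-step kinetic temperature and the
  velocity update solved by a three-pass fixed-point iteration
  (DL_POLY-classic style). With the center-of-mass momentum removed at
  initialization it stays zero, so the kinetic temperature uses
  3N − 3 degrees of freedom.
* **Langevin** (BBK-style leap-frog, friction γ = 1/τ by default):
  better ergodicity for small systems; thermalizes all 3N degrees of
  freedom. It is ~2.7× slower per step here (per-component normal
  draws), so scaled-down production runs default to Nosé–Hoover.
* **NVE** for integrator validation: the secular energy drift over 10⁴
  steps is below 10⁻⁴ relative, and energy fluctuations scale as dt²
  (second-order integrator).

Velocities are initialized from a Maxwell–Boltzmann distribution at the
target temperature with zero total momentum. All randomness flows from
one seed per run; identical seed and configuration reproduce the
trajectory bit-for-bit within a build. Nonbonded pairs use a Verlet
neighbor list with a 0.3 σ skin, rebuilt when any bead has moved more
than half the skin. Integration aborts with a step-indexed error on
bond overstretch, a bead entering a post core, or non-finite energy.

Initial conformations are a fully straightened backbone (linear) or a
completely prolonged rectangular loop with side lengths ≈ L/2 and l
(circular), with the principal axis parallel or perpendicular to the
post axes; in-array placements run through interstitial cell centers
and refuse perpendicular placements that cannot clear the posts.

## Observables and estimators

Per-frame quantities (axial span, gyration components, occupation
number) are reported as means with block-averaged standard errors
(≥ 10 blocks). The lateral gyration component uses the factor-½
convention R_gyz = √((R_gy² + R_gz²)/2), so R_g² = R_gx² + 2 R_gyz².

The structure factor is the orientation-averaged Debye sum over all N²
pairs. The direct O(N²·n_q) evaluation is the reference path; a
pair-distance histogram (2000 bins by default) accelerates it with a
per-pair error of order (q·Δr)²/6, verified against the direct sum in
the tests. The default q grid is logarithmic from 2π/(2·max span) to
2π/(0.5 l), 200 points. A running log–log slope utility assists manual
reading of hump onsets (near 2π/S_p or 2π/d_c) and slope regimes (−1
rod, −2 extended de Gennes, −5/3 classic de Gennes); no automatic
classification of measured S(q) is attempted.

Tangent correlations C(n_s) = ⟨uᵢ·uᵢ₊ₙ⟩ average over all frames and
all bond pairs; circular chains wrap indices, which enforces the ring
inversion symmetry C(n_s) = C(N_bonds − n_s) identically.

**Persistence length.** P is obtained by least squares on
ln C(n_s) = −n_s·l/P over the window n_s ≥ 1 with C ≥ e^{−1/2}
(separations up to about half a persistence length). The window choice
matters: for a self-avoiding chain the decay is exponential only at
short contour separations — beyond roughly P/2 the excluded-volume
swelling makes C decay slower than exponentially, and at modest chain
lengths (L/P ≲ 15) the tail also carries slowly relaxing global modes.
Fitting out to C = e^{−1} inflates P by 25% or more with large
run-to-run scatter, while the e^{−1/2} window recovers both the planted
value of ideal wormlike-chain fixtures and the expected 19.4–19.7 σ for
the simulated b = 20 chain. The fit fails loudly if fewer than three
usable points remain.

**Deflection-correlation fit.** Under strong (Odijk) confinement the
tangent correlations follow a damped oscillation,
C(n_s) = 1 − (λ/2P)[1 + 2 e^{−n_s l/λ} sin(n_s l/λ − π/4)], with
λ = c(PD²)^{1/3}; (P, c) are fitted by nonlinear least squares
(initial guesses: nominal b·l and c = 1) with covariance-based
uncertainties. The first minimum sits at n_s·l = (π/2)λ. Applying this
single-channel model inside an interstitial volume is an approximation;
results are labelled accordingly.

## Scaling theory

Approximating the interstitial space by a channel (diameter d_c) and
the passage aperture by a slit (width w_p), with confinement free
energies scaling as size^{−5/3} and the channel costing twice the slit
at equal size, multi-cell occupancy becomes favorable below
d_c/w_p = 2^{3/5} ≈ 1.52. The channel-extension formulas are the Odijk
law R = L[1 − A(D/P)^{2/3}] (A = 0.1701; L/2 option for circular
chains, whose two strands traverse the channel side by side) and the de
Gennes law R = L(wP/D²)^{1/3} (log–log slope −2/3 in D). Regime
classification: Odijk for D ≤ P (ties to the stiffer regime), extended
de Gennes for P < D ≤ P²/w, classic de Gennes beyond.

## Synthetic-data generator

`nanopost.fixtures` supplies deterministic conformations so every
analysis operation is testable without dynamics: straight rods,
prolonged rectangular loops, regular polygon rings (closed-form tangent
correlations cos(2πn_s/N)), two-bead frames (closed-form structure
factor), beads planted at chosen interstitial cells (known occupation
number), and ideal wormlike chains sampled from the exact Boltzmann
distribution of the discrete bending energy, p(cos θ) ∝ exp(b cos θ),
parameterized either by b or by a target persistence length (solving
⟨cos θ⟩ = e^{−l/P}). The ideal sampler has no excluded volume — which
is precisely what makes it the clean oracle for the persistence
estimator, and also why passing that test says nothing about
excluded-volume bias (covered separately by the calibration runs).
Fixtures emulate neither thermal bond-length fluctuation nor
bead–post equilibrium structure; conclusions about those rest on the
dynamics tests.

## Scaled-down study conditions

Reference-scale runs (N = 1000, ~2×10⁸ steps) are configuration-
reachable but not defaults. The package's own study conditions, chosen
so that local properties are converged:

* Flexible bond-length calibration: N = 100, 2×10⁵ equilibration +
  10⁶ production steps, Nosé–Hoover, sampling every 10³ steps.
* Persistence-length calibration: N = 300, b = 20, three independent
  runs of 6×10⁵ + 2×10⁶ steps each, pooled correlation functions. Runs
  start from an ideal-WLC coil rather than a straight rod: local bond
  statistics then equilibrate within a few hundred τ, whereas straight
  starts at these chain lengths retain extended-state memory beyond
  1.5×10⁴ τ and bias the correlation tail upward. (Straight starts
  remain the default for confined-chain runs, where they are always
  placeable.)
* Confined-chain trend runs: N = 100, 2×10⁵ + 4×10⁵ steps per
  geometry. These reproduce directions of change (occupancy falling
  with d_c/w_p; relative span falling with d_c at constant spacing),
  not full-scale magnitudes.

Equilibration convergence is monitored by a block-stationarity check on
the radius of gyration and potential energy (relative change < 5%
between consecutive chunks by default); non-convergence flags the
result rather than discarding it.

## Known limitations

* No hydrodynamics, electrostatics, or external fields; posts are
  ideal smooth cylinders of infinite length; square lattices only.
* The damped-oscillation correlation model assumes a single cylindrical
  channel; its use inside an interstitial volume is heuristic.
* At desk scale the confined-chain observables are direction-accurate
  but not magnitude-accurate relative to reference-scale runs; the
  persistence estimator's window sensitivity is documented above and
  its defaults should be revisited for chains with L/P < 5.
* The printed crossover P²/w ≈ 418 depends on whether w = 0.9 or
  w ≈ l = 0.97 is used with P = 19.724; both conventions are exposed
  and neither is canonical here.
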