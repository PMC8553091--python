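# Methods

## Model

`lamelliflow` simulates a 2 µm-wide strip of a stationary cell's
lamellipodium as a three-dimensional Brownian-dynamics model of discrete
actin filaments.  The box is periodic along x, open along y (the
retrograde-flow direction, leading edge at y = 0) and confined to
0 ≤ z ≤ 0.2 µm by soft walls that push straying beads back with a constant
1 pN.  Each filament is a chain of beads connected by stiff harmonic
springs; one bead–spring–bead segment has rest length l₀ = 0.1 µm and
stands for 37 actin monomers.  All quantities are kept in (pN, µm, s);
1 Pa·s of viscosity is then 1 pN·s/µm², and 1 pN/µm² of stress is 1 Pa.

Every bead obeys the overdamped equation of motion

    ζᵢ dr_i/dt = F_spring + F_bend + F_crosslink + F_excluded
                 + F_leading + F_motor + F_confine + F_thermal

with ζᵢ the orientation-averaged drag of a cylindrical segment,
ζ_b = 4πη l₀ / [ln(l₀/d) + 0.84] = 0.108 pN·s/µm at the reference
viscosity η = 0.3 Pa·s and diameter d = 7 nm.  The force channels:

- **Stretching** — harmonic bonds, k_actin = 1000 pN/µm.
- **Bending** — a cosine potential per interior bead triplet,
  E = (κ/l₀)(1 − cos θ), with flexural rigidity κ = kBT·l_p and
  persistence length l_p = 17 µm.  The thermal energy is fixed at
  kBT = 4.11×10⁻³ pN·µm (≈ 298 K); together with l_p this sets κ.
- **Crosslinks** — springs between beads of different filaments
  (k = 100 pN/µm, rest length 35 nm), typed permanent (Arp2/3-like,
  removed only with their beads), long-lived (exponential lifetime, used
  in the arc scenario), dynamic (α-actinin/filamin-like, exponential
  lifetime 1 s, replenished every 0.025 s up to a cap set by the
  configured concentration over the front 9.5 µm of the box), or branch
  (a stiff tether plus the angular restraint below).
- **Excluded volume** — when the closest approach between two filament
  segments falls below d = 7 nm, a repulsion of magnitude
  1690 pN/µm × overlap acts along the closest-approach direction,
  distributed to the four endpoint beads by the lever rule (the endpoint
  nearer the witness point takes the larger share).
- **Leading-edge pushing** — polymerization against the membrane is a
  constant total force of 1.5 pN per filament that has at least one bead
  at y ≤ 0, split equally over all its beads and directed along the
  filament's barbed→pointed axis (taken from the segment closest to the
  pointed end).  An 11-bead filament receives 0.136 pN per bead.
- **Motor pulling** — three modes: *uniform* (0.002 pN in +y on every
  bead), *back* (0.004 pN in +y on beads with y > 3.25 µm), and
  *membrane* (0.02 pN along the barbed→pointed axis on beads in the
  bottom 20 nm of the box that are outside the adhesion capsule).
- **Branch angle** — daughter filaments nucleated off a mother bead are
  restrained to the Arp2/3 angle θ₀ = 70° by
  E = ε(cos θ − cos θ₀)² with ε = 1 pN·µm.
- **Thermal** — independent Gaussian kicks per component with variance
  2 kBT ζᵢ/dt.  Focal-adhesion-bound beads use their elevated drag in the
  noise amplitude too, so fluctuation and dissipation stay consistent and
  bound beads equilibrate at the correct temperature.

## Focal adhesion (molecular clutch)

The nascent adhesion is a capsule-shaped region (0.25 µm wide, 1.25 µm
long, 0.1 µm high, long axis parallel to the leading edge) near the
z = 0 substrate.  Beads inside bind and unbind with first-order rates
k_bind = 10/s and k_unbind = 1/s (bound fraction 10/11 at equilibrium);
bound beads feel a drag elevated by the viscosity ratio κ_FA.  κ_FA = 1
is the no-adhesion limit; sweeping κ_FA = 1–500 implements the clutch:
stronger adhesions brake retrograde flow.

## Network remodeling

Filaments are inserted at a fixed rate of 23.4/s (a deterministic
fractional accumulator, not a Poisson process, for reproducibility):
11 beads, 1 µm long, pointed end at y = 0.5 µm, in-plane angle uniform in
±70° about −y, out-of-plane angle uniform in ±10°.  Each new filament
receives up to five permanent crosslinks to pre-existing beads 30–40 nm
away.  Dynamic crosslinks are topped up to their concentration cap every
0.025 s among unbonded inter-filament bead pairs in the same distance
window.  Every actin bond draws a lifetime τ = τ_age − ln(u)/r_age at
creation (minimum 125 s, mean 130 s at reference values) and is severed
when the clock passes it; mid-chain severing splits the filament (the
barbed-side fragment keeps the filament's identity, since pushing is
defined from the pointed end), and single-bead leftovers are pruned
together with their crosslinks.

Scenario variants: *cytochalasin D* stops insertion and pushing after
steady state; *arcs* move the adhesion to the back (front edge
y = 2.375 µm, κ_FA = 250) and sweep the dynamic-crosslinker
concentration with either permanent or 20 s-lifetime crosslinkers;
*microspikes* insert every other filament vertically (axis along y),
either 35 nm from an existing bead or at random x; *branching* replaces
pointed-end insertion by 70°-restrained daughters nucleated on mother
beads at y = 0.20–0.25 µm, with pushing reduced to 30% (the scenario
bootstraps with ordinary insertion for the first quarter of the
equilibration, since branch nucleation needs mother beads to exist).

## Integration and performance

Positions advance by explicit Euler–Maruyama steps of dt = 10⁻⁵ s (the
excluded-volume stiffness limits the step).  The driver freezes the
topology for chunks of up to 250 steps; remodeling events (adhesion
binding, bond expiry, insertion, dynamic-link refresh) run at chunk
boundaries, which are aligned to the 0.025 s crosslinker cadence, to
every scheduled bond expiry and to requested output times.  Adhesion
binding uses the exact first-order probabilities 1 − exp(−kΔ) over the
realized interval, so its stationary statistics are independent of the
cadence; insertion counts are likewise exact because the accumulator
integrates rate × elapsed time.  This is the one deliberate departure
from per-timestep event processing, and it quantizes event timing to at
most the 25 ms cadence against binding/turnover timescales of 0.1–100 s.

Everything is counted in integer steps and all randomness flows through
one seeded PCG64 generator in a fixed order, so a run is a deterministic
function of (parameters, seed); checkpoints store the generator state and
a restarted run is bit-identical to an uninterrupted one.

Excluded-volume partners come from a cell list over segment midpoints,
filtered to pairs whose true segment–segment distance is below
d_excluded + 40 nm (the skin) and rebuilt whenever any bead has moved
more than half the skin since the last build, which guarantees no
interacting pair is ever missed.  An instability guard aborts with a
diagnostic if any force-driven displacement exceeds l₀/2 in one step.
Unphysical segment crossings can be counted between saved frames (a
chirality-flip test on close pairs); the audit is diagnostic only, and
nothing is corrected, matching the model's monitoring-only stance.

## Observables

- **Retrograde flow** — per-bead dy/dt by finite differences between
  frames ~1 s apart, matched by persistent bead ids; profiles are binned
  along y, and the global speed is the all-bead mean.
- **Density** — 37 monomers per bond, half attributed to each endpoint
  bead, binned along y and converted to µM (1 µM = 602.214 µm⁻³).
- **Bond tension** — k(l₀ − d) per bond (positive = compression),
  averaged over time and z onto an xy grid.
- **Filament bending** — for intact 11-bead filaments, the angle between
  the two 0.5 µm half-chords (beads 0→5 and 5→10); severed fragments are
  excluded.  Mean and upper quartile per y bin.
- **Force balance** — time-averaged per-channel force sums per µm of
  leading edge and per bead; the drag side is accumulated as the
  deterministic force sum ζv split over unbound (cytoplasm) and bound
  (adhesion) beads.
- **Virial stress** — σ_ab = (1/V) Σ T d d̂_a d̂_b over pair interactions
  (tension positive when stretched), with three-body bending/branch terms
  decomposed about the triplet centroid; interactions are weighted by the
  fraction of their beads inside the selection.  σ_T = σ_yy − ½(σ_xx +
  σ_zz).  Reported in Pa.
- **Bundling diagnostics** — a 2D nematic order parameter of segment
  orientations in a y band, and a monomer-weighted x histogram whose
  persistent peaks signal microspike bundles.

## Mechanical characterization

A 4×4×0.2 µm patch is prepared from a steady state by freezing turnover
and external forces, equilibrating, tiling the periodic box once along x
(reconnecting bonds across the seam) and cutting to the target window;
fragments disconnected by the cut are detected by a connected-components
audit.  Uniaxial tests clamp the beads initially within 0.25 µm of either
y face and drive them apart (extension) or together (compression) at a
relative speed of 0.05 gauge lengths per second (0.2 µm/s on the 4 µm
gauge; the clamp motion is split symmetrically), sampling σ_T over the
non-clamped beads up to 50% engineering strain.  The elastic modulus is
the secant σ_T/strain at strain 0.2.  During testing only the dynamic
crosslinks present at the start may unbind and rebind (their cap is set
to that count); compression can optionally run without the top z wall,
which lets the sheet buckle, visible as a peak in the stress–strain
curve.  Stresses are normalized by the initial patch volume (engineering
convention).

## Scaled-down ("desk") preset

Reference-scale runs (300 s of a ~10 µm lamellipodium, ~30 000 beads at
dt = 10⁻⁵ s) are cluster-scale.  The desk preset used by the test-suite
protocols shortens the mean bond lifetime from 130 s to 7 s
(τ_age = 6 s, r_age = 1/s), which scales the lamellipodium to ~1.5 µm and
a few thousand beads; the adhesion capsule's front edge moves to
y = 0.6 µm so it remains inside the short lamellipodium, runs equilibrate
for 6 s and measure for 3 s, and the post-cytochalasin measurement window
is the same fraction of the mean lifetime as the reference protocol's
30–35 s out of 130 s.  One force is rescaled: total motor pulling is
proportional to the bead count while the leading-edge push is set by the
insertion rate, so the shortened network would lose almost all of its
pulling share; the desk preset raises the per-bead uniform pull 4× (to
0.008 pN) so that pulling keeps roughly its reference-scale fraction
(~1/3–1/2) of the total drive — without this, stopping polymerization
stops essentially all flow and the inhibition response cannot be
observed.  Desk mechanical tests use a small synthetic
Mikado-style patch (~90 random crosslinked filaments over 2×2×0.2 µm)
strained at 0.5/s.  Desk runs reproduce the model's qualitative behavior
(clutch monotonicity, partial flow reduction under polymerization
inhibition, stress stiffening, extension stiffer than compression) but
not the reference-scale numbers: the flow is a few-fold faster (fewer
beads share the same driving forces), densities are lower, and moduli
depend on the synthetic patch's density rather than the grown network's.

## Known limitations

- No force-dependent polymerization, explicit motors, deformable leading
  edge, molecular adhesion components, or bending-induced severing; the
  leading edge is fixed and pulling forces are external fields.
- The dynamic-crosslinker scheme does not satisfy detailed balance (links
  are inserted at random among eligible pairs and decay independently).
- First-order Euler–Maruyama only; no hydrodynamic interactions.
- Filament insertion does not reject overlaps; excluded volume resolves
  them over subsequent steps.
- The fractional-accumulator insertion count sits exactly on an integer
  boundary for some (rate, duration) combinations, where floating-point
  rounding decides the last insertion; counts are still reproducible
  run-to-run.
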