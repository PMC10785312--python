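# Methods

`mesocat` simulates a catalytically activated ring-closing/polymerization
competition — a coarse-grained diene metathesis — at fixed two-site
catalysts, with and without confinement, under grand-canonical reservoir
coupling. This note records the model, its parameters, the numerical
choices, and what the shipped tests and the acceptance script do and do
not demonstrate.

## Model

**Substrate.** Oligomers are Kremer–Grest bead–spring chains of
`N_m ∈ {22, 29}` beads: all bead pairs repel through the purely repulsive
WCA potential (ε = 0.833 k_BT, σ = 1 reduced length = 1.535 Å = 0.1535 nm,
cutoff 2^{1/6}σ) and bonded neighbours attract through a FENE spring
(K = 30 ε/σ², r_max = 1.5σ — the standard values for this model; they are
not part of the calibration). Backbone rigidity is a harmonic bending
potential U = ½ K_angle (φ − π)² with the calibrated stiffnesses
K_22 = 5.09 k_BT and K_29 = 4.32 k_BT. With the ½-prefactor convention
these stiffnesses reproduce the published hydrodynamic radii of both
substrates (see below), which is the consistency check available to fix
the convention. The implicit solvent is a Langevin thermostat with a
globally constant friction γ = 1 τ⁻¹ and timestep dt = 0.01 τ (τ the
reduced time unit); neither value is prescribed by the source material,
and both are exposed in the configuration. T = 300 K defines the energy
unit.

**Catalyst.** Each catalyst is an immobile impenetrable holder sphere
(radius 0.5 nm; soft WCA with length scale equal to the core radius, so a
bead touching the surface feels about one ε) carrying two permeable
reactive sites 1.3σ apart. Site centres sit 0.7 nm (`d_cat`) from the
wall and protrude one site radius (0.5σ) above the holder surface; with
the sites *on* the surface, the capture volume lies inside the holder's
repulsion halo and measured binding rates drop by over an order of
magnitude, which defeats the model's premise that reaction events are
frequent enough for statistics. In the resting state one site holds the
carbene carbon C0 (initially an artificial cap bead) through a harmonic
tether (k = 100 ε/σ², r₀ = 0.97σ); the other site accepts collisions.

**Reaction.** A label-flagged bead (the first two and last two beads of
each substrate are flagged as the olefin carbon pairs) that enters the
free site's capture sphere (radius 1.0σ) binds with probability
P_bond = 1 as C1; its flagged bond partner C2 then bonds to C0, closing
the transient 4-ring C0–metal–C1–C2–C0. New bonds are harmonic (they can
form far from rest length). The ring opens at rate 1/τ_break
(τ_break = 10 τ, accelerated): *forward* frees the C0–C2 pair and leaves
C1 on the metal (the C0–C2 bond becomes a regular FENE chain bond);
*backward* exactly undoes the binding. Directions are drawn 50/50.
Released molecules are classified from topology and lineage tags:

- cyclic → ring-closed (RC);
- exactly two beads → byproduct (the ethylene analog), whatever its
  lineages;
- at least two substrate backbones, each contributing ≥ 2 beads → P
  (polymerized);
- otherwise (one backbone, possibly with an exchanged end carbon) →
  chain transfer, returned to the substrate pool and not counted.

A released molecule containing one full backbone plus a *single* foreign
end carbon is chemically an end-group exchange, not a condensation;
counting it as P (as a literal "two lineages" rule would) would halve
every selectivity. A lone bead left on the metal after a release is
retagged as a carbene cap for the same reason. Selectivity is
S_RC = N_RC/(N_RC + N_P). P_bond, τ_break, the capture radius and the
site protrusion set the throughput of both channels equally, so S_RC is
insensitive to them to first order; the shipped tests verify the
τ_break half/double invariance within statistics.

**Geometries.** Bulk (periodic box, catalysts fixed and well separated);
single planar wall (repulsive analytic WCA wall, catalysts at `d_cat`);
slit and cylindrical pores as finite membranes of length l = 35.8 nm
embedded in an open outside volume (L_y = 10.21 nm lateral period,
34.2 nm outside extent), with capped rims so beads enter only through the
openings. Catalyst counts follow floor(σ_cat·A) at σ_cat = 0.036 nm⁻²
with the area taken on the surface through the sites (one wall for
flat/slit, the shell of radius r − d_cat for cylinders), which reproduces
13 catalysts for every slit and 3 for the narrowest cylinder. Planar
catalysts are placed uniformly with ≥ 2.5 nm separation (slit catalysts
alternate walls); cylinder catalysts are equally spaced axially with
random azimuth and axial site-pair orientation (exactly `d_cat` from the
curved wall).

**Reservoir.** Substrate exchanges with an ideal reservoir of
ρ_res = 0.015 nm⁻³ at zero excess chemical potential inside the coupled
region only: beyond 9 nm from the flat wall, the outside volume minus a
5 nm entry padding for pores, and beyond a configurable distance from
every catalyst in bulk (the source prints 9 nm only for the flat wall;
scaled-down bulk runs here use 4 nm, far beyond the reach of an attached
chain). Whole molecules are inserted in Boltzmann-sampled single-chain
conformations from a pre-sampled library (so only intermolecular + wall
energy enters the Metropolis weight) and deleted with the matching
reverse acceptance; the thermal-wavelength constant is absorbed into the
activity by writing both acceptances in terms of ρ_res. Products have
μ = −∞: they are removed unconditionally once fully inside the coupled
region, and never inserted. Runs start from a Poisson filling of the
whole accessible volume at ρ_res (rejecting overlaps), which skips one
box-diffusion time of equilibration.

**Conformer library.** Sampled from a long single-chain Langevin run; a
pilot run measures the integrated end-to-end autocorrelation time and
production snapshots are taken every ≥ 2× that time. Libraries store
centred conformers and their internal energies.

## Observables

- **R_H**: the harmonic-mean bead–bead distance over the conformer
  ensemble, 1/R_H = ⟨1/r_ij⟩ averaged over all N(N−1) ordered pairs.
  (With a 1/N² normalization instead, both substrates come out ~4%
  large; the pair-count normalization reproduces both published values
  simultaneously, so it is what that source computed.)
- **ρ_e**: time-averaged number density of terminal flagged beads of
  intact substrates in the window 0.4–1.0 nm from the wall (each
  substrate contributes two ends; far from walls this reads twice the
  molecule density). A molecule-equivalent convention (dividing by two)
  is ruled out by consistency: it would place the published *reacting*
  value above the equilibrium window density, and reactions only
  deplete. Probe volumes are a slab (flat), two slabs (slit) or an
  annular shell (cylinder).
- **S_RC** from the event ledger, pooled over replicas; binomial and
  across-replica errors are both available.
- End-to-end distances of intact substrates; axial substrate density
  profiles along pores.
- Reported reservoir densities count molecules by centre-of-mass
  membership of the coupled region (whole-molecule containment — the
  exchange rule — systematically undercounts near the coupling surface).

## Numerical choices

- BAOAB splitting of Langevin dynamics; velocity Verlet at γ = 0 (energy
  drift < 10⁻⁴ ε per step per bead is verified). Thermostat noise is
  seeded per block by (master seed, global step), making runs
  bit-reproducible and checkpoint restarts exact.
- Cell-list neighbour search with a 0.9σ skin, rebuilt on half-skin
  displacement; dilute systems cap the cell count at ~2 per bead.
- Harmonic reaction bonds are force-capped: quadratic within 0.5σ of
  rest, linear beyond (constant force k/2). Bonds formed at collision
  geometry can be stretched by > 1σ; an uncapped k = 100 spring then
  detonates neighbouring FENE bonds at dt = 0.01.
- The metallacycle lives at least 1 τ before breakup so its fresh bonds
  relax; a surviving C0–C2 bond converts harmonic → FENE only once
  shorter than 1.35σ (deferred otherwise). No distance precondition is
  placed on binding — an earlier C0–C2 cutoff suppressed exactly the
  productive (outer-bead-first) collisions and was removed.
- Binding detection is entry-triggered: a flagged bead fires only on the
  step it crosses into an accepting capture sphere, and beads already
  inside when a site (re)activates — e.g. a freshly released chain end —
  must leave and re-enter first. Level-triggered detection produces an
  unphysical same-step rebinding loop that locks catalysts into endless
  end-group exchange.
- In rare energetic cascades (a reaction bond formed far from rest), a
  chain bond can overshoot its finite extensibility within one step; the
  integrator then pulls that pair back inside and re-thermalizes it
  (counted, typically zero to a few per million steps) instead of
  aborting.
- Angle terms are regenerated from the FENE bond graph (every adjacent
  FENE bond pair bends); harmonic reaction bonds carry no bending.
- Bending forces use the (φ − π)/sin φ → −1 limit near straight angles.
- The bulk coupled volume with overlapping buffer spheres is computed by
  a deterministic Monte Carlo estimate (relative error ~10⁻³).

## What the tests show — and what they do not

The synthetic systems here *are* the study systems (there is no external
data): the generator defaults encode the study conditions (ρ_res =
0.015 nm⁻³, chain lengths and stiffnesses, σ_cat, d_cat, l_ex, wall/pore
dimensions). Scaled-down run sizes are the package's own desk-scale
protocol:

- R_H uses 1 200–5 000 conformers (statistical error ≪ 0.01 nm).
- Reservoir densities use a 10 nm box and a few × 10⁵ steps (~1%
  statistical error).
- The reacting flat-wall and bulk systems use reduced boxes
  (16 nm wall-normal extent; 12 nm bulk box with 3 catalysts) and
  ~10⁶ steps per replica. **Event statistics are the binding
  constraint**: at the study density, a catalyst binds a substrate end
  roughly once per 10⁴ τ (10⁶ steps), so desk-scale runs accumulate
  only of order ten productive events per system. The selectivities the
  acceptance script prints are therefore order-of-magnitude checks with
  binomial errors of tens of percentage points, not converged values;
  converged selectivities at these conditions require cluster-scale
  runs (the monotone trend and invariance tests instead run at elevated
  density where events are frequent).
- The end-monomer depletion at the wall is dominated by the entropic
  equilibrium effect at desk scale (window density ~40% of its
  far-field value); the additional reaction-drainage contribution is
  weak at our event rates, so the measured reacting ρ_e sits ~20%
  above the published full-throughput value.

Passing tests demonstrate correct potentials and forces, correct
grand-canonical statistics, exact event bookkeeping, and the qualitative
confinement physics (wall depletion, its ordering with pore size and
curvature); they do not demonstrate quantitative selectivity agreement at
desk scale, for the statistical reason above.

## Known limitations

Hydrodynamic interactions, attractive wall chemistry, stereochemistry,
explicit ligands, catalyst decomposition and pressure coupling are out of
scope by design. The effective Rg-scaling exponent of short flexible
chains (N = 16–64) is ~0.63, above the asymptotic self-avoiding 0.588,
as expected from corrections to scaling — tests assert good-solvent
swelling, not the asymptotic exponent.
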