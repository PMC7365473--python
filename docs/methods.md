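# Methods

## Model overview

`minifil` treats the nonmuscle myosin II rod — the ~160 nm coiled-coil tail
of the heavy-chain dimer — as a rigid linear chain of point charges and asks
how long two such rods stay in contact when they meet at an axial stagger
`s`.  Three layers build on each other: screened electrostatics of straight
rod pairs, elastic splaying of a partially attached rod, and a
first-passage-time treatment of the zipping/unzipping dynamics.  The model's
output is relative: contact times carry units of nm² (D·T₁ with the
effective diffusion constant left uncalibrated) and are compared across
staggers, orientations and rod pairings, never as absolute times.

## Charge chains

One charge site per rod residue on a lattice of 0.1456 nm (the coiled-coil
rise per residue).  Arg/Lys contribute +2e, Asp/Glu −2e — the factor 2
because the rod contains two identical heavy chains — and all other residues
0.  Residues at heptad positions *a* and *d* face the hydrophobic core and
are cancelled to 0 regardless of identity.  Skip residues (isolated
insertions that interrupt the heptad phase) are kept as charge sites;
their register label is never *a*/*d*, so their charges survive.  The
rotational placement of charges around the rod axis is not modelled; prior
work found it immaterial at this level of coarse graining.

The heptad register is an *input*: either a per-residue TSV (as produced
from a paircoil run) or a fallback that cycles a–g from a configured phase
and holds the phase across configured skip positions.
`suggest_register_phase` offers a one-line heuristic (maximise hydrophobic
occupancy of *a*/*d*) for exploratory use; it is not a coiled-coil
predictor.  Rod boundaries are likewise configuration values: the rod
interval should cover the coiled-coil and exclude the non-helical
tailpiece, whose exact length is not known; `scripts/fetch_sequences.py`
writes a default annotation (C-terminal 1085 residues, ending 35 before the
chain end) that users should refine per isoform.

## Electrostatics

Mobile ions screen the Coulomb interaction; in the weak-coupling,
small-potential limit the pair energy in k_BT is

    E(r) = q₁ q₂ (l_B / r) · exp(−r / l_DH)

with the Bjerrum length l_B = e²/(4π ε ε₀ k_BT) ≈ 0.70 nm (ε = 80,
T = 298 K so that k_BT = 0.593 kcal/mol) and screening length l_DH.  The
default l_DH = 1.3 nm is the standard value quoted for ~100 mM NaCl;
recomputing from the Debye formula at exactly 100 mM gives ≈ 0.96 nm, and
both are exposed in `ElectrostaticParams` (energy magnitudes shift by tens
of percent between the two; stagger locations do not move).  Rod-rod
energies are plain double sums over cross-chain pairs; a default pair
cutoff of 12 l_DH (≈ 15.6 nm) zeroes far pairs and changes rod-scale
energies by < 10⁻³ k_BT relative to the literal sum (`pair_cutoff=None`
recovers it exactly).  Two rods sit 2 nm apart axis-to-axis (1 nm rod
radius).  Straight-rod stagger scans default to one lattice site of
resolution and use an exact lattice-correlation contraction; off-lattice
staggers fall back to the generic pairwise sum.

Stagger conventions: rod A spans z ∈ [0, L]; parallel partners shift by
+s; antiparallel partners are reversed with their C-terminal tip at z = s,
so equal-length rods overlap over L_max = L − s and s ≈ 113–118 nm
corresponds to the observed 43–45 nm antiparallel overlap.  Negative
antiparallel staggers (tips not in contact) are rejected.

## Splaying

The rod is a worm-like chain with persistence length l_p = 130 nm; a bent
segment of arc length L_a and radius R costs E = l_p L_a / (2R²) k_BT.
At stagger s and overlap L_o the mobile rod is straight along its attached
C-terminal segment (contour length L_o, tip-first attachment — the
positively charged tip binds inside the partner's span, which for parallel
hetero-pairs places the bent rod's tip s before the straight rod's tip),
then departs along a tangent-continuous planar arc curving away from the
partner, then continues straight.  For each (s, L_o) cell the total
(electrostatic + bending) energy is minimised over a grid
R ∈ [75, 300] nm × L_a ∈ [15, 40] nm (16 × 11 points by default; the grid
resolution is a package choice — only the ranges are part of the model).
All charges of both rods enter the electrostatic sum, including the
bent-away tail.  Ties break toward larger R, then smaller L_a.

Arcs longer than the remaining contour are clamped, so the candidate family
approaches the straight rod continuously as L_o → L_max.  The straight
(no-bend) configuration competes only where it is geometrically consistent,
i.e. at L_o = L_max: a straight rod at stagger s *has* overlap L_max, and
admitting it at smaller L_o would cap every overlap potential at the
constant straight-rod energy, erasing the L_o-dependence the kinetics step
integrates over.  With this choice a neutral pair's landscape is the
minimal grid bending energy (l_p·15/(2·300²) ≈ 0.011 k_BT) at inner cells
and exactly zero at L_o = L_max.

Grids are lattice-aligned: staggers and overlaps advance in steps of 7
lattice sites (1.019 nm; the nominal "1 nm" grid rounded to the lattice),
and each stagger's column ends with the exact L_max cell.  Alignment lets
the production engine treat the attached segment exactly through one
convolution of the partner's charges with the lattice pair kernel (prefix
sums give every L_o at once) and read arc/tail contributions from a
tabulated near field Φ(y, z) — lattice-spaced in z, 0.05 nm in y — by
bilinear interpolation, summing only over the bent rod's charged sites.
The literal per-cell enumeration (`optimize_bend`,
`engine="reference"`) is retained as the oracle; the two agree to the
bilinear interpolation error, ≲ 2·10⁻³ k_BT per cell, at ~100× speed
difference.

## Contact times

Dimer formation is a two-step process: the tip attaches at stagger s with
an initial contact of 25 residues (x₀ = 3.6 nm of overlap; the result is
insensitive to this choice), then the overlap x = L_o diffuses in V(L_o) —
the landscape column at fixed s — with constant effective diffusion D.
Detachment requires unzipping back through x = 0 (absorbing boundary);
x = L_max(s) reflects.  The mean first passage time

    T₁(x₀) = (1/D) ∫₀^{x₀} dz e^{V(z)} ∫_z^{a} dy e^{−V(y)}

is evaluated by trapezoidal quadrature on a 0.02 nm grid after linear
interpolation of V between landscape cells; subtracting min V from both
exponents leaves the product invariant and prevents overflow.  The flat
potential reproduces the closed form (2Lx₀ − x₀²)/(2D) to < 10⁻³ relative
error, and halving the quadrature step changes landscape-column results by
< 0.5 %.  Staggers with L_max < x₀ admit no contact and are reported as
absent.  Profiles over s and the ordered-pair matrix (straight rod first,
bent rod second — the two orders are distinct computations for
hetero-pairs) report D·T₁ and peak staggers.

## Synthetic rods

`make_periodic_rod` emulates exactly the features of the NM2 rod that the
model exercises: a 196-site charge repeat (alternating 98-site negative and
neutral blocks), a positively charged C-terminal tip occupying the final
half-period, and rod-scale length (1085 sites ≈ 158 nm).  The tip's +2e
sites mirror the blocks' −2e pattern, so tip-over-block alignment is
sharply optimal; site patterns are placed symmetrically within the
half-period from a seeded generator and are bit-reproducible given the
seed.  Default block/tip total charges are ±16 e: the alignment energy dip
grows linearly with amplitude while the finite-rod envelope tilt (a net
negatively charged rod whose overlap shrinks with stagger) grows
quadratically, so moderate amplitudes pin the parallel self-scan minima at
exactly 98/294/490 sites; amplitudes near the real windowed charge of the
NM2 rod (~±40 e) displace them by a few sites.  What the fixture does *not*
emulate: isoform-specific charge statistics, the dense mixed +/− charge
background of real rods, skip residues, and realistic absolute energy
scales (the default rod's wells are a factor ~2–6 shallower).  Passing
tests on the fixture therefore validates the machinery and the
repeat-alignment physics, not isoform-specific numbers; those require the
real sequences plus a register annotation.

`make_test_potential` provides flat, linear and square-well 1-D potentials
with closed-form first-passage references for validating the quadrature.

## Numerical and degenerate-input choices

* Charges are validated to {−2, 0, +2} e; coincident cross-chain sites and
  non-positive pair distances raise (point-charge singularity).
* Local minima/maxima of scans and profiles use strict-neighbour peak
  finding with optional moving-average smoothing and a prominence filter
  (default none for scans; 5 % of the maximum for contact-time peaks).
* The fast landscape engine requires a finite pair cutoff or screening
  length; otherwise use the reference engine.
* Overlap potentials interpolate linearly; exponentials are evaluated in
  double precision after the min-V shift (|V| stays ≲ 10² k_BT).
* Determinism: identical configurations yield byte-identical outputs; the
  only randomness is the seeded synthetic-rod site placement.

## Problem sizes

Default production grids (stagger and overlap steps of 7 lattice sites,
16 × 11 bend candidates) evaluate a full rod-scale landscape-plus-profile
in a few seconds on one core; the test suite exercises reference-oracle
comparisons on 36–160-site chains and one full-size cell, and the
acceptance script runs the complete synthetic pipeline at the default
sizes.

## Known limitations

* Linearised electrostatics with a uniform dielectric: no nonlinear
  Poisson–Boltzmann effects, counterion condensation, explicit ions or
  dielectric boundaries.
* Single planar circular-arc bending of one rod only; no thermal ensemble
  of bent shapes, no out-of-plane splay.
* Constant effective diffusion along the overlap coordinate; contact times
  are relative.
* Skip residues perturb only the charge pattern's register, not local
  geometry or flexibility.
* The Gouy–Chapman length sometimes quoted for myosin rods is narrative
  context for the weak-coupling regime and is not computed here.
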