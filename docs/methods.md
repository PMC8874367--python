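# Methods

`ngc-elute` simulates how efficiently different drug carriers elute a growth
factor (GDNF) inside a "relay"-type multichannel nerve guide conduit (NGC): a
tubular scaffold whose two multichannel segments are joined by three loading
cavities (front, middle, back) that hold the drug release system.  The
readout throughout is the domain-averaged GDNF volume fraction at the end of
a scheduled release, compared across carriers under two protocols.

## Geometry

The 3D conduit (2 mm outer diameter, 0.2 mm wall, nine 0.34 mm channels) is
reduced to a 2D longitudinal section.  A diametral cut of a 1-center +
8-ring channel packing shows three lumens, so the section carries three
parallel channels by default (`n_channels_2d`, configurable).  The three
cavities span the full 1.6 mm inner diameter and are 1.0 mm long; the bulk
hydrogel (0.5 mm diameter) therefore occupies exactly half of the middle
cavity.  The conduit segment length is not part of the published geometry; it
defaults to 2.17 mm so that a hydrogel film lining both segments of all nine
3D channels has an emission surface of ~166x the default microsphere system,
the published area ratio between the two.  The left exterior edge is the
interstitial-fluid inlet (inlet 1), the right exterior edge the outlet; all
other exterior faces are walls.

The domain is rasterized on a uniform cell-centered grid (default
h = 0.02 mm, 17 cells per channel) by center sampling.  Vertical coordinates
are handled as exact signed half-integer multiples of h measured from the
mid-axis, so mirror-symmetric configurations rasterize mirror-symmetrically
to the bit.  Grids whose dimensions are not integer multiples of h are
truncated by less than one cell at the far end rather than padded.
Rasterization is deterministic; building a grid twice yields identical
arrays.

Release systems are placed as analytic bodies and then rasterized:

* **single-layer microspheres** — n discs per selected cavity (default 8 of
  0.1 mm), split evenly between rows tangent to the upper and lower cavity
  surfaces (odd counts put the extra disc on top), centers
  `adjacent_distance` apart (default 0.2 mm), centered axially;
* **double-layer microspheres** — a second row stacked `layer_gap`
  (default 0.02 mm) inside the first; the stack (2d + gap = 0.22 mm) exceeds
  half the 0.34 mm channel diameter, which the geometry report surfaces as a
  blockage ratio;
* **bulk hydrogel** — one 0.5 mm disc centered in the middle cavity;
* **hydrogel film** — a `film_thickness` layer (0.1-0.15 mm) lining the
  upper and lower surface of every channel along both segments.  A film
  of half the channel diameter or more raises a blockage error.

Body cells adjacent to remaining fluid become *release-inlet* cells (their
fluid-facing faces are inlet 2); interior body cells become walls.  Bodies
that do not fit their cavity raise placement errors before rasterization.

The porosity reported for the empty default section is ~0.79 (cavities plus
channel lumens over the inner area).  The scaffold's nominal 40 % porosity is
a 3D bulk property that a 2D longitudinal section does not preserve; the
module reports porosity but does not enforce a target.

## Release schedule

The experimental release profile — 5 ng burst over the first day, 1.5 ng
sustained over the following 59 days — is proportionally narrowed by 1e-4 to
a 519 s schedule (9 s burst + 510 s continuous after rounding the phase
times to whole seconds).  Release velocities (mass/time) are invariant under
exact proportional scaling; the time rounding shifts the burst velocity from
5.79e-5 to 5.56e-5 ng/s, which is retained as the reference value.

Emission areas for time budgeting follow the spherical-surface convention
`quantity x pi x d^2` (the bulk hydrogel counts as one sphere), even though
the transport model is 2D.  Under the **constant-mass** protocol the burst
and continuous durations are each scaled by `reference_area / area`
(reference: 0.251 mm^2 at 519 s) and rounded to the nearest 0.5 s
*separately* — the rule that reproduces the published budget table,
including its 6 + 326.5 = 332.5 s row where scaling the total directly gives
332.16 s.  For display, the table's quantity sweep scales the *rounded*
8-sphere batch area by quantity/8 (so 16 spheres print 0.502 rather than
round(0.502655) = 0.503); the exact areas are always used for scheduling.
Films are excluded from constant-mass comparisons: at ~166x the reference
area the scaled time would drop below one 0.5 s step.

## Boundary speed

One fixed boundary speed per release phase applies to every system — this is
what makes released mass proportional to emission surface and the constant-
mass budget meaningful.  The reference conversion divides the narrowed mass
rate by the GDNF density and the reference footprint (0.2513 mm^2 at 1 mm
out-of-plane depth; the depth is configurable and recorded).  In the 2D
section the released mass scales with the carrier's emitting *perimeter*
(`n pi d` for discs, the lined channel surfaces for films); the per-face
speed is renormalized so each case's integrated 2D emission equals that
analytic perimeter, which removes a few percent of rasterization noise and
makes the default case emit exactly the narrowed profile's mass over its
schedule.

## Flow and transport model

Interstitial fluid (1000 kg/m^3, 3.5e-3 Pa s) and GDNF (1370 kg/m^3,
1.5e-3 Pa s) are treated as interpenetrating Newtonian incompressible
continua sharing one momentum equation — a mixture model with
volume-fraction-weighted density and viscosity and a drift (slip) velocity
between phases.  At a GDNF loading of ~1e-10 the homogeneous limit applies,
so the drift closure defaults to zero slip; an algebraic local-equilibrium
closure (relaxation time `rho_p d_p^2 / 18 mu_c` times the resolved
acceleration) is available behind a flag and vanishes for matched phase
densities.  The model is isothermal; no energy equation is solved.  Gravity
and body forces default to zero (planar section, no orientation given), and
GDNF molecular diffusion defaults to zero (transport by resolved flow only);
both are configurable.

Boundary conditions: inlet 1 carries a fixed physiological interstitial-fluid
velocity with alpha = 0.  No measured value accompanies the study, so it
defaults to 1e-6 m/s (1 um/s, within the range reported for interstitial
flow) and is written to every run log.  Inlet 2 (release faces) carries the
schedule's current speed with alpha = 1 — burst speed while t < 9 s, then the
continuous speed.  The outlet is a fixed-pressure boundary; everything else
is no-slip.  Runs start from rest with alpha = 0 and p = 0.

**Numerics.**  Staggered (MAC) finite volumes on the raster.  Each 0.5 s
step solves momentum (implicit Euler viscous terms with face-interpolated
mixture viscosity, explicit first-order upwind convection) together with
discrete continuity as one coupled sparse velocity-pressure system, with the
outlet pressure anchored through the boundary-face normal-momentum relation.
The flow is deep in the creeping regime (Re ~ 1e-5; the viscous time
rho h^2/mu ~ 1e-4 s is four orders below the step), where pressure-correction
splittings stall — a projection variant converged at under a percent per
step in testing, never reaching the quasi-steady balance within a burst
phase.  The coupled solve has no splitting error: it reaches the steady
Stokes balance within ~3 steps of any boundary change, matches the plane-
Poiseuille profile to 0.25 % at 20 cells across a channel, and leaves the
discrete divergence at round-off (checked each step against
`pressure_tolerance`, default 1e-8 s^-1).  No-slip on walls tangent to a
velocity face is imposed by ghost reflection (the wall plane sits half a
cell from the face), which keeps the Poiseuille benchmark second-order.

The sparse operator is factorized once per case and reused: the mixture
coefficients depend on alpha only at the 1e-10 level, far below
discretization error (they are rebuilt if max alpha exceeds 1e-3).  Because
the velocity field is quasi-steady between the burst-continuous switch, the
runner also skips the flow solve once three consecutive solves change the
velocity by less than 1e-9 relative, resuming at the next boundary change
(`quasi_steady`, on by default; transport still runs every step).  A full
16-case study at h = 0.02 mm (36,700 cells, 1038 steps per case) runs in
about half a minute on one CPU.

Volume-fraction transport is conservative finite-volume advection by the
solved face fluxes, first-order upwind by default (bounded in [0, 1] for
CFL < 1; typical CFL here is ~0.03) with a van Leer limited scheme
available.  Release cells carry alpha = 1 and walls alpha = 0, so boundary
face values need no special casing.  A cumulative ledger integrates the
emitted (release faces), exited (open boundaries) and stored GDNF volume
from the same fluxes as the update, so it closes to round-off — far inside
the 1 % acceptance bound.

A steady-state detector reports the first time the fluid-mean alpha changes
by less than 1e-6 relative for 20 consecutive steps; it never stops a run.

## Readouts and protocols

The performance scalar is the area-weighted mean of alpha over fluid cells
(walls and release bodies excluded) at the final scheduled step; a
whole-domain variant is available behind a flag and written alongside.
Comparisons report pairwise ratios and percentage changes
`(new - old)/old x 100` against the default single-layer baseline, plus a
rank order.  The study enumerates sixteen release-system cases — the default
single layer; placement variants (front, back, pairs, all three); quantity 4
and 6; diameters 0.125 and 0.15 mm; spacings 0.15 and 0.25 mm; the combined
model (0.15 mm spacing in all three cavities, 24 spheres); the double layer;
the bulk hydrogel — under both protocols, and the three film thicknesses
under constant time only.  Everything is deterministic: reruns are
byte-identical.

## What the model does and does not show

The study-condition defaults above reproduce the published *comparative*
structure where that structure follows from the physics:

* constant time — double layer > default single layer > bulk hydrogel, with
  double/single ~= 2.0 (published ~1.8) and bulk/single ~= 0.63 (published
  0.67): at a common boundary speed these ratios track the carriers'
  2D emitting perimeters;
* constant mass — double ~= single (ratio 1.01 vs published 0.98) and
  bulk/single ~= 0.21 (published 0.199);
* films — mean alpha strictly increasing with thickness.

Two published quantities are *not* reproduced, for reasons the model makes
explicit.  The transport problem is linear in the release sources (alpha
never feeds back on the flow at this loading), so the combined model — three
cavities' worth of spheres emitting at the common speed, i.e. 3x the default
mass — yields +200 % over the default in the storage-dominated regime and
+200 % again at full steady state; the published +67 % cannot arise from a
linear mixture model with a tripled source, even though the same paper's
double-layer (2x -> 1.86x) and bulk (0.625x perimeter -> 0.67x) figures are
exactly what linearity predicts.  Likewise the film sweep's published
+328 %-then-+30 % increments: film emission here is thickness-independent
(same lined perimeter) and outflow at 1 um/s is negligible over 519 s, so
the gain per thickness step is the ~12 % shrinkage of the fluid volume.  The
published attribution of the thin film's poor performance to *high* flow
velocity is inconsistent with the stated fixed-velocity inlet, under which a
thinner film gives wider channels and hence lower channel velocity; a
pressure-driven inlet would be needed to produce that pattern, and the
stated boundary condition is implemented instead.

Other limitations: the 2D section cannot represent the 3D ring of nine
channels or the scaffold's bulk porosity; carrier degradation, swelling and
hydrogel mechanics are outside the transport model (release enters only
through the imposed profile); absolute volume-fraction magnitudes depend on
the assumed out-of-plane depth and interstitial velocity and are therefore
reported for comparison between cases, not as calibrated concentrations.
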