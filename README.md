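# ngc-elute

Growth-factor eluting efficiency of drug release systems embedded in a
"relay"-type multichannel nerve guide conduit (NGC), computed with a 2D
two-phase mixture-flow simulation.

Nerve guide conduits bridge the stumps of a severed peripheral nerve; for
long gaps they need a sustained supply of growth factor inside the lumen.
The relay design joins two multichannel conduit segments with three loading
cavities that hold a drug carrier.  This package asks: *which carrier —
single- or double-layer microspheres, a bulk hydrogel, or a hydrogel film —
keeps the most GDNF in the scaffold, and how do microsphere quantity,
diameter, spacing and placement change that?*

The model treats interstitial fluid and GDNF as interpenetrating Newtonian
continua (a mixture model): one momentum equation with volume-fraction
weighted properties,

    rho_m = sum_k alpha_k rho_k,    mu_m = sum_k alpha_k mu_k,

incompressible continuity, and conservative transport of the GDNF volume
fraction alpha by the mixture flux (optional drift velocity and diffusion).
Release enters as a velocity boundary condition on the carrier surfaces: a
60-day burst + sustained profile proportionally narrowed to 519 s (9 s burst
at 5.56e-5 ng/s, 510 s continuous at 2.94e-7 ng/s), applied either for equal
time (released mass tracks the carrier's emission surface) or for equal mass
(simulation time scaled by `reference_area / area`).  The readout is the
fluid-mean alpha at the last time step.  The solver is a staggered
finite-volume scheme with a coupled implicit velocity-pressure solve per
step; everything is deterministic.

## Worked example

```python
from ngc_elute import (GeometrySpec, ReleaseSystemSpec, build_relay_ngc,
                       place_release_system, run_case, mean_volume_fraction,
                       modified_profile, schedule_constant_time)

grid = place_release_system(build_relay_ngc(GeometrySpec(), h=0.02),
                            ReleaseSystemSpec.double_layer())
run = run_case(grid, schedule_constant_time(modified_profile()))
print(mean_volume_fraction(run.state, grid))   # -> 1.2410e-09
```

(The study runner in `ngc_elute.study` additionally renormalizes the
boundary speed to the carrier's analytic 2D perimeter — see
`docs/methods.md` — so its absolute readouts differ from this direct call
by a constant factor; all ratios between cases are unaffected.)

The full comparisons are driven by the numbered scripts under `analysis/`
(or the `ngc-elute` CLI).  `python analysis/02_constant_time_study.py` runs
all sixteen release-system cases for 519 s each at h = 0.02 mm and prints,
among others:

```
double/single ratio: 2.01   bulk/single ratio: 0.63
combined model vs default: +204.5 %
```

meaning: at equal release time the double-layer system holds about twice the
GDNF volume fraction of the default single layer (its emitting surface is
twice as large), the bulk hydrogel holds ~0.63x (its 2D perimeter is
smaller), and putting microspheres in all three cavities triples the source
and the stored fraction accordingly.  `analysis/03_constant_mass_study.py`
repeats the grid at equal released mass (double/single 1.01, bulk/single
0.21), and `analysis/04_film_study.py` sweeps the film thickness:

```
film_t0.100: mean GDNF volume fraction 7.326e-10
film_t0.125: mean GDNF volume fraction 8.172e-10
film_t0.150: mean GDNF volume fraction 9.225e-10
```

— thicker films hold the same released mass in a smaller lumen, so the mean
volume fraction rises monotonically.  Each script writes per-case readouts,
comparison tables and GDNF mass ledgers under `results/`.

`analysis/01_release_tables.py` regenerates the release-profile narrowing
and the constant-mass time budget (e.g. a 16-sphere system releases for
4.5 + 255 = 259.5 s, the bulk hydrogel for 3 + 163 = 166 s).

See `docs/methods.md` for the model, its numerical choices, and a frank
account of which published comparisons the physics reproduces and which it
cannot.

## Configuration

Geometry, release system and solver settings can be read from a YAML file
(see `configs/default.yaml` for the documented schema) and passed to the CLI:

```sh
ngc-elute run --mode constant_time --config configs/default.yaml --out results/ct
ngc-elute tables --out results/tables
ngc-elute report --study-dir results/ct
```
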