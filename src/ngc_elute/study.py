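"""Parametric study runner: the four release systems and feature sweeps.

Enumerates the published case grid — the default single-layer microsphere
system and its quantity/diameter/spacing/placement variations, the
double-layer system, the bulk hydrogel, the combined model (0.15 mm spacing
in all three cavities) — under the constant-time and constant-mass
protocols, plus the hydrogel-film thickness sweep (constant time only: the
film's emission surface is ~166x the reference, so an equal-mass budget
would fall below one time step).

Everything is deterministic: no random numbers appear anywhere in the
pipeline, so identical configurations reproduce identical output files.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

import ngc_elute
from ngc_elute.geometry import (
    DomainGrid,
    GeometrySpec,
    ReleaseSystemSpec,
    build_relay_ngc,
    place_release_system,
    release_perimeter_2d,
    report_geometry,
)
from ngc_elute.metrics import CaseReadout, compare_cases, mean_volume_fraction
from ngc_elute.mixture_solver import (
    DEFAULT_PHASES,
    CaseRun,
    SolverConfig,
    run_case,
)
from ngc_elute.release_model import (
    REFERENCE_PERIMETER_MM,
    ReleaseSchedule,
    emission_area,
    modified_profile,
    schedule_constant_mass,
    schedule_constant_time,
)

__all__ = ["StudyCase", "StudyResult", "build_manifest", "run_study", "run_single_case"]

MODES = ("constant_time", "constant_mass", "film")

#: Baseline case of each mode (the reference for ratios / % changes).
BASELINES = {"constant_time": "a_single_default", "constant_mass": "a_single_default", "film": "film_t0.100"}


@dataclass(frozen=True)
class StudyCase:
    """One fully determined simulation case (no stochastic elements)."""

    case_id: str
    label: str
    rss: ReleaseSystemSpec
    mode: str
    geometry: GeometrySpec = field(default_factory=GeometrySpec)

    def schedule(self, dt: float = 0.5, face_length_mm: float | None = None) -> ReleaseSchedule:
        """Time budget + boundary speeds for this case.

        ``face_length_mm`` is the 2D face length converting the case's mass
        rate into a per-face speed (defaults to the reference footprint; the
        study runner passes the rasterized length, renormalized so the
        integrated 2D emission matches the carrier's analytic perimeter).
        """
        p = modified_profile()
        kw = {} if face_length_mm is None else {"face_length_mm": face_length_mm}
        if self.mode in ("constant_time", "film"):
            return schedule_constant_time(p, dt, **kw)
        if self.mode == "constant_mass":
            return schedule_constant_mass(p, emission_area(self.rss), dt=dt, **kw)
        raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class StudyResult:
    """Per-case readouts plus comparisons and provenance."""

    readouts: dict[str, CaseReadout]
    comparisons: pd.DataFrame
    failures: dict[str, str]
    provenance: dict

    @property
    def ok(self) -> bool:
        return not self.failures


def _sphere_cases(mode: str, geom: GeometrySpec) -> list[StudyCase]:
    S = ReleaseSystemSpec.single_layer
    defs: list[tuple[str, str, ReleaseSystemSpec]] = [
        ("a_single_default", "single layer, 8x0.1mm @0.2mm, middle", S()),
        ("b_single_front", "single layer, front cavity", S(placements=("front",))),
        ("c_single_back", "single layer, back cavity", S(placements=("back",))),
        ("d_single_fmb", "single layer, front+middle+back (24)", S(placements=("front", "middle", "back"))),
        ("e_single_fb", "single layer, front+back (16)", S(placements=("front", "back"))),
        ("f_single_fm", "single layer, front+middle (16)", S(placements=("front", "middle"))),
        ("g_single_mb", "single layer, middle+back (16)", S(placements=("middle", "back"))),
        ("h_single_q6", "single layer, 6 microspheres", S(quantity=6)),
        ("i_single_q4", "single layer, 4 microspheres", S(quantity=4)),
        ("j_single_d150", "single layer, 0.15 mm spheres", S(diameter=0.15)),
        ("k_single_d125", "single layer, 0.125 mm spheres", S(diameter=0.125)),
        ("l_single_s150", "single layer, 0.15 mm spacing", S(spacing=0.15)),
        ("m_single_s250", "single layer, 0.25 mm spacing", S(spacing=0.25)),
        ("n_combined", "combined: 0.15 mm spacing, front+middle+back", S(spacing=0.15, placements=("front", "middle", "back"))),
        ("o_double_layer", "double layer, 16x0.1mm, middle", ReleaseSystemSpec.double_layer()),
        ("p_bulk_hydrogel", "bulk hydrogel, 0.5 mm, middle", ReleaseSystemSpec.bulk_hydrogel()),
    ]
    return [StudyCase(cid, lab, rss, mode, geom) for cid, lab, rss in defs]


def build_manifest(mode: str, geom: GeometrySpec | None = None) -> list[StudyCase]:
    """Deterministic, complete case list for one protocol mode."""
    geom = geom or GeometrySpec()
    if mode in ("constant_time", "constant_mass"):
        return _sphere_cases(mode, geom)
    if mode == "film":
        return [
            StudyCase(
                f"film_t{t:.3f}",
                f"hydrogel film, {t} mm thick",
                ReleaseSystemSpec.hydrogel_film(t, geom),
                "film",
                geom,
            )
            for t in (0.1, 0.125, 0.15)
        ]
    raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


def run_single_case(
    case: StudyCase,
    h: float = 0.02,
    config: SolverConfig | None = None,
    phases=DEFAULT_PHASES,
) -> tuple[CaseReadout, CaseRun, DomainGrid]:
    """Build, schedule and integrate one case; return its readout and run.

    The per-face boundary speed is the case's mass-release rate divided by a
    face length renormalized so that the integrated 2D emission equals the
    analytic emitting perimeter of the carrier (removing rasterization noise
    of a few percent from the emitted mass): the total emitted GDNF volume of
    the default case over its schedule is exactly the profile's released mass
    over the phase density.
    """
    config = config or SolverConfig()
    grid = place_release_system(build_relay_ngc(case.geometry, h), case.rss)
    perim = release_perimeter_2d(case.rss, case.geometry)
    raster = grid.release_face_length_mm()
    if perim > 0 and raster > 0:
        face_length = raster * REFERENCE_PERIMETER_MM / perim
    else:
        face_length = None
    sched = case.schedule(config.dt, face_length_mm=face_length)
    run = run_case(grid, sched, phases, config)
    readout = CaseReadout(
        case_id=case.case_id,
        mode=case.mode,
        final_time=run.state.t,
        mean_alpha=mean_volume_fraction(run.state, grid),
        max_velocity=run.max_velocity,
        steady_state_time=run.steady_state_time,
    )
    return readout, run, grid


def run_study(
    manifest: list[StudyCase],
    h: float = 0.02,
    out_dir: str | Path | None = None,
    config: SolverConfig | None = None,
    write_fields: bool = False,
) -> StudyResult:
    """Run every case in a manifest; write readouts, comparisons and ledgers.

    Individual case failures are recorded and the study continues;
    ``StudyResult.ok`` is False when anything failed.
    """
    config = config or SolverConfig()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        (out / "ledgers").mkdir(parents=True, exist_ok=True)

    readouts: dict[str, CaseReadout] = {}
    extras = []
    failures: dict[str, str] = {}
    for case in manifest:
        try:
            readout, run, grid = run_single_case(case, h, config)
        except Exception as exc:  # noqa: BLE001 - study must keep going
            failures[case.case_id] = f"{type(exc).__name__}: {exc}"
            continue
        readouts[case.case_id] = readout
        geo = report_geometry(grid)
        extras.append(
            {
                "case_id": case.case_id,
                "label": case.label,
                "mode": case.mode,
                "final_time_s": readout.final_time,
                "mean_alpha": readout.mean_alpha,
                "mean_alpha_domain": readout.mean_alpha
                * grid.fluid.sum()
                / grid.cell_role.size,
                "max_velocity_m_s": readout.max_velocity,
                "steady_state_time_s": readout.steady_state_time,
                "conservation_error": run.conservation_error,
                "cfl_max": run.cfl_max,
                "emission_area_mm2": emission_area(case.rss) if case.rss.kind != "none" else 0.0,
                "porosity": geo["porosity"],
                "blockage_ratio": geo["blockage_ratio"],
            }
        )
        if out is not None:
            run.ledger.to_csv(out / "ledgers" / f"{case.case_id}.csv", index=False)
            if write_fields:
                from ngc_elute.io import write_vtk

                write_vtk(run.state, grid, out / f"{case.case_id}.vtk")

    mode = manifest[0].mode if manifest else "constant_time"
    baseline = BASELINES.get(mode)
    if baseline in readouts and len(readouts) >= 2:
        comparisons = compare_cases(list(readouts.values()), baseline)
    else:
        comparisons = pd.DataFrame()

    prov = {
        "package_version": ngc_elute.__version__,
        "resolution_mm": h,
        "dt_s": config.dt,
        "inlet1_speed_m_s": config.inlet1_speed,
        "advection_scheme": config.advection_scheme,
        "drift_closure": config.drift_closure,
        "depth_mm": config.depth_mm,
        "config_hash": hashlib.sha256(repr(config).encode()).hexdigest()[:16],
        "n_cases": len(manifest),
        "n_failed": len(failures),
    }
    result = StudyResult(readouts=readouts, comparisons=comparisons, failures=failures, provenance=prov)

    if out is not None:
        pd.DataFrame(extras).to_csv(out / "readouts.csv", index=False)
        if not comparisons.empty:
            comparisons.to_csv(out / "comparisons.csv")
        with open(out / "run_log.txt", "w") as f:
            for k, v in prov.items():
                f.write(f"{k}: {v}\n")
            for cid, msg in failures.items():
                f.write(f"FAILED {cid}: {msg}\n")
    return result
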