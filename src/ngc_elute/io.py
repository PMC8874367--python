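"""Config parsing and field export (CSV masks, legacy-VTK snapshots).

The configuration file is plain YAML with three optional sections —
``geometry``, ``release_system`` and ``solver`` — whose keys mirror the
dataclass fields of :class:`~ngc_elute.geometry.GeometrySpec`,
:class:`~ngc_elute.geometry.ReleaseSystemSpec` and
:class:`~ngc_elute.mixture_solver.SolverConfig`::

    geometry:
      ngc_diameter: 2.0        # mm
      channel_diameter: 0.34   # mm
    release_system:
      kind: single_layer_microsphere
      microsphere_quantity: 8
      placements: [middle]
    solver:
      inlet1_speed: 1.0e-6     # m/s

Unknown keys raise immediately so typos cannot silently fall back to
defaults.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

from ngc_elute.geometry import DomainGrid, GeometrySpec, ReleaseSystemSpec
from ngc_elute.mixture_solver import MixtureState, SolverConfig

__all__ = ["load_config", "write_vtk", "write_grid_vtk"]


def _build(cls, section: dict, name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    bad = set(section) - allowed
    if bad:
        raise KeyError(f"unknown keys in config section {name!r}: {sorted(bad)}")
    if "placements" in section:
        section = {**section, "placements": tuple(section["placements"])}
    for tup in ("gravity", "body_force"):
        if tup in section:
            section = {**section, tup: tuple(section[tup])}
    return cls(**section)


def load_config(path) -> tuple[GeometrySpec, ReleaseSystemSpec, SolverConfig]:
    """Read geometry/release-system/solver settings from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    geom = _build(GeometrySpec, raw.get("geometry", {}) or {}, "geometry")
    rss_raw = raw.get("release_system", {}) or {}
    if rss_raw:
        rss = _build(ReleaseSystemSpec, rss_raw, "release_system")
    else:
        rss = ReleaseSystemSpec.none()
    solver = _build(SolverConfig, raw.get("solver", {}) or {}, "solver")
    return geom, rss, solver


def _vtk_header(f, grid: DomainGrid, title: str) -> None:
    h = grid.h
    f.write("# vtk DataFile Version 3.0\n")
    f.write(f"{title}\n")
    f.write("ASCII\n")
    f.write("DATASET STRUCTURED_POINTS\n")
    f.write(f"DIMENSIONS {grid.nx + 1} {grid.ny + 1} 1\n")
    f.write("ORIGIN 0 0 0\n")
    f.write(f"SPACING {h} {h} {h}\n")
    f.write(f"CELL_DATA {grid.nx * grid.ny}\n")


def _write_scalar(f, name: str, data: np.ndarray, fmt: str = "%.9e") -> None:
    f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
    np.savetxt(f, data.reshape(1, -1), fmt=fmt)


def write_grid_vtk(grid: DomainGrid, path) -> None:
    """Cell-role raster as a legacy-VTK structured-points file."""
    with open(path, "w") as f:
        _vtk_header(f, grid, "relay NGC cell roles")
        f.write("SCALARS cell_role int 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, grid.cell_role.reshape(1, -1), fmt="%d")


def write_vtk(state: MixtureState, grid: DomainGrid, path) -> None:
    """Velocity, pressure and volume-fraction snapshot in legacy-VTK format."""
    uc = 0.5 * (state.u[:, :-1] + state.u[:, 1:])
    vc = 0.5 * (state.v[:-1, :] + state.v[1:, :])
    with open(path, "w") as f:
        _vtk_header(f, grid, f"mixture state t={state.t} s")
        _write_scalar(f, "alpha", state.alpha)
        _write_scalar(f, "pressure", state.p)
        f.write("VECTORS velocity float\n")
        vec = np.stack([uc.ravel(), vc.ravel(), np.zeros(uc.size)], axis=1)
        np.savetxt(f, vec, fmt="%.9e")
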