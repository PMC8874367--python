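"""Parametric relay-conduit geometry and release-system placement.

The relay nerve-guide conduit is modeled as a 2D longitudinal (axial) section:
three full-width loading cavities (front, middle, back) joined by two
multichannel conduit segments.  A diametral cut of the 3D conduit (one center
channel plus a ring of eight) shows three channel lumens, so the section
carries ``n_channels_2d = 3`` parallel channels by default.

The domain is rasterized onto a uniform cell-centered grid with three cell
roles: ``fluid``, ``wall`` and ``release_inlet`` (the fluid-facing surface
cells of an embedded drug carrier; their faces become the release boundary).
The left exterior edge is the interstitial-fluid inlet (inlet 1), the right
exterior edge the outlet; every other exterior face is a wall.

Vertical coordinates are handled as exact signed half-integer multiples of the
cell size measured from the conduit mid-axis, so that the rasterization of a
mirror-symmetric configuration is mirror-symmetric to the bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "GeometrySpec",
    "ReleaseSystemSpec",
    "DomainGrid",
    "UnresolvableGeometryError",
    "PlacementError",
    "BlockageError",
    "FLUID",
    "WALL",
    "RELEASE_INLET",
    "build_relay_ngc",
    "place_release_system",
    "report_geometry",
    "release_perimeter_2d",
]

FLUID, WALL, RELEASE_INLET = 0, 1, 2

CAVITY_NAMES = ("front", "middle", "back")


class UnresolvableGeometryError(ValueError):
    """A geometric feature is too thin for the requested cell size."""


class PlacementError(ValueError):
    """A release body does not fit inside its cavity or overlaps walls."""


class BlockageError(ValueError):
    """A film or assembly would occlude a channel."""


@dataclass(frozen=True)
class GeometrySpec:
    """Dimensions of the relay multichannel conduit (all lengths in mm).

    ``segment_length`` defaults to 2.17 mm so that the hydrogel film lining
    both conduit segments of all nine 3D channels has an emission surface of
    ~166x the default single-layer microsphere system (the published area
    ratio between the two).
    """

    ngc_diameter: float = 2.0
    channel_diameter: float = 0.34
    n_channels_3d: int = 9
    n_channels_2d: int = 3
    wall_thickness: float = 0.2
    cavity_length: float = 1.0
    n_cavities: int = 3
    segment_length: float = 2.17
    total_porosity_target: float = 0.40

    def __post_init__(self) -> None:
        for name in (
            "ngc_diameter",
            "channel_diameter",
            "wall_thickness",
            "cavity_length",
            "segment_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.channel_diameter >= self.ngc_diameter:
            raise ValueError("channel_diameter must be < ngc_diameter")
        if self.n_channels_2d < 1:
            raise ValueError("n_channels_2d must be >= 1")
        if self.n_cavities != 3:
            raise ValueError("the relay design has exactly 3 cavities (front/middle/back)")
        if self.inner_diameter <= 0:
            raise ValueError("wall_thickness leaves no lumen")
        if self.n_channels_2d * self.channel_diameter > self.inner_diameter:
            raise ValueError("channels do not fit inside the inner diameter")

    @property
    def inner_diameter(self) -> float:
        return self.ngc_diameter - 2.0 * self.wall_thickness

    @property
    def total_length(self) -> float:
        return self.n_cavities * self.cavity_length + 2.0 * self.segment_length

    @property
    def channel_gap(self) -> float:
        """Wall material between/around channels in the 2D section."""
        n = self.n_channels_2d
        return (self.inner_diameter - n * self.channel_diameter) / (n + 1)

    def channel_offsets(self) -> np.ndarray:
        """Signed channel-center offsets from the conduit mid-axis (mm)."""
        n = self.n_channels_2d
        pitch = self.channel_diameter + self.channel_gap
        return (np.arange(n) - (n - 1) / 2.0) * pitch

    def cavity_span(self, name: str) -> tuple[float, float]:
        """Axial [start, end) of a named cavity (mm from the inlet edge)."""
        i = CAVITY_NAMES.index(name)
        start = i * (self.cavity_length + self.segment_length)
        return start, start + self.cavity_length

    def segment_spans(self) -> list[tuple[float, float]]:
        c, s = self.cavity_length, self.segment_length
        return [(c, c + s), (2 * c + s, 2 * c + 2 * s)]

    def cavity_center_x(self, name: str) -> float:
        a, b = self.cavity_span(name)
        return 0.5 * (a + b)


@dataclass(frozen=True)
class ReleaseSystemSpec:
    """A drug carrier embedded in the conduit (all lengths in mm).

    ``microsphere_quantity`` counts spheres *per selected cavity* (all layers
    included), matching the convention in which a front+middle+back placement
    of the 8-sphere system totals 24 spheres.
    """

    kind: str
    microsphere_diameter: float = 0.1
    microsphere_quantity: int = 8
    adjacent_distance: float = 0.2
    placements: tuple[str, ...] = ("middle",)
    layer_gap: float = 0.02
    hydrogel_diameter: float = 0.5
    film_thickness: float = 0.1
    # film emission-area context, filled by the hydrogel_film constructor
    film_lined_length_mm: float | None = None
    film_channel_context: tuple[int, float] | None = None

    KINDS = (
        "single_layer_microsphere",
        "double_layer_microsphere",
        "bulk_hydrogel",
        "hydrogel_film",
        "none",
    )

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown release-system kind: {self.kind!r}")
        if self.microsphere_quantity < 0:
            raise ValueError("microsphere_quantity must be >= 0")
        bad = set(self.placements) - set(CAVITY_NAMES)
        if bad:
            raise ValueError(f"unknown placements: {sorted(bad)}")

    @property
    def total_quantity(self) -> int:
        """Total sphere count across all selected cavities (0 for hydrogels... 1 for bulk)."""
        if self.kind in ("single_layer_microsphere", "double_layer_microsphere"):
            return self.microsphere_quantity * len(self.placements)
        if self.kind == "bulk_hydrogel":
            return 1
        return 0

    @property
    def assembly_thickness(self) -> float:
        """Vertical extent of the carrier stack on one cavity surface."""
        if self.kind == "single_layer_microsphere":
            return self.microsphere_diameter
        if self.kind == "double_layer_microsphere":
            return 2.0 * self.microsphere_diameter + self.layer_gap
        if self.kind == "hydrogel_film":
            return self.film_thickness
        return 0.0

    @classmethod
    def single_layer(
        cls,
        quantity: int = 8,
        diameter: float = 0.1,
        spacing: float = 0.2,
        placements: tuple[str, ...] = ("middle",),
    ) -> "ReleaseSystemSpec":
        return cls(
            kind="single_layer_microsphere",
            microsphere_diameter=diameter,
            microsphere_quantity=quantity,
            adjacent_distance=spacing,
            placements=tuple(placements),
        )

    @classmethod
    def double_layer(
        cls,
        quantity: int = 16,
        diameter: float = 0.1,
        spacing: float = 0.2,
        layer_gap: float = 0.02,
        placements: tuple[str, ...] = ("middle",),
    ) -> "ReleaseSystemSpec":
        return cls(
            kind="double_layer_microsphere",
            microsphere_diameter=diameter,
            microsphere_quantity=quantity,
            adjacent_distance=spacing,
            layer_gap=layer_gap,
            placements=tuple(placements),
        )

    @classmethod
    def bulk_hydrogel(cls, diameter: float = 0.5) -> "ReleaseSystemSpec":
        return cls(kind="bulk_hydrogel", hydrogel_diameter=diameter, placements=("middle",))

    @classmethod
    def hydrogel_film(
        cls, thickness: float = 0.1, geom: GeometrySpec | None = None
    ) -> "ReleaseSystemSpec":
        geom = geom or GeometrySpec()
        return cls(
            kind="hydrogel_film",
            film_thickness=thickness,
            placements=(),
            film_lined_length_mm=2.0 * geom.segment_length,
            film_channel_context=(geom.n_channels_3d, geom.channel_diameter),
        )

    @classmethod
    def none(cls) -> "ReleaseSystemSpec":
        return cls(kind="none", microsphere_quantity=0, placements=())


@dataclass
class DomainGrid:
    """Rasterized 2D computational domain.

    ``cell_role[j, i]`` indexes rows (y, bottom to top) then columns (x, inlet
    to outlet); cells are ``h`` mm squares with the origin at the bottom-left
    (inlet) corner.  ``release_body`` marks every cell of a drug carrier
    (surface cells carry role ``RELEASE_INLET``; interior body cells are
    walls).
    """

    h: float
    nx: int
    ny: int
    cell_role: np.ndarray
    spec: GeometrySpec
    rss: ReleaseSystemSpec | None = None
    release_body: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.release_body is None:
            self.release_body = np.zeros((self.ny, self.nx), dtype=bool)

    @property
    def fluid(self) -> np.ndarray:
        return self.cell_role == FLUID

    @property
    def wall(self) -> np.ndarray:
        return self.cell_role == WALL

    @property
    def release(self) -> np.ndarray:
        return self.cell_role == RELEASE_INLET

    @property
    def solid(self) -> np.ndarray:
        """Cells excluded from the flow (walls and release bodies)."""
        return self.cell_role != FLUID

    def x_centers(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.h

    def y_signed(self) -> np.ndarray:
        """Cell-center y offsets from the mid-axis; exactly antisymmetric."""
        return (2 * np.arange(self.ny) + 1 - self.ny) * (self.h / 2.0)

    def y_centers(self) -> np.ndarray:
        return self.y_signed() + self.ny * self.h / 2.0

    def copy(self) -> "DomainGrid":
        return DomainGrid(
            h=self.h,
            nx=self.nx,
            ny=self.ny,
            cell_role=self.cell_role.copy(),
            spec=self.spec,
            rss=self.rss,
            release_body=self.release_body.copy(),
        )

    def assert_connected(self) -> None:
        """The fluid region must be one component touching inlet and outlet."""
        labels, n = ndimage.label(self.fluid)
        if n == 0:
            raise UnresolvableGeometryError("no fluid cells in the domain")
        left = set(np.unique(labels[:, 0])) - {0}
        right = set(np.unique(labels[:, -1])) - {0}
        through = left & right
        if not through:
            raise BlockageError("no fluid path connects inlet 1 to the outlet")
        if n > 1:
            # isolated pockets are a rasterization defect worth failing on
            sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
            raise UnresolvableGeometryError(
                f"fluid region has {n} components (sizes {sizes.astype(int).tolist()})"
            )

    def mask_csv(self, path) -> None:
        """Plain integer dump of cell roles (one row per grid row, top first)."""
        np.savetxt(path, self.cell_role[::-1], fmt="%d", delimiter=",")

    def release_face_length_mm(self) -> float:
        """Total rasterized length of release-to-fluid faces (mm)."""
        R, F = self.release, self.fluid
        n = 0
        n += int((R[:, :-1] & F[:, 1:]).sum() + (R[:, 1:] & F[:, :-1]).sum())
        n += int((R[:-1, :] & F[1:, :]).sum() + (R[1:, :] & F[:-1, :]).sum())
        return n * self.h


def build_relay_ngc(spec: GeometrySpec, h: float) -> DomainGrid:
    """Rasterize the empty relay conduit at cell size ``h`` (mm).

    Raises :class:`UnresolvableGeometryError` when a channel, cavity or wall
    gap would span fewer than the minimum number of cells.
    """
    if h <= 0:
        raise ValueError("h must be > 0")
    if spec.channel_diameter < 4.0 * h:
        raise UnresolvableGeometryError(
            f"channel diameter {spec.channel_diameter} mm needs >= 4 cells, h={h} mm"
        )
    for name, size in (
        ("cavity_length", spec.cavity_length),
        ("wall_thickness", spec.wall_thickness),
        ("inter-channel gap", spec.channel_gap),
    ):
        if 0 < size < 2.0 * h:
            raise UnresolvableGeometryError(f"{name} ({size} mm) thinner than 2h ({2*h} mm)")

    # the raster covers floor(L/h) whole cells; when h does not divide a
    # dimension exactly the domain is truncated by less than one cell rather
    # than padded with a dead wall layer at the outlet
    nx = int(math.floor(spec.total_length / h + 1e-9))
    ny = int(math.floor(spec.ngc_diameter / h + 1e-9))
    role = np.full((ny, nx), WALL, dtype=np.uint8)

    x = (np.arange(nx) + 0.5) * h
    ys = (2 * np.arange(ny) + 1 - ny) * (h / 2.0)  # signed, antisymmetric
    inner = np.abs(ys) < spec.inner_diameter / 2.0

    # cavities: full inner diameter
    in_cavity = np.zeros(nx, dtype=bool)
    for name in CAVITY_NAMES:
        a, b = spec.cavity_span(name)
        in_cavity |= (x >= a) & (x < b)
    role[np.ix_(inner, in_cavity)] = FLUID

    # conduit segments: channel lumens only
    in_segment = np.zeros(nx, dtype=bool)
    for a, b in spec.segment_spans():
        in_segment |= (x >= a) & (x < b)
    in_channel = np.zeros(ny, dtype=bool)
    for off in spec.channel_offsets():
        in_channel |= np.abs(ys - off) < spec.channel_diameter / 2.0
    role[np.ix_(inner & in_channel, in_segment)] = FLUID

    grid = DomainGrid(h=h, nx=nx, ny=ny, cell_role=role, spec=spec)
    grid.assert_connected()
    return grid


def _sphere_centers(
    spec: GeometrySpec, rss: ReleaseSystemSpec, cavity: str
) -> list[tuple[float, float, float]]:
    """Disc centers (x, y_signed, r) for one cavity of a microsphere system.

    Spheres sit tangent to the cavity top/bottom surfaces, split evenly
    between the two (odd counts put the extra sphere on top); a double layer
    stacks a second row ``layer_gap`` inside the first.  Rows are centered on
    the cavity mid-plane with centers ``adjacent_distance`` apart.
    """
    n = rss.microsphere_quantity
    d, r, s = rss.microsphere_diameter, rss.microsphere_diameter / 2.0, rss.adjacent_distance
    xc = spec.cavity_center_x(cavity)
    surface = spec.inner_diameter / 2.0  # |y_signed| of the cavity surface
    n_top, n_bot = math.ceil(n / 2), math.floor(n / 2)
    discs: list[tuple[float, float, float]] = []
    for count, sign in ((n_top, +1.0), (n_bot, -1.0)):
        if rss.kind == "single_layer_microsphere":
            rows = [(count, surface - r)]
        else:  # double layer: tangent row gets the extra sphere of an odd count
            rows = [
                (math.ceil(count / 2), surface - r),
                (math.floor(count / 2), surface - r - d - rss.layer_gap),
            ]
        for m, ydist in rows:
            for i in range(m):
                dx = (i - (m - 1) / 2.0) * s
                discs.append((xc + dx, sign * ydist, r))
    return discs


def _check_in_cavity(
    spec: GeometrySpec, cavity: str, discs: list[tuple[float, float, float]], what: str
) -> None:
    a, b = spec.cavity_span(cavity)
    half = spec.inner_diameter / 2.0
    tol = 1e-9
    for x, ysc, r in discs:
        if x - r < a - tol or x + r > b + tol:
            raise PlacementError(
                f"{what} assembly exceeds the {cavity} cavity axially "
                f"(body [{x - r:.4f}, {x + r:.4f}] vs cavity [{a}, {b}])"
            )
        if abs(ysc) + r > half + tol:
            raise PlacementError(f"{what} assembly exceeds the cavity surfaces vertically")


def place_release_system(grid: DomainGrid, rss: ReleaseSystemSpec) -> DomainGrid:
    """Embed a release system, marking its fluid-facing surface as inlet 2.

    Returns a new grid; body interiors become walls, surface cells
    ``RELEASE_INLET``.  Raises :class:`PlacementError` when an assembly does
    not fit its cavity and :class:`BlockageError` when a film would close a
    channel.
    """
    spec = grid.spec
    out = grid.copy()
    out.rss = rss

    if rss.kind == "none" or (
        rss.kind in ("single_layer_microsphere", "double_layer_microsphere")
        and rss.microsphere_quantity == 0
    ):
        return out

    body = np.zeros((grid.ny, grid.nx), dtype=bool)
    x = grid.x_centers()[None, :]
    ys = grid.y_signed()[:, None]

    if rss.kind in ("single_layer_microsphere", "double_layer_microsphere"):
        for cavity in rss.placements:
            discs = _sphere_centers(spec, rss, cavity)
            _check_in_cavity(spec, cavity, discs, rss.kind)
            for xc, ysc, r in discs:
                body |= (x - xc) ** 2 + (ys - ysc) ** 2 <= r**2
    elif rss.kind == "bulk_hydrogel":
        r = rss.hydrogel_diameter / 2.0
        if rss.hydrogel_diameter > spec.cavity_length + 1e-9:
            raise PlacementError("bulk hydrogel diameter exceeds the cavity length")
        if rss.hydrogel_diameter > spec.inner_diameter + 1e-9:
            raise PlacementError("bulk hydrogel diameter exceeds the lumen")
        xc = spec.cavity_center_x("middle")
        body |= (x - xc) ** 2 + ys**2 <= r**2
    elif rss.kind == "hydrogel_film":
        t = rss.film_thickness
        if t >= spec.channel_diameter / 2.0:
            raise BlockageError(
                f"film thickness {t} mm would occlude the {spec.channel_diameter} mm channels"
            )
        in_segment = np.zeros(grid.nx, dtype=bool)
        for a, b in spec.segment_spans():
            in_segment |= (x[0] >= a) & (x[0] < b)
        half_ch = spec.channel_diameter / 2.0
        lining = np.zeros(grid.ny, dtype=bool)
        for off in spec.channel_offsets():
            dist = np.abs(ys[:, 0] - off)
            lining |= (dist < half_ch) & (dist > half_ch - t)
        body |= np.outer(lining, in_segment)

    body &= grid.fluid  # bodies only displace fluid
    # surface cells: body cells with at least one remaining-fluid 4-neighbor
    fluid_left = grid.fluid & ~body
    nb = np.zeros_like(body)
    nb[1:, :] |= fluid_left[:-1, :]
    nb[:-1, :] |= fluid_left[1:, :]
    nb[:, 1:] |= fluid_left[:, :-1]
    nb[:, :-1] |= fluid_left[:, 1:]
    surface = body & nb

    out.cell_role[body] = WALL
    out.cell_role[surface] = RELEASE_INLET
    out.release_body = body
    out.assert_connected()
    if not surface.any():
        raise PlacementError("release system rasterized to zero surface cells; refine h")
    return out


def release_perimeter_2d(rss: ReleaseSystemSpec, spec: GeometrySpec | None = None) -> float:
    """Analytic emitting perimeter of the release system in the 2D section (mm).

    Microspheres appear as discs (``pi * d`` each), the bulk hydrogel as one
    disc, and the film as the inner surfaces lining both conduit segments of
    every sectioned channel.  This perimeter — not the 3D spherical-surface
    emission area used for time budgeting — is what sets the case's released
    mass in the 2D transport model.
    """
    spec = spec or GeometrySpec()
    if rss.kind in ("single_layer_microsphere", "double_layer_microsphere"):
        return rss.total_quantity * math.pi * rss.microsphere_diameter
    if rss.kind == "bulk_hydrogel":
        return math.pi * rss.hydrogel_diameter
    if rss.kind == "hydrogel_film":
        return 2.0 * spec.n_channels_2d * 2.0 * spec.segment_length
    return 0.0


def report_geometry(grid: DomainGrid) -> dict:
    """Porosity, release footprint and blockage summary of a rasterized grid.

    Porosity is the fluid-area fraction of the conduit interior (the region
    inside the outer walls); the footprint is the rasterized area of the
    release bodies.  The blockage ratio relates the carrier stack thickness to
    the channel diameter (reported for double layers and films).
    """
    spec = grid.spec
    ys = grid.y_signed()
    inner = np.abs(ys) < spec.inner_diameter / 2.0
    inner_cells = int(inner.sum()) * grid.nx
    fluid_inner = int((grid.fluid | grid.release | grid.release_body)[inner, :].sum())
    # release bodies count as part of the pore space they occupy
    porosity = fluid_inner / inner_cells if inner_cells else float("nan")

    footprint = float(grid.release_body.sum()) * grid.h**2
    report = {
        "porosity": porosity,
        "porosity_target": spec.total_porosity_target,
        "release_footprint_mm2": footprint,
        "n_release_surface_cells": int(grid.release.sum()),
        "blockage_ratio": None,
    }
    rss = grid.rss
    if rss is not None and rss.kind == "double_layer_microsphere":
        report["blockage_ratio"] = rss.assembly_thickness / spec.channel_diameter
    elif rss is not None and rss.kind == "hydrogel_film":
        report["blockage_ratio"] = 2.0 * rss.film_thickness / spec.channel_diameter
    return report
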