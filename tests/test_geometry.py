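"""Rasterized relay-conduit geometry and release-system placement."""

import math

import numpy as np
import pytest
from scipy import ndimage

from ngc_elute.geometry import (
    FLUID,
    RELEASE_INLET,
    WALL,
    BlockageError,
    GeometrySpec,
    PlacementError,
    ReleaseSystemSpec,
    UnresolvableGeometryError,
    build_relay_ngc,
    place_release_system,
    report_geometry,
)

RSS = ReleaseSystemSpec


def analytic_porosity(spec: GeometrySpec) -> float:
    """Closed-form fluid fraction of the conduit interior."""
    cavities = spec.n_cavities * spec.cavity_length * spec.inner_diameter
    channels = spec.n_channels_2d * spec.channel_diameter * 2 * spec.segment_length
    return (cavities + channels) / (spec.total_length * spec.inner_diameter)


class TestBuildRelay:
    def test_layout(self, default_spec, coarse_grid):
        g = coarse_grid
        assert g.nx == int(default_spec.total_length / g.h + 1e-9)
        assert g.ny == int(default_spec.ngc_diameter / g.h + 1e-9)
        # middle cavity spans the full inner diameter, one cavity_length long
        a, b = default_spec.cavity_span("middle")
        assert (a, b) == (3.17, 4.17)
        i0, i1 = int(a / g.h), int(b / g.h)
        inner = np.abs(g.y_signed()) < default_spec.inner_diameter / 2
        assert g.fluid[np.ix_(inner, np.arange(i0 + 1, i1 - 1))].all()

    def test_mirror_symmetry(self, coarse_grid):
        assert np.array_equal(coarse_grid.cell_role, coarse_grid.cell_role[::-1])

    def test_connected_single_component(self, coarse_grid):
        labels, n = ndimage.label(coarse_grid.fluid)
        assert n == 1

    def test_porosity_matches_analytic(self, default_spec):
        g = build_relay_ngc(default_spec, 0.02)
        assert report_geometry(g)["porosity"] == pytest.approx(
            analytic_porosity(default_spec), rel=0.02
        )

    def test_wall_area_converges_under_refinement(self, default_spec):
        coarse = build_relay_ngc(default_spec, 0.04)
        fine = build_relay_ngc(default_spec, 0.02)
        a_coarse = coarse.wall.sum() * 0.04**2
        a_fine = fine.wall.sum() * 0.02**2
        assert abs(a_coarse - a_fine) / a_fine < 0.05

    def test_single_lumen_degenerate(self):
        spec = GeometrySpec(channel_diameter=1.6, n_channels_2d=1)
        g = build_relay_ngc(spec, 0.02)
        assert report_geometry(g)["porosity"] == pytest.approx(1.0)

    def test_unresolvable_channel(self, default_spec):
        with pytest.raises(UnresolvableGeometryError):
            build_relay_ngc(default_spec, 0.1)  # < 4 cells per channel

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            GeometrySpec(channel_diameter=2.5)
        with pytest.raises(ValueError):
            GeometrySpec(n_cavities=2)
        with pytest.raises(ValueError):
            GeometrySpec(n_channels_2d=0)


def _disc_count(grid) -> int:
    _, n = ndimage.label(grid.release_body)
    return n


class TestPlacement:
    def test_single_layer_symmetric_rows(self, coarse_grid):
        g = place_release_system(coarse_grid, RSS.single_layer(quantity=8))
        assert _disc_count(g) == 8
        # 4 discs tangent to the upper surface, 4 to the lower, symmetric
        assert np.array_equal(g.cell_role, g.cell_role[::-1])
        top = g.release_body[g.ny // 2 :, :].sum()
        bottom = g.release_body[: g.ny // 2, :].sum()
        assert top == bottom

    def test_triple_placement_gives_24_discs(self, coarse_grid):
        g = place_release_system(
            coarse_grid, RSS.single_layer(quantity=8, placements=("front", "middle", "back"))
        )
        assert _disc_count(g) == 24

    def test_zero_quantity_is_noop(self, coarse_grid):
        g = place_release_system(coarse_grid, RSS.single_layer(quantity=0))
        assert (g.cell_role == coarse_grid.cell_role).all()
        assert g.release.sum() == 0

    def test_release_surface_borders_fluid(self, coarse_single_layer):
        g = coarse_single_layer
        R, F = g.release, g.fluid
        nb = np.zeros_like(R)
        nb[1:, :] |= F[:-1, :]
        nb[:-1, :] |= F[1:, :]
        nb[:, 1:] |= F[:, :-1]
        nb[:, :-1] |= F[:, 1:]
        assert (nb | ~R).all()  # every release-inlet cell touches fluid

    def test_bulk_hydrogel_half_of_middle_cavity(self, default_spec):
        g = place_release_system(build_relay_ngc(default_spec, 0.02), RSS.bulk_hydrogel(0.5))
        xs = g.x_centers()[g.release_body.any(axis=0)]
        a, b = default_spec.cavity_span("middle")
        assert xs.min() > a and xs.max() < b
        assert xs.max() - xs.min() == pytest.approx(0.5, abs=2 * g.h)
        assert (b - a) == pytest.approx(2 * 0.5)  # hydrogel fills half the cavity
        # rasterized footprint converges on the analytic disc area
        assert g.release_body.sum() * g.h**2 == pytest.approx(math.pi * 0.25**2, rel=0.05)

    def test_film_lines_channels(self, default_spec):
        g = place_release_system(build_relay_ngc(default_spec, 0.02), RSS.hydrogel_film(0.1, default_spec))
        assert np.array_equal(g.cell_role, g.cell_role[::-1])
        # the channel core stays open
        labels, n = ndimage.label(g.fluid)
        assert n == 1

    def test_film_blockage(self, coarse_grid, default_spec):
        with pytest.raises(BlockageError):
            place_release_system(coarse_grid, RSS.hydrogel_film(0.2, default_spec))

    def test_oversized_assembly_rejected(self, coarse_grid):
        with pytest.raises(PlacementError):
            place_release_system(coarse_grid, RSS.single_layer(quantity=8, spacing=0.35))
        with pytest.raises(PlacementError):
            place_release_system(coarse_grid, RSS.bulk_hydrogel(diameter=1.2))


class TestReport:
    def test_double_layer_blockage_ratio(self, coarse_grid):
        g = place_release_system(coarse_grid, RSS.double_layer())
        r = report_geometry(g)
        assert r["blockage_ratio"] == pytest.approx((2 * 0.1 + 0.02) / 0.34)
        assert r["blockage_ratio"] > 200.0 / 340.0  # stack exceeds half the channel

    def test_footprint_reported(self, default_spec):
        # at h = 0.02 a 0.1 mm disc spans 5 cells; the rasterized footprint
        # should be within ~15 % of the analytic disc area
        g = place_release_system(build_relay_ngc(default_spec, 0.02), RSS.single_layer())
        r = report_geometry(g)
        assert r["release_footprint_mm2"] == pytest.approx(8 * math.pi * 0.05**2, rel=0.15)
        assert r["n_release_surface_cells"] > 0

    def test_raster_deterministic(self, default_spec):
        a = place_release_system(build_relay_ngc(default_spec, 0.04), RSS.single_layer())
        b = place_release_system(build_relay_ngc(default_spec, 0.04), RSS.single_layer())
        assert np.array_equal(a.cell_role, b.cell_role)
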