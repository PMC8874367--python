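"""Release-profile arithmetic, emission areas and time budgeting."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ngc_elute.geometry import GeometrySpec, ReleaseSystemSpec, release_perimeter_2d
from ngc_elute.release_model import (
    REFERENCE_AREA_MM2,
    ReleaseProfile,
    ReleaseSchedule,
    emission_area,
    inlet_speed,
    modified_profile,
    narrowed_profile,
    original_profile,
    printed_area,
    release_velocities,
    scale_profile,
    schedule_constant_mass,
    schedule_constant_time,
    constant_mass_budget_table,
)

RSS = ReleaseSystemSpec


class TestReleaseVelocities:
    def test_sixty_day_profile(self):
        bv, cv = release_velocities(original_profile())
        assert bv == pytest.approx(5.79e-5, abs=5e-8)
        assert cv == pytest.approx(2.94e-7, abs=5e-10)

    def test_narrowed_profile(self):
        p = modified_profile()
        assert (p.burst_time, p.continuous_time) == (9.0, 510.0)
        assert (p.burst_mass, p.continuous_mass) == (pytest.approx(5e-4), pytest.approx(1.5e-4))
        bv, cv = release_velocities(p)
        assert bv == pytest.approx(5.56e-5, abs=5e-8)
        assert cv == pytest.approx(2.94e-7, abs=5e-10)

    def test_equal_phases_forbidden(self):
        # equal masses over equal times give equal velocities, which violates
        # the burst-faster-than-continuous invariant
        with pytest.raises(ValueError, match="burst velocity"):
            ReleaseProfile(1.0, 10.0, 1.0, 10.0)

    def test_positive_fields_required(self):
        with pytest.raises(ValueError):
            ReleaseProfile(0.0, 10.0, 1.0, 100.0)


class TestScaleProfile:
    @given(
        bm=st.floats(1e-6, 1e3),
        bt=st.floats(1e-3, 1e6),
        cm=st.floats(1e-6, 1e3),
        ct_mult=st.floats(1.5, 1e4),
        factor=st.floats(1e-8, 1e6),
    )
    @settings(max_examples=200, deadline=None)
    def test_velocities_invariant(self, bm, bt, cm, ct_mult, factor):
        # continuous time chosen so the continuous velocity is strictly slower
        ct = ct_mult * cm * bt / bm
        p = ReleaseProfile(bm, bt, cm, ct)
        before = release_velocities(p)
        after = release_velocities(scale_profile(p, factor))
        assert after[0] == pytest.approx(before[0], rel=1e-12)
        assert after[1] == pytest.approx(before[1], rel=1e-12)

    def test_identity(self):
        p = original_profile()
        assert scale_profile(p, 1.0) == p

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            scale_profile(original_profile(), 0.0)

    def test_narrowing_rounds_times_to_seconds(self):
        p = narrowed_profile(original_profile(), 1e-4)
        assert p.burst_time == 9.0  # 8.64 rounded
        assert p.continuous_time == 510.0  # 509.76 rounded


# the nine published budget rows: spec, placement label, printed area,
# burst / continuous / total times
BUDGET_ROWS = [
    (RSS.single_layer(8, 0.1), 0.251, 9.0, 510.0, 519.0),
    (RSS.single_layer(8, 0.1, placements=("front", "middle")), 0.502, 4.5, 255.0, 259.5),
    (RSS.single_layer(8, 0.1, placements=("front", "middle", "back")), 0.753, 3.0, 170.0, 173.0),
    (RSS.single_layer(8, 0.125), 0.393, 6.0, 326.5, 332.5),
    (RSS.single_layer(8, 0.15), 0.565, 4.0, 226.5, 230.5),
    (RSS.single_layer(6, 0.1), 0.188, 12.0, 680.0, 692.0),
    (RSS.single_layer(4, 0.1), 0.126, 18.0, 1020.0, 1038.0),
    (RSS.double_layer(16, 0.1), 0.502, 4.5, 255.0, 259.5),
    (RSS.bulk_hydrogel(0.5), 0.785, 3.0, 163.0, 166.0),
]


class TestEmissionArea:
    @pytest.mark.parametrize("rss,printed,_b,_c,_t", BUDGET_ROWS)
    def test_printed_areas(self, rss, printed, _b, _c, _t):
        assert printed_area(rss) == printed
        # the exact spherical-surface area agrees to the printed resolution
        assert emission_area(rss) == pytest.approx(printed, abs=1.5e-3)

    def test_sphere_surface_convention(self):
        assert emission_area(RSS.single_layer(8, 0.1)) == pytest.approx(8 * math.pi * 0.01)
        assert emission_area(RSS.bulk_hydrogel(0.5)) == pytest.approx(math.pi * 0.25)

    def test_film_area_ratio(self):
        geom = GeometrySpec()
        film = RSS.hydrogel_film(0.1, geom)
        ratio = emission_area(film) / REFERENCE_AREA_MM2
        # the film lines both conduit segments of all nine 3D channels,
        # ~166x the default microsphere system
        assert ratio == pytest.approx(166.0, rel=0.01)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            RSS(kind="nanorod")


class TestSchedules:
    @pytest.mark.parametrize("rss,_a,burst,cont,total", BUDGET_ROWS)
    def test_constant_mass_budget(self, rss, _a, burst, cont, total):
        s = schedule_constant_mass(modified_profile(), emission_area(rss))
        assert (s.burst_time, s.continuous_time, s.total_time) == (burst, cont, total)

    def test_constant_time_uses_profile_times(self):
        s = schedule_constant_time(modified_profile())
        assert s.total_time == 519.0
        assert (s.burst_time, s.continuous_time) == (9.0, 510.0)

    def test_dt_longer_than_schedule_rejected(self):
        with pytest.raises(ValueError):
            ReleaseSchedule(burst_time=0.1, continuous_time=0.2, burst_speed=1, continuous_speed=0.1, dt=0.5)

    def test_identity_at_reference_area(self):
        p = modified_profile()
        s = schedule_constant_mass(p, REFERENCE_AREA_MM2)
        assert (s.burst_time, s.continuous_time) == (p.burst_time, p.continuous_time)

    @given(area=st.floats(0.05, 50.0))
    @settings(max_examples=100, deadline=None)
    def test_mass_budget_conserved(self, area):
        # area x time stays at the reference product to schedule rounding
        p = modified_profile()
        s = schedule_constant_mass(p, area)
        assert abs(area * s.total_time - REFERENCE_AREA_MM2 * 519.0) <= area * 0.5 + 1e-9

    def test_speed_switches_at_burst_end(self):
        s = schedule_constant_time(modified_profile())
        assert s.speed_at(0.0) == s.burst_speed
        assert s.speed_at(8.99) == s.burst_speed
        assert s.speed_at(9.0) == s.continuous_speed

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            schedule_constant_mass(modified_profile(), 0.0)


class TestInletSpeed:
    def test_reference_conversion(self):
        # 5.56e-5 ng/s of GDNF (1370 kg/m^3) through the 0.2513 mm^2 reference
        # footprint at 1 mm depth: hand unit conversion gives ~1.61e-13 m/s
        s = inlet_speed(5.56e-5, 1370.0, REFERENCE_AREA_MM2, 1.0)
        assert s == pytest.approx(1.615e-13, rel=1e-3)

    def test_linearity(self):
        s1 = inlet_speed(1.0, 1370.0, 1.0)
        assert inlet_speed(2.0, 1370.0, 1.0) == pytest.approx(2 * s1)
        assert inlet_speed(1.0, 1370.0, 2.0) == pytest.approx(s1 / 2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            inlet_speed(1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            inlet_speed(1.0, 1370.0, -1.0)


class TestPerimeter2D:
    def test_disc_perimeters(self):
        assert release_perimeter_2d(RSS.single_layer(8, 0.1)) == pytest.approx(8 * math.pi * 0.1)
        assert release_perimeter_2d(RSS.double_layer(16, 0.1)) == pytest.approx(16 * math.pi * 0.1)
        assert release_perimeter_2d(RSS.bulk_hydrogel(0.5)) == pytest.approx(math.pi * 0.5)

    def test_film_lining(self):
        geom = GeometrySpec()
        p = release_perimeter_2d(RSS.hydrogel_film(0.1, geom), geom)
        assert p == pytest.approx(2 * geom.n_channels_2d * 2 * geom.segment_length)


def test_budget_table_matches_published_rows():
    df = constant_mass_budget_table()
    assert list(df["surface_area_mm2"]) == [0.251, 0.502, 0.753, 0.393, 0.565, 0.188, 0.126, 0.502, 0.785]
    assert list(df["total_time_s"]) == [519.0, 259.5, 173.0, 332.5, 230.5, 692.0, 1038.0, 259.5, 166.0]
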