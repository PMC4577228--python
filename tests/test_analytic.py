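import math

import numpy as np
import pytest
from scipy.optimize import brentq

from mlcedge import (
    GeometryError,
    Point2D,
    Ray,
    chord_construction_position,
    compute_offsets,
    geometric_position,
    half_value_layer,
    leaf_cross_section,
    leaf_positions,
    path_length,
    physical_position,
    tangent_point,
)
from conftest import ORACLE_NOMINALS, ORACLE_RADII

GRID = [(r, n) for r in ORACLE_RADII for n in ORACLE_NOMINALS]


def projection_oracle(geom, cs, n_samples=100_000):
    """Light-field edge by brute force: min projection of dense outline samples."""
    phi_max = math.asin(cs.leaf_height / 2 / cs.radius)
    phi = np.linspace(-phi_max, phi_max, n_samples)
    arc_x = cs.center.x - cs.radius * np.cos(phi)
    arc_z = cs.center.z + cs.radius * np.sin(phi)
    flat_x = np.linspace(cs.corner_x, cs.corner_x + cs.body_extent, 1000)
    xs = np.concatenate([arc_x, flat_x, flat_x])
    zs = np.concatenate([arc_z, np.full(1000, cs.z_top), np.full(1000, cs.z_bottom)])
    return (xs * geom.sad / (geom.sad - zs)).min()


def transmission_oracle(geom, cs):
    """Physical edge by definition: ray whose primary transmission is 50%."""
    L = half_value_layer(geom.mu)
    S = Point2D(0.0, geom.sad)
    x_g = geometric_position(geom, cs)
    return brentq(
        lambda x: path_length(cs, Ray(S, x)) - L, x_g - 1e-9, x_g + 2.0, xtol=1e-12
    )


class TestHalfValueLayer:
    def test_tungsten_value(self):
        assert half_value_layer(0.96) == pytest.approx(0.7220283, abs=1e-6)

    def test_log2_gives_unit_layer_and_doubling_mu_halves_it(self):
        assert half_value_layer(math.log(2.0)) == pytest.approx(1.0)
        assert half_value_layer(1.2) == pytest.approx(2 * half_value_layer(2.4))

    def test_nonpositive_mu_rejected(self):
        with pytest.raises(GeometryError):
            half_value_layer(0.0)


class TestTangentPoint:
    def test_central_leaf_grazes_at_tip(self, geom):
        cs = leaf_cross_section(geom, 0.0, 15.0)
        T = tangent_point(geom, cs)
        assert T == pytest.approx(Point2D(0.0, 54.0))
        # perpendicularity of CT and ST at the tangency
        dot = (T.x - cs.center.x) * (T.x - 0.0) + (T.z - cs.center.z) * (T.z - geom.sad)
        assert dot == pytest.approx(0.0, abs=1e-9)

    def test_clamps_to_proximal_corner_for_large_radius_far_leaf(self, geom):
        cs = leaf_cross_section(geom, -20.0, 25.0)
        T = tangent_point(geom, cs)
        assert T.z == pytest.approx(cs.z_top)
        assert T.x == pytest.approx(15.8 - math.sqrt(625.0 - 16.0))

    def test_arc_tangency_satisfies_perpendicularity_when_unclamped(self, geom):
        cs = leaf_cross_section(geom, 10.0, 8.0)
        T = tangent_point(geom, cs)
        assert cs.z_bottom < T.z < cs.z_top
        dot = (T.x - cs.center.x) * T.x + (T.z - cs.center.z) * (T.z - geom.sad)
        assert dot == pytest.approx(0.0, abs=1e-9)


class TestGeometricPosition:
    def test_central_leaf_edge_on_axis(self, geom):
        assert geometric_position(geom, leaf_cross_section(geom, 0.0, 15.0)) == pytest.approx(0.0)

    def test_corner_case_matches_corner_projection(self, geom):
        cs = leaf_cross_section(geom, -20.0, 25.0)
        x_u = 15.8 - math.sqrt(609.0)
        assert geometric_position(geom, cs) == pytest.approx(x_u * 100.0 / 42.0)

    @pytest.mark.parametrize("radius, nominal", GRID)
    def test_equals_min_projection_oracle_on_grid(self, geom, radius, nominal):
        cs = leaf_cross_section(geom, nominal, radius)
        assert geometric_position(geom, cs) == pytest.approx(
            projection_oracle(geom, cs), abs=1e-5
        )


class TestPhysicalPosition:
    def test_central_leaf_closed_form(self, geom):
        # small-angle solution of 15 cos(t) - 46 sin(t) = sqrt(225 - (L/2)^2)
        cs = leaf_cross_section(geom, 0.0, 15.0)
        assert physical_position(geom, cs) == pytest.approx(0.009446, abs=1e-5)

    def test_half_value_rule_holds_on_returned_ray(self, geom):
        L = half_value_layer(geom.mu)
        for radius, nominal in ((15.0, 0.0), (25.0, -20.0), (4.0, 10.0)):
            cs = leaf_cross_section(geom, nominal, radius)
            x_p = physical_position(geom, cs)
            ray = Ray(Point2D(0.0, geom.sad), x_p)
            assert path_length(cs, ray) == pytest.approx(L, abs=1e-6)

    @pytest.mark.parametrize("radius, nominal", GRID)
    def test_equals_point_source_transmission_oracle_on_grid(self, geom, radius, nominal):
        cs = leaf_cross_section(geom, nominal, radius)
        assert physical_position(geom, cs) == pytest.approx(
            transmission_oracle(geom, cs), abs=1e-4
        )

    @pytest.mark.parametrize("radius, nominal", GRID)
    def test_chord_construction_agrees_where_secant_is_on_arc(self, geom, radius, nominal):
        cs = leaf_cross_section(geom, nominal, radius)
        pos = leaf_positions(geom, nominal, radius)
        A, B = pos.secant_points
        on_arc = (
            abs(math.hypot(A.x - cs.center.x, A.z - cs.center.z) - radius) < 1e-9
            and abs(math.hypot(B.x - cs.center.x, B.z - cs.center.z) - radius) < 1e-9
        )
        if on_arc:
            assert pos.x_physical == pytest.approx(
                chord_construction_position(geom, cs), abs=1e-9
            )

    def test_secant_collinear_with_source(self, geom):
        pos = leaf_positions(geom, 10.0, 15.0)
        A, B = pos.secant_points
        cross = (A.x - 0.0) * (B.z - geom.sad) - (B.x - 0.0) * (A.z - geom.sad)
        assert cross == pytest.approx(0.0, abs=1e-9)


class TestOffsets:
    def test_pno_is_sum_of_lpo_and_rfo(self, geom):
        off = compute_offsets(leaf_positions(geom, -7.0, 20.0))
        assert off.pno == pytest.approx(off.lpo + off.rfo, abs=1e-12)

    def test_central_leaf_offsets(self, geom):
        off = compute_offsets(leaf_positions(geom, 0.0, 15.0))
        assert off.lpo == pytest.approx(0.0, abs=1e-9)
        assert off.rfo == pytest.approx(0.094, abs=2e-3)

    def test_mean_rfo_for_reference_radius(self, geom):
        rfos = [
            compute_offsets(leaf_positions(geom, float(n), 15.0)).rfo
            for n in range(-20, 21)
        ]
        assert np.mean(rfos) == pytest.approx(0.10, abs=0.02)
        # the curve is nearly flat across the field
        assert max(rfos) - min(rfos) <= 0.05

    @pytest.mark.parametrize("radius, nominal", GRID)
    def test_rfo_positive_on_grid(self, geom, radius, nominal):
        assert compute_offsets(leaf_positions(geom, nominal, radius)).rfo >= 0.0

    def test_mirrored_leaf_negates_all_offsets(self, geom):
        right = compute_offsets(leaf_positions(geom, 10.0, 15.0, bank="right"))
        left = compute_offsets(leaf_positions(geom, 10.0, 15.0, bank="left"))
        assert left.lpo == pytest.approx(-right.lpo, abs=1e-9)
        assert left.rfo == pytest.approx(-right.rfo, abs=1e-9)
        assert left.pno == pytest.approx(-right.pno, abs=1e-9)


def test_analytic_table_layout(geom):
    from mlcedge import analytic_table

    df = analytic_table(geom, [15.0], [-1.0, 0.0, 1.0])
    assert list(df.columns) == [
        "radius_cm", "source_fwhm_mm", "nominal_cm", "x_mech_cm",
        "x_geom_cm", "x_phys_cm", "lpo_mm", "rfo_mm", "pno_mm",
    ]
    assert len(df) == 3
    assert (df["pno_mm"] - df["lpo_mm"] - df["rfo_mm"]).abs().max() < 1e-9
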