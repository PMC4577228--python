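"""Analytical leaf-position algorithms for rounded leaf ends.

Four positions on the scoring plane are distinguished for a leaf at nominal
position x_N:

* mechanical position  E - the arc apex on the collimator middle plane,
  x_E = x_N * SCD / SAD;
* nominal position     N - the uncalibrated projection of E, i.e. x_N itself;
* geometric position   G - the light-field edge: scoring-plane projection of
  the ray from the source grazing the leaf outline;
* physical position    P - the radiation-field edge under the half-value-layer
  rule: the intercept of the secant ray whose in-leaf path equals
  L = -ln(0.5)/mu, so its primary transmission is exactly 50%.

The derived offsets (reported in mm) are LPO = G - N, RFO = P - G and
PNO = P - N, with PNO = LPO + RFO by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .geometry import (
    GeometryError,
    LeafCrossSection,
    NumericalError,
    Point2D,
    Ray,
    TreatmentGeometry,
    leaf_cross_section,
    mirror,
    path_length,
    project_to_scoring_plane,
)

__all__ = [
    "LeafPositions",
    "Offsets",
    "half_value_layer",
    "tangent_point",
    "geometric_position",
    "physical_position",
    "chord_construction_position",
    "leaf_positions",
    "compute_offsets",
    "analytic_table",
]


@dataclass(frozen=True)
class Offsets:
    """Leaf-position offset, radiation-field offset and their sum (mm)."""

    lpo: float
    rfo: float
    pno: float


@dataclass(frozen=True)
class LeafPositions:
    """The four scoring/middle-plane positions of one leaf plus construction points."""

    x_nominal: float
    x_mechanical: float
    x_geometric: float
    x_physical: float
    tangent_point: Point2D
    secant_points: tuple[Point2D, Point2D]


def half_value_layer(mu: float) -> float:
    """Half-value layer L = -ln(0.5)/mu (cm) of the leaf material."""
    if mu <= 0:
        raise GeometryError(f"mu must be positive, got {mu}")
    return -math.log(0.5) / mu


def _tangents_from_point(S: Point2D, C: Point2D, radius: float) -> tuple[Point2D, Point2D]:
    """Both tangency points of lines from external point S to circle (C, radius)."""
    dx, dz = S.x - C.x, S.z - C.z
    d2 = dx * dx + dz * dz
    if d2 <= radius * radius:
        raise GeometryError("point is not outside the circle")
    k = radius * radius / d2
    h = radius * math.sqrt(d2 - radius * radius) / d2
    bx, bz = C.x + k * dx, C.z + k * dz
    return (
        Point2D(bx - h * dz, bz + h * dx),
        Point2D(bx + h * dz, bz - h * dx),
    )


def _canonical(cs: LeafCrossSection) -> tuple[LeafCrossSection, float]:
    """Right-bank view of a cross-section and the sign restoring the original."""
    if cs.bank == "left":
        return mirror(cs), -1.0
    return cs, 1.0


def tangent_point(geom: TreatmentGeometry, cs: LeafCrossSection) -> Point2D:
    """Grazing point T of the light-field ray from the source on the leaf outline.

    T is the arc tangency with x_T < x_C when its height falls within the
    leaf slab; when the tangency falls outside the slab, or the source lies
    inside the arc circle, the grazing point clamps to the proximal corner U
    (tangency above the slab, or source inside the circle) or the distal
    corner V (tangency below the slab).
    """
    cs0, sign = _canonical(cs)
    S = Point2D(0.0, geom.sad)
    C = cs0.center
    d = math.hypot(S.x - C.x, S.z - C.z)
    if d <= cs0.radius:
        T = cs0.corner_proximal
    else:
        cands = [
            t for t in _tangents_from_point(S, C, cs0.radius) if t.x < C.x + 1e-12
        ]
        if not cands:
            raise NumericalError("no field-side tangency", cs0, S)
        T = min(cands, key=lambda t: project_to_scoring_plane(t, geom.sad))
        if T.z > cs0.z_top:
            T = cs0.corner_proximal
        elif T.z < cs0.z_bottom:
            T = cs0.corner_distal
    return Point2D(sign * T.x, T.z)


def geometric_position(geom: TreatmentGeometry, cs: LeafCrossSection) -> float:
    """Light-field edge x_G (cm): projection of the grazing point onto z = 0.

    Equals the minimum (for a right-bank leaf) over all outline points of
    their source projection onto the scoring plane.
    """
    T = tangent_point(geom, cs)
    return project_to_scoring_plane(T, geom.sad)


def _arc_param(cs: LeafCrossSection, phi):
    """Field-side arc point (x_C - R cos(phi), z_C + R sin(phi)) of a right-bank leaf."""
    return Point2D(
        cs.center.x - cs.radius * math.cos(phi),
        cs.center.z + cs.radius * math.sin(phi),
    )


def _collinear(S: Point2D, A: Point2D, B: Point2D) -> float:
    return (A.x - S.x) * (B.z - S.z) - (B.x - S.x) * (A.z - S.z)


def chord_construction_position(geom: TreatmentGeometry, cs: LeafCrossSection) -> float:
    """Closed-form physical edge when the half-value chord lies fully on the arc.

    A chord of length L in a circle of radius R runs at distance
    sqrt(R^2 - (L/2)^2) from the center, so the secant ray is the field-side
    tangent from the source to the concentric circle of that radius.
    """
    cs0, sign = _canonical(cs)
    L = half_value_layer(geom.mu)
    h = math.sqrt(cs0.radius**2 - (L / 2) ** 2)
    S = Point2D(0.0, geom.sad)
    cands = [
        t
        for t in _tangents_from_point(S, cs0.center, h)
        if t.x < cs0.center.x + 1e-12
    ]
    if not cands:
        raise NumericalError("no field-side chord tangency", cs0)
    W = min(cands, key=lambda t: project_to_scoring_plane(t, geom.sad))
    return sign * project_to_scoring_plane(W, geom.sad)


def physical_position(geom: TreatmentGeometry, cs: LeafCrossSection) -> float:
    """Radiation-field edge x_P (cm) under the half-value-layer rule.

    Finds the secant line through the source whose in-leaf segment AB has
    length L = half_value_layer(mu).  Solved first with both endpoints on
    the arc; if the proximal endpoint lands above the leaf slab (or the
    source lies inside the arc circle) it is re-solved with A on the flat
    top face, and if the distal endpoint lands below the slab with B on the
    flat bottom face.  The returned ray is verified post hoc to carry an
    in-leaf path of exactly L.
    """
    x_p, _ = _physical_solution(geom, cs)
    return x_p


def _physical_solution(
    geom: TreatmentGeometry, cs: LeafCrossSection
) -> tuple[float, tuple[Point2D, Point2D]]:
    cs0, sign = _canonical(cs)
    L = half_value_layer(geom.mu)
    S = Point2D(0.0, geom.sad)
    C = cs0.center
    R = cs0.radius
    d = math.hypot(S.x - C.x, S.z - C.z)
    phi_max = math.asin(cs0.leaf_height / 2 / R)
    delta = (L / 2) / R

    # initial angle from the grazing construction
    T = tangent_point(geom, cs0)
    phi_t = math.asin(min(max((T.z - C.z) / R, -1.0), 1.0))
    phi_t = min(max(phi_t, -phi_max), phi_max)

    def solve(fun, x0) -> optimize.OptimizeResult:
        return optimize.root(fun, x0, method="hybr", tol=1e-13)

    A = B = None
    if d > R:
        def arc_arc(v):
            Pa = _arc_param(cs0, v[0])
            Pb = _arc_param(cs0, v[1])
            return [
                _collinear(S, Pa, Pb),
                math.hypot(Pa.x - Pb.x, Pa.z - Pb.z) - L,
            ]

        sol = solve(arc_arc, [phi_t + delta, phi_t - delta])
        if sol.success:
            A = _arc_param(cs0, sol.x[0])
            B = _arc_param(cs0, sol.x[1])
            if A.z < B.z:
                A, B = B, A

    tol = 1e-9
    if A is None or A.z > cs0.z_top + tol or d <= R:
        # secant enters through the proximal flat face
        def flat_top(v):
            Pa = Point2D(v[0], cs0.z_top)
            Pb = _arc_param(cs0, v[1])
            return [
                _collinear(S, Pa, Pb),
                math.hypot(Pa.x - Pb.x, Pa.z - Pb.z) - L,
            ]

        sol = solve(flat_top, [cs0.corner_x + L / 4, phi_max - 2 * delta])
        if not sol.success:
            raise NumericalError("proximal-flat secant solve failed", sol.message, cs0)
        A = Point2D(sol.x[0], cs0.z_top)
        B = _arc_param(cs0, sol.x[1])
    elif B.z < cs0.z_bottom - tol:
        # secant exits through the distal flat face
        def flat_bottom(v):
            Pa = _arc_param(cs0, v[0])
            Pb = Point2D(v[1], cs0.z_bottom)
            return [
                _collinear(S, Pa, Pb),
                math.hypot(Pa.x - Pb.x, Pa.z - Pb.z) - L,
            ]

        sol = solve(flat_bottom, [-phi_max + 2 * delta, cs0.corner_x + L / 4])
        if not sol.success:
            raise NumericalError("distal-flat secant solve failed", sol.message, cs0)
        A = _arc_param(cs0, sol.x[0])
        B = Point2D(sol.x[1], cs0.z_bottom)

    x_p = project_to_scoring_plane(A, geom.sad)
    # post-hoc verification against the exact ray-path geometry
    achieved = path_length(cs0, Ray(S, x_p))
    if abs(achieved - L) > 1e-6:
        # fall back to the closed-form chord construction before giving up
        x_alt = chord_construction_position(geom, cs0)
        if abs(path_length(cs0, Ray(S, x_alt)) - L) <= 1e-6:
            return sign * x_alt, (Point2D(sign * A.x, A.z), Point2D(sign * B.x, B.z))
        raise NumericalError(
            "half-value secant verification failed",
            {"target_L": L, "achieved": achieved, "x_p": x_p},
        )
    return sign * x_p, (Point2D(sign * A.x, A.z), Point2D(sign * B.x, B.z))


def leaf_positions(
    geom: TreatmentGeometry,
    nominal_x: float,
    radius: float,
    bank: str = "right",
    body_extent: float = 20.0,
) -> LeafPositions:
    """Compute all four positions (cm) for one leaf configuration."""
    cs = leaf_cross_section(geom, nominal_x, radius, body_extent)
    if bank == "left":
        cs = mirror(cs)
        nominal_x = -nominal_x
    elif bank != "right":
        raise GeometryError(f"bank must be 'right' or 'left', got {bank!r}")
    x_g = geometric_position(geom, cs)
    x_p, secant = _physical_solution(geom, cs)
    return LeafPositions(
        x_nominal=nominal_x,
        x_mechanical=nominal_x * geom.scd / geom.sad,
        x_geometric=x_g,
        x_physical=x_p,
        tangent_point=tangent_point(geom, cs),
        secant_points=secant,
    )


def compute_offsets(positions: LeafPositions) -> Offsets:
    """LPO / RFO / PNO in millimetres from the computed positions."""
    lpo = (positions.x_geometric - positions.x_nominal) * 10.0
    rfo = (positions.x_physical - positions.x_geometric) * 10.0
    return Offsets(lpo=lpo, rfo=rfo, pno=lpo + rfo)


def analytic_table(
    geom: TreatmentGeometry,
    radii,
    nominals,
) -> "pandas.DataFrame":
    """Positions and offsets for every (radius, nominal) pair as a DataFrame."""
    import pandas as pd

    rows = []
    for radius in radii:
        for nominal in nominals:
            pos = leaf_positions(geom, float(nominal), float(radius))
            off = compute_offsets(pos)
            rows.append(
                {
                    "radius_cm": radius,
                    "source_fwhm_mm": np.nan,
                    "nominal_cm": nominal,
                    "x_mech_cm": pos.x_mechanical,
                    "x_geom_cm": pos.x_geometric,
                    "x_phys_cm": pos.x_physical,
                    "lpo_mm": off.lpo,
                    "rfo_mm": off.rfo,
                    "pno_mm": off.pno,
                }
            )
    return pd.DataFrame(rows)
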