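"""Two-dimensional treatment-head geometry for a rounded-end MLC leaf.

Coordinate frame
----------------
The origin sits at the isocenter, ``z`` increases toward the radiation
source, and the scoring plane is ``z = 0``.  The (point) source sits at
``(0, SAD)``.  A single-focused multileaf collimator translates its leaves
linearly in ``x``; the leaf tip is machined as a circular arc in the x-z
plane so that a linearly moving leaf approximates the diverging beam.

A leaf of the right bank has its body toward ``+x`` and its arc tip bulging
toward the open field (``-x``).  The collimator middle plane, where the
mechanical tip position is defined, lies at ``z = SAD - SCD``.

All lengths are centimetres; offsets are converted to millimetres only at
the reporting layer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

__all__ = [
    "GeometryError",
    "NumericalError",
    "Point2D",
    "Ray",
    "TreatmentGeometry",
    "LeafCrossSection",
    "leaf_cross_section",
    "left_boundary",
    "path_length",
    "path_lengths",
    "mirror",
    "project_to_scoring_plane",
    "load_geometry",
]


class GeometryError(ValueError):
    """Invalid or unsupported treatment-head / leaf geometry."""


class NumericalError(RuntimeError):
    """A solver failed to converge; carries diagnostics in ``args``."""


class Point2D(NamedTuple):
    x: float
    z: float


class Ray(NamedTuple):
    """A beam line from a point on the source plane to the scoring plane."""

    source_point: Point2D
    scoring_x: float


@dataclass(frozen=True)
class TreatmentGeometry:
    """Machine constants of the simplified treatment head.

    Parameters
    ----------
    sad : float
        Source-to-axis distance (cm).  Default 100.
    scd : float
        Source-to-collimator distance, measured to the leaf middle plane
        (cm).  Default 46, which places the middle plane at z = 54 cm and
        the 8 cm leaf slab at z in [50, 58] cm.
    sdd : float
        Source-to-diaphragm distance (cm); informational only, the
        diaphragms are retracted and never modelled.
    leaf_height : float
        Leaf thickness along z (cm).
    mu : float
        Linear attenuation coefficient of the tungsten leaf (1/cm) for the
        monoenergetic primary beam.
    max_half_field : float
        Half of the maximum field size at isocenter (cm); nominal leaf
        positions must stay within +/- this value.
    """

    sad: float = 100.0
    scd: float = 46.0
    sdd: float = 33.9
    leaf_height: float = 8.0
    mu: float = 0.96
    max_half_field: float = 20.0

    def __post_init__(self) -> None:
        if not (self.sad > self.scd > 0):
            raise GeometryError(f"require sad > scd > 0, got sad={self.sad}, scd={self.scd}")
        if self.leaf_height <= 0:
            raise GeometryError(f"leaf_height must be positive, got {self.leaf_height}")
        if self.mu <= 0:
            raise GeometryError(f"mu must be positive, got {self.mu}")
        mid = self.sad - self.scd
        if not (0 < mid < self.sad):
            raise GeometryError("collimator middle plane must lie strictly between isocenter and source")
        slab_top = mid + self.leaf_height / 2
        if slab_top >= self.sad:
            raise GeometryError("leaf slab reaches the source plane")

    @property
    def source_z(self) -> float:
        return self.sad

    @property
    def collimator_z(self) -> float:
        """z of the collimator (leaf) middle plane."""
        return self.sad - self.scd

    @property
    def source_point(self) -> Point2D:
        return Point2D(0.0, self.sad)


_CONFIG_KEYS = {
    "sad_cm": "sad",
    "scd_cm": "scd",
    "sdd_cm": "sdd",
    "leaf_height_cm": "leaf_height",
    "mu_per_cm": "mu",
    "max_half_field_cm": "max_half_field",
}


def load_geometry(path) -> TreatmentGeometry:
    """Read a geometry config file (YAML or JSON) with keys like ``sad_cm``.

    Unknown keys raise; missing keys fall back to the defaults.
    """
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise GeometryError(f"geometry config {path} must be a mapping")
    unknown = set(data) - set(_CONFIG_KEYS)
    if unknown:
        raise GeometryError(f"unknown geometry keys: {sorted(unknown)}")
    return TreatmentGeometry(**{_CONFIG_KEYS[k]: float(v) for k, v in data.items()})


def dump_geometry(geom: TreatmentGeometry, path) -> None:
    data = {k: getattr(geom, attr) for k, attr in _CONFIG_KEYS.items()}
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)
        fh.write("\n")


@dataclass(frozen=True)
class LeafCrossSection:
    """A single leaf's outline in the x-z plane.

    The outline is the circular-arc tip (center ``center``, radius
    ``radius``) joined to flat proximal (top) and distal (bottom) faces, with
    the body extending ``body_extent`` behind the tip corners.  The arc must
    span the full leaf height (``radius >= leaf_height / 2``), as it does on
    clinical leaves.
    """

    center: Point2D
    radius: float
    z_top: float
    z_bottom: float
    body_extent: float = 20.0
    bank: str = "right"

    def __post_init__(self) -> None:
        if self.bank not in ("right", "left"):
            raise GeometryError(f"bank must be 'right' or 'left', got {self.bank!r}")
        lh = self.z_top - self.z_bottom
        if lh <= 0:
            raise GeometryError("z_top must exceed z_bottom")
        if self.radius < lh / 2:
            raise GeometryError(
                f"arc radius {self.radius} cm does not span the leaf height {lh} cm "
                "(need radius >= leaf_height / 2)"
            )
        if self.body_extent <= 0:
            raise GeometryError("body_extent must be positive")

    @property
    def leaf_height(self) -> float:
        return self.z_top - self.z_bottom

    @property
    def corner_offset(self) -> float:
        """|x_corner - x_center|: half-chord of the arc at the flat faces."""
        half = self.leaf_height / 2
        return math.sqrt(self.radius**2 - half**2)

    @property
    def corner_x(self) -> float:
        """Field-side x of the two tip corners (top and bottom share it)."""
        if self.bank == "right":
            return self.center.x - self.corner_offset
        return self.center.x + self.corner_offset

    @property
    def corner_proximal(self) -> Point2D:
        """Tip corner on the source-facing (top) flat."""
        return Point2D(self.corner_x, self.z_top)

    @property
    def corner_distal(self) -> Point2D:
        """Tip corner on the bottom flat."""
        return Point2D(self.corner_x, self.z_bottom)

    @property
    def tip_x(self) -> float:
        """x of the arc apex (the mechanical tip) on the middle plane."""
        if self.bank == "right":
            return self.center.x - self.radius
        return self.center.x + self.radius


def leaf_cross_section(
    geom: TreatmentGeometry,
    nominal_x: float,
    radius: float,
    body_extent: float = 20.0,
) -> LeafCrossSection:
    """Build the right-bank leaf cross-section for a nominal leaf position.

    The nominal position ``nominal_x`` (cm, at isocenter) back-projects to
    the mechanical tip on the collimator middle plane, x_E = x_N * SCD/SAD;
    the arc center then sits one radius behind the tip, x_C = x_E + R.
    """
    if radius < geom.leaf_height / 2:
        raise GeometryError(
            f"arc radius {radius} cm does not span the leaf height {geom.leaf_height} cm"
        )
    x_mech = nominal_x * geom.scd / geom.sad
    zc = geom.collimator_z
    return LeafCrossSection(
        center=Point2D(x_mech + radius, zc),
        radius=radius,
        z_top=zc + geom.leaf_height / 2,
        z_bottom=zc - geom.leaf_height / 2,
        body_extent=body_extent,
        bank="right",
    )


def left_boundary(cs: LeafCrossSection, z):
    """Field-facing arc boundary of the leaf at height(s) ``z``.

    For the canonical right-bank leaf this is x_C - sqrt(R^2 - (z - z_C)^2);
    a left-bank leaf returns the mirrored (+sqrt) branch.  ``z`` outside the
    leaf slab raises.
    """
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr < cs.z_bottom - 1e-12) or np.any(z_arr > cs.z_top + 1e-12):
        raise GeometryError(f"z outside leaf slab [{cs.z_bottom}, {cs.z_top}]")
    zc = cs.center.z
    half = np.sqrt(np.maximum(cs.radius**2 - (z_arr - zc) ** 2, 0.0))
    out = cs.center.x - half if cs.bank == "right" else cs.center.x + half
    return float(out) if np.isscalar(z) or np.ndim(z) == 0 else out


def mirror(obj):
    """Reflect across the central axis (x -> -x).

    Accepts a :class:`LeafCrossSection` (bank flips), :class:`Ray`,
    :class:`Point2D`, or a bare x-coordinate.  Involution: mirror(mirror(o))
    round-trips.
    """
    if isinstance(obj, LeafCrossSection):
        return replace(
            obj,
            center=Point2D(-obj.center.x, obj.center.z),
            bank="left" if obj.bank == "right" else "right",
        )
    if isinstance(obj, Ray):
        return Ray(Point2D(-obj.source_point.x, obj.source_point.z), -obj.scoring_x)
    if isinstance(obj, Point2D):
        return Point2D(-obj.x, obj.z)
    return -obj


def project_to_scoring_plane(point: Point2D, sad: float) -> float:
    """x-intercept at z = 0 of the line from the on-axis source through ``point``."""
    if point.z >= sad:
        raise GeometryError("point must lie below the source plane")
    return point.x * sad / (sad - point.z)


def path_lengths(cs: LeafCrossSection, source_x, scoring_x, source_z: float):
    """Exact in-leaf path length for rays from (source_x, source_z) to (scoring_x, 0).

    Vectorised over broadcastable ``source_x`` / ``scoring_x`` arrays.  The
    leaf region is convex (the arc boundary is a convex function of z within
    the slab), so every ray meets it in at most one segment whose endpoints
    are found analytically from the circle-line intersection clipped to the
    z-slab and the finite body extent.
    """
    sx = np.asarray(source_x, dtype=float)
    ex = np.asarray(scoring_x, dtype=float)
    if cs.bank == "left":
        cs = mirror(cs)
        sx, ex = -sx, -ex
    sx, ex = np.broadcast_arrays(sx, ex)
    sx = sx.astype(float)
    ex = ex.astype(float)

    xc, zc = cs.center
    R = cs.radius
    zt, zb = cs.z_top, cs.z_bottom
    if source_z <= zt:
        raise GeometryError("source plane must lie above the leaf slab")

    dz = -source_z  # z(t) = source_z + t * dz, so z(0)=source_z, z(1)=0
    dx = ex - sx
    lo = np.full(sx.shape, (zt - source_z) / dz)
    hi = np.full(sx.shape, (zb - source_z) / dz)

    # finite body: x <= x_right
    x_right = cs.corner_x + cs.body_extent
    with np.errstate(divide="ignore", invalid="ignore"):
        t_cross = (x_right - sx) / dx
    hi = np.where(dx > 0, np.minimum(hi, t_cross), hi)
    lo = np.where(dx < 0, np.maximum(lo, t_cross), lo)
    empty = (dx == 0) & (sx > x_right)

    # circle-line intersection: A t^2 + B t + C = 0
    fx = sx - xc
    fz = source_z - zc
    A = dx * dx + dz * dz
    B = 2.0 * (fx * dx + fz * dz)
    C = fx * fx + fz * fz - R * R
    disc = B * B - 4.0 * A * C
    has = disc > 0
    sq = np.sqrt(np.maximum(disc, 0.0))
    r1 = (-B - sq) / (2.0 * A)
    r2 = (-B + sq) / (2.0 * A)

    def x_at(t):
        return sx + t * dx

    def g(t):
        # signed distance past the arc boundary (>= 0 means inside the leaf
        # in x); concave in t within the slab, so {g >= 0} is one interval
        z = source_z + t * dz
        dzc = z - zc
        half = np.sqrt(np.maximum(R * R - dzc * dzc, 0.0))
        return x_at(t) - (xc - half)

    g_lo = g(lo)
    g_hi = g(hi)
    tol = 1e-9
    v1 = has & (r1 >= lo) & (r1 <= hi) & (x_at(r1) <= xc + tol)
    v2 = has & (r2 >= lo) & (r2 <= hi) & (x_at(r2) <= xc + tol)
    r_min = np.where(v1, r1, np.where(v2, r2, np.nan))
    r_max = np.where(v2, r2, np.where(v1, r1, np.nan))

    a = np.where(g_lo >= 0, lo, r_min)
    b = np.where(g_hi >= 0, hi, r_max)
    length = (b - a) * np.sqrt(A)
    length = np.where(np.isnan(length), 0.0, np.maximum(length, 0.0))
    length = np.where(empty | (lo > hi), 0.0, length)
    return length


def path_length(cs: LeafCrossSection, ray: Ray) -> float:
    """In-leaf path length (cm) of a single ray; 0 for a miss."""
    out = path_lengths(
        cs,
        np.asarray(ray.source_point.x, dtype=float),
        np.asarray(ray.scoring_x, dtype=float),
        ray.source_point.z,
    )
    return float(out)
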