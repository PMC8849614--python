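"""Parametric rosette shapes with exact vector-geometry descriptors.

A synthetic rosette is a star-like assemblage of leaves around a central
disk, mimicking the spiral phyllotaxis of an Arabidopsis rosette: leaf k
points at k times the divergence angle (golden angle, 137.5 degrees, by
default), and consists of a petiole rectangle running from the centre and
an elliptical blade at its end.  Because the shape is a union of disks,
rectangles and ellipses, every shape descriptor can be computed from
exact vector geometry, making these rosettes the ground-truth oracle for
the raster morphometry pipeline.

Rasterization rule: a pixel is foreground iff its centre lies inside the
exact (non-polygonal) union of the primitives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import shapely.affinity
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union

from rosetteqtl.morphometry import (
    DescriptorVector,
    RosetteMask,
    _CIRCLE_QUAD_SEGS,
    _poly_perimeter,
    _shoelace,
)

__all__ = [
    "RosetteSpec",
    "AnalyticShape",
    "generate_rosette_mask",
    "analytic_descriptors",
    "random_rosette_specs",
]

GOLDEN_ANGLE_DEG = 137.5


class RosetteSpecError(ValueError):
    """Raised for invalid or non-fitting rosette specifications."""


@dataclass(frozen=True)
class LeafGeometry:
    """One leaf: orientation plus petiole/blade dimensions (mm)."""

    angle_deg: float
    blade_length: float
    blade_width: float
    petiole_length: float
    petiole_width: float


@dataclass(frozen=True)
class RosetteSpec:
    """Parameters of one synthetic rosette.

    All lengths in mm.  ``length_jitter`` multiplies each leaf's blade and
    petiole lengths by an independent uniform factor in
    [1 - jitter, 1 + jitter] drawn from ``seed``, so a single spec family
    produces a deterministic variety of star shapes.
    """

    n_leaves: int = 8
    divergence_angle_deg: float = GOLDEN_ANGLE_DEG
    blade_length_mm: float = 18.0
    blade_width_mm: float = 6.0
    petiole_length_mm: float = 10.0
    petiole_width_mm: float = 1.5
    center_radius_mm: float = 2.5
    image_size_px: int = 1024
    mm_per_px: float = 0.09
    seed: int = 0
    length_jitter: float = 0.0

    def validate(self) -> None:
        if self.n_leaves < 0:
            raise RosetteSpecError("n_leaves must be >= 0")
        for name in (
            "blade_length_mm",
            "blade_width_mm",
            "petiole_length_mm",
            "petiole_width_mm",
            "center_radius_mm",
            "mm_per_px",
        ):
            if getattr(self, name) <= 0:
                raise RosetteSpecError(f"{name} must be positive")
        if self.image_size_px < 16:
            raise RosetteSpecError("image_size_px must be >= 16")
        if not 0 <= self.length_jitter < 1:
            raise RosetteSpecError("length_jitter must be in [0, 1)")
        if self.n_leaves > 0 and self.blade_width_mm <= 1.2 * self.petiole_width_mm:
            raise RosetteSpecError(
                "blade_width_mm must exceed petiole_width_mm by at least 20%"
            )

    def leaves(self) -> list[LeafGeometry]:
        self.validate()
        rng = np.random.default_rng(self.seed)
        out = []
        for k in range(self.n_leaves):
            fb, fp = 1.0, 1.0
            if self.length_jitter > 0:
                fb = 1.0 + self.length_jitter * rng.uniform(-1, 1)
                fp = 1.0 + self.length_jitter * rng.uniform(-1, 1)
            out.append(
                LeafGeometry(
                    angle_deg=(k * self.divergence_angle_deg) % 360.0,
                    blade_length=self.blade_length_mm * fb,
                    blade_width=self.blade_width_mm,
                    petiole_length=self.petiole_length_mm * fp,
                    petiole_width=self.petiole_width_mm,
                )
            )
        return out


@dataclass
class AnalyticShape:
    """Exact planar geometry of one rosette.

    ``polygon`` is the shapely union of the primitives (ellipses and the
    central disk discretised at high vertex density); the primitive
    parameters themselves are kept so rasterization can use the exact
    quadratic forms.  The skeleton is the exact medial axis of the
    primitive decomposition: one radial branch per leaf, from the centre
    to the medial-axis endpoint of the blade ellipse (which falls short of
    the blade tip by b^2/a for semi-axes a >= b).
    """

    center_radius: float
    leaves: list[LeafGeometry]
    polygon: Polygon = field(repr=False)

    # -- skeleton ----------------------------------------------------------
    def tip_distances(self, terminal_salience: float = 0.0) -> np.ndarray:
        """Distance from centre to each leaf's skeleton endpoint.

        With ``terminal_salience`` = 0 this is the exact medial axis, one
        radial branch per leaf ending at the blade ellipse's medial-axis
        endpoint (short of the tip by b^2/a).  A positive value gives the
        salience-pruned medial axis: each branch ends where the remaining
        terminal piece — its length plus the endpoint inscribed radius
        minus the local inscribed radius — falls below the threshold,
        matching the pruning rule of the raster pipeline (in mm).
        """
        out = []
        for lf in self.leaves:
            d_center = _blade_center_u(self.center_radius, lf)
            out.append(d_center + _blade_axis_reach(lf, terminal_salience))
        return np.array(out)

    def skeleton_length(self, terminal_salience: float = 0.0) -> float:
        return float(self.tip_distances(terminal_salience).sum())

    def tip_points(self, terminal_salience: float = 0.0) -> np.ndarray:
        """Skeleton endpoints of the leaves, (k, 2) xy in mm."""
        pts = []
        for lf, d in zip(self.leaves, self.tip_distances(terminal_salience)):
            t = math.radians(lf.angle_deg)
            pts.append((d * math.cos(t), d * math.sin(t)))
        return np.array(pts).reshape(-1, 2)

    # -- scalar geometry ---------------------------------------------------
    @property
    def area(self) -> float:
        return self.polygon.area

    @property
    def perimeter(self) -> float:
        return self.polygon.length

    @property
    def convex_hull(self) -> Polygon:
        return self.polygon.convex_hull

    def second_moment_axes(self) -> tuple[float, float]:
        """Full axes (4*sqrt(eigenvalue)) of the second-moment ellipse."""
        cov = _polygon_covariance(self.polygon)
        lam = np.clip(np.linalg.eigvalsh(cov), 0.0, None)
        return 4.0 * math.sqrt(lam[1]), 4.0 * math.sqrt(lam[0])


def _blade_axis_reach(lf: LeafGeometry, terminal_salience: float) -> float:
    """Axial distance from the blade centre to the skeleton branch end.

    For semi-axes a >= b the medial axis of the blade ellipse runs along
    the major axis out to x_m = (a^2 - b^2)/a, where the inscribed radius
    is rho = b^2/a; along the axis the inscribed radius is
    D(x) = b*sqrt(1 - x^2/(a^2 - b^2)).  Pruning at salience t ends the
    branch at the largest x with (x_m - x) + rho - D(x) >= t; if even the
    whole blade-interior branch is below threshold the end point recedes
    into the petiole, where D equals the petiole half-width.
    """
    from scipy.optimize import brentq

    a, b = lf.blade_length / 2.0, lf.blade_width / 2.0
    hw = lf.petiole_width / 2.0
    if a <= b:  # near-circular blade: no axial medial branch inside it
        x_m, rho = 0.0, a
    else:
        k2 = a * a - b * b
        x_m, rho = k2 / a, b * b / a
    t = terminal_salience
    if t <= 0:
        return x_m
    if a > b:
        k2 = a * a - b * b

        def salience(x: float) -> float:
            return (x_m - x) + rho - b * math.sqrt(max(0.0, 1.0 - x * x / k2))

        # blade interior extends inward to where D reaches the petiole width
        x_lo = -math.sqrt(k2 * max(0.0, 1.0 - (hw / b) ** 2))
        if salience(x_m) < t <= salience(x_lo):
            return brentq(lambda x: salience(x) - t, x_lo, x_m, xtol=1e-10)
        if t <= salience(x_m):
            return x_m
    # end point recedes into the petiole (inscribed radius = hw there)
    return x_m + rho - hw - t


def _polygon_covariance(poly: Polygon) -> np.ndarray:
    """Central second-moment (covariance) matrix of a filled polygon."""
    if poly.is_empty or poly.area <= 0:
        raise RosetteSpecError("degenerate (zero-area) geometry")
    geoms = poly.geoms if poly.geom_type == "MultiPolygon" else [poly]
    A = Sx = Sy = Sxx = Syy = Sxy = 0.0
    for g in geoms:
        rings = [(np.asarray(g.exterior.coords), 1.0)]
        rings += [(np.asarray(r.coords), -1.0) for r in g.interiors]
        for coords, sign in rings:
            x, y = coords[:-1, 0], coords[:-1, 1]
            x1, y1 = coords[1:, 0], coords[1:, 1]
            cr = x * y1 - x1 * y
            a = 0.5 * cr.sum()
            if a < 0:  # normalise ring orientation
                x, y, x1, y1, cr, a = x1, y1, x, y, -cr, -a
            A += sign * a
            Sx += sign * np.sum((x + x1) * cr) / 6.0
            Sy += sign * np.sum((y + y1) * cr) / 6.0
            Sxx += sign * np.sum((x * x + x * x1 + x1 * x1) * cr) / 12.0
            Syy += sign * np.sum((y * y + y * y1 + y1 * y1) * cr) / 12.0
            Sxy += sign * np.sum((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cr) / 24.0
    cx, cy = Sx / A, Sy / A
    return np.array(
        [
            [Sxx / A - cx * cx, Sxy / A - cx * cy],
            [Sxy / A - cx * cy, Syy / A - cy * cy],
        ]
    )


def _blade_center_u(center_radius: float, lf: LeafGeometry) -> float:
    """Axial position of the blade-ellipse centre.

    The blade is shifted inward so the petiole's end corners lie strictly
    inside the ellipse: a rectangle butted against the ellipse vertex would
    meet it tangentially and open an unresolvable sliver notch at the
    junction, whereas the embedded junction is transversal.
    """
    a, b = lf.blade_length / 2.0, lf.blade_width / 2.0
    hw = lf.petiole_width / 2.0
    ratio = min(hw / b, 0.95)
    embed = a * (1.0 - math.sqrt(1.0 - ratio * ratio)) + min(0.5, 0.25 * a)
    return center_radius + lf.petiole_length + a - embed


def _petiole_start_u(center_radius: float, lf: LeafGeometry) -> float:
    """Axial position where the petiole rectangle begins.

    The petiole is anchored just inside the disk edge (corners strictly
    inside the circle) instead of running through the centre, so petioles
    of different leaves never cross each other and each disk junction is
    transversal.
    """
    hw = lf.petiole_width / 2.0
    if hw >= center_radius:
        return 0.0
    inside = math.sqrt(center_radius**2 - hw * hw)
    return max(0.0, inside - min(1.0, 0.4 * center_radius))


def _leaf_polygons(center_radius: float, lf: LeafGeometry) -> list[Polygon]:
    a, b = lf.blade_length / 2.0, lf.blade_width / 2.0
    u_max = center_radius + lf.petiole_length
    u0 = _petiole_start_u(center_radius, lf)
    hw = lf.petiole_width / 2.0
    rect = Polygon([(u0, -hw), (u_max, -hw), (u_max, hw), (u0, hw)])
    ell = shapely.affinity.scale(
        Point(0, 0).buffer(1.0, quad_segs=_CIRCLE_QUAD_SEGS), a, b
    )
    ell = shapely.affinity.translate(ell, xoff=_blade_center_u(center_radius, lf))
    return [
        shapely.affinity.rotate(p, lf.angle_deg, origin=(0, 0)) for p in (rect, ell)
    ]


def build_analytic_shape(spec: RosetteSpec) -> AnalyticShape:
    """Exact vector geometry of the rosette described by ``spec``."""
    leaves = spec.leaves()
    parts = [Point(0, 0).buffer(spec.center_radius_mm, quad_segs=_CIRCLE_QUAD_SEGS)]
    for lf in leaves:
        parts.extend(_leaf_polygons(spec.center_radius_mm, lf))
    poly = unary_union(parts)
    return AnalyticShape(
        center_radius=spec.center_radius_mm, leaves=leaves, polygon=poly
    )


def generate_rosette_mask(spec: RosetteSpec) -> tuple[RosetteMask, AnalyticShape]:
    """Render one rosette to a binary mask plus its exact vector geometry.

    A pixel is foreground iff its centre lies inside the exact union of
    the primitives (central disk, petiole rectangles, blade ellipses), so
    identical spec + seed gives bitwise-identical masks.  Raises if any
    leaf would extend beyond the image frame.
    """
    spec.validate()
    shape = build_analytic_shape(spec)
    n, s = spec.image_size_px, spec.mm_per_px
    half_frame = (n / 2.0 - 2.0) * s
    for k, lf in enumerate(shape.leaves):
        reach = _blade_center_u(spec.center_radius_mm, lf) + lf.blade_length / 2.0
        if reach > half_frame:
            raise RosetteSpecError(
                f"leaf {k} (reach {reach:.1f} mm) exceeds the "
                f"{half_frame:.1f} mm half-frame; increase image_size_px "
                "or mm_per_px"
            )
    if spec.center_radius_mm > half_frame:
        raise RosetteSpecError("center disk exceeds the image frame")

    # pixel-centre coordinates in mm, origin at the image centre
    c = (np.arange(n) + 0.5 - n / 2.0) * s
    X, Y = np.meshgrid(c, c)  # X: column coord, Y: row coord
    fg = X * X + Y * Y <= spec.center_radius_mm**2
    for lf in shape.leaves:
        t = math.radians(lf.angle_deg)
        ct, st = math.cos(t), math.sin(t)
        U = X * ct + Y * st
        V = -X * st + Y * ct
        a, b = lf.blade_length / 2.0, lf.blade_width / 2.0
        u_max = spec.center_radius_mm + lf.petiole_length
        u0 = _petiole_start_u(spec.center_radius_mm, lf)
        fg |= (U >= u0) & (U <= u_max) & (np.abs(V) <= lf.petiole_width / 2.0)
        du = U - _blade_center_u(spec.center_radius_mm, lf)
        fg |= (du * du) / (a * a) + (V * V) / (b * b) <= 1.0
    mask = RosetteMask(
        pixels=fg.astype(np.uint8),
        mm_per_px=s,
        source_id=f"synthetic-seed{spec.seed}",
    )
    return mask, shape


def analytic_descriptors(
    shape: AnalyticShape, terminal_salience_mm: float = 0.0
) -> DescriptorVector:
    """Evaluate all nine descriptors on exact vector geometry.

    This is the oracle counterpart of raster ``measure_rosette``: areas
    and perimeters by exact polygon arithmetic, the hull by exact convex
    hull, the circle-overlap by high-resolution polygon intersection, the
    skeleton by the exact medial axis of the primitive decomposition.
    ``terminal_salience_mm`` truncates skeleton branch ends by the same
    maximal-disc salience rule the raster pipeline uses for spur pruning
    (pass the pruning cutoff times mm-per-px to mirror a given raster).
    """
    poly = shape.polygon
    if poly.is_empty or poly.area <= 0:
        raise RosetteSpecError("degenerate (zero-area) geometry")
    area = poly.area
    perim = poly.length
    hull = poly.convex_hull
    hull_area, hull_perim = hull.area, hull.length

    centroid = poly.centroid
    radius = math.sqrt(hull_area / math.pi)
    circle = centroid.buffer(radius, quad_segs=_CIRCLE_QUAD_SEGS)
    inter = hull.intersection(circle).area
    num = (circle.area - inter) + (hull_area - inter)
    rms = num / (num + 2.0 * inter) if (num + inter) > 0 else 0.0

    skel = shape.skeleton_length(terminal_salience_mm)
    tips = shape.tip_points(terminal_salience_mm)
    if tips.shape[0] >= 3:
        rel = tips - np.array([centroid.x, centroid.y])
        order = np.argsort(np.arctan2(rel[:, 1], rel[:, 0]))
        tip_poly = tips[order]
        iso = 4.0 * math.pi * _shoelace(tip_poly) / _poly_perimeter(tip_poly) ** 2
    else:
        iso = 4.0 * math.pi * hull_area / hull_perim**2

    major, minor = shape.second_moment_axes()
    ecc = (
        math.sqrt(max(0.0, 1.0 - (minor / major) ** 2)) if major > 0 else 0.0
    )

    return DescriptorVector(
        PRA=area,
        PL=perim,
        Compactness=area / hull_area,
        RMS=rms,
        SOL=skel * skel / area,
        RND=4.0 * math.pi * area / perim**2,
        RCH=4.0 * math.pi * hull_area / hull_perim**2,
        ISO=iso,
        ECC=ecc,
    )


def _min_angular_gap_deg(n_leaves: int, divergence_deg: float) -> float:
    if n_leaves < 2:
        return 360.0
    ang = np.sort(np.array([(k * divergence_deg) % 360.0 for k in range(n_leaves)]))
    gaps = np.diff(np.append(ang, ang[0] + 360.0))
    return float(gaps.min())


def leaves_are_disjoint(
    center_radius: float, leaves: list[LeafGeometry], clearance: float = 0.3
) -> bool:
    """True when no two leaves come closer than ``clearance`` mm.

    Only shapes whose leaves are mutually disjoint have exactly known
    skeletons and tip polygons, so the oracle spec sampler rejects
    colliding draws.
    """
    parts = [unary_union(_leaf_polygons(center_radius, lf)) for lf in leaves]
    for i in range(len(parts)):
        for j in range(i + 1, len(parts)):
            if parts[i].distance(parts[j]) < clearance:
                return False
    return True


def random_rosette_specs(
    n: int, seed: int = 0, image_size_px: int = 1024
) -> list[RosetteSpec]:
    """Draw ``n`` varied, frame-fitting, non-self-overlapping rosette specs.

    Leaf number, blade/petiole dimensions and the physical scale all vary,
    spanning compact many-leaved rosettes to sparse elongated ones.  Draws
    whose leaves would collide (blades touching neighbouring blades or
    petioles) are rejected and redrawn, keeping every generated rosette an
    exact oracle for the raster pipeline.
    """
    rng = np.random.default_rng(seed)
    specs: list[RosetteSpec] = []
    while len(specs) < n:
        blade = rng.uniform(12.0, 22.0)
        petiole = rng.uniform(6.0, 14.0)
        pw = rng.uniform(1.2, 2.0)
        n_leaves = int(rng.integers(5, 11))
        gap = math.radians(_min_angular_gap_deg(n_leaves, GOLDEN_ANGLE_DEG))
        # disk large enough to contain all petiole near-crossings
        r0 = pw / math.sin(min(gap, math.pi / 2)) + rng.uniform(0.5, 1.5)
        reach = (r0 + petiole + blade) * 1.15  # jitter headroom
        spec = RosetteSpec(
            n_leaves=n_leaves,
            blade_length_mm=blade,
            blade_width_mm=rng.uniform(4.0, 7.0),
            petiole_length_mm=petiole,
            petiole_width_mm=pw,
            center_radius_mm=r0,
            image_size_px=image_size_px,
            mm_per_px=2.0 * reach * 1.1 / image_size_px,
            seed=int(rng.integers(0, 2**31 - 1)),
            length_jitter=0.15,
        )
        if leaves_are_disjoint(spec.center_radius_mm, spec.leaves()):
            specs.append(spec)
    return specs
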