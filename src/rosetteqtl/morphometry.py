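"""Raster morphometry: nine shape descriptors from a binary rosette mask.

The descriptors split into three groups.  Size: projected rosette area
(PRA, mm^2) and perimeter length (PL, mm).  Ground coverage: Compactness
(area over convex-hull area) and rotational mass symmetry (RMS, the
convex-hull area falling outside the equal-area circle centred on the
plant centroid, as a fraction of the hull).  Geometry: slenderness of
leaves (SOL, squared skeleton length over area), roundness
(RND = 4*pi*A/P^2), convex-hull roundness (RCH), isotropy (ISO, roundness
of the polygon spanned by the leaf tips) and eccentricity (ECC, from the
ellipse sharing the mask's second central moments).

All lengths are converted to millimetres through the mask's ``mm_per_px``
scale, so the seven ratio descriptors are dimensionless and scale
invariant by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from shapely.geometry import Point, Polygon
from skimage import measure as skmeasure
from skimage.morphology import medial_axis

__all__ = [
    "DESCRIPTOR_NAMES",
    "RosetteMask",
    "RegionGeometry",
    "DescriptorVector",
    "extract_region_geometry",
    "compactness",
    "rotational_mass_symmetry",
    "slenderness_of_leaves",
    "roundness",
    "roundness_convex_hull",
    "isotropy",
    "eccentricity",
    "measure_rosette",
]

#: Canonical descriptor order (size, coverage, geometry).
DESCRIPTOR_NAMES = (
    "PRA",
    "PL",
    "Compactness",
    "RMS",
    "SOL",
    "RND",
    "RCH",
    "ISO",
    "ECC",
)

_CIRCLE_QUAD_SEGS = 256  # vertex density of the polygonal circle used for RMS
_CONTOUR_SIGMA_PX = 1.0  # Gaussian sigma for sub-pixel boundary extraction
_SKELETON_SALIENCE_PX = 3.0  # maximal-disc salience cutoff for spur pruning
_SKELETON_SIGMA_PX = 2.0  # boundary regularization before skeletonization


class MorphometryError(ValueError):
    """Raised for degenerate masks (empty, zero area)."""


@dataclass
class RosetteMask:
    """Binary raster of a single plant plus its physical pixel scale.

    ``pixels`` is a 2-D array where nonzero means foreground; ``mm_per_px``
    is the side length of one pixel in millimetres.
    """

    pixels: np.ndarray
    mm_per_px: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise MorphometryError("mask must be a 2-D array")
        if self.mm_per_px <= 0:
            raise MorphometryError("mm_per_px must be positive")

    @property
    def foreground(self) -> np.ndarray:
        return self.pixels != 0


@dataclass
class RegionGeometry:
    """Geometric measurements of one rosette region, all in mm units."""

    area: float
    perimeter: float
    area_convex_hull: float
    perimeter_convex_hull: float
    perimeter_skeleton: float
    major_axis_length: float
    minor_axis_length: float
    centroid: tuple[float, float]
    tip_polygon: np.ndarray  # (k, 2) ordered vertices; may use hull fallback
    tip_polygon_is_fallback: bool
    area_circle_only: float
    area_convex_hull_only: float
    area_intersection: float
    area_polygon: float
    perimeter_polygon: float
    skeleton_endpoints: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))


@dataclass
class DescriptorVector:
    """The nine shape descriptors of one rosette."""

    PRA: float
    PL: float
    Compactness: float
    RMS: float
    SOL: float
    RND: float
    RCH: float
    ISO: float
    ECC: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in DESCRIPTOR_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in DESCRIPTOR_NAMES])


# ---------------------------------------------------------------------------
# skeleton graph helpers


def _skeleton_graph(skel: np.ndarray):
    """8-connected pixel graph of a thinned skeleton.

    Returns (nodes, adjacency) where nodes are (row, col) tuples and
    adjacency maps node -> {neighbour: step length in px}.  A diagonal
    step is dropped when the two pixels already share an orthogonal
    skeleton neighbour, so staircase chains are measured as polylines
    rather than as triangle fans.
    """
    coords = np.argwhere(skel)
    on = set(map(tuple, coords))
    adj: dict[tuple[int, int], dict[tuple[int, int], float]] = {c: {} for c in on}
    for r, c in on:
        for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
            nb = (r + dr, c + dc)
            if nb not in on:
                continue
            if dr and dc:
                # skip diagonal if an orthogonal 2-step path exists
                if (r, c + dc) in on or (r + dr, c) in on:
                    continue
                w = math.sqrt(2.0)
            else:
                w = 1.0
            adj[(r, c)][nb] = w
            adj[nb][(r, c)] = w
    return adj


def _prune_spurs(adj, dist: np.ndarray, min_salience_px: float):
    """Iteratively remove low-salience endpoint branches of a medial axis.

    The salience of an endpoint branch is its path length plus the
    inscribed radius at the endpoint minus the inscribed radius at the
    junction it joins (the classical maximal-disc significance).  Branches
    produced by boundary staircase noise have salience near zero — they
    only just reach past their junction's inscribed disc — and are removed,
    while genuine limbs keep their full medial length.  A raster disk, whose
    medial web is entirely noise by this measure, collapses to (nearly) a
    point; a bare two-endpoint path is never pruned away entirely.
    """
    from shapely.geometry import LineString

    # salience already removed beyond a node, so repeated pruning at noise
    # junctions accumulates instead of resetting (cumulative-salience rule)
    credit: dict[tuple[int, int], float] = {}
    changed = True
    while changed:
        changed = False
        endpoints = [n for n, nbrs in adj.items() if len(nbrs) == 1]
        for ep in endpoints:
            if ep not in adj or len(adj[ep]) != 1:
                continue
            path = [ep]
            prev, cur = None, ep
            at_junction = False
            while True:
                if cur is not ep and len(adj[cur]) >= 3:
                    at_junction = True
                    break
                nbrs = [n for n in adj[cur] if n != prev]
                if not nbrs:
                    break  # other endpoint: bare path
                prev, cur = cur, nbrs[0]
                path.append(cur)
            if not at_junction:
                continue
            # polyline (not staircase-chain) length, so straight noise spurs
            # measure their true extent and keep near-zero salience
            if len(path) == 2:
                length = math.dist(path[0], path[1])
            else:
                length = LineString(path).simplify(1.0).length
            salience = length + dist[ep] + credit.get(ep, 0.0) - dist[cur]
            if salience >= min_salience_px:
                continue
            for node in path[:-1]:  # drop everything before the junction
                for nb in list(adj.get(node, {})):
                    adj[nb].pop(node, None)
                adj.pop(node, None)
                credit.pop(node, None)
            credit[cur] = max(credit.get(cur, 0.0), salience)
            changed = True
    return adj


def _graph_paths(adj):
    """Maximal paths between skeleton nodes of degree != 2 (plus cycles)."""
    paths = []
    visited: set[tuple] = set()

    def walk(start, nxt):
        path = [start, nxt]
        visited.add((start, nxt))
        visited.add((nxt, start))
        prev, cur = start, nxt
        while len(adj[cur]) == 2:
            cand = [m for m in adj[cur] if m != prev]
            if not cand or (cur, cand[0]) in visited:
                break
            prev, cur = cur, cand[0]
            visited.add((prev, cur))
            visited.add((cur, prev))
            path.append(cur)
        return path

    terminals = [n for n, nbrs in adj.items() if len(nbrs) != 2]
    for t in terminals:
        for nb in adj[t]:
            if (t, nb) not in visited:
                paths.append(walk(t, nb))
    for node, nbrs in adj.items():  # pure cycles have no terminals
        for nb in nbrs:
            if (node, nb) not in visited:
                paths.append(walk(node, nb))
    return paths


def _extend_terminal(ep, direction, dist, max_step=0.5):
    """March an endpoint outward to the true medial-axis terminus.

    Along the medial branch inside a cap, the inscribed radius D falls
    slower than unit rate, so g(l) = D + l climbs; past the medial
    endpoint the nearest boundary is the cap tip itself and g plateaus.
    Discrete thinning stops branches early in shallow caps; riding g to
    its plateau recovers the missing terminal piece.  Returns the added
    length and the new endpoint position (px).
    """
    cand = np.asarray(direction, dtype=float)
    pos = np.array(ep, dtype=float)
    g = float(ndimage.map_coordinates(dist, pos.reshape(2, 1), order=1)[0])
    length = 0.0
    for _ in range(400):
        nxt = pos + max_step * cand
        if not (0 <= nxt[0] < dist.shape[0] - 1 and 0 <= nxt[1] < dist.shape[1] - 1):
            break
        d_next = float(ndimage.map_coordinates(dist, nxt.reshape(2, 1), order=1)[0])
        if d_next <= 0.25:  # reached the boundary
            break
        g_next = d_next + length + max_step
        if g_next < g + 0.02 * max_step:
            break
        g, pos, length = g_next, nxt, length + max_step
    return length, pos


def _graph_length_endpoints(adj, dist=None):
    """Skeleton length (px) and endpoint coordinates.

    Branch chains are simplified with a 1-px tolerance before measuring,
    which removes the systematic overestimate of stepping along staircase
    pixel chains at oblique angles.  When a distance transform is given,
    terminal branches are additionally extended to the medial-axis
    terminus of their cap (see ``_extend_terminal``).
    """
    from shapely.geometry import LineString

    total = 0.0
    endpoints = []
    for path in _graph_paths(adj):
        if len(path) == 2:
            total += math.dist(path[0], path[1])
        else:
            total += LineString(path).simplify(1.0).length
        for idx in (0, -1):
            node = path[idx]
            if len(adj[node]) != 1:
                continue
            ep = np.array(node, dtype=float)
            if dist is not None and len(path) >= 2:
                # branch direction from the simplified polyline's terminal
                # segment: robust to single-pixel chain wiggle
                simp = np.asarray(
                    LineString(path).simplify(1.0).coords
                    if len(path) > 2
                    else path,
                    dtype=float,
                )
                inner = simp[1] if idx == 0 else simp[-2]
                vec = ep - inner
                norm = np.hypot(*vec)
                if norm > 0:
                    extra, ep = _extend_terminal(node, vec / norm, dist)
                    total += extra
            endpoints.append(ep)
    # deduplicate endpoints shared by several paths
    uniq: list[np.ndarray] = []
    for ep in endpoints:
        if not any(np.allclose(ep, u) for u in uniq):
            uniq.append(ep)
    return total, np.array(uniq, dtype=float).reshape(-1, 2)


# ---------------------------------------------------------------------------


def _shoelace(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def _poly_perimeter(poly: np.ndarray) -> float:
    d = np.diff(np.vstack([poly, poly[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def extract_region_geometry(mask: RosetteMask) -> RegionGeometry:
    """Measure the raw geometric quantities behind the nine descriptors.

    The foreground region is reduced to its largest connected component
    (8-connectivity).  Area is the pixel count; the perimeter is the length
    of the sub-pixel outer contour traced at the 0.5 level of the Gaussian
    boundary model; the convex hull is taken over pixel corner points so
    that hull area >= area holds exactly; the skeleton is the Euclidean
    medial axis of the regularized mask with maximal-disc salience pruning
    and terminal extension (structures narrower than ~4 px are below the
    regularization scale and do not contribute skeleton branches).
    """
    fg = mask.foreground
    if not fg.any():
        raise MorphometryError("mask has no foreground pixels")
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        warnings.warn(
            f"mask has {n} connected components; keeping the largest",
            stacklevel=2,
        )
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        fg = labels == (int(np.argmax(sizes)) + 1)

    s = mask.mm_per_px
    npix = int(fg.sum())
    area = npix * s * s

    # outer boundary: longest 0.5-level contour of the lightly smoothed mask.
    # The Gaussian (sigma = 1 px) recovers sub-pixel boundary position and
    # suppresses the staircase overestimate of binary marching squares.
    padded = np.pad(fg.astype(float), 4)
    smoothed = ndimage.gaussian_filter(padded, _CONTOUR_SIGMA_PX)
    contours = skmeasure.find_contours(smoothed, 0.5)
    contour = max(contours, key=lambda c: len(c))
    dseg = np.diff(contour, axis=0)
    perimeter = float(np.hypot(dseg[:, 0], dseg[:, 1]).sum()) * s

    # convex hull over pixel corners of the boundary pixels
    eroded = ndimage.binary_erosion(fg, structure=np.ones((3, 3)))
    boundary = np.argwhere(fg & ~eroded)
    corners = np.concatenate(
        [boundary + np.array(off) for off in ((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))]
    )
    hull = ConvexHull(corners)
    hull_poly_px = corners[hull.vertices]  # (row, col) in px
    area_hull = hull.volume * s * s
    perim_hull = hull.area * s

    # centroid and second central moments of pixel centers
    coords = np.argwhere(fg).astype(float)
    centroid_px = coords.mean(axis=0)
    centred = coords - centroid_px
    cov = centred.T @ centred / npix
    lam = np.linalg.eigvalsh(cov)  # ascending
    lam = np.clip(lam, 0.0, None)
    major = 4.0 * math.sqrt(lam[1]) * s
    minor = 4.0 * math.sqrt(lam[0]) * s
    centroid_mm = (centroid_px[0] * s, centroid_px[1] * s)

    # skeleton: Euclidean medial axis + salience pruning.  The mask is
    # re-binarized from the same Gaussian boundary model as the contour:
    # raw masks carry boundary roughness at the 1-2 px scale (all the more
    # after resampling or rotation) whose corner spurs would survive any
    # length- or salience-based pruning; regularization keeps the true
    # boundary within ~0.2 px while pushing roughness below a pixel.
    # Staircase-noise branches then have near-zero salience however long
    # they are, so the pruning cutoff is a small fixed pixel count.
    skel_fg = ndimage.gaussian_filter(fg.astype(float), _SKELETON_SIGMA_PX) > 0.5
    if not skel_fg.any():  # tiny region erased by smoothing: fall back
        skel_fg = fg
    # rng pins medial_axis tie-breaking so measurement is deterministic
    skel, dist = medial_axis(skel_fg, return_distance=True, rng=0)
    adj = _skeleton_graph(skel)
    adj = _prune_spurs(adj, dist, _SKELETON_SALIENCE_PX)
    skel_len_px, endpoints_px = _graph_length_endpoints(adj, dist)
    perimeter_skeleton = skel_len_px * s
    endpoints_mm = endpoints_px * s

    # tip polygon: skeleton endpoints ordered by angle about the centroid
    fallback = endpoints_mm.shape[0] < 3
    if fallback:
        tip_poly = hull_poly_px * s
    else:
        rel = endpoints_mm - np.array(centroid_mm)
        order = np.argsort(np.arctan2(rel[:, 1], rel[:, 0]))
        tip_poly = endpoints_mm[order]
    area_polygon = _shoelace(tip_poly)
    perimeter_polygon = _poly_perimeter(tip_poly)

    # circle of the same area as the convex hull, centred on the centroid
    hull_shapely = Polygon(hull_poly_px * s)
    radius = math.sqrt(area_hull / math.pi)
    circle = Point(centroid_mm).buffer(radius, quad_segs=_CIRCLE_QUAD_SEGS)
    inter = hull_shapely.intersection(circle).area
    area_hull_only = hull_shapely.area - inter
    area_circle_only = circle.area - inter

    return RegionGeometry(
        area=area,
        perimeter=perimeter,
        area_convex_hull=area_hull,
        perimeter_convex_hull=perim_hull,
        perimeter_skeleton=perimeter_skeleton,
        major_axis_length=major,
        minor_axis_length=minor,
        centroid=centroid_mm,
        tip_polygon=tip_poly,
        tip_polygon_is_fallback=fallback,
        area_circle_only=area_circle_only,
        area_convex_hull_only=area_hull_only,
        area_intersection=inter,
        area_polygon=area_polygon,
        perimeter_polygon=perimeter_polygon,
        skeleton_endpoints=endpoints_mm,
    )


def compactness(g: RegionGeometry) -> float:
    """Area over convex-hull area; 1 for a gap-free convex rosette."""
    return g.area / g.area_convex_hull


def rotational_mass_symmetry(g: RegionGeometry) -> float:
    """Convex-hull mass displaced off the equal-area centred circle.

    With the circle chosen to have the same area as the convex hull and
    centred on the plant centroid, the hull-only and circle-only areas are
    equal, and the index reduces to 1 - intersection/hull: 0 when the hull
    coincides with its circle (round, centred rosettes), approaching 1 for
    strongly eccentric or offset shapes.
    """
    num = g.area_circle_only + g.area_convex_hull_only
    den = num + 2.0 * g.area_intersection
    return num / den if den > 0 else 0.0


def slenderness_of_leaves(g: RegionGeometry) -> float:
    """Squared skeleton length over area (dimensionless); ~0 for a disk."""
    return g.perimeter_skeleton**2 / g.area


def roundness(g: RegionGeometry) -> float:
    """Isoperimetric quotient 4*pi*A/P^2; 1 for a disk."""
    return 4.0 * math.pi * g.area / g.perimeter**2


def roundness_convex_hull(g: RegionGeometry) -> float:
    """Roundness of the convex hull."""
    return 4.0 * math.pi * g.area_convex_hull / g.perimeter_convex_hull**2


def isotropy(g: RegionGeometry) -> float:
    """Roundness of the leaf-tip polygon (hull fallback below 3 tips)."""
    if g.perimeter_polygon <= 0:
        return float("nan")
    return 4.0 * math.pi * g.area_polygon / g.perimeter_polygon**2


def eccentricity(g: RegionGeometry) -> float:
    """Eccentricity of the second-moment ellipse: 0 = circle, -> 1 = line."""
    if g.major_axis_length == 0:
        return 0.0
    ratio = g.minor_axis_length / g.major_axis_length
    return math.sqrt(max(0.0, 1.0 - ratio * ratio))


def descriptors_from_geometry(g: RegionGeometry) -> DescriptorVector:
    """Assemble the nine-descriptor vector from measured geometry."""
    return DescriptorVector(
        PRA=g.area,
        PL=g.perimeter,
        Compactness=compactness(g),
        RMS=rotational_mass_symmetry(g),
        SOL=slenderness_of_leaves(g),
        RND=roundness(g),
        RCH=roundness_convex_hull(g),
        ISO=isotropy(g),
        ECC=eccentricity(g),
    )


def measure_rosette(mask: RosetteMask) -> DescriptorVector:
    """Compute all nine shape descriptors for one binary rosette mask."""
    return descriptors_from_geometry(extract_region_geometry(mask))
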