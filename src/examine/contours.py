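"""Euler-diagram-style set contours from a trained neuron field.

For an active annotation set, the corresponding component of every neuron
forms a scalar field over the grid — a fuzzy membership landscape.
Thresholding the field selects a set of tiles, whose union is refined into
the drawn shape: staircase corners are tightened with shortcuts across
item-free tiles, the outline is smoothed morphologically (dilate r, erode
2r, dilate r — Minkowski sum/subtraction with a disc), nesting erosion
separates outlines of overlapping sets, and the painted ribbon is the
difference between each body and an eroded copy of itself.

The geometric scales are all bounded by a fraction of the tile size, which
guarantees the central contract: a node's cell center lies inside a set's
final contour if and only if the node belongs to the set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPolygon, Point, Polygon, box
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from examine.hypergraph import AnnotatedModule
from examine.rsom import Layout, NeuronGrid

__all__ = [
    "GeometryParams",
    "SetContour",
    "ContainmentError",
    "scalar_field",
    "tile_body",
    "tiles_to_polygon",
    "tighten",
    "smooth",
    "nest_and_ribbon",
    "build_contours",
]


class ContainmentError(RuntimeError):
    """A contour lost or gained an item it must (not) contain."""


@dataclass(frozen=True)
class GeometryParams:
    """Tunable scales of the contour geometry, in canvas units.

    tile
        Edge length of one grid cell (canvas units per cell).
    tau
        Threshold fraction: a tile joins a set's body when the neuron
        component is at least ``tau * w_i`` (the set's weight scales the
        field, so the threshold scales with it).
    r
        Morphological smoothing radius.  Default 0.15 * tile.
    delta
        Erosion step between nesting levels.  Default 0.05 * tile.
    e
        Ribbon width (erosion distance between a body and the hole cut
        out of it).  Default 0.12 * tile.
    arc_tol
        Acceptable area error when circular arcs are approximated by
        polygons.  Default 1e-3 * tile**2.
    quad_segs
        Segments per quarter circle in Minkowski (buffer) operations.
    """

    tile: float = 1.0
    tau: float = 0.5
    r: float = None  # type: ignore[assignment]
    delta: float = None  # type: ignore[assignment]
    e: float = None  # type: ignore[assignment]
    arc_tol: float = None  # type: ignore[assignment]
    quad_segs: int = 16

    def __post_init__(self) -> None:
        if self.tile <= 0:
            raise ValueError("tile must be positive")
        if not (0.0 < self.tau <= 1.0):
            raise ValueError("tau must lie in (0, 1]")
        for name, default in (
            ("r", 0.15 * self.tile),
            ("delta", 0.05 * self.tile),
            ("e", 0.12 * self.tile),
            ("arc_tol", 1e-3 * self.tile**2),
        ):
            if getattr(self, name) is None:
                object.__setattr__(self, name, default)
            elif getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.quad_segs < 4:
            raise ValueError("quad_segs must be >= 4")
        if self.r + self.e >= 0.5 * self.tile:
            raise ValueError(
                "r + e must stay below half a tile so member cell centers "
                "remain inside their ribbons"
            )

    def nesting_step(self, depth_max: int) -> float:
        """Erosion step actually used for ``depth_max`` nesting levels.

        Shrinks ``delta`` when necessary so that
        r + depth_max * step + e < 0.5 * tile, preserving the
        containment guarantee for arbitrarily many active sets.
        """
        if depth_max <= 0:
            return self.delta
        headroom = 0.5 * self.tile - self.r - self.e
        return min(self.delta, 0.95 * headroom / depth_max)


@dataclass
class SetContour:
    """Drawable geometry of one active set.

    ``body`` is the set's region at its nesting erosion level, ``eroded``
    the copy shrunk by the ribbon width, and ``ribbon`` their difference —
    the opaque colored annulus actually painted.  ``z`` is the drawing
    rank: 0 is the largest body, drawn first (furthest back).
    """

    set_id: str
    body: BaseGeometry
    eroded: BaseGeometry
    ribbon: BaseGeometry
    z: int
    color: str | None = None


def scalar_field(grid: NeuronGrid, component_index: int) -> np.ndarray:
    """The i-th component of every neuron, as an (N, N) array.

    ``field[y, x]`` is the component value at cell (x, y); an exact
    slice, no smoothing.
    """
    if not (0 <= component_index < grid.dimension):
        raise IndexError(
            f"component {component_index} out of range for dimension {grid.dimension}"
        )
    return np.array(grid.values[:, :, component_index], dtype=np.float64)


def tile_body(
    field: np.ndarray,
    layout: Layout,
    set_members: set[str],
    params: GeometryParams,
    weight: float = 1.0,
) -> set[tuple[int, int]]:
    """Threshold the field into the set of cells forming a contour body.

    A cell joins when its value reaches ``tau * weight``.  Reserved cells
    of member nodes are force-included and reserved cells of non-member
    nodes force-excluded, making "a node is inside the contour iff it is
    in the set" a hard guarantee rather than a property of converged
    training.  A weight of 0 flattens the field, so only member cells
    remain.
    """
    side = field.shape[0]
    if field.shape != (side, side):
        raise ValueError("field must be square")
    if layout.side != side:
        raise ValueError("field and layout disagree on grid side")
    cells: set[tuple[int, int]] = set()
    if weight > 0:
        ys, xs = np.nonzero(field >= params.tau * weight)
        cells = {(int(x), int(y)) for x, y in zip(xs, ys)}
    for node_id, cell in layout.positions.items():
        if node_id in set_members:
            cells.add(cell)
        else:
            cells.discard(cell)
    return cells


def tiles_to_polygon(
    cells: set[tuple[int, int]], params: GeometryParams
) -> BaseGeometry:
    """Union of the cells' axis-aligned squares, tile-scaled.

    Returns a (Multi)Polygon whose area is exactly ``len(cells) * tile**2``.
    """
    t = params.tile
    if not cells:
        return Polygon()
    boxes = [box(x * t, y * t, (x + 1) * t, (y + 1) * t) for x, y in sorted(cells)]
    return unary_union(boxes)


def _rings(geom: BaseGeometry):
    """All rings (exterior + interior) of a (Multi)Polygon."""
    if geom.is_empty:
        return
    polys = geom.geoms if isinstance(geom, MultiPolygon) else [geom]
    for p in polys:
        yield p.exterior
        yield from p.interiors


def tighten(
    polygon: BaseGeometry,
    item_cells: set[tuple[int, int]],
    params: GeometryParams,
) -> BaseGeometry:
    """One corner-cutting pass: shortcut staircase corners across free tiles.

    Every convex right-angle corner of the tile union is replaced by its
    diagonal chord — the cut-off triangle (legs at most one tile, at most
    half of each incident edge) is removed — unless that triangle overlaps
    a cell containing a placed item.  Item cell centers therefore keep
    their in/out status, and the area never increases.
    """
    if polygon.is_empty:
        return polygon
    t = params.tile
    eps = 1e-9 * t * t  # area tolerance
    ceps = 1e-9 * t  # coordinate tolerance
    item_boxes = [
        box(x * t, y * t, (x + 1) * t, (y + 1) * t) for x, y in sorted(item_cells)
    ]
    cuts = []
    for ring in _rings(polygon):
        coords = list(ring.coords)  # closed: first == last
        n = len(coords) - 1
        if n < 3:
            continue
        for i in range(n):
            p = np.asarray(coords[(i - 1) % n])
            v = np.asarray(coords[i])
            q = np.asarray(coords[(i + 1) % n])
            ep, eq = p - v, q - v
            lp, lq = float(np.hypot(*ep)), float(np.hypot(*eq))
            if lp == 0 or lq == 0:
                continue
            # staircase corners only: both incident edges axis-aligned,
            # meeting at a right angle
            if not (
                (abs(ep[0]) < ceps or abs(ep[1]) < ceps)
                and (abs(eq[0]) < ceps or abs(eq[1]) < ceps)
                and abs(ep @ eq) < eps
            ):
                continue
            a = v + ep / lp * min(t, lp / 2.0)
            b = v + eq / lq * min(t, lq / 2.0)
            tri = Polygon([tuple(a), tuple(v), tuple(b)])
            if tri.area < eps:
                continue
            # convex for the polygon: the cut-off triangle lies inside it
            if tri.intersection(polygon).area < tri.area - eps:
                continue
            if any(tri.intersection(bx).area > eps for bx in item_boxes):
                continue
            cuts.append(tri)
    if not cuts:
        return polygon
    return polygon.difference(unary_union(cuts))


def smooth(polygon: BaseGeometry, params: GeometryParams) -> BaseGeometry:
    """Morphological closing then opening: dilate r, erode 2r, dilate r.

    Dilation and erosion are Minkowski sum/subtraction with a disc of
    radius r (buffers with round joins); circular arcs are approximated
    with ``quad_segs`` segments per quarter circle, keeping the area
    error within ``arc_tol``.  Empty input stays empty.
    """
    if polygon.is_empty:
        return polygon
    r, q = params.r, params.quad_segs
    return (
        polygon.buffer(r, quad_segs=q)
        .buffer(-2.0 * r, quad_segs=q)
        .buffer(r, quad_segs=q)
    )


def nest_and_ribbon(
    bodies: list[tuple[str, BaseGeometry]],
    params: GeometryParams,
    member_points: dict[str, list[tuple[float, float]]] | None = None,
) -> list[SetContour]:
    """Assign nesting levels and cut ribbons; returns contours in z-order.

    Sets are ranked by descending body area (ties by input order); the
    rank-k body is eroded by k nesting steps so outlines of nested or
    overlapping sets keep a visible distance, then the ribbon is the body
    minus a copy eroded by the ribbon width e.  If ``member_points`` is
    given, every member point is verified to remain inside its set's
    final body (:class:`ContainmentError` otherwise).
    """
    order = sorted(range(len(bodies)), key=lambda i: (-bodies[i][1].area, i))
    step = params.nesting_step(len(bodies) - 1)
    out: list[SetContour] = []
    for z, i in enumerate(order):
        set_id, body = bodies[i]
        shrunk = body.buffer(-z * step, quad_segs=params.quad_segs) if z else body
        eroded = shrunk.buffer(-params.e, quad_segs=params.quad_segs)
        ribbon = shrunk.difference(eroded)
        if member_points is not None:
            for pt in member_points.get(set_id, []):
                if not shrunk.covers(Point(pt)):
                    raise ContainmentError(
                        f"member point {pt} escaped contour of set {set_id!r}"
                    )
        out.append(
            SetContour(set_id=set_id, body=shrunk, eroded=eroded, ribbon=ribbon, z=z)
        )
    return out


def build_contours(
    module: AnnotatedModule,
    grid: NeuronGrid,
    layout: Layout,
    params: GeometryParams | None = None,
) -> list[SetContour]:
    """Full contour pipeline for every active set of a trained module.

    Slices the neuron field per active set, thresholds it into tiles,
    tightens, smooths, then nests and ribbons the bodies.  Verifies the
    containment contract in both directions: member cell centers inside
    the final body, non-member cell centers outside.
    """
    if params is None:
        params = GeometryParams(tile=layout.tile)
    n_edges = len(module.interactions)
    item_cells = set(layout.positions.values())
    bodies: list[tuple[str, BaseGeometry]] = []
    member_points: dict[str, list[tuple[float, float]]] = {}
    for j, s in enumerate(module.active_sets):
        field = scalar_field(grid, n_edges + j)
        cells = tile_body(field, layout, set(s.members), params, weight=s.weight)
        poly = tiles_to_polygon(cells, params)
        poly = tighten(poly, item_cells, params)
        poly = smooth(poly, params)
        bodies.append((s.id, poly))
        member_points[s.id] = [layout.center(nid) for nid in sorted(s.members)]
    contours = nest_and_ribbon(bodies, params, member_points)
    by_id = {s.id: s for s in module.active_sets}
    for c in contours:
        members = by_id[c.set_id].members
        for nid in layout.positions:
            if nid not in members and c.body.covers(Point(layout.center(nid))):
                raise ContainmentError(
                    f"non-member {nid!r} inside contour of set {c.set_id!r}"
                )
    return contours
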