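"""Reservation-based self-organizing-map (RSOM) layout.

A standard SOM maps high-dimensional items onto a 2D neuron grid by
competitive learning; similar items land on nearby cells.  The variant
implemented here adds *reservations*: within each training epoch every
item claims the unreserved neuron closest to it (cosine distance) and
subsequent items ignore that cell, so similar items "trickle outwards"
into distinct cells instead of piling up.  After the final epoch the
reservation map is an injective node -> cell layout, and the trained
neuron field doubles as a fuzzy membership landscape from which set
contours are derived (:mod:`examine.contours`).

Training items are the membership vectors of :func:`examine.hypergraph.encode`;
interactions and annotation sets therefore shape the layout on equal terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from examine.hypergraph import AnnotatedModule, MembershipMatrix, with_set_weight

__all__ = [
    "TrainingSchedule",
    "NeuronGrid",
    "Layout",
    "cosine_distance",
    "grid_side",
    "init_grid",
    "train_epoch",
    "train",
    "retrain",
    "set_dominance",
]

#: Training strength used when warm-starting from a previous grid so the
#: previous layout (the user's mental map) is largely preserved.
WARM_START_C = 0.01
#: Default cold-start training strength.
COLD_START_C = 0.5
#: Default grid-side cap; keeps radius schedules meaningful for big modules.
DEFAULT_GRID_CAP = 64


def cosine_distance(q: np.ndarray, p: np.ndarray) -> float:
    """Metric form of cosine similarity: arccos(q.p / (|q||p|)) / pi.

    Symmetric, in [0, 1]; 0 for parallel non-zero vectors, 1 for
    antiparallel ones.  The normalized dot product is clamped to
    [-1, 1] before the arccos to absorb rounding.  Zero vectors make
    the quotient undefined; by convention d(0, 0) = 0 and
    d(0, p != 0) = 1.
    """
    q = np.asarray(q, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if q.shape != p.shape:
        raise ValueError(f"vector length mismatch: {q.shape} vs {p.shape}")
    nq = math.sqrt(float(q @ q))
    np_ = math.sqrt(float(p @ p))
    if nq == 0.0 and np_ == 0.0:
        return 0.0
    if nq == 0.0 or np_ == 0.0:
        return 1.0
    if np.array_equal(q, p):
        return 0.0  # exact self-similarity, immune to rounding in acos
    cos = float(q @ p) / (nq * np_)
    cos = max(-1.0, min(1.0, cos))
    return math.acos(cos) / math.pi


@dataclass(frozen=True)
class TrainingSchedule:
    """Linear annealing schedule for strength alpha and radius r.

    alpha(i) = c * (1 - i/I) and radius(i) = floor((1 - i/I) * N), so the
    neighborhood starts grid-wide and shrinks to the single winning cell
    while the training strength decays from ``c`` to 0.  ``seed`` drives
    all randomness of the run (grid initialization and per-epoch item
    shuffles) through derived sub-streams.

    ``radius_start`` caps the initial neighborhood radius (default: the
    grid side).  Warm starts rely on this: restarting the radius at N
    would let even a tiny strength flatten the trained landscape over
    the course of the run, erasing the layout being preserved, so
    :func:`retrain` restarts the radius at N/4 instead.
    """

    c: float
    iterations: int
    seed: int
    radius_start: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.c < 1.0):
            raise ValueError("c must lie in (0, 1)")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.radius_start is not None and self.radius_start < 0:
            raise ValueError("radius_start must be >= 0")

    @classmethod
    def for_items(
        cls,
        n_items: int,
        seed: int,
        c: float = COLD_START_C,
        iterations: int | None = None,
    ) -> "TrainingSchedule":
        """Default schedule: I = ceil(10^6 / |T|) iterations."""
        if iterations is None:
            iterations = math.ceil(1_000_000 / max(1, n_items))
        return cls(c=c, iterations=iterations, seed=seed)

    def alpha(self, i: int) -> float:
        return self.c * (1.0 - i / self.iterations)

    def radius(self, i: int, side: int) -> int:
        r0 = side if self.radius_start is None else min(self.radius_start, side)
        return math.floor((1.0 - i / self.iterations) * r0)


@dataclass
class NeuronGrid:
    """N x N grid of M-dimensional neurons plus the reservation map.

    ``values[y, x]`` is the neuron vector of cell (x, y); ``reservations``
    maps node ids to their reserved cells (injective).  ``component_keys``
    records the identity of each vector component so grids can be
    reconciled across module edits.
    """

    side: int
    values: np.ndarray  # (side, side, M) float64
    reservations: dict[str, tuple[int, int]] = field(default_factory=dict)
    component_keys: list[tuple[str, str]] = field(default_factory=list)

    @property
    def dimension(self) -> int:
        return self.values.shape[2]

    def copy(self) -> "NeuronGrid":
        return NeuronGrid(
            side=self.side,
            values=self.values.copy(),
            reservations=dict(self.reservations),
            component_keys=list(self.component_keys),
        )


@dataclass
class Layout:
    """Final injective node -> integer cell assignment."""

    positions: dict[str, tuple[int, int]]
    side: int
    tile: float = 1.0

    def center(self, node_id: str) -> tuple[float, float]:
        """Canvas-unit center of a node's cell."""
        x, y = self.positions[node_id]
        return ((x + 0.5) * self.tile, (y + 0.5) * self.tile)


def grid_side(n_items: int, cap: int = DEFAULT_GRID_CAP, mode: str = "side") -> int:
    """Grid side N for a module of ``n_items`` nodes.

    ``mode="side"`` (default): N = min(2|T|, cap), giving the layout room
    to breathe.  ``mode="cells"``: the more frugal reading with about
    2|T| cells in total, N = ceil(sqrt(2|T|)).
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    if mode == "side":
        side = min(2 * n_items, cap)
    elif mode == "cells":
        side = math.ceil(math.sqrt(2 * n_items))
    else:
        raise ValueError(f"unknown grid mode {mode!r}")
    # always enough cells for an injective layout
    return max(side, math.ceil(math.sqrt(n_items)), 1)


def init_grid(
    side: int, m: int, weights: np.ndarray, rng: np.random.Generator
) -> NeuronGrid:
    """Random initial grid: component i uniform on [0, weights[i]].

    ``weights`` are per-component upper bounds — the component's data
    range, i.e. its set weight w_i when the component has any member and
    0 otherwise, so neurons start inside the span of the training items.
    Each component draws from its own sub-stream spawned off ``rng``,
    which makes the draw for component i independent of how many further
    components exist.
    """
    if side < 1 or m < 0:
        raise ValueError("side must be >= 1 and m >= 0")
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (m,):
        raise ValueError("weights must have length m")
    values = np.empty((side, side, m), dtype=np.float64)
    children = rng.spawn(m) if m > 0 else []
    for i in range(m):
        values[:, :, i] = children[i].uniform(0.0, weights[i], size=(side, side))
    return NeuronGrid(side=side, values=values)


@njit(cache=True)
def _epoch_kernel(
    raw,  # (C, M) float64 lazily-scaled neuron values; actual q = g[c] * raw[c]
    g,  # (C,) float64 per-cell pending scale factors
    norms2,  # (C,) float64 squared norms of the *actual* neuron vectors
    it_idx,  # (T, K) int64 sparse component indices per item (padded)
    it_val,  # (T, K) float64 sparse component values per item
    it_nnz,  # (T,) int64
    it_norm,  # (T,) float64 item vector norms
    order,  # (T,) int64 processing order of items
    alpha,  # float64
    radius,  # int64 Chebyshev neighborhood radius
    side,  # int64
    res_out,  # (T,) int64 reserved cell per item, written
):  # pragma: no cover - exercised via train/train_epoch
    # The convex update q <- (1-a) q + a t touches every component of q,
    # but t is sparse; representing q = g * raw turns the update into a
    # scalar multiply on g plus sparse additions on raw, and the squared
    # norm follows in closed form.  g is folded back into raw before it
    # can underflow.
    n_cells = raw.shape[0]
    m = raw.shape[1]
    reserved = np.zeros(n_cells, dtype=np.bool_)
    one_minus_a = 1.0 - alpha
    for k in range(order.shape[0]):
        t = order[k]
        tn = it_norm[t]
        nnz = it_nnz[t]
        best = -1
        best_s = -3.0  # below any similarity; ties keep smallest index
        for cell in range(n_cells):
            if reserved[cell]:
                continue
            nq2 = norms2[cell]
            if tn == 0.0:
                s = 1.0 if nq2 <= 0.0 else -1.0
            elif nq2 <= 0.0:
                s = -1.0
            else:
                dot = 0.0
                for j in range(nnz):
                    dot += it_val[t, j] * raw[cell, it_idx[t, j]]
                dot *= g[cell]
                s = dot / (tn * math.sqrt(nq2))
                if s > 1.0:
                    s = 1.0
                elif s < -1.0:
                    s = -1.0
            if s > best_s:
                best_s = s
                best = cell
        reserved[best] = True
        res_out[t] = best
        if alpha > 0.0:
            cy = best // side
            cx = best % side
            y0 = max(0, cy - radius)
            y1 = min(side - 1, cy + radius)
            x0 = max(0, cx - radius)
            x1 = min(side - 1, cx + radius)
            for yy in range(y0, y1 + 1):
                base = yy * side
                for xx in range(x0, x1 + 1):
                    c2 = base + xx
                    if alpha >= 1.0:
                        for mm in range(m):
                            raw[c2, mm] = 0.0
                        for j in range(nnz):
                            raw[c2, it_idx[t, j]] = it_val[t, j]
                        g[c2] = 1.0
                        norms2[c2] = tn * tn
                        continue
                    qt = 0.0
                    for j in range(nnz):
                        qt += it_val[t, j] * raw[c2, it_idx[t, j]]
                    qt *= g[c2]
                    n2 = (
                        one_minus_a * one_minus_a * norms2[c2]
                        + 2.0 * alpha * one_minus_a * qt
                        + alpha * alpha * tn * tn
                    )
                    norms2[c2] = n2 if n2 > 0.0 else 0.0
                    gn = g[c2] * one_minus_a
                    for j in range(nnz):
                        raw[c2, it_idx[t, j]] += alpha * it_val[t, j] / gn
                    if gn < 1e-100:
                        for mm in range(m):
                            raw[c2, mm] *= gn
                        gn = 1.0
                    g[c2] = gn


def _sparse_items(values: np.ndarray):
    """CSR-like padded sparse view of the item matrix for the kernel."""
    t, m = values.shape
    nnz = (values != 0.0).sum(axis=1).astype(np.int64)
    k = max(1, int(nnz.max()) if t else 1)
    idx = np.zeros((t, k), dtype=np.int64)
    val = np.zeros((t, k), dtype=np.float64)
    for i in range(t):
        nz = np.flatnonzero(values[i])
        idx[i, : nz.size] = nz
        val[i, : nz.size] = values[i, nz]
    norms = np.sqrt((values**2).sum(axis=1))
    return idx, val, nnz, norms


def train_epoch(
    grid: NeuronGrid,
    matrix: MembershipMatrix,
    alpha: float,
    radius: int,
    rng: np.random.Generator,
) -> NeuronGrid:
    """Run one reservation epoch, returning the updated grid.

    Reservations are cleared, items are processed in an rng-shuffled
    order, each reserves the unreserved neuron minimizing cosine
    distance (ties go to the smaller row-major cell index) and every
    neuron within Chebyshev ``radius`` of the reserved cell — reserved
    or not — moves by the convex rule q <- q + alpha (t - q).
    """
    n_items = len(matrix.node_ids)
    if matrix.dimension != grid.dimension:
        raise ValueError(
            f"matrix dimension {matrix.dimension} != grid dimension {grid.dimension}"
        )
    if n_items > grid.side**2:
        raise ValueError(f"{n_items} items exceed {grid.side ** 2} grid cells")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    out = grid.copy()
    raw = np.ascontiguousarray(out.values.reshape(-1, out.dimension))
    g = np.ones(raw.shape[0], dtype=np.float64)
    norms2 = (raw**2).sum(axis=1)
    it_idx, it_val, it_nnz, it_norm = _sparse_items(matrix.values)
    order = rng.permutation(n_items).astype(np.int64)
    res = np.empty(n_items, dtype=np.int64)
    _epoch_kernel(
        raw, g, norms2, it_idx, it_val, it_nnz, it_norm, order,
        float(alpha), int(radius), int(out.side), res,
    )
    out.values = (raw * g[:, None]).reshape(out.side, out.side, out.dimension)
    out.reservations = {
        matrix.node_ids[i]: (int(res[i] % out.side), int(res[i] // out.side))
        for i in range(n_items)
    }
    assert len(set(out.reservations.values())) == n_items
    return out


def _reconcile(
    grid: NeuronGrid,
    matrix: MembershipMatrix,
    upper: np.ndarray,
    init_rng: np.random.Generator,
) -> np.ndarray:
    """Carry neuron planes across a component change (warm start).

    Components present in the old grid (same interaction/set identity)
    keep their trained values; new components are initialized uniform on
    [0, upper_i]; removed components are dropped.
    """
    side = grid.side
    m_new = matrix.dimension
    old_index = {key: i for i, key in enumerate(grid.component_keys)}
    values = np.empty((side, side, m_new), dtype=np.float64)
    children = init_rng.spawn(m_new) if m_new > 0 else []
    for i, key in enumerate(matrix.component_keys):
        j = old_index.get(key)
        if j is not None and j < grid.dimension:
            values[:, :, i] = grid.values[:, :, j]
        else:
            values[:, :, i] = children[i].uniform(0.0, upper[i], size=(side, side))
    return values


def train(
    matrix: MembershipMatrix,
    schedule: TrainingSchedule,
    grid: NeuronGrid | None = None,
    *,
    side: int | None = None,
    grid_cap: int = DEFAULT_GRID_CAP,
    grid_mode: str = "side",
    tile: float = 1.0,
) -> tuple[Layout, NeuronGrid]:
    """Train the RSOM for ``schedule.iterations`` epochs.

    Cold starts draw a fresh random grid; passing ``grid`` warm-starts
    from a previous neuron configuration (use :func:`retrain`, which also
    picks the low preservation strength c = 0.01).  The final epoch's
    reservation map becomes the returned :class:`Layout`.  The result is
    a pure function of (matrix, schedule, grid): identical inputs give
    bit-identical outputs.
    """
    n_items = len(matrix.node_ids)
    if grid is not None:
        side = grid.side
    elif side is None:
        side = grid_side(n_items, cap=grid_cap, mode=grid_mode)
    if n_items > side**2:
        raise ValueError(f"{n_items} items exceed {side ** 2} grid cells")

    root = np.random.SeedSequence(schedule.seed)
    init_ss, order_ss = root.spawn(2)
    upper = matrix.values.max(axis=0) if n_items else np.zeros(matrix.dimension)

    if grid is None:
        start = init_grid(side, matrix.dimension, upper, np.random.default_rng(init_ss))
    else:
        start = NeuronGrid(side=side, values=_reconcile(
            grid, matrix, upper, np.random.default_rng(init_ss)))

    raw = np.ascontiguousarray(start.values.reshape(-1, matrix.dimension))
    g = np.ones(raw.shape[0], dtype=np.float64)
    norms2 = (raw**2).sum(axis=1)
    it_idx, it_val, it_nnz, it_norm = _sparse_items(matrix.values)
    order_rng = np.random.default_rng(order_ss)
    n_iter = schedule.iterations
    res = np.empty(max(1, n_items), dtype=np.int64)
    orders = np.argsort(order_rng.random((n_iter, n_items)), axis=1).astype(np.int64)
    for i in range(n_iter):
        _epoch_kernel(
            raw, g, norms2, it_idx, it_val, it_nnz, it_norm, orders[i],
            schedule.alpha(i), schedule.radius(i, side), side, res,
        )
    final = NeuronGrid(
        side=side,
        values=(raw * g[:, None]).reshape(side, side, matrix.dimension),
        reservations={
            matrix.node_ids[i]: (int(res[i] % side), int(res[i] // side))
            for i in range(n_items)
        },
        component_keys=list(matrix.component_keys),
    )
    layout = Layout(positions=dict(final.reservations), side=side, tile=tile)
    assert len(set(layout.positions.values())) == n_items, "layout must be injective"
    return layout, final


def retrain(
    matrix: MembershipMatrix,
    grid: NeuronGrid,
    seed: int,
    iterations: int | None = None,
    c: float = WARM_START_C,
) -> tuple[Layout, NeuronGrid]:
    """Warm-start training from a previous grid (mental-map preservation).

    Starts the strength schedule at the low c = 0.01, and the radius
    schedule at N/4 rather than N, so an unchanged or mildly edited
    module keeps nodes close to where they were while the field adapts
    locally to the new component set.
    """
    sched = TrainingSchedule.for_items(len(matrix.node_ids), seed, c=c,
                                       iterations=iterations)
    sched = TrainingSchedule(
        c=sched.c, iterations=sched.iterations, seed=sched.seed,
        radius_start=max(2, grid.side // 4),
    )
    return train(matrix, sched, grid=grid)


def set_dominance(module: AnnotatedModule, set_id: str, weight: float) -> AnnotatedModule:
    """Return a module with one set's dominance weight w changed.

    The encoding reflects the new weight, so raising w pulls the set's
    members together in the layout; w = 0 removes the set's influence on
    distances entirely (network topology alone defines the layout).
    """
    return with_set_weight(module, set_id, weight)
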