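"""File formats, synthetic-module generation, and run orchestration.

Reads the standard text formats of the field — a TSV node table, SIF or
two-column TSV interactions, GMT gene-set memberships (long-format TSV
also accepted) and a TSV set-metadata table — into a validated
:class:`~examine.hypergraph.AnnotatedModule`, and writes them back.  A
seeded generator produces synthetic modules with the data characteristics
the layout targets: small sparse topology, annotation sets outnumbering
interactions, cardinalities from singletons to the whole module, and
tunable pairwise overlap.  :func:`run` composes encode -> train ->
contours -> render and emits a self-contained layout JSON plus the SVG.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape

from examine.contours import GeometryParams, SetContour, build_contours
from examine.hypergraph import (
    AnnotatedModule,
    AnnotationSet,
    Interaction,
    Node,
    build_module,
    encode,
    figure2_fixture,
)
from examine.render import Style, assign_colors, render_svg
from examine.rsom import (
    COLD_START_C,
    DEFAULT_GRID_CAP,
    Layout,
    TrainingSchedule,
    set_dominance,
    train,
)

__all__ = [
    "InputFormatError",
    "RunConfig",
    "read_inputs",
    "write_module",
    "generate_module",
    "run",
    "layout_from_doc",
    "module_from_doc",
    "contours_from_doc",
]

logger = logging.getLogger("examine")


class InputFormatError(ValueError):
    """Malformed input file; message carries file and line number."""


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_node_table(path: str | Path) -> list[Node]:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise InputFormatError(f"{path}: cannot parse as TSV ({exc})") from exc
    cols = list(df.columns)
    for required in ("id", "label", "score"):
        if required not in cols:
            raise InputFormatError(f"{path}:1: missing column {required!r}")
    nodes = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        try:
            score = float(row["score"]) if row["score"] != "" else 0.0
        except ValueError as exc:
            raise InputFormatError(
                f"{path}:{line}: invalid score {row['score']!r}"
            ) from exc
        url = row.get("url", "") if "url" in cols else ""
        nodes.append(
            Node(id=row["id"], label=row["label"], score=score, url=url or None)
        )
    return nodes


def _read_edges(path: str | Path) -> list[Interaction]:
    """SIF ("A interacts B [C ...]") or headerless 2-column TSV."""
    path = Path(path)
    is_sif = path.suffix.lower() == ".sif"
    edges: list[Interaction] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            stripped = raw.strip()
            if not stripped:
                continue
            fields = stripped.split("\t") if "\t" in stripped else stripped.split()
            if is_sif:
                if len(fields) == 1:
                    continue  # isolated node record, no edges
                if len(fields) < 3:
                    raise InputFormatError(
                        f"{path}:{lineno}: SIF line needs 'source relation "
                        f"target...', got {len(fields)} fields"
                    )
                src, targets = fields[0], fields[2:]
            else:
                if len(fields) != 2:
                    raise InputFormatError(
                        f"{path}:{lineno}: expected 2 tab-separated node ids, "
                        f"got {len(fields)} fields"
                    )
                src, targets = fields[0], [fields[1]]
            for tgt in targets:
                try:
                    edges.append(Interaction(src, tgt))
                except ValueError as exc:
                    raise InputFormatError(f"{path}:{lineno}: {exc}") from exc
    return edges


def _read_memberships(path: str | Path) -> list[tuple[str, str, list[str]]]:
    """GMT records (id, description, members) or long-format TSV pairs."""
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        records = []
        with open(path, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                stripped = raw.rstrip("\n")
                if not stripped.strip():
                    continue
                fields = stripped.split("\t")
                if len(fields) < 2:
                    raise InputFormatError(
                        f"{path}:{lineno}: GMT line needs at least id and "
                        f"description"
                    )
                members = [f for f in fields[2:] if f]
                if not members:
                    warnings.warn(
                        f"{path}:{lineno}: set {fields[0]!r} has no members",
                        stacklevel=2,
                    )
                records.append((fields[0], fields[1], members))
        return records
    # long format: set_id <tab> node_id
    order: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            stripped = raw.strip()
            if not stripped:
                continue
            fields = stripped.split("\t") if "\t" in stripped else stripped.split()
            if len(fields) != 2:
                raise InputFormatError(
                    f"{path}:{lineno}: expected 'set_id<TAB>node_id'"
                )
            order.setdefault(fields[0], []).append(fields[1])
    return [(sid, sid, members) for sid, members in order.items()]


def _read_set_meta(path: str | Path) -> dict[str, tuple[str, float, float]]:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001
        raise InputFormatError(f"{path}: cannot parse as TSV ({exc})") from exc
    for required in ("id", "category", "p_value"):
        if required not in df.columns:
            raise InputFormatError(f"{path}:1: missing column {required!r}")
    meta = {}
    for idx, row in df.iterrows():
        line = int(idx) + 2
        try:
            p = float(row["p_value"])
        except ValueError as exc:
            raise InputFormatError(
                f"{path}:{line}: invalid p_value {row['p_value']!r}"
            ) from exc
        weight = 1.0
        if "weight" in df.columns and row["weight"] != "":
            try:
                weight = float(row["weight"])
            except ValueError as exc:
                raise InputFormatError(
                    f"{path}:{line}: invalid weight {row['weight']!r}"
                ) from exc
        meta[row["id"]] = (row["category"] or "uncategorized", p, weight)
    return meta


def read_inputs(
    node_table: str | Path,
    edge_file: str | Path,
    gmt_file: str | Path,
    set_meta: str | Path | None = None,
    active: list[str] | None = None,
) -> AnnotatedModule:
    """Assemble a validated module from the four standard input files.

    Sets missing from the metadata table fall back to p-value 1 and
    category "uncategorized" (with a warning).  ``active`` defaults to
    all sets in file order.
    """
    nodes = _read_node_table(node_table)
    edges = _read_edges(edge_file)
    records = _read_memberships(gmt_file)
    meta = _read_set_meta(set_meta) if set_meta is not None else {}
    sets = []
    for sid, label, members in records:
        if sid in meta:
            category, p, weight = meta[sid]
        else:
            if set_meta is not None:
                warnings.warn(
                    f"set {sid!r} missing from {set_meta}; using p=1, "
                    f"category 'uncategorized'",
                    stacklevel=2,
                )
            category, p, weight = "uncategorized", 1.0, 1.0
        sets.append(
            AnnotationSet(
                id=sid, label=label, category=category, p_value=p,
                members=frozenset(members), weight=weight,
            )
        )
    return build_module(nodes, edges, sets, active=active)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_module(module: AnnotatedModule, prefix: str | Path) -> dict[str, Path]:
    """Write a module as ``<prefix>_{nodes.tsv,edges.sif,sets.gmt,set_meta.tsv}``.

    Inverse of :func:`read_inputs` (up to the active-set selection, which
    is a run parameter, not part of the files).
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "nodes": prefix.parent / f"{prefix.name}_nodes.tsv",
        "edges": prefix.parent / f"{prefix.name}_edges.sif",
        "sets": prefix.parent / f"{prefix.name}_sets.gmt",
        "set_meta": prefix.parent / f"{prefix.name}_set_meta.tsv",
    }
    with open(paths["nodes"], "w", encoding="utf-8") as fh:
        fh.write("id\tlabel\tscore\turl\n")
        for n in module.nodes:
            fh.write(f"{n.id}\t{n.label}\t{n.score!r}\t{n.url or ''}\n")
    with open(paths["edges"], "w", encoding="utf-8") as fh:
        for e in module.interactions:
            fh.write(f"{e.a}\tinteracts\t{e.b}\n")
    with open(paths["sets"], "w", encoding="utf-8") as fh:
        for s in module.sets:
            members = "\t".join(sorted(s.members))
            fh.write(f"{s.id}\t{s.label}" + (f"\t{members}" if members else "") + "\n")
    with open(paths["set_meta"], "w", encoding="utf-8") as fh:
        fh.write("id\tcategory\tp_value\tweight\n")
        for s in module.sets:
            fh.write(f"{s.id}\t{s.category}\t{s.p_value!r}\t{s.weight!r}\n")
    return paths


# ---------------------------------------------------------------------------
# synthetic modules
# ---------------------------------------------------------------------------

def generate_module(
    n_nodes: int = 17,
    n_edges: int = 20,
    n_sets: int = 25,
    seed: int = 0,
    overlap: float = 0.5,
    n_active: int = 3,
    out_prefix: str | Path | None = None,
) -> AnnotatedModule:
    """Seeded synthetic annotated module with realistic data shape.

    The interaction graph is a uniform random spanning tree plus extra
    random edges, so it is connected and sparse; the default 25 sets
    outnumber the default 20 interactions; set cardinalities are drawn
    uniformly from 1..n_nodes; members are sampled with a shared
    popularity bias so expected pairwise Jaccard overlap rises with
    ``overlap`` in [0, 1].  Enrichment p-values are log-uniform on
    [1e-8, 1e-2], expression scores standard normal, categories cycle
    through pathway/process/function, and the ``n_active`` most
    significant sets are active.  Fully reproducible from ``seed``;
    optionally writes the module files with :func:`write_module`.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if not (0.0 <= overlap <= 1.0):
        raise ValueError("overlap must lie in [0, 1]")
    max_edges = n_nodes * (n_nodes - 1) // 2
    min_edges = n_nodes - 1 if n_nodes > 1 else 0
    if not (min_edges <= n_edges <= max_edges):
        raise ValueError(
            f"n_edges={n_edges} infeasible for {n_nodes} connected nodes "
            f"(need {min_edges}..{max_edges})"
        )
    if n_sets < 0 or n_active < 0:
        raise ValueError("n_sets and n_active must be >= 0")
    n_active = min(n_active, n_sets)

    root = np.random.SeedSequence(seed)
    graph_ss, sets_ss, stats_ss = root.spawn(3)
    graph_rng = np.random.default_rng(graph_ss)
    sets_rng = np.random.default_rng(sets_ss)
    stats_rng = np.random.default_rng(stats_ss)

    ids = [f"g{i + 1:02d}" for i in range(n_nodes)]
    scores = stats_rng.standard_normal(n_nodes)
    nodes = [
        Node(id=ids[i], label=f"Gene{i + 1}", score=float(scores[i]))
        for i in range(n_nodes)
    ]

    edges: list[Interaction] = []
    if n_nodes > 1:
        tree = nx.random_labeled_tree(
            n_nodes, seed=int(graph_rng.integers(2**31 - 1))
        )
        pairs = {tuple(sorted(e)) for e in tree.edges()}
        while len(pairs) < n_edges:
            i, j = graph_rng.integers(0, n_nodes, size=2)
            if i != j:
                pairs.add(tuple(sorted((int(i), int(j)))))
        edges = [Interaction(ids[i], ids[j]) for i, j in sorted(pairs)]

    # popularity bias shared by all sets drives overlap
    perm = sets_rng.permutation(n_nodes)
    pop = np.empty(n_nodes)
    pop[perm] = 0.8 ** np.arange(n_nodes)
    pop = pop / pop.sum()
    weights = (1.0 - overlap) / n_nodes + overlap * pop

    categories = ["pathway", "process", "function"]
    p_values = 10.0 ** stats_rng.uniform(-8.0, -2.0, size=n_sets)
    sets = []
    for j in range(n_sets):
        size = int(sets_rng.integers(1, n_nodes + 1))
        # weighted sampling without replacement (Gumbel top-k)
        keys = np.log(weights) + sets_rng.gumbel(size=n_nodes)
        members = frozenset(ids[k] for k in np.argsort(-keys)[:size])
        sets.append(
            AnnotationSet(
                id=f"s{j + 1:02d}",
                label=f"Annotation {j + 1}",
                category=categories[j % len(categories)],
                p_value=float(p_values[j]),
                members=members,
            )
        )
    active = [s.id for s in sorted(sets, key=lambda s: (s.p_value, s.id))[:n_active]]
    module = build_module(nodes, edges, sets, active=active)
    if out_prefix is not None:
        write_module(module, out_prefix)
    return module


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything a layout run depends on besides the module files.

    The seed is mandatory and drives all randomness; geometry fields of
    ``None`` take the :class:`GeometryParams` defaults.  ``weights`` maps
    set ids to dominance weights; entries for inactive sets are ignored
    with a warning.
    """

    seed: int
    iterations: int | None = None
    c_cold: float = COLD_START_C
    c_warm: float = 0.01
    grid_cap: int = DEFAULT_GRID_CAP
    grid_mode: str = "side"
    tile: float = 1.0
    tau: float = 0.5
    r: float | None = None
    delta: float | None = None
    e: float | None = None
    quad_segs: int = 16
    palette: str = "set2"
    active: list[str] | None = None
    weights: dict[str, float] = field(default_factory=dict)

    def geometry(self) -> GeometryParams:
        return GeometryParams(
            tile=self.tile, tau=self.tau, r=self.r, delta=self.delta,
            e=self.e, quad_segs=self.quad_segs,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _geom_to_json(geom) -> dict:
    return geom_mapping(geom)


def run(module: AnnotatedModule, config: RunConfig) -> tuple[dict, str]:
    """Lay out, contour and render a module; returns (layout doc, SVG).

    The layout doc is a JSON-serializable dict holding the module, the
    node positions, per-set contour geometry with colors and z-order,
    and a provenance block (seed + full config + config hash) from which
    the identical run can be reproduced.  Stage timings and schedule
    parameters are logged, never embedded, so reruns are byte-identical.
    """
    if config.active is not None:
        module = build_module(module.nodes, module.interactions, module.sets,
                              active=list(config.active))
    for sid, w in sorted(config.weights.items()):
        if sid not in module.active:
            warnings.warn(
                f"dominance weight for inactive set {sid!r} ignored", stacklevel=2
            )
            continue
        module = set_dominance(module, sid, w)

    t0 = time.perf_counter()
    matrix = encode(module)
    n_items = len(matrix.node_ids)
    schedule = TrainingSchedule.for_items(
        n_items, config.seed, c=config.c_cold, iterations=config.iterations
    )
    logger.info(
        "training schedule: c=%g, I=%d, seed=%d", schedule.c,
        schedule.iterations, schedule.seed,
    )
    layout, grid = train(
        matrix, schedule, grid_cap=config.grid_cap, grid_mode=config.grid_mode,
        tile=config.tile,
    )
    t1 = time.perf_counter()
    logger.info("training: %.2fs (N=%d, M=%d)", t1 - t0, layout.side,
                matrix.dimension)
    params = config.geometry()
    contours = build_contours(module, grid, layout, params)
    t2 = time.perf_counter()
    logger.info("contours: %.2fs (%d sets)", t2 - t1, len(contours))

    style = Style(palette=tuple(assign_palette(config.palette)))
    colors = assign_colors(module.active, style)
    for c in contours:
        c.color = colors[c.set_id]

    doc = {
        "grid_side": layout.side,
        "tile": layout.tile,
        "positions": {nid: list(cell) for nid, cell in sorted(layout.positions.items())},
        "nodes": [
            {"id": n.id, "label": n.label, "score": n.score, "url": n.url}
            for n in module.nodes
        ],
        "interactions": [[e.a, e.b] for e in module.interactions],
        "sets": [
            {
                "id": s.id, "label": s.label, "category": s.category,
                "p_value": s.p_value, "weight": s.weight,
                "members": sorted(s.members), "active": s.id in module.active,
            }
            for s in module.sets
        ],
        "active": list(module.active),
        "contours": [
            {
                "set_id": c.set_id, "z": c.z, "color": c.color,
                "body": _geom_to_json(c.body),
                "eroded": _geom_to_json(c.eroded),
                "ribbon": _geom_to_json(c.ribbon),
            }
            for c in sorted(contours, key=lambda c: c.z)
        ],
        "provenance": {
            "seed": config.seed,
            "config": config.to_dict(),
            "config_hash": config.digest(),
        },
    }
    # render from the serialized doc so `render` from the JSON file is
    # guaranteed to reproduce the same bytes
    svg = render_svg(module_from_doc(doc), layout_from_doc(doc),
                     contours_from_doc(doc), style)
    t3 = time.perf_counter()
    logger.info("render: %.2fs", t3 - t2)
    return doc, svg


def assign_palette(name: str) -> list[str]:
    from examine.render import PALETTES

    if name not in PALETTES:
        raise ValueError(f"unknown palette {name!r}; choose from {sorted(PALETTES)}")
    return PALETTES[name]


def layout_from_doc(doc: dict) -> Layout:
    return Layout(
        positions={nid: tuple(cell) for nid, cell in doc["positions"].items()},
        side=int(doc["grid_side"]),
        tile=float(doc["tile"]),
    )


def module_from_doc(doc: dict) -> AnnotatedModule:
    nodes = [
        Node(id=n["id"], label=n["label"], score=n["score"], url=n.get("url"))
        for n in doc["nodes"]
    ]
    edges = [Interaction(a, b) for a, b in doc["interactions"]]
    sets = [
        AnnotationSet(
            id=s["id"], label=s["label"], category=s["category"],
            p_value=s["p_value"], members=frozenset(s["members"]),
            weight=s.get("weight", 1.0),
        )
        for s in doc["sets"]
    ]
    return build_module(nodes, edges, sets, active=list(doc["active"]))


def contours_from_doc(doc: dict) -> list[SetContour]:
    return [
        SetContour(
            set_id=c["set_id"],
            body=geom_shape(c["body"]),
            eroded=geom_shape(c["eroded"]),
            ribbon=geom_shape(c["ribbon"]),
            z=int(c["z"]),
            color=c.get("color"),
        )
        for c in doc["contours"]
    ]


def write_run(
    module: AnnotatedModule,
    config: RunConfig,
    out_json: str | Path,
    out_svg: str | Path | None = None,
) -> dict:
    """Run and write the layout JSON (and optionally the SVG)."""
    doc, svg = run(module, config)
    out_json = Path(out_json)
    out_json.parent.mkdir(parents=True, exist_ok=True)
    out_json.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n",
                        encoding="utf-8")
    if out_svg is not None:
        Path(out_svg).write_text(svg, encoding="utf-8")
    return doc


# packaged worked-example files -------------------------------------------

def fixture_files(out_prefix: str | Path) -> dict[str, Path]:
    """Write the six-gene worked-example module files to ``out_prefix``."""
    return write_module(figure2_fixture(), out_prefix)
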