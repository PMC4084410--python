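"""Data model for annotated modules and their bit-vector encoding.

An annotated module is a hypergraph: binary edges (pairwise interactions
between genes) and n-ary edges (annotation sets over the genes) on a common
node set.  Both kinds of edge are unified by encoding every node as a
membership vector with one component per interaction and one per *active*
annotation set; component ``i`` holds the component's weight ``w_i`` when
the node belongs to it and 0 otherwise.  These vectors are the training
items of the self-organizing-map layout (:mod:`examine.rsom`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Node",
    "Interaction",
    "AnnotationSet",
    "AnnotatedModule",
    "MembershipMatrix",
    "build_module",
    "encode",
    "figure2_fixture",
]


class ModuleValidationError(ValueError):
    """Raised when a module's parts violate referential integrity."""


@dataclass(frozen=True)
class Node:
    """A gene/protein in the module.

    ``score`` is a signed differential-expression statistic (negative =
    under-expressed, positive = over-expressed); ``url`` optionally links
    to an external information source.
    """

    id: str
    label: str = ""
    score: float = 0.0
    url: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModuleValidationError("node id must be non-empty")
        if not math.isfinite(self.score):
            raise ModuleValidationError(f"node {self.id!r}: score must be finite")
        if not self.label:
            object.__setattr__(self, "label", self.id)


@dataclass(frozen=True)
class Interaction:
    """An undirected interaction between two distinct nodes.

    Endpoints are stored sorted so that ``Interaction(a, b)`` and
    ``Interaction(b, a)`` compare equal.
    """

    a: str
    b: str

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ModuleValidationError(f"self-interaction on {self.a!r}")
        if self.b < self.a:
            a, b = self.a, self.b
            object.__setattr__(self, "a", b)
            object.__setattr__(self, "b", a)

    @property
    def endpoints(self) -> frozenset[str]:
        return frozenset((self.a, self.b))

    def key(self) -> tuple[str, str]:
        return (self.a, self.b)


@dataclass
class AnnotationSet:
    """An annotation set: members, grouping category, enrichment p-value.

    ``weight`` is the set-dominance weight w: raising it amplifies the
    set's influence on the layout distance, pulling members together.
    """

    id: str
    label: str = ""
    category: str = "uncategorized"
    p_value: float = 1.0
    members: frozenset[str] = field(default_factory=frozenset)
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.id:
            raise ModuleValidationError("set id must be non-empty")
        if not self.label:
            self.label = self.id
        if not (0.0 < self.p_value <= 1.0):
            raise ModuleValidationError(
                f"set {self.id!r}: p_value must lie in (0, 1], got {self.p_value}"
            )
        if not (self.weight >= 0.0 and math.isfinite(self.weight)):
            raise ModuleValidationError(
                f"set {self.id!r}: weight must be finite and >= 0"
            )
        self.members = frozenset(self.members)


@dataclass
class AnnotatedModule:
    """A validated annotated module: the hypergraph being laid out.

    ``nodes`` is the ordered item set; ``interactions`` and ``active``
    keep stable input order because they define the component order of
    the membership encoding.
    """

    nodes: list[Node]
    interactions: list[Interaction]
    sets: list[AnnotationSet]
    active: list[str]

    # -- lookups -------------------------------------------------------
    @property
    def node_ids(self) -> list[str]:
        return [n.id for n in self.nodes]

    def node(self, node_id: str) -> Node:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def get_set(self, set_id: str) -> AnnotationSet:
        for s in self.sets:
            if s.id == set_id:
                return s
        raise KeyError(set_id)

    @property
    def active_sets(self) -> list[AnnotationSet]:
        return [self.get_set(sid) for sid in self.active]

    def categories(self) -> list[str]:
        """Distinct set categories, in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.sets:
            seen.setdefault(s.category, None)
        return list(seen)

    def component_keys(self) -> list[tuple[str, str]]:
        """Stable identity of each encoding component.

        Interactions first (input order), then active sets (selection
        order).  Used to reconcile neuron grids across module edits
        (warm starts after a set is toggled).
        """
        keys = [("interaction", f"{e.a}\t{e.b}") for e in self.interactions]
        keys += [("set", sid) for sid in self.active]
        return keys


@dataclass
class MembershipMatrix:
    """Per-node membership vectors over interactions + active sets.

    ``values[k, i]`` is w_i if node k belongs to component i else 0.
    Interactions always carry weight 1; active sets carry their
    dominance weight.
    """

    node_ids: list[str]
    component_keys: list[tuple[str, str]]
    values: np.ndarray  # (|nodes|, M) float64
    weights: np.ndarray  # (M,) component weights w_i

    @property
    def dimension(self) -> int:
        return self.values.shape[1]

    def vector(self, node_id: str) -> np.ndarray:
        return self.values[self.node_ids.index(node_id)]


def build_module(
    nodes: list[Node],
    interactions: list[Interaction],
    sets: list[AnnotationSet],
    active: list[str] | None = None,
) -> AnnotatedModule:
    """Validate parts and assemble an :class:`AnnotatedModule`.

    Duplicate interactions are collapsed (keeping first occurrence);
    self-pairs are rejected by :class:`Interaction` itself.  Any
    interaction endpoint or set member absent from the node table is an
    error — modules are curated inputs, nodes are never created
    implicitly.

    Parameters
    ----------
    active
        Ordered selection of set ids to lay out.  Defaults to all sets
        in input order.
    """
    if not nodes:
        raise ModuleValidationError("module must contain at least one node")
    ids = [n.id for n in nodes]
    id_set = set(ids)
    if len(ids) != len(id_set):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ModuleValidationError(f"duplicate node ids: {dup}")

    deduped: list[Interaction] = []
    seen_pairs: set[tuple[str, str]] = set()
    for e in interactions:
        for end in (e.a, e.b):
            if end not in id_set:
                raise ModuleValidationError(
                    f"interaction {e.a!r}--{e.b!r} references unknown node {end!r}"
                )
        if e.key() not in seen_pairs:
            seen_pairs.add(e.key())
            deduped.append(e)

    set_ids = [s.id for s in sets]
    if len(set_ids) != len(set(set_ids)):
        dup = sorted({i for i in set_ids if set_ids.count(i) > 1})
        raise ModuleValidationError(f"duplicate set ids: {dup}")
    for s in sets:
        missing = s.members - id_set
        if missing:
            raise ModuleValidationError(
                f"set {s.id!r} references unknown node(s) {sorted(missing)}"
            )

    if active is None:
        active = list(set_ids)
    for sid in active:
        if sid not in set_ids:
            raise ModuleValidationError(f"active selection names unknown set {sid!r}")
    if len(active) != len(set(active)):
        raise ModuleValidationError("active selection contains duplicates")

    return AnnotatedModule(
        nodes=list(nodes), interactions=deduped, sets=list(sets), active=list(active)
    )


def encode(module: AnnotatedModule) -> MembershipMatrix:
    """Encode every node as a weighted membership bit vector.

    Component order is interactions in input order followed by active
    sets in selection order, so M = |interactions| + |active|.  Entry
    (k, i) equals the component's weight when node k is an endpoint of
    interaction i (first block) or a member of active set i (second
    block), and 0 otherwise.  Deterministic: repeated calls on the same
    module yield identical matrices.
    """
    ids = module.node_ids
    index = {nid: k for k, nid in enumerate(ids)}
    n_edges = len(module.interactions)
    act = module.active_sets
    m = n_edges + len(act)
    values = np.zeros((len(ids), m), dtype=np.float64)
    weights = np.ones(m, dtype=np.float64)

    for i, e in enumerate(module.interactions):
        values[index[e.a], i] = 1.0
        values[index[e.b], i] = 1.0
    for j, s in enumerate(act):
        weights[n_edges + j] = s.weight
        for nid in s.members:
            values[index[nid], n_edges + j] = s.weight

    return MembershipMatrix(
        node_ids=list(ids),
        component_keys=module.component_keys(),
        values=values,
        weights=weights,
    )


#: Synthetic p-values and expression scores for the worked six-gene
#: example: the source enumerates nodes, edges and pathway memberships
#: but no per-gene statistics, so these are illustrative placeholders.
_FIG2_SCORES = {
    "Calm1": -0.8,
    "Calm2": -1.2,
    "Calm3": -0.5,
    "Kras": 1.4,
    "Nr3c2": -2.1,
    "Plcb4": 1.9,
}
_FIG2_PVALUES = {"glioma": 1.0e-4, "ltp": 2.0e-4, "gnrh": 3.0e-4}


def figure2_fixture() -> AnnotatedModule:
    """The six-gene worked example module.

    Nodes v1..v6 = Calm1, Calm2, Calm3, Kras, Nr3c2, Plcb4; seven
    interactions S1..S7 and three KEGG pathway sets (Glioma, Long-term
    potentiation, GnRH signaling pathway), all three active.  Kras and
    Plcb4 have further interactions outside this subnetwork which are
    deliberately ignored.  Expression scores and enrichment p-values are
    synthetic placeholders (see module data files).
    """
    v = ["Calm1", "Calm2", "Calm3", "Kras", "Nr3c2", "Plcb4"]
    nodes = [Node(id=g, label=g, score=_FIG2_SCORES[g]) for g in v]
    # S1..S7, as (v_i, v_j) index pairs
    edge_pairs = [(1, 4), (1, 6), (2, 4), (2, 6), (3, 4), (3, 6), (4, 5)]
    interactions = [Interaction(v[i - 1], v[j - 1]) for i, j in edge_pairs]
    sets = [
        AnnotationSet(
            id="glioma",
            label="Glioma",
            category="pathway",
            p_value=_FIG2_PVALUES["glioma"],
            members=frozenset(v[k - 1] for k in (1, 2, 3, 4)),
        ),
        AnnotationSet(
            id="ltp",
            label="Long-term potentiation",
            category="pathway",
            p_value=_FIG2_PVALUES["ltp"],
            members=frozenset(v[k - 1] for k in (1, 2, 3, 4, 6)),
        ),
        AnnotationSet(
            id="gnrh",
            label="GnRH signaling pathway",
            category="pathway",
            p_value=_FIG2_PVALUES["gnrh"],
            members=frozenset(v[k - 1] for k in (1, 2, 3, 4, 6)),
        ),
    ]
    return build_module(nodes, interactions, sets, active=["glioma", "ltp", "gnrh"])


def with_set_weight(module: AnnotatedModule, set_id: str, weight: float) -> AnnotatedModule:
    """Return a copy of ``module`` with one set's dominance weight changed."""
    if weight < 0 or not math.isfinite(weight):
        raise ModuleValidationError("weight must be finite and >= 0")
    found = False
    new_sets = []
    for s in module.sets:
        if s.id == set_id:
            s = replace(s, members=s.members, weight=weight)
            found = True
        new_sets.append(s)
    if not found:
        raise KeyError(set_id)
    return AnnotatedModule(
        nodes=list(module.nodes),
        interactions=list(module.interactions),
        sets=new_sets,
        active=list(module.active),
    )
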