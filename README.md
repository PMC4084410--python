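# examine-layout

Unified layout and static rendering of **annotated network modules**:
small subnetworks of genes/proteins extracted by integrative network
analysis, together with the overlapping annotation sets (enriched
pathways, GO terms, …) that describe them.  The package lays out nodes,
interactions *and* annotation sets in one pass, draws the sets as nested
Euler-diagram-style contours on top of the node-link diagram, and emits a
deterministic SVG figure.  It is aimed at computational biologists who
have a module in hand (from heinz-style module extraction plus enrichment
analysis, or any other source) and want a faithful picture of how its
interactions and annotations interlock.

## Method

A module is a hypergraph: binary edges S_1…S_k (interactions) and n-ary
edges S_{k+1}…S_M (active annotation sets) over the node set V.  Every
node t ∈ V gets a membership vector **t** = (t_1, …, t_M) with
t_i = w_i if t ∈ S_i and 0 otherwise, where w_i is the set's dominance
weight (1 by default, always 1 for interactions).

The vectors are embedded on an N×N neuron grid (N = min(2|V|, 64)) by a
**reservation-based self-organizing map**: in each of I = ⌈10⁶/|V|⌉
epochs, items (in shuffled order) reserve the unreserved neuron
minimizing the metric cosine distance

    d(q, p) = arccos( q·p / (|q||p|) ) / π,

then train all neurons within Chebyshev radius r_i of the reserved cell
by q ← q + α_i (t − q), with linear annealing α_i = c·(1 − i/I),
r_i = ⌊(1 − i/I)·N⌋.  Reservations force an injective node → cell
layout; similar items "trickle outwards" instead of overlapping.

For each active set, the corresponding neuron components form a scalar
field; thresholding at τ·w_i (τ = ½, member cells force-included,
non-member cells force-excluded), corner tightening, morphological
smoothing (dilate r, erode 2r, dilate r), per-rank nesting erosion and
ribbon cutting (body minus its e-eroded copy) yield the drawn contours.
A node's cell center lies inside a set's contour **iff** the node
belongs to the set — guaranteed because all geometric radii are bounded
by a fraction of the tile size.  See `docs/methods.md` for the full
account.

## Worked example

The packaged six-gene module (Calm1, Calm2, Calm3, Kras, Nr3c2, Plcb4
with seven interactions and three KEGG pathway sets; the shipped
p-values/scores are illustrative placeholders):

```python
from examine import figure2_fixture, encode, cosine_distance
from examine.io import RunConfig, run

module = figure2_fixture()
matrix = encode(module)
print(matrix.vector("Nr3c2").astype(int).tolist())
print(matrix.vector("Plcb4").astype(int).tolist())
print(cosine_distance(matrix.vector("Nr3c2"), matrix.vector("Plcb4")))

doc, svg = run(module, RunConfig(seed=7, iterations=2000))
print(doc["grid_side"], doc["positions"]["Kras"])
```

prints

```
[0, 0, 0, 0, 0, 0, 1, 0, 0, 0]
[0, 1, 0, 1, 0, 1, 0, 0, 1, 1]
0.5
12 [6, 8]
```

Nr3c2 touches only the seventh interaction, Plcb4 is an endpoint of
interactions 2, 4 and 6 and a member of the last two pathway sets; the
two vectors are orthogonal, so their cosine distance is exactly ½.  The
run places the six genes injectively on a 12×12 grid and produces three
contours whose z-order is descending by area (`doc["contours"]`), plus
the rendered SVG.

## Command line

```sh
examine fixture  --out-prefix fig2                 # write the example files
examine layout   --nodes fig2_nodes.tsv --edges fig2_edges.sif \
                 --sets fig2_sets.gmt --set-meta fig2_set_meta.tsv \
                 --seed 7 --out fig2.json --svg fig2.svg
examine render   fig2.json --svg again.svg         # byte-identical re-render
examine simulate --seed 1 --out-prefix synth       # synthetic module files
```

Inputs: node table TSV (`id label score [url]`), interactions as SIF or
2-column TSV, memberships as GMT (or long-format TSV), set metadata TSV
(`id category p_value [weight]`).  The layout JSON is self-contained
(module, positions, contour polygons, colors, provenance with seed and
config hash), so rendering can be repeated without retraining.

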