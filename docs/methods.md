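# Methods

## Problem and model

An *annotated module* is the typical end product of integrative network
analysis: a small subnetwork of genes/proteins (nodes plus pairwise
interactions) together with a system of enriched annotation sets —
pathways, processes, functions — each with an overrepresentation p-value.
The data shape this package targets is characteristic: a small, sparse,
connected interaction graph (dozens of nodes and edges); annotation sets
that outnumber the interactions; set cardinalities ranging from a single
gene to the whole module; and frequent overlap between sets.

Such a module is a hypergraph with binary edges (interactions) and n-ary
edges (annotation sets).  Rather than laying out the network first and
painting set regions afterwards, both edge kinds enter the layout on
equal terms.  Every node t is encoded as a membership vector
t = (t_1, …, t_M) with one component per interaction and one per *active*
annotation set, in that order; t_i = w_i if the node belongs to component
i and 0 otherwise, where w_i is the component's dominance weight
(interactions always have w = 1).  Inactive sets contribute no
components, so toggling a set changes M.

## Reservation-based SOM layout

The membership vectors are embedded on an N×N neuron grid by a
self-organizing map with one modification: within every epoch each item
*reserves* the unreserved neuron nearest to it and later items ignore
reserved cells.  Similar items therefore trickle outwards into distinct
cells instead of collapsing onto one, and the final epoch's reservation
map is an injective node → cell layout.

- **Distance.** Metric cosine distance d(q, p) = arccos(q·p / (|q||p|)) / π,
  which behaves better than Euclidean norms in the high-dimensional,
  sparse membership space.  The normalized dot product is clamped to
  [−1, 1]; by convention d(0, 0) = 0 and d(0, p≠0) = 1 (zero vectors
  arise for isolated, unannotated nodes).
- **Schedules.** Strength α_i = c·(1 − i/I) and radius
  r_i = ⌊(1 − i/I)·N⌋ both decay linearly over I epochs.  Defaults:
  c = 0.5 for cold starts (the constant is otherwise unconstrained, so a
  mid-range value was fixed once), I = ⌈10⁶/|T|⌉, and the Chebyshev
  (square) neighborhood clipped at the grid border.  Updates are the
  convex rule q ← q + α(t − q), so every neuron component stays within
  [0, w_max] for the whole run.
- **Grid size.** "Twice the number of items" is read as the grid *side*,
  N = min(2|T|, 64); the cap keeps the annealing schedule meaningful for
  larger modules.  The frugal alternative reading (≈2|T| cells in total,
  N = ⌈√(2|T|)⌉) is available via `grid_mode="cells"`.
- **Ties and order.** The best-matching-unit search breaks distance ties
  toward the smaller row-major cell index, and items are processed in an
  RNG-shuffled order each epoch to avoid systematic order bias.  All
  randomness (grid initialization, shuffles) flows from one seed through
  spawned sub-streams, so runs are bit-for-bit reproducible and adding a
  pipeline stage never perturbs earlier draws.
- **Initialization.** Neuron component i is drawn uniformly on [0, u_i],
  where u_i is the maximum of component i over the items — the set
  weight w_i when the component has members, and 0 for an empty set.
  Initializing inside the data range (rather than on [0, w_i]
  unconditionally) makes an exact invariance hold: appending a
  member-less active set leaves every cosine distance, and therefore the
  layout, unchanged.  Each component draws from its own spawned
  sub-stream so appending component M+1 does not perturb components
  1..M.
- **Neighborhood membership.** Whether reserved neighbors should also be
  trained is an open choice; here *all* neurons within the radius are
  updated, which keeps the field smooth around crowded regions.

### Set dominance

Raising a set's weight w scales its component in every member's vector,
increasing its influence on the distance and pulling its members
together; w = 0 removes the set's influence entirely, leaving the
network topology to define the layout alone.  The contour threshold
scales with w (below) so dominant sets do not trivially flood the grid.

### Layout preservation (warm starts)

When the active selection changes, retraining starts from the previous
neuron configuration with a low strength c = 0.01 so the user's mental
map survives.  Components are matched across the edit by identity
(interaction endpoints / set id): surviving components keep their trained
neuron planes, new ones are freshly initialized, removed ones are
dropped.  One deviation from the plain schedule proved necessary: if the
radius also restarted at N, the accumulated grid-wide low-strength
updates would flatten the trained landscape over the run and the
"preserved" layout would drift as far as an independent cold start
(measured: mean displacement ≈ 10–21 cells on N = 34, versus ≈ 2 with
the fix).  Warm starts therefore restart the radius at N/4; the measured
mean displacement for an unchanged module is tracked as a regression
metric and bounded at 0.15·N in the tests.

## Contours

For active set S_i, the i-th component of every neuron is a scalar field
— a fuzzy membership landscape.  The drawn geometry is derived in five
steps:

1. **Threshold.** Tiles with field value ≥ τ·w_i (τ = 1/2) form the
   initial body.  The reserved cells of member nodes are force-included
   and those of non-member nodes force-excluded, turning "a node is
   inside the contour iff it belongs to the set" into a hard
   post-condition instead of a property of converged training.
2. **Tile union.** Cells become axis-aligned squares merged into
   (multi)polygons; area is exactly the cell count times tile².
3. **Tighten.** One corner-cutting pass replaces each convex right-angle
   staircase corner by its diagonal chord (legs at most one tile and at
   most half of each incident edge) unless the cut-off triangle overlaps
   a tile containing *any* placed item.  Item cell centers keep their
   in/out status and the area never grows.
4. **Smooth.** Morphological closing then opening: dilate r, erode 2r,
   dilate r, with discs of radius r = 0.15·tile (Minkowski sum and
   subtraction, implemented as round-joined buffers with 16 segments per
   quarter circle; the polygonal arc error stays within
   arc_tol = 10⁻³·tile²).
5. **Nest and ribbon.** Sets are ranked by descending body area (ties by
   input order; for truly nested sets the subset can never out-rank its
   superset).  The rank-k body is eroded by k·δ (δ = 0.05·tile) so
   outlines keep visible distance, and the painted ribbon is the body
   minus a copy eroded by the ribbon width e = 0.12·tile.

Because r + k·δ + e < tile/2, a cell center force-included in the tile
body can never be lost by the later erosions, and a force-excluded
center (≥ tile/2 from the body everywhere) can never be swallowed by the
closing (reach ≤ 2r < tile/2) — the containment contract holds by
construction and is re-verified at run time in both directions.  When
many sets are active, the nesting step δ is shrunk automatically so the
inequality keeps holding at depth; the alternative (a hard error) would
make deep selections unusable.  Whether tightening precedes smoothing is
not externally constrained; tighten-then-smooth is used.

## Rendering

The SVG shows a set overview pane (sets grouped by category, ascending
p-value, ties by id) and the network pane.  Painting order: opaque set
ribbons largest-first, white link halos, link curves (quadratic, control
point perpendicular at 10% of the segment, side fixed by endpoint-id
order), dashed contour outlines (so occluded sections can be inferred),
then node labels on white boxes whose border color encodes the
expression score (gray → green for negative, gray → red for positive,
saturating at |score| = 2).  Set colors cycle through a Color Brewer
qualitative palette in selection order; text and outlines are dark gray
(#404040) rather than black.  Significance circles scale with −log10(p),
clipped at a maximum radius, and carry the p-value's base-10 exponent as
text; exact sizing constants are free choices, only proportionality and
monotonicity are contractual.  Coordinates are emitted at fixed
3-decimal precision and nothing time- or machine-dependent is written,
so identical inputs produce byte-identical documents.

## Synthetic modules

The generator emulates the targeted data shape: a uniform random
spanning tree plus random extra edges (connected, sparse); 25 sets
against 20 interactions by default (sets outnumber interactions);
cardinalities uniform on 1..n; member sampling biased toward a shared,
geometrically decaying popularity ranking so the expected pairwise
Jaccard overlap rises monotonically with the `overlap` parameter in
[0, 1] (default 0.5); enrichment p-values log-uniform on [10⁻⁸, 10⁻²];
expression scores standard normal; the 3 most significant sets active by
default.  Everything derives from a single seed.

What the generator does *not* emulate: ontology structure among sets
(parent terms containing child terms other than by chance), degree
distributions of curated interactomes, and correlation between a gene's
expression score and its annotations.  Tests passing on synthetic
modules therefore validate the layout/geometry machinery, not biological
faithfulness of any particular figure.

The packaged six-gene worked example (Calm1, Calm2, Calm3, Kras, Nr3c2,
Plcb4; seven interactions; the Glioma, Long-term potentiation and GnRH
signaling pathway sets) ships with *synthetic placeholder* p-values and
expression scores — the source enumeration contains none — marked as
such in the data files' provenance.

## Problem sizes and numerical choices

Tests and the acceptance script train small modules (|T| ≤ 40) at
I = 2000 epochs, a converged setting for these sizes chosen to keep the
suites quick; the production default I = ⌈10⁶/|T|⌉ is exercised once in
the production-scale check (17 nodes, 20 edges, 25 sets, ≈59k epochs).
The training kernel stores neurons as a lazily-scaled product (a scalar
per cell times a sparse-updated vector) so the per-item cost scales with
the items' nonzeros instead of M; the scale is folded back before it can
underflow, and squared norms are maintained in closed form (clamped at
zero against rounding drift).  Geometry comparisons in tests use the
arc_tol area tolerance; degenerate inputs (empty bodies, single cells,
member-less sets) are exercised explicitly.

## Known limitations

- Layout quality degrades beyond roughly a hundred nodes or dozens of
  simultaneously active sets; the method is built for focused modules.
- Unnecessary link/contour crossings can occur; no global aesthetic
  optimization is attempted.
- Label boxes use deterministic approximate text metrics; very long
  labels can overlap at dense spots.
- Nesting order for partially overlapping (non-nested) sets is an
  area-rank heuristic.
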