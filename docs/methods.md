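# Methods

## Maps and their element subset

An interaction map is a set of drawn glyphs (elements) with types
(gene / mRNA / protein / other), planar coordinates, ontology
annotations, a set of reactions (hyperedges over elements with
reactant/product/modifier roles), and optional named annotation areas.
Clustering always operates on the ordered subset of gene, mRNA and
protein elements; this subset indexes every distance matrix.

The CellDesigner reader treats each *species alias* (a drawn glyph with
its own bounds) as one element by default, inheriting the species'
class and MIRIAM annotations. The layout distance is only meaningful
per glyph: a species drawn twice occupies two places. A `per_alias=False`
flag collapses to one element per species for files where the
alias-level view is not wanted; both counting modes are exposed because
published element totals do not disambiguate them. Coordinates are glyph
centers (x + w/2, y + h/2); any fixed convention works because min–max
normalization follows. Elements without layout are kept but excluded
from Euclidean computations. Annotation areas are not uniformly
machine-readable in CellDesigner files, so they are ingested from a
sidecar table (area name, member ids).

## Distance functions

**Euclidean.** Planar distance between glyph centers, in diagram units
(pixels). Rationale: curators draw related elements together, so layout
distance encodes expert knowledge.

**Network.** Each reaction is expanded into a clique over its
participants (roles and direction ignored), and the distance is the
unweighted shortest-path hop count. Every unconnected pair — including
isolated vertices — is set to twice the largest *finite* shortest path
observed anywhere in the graph, computed once globally, not per
component pair. An edgeless graph has no finite path; the constant must
then be supplied explicitly.

**Ontology.** Element similarity uses the Wang graph-based measure,
which needs only the ontology topology (no annotation corpus), with
semantic contribution weights 0.8 for `is_a` and 0.6 for `part_of`
edges, combined across the two term sets by the best-match average
(sum of row-wise and column-wise maxima of the term-pair similarity
matrix divided by their count). `max` and `avg` combinations are
available for sensitivity analyses. The distance is d = 1/(1+sim), so
annotated pairs lie in [0.5, 1]. Two deliberate conventions:

* the diagonal is forced to 0 (although 1/(1+1) = 0.5) so that medoid
  self-assignment is free — otherwise inertia semantics break;
* pairs with an unannotated member are imputed at the maximum (1.0),
  keeping all matrices on one complete label set rather than dropping
  elements.

**Normalization and combination.** Min–max over the off-diagonal maps a
matrix onto [0, 1] (diagonal kept at 0) or [−1, 1] (diagonal carried
through the same affine map). The paired-metric benchmark multiplies two
[−1, 1]-normalized matrices entrywise ("signed" mode). That construction
is order-pathological: two large dissimilarities (both ≈ +1) and two
small ones (both ≈ −1) both multiply to ≈ +1 — "far × far" and
"near × near" become indistinguishable. It is implemented as specified
because it is the benchmark, and an "unsigned" mode ([0, 1]
normalization, order-sane) is provided as the recommended alternative;
both are tested. After the product, the minimum is subtracted and the
diagonal re-zeroed so the result is a valid dissimilarity.

## Bi-level medoid model

Binary variables: x_jj = 1 if element j is a medoid, x_ij = 1 if i is
assigned to medoid j. The leader minimizes the bi-objective
(Σ_ij d¹_ij x_ij, Σ_j x_jj); the follower, with medoids fixed, minimizes
Σ_ij d²_ij x_ij subject to one owner per element and x_ij ≤ x_jj. The
follower's constraint matrix is totally unimodular, so the LP optimum is
integral and the problem separates per element: each element takes its
d²-nearest medoid. That separable argmin is the runtime solver; its
equivalence with an LP solve (and with full enumeration at tiny sizes)
is asserted in the test suite, never assumed. Ties between equidistant
medoids break to the lowest element index, making evaluation
deterministic. Swapping (d¹, d²) changes the game — the tests carry a
4×4 instance whose two fronts differ.

## Evolutionary optimization

NSGA-II over medoid bit-vectors: binary tournament on (non-domination
rank, crowding distance), single-point crossover at probability 0.8,
per-bit flip mutation at probability 1/N, elitist environmental
selection, and an exact follower solve inside every evaluation. An
all-zero genome is repaired by setting one uniformly random bit.
Initialization sets each bit with probability k₀/N with k₀ = √N by
default, seeding the population across the cluster-count range.
The algorithm keeps a best-ever archive per cluster count; the returned
front is the non-dominated staircase of that archive. Independent runs
(seeds spawned from the run seed) are merged by union, dropping
duplicates and dominated points. An optional stagnation window stops a
run early when the archive has not improved for W generations; the
generation cap is the default stopping rule.

Full-scale defaults mirror the experimental settings (population 100,
30000 generations, 30 independent runs). Desk-scale defaults —
population 40, 500 generations, 5 runs — are what the tests, examples
and the acceptance script use; at the synthetic sizes below the EA's
evaluation cache typically visits a large share of the genome space, so
results at k ≤ 3 coincide with exhaustive optima.

Post-processing may keep, per cluster count, the front solution with the
best F5 against the expert reference. This uses external information by
design and never feeds back into the optimization.

## Ward benchmark

Agglomerative clustering with the Lance–Williams recurrence and Ward
coefficients, applied to the supplied matrix as-is (entries treated as
squared-Euclidean-like), with deterministic smallest-pair-index
tie-breaking. Merge heights are the Lance–Williams values; for genuinely
squared-Euclidean input they equal twice the within-cluster
sum-of-squares increase, which is what the brute-force test oracle
recomputes from the raw matrix via the centroid identity. A
product-combined matrix is generally not Euclidean-embeddable; the
linkage is still computed (that is the benchmark), a warning is emitted
when the double-centered Gram matrix has a clearly negative eigenvalue
(checked up to n = 600), and height inversions are logged rather than
fatal. Cutting the dendrogram at k undoes the last k−1 merges; cuts are
nested across k.

## Evaluation

**F5.** For reference class c and cluster g with precision
P = |c∩g|/|g| and recall R = |c∩g|/|c|,
F_β = (1+β²)PR/(β²P+R), with β = 5 weighting recall 25-fold. Each class
takes its best-matching cluster, and scores are averaged weighted by
class size. Elements outside every class are ignored; overlapping
classes are tolerated by best-match. A symmetric per-cluster variant is
available behind a flag.

**Enrichment.** Per cluster, for each term present in it: the raw
p-value is the hypergeometric upper tail of drawing at least the
observed number of carriers in a sample of the cluster's size from the
whole-map background. Benjamini–Hochberg adjustment is applied within
each cluster separately (global adjustment available as an option). No
minimum cluster size or term frequency is imposed by default; flags
exist. The discovery summary is the number of unique terms enriched at a
cutoff (0.05 / 0.01 / 0.001) across all clusters. Disease-ontology
style annotation tables run through the same machinery; annotation
propagation to ancestors is available as an option and off by default.

## Synthetic maps

The generator plants G groups (default 3 × 20 elements) and emits the
three signals the metrics read:

* coordinates: Gaussian blobs (σ = 50 px) around grid centers separated
  by 1000 px — a 20:1 separation-to-spread ratio, well clear of overlap;
* reactions: 1.5 reactions per element at arity 3 (after clique
  expansion, a within-group density similar to a curated map's giant
  component), drawn within a single group with probability 0.9 and
  across groups otherwise;
* annotations: a tree ontology with one characteristic branch of 3 leaf
  terms per group; each element draws 2 terms, each from its own group's
  branch with probability 0.9 (the annotation fidelity) and from another
  group's branch otherwise.

Two terms per element make a completely misannotated element rare
(≈ 1%), which is what keeps the ontology metric individually informative
at 0.9 fidelity — a scientist's "noisy but usable" annotation regime.
`conflict_mode` decouples chosen signals from the planted groups
(`spatial_only`, `network_only`, `shuffled`), giving controlled
analogues of metric disagreement. The planted groups double as the
expert annotation areas and as the ground truth.

What the generator does **not** emulate: realistic glyph geometry,
compartment structure, literature-like annotation sparsity (real maps
have many unannotated elements), heavy-tailed degree distributions, or
ontology DAG complexity (the synthetic ontology is a tree by default; a
`dag_twist` flag adds cross-links for property tests). Passing tests on
synthetic maps therefore demonstrate algorithmic correctness and signal
separation, not performance on real curated maps.

`reorganize` emulates curatorial rearrangement: a fraction of elements
is duplicated (fresh ids, inherited annotations, joining their
originals' reactions, placed with a small jitter), within-area layout is
contracted toward the area centroid, and reactions whose participant
sets become exact duplicates are removed.

## Numerical choices and degenerate inputs

* Distance matrices are validated for symmetry, zero diagonal and
  finiteness on construction; dominance and staircase comparisons use an
  absolute tolerance of 1e-12.
* Min–max normalization of a constant matrix is an error.
* Follower assignment with an all-zero genome is an error (repair
  first); the repair is idempotent.
* All randomness flows through seeded `numpy` generators; identical
  seeds give bit-identical fronts and byte-identical generated maps.

## Problem sizes used by the tests and the acceptance script

The test suite and `scripts/acceptance.py` run at desk scale, chosen as
the smallest sizes at which every property is non-trivially exercised:
60-element synthetic maps (3 × 20), EA populations of 20–40 with
200–500 generations and 2–3 independent runs, follower and Ward oracles
at N ≤ 10, and enrichment backgrounds ≤ 50. The full-scale configuration
(population 100, 30000 generations, 30 runs) is available through
`EAConfig()` defaults and the CLI `--paper-scale` switch.

## Known limitations

* The signed product combination is kept for benchmark fidelity despite
  its order pathology; prefer unsigned for new analyses.
* Ward on combined matrices may produce height inversions (logged).
* The exact semantic-similarity variant and term-set combination used
  with real GO releases are configuration, not fixed facts; results on
  real maps will depend on the ontology release and annotation source.
* A Resnik (most-informative-common-ancestor) similarity is available
  behind `measure="resnik"` for sensitivity runs, but it requires
  user-supplied per-term information content — no corpus estimation is
  provided.
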