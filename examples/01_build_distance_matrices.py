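"""Build the three distance matrices over a synthetic disease map.

Generates a small map with three planted functional areas, selects its
gene/mRNA/protein elements, and constructs the layout (Euclidean),
interaction-network (shortest path) and ontology (Wang semantic)
dissimilarity matrices that every clustering method in the package
consumes.
"""

from mapclust import (
    clique_expand,
    euclidean_matrix,
    network_matrix,
    ontology_matrix,
    select_entities,
)
from mapclust.synthetic import SyntheticConfig, generate

imap, truth, ontology = generate(SyntheticConfig(rng_seed=1))
subset = select_entities(imap, {"gene", "mRNA", "protein"})
print(f"map: {len(imap.elements)} elements, {len(imap.reactions)} reactions, "
      f"{len(imap.areas)} annotation areas; clustering {len(subset)} entities")

matrices = {
    "euclidean (px)": euclidean_matrix(imap, subset),
    "network (hops)": network_matrix(clique_expand(imap, subset), labels=subset),
    "ontology (1/(1+sim))": ontology_matrix(subset, ontology),
}
for name, m in matrices.items():
    off = m.offdiag()
    print(f"{name:22s} min {off.min():8.3f}  mean {off.mean():8.3f}  "
          f"max {off.max():8.3f}")

# The three scales are incomparable (pixels, hops, a bounded score in
# [0.5, 1]); min-max normalization puts them on a common footing before
# any combination — see the clustering examples.
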