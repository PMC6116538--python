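"""Pairwise dissimilarity matrices over a map's element subset.

Three constructions reflect three readings of a curated map:

* ``euclidean_matrix`` — planar distance between glyph centers; the
  curator places related elements close together, so layout encodes
  expert knowledge.
* ``network_matrix`` — unweighted shortest-path hop counts on the
  clique-expanded reaction graph; unconnected pairs are set to twice the
  largest finite shortest path observed anywhere in the graph.
* ``ontology_matrix`` — d = 1 / (1 + similarity) with Wang/BMA semantic
  similarity between the elements' ontology annotations.

``normalize`` min–max maps matrices to [0, 1] or [−1, 1] and
``combine_product`` forms the entrywise product used by the hierarchical
benchmark on paired metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .map_model import InteractionMap
from .ontology import OntologyAnnotation, element_similarity

logger = logging.getLogger(__name__)

METRICS = ("euclidean", "network", "ontology", "combined")
NORMALIZATIONS = ("raw", "unit_interval", "signed_unit_interval")


@dataclass
class DistanceMatrix:
    """A labeled, symmetric, zero-diagonal dissimilarity matrix."""

    labels: list[str]
    values: np.ndarray
    metric: str
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.labels)
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric tag: {self.metric!r}")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization tag: {self.normalization!r}")
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains non-finite entries")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if self.normalization != "signed_unit_interval":
            # signed matrices carry the affine image of 0 on the diagonal
            if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
                raise ValueError("matrix diagonal is not zero")
            if np.any(self.values < -1e-12):
                raise ValueError("matrix has negative entries")

    @property
    def n(self) -> int:
        return len(self.labels)

    def offdiag(self) -> np.ndarray:
        """Off-diagonal entries (condensed upper triangle)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", index_label="element_id"
        )

    @classmethod
    def from_tsv(cls, path: str | Path, metric: str = "combined",
                 normalization: str = "raw") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=list(df.columns), values=df.to_numpy(dtype=float),
                   metric=metric, normalization=normalization)


def euclidean_matrix(imap: InteractionMap, subset: Sequence[str]) -> DistanceMatrix:
    """Planar Euclidean distances between glyph centers, in diagram units."""
    by_id = {e.element_id: e for e in imap.elements}
    missing = [eid for eid in subset if eid not in by_id]
    if missing:
        raise ValueError(f"subset contains unknown elements: {missing}")
    no_coords = [eid for eid in subset if not by_id[eid].has_coordinates]
    if no_coords:
        raise ValueError(f"elements lack layout coordinates: {no_coords}")
    pts = np.array([[by_id[eid].x, by_id[eid].y] for eid in subset], dtype=float)
    diff = pts[:, None, :] - pts[None, :, :]
    values = np.sqrt((diff**2).sum(axis=2))
    return DistanceMatrix(labels=list(subset), values=values, metric="euclidean")


def network_matrix(
    graph: nx.Graph,
    labels: Sequence[str] | None = None,
    disconnected_fallback: float | None = None,
) -> DistanceMatrix:
    """Shortest-path hop counts; unconnected pairs get 2 x max finite path.

    The unconnected-pair constant is computed once over the whole graph
    (the largest finite shortest path between any two vertices), not per
    component pair.  A graph with no edges has no finite path and raises
    unless ``disconnected_fallback`` supplies the constant directly.
    """
    if labels is None:
        labels = list(graph.nodes)
    labels = list(labels)
    n = len(labels)
    idx = {eid: i for i, eid in enumerate(labels)}
    values = np.full((n, n), np.inf)
    np.fill_diagonal(values, 0.0)
    max_finite = 0.0
    for src, dists in nx.all_pairs_shortest_path_length(graph):
        if src not in idx:
            continue
        i = idx[src]
        for dst, d in dists.items():
            if dst in idx:
                values[i, idx[dst]] = float(d)
                if d > max_finite:
                    max_finite = float(d)
    unconnected = ~np.isfinite(values)
    if unconnected.any():
        if max_finite > 0:
            fill = 2.0 * max_finite
        elif disconnected_fallback is not None:
            fill = float(disconnected_fallback)
        else:
            raise ValueError(
                "graph has no edges: max finite shortest path undefined "
                "(pass disconnected_fallback)"
            )
        values[unconnected] = fill
    return DistanceMatrix(labels=labels, values=values, metric="network")


def ontology_matrix(
    subset: Sequence[str],
    ann: OntologyAnnotation,
    combine: str = "bma",
    measure: str = "wang",
) -> DistanceMatrix:
    """Semantic dissimilarity d = 1/(1 + similarity) per element pair.

    Pairs with an unannotated member are imputed at the matrix maximum
    (1.0, the value of zero similarity) so every matrix shares one label
    set.  The diagonal is forced to 0 — self-dissimilarity 1/(1+1) = 0.5
    would charge medoids for owning themselves and break inertia
    semantics (a deliberate deviation, logged).
    """
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    annotated = [eid for eid in subset if ann.terms_of(eid)]
    if not annotated:
        raise ValueError("no element in the subset has ontology annotations")
    unannotated = set(subset) - set(annotated)
    if unannotated:
        logger.warning(
            "%d unannotated element(s); their pairwise distances are imputed "
            "at 1.0: %s", len(unannotated), sorted(unannotated)[:10],
        )
    n = len(subset)
    values = np.full((n, n), 1.0)
    ann_idx = [i for i, eid in enumerate(subset) if eid in set(annotated)]
    for a_pos, i in enumerate(ann_idx):
        for j in ann_idx[a_pos + 1 :]:
            sim = element_similarity(subset[i], subset[j], ann,
                                     combine=combine, measure=measure)
            values[i, j] = values[j, i] = 1.0 / (1.0 + sim)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(labels=subset, values=values, metric="ontology")


def normalize(m: DistanceMatrix, target: str = "unit_interval") -> DistanceMatrix:
    """Affine min–max map of the off-diagonal entries onto [0,1] or [−1,1].

    For ``unit_interval`` the diagonal stays 0; for ``signed_unit_interval``
    the diagonal is carried through the same affine map (so a zero diagonal
    maps to the image of 0 — the convention used by the signed product
    combination).
    """
    if target not in ("unit_interval", "signed_unit_interval"):
        raise ValueError(f"unknown normalization target: {target!r}")
    off = m.offdiag()
    lo, hi = float(off.min()), float(off.max())
    if hi <= lo:
        raise ValueError("cannot normalize a constant matrix")
    if target == "unit_interval":
        values = (m.values - lo) / (hi - lo)
        np.fill_diagonal(values, 0.0)
    else:
        values = 2.0 * (m.values - lo) / (hi - lo) - 1.0
    out = replace(m, values=values, normalization=target)
    return out


def combine_product(
    m1: DistanceMatrix, m2: DistanceMatrix, mode: str = "signed"
) -> DistanceMatrix:
    """Entrywise product of two min–max-normalized matrices.

    ``signed`` normalizes both factors to [−1, 1] before multiplying (the
    benchmark construction); ``unsigned`` uses [0, 1], which preserves the
    ordering sanity that two large dissimilarities never multiply into a
    small one.  The product is shifted to be nonnegative (minimum
    subtracted) and the diagonal re-zeroed so the result is a valid
    dissimilarity.
    """
    if m1.labels != m2.labels:
        raise ValueError("matrices have different labels/ordering")
    if mode == "signed":
        target = "signed_unit_interval"
    elif mode == "unsigned":
        target = "unit_interval"
    else:
        raise ValueError(f"unknown combination mode: {mode!r}")
    n1 = m1 if m1.normalization == target else normalize(m1, target)
    n2 = m2 if m2.normalization == target else normalize(m2, target)
    prod = n1.values * n2.values
    iu = np.triu_indices(len(m1.labels), k=1)
    shift = float(prod[iu].min())
    values = prod - min(shift, 0.0)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(
        labels=list(m1.labels), values=values, metric="combined",
        normalization="raw",
    )
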