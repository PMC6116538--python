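"""Agglomerative hierarchical clustering with Ward's criterion (HCW).

The benchmark clustering: Ward linkage run directly on a supplied
dissimilarity matrix — a single metric or the entrywise product of two
normalized metrics.  The Lance–Williams recurrence with the Ward
coefficients

    alpha_i = (n_i + n_k) / (n_i + n_j + n_k),
    beta    = -n_k / (n_i + n_j + n_k),  gamma = 0

is applied to the matrix as given, treating its entries as
squared-Euclidean-like.  A product-combined matrix is generally not a
Euclidean squared distance; the linkage is still computed (that is the
benchmark's construction) but a warning is emitted when the input is
detectably non-Euclidean, and height inversions are logged rather than
fatal.  Ties are broken deterministically by the smallest pair index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .distances import DistanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class Clustering:
    """A flat partition: contiguous cluster ids 0..k-1 over the subset."""

    element_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.element_ids):
            raise ValueError("labels length does not match element ids")
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("cluster ids must be contiguous 0..k-1")

    @property
    def k(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def members(self, cluster_id: int) -> list[str]:
        return [e for e, c in zip(self.element_ids, self.labels) if c == cluster_id]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"element_id": self.element_ids, "cluster_id": self.labels}
        ).to_csv(path, sep="\t", index=False)


def relabel_contiguous(raw_labels: Sequence[int], element_ids: Sequence[str]) -> Clustering:
    """Build a Clustering from arbitrary ids, renumbered by first occurrence."""
    mapping: dict[int, int] = {}
    labels = np.empty(len(raw_labels), dtype=int)
    for i, lab in enumerate(raw_labels):
        labels[i] = mapping.setdefault(lab, len(mapping))
    return Clustering(element_ids=list(element_ids), labels=labels)


@dataclass
class Dendrogram:
    """Merge list: (left id, right id, height, merged size) per step.

    Original elements are ids 0..N-1; the cluster formed at step s gets
    id N+s (the scipy convention).
    """

    element_ids: list[str]
    merges: list[tuple[int, int, float, int]]

    @property
    def n(self) -> int:
        return len(self.element_ids)

    def to_json(self, path: str | Path) -> None:
        import json

        Path(path).write_text(
            json.dumps({"element_ids": self.element_ids, "merges": self.merges}, indent=1)
        )


def _is_detectably_non_euclidean(values: np.ndarray) -> bool:
    """Check whether entries, read as squared distances, embed in Euclidean
    space: the double-centered Gram matrix must be PSD."""
    n = len(values)
    if n > 600:  # O(n^3) check not worth it on large inputs
        return False
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ values @ j
    lo = scipy.linalg.eigh(gram, eigvals_only=True, subset_by_index=[0, 0])[0]
    scale = max(1.0, float(np.abs(values).max()))
    return lo < -1e-8 * scale


def ward_linkage(m: DistanceMatrix, check_euclidean: bool = True) -> Dendrogram:
    """Lance–Williams Ward agglomeration on the supplied dissimilarity."""
    m.validate()
    n = m.n
    if n < 2:
        raise ValueError("need at least two elements to cluster")
    if check_euclidean and m.metric == "combined" and _is_detectably_non_euclidean(m.values):
        logger.warning(
            "combined matrix is not embeddable as squared Euclidean distances; "
            "Ward heights may show inversions"
        )
    D = m.values.astype(float).copy()
    np.fill_diagonal(D, np.inf)
    sizes = np.ones(n)
    cluster_id = np.arange(n)
    active = np.ones(n, dtype=bool)
    merges: list[tuple[int, int, float, int]] = []
    last_height = -np.inf
    for step in range(n - 1):
        # row-major scan of the upper triangle -> smallest-pair-index ties
        masked = np.where(active[:, None] & active[None, :], D, np.inf)
        masked[np.tril_indices(n)] = np.inf
        flat = int(np.argmin(masked))
        a, b = divmod(flat, n)
        height = float(masked[a, b])
        if height < last_height - 1e-12:
            logger.warning(
                "Ward height inversion at step %d: %.6g after %.6g",
                step, height, last_height,
            )
        last_height = max(last_height, height)
        na, nb = sizes[a], sizes[b]
        others = active.copy()
        others[[a, b]] = False
        nk = sizes[others]
        total = na + nb + nk
        D_new = ((na + nk) * D[a, others] + (nb + nk) * D[b, others]
                 - nk * height) / total
        D[a, others] = D_new
        D[others, a] = D_new
        active[b] = False
        left, right = sorted((int(cluster_id[a]), int(cluster_id[b])))
        merges.append((left, right, height, int(na + nb)))
        sizes[a] = na + nb
        cluster_id[a] = n + step
    return Dendrogram(element_ids=list(m.labels), merges=merges)


def cut(dendrogram: Dendrogram, k: int) -> Clustering:
    """The k-cluster partition obtained by undoing the last k-1 merges."""
    n = dendrogram.n
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step, (left, right, _, _) in enumerate(dendrogram.merges[: n - k]):
        new_id = n + step
        parent[find(left)] = new_id
        parent[find(right)] = new_id
    roots = [find(i) for i in range(n)]
    return relabel_contiguous(roots, dendrogram.element_ids)


def hcw_sweep(
    m: DistanceMatrix, k_range: Sequence[int], check_euclidean: bool = True
) -> dict[int, Clustering]:
    """One linkage computation, cut at every requested cluster count."""
    dend = ward_linkage(m, check_euclidean=check_euclidean)
    return {k: cut(dend, k) for k in k_range}
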