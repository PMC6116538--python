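"""Clustering evaluation: expert F-measure and enrichment-based discovery.

*Expert-based*: the F-measure with beta = 5 (recall weighted 25-fold)
against the curators' annotation areas.  For each reference class the
best-matching cluster's F_beta is taken and the scores are averaged
weighted by class size; elements in no reference class are ignored.
Classes may overlap — best-match tolerates it.

*Discovery-based*: per-cluster hypergeometric over-representation tests
of ontology terms against the whole-map background, Benjamini–Hochberg
adjusted within each cluster; the number of unique terms enriched at a
cutoff across all clusters measures how much structure a clustering
surfaces beyond the expert annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .hierarchical import Clustering


@dataclass
class ReferenceClasses:
    """Named expert classes (annotation areas) restricted to the clustered subset."""

    classes: list[tuple[str, set[str]]]

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("reference must contain at least one class")
        for name, members in self.classes:
            if not members:
                raise ValueError(f"reference class {name!r} is empty")

    @classmethod
    def from_areas(cls, areas, subset: Sequence[str]) -> "ReferenceClasses":
        subset_set = set(subset)
        classes = []
        for area in areas:
            members = area.member_ids & subset_set
            if members:
                classes.append((area.area_name, members))
        return cls(classes=classes)

    @classmethod
    def from_truth(cls, truth: Mapping[str, str], subset: Sequence[str]) -> "ReferenceClasses":
        """Reference classes from an element -> group-label table."""
        subset_set = set(subset)
        by_group: dict[str, set[str]] = {}
        for eid, group in truth.items():
            if eid in subset_set:
                by_group.setdefault(str(group), set()).add(eid)
        return cls(classes=sorted(by_group.items()))


def _pair_f_beta(intersection: int, cluster_size: int, class_size: int,
                 beta2: float) -> float:
    if intersection == 0:
        return 0.0
    p = intersection / cluster_size
    r = intersection / class_size
    return (1.0 + beta2) * p * r / (beta2 * p + r)


def f_beta(
    labels: Sequence[int],
    element_ids: Sequence[str],
    ref: ReferenceClasses,
    beta: float = 5.0,
    variant: str = "per_class",
) -> float:
    """Class-size-weighted best-match F_beta of a clustering against the
    reference; ``variant="per_cluster"`` scores the symmetric direction
    (each cluster matched to its best class, weighted by cluster size)."""
    labels = np.asarray(labels)
    beta2 = beta * beta
    clusters: dict[int, set[str]] = {}
    for eid, lab in zip(element_ids, labels):
        clusters.setdefault(int(lab), set()).add(eid)
    if variant == "per_class":
        total = sum(len(members) for _, members in ref.classes)
        score = 0.0
        for _, members in ref.classes:
            best = max(
                _pair_f_beta(len(members & g), len(g), len(members), beta2)
                for g in clusters.values()
            )
            score += len(members) / total * best
        return score
    if variant == "per_cluster":
        total = sum(len(g) for g in clusters.values())
        score = 0.0
        for g in clusters.values():
            best = max(
                _pair_f_beta(len(members & g), len(g), len(members), beta2)
                for _, members in ref.classes
            )
            score += len(g) / total * best
        return score
    raise ValueError(f"unknown F-measure variant: {variant!r}")


def f_beta_of(clustering: Clustering, ref: ReferenceClasses, beta: float = 5.0,
              variant: str = "per_class") -> float:
    return f_beta(clustering.labels, clustering.element_ids, ref, beta=beta,
                  variant=variant)


@dataclass
class EnrichmentRecord:
    cluster_id: int
    term_id: str
    a: int                      # annotated elements inside the cluster
    cluster_size: int
    background_annotated: int
    background_size: int
    p_raw: float
    p_adj: float = 1.0
    enriched: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.a <= min(self.cluster_size, self.background_annotated):
            raise ValueError("inconsistent enrichment counts")


def enrich(
    clustering: Clustering,
    term_map: Mapping[str, set[str]],
    background: Sequence[str],
    alpha: float = 0.05,
    adjust_scope: str = "per_cluster",
    min_cluster_size: int = 0,
    min_term_count: int = 0,
    propagate: "object | None" = None,
) -> list[EnrichmentRecord]:
    """Hypergeometric over-representation of terms per cluster.

    For a cluster of size n drawn from a background of size M in which K
    elements carry term T, the raw p-value is the upper-tail probability
    of seeing >= a carriers in the cluster.  Adjustment is
    Benjamini–Hochberg across the terms of each cluster separately
    (``adjust_scope="global"`` adjusts across all clusters instead).
    ``propagate`` may be an :class:`~mapclust.ontology.OntologyAnnotation`;
    annotations are then propagated to ancestor terms first.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    background = list(background)
    bg_set = set(background)
    clustered = set(clustering.element_ids)
    if not clustered <= bg_set:
        raise ValueError("background must contain every clustered element")

    if propagate is not None:
        term_map = {
            e: {anc for t in terms if t in propagate.dag
                for anc in propagate._svalues(t)}
            for e, terms in term_map.items()
        }

    M = len(background)
    bg_term_count: dict[str, int] = {}
    for eid in background:
        for t in term_map.get(eid, ()):  # noqa: B905
            bg_term_count[t] = bg_term_count.get(t, 0) + 1

    records: list[EnrichmentRecord] = []
    for cid in range(clustering.k):
        members = clustering.members(cid)
        n = len(members)
        if n < min_cluster_size:
            continue
        counts: dict[str, int] = {}
        for eid in members:
            for t in term_map.get(eid, ()):
                counts[t] = counts.get(t, 0) + 1
        cluster_records = []
        for t in sorted(counts):
            a = counts[t]
            K = bg_term_count[t]
            if K < min_term_count:
                continue
            p_raw = float(hypergeom.sf(a - 1, M, K, n))
            cluster_records.append(
                EnrichmentRecord(
                    cluster_id=cid, term_id=t, a=a, cluster_size=n,
                    background_annotated=K, background_size=M,
                    p_raw=min(p_raw, 1.0),
                )
            )
        if adjust_scope == "per_cluster" and cluster_records:
            _bh(cluster_records, alpha)
        records.extend(cluster_records)
    if adjust_scope == "global" and records:
        _bh(records, alpha)
    elif adjust_scope not in ("per_cluster", "global"):
        raise ValueError(f"unknown adjust scope: {adjust_scope!r}")
    return records


def _bh(records: list[EnrichmentRecord], alpha: float) -> None:
    pvals = [r.p_raw for r in records]
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    for r, pa, rej in zip(records, p_adj, reject):
        r.p_adj = float(max(pa, r.p_raw))
        r.enriched = bool(rej)


def count_unique_terms(records: Sequence[EnrichmentRecord], alpha: float) -> int:
    """Number of distinct terms enriched (p_adj <= alpha) in any cluster."""
    return len({r.term_id for r in records if r.p_adj <= alpha})


def records_to_tsv(records: Sequence[EnrichmentRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "cluster_id": r.cluster_id, "term_id": r.term_id, "a": r.a,
                "cluster_size": r.cluster_size,
                "background_annotated": r.background_annotated,
                "background_size": r.background_size,
                "p_raw": r.p_raw, "p_adj": r.p_adj, "enriched": r.enriched,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def evaluate_solution_set(
    solutions: Mapping[int, Clustering],
    ref: ReferenceClasses | None,
    term_maps: Mapping[str, Mapping[str, set[str]]],
    alphas: Sequence[float],
    background: Sequence[str],
    method: str = "",
    metric_pair: str = "",
    beta: float = 5.0,
) -> pd.DataFrame:
    """Tidy per-solution table: F5 plus unique enriched-term counts per
    ontology and cutoff — the raw material of method-ranking comparisons
    (methods ranked by F-measure summed over their solutions)."""
    rows = []
    for k in sorted(solutions):
        clu = solutions[k]
        row: dict[str, object] = {
            "method": method, "metric_pair": metric_pair, "k": k,
            "f5": f_beta_of(clu, ref, beta=beta) if ref is not None else np.nan,
        }
        for name, tmap in term_maps.items():
            recs = enrich(clu, tmap, background, alpha=max(alphas))
            for alpha in alphas:
                row[f"unique_{name}_terms_p{alpha:g}"] = count_unique_terms(recs, alpha)
        rows.append(row)
    return pd.DataFrame(rows)
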