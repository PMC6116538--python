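"""Ontology handling and semantic similarity between annotated elements.

Elements of a map carry ontology term annotations (Gene Ontology or
Disease Ontology).  Pairwise element similarity is computed with the
Wang graph-based measure over the term DAG — the measure needs no
annotation corpus, only the ontology topology, which keeps it fully
reproducible.  Term-set similarities are combined with the best-match
average (BMA); ``max`` and ``avg`` combinations are available for
sensitivity analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

#: Wang semantic-contribution weight per edge type.
DEFAULT_EDGE_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


@dataclass
class OntologyAnnotation:
    """An ontology DAG plus an element -> term-set annotation table.

    ``dag`` is a directed graph with edges child -> parent, each carrying
    a Wang contribution ``weight``.  Terms annotating an element that are
    absent from the DAG are dropped with a warning at attach time.
    """

    dag: nx.DiGraph
    element_terms: dict[str, set[str]] = field(default_factory=dict)
    namespace: str = "BP"
    term_ic: dict[str, float] | None = None  # information content, for Resnik

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.dag):
            raise ValueError("ontology graph must be acyclic")
        self._svalue_cache: dict[str, dict[str, float]] = {}
        self.element_terms = {
            e: self._filter_terms(e, terms) for e, terms in self.element_terms.items()
        }

    def _filter_terms(self, element: str, terms: set[str]) -> set[str]:
        known = {t for t in terms if t in self.dag}
        dropped = terms - known
        if dropped:
            logger.warning(
                "element %s: dropping %d unknown term(s): %s",
                element, len(dropped), sorted(dropped),
            )
        return known

    def attach(self, element_terms: dict[str, set[str]]) -> None:
        for e, terms in element_terms.items():
            self.element_terms[e] = self._filter_terms(e, set(terms))

    def terms_of(self, element: str) -> set[str]:
        return self.element_terms.get(element, set())

    # -- Wang measure -------------------------------------------------------

    def _svalues(self, term: str) -> dict[str, float]:
        """S-values of ``term``'s ancestor closure (semantic contributions).

        S(term) = 1; for an ancestor a, S(a) = max over child edges on a
        path from ``term`` of (edge weight x S(child)).
        """
        cached = self._svalue_cache.get(term)
        if cached is not None:
            return cached
        if term not in self.dag:
            raise KeyError(f"unknown ontology term: {term}")
        s = {term: 1.0}
        frontier = [term]
        while frontier:
            nxt = []
            for child in frontier:
                for _, parent, data in self.dag.out_edges(child, data=True):
                    w = data.get("weight", DEFAULT_EDGE_WEIGHTS["is_a"])
                    cand = w * s[child]
                    if cand > s.get(parent, 0.0):
                        s[parent] = cand
                        nxt.append(parent)
            frontier = nxt
        self._svalue_cache[term] = s
        return s


def term_similarity(
    t1: str, t2: str, ann: OntologyAnnotation, measure: str = "wang"
) -> float:
    """Similarity of two terms, in [0, 1].

    ``wang`` (default) is the graph-based shared-semantic-contribution
    measure; ``resnik`` is the information content of the most
    informative common ancestor, normalized by the maximum IC, and
    requires ``ann.term_ic`` to be supplied (no corpus estimation is
    done here).
    """
    sa = ann._svalues(t1)
    sb = ann._svalues(t2)
    shared = sa.keys() & sb.keys()
    if not shared:
        return 0.0
    if measure == "wang":
        num = sum(sa[t] + sb[t] for t in shared)
        return num / (sum(sa.values()) + sum(sb.values()))
    if measure == "resnik":
        if not ann.term_ic:
            raise ValueError("resnik similarity requires term_ic on the ontology")
        max_ic = max(ann.term_ic.values())
        if max_ic <= 0:
            return 0.0
        mica = max(ann.term_ic.get(t, 0.0) for t in shared)
        return mica / max_ic
    raise ValueError(f"unknown similarity measure: {measure!r}")


def element_similarity(
    e1: str, e2: str, ann: OntologyAnnotation, combine: str = "bma",
    measure: str = "wang",
) -> float:
    """Similarity of two elements from their term sets.

    ``bma`` (default) is the best-match average: the mean of all row-wise
    and column-wise maxima of the term-pair similarity matrix.
    """
    terms1 = sorted(ann.terms_of(e1))
    terms2 = sorted(ann.terms_of(e2))
    if not terms1 or not terms2:
        raise ValueError(f"element(s) without annotation: {e1!r} and/or {e2!r}")
    sim = [[term_similarity(a, b, ann, measure=measure) for b in terms2]
           for a in terms1]
    if combine == "bma":
        row_max = [max(row) for row in sim]
        col_max = [max(sim[i][j] for i in range(len(terms1))) for j in range(len(terms2))]
        return (sum(row_max) + sum(col_max)) / (len(row_max) + len(col_max))
    if combine == "max":
        return max(max(row) for row in sim)
    if combine == "avg":
        return sum(sum(row) for row in sim) / (len(terms1) * len(terms2))
    raise ValueError(f"unknown combine mode: {combine!r}")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_obo(
    path: str | Path,
    edge_weights: dict[str, float] | None = None,
    namespace: str = "BP",
) -> OntologyAnnotation:
    """Load an OBO 1.2 ontology; is_a and part_of edges carry Wang weights."""
    weights = dict(DEFAULT_EDGE_WEIGHTS)
    if edge_weights:
        weights.update(edge_weights)
    raw = obonet.read_obo(str(path))
    dag = nx.DiGraph()
    dag.add_nodes_from(raw.nodes(data=True))
    for child, parent, key in raw.edges(keys=True):
        if key in weights:
            dag.add_edge(child, parent, relation=key, weight=weights[key])
    return OntologyAnnotation(dag=dag, namespace=namespace)


def read_annotation_tsv(path: str | Path) -> dict[str, set[str]]:
    """Read an element -> term table: two TSV columns element_id, term_id."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("element_id", "term_id"):
        if col not in df.columns:
            raise ValueError(f"annotation table missing column: {col}")
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.element_id, set()).add(row.term_id)
    return out


def read_gaf(path: str | Path, namespace_map: dict[str, str] | None = None) -> dict[str, set[str]]:
    """Read a GAF 2.x association file into an object-id -> term-set table.

    ``namespace_map`` optionally maps GAF DB object ids onto map element
    ids (e.g. via the elements' external ids); unmapped ids pass through.
    """
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                continue
            obj_id, term = fields[1], fields[4]
            if namespace_map is not None:
                obj_id = namespace_map.get(obj_id, obj_id)
            out.setdefault(obj_id, set()).add(term)
    return out


def write_obo(ann: OntologyAnnotation, path: str | Path) -> None:
    """Serialize the DAG as a minimal OBO 1.2 file (used by the generator)."""
    lines = ["format-version: 1.2", ""]
    for node in sorted(ann.dag.nodes):
        lines.append("[Term]")
        lines.append(f"id: {node}")
        name = ann.dag.nodes[node].get("name", node)
        lines.append(f"name: {name}")
        for _, parent, data in sorted(ann.dag.out_edges(node, data=True)):
            rel = data.get("relation", "is_a")
            if rel == "is_a":
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: {rel} {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
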