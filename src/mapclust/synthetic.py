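"""Synthetic interaction maps with planted multi-signal cluster structure.

The generator emulates the three signals a curated disease map carries —
expert layout (elements of a functional area drawn together), reaction
connectivity (interactions mostly within an area), and ontology
annotation (elements of an area share characteristic terms) — as planted
groups.  ``conflict_mode`` decouples chosen signals from the planted
groups, giving controlled analogues of the situations where different
distance metrics disagree:

* ``aligned`` — all three signals follow the planted groups;
* ``spatial_only`` — only the layout follows the groups; reactions and
  annotations are random;
* ``network_only`` — only the reaction structure follows the groups;
* ``shuffled`` — nothing does.

``reorganize`` emulates the curatorial rearrangement benchmark: a
fraction of elements is duplicated, within-group layout is contracted,
and reactions made redundant by duplication are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx
import numpy as np

from .map_model import AnnotationArea, InteractionMap, MapElement, Reaction
from .ontology import OntologyAnnotation

_CLASS_CYCLE = ("protein", "gene", "mRNA")


@dataclass
class SyntheticConfig:
    """Knobs of the planted-structure generator.

    Defaults describe a small but well-separated map: three groups of 20
    elements, spatial separation 20x the within-group spread, 90% of
    reactions within a group, and 90% annotation fidelity — strong but
    not noiseless structure, the regime in which every metric should be
    individually informative.
    """

    n_clusters: int = 3
    cluster_sizes: list[int] | None = None          # default: 20 per group
    spatial_separation: float = 1000.0               # grid step between centers, px
    spatial_sd: float = 50.0                         # within-group coordinate spread
    reaction_arity: int = 3
    reactions_per_element: float = 1.5
    p_within: float = 0.9
    p_between: float = 0.1
    ontology_depth: int = 3                          # edges root -> leaf term
    terms_per_group: int = 3
    terms_per_element: int = 2
    annotation_fidelity: float = 0.9
    conflict_mode: str = "aligned"
    dag_twist: bool = False                          # add cross-links (DAG, not tree)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_sizes is None:
            self.cluster_sizes = [20] * self.n_clusters
        if len(self.cluster_sizes) != self.n_clusters:
            raise ValueError("cluster_sizes length must equal n_clusters")
        if any(s <= 0 for s in self.cluster_sizes):
            raise ValueError("cluster sizes must be positive")
        for p in (self.p_within, self.p_between, self.annotation_fidelity):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.reaction_arity < 2:
            raise ValueError("reaction arity must be >= 2")
        if self.ontology_depth < 2:
            raise ValueError("ontology depth must be >= 2")
        if self.conflict_mode not in ("aligned", "spatial_only", "network_only", "shuffled"):
            raise ValueError(f"unknown conflict mode: {self.conflict_mode!r}")


@dataclass
class PlantedTruth:
    """Ground truth of the generator: element -> group, group -> terms."""

    labels: dict[str, int]
    group_terms: dict[int, list[str]] = field(default_factory=dict)

    def as_reference_dict(self) -> dict[str, str]:
        return {e: str(g) for e, g in self.labels.items()}


class SyntheticMap(NamedTuple):
    map: InteractionMap
    truth: PlantedTruth
    ontology: OntologyAnnotation


def _build_ontology(config: SyntheticConfig, rng: np.random.Generator
                    ) -> tuple[nx.DiGraph, dict[int, list[str]]]:
    dag = nx.DiGraph()
    root = "SYN:0000000"
    dag.add_node(root, name="root")
    group_terms: dict[int, list[str]] = {}
    counter = 1
    for g in range(config.n_clusters):
        parent = root
        for _ in range(config.ontology_depth - 1):
            node = f"SYN:{counter:07d}"
            counter += 1
            dag.add_node(node, name=f"group{g}-branch")
            dag.add_edge(node, parent, relation="is_a", weight=0.8)
            parent = node
        leaves = []
        for _ in range(config.terms_per_group):
            node = f"SYN:{counter:07d}"
            counter += 1
            dag.add_node(node, name=f"group{g}-term")
            dag.add_edge(node, parent, relation="is_a", weight=0.8)
            leaves.append(node)
        group_terms[g] = leaves
    if config.dag_twist and config.n_clusters > 1:
        # cross-link one leaf per group under another group's branch
        for g in range(config.n_clusters):
            other = (g + 1) % config.n_clusters
            leaf = group_terms[g][0]
            target_branch = list(dag.successors(group_terms[other][0]))[0]
            if not dag.has_edge(leaf, target_branch):
                dag.add_edge(leaf, target_branch, relation="part_of", weight=0.6)
    return dag, group_terms


def generate(config: SyntheticConfig) -> SyntheticMap:
    """Generate a map with planted groups, its truth and its ontology."""
    rng = np.random.default_rng(config.rng_seed)
    G = config.n_clusters
    sizes = config.cluster_sizes
    N = sum(sizes)
    mode = config.conflict_mode
    spatial_on = mode in ("aligned", "spatial_only")
    network_on = mode in ("aligned", "network_only")
    onto_on = mode == "aligned"

    cols = math.ceil(math.sqrt(G))
    centers = np.array(
        [[(g % cols) * config.spatial_separation,
          (g // cols) * config.spatial_separation] for g in range(G)]
    )
    canvas = centers.max(axis=0) + config.spatial_separation

    dag, group_terms = _build_ontology(config, rng)
    all_terms = [t for leaves in group_terms.values() for t in leaves]

    elements: list[MapElement] = []
    labels: dict[str, int] = {}
    group_members: dict[int, list[str]] = {g: [] for g in range(G)}
    for g in range(G):
        for i in range(sizes[g]):
            eid = f"e{g}_{i}"
            if spatial_on:
                xy = centers[g] + rng.normal(0.0, config.spatial_sd, size=2)
            else:
                xy = rng.uniform(0.0, 1.0, size=2) * canvas
            terms: set[str] = set()
            for _ in range(config.terms_per_element):
                if onto_on and rng.random() < config.annotation_fidelity:
                    terms.add(group_terms[g][rng.integers(config.terms_per_group)])
                elif onto_on:
                    others = [t for gg, ts in group_terms.items() if gg != g for t in ts]
                    pool = others or group_terms[g]  # single-group maps
                    terms.add(pool[rng.integers(len(pool))])
                else:
                    terms.add(all_terms[rng.integers(len(all_terms))])
            elements.append(
                MapElement(
                    element_id=eid,
                    name=f"element {eid}",
                    element_class=_CLASS_CYCLE[i % len(_CLASS_CYCLE)],
                    x=float(xy[0]),
                    y=float(xy[1]),
                    term_ids=terms,
                )
            )
            labels[eid] = g
            group_members[g].append(eid)

    all_ids = [e.element_id for e in elements]
    group_weights = np.array(sizes, dtype=float) / N
    n_reactions = round(config.reactions_per_element * N)
    reactions: list[Reaction] = []
    p_total = config.p_within + config.p_between
    for r in range(n_reactions):
        arity = config.reaction_arity
        if network_on and p_total > 0 and rng.random() < config.p_within / p_total:
            g = int(rng.choice(G, p=group_weights))
            pool = group_members[g]
            members = list(rng.choice(pool, size=min(arity, len(pool)), replace=False))
        else:
            members = list(rng.choice(all_ids, size=min(arity, N), replace=False))
            if network_on and len({labels[m] for m in members}) < 2 and G > 1:
                # force a genuinely cross-group reaction
                g1, g2 = rng.choice(G, size=2, replace=False)
                members[0] = group_members[int(g1)][
                    rng.integers(len(group_members[int(g1)]))
                ]
                members[1] = group_members[int(g2)][
                    rng.integers(len(group_members[int(g2)]))
                ]
                members = list(dict.fromkeys(members))
        if len(members) < 2:
            continue
        # roles are arbitrary: clique expansion ignores them
        participants = [(members[0], "reactant"), (members[-1], "product")]
        participants += [(m, "modifier") for m in members[1:-1]]
        reactions.append(Reaction(reaction_id=f"re{r}", participants=participants))

    areas = [
        AnnotationArea(area_name=f"group_{g}", member_ids=set(group_members[g]))
        for g in range(G)
    ]
    if mode == "shuffled":
        perm = rng.permutation(N)
        coords = [(elements[j].x, elements[j].y) for j in range(N)]
        for i, j in enumerate(perm):
            elements[i].x, elements[i].y = coords[j]

    imap = InteractionMap(elements=elements, reactions=reactions, areas=areas)
    ann = OntologyAnnotation(
        dag=dag, element_terms={e.element_id: set(e.term_ids) for e in elements}
    )
    truth = PlantedTruth(labels=labels, group_terms=group_terms)
    return SyntheticMap(map=imap, truth=truth, ontology=ann)


# ---------------------------------------------------------------------------
# Content rearrangement
# ---------------------------------------------------------------------------

def reorganize(
    imap: InteractionMap,
    dup_fraction: float = 0.1,
    shrink_factor: float = 0.8,
    rng_seed: int = 0,
) -> InteractionMap:
    """Emulate curatorial content rearrangement.

    ``dup_fraction`` of the elements are duplicated (fresh ids, inherited
    annotations and reactions, placed next to the original with a small
    jitter); within-area coordinates are contracted toward the area
    centroid by ``shrink_factor``; reactions whose participant sets
    become exact duplicates are removed as redundant.
    """
    if not 0.0 <= dup_fraction <= 1.0 or not 0.0 <= shrink_factor <= 1.0 + 1e-12:
        raise ValueError("dup_fraction and shrink_factor must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    elements = [
        MapElement(e.element_id, e.name, e.element_class, e.x, e.y,
                   set(e.term_ids), dict(e.external_ids))
        for e in imap.elements
    ]
    reactions = [Reaction(r.reaction_id, list(r.participants)) for r in imap.reactions]
    areas = [AnnotationArea(a.area_name, set(a.member_ids)) for a in imap.areas]

    n_dup = round(dup_fraction * len(elements))
    if n_dup:
        picked = rng.choice(len(imap.elements), size=n_dup, replace=False)
        for idx in sorted(int(i) for i in picked):
            orig = imap.elements[idx]
            dup_id = f"{orig.element_id}~dup"
            jitter = rng.normal(0.0, 5.0, size=2)
            elements.append(
                MapElement(
                    element_id=dup_id, name=orig.name,
                    element_class=orig.element_class,
                    x=None if orig.x is None else float(orig.x + jitter[0]),
                    y=None if orig.y is None else float(orig.y + jitter[1]),
                    term_ids=set(orig.term_ids),
                    external_ids=dict(orig.external_ids),
                )
            )
            for r in reactions:  # the copy joins its original's reactions
                for eid, role in list(r.participants):
                    if eid == orig.element_id:
                        r.participants.append((dup_id, role))
            for a in areas:
                if orig.element_id in a.member_ids:
                    a.member_ids.add(dup_id)

    kept = reactions
    if n_dup:  # only duplication can make reactions redundant
        seen: set[frozenset[str]] = set()
        kept = []
        for r in reactions:
            key = frozenset(r.participant_ids())
            if key in seen:
                continue  # redundant after duplication
            seen.add(key)
            kept.append(r)

    if abs(shrink_factor - 1.0) > 1e-12:
        groups: dict[str, str | None] = {}
        for e in elements:
            groups[e.element_id] = None
            for a in areas:
                if e.element_id in a.member_ids:
                    groups[e.element_id] = a.area_name
                    break
        by_group: dict[str | None, list[MapElement]] = {}
        for e in elements:
            if e.has_coordinates:
                by_group.setdefault(groups[e.element_id], []).append(e)
        for members in by_group.values():
            cx = float(np.mean([e.x for e in members]))
            cy = float(np.mean([e.y for e in members]))
            for e in members:
                e.x = cx + shrink_factor * (e.x - cx)
                e.y = cy + shrink_factor * (e.y - cy)

    return InteractionMap(elements=elements, reactions=kept, areas=areas)
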