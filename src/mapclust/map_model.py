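"""Data model for annotated molecular interaction maps.

A curated disease map (a CellDesigner diagram such as the Parkinson's
disease map or AlzPathway) is represented as an :class:`InteractionMap`:
drawn glyphs with layout coordinates, typed elements (gene / mRNA /
protein / other), reactions as hyperedges over elements, and optional
expert annotation areas (named groups of elements used as an external
reference for clustering evaluation).

Readers are provided for CellDesigner SBML Level 2 exports and for a
plain TSV dialect used by the synthetic generator and third-party
tooling.  ``clique_expand`` converts the reaction hypergraph into a
simple undirected graph by replacing every multi-participant reaction
with a clique over its participants.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from lxml import etree

logger = logging.getLogger(__name__)

ELEMENT_CLASSES = ("gene", "mRNA", "protein", "other")

#: CellDesigner species classes mapped onto the coarse element classes.
_CD_CLASS_MAP = {
    "GENE": "gene",
    "RNA": "mRNA",
    "ANTISENSE_RNA": "mRNA",
    "PROTEIN": "protein",
    "RECEPTOR": "protein",
    "ION_CHANNEL": "protein",
    "TRUNCATED": "protein",
}

#: MIRIAM URI patterns -> (namespace, identifier) extraction.
_MIRIAM_RE = re.compile(
    r"(?:urn:miriam:(?P<ns1>[^:]+):(?P<id1>[^\"']+)"
    r"|https?://identifiers\.org/(?P<ns2>[^/]+)/(?P<id2>[^\"'/]+))"
)


@dataclass
class MapElement:
    """One drawn glyph of the map.

    ``x``/``y`` are the glyph *center* in diagram units (pixels); they are
    ``None`` for elements the source file draws without layout, which are
    kept in the map but excluded from Euclidean computations.
    """

    element_id: str
    name: str = ""
    element_class: str = "other"
    x: float | None = None
    y: float | None = None
    term_ids: set[str] = field(default_factory=set)
    external_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.element_class not in ELEMENT_CLASSES:
            raise ValueError(
                f"unknown element class {self.element_class!r} for {self.element_id!r}"
            )

    @property
    def has_coordinates(self) -> bool:
        return self.x is not None and self.y is not None


@dataclass
class Reaction:
    """A reaction hyperedge: participants are (element_id, role) pairs."""

    reaction_id: str
    participants: list[tuple[str, str]]

    def participant_ids(self) -> list[str]:
        return [eid for eid, _ in self.participants]


@dataclass
class AnnotationArea:
    """A named expert annotation area, e.g. "Mitophagy" or "Glycolysis"."""

    area_name: str
    member_ids: set[str]


@dataclass
class InteractionMap:
    elements: list[MapElement]
    reactions: list[Reaction]
    areas: list[AnnotationArea] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [e.element_id for e in self.elements]
        id_set = set(ids)
        if len(ids) != len(id_set):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate element ids: {dupes}")
        dangling = sorted(
            {
                eid
                for r in self.reactions
                for eid in r.participant_ids()
                if eid not in id_set
            }
        )
        if dangling:
            raise ValueError(f"reactions reference unknown elements: {dangling}")
        for area in self.areas:
            unknown = sorted(area.member_ids - id_set)
            if unknown:
                raise ValueError(
                    f"area {area.area_name!r} references unknown elements: {unknown}"
                )

    def element_by_id(self, element_id: str) -> MapElement:
        for e in self.elements:
            if e.element_id == element_id:
                return e
        raise KeyError(element_id)

    @property
    def element_ids(self) -> list[str]:
        return [e.element_id for e in self.elements]


def select_entities(imap: InteractionMap, classes: Iterable[str]) -> list[str]:
    """Return ids of elements whose class is in ``classes``, in map order.

    The returned ordered subset is the common index basis of every distance
    matrix built from this map.
    """
    classes = set(classes)
    if not classes:
        raise ValueError("classes must be non-empty")
    unknown = classes - set(ELEMENT_CLASSES)
    if unknown:
        raise ValueError(f"unknown element classes: {sorted(unknown)}")
    subset = [e.element_id for e in imap.elements if e.element_class in classes]
    if not subset:
        raise ValueError(f"no elements of class {sorted(classes)} in map")
    return subset


def clique_expand(imap: InteractionMap, subset: Sequence[str]) -> nx.Graph:
    """Replace each reaction hyperedge by a clique over its in-subset participants.

    Roles and direction are ignored; duplicate edges collapse; reactions
    with fewer than two in-subset participants contribute no edges.
    """
    subset_set = set(subset)
    missing = subset_set - set(imap.element_ids)
    if missing:
        raise ValueError(f"subset contains unknown elements: {sorted(missing)}")
    g = nx.Graph()
    g.add_nodes_from(subset)
    for r in imap.reactions:
        members = sorted({eid for eid in r.participant_ids() if eid in subset_set})
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                g.add_edge(a, b)
    return g


# ---------------------------------------------------------------------------
# CellDesigner SBML reader
# ---------------------------------------------------------------------------

def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _find_descendants(node, local_name: str):
    return [el for el in node.iter() if isinstance(el.tag, str) and _local(el.tag) == local_name]


def _parse_miriam(node) -> dict[str, str]:
    """Extract MIRIAM resource URIs from an annotation subtree."""
    out: dict[str, str] = {}
    for el in node.iter():
        for attr, value in el.attrib.items():
            if _local(attr) != "resource":
                continue
            m = _MIRIAM_RE.search(value)
            if not m:
                continue
            ns = m.group("ns1") or m.group("ns2")
            ident = m.group("id1") or m.group("id2")
            ident = ident.replace("%3A", ":").replace("%3a", ":")
            out[ns] = ident
    return out


def read_celldesigner(path: str | Path, per_alias: bool = True) -> InteractionMap:
    """Read a CellDesigner SBML Level 2 file into an :class:`InteractionMap`.

    Each species *alias* (a drawn glyph, with its own bounds) becomes one
    element by default, inheriting the species' class and annotations; with
    ``per_alias=False`` one element per species is created instead, taking
    coordinates from the first alias.  Glyph centers (x + w/2, y + h/2)
    are used as coordinates.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed SBML in {path.name}: {exc}") from exc
    root = tree.getroot()

    # species -> (name, class, term_ids, external_ids)
    species_info: dict[str, dict] = {}
    for los in _find_descendants(root, "listOfSpecies"):
        for sp in los:
            if not isinstance(sp.tag, str) or _local(sp.tag) != "species":
                continue
            sid = sp.get("id")
            if sid is None:
                continue
            cd_class = "other"
            for cls_el in _find_descendants(sp, "class"):
                cd_class = (cls_el.text or "").strip().upper()
                break
            external = _parse_miriam(sp)
            terms = {
                v
                for ns, v in external.items()
                if ns in ("obo.go", "go", "obo.do", "doid")
            }
            species_info[sid] = {
                "name": sp.get("name", sid),
                "element_class": _CD_CLASS_MAP.get(cd_class, "other"),
                "term_ids": terms,
                "external_ids": external,
            }

    # aliases: glyph bounds per species
    aliases: list[tuple[str, str, float | None, float | None]] = []
    for alias in _find_descendants(root, "speciesAlias"):
        aid = alias.get("id")
        sid = alias.get("species")
        if aid is None or sid is None or sid not in species_info:
            continue
        cx = cy = None
        for bounds in _find_descendants(alias, "bounds"):
            try:
                x = float(bounds.get("x"))
                y = float(bounds.get("y"))
                w = float(bounds.get("w", 0.0))
                h = float(bounds.get("h", 0.0))
                cx, cy = x + w / 2.0, y + h / 2.0
            except (TypeError, ValueError):
                pass
            break
        aliases.append((aid, sid, cx, cy))

    elements: list[MapElement] = []
    alias_of_species: dict[str, list[str]] = {}
    if per_alias and aliases:
        seen_species = set()
        for aid, sid, cx, cy in aliases:
            info = species_info[sid]
            elements.append(
                MapElement(
                    element_id=aid,
                    name=info["name"],
                    element_class=info["element_class"],
                    x=cx,
                    y=cy,
                    term_ids=set(info["term_ids"]),
                    external_ids=dict(info["external_ids"]),
                )
            )
            alias_of_species.setdefault(sid, []).append(aid)
            seen_species.add(sid)
        for sid, info in species_info.items():
            if sid not in seen_species:
                elements.append(
                    MapElement(
                        element_id=sid,
                        name=info["name"],
                        element_class=info["element_class"],
                        term_ids=set(info["term_ids"]),
                        external_ids=dict(info["external_ids"]),
                    )
                )
                alias_of_species.setdefault(sid, []).append(sid)
    else:
        coords: dict[str, tuple[float | None, float | None]] = {}
        for aid, sid, cx, cy in aliases:
            coords.setdefault(sid, (cx, cy))
        for sid, info in species_info.items():
            cx, cy = coords.get(sid, (None, None))
            elements.append(
                MapElement(
                    element_id=sid,
                    name=info["name"],
                    element_class=info["element_class"],
                    x=cx,
                    y=cy,
                    term_ids=set(info["term_ids"]),
                    external_ids=dict(info["external_ids"]),
                )
            )
            alias_of_species.setdefault(sid, []).append(sid)

    no_coords = [e.element_id for e in elements if not e.has_coordinates]
    if no_coords:
        logger.warning(
            "%d element(s) without layout coordinates (excluded from Euclidean "
            "computations): %s", len(no_coords), no_coords[:10],
        )

    reactions: list[Reaction] = []
    for lor in _find_descendants(root, "listOfReactions"):
        for rx in lor:
            if not isinstance(rx.tag, str) or _local(rx.tag) != "reaction":
                continue
            rid = rx.get("id", f"re{len(reactions)}")
            participants: list[tuple[str, str]] = []
            role_lists = (
                ("listOfReactants", "reactant"),
                ("listOfProducts", "product"),
                ("listOfModifiers", "modifier"),
            )
            for list_name, role in role_lists:
                for lst in _find_descendants(rx, list_name):
                    for ref in lst:
                        if not isinstance(ref.tag, str):
                            continue
                        sid = ref.get("species")
                        if sid is None or sid not in species_info:
                            continue
                        for eid in alias_of_species.get(sid, []):
                            participants.append((eid, role))
            if participants:
                reactions.append(Reaction(reaction_id=rid, participants=participants))

    return InteractionMap(elements=elements, reactions=reactions)


# ---------------------------------------------------------------------------
# Generic TSV map dialect
# ---------------------------------------------------------------------------

_ELEMENT_COLS = ["element_id", "name", "class", "x", "y", "terms"]
_REACTION_COLS = ["reaction_id", "element_id", "role"]
_AREA_COLS = ["area_name", "element_id"]


def read_generic_map(
    elements_table: str | Path,
    reactions_table: str | Path | None = None,
    areas_table: str | Path | None = None,
) -> InteractionMap:
    """Read the generic TSV map dialect (see :func:`write_generic_map`)."""
    edf = pd.read_csv(elements_table, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _ELEMENT_COLS if c not in edf.columns]
    if missing:
        raise ValueError(f"elements table missing columns: {missing}")
    elements = []
    for row in edf.to_dict("records"):  # "class" is a keyword: no itertuples
        terms = {t for t in str(row["terms"]).split("|") if t}
        elements.append(
            MapElement(
                element_id=row["element_id"],
                name=row["name"],
                element_class=row["class"],
                x=float(row["x"]) if row["x"] != "" else None,
                y=float(row["y"]) if row["y"] != "" else None,
                term_ids=terms,
            )
        )

    reactions: list[Reaction] = []
    if reactions_table is not None:
        rdf = pd.read_csv(reactions_table, sep="\t", dtype=str, keep_default_na=False)
        missing = [c for c in _REACTION_COLS if c not in rdf.columns]
        if missing:
            raise ValueError(f"reactions table missing columns: {missing}")
        if len(rdf):
            for rid, grp in rdf.groupby("reaction_id", sort=False):
                participants = list(zip(grp["element_id"], grp["role"]))
                reactions.append(Reaction(reaction_id=rid, participants=participants))

    areas: list[AnnotationArea] = []
    if areas_table is not None:
        adf = pd.read_csv(areas_table, sep="\t", dtype=str, keep_default_na=False)
        missing = [c for c in _AREA_COLS if c not in adf.columns]
        if missing:
            raise ValueError(f"areas table missing columns: {missing}")
        if len(adf):
            for name, grp in adf.groupby("area_name", sort=False):
                areas.append(AnnotationArea(area_name=name, member_ids=set(grp["element_id"])))

    return InteractionMap(elements=elements, reactions=reactions, areas=areas)


def write_generic_map(
    imap: InteractionMap,
    elements_table: str | Path,
    reactions_table: str | Path | None = None,
    areas_table: str | Path | None = None,
) -> None:
    """Write an :class:`InteractionMap` as the generic TSV dialect."""
    rows = []
    for e in imap.elements:
        rows.append(
            {
                "element_id": e.element_id,
                "name": e.name,
                "class": e.element_class,
                "x": "" if e.x is None else repr(float(e.x)),
                "y": "" if e.y is None else repr(float(e.y)),
                "terms": "|".join(sorted(e.term_ids)),
            }
        )
    pd.DataFrame(rows, columns=_ELEMENT_COLS).to_csv(elements_table, sep="\t", index=False)

    if reactions_table is not None:
        rrows = [
            {"reaction_id": r.reaction_id, "element_id": eid, "role": role}
            for r in imap.reactions
            for eid, role in r.participants
        ]
        pd.DataFrame(rrows, columns=_REACTION_COLS).to_csv(
            reactions_table, sep="\t", index=False
        )
    if areas_table is not None:
        arows = [
            {"area_name": a.area_name, "element_id": eid}
            for a in imap.areas
            for eid in sorted(a.member_ids)
        ]
        pd.DataFrame(arows, columns=_AREA_COLS).to_csv(areas_table, sep="\t", index=False)


def map_to_json(imap: InteractionMap, path: str | Path) -> None:
    """Dump a map to a single JSON file (round-trippable alternative to TSV)."""
    doc = {
        "elements": [
            {
                "element_id": e.element_id,
                "name": e.name,
                "class": e.element_class,
                "x": e.x,
                "y": e.y,
                "terms": sorted(e.term_ids),
                "external_ids": e.external_ids,
            }
            for e in imap.elements
        ],
        "reactions": [
            {"reaction_id": r.reaction_id, "participants": r.participants}
            for r in imap.reactions
        ],
        "areas": [
            {"area_name": a.area_name, "member_ids": sorted(a.member_ids)}
            for a in imap.areas
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))
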