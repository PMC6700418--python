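"""KGML pathway parsing and reconstruction of the merged KO pathway network.

KEGG distributes each pathway map as a KGML document: ``entry`` elements
(ortholog boxes, compounds, links to other maps) connected by ``relation``
elements.  Two relation types matter here: ``ECrel`` (two enzymes coupled by a
shared compound in successive reactions) and ``maplink`` (an entry pointing at
another pathway map).  Merging all non-overview maps on these relations yields
one network whose adjacent KO pairs are the candidate universe for
interspecific interaction scoring.

Pairs are additionally classified as metabolic--metabolic or
metabolic--non-metabolic (boundary) using the three transporter/signalling
maps (ABC transporters 02010, two-component system 02020, PTS 02060): a
producer enzyme on a metabolic map linked through a shared compound to an
uptake protein on one of those maps sits at the interface between
intracellular and extracellular metabolism.
"""

from __future__ import annotations

import csv
import logging
import re
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

KO_PATTERN = re.compile(r"K\d{5}")
COMPOUND_PATTERN = re.compile(r"C\d{5}")
MAP_ID_PATTERN = re.compile(r"(\d{5})")

#: ABC transporters, two-component system, phosphotransferase system (PTS).
DEFAULT_NONMETABOLIC_MAPS = frozenset({"02010", "02020", "02060"})

#: KEGG global/overview map prefixes (011xx metabolism overviews, 012xx
#: degradation overviews); configurable because KEGG does not freeze the list.
DEFAULT_OVERVIEW_PREFIXES = ("011", "012")

PAIR_CLASS_METABOLIC = "metabolic_metabolic"
PAIR_CLASS_BOUNDARY = "metabolic_nonmetabolic"
PAIR_CLASS_UNCLASSIFIED = "unclassified"


class KgmlError(ValueError):
    """Malformed or non-KGML input."""


@dataclass(frozen=True)
class Entry:
    """One KGML ``entry`` element (ortholog, compound or map link)."""

    entry_id: str
    entry_type: str  # "ortholog" | "compound" | "map"
    ko_ids: tuple[str, ...] = ()
    compound_id: Optional[str] = None  # for compound entries
    target_map: Optional[str] = None  # for map entries


@dataclass(frozen=True)
class Relation:
    """One KGML ``relation``; compound resolved from the subtype entry."""

    entry1: str
    entry2: str
    relation_type: str  # "ecrel" | "maplink" | "other"
    compound_entry_id: Optional[str] = None
    compound_id: Optional[str] = None


@dataclass
class KgmlDocument:
    map_id: str
    entries: list[Entry]
    relations: list[Relation]

    def entry(self, entry_id: str) -> Entry:
        return self._index()[entry_id]

    def _index(self) -> Mapping[str, Entry]:
        return {e.entry_id: e for e in self.entries}


@dataclass(frozen=True)
class AdjacentPair:
    """An unordered adjacent KO pair with its intermediate compound(s)."""

    ko_a: str
    ko_b: str
    compounds: frozenset[str] = frozenset()
    pair_class: str = PAIR_CLASS_UNCLASSIFIED

    def __post_init__(self) -> None:
        if self.ko_a >= self.ko_b:
            raise ValueError(f"pair not canonically ordered: {self.ko_a!r} >= {self.ko_b!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.ko_a, self.ko_b)


@dataclass(frozen=True)
class ModuleDefinition:
    """A pathway module: terminal (edge) vs intermediate (internal) compounds."""

    module_id: str
    edge_compounds: frozenset[str]
    internal_compounds: frozenset[str]

    def __post_init__(self) -> None:
        overlap = self.edge_compounds & self.internal_compounds
        if overlap:
            raise ValueError(
                f"module {self.module_id}: compounds both edge and internal: {sorted(overlap)}"
            )


@dataclass
class PathwayGraph:
    """Merged undirected KO network with compound-labelled edges.

    ``graph`` is a :class:`networkx.Graph` whose nodes are KO ids (node
    attribute ``maps``: set of source map ids) and whose edges carry
    ``compounds`` (set, possibly empty) and ``maps`` (set of contributing
    map ids).  ``map_category`` maps each seen map id to ``metabolic``,
    ``non_metabolic`` or ``overview``.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    map_category: dict[str, str] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edge_records(self) -> list[tuple[str, str, frozenset[str], frozenset[str]]]:
        """Canonical sorted edge list: (ko_a, ko_b, compounds, maps)."""
        records = []
        for u, v, data in self.graph.edges(data=True):
            a, b = sorted((u, v))
            records.append((a, b, frozenset(data.get("compounds", ())), frozenset(data.get("maps", ()))))
        return sorted(records)

    def ko_maps(self, ko: str) -> frozenset[str]:
        if ko not in self.graph:
            return frozenset()
        return frozenset(self.graph.nodes[ko].get("maps", ()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayGraph):
            return NotImplemented
        return self.nodes == other.nodes and self.edge_records() == other.edge_records()


def canonical_ko(token: str) -> Optional[str]:
    m = KO_PATTERN.search(token)
    return m.group(0) if m else None


def parse_kgml(xml_text: str) -> KgmlDocument:
    """Parse one KGML document.

    Only ``ortholog``, ``compound`` and ``map`` entries are honoured (KGML
    ``gene`` entries are organism-specific and the analysis works at KO
    level).  Relation types other than ECrel/maplink are retained with
    ``relation_type="other"``.  The compound of a relation (``subtype`` with
    ``name="compound"``) is resolved to its C-number through the referenced
    compound entry when possible.
    """
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError as exc:
        line, col = exc.position
        raise KgmlError(f"malformed KGML XML at line {line}, column {col}: {exc}") from exc
    if root.tag != "pathway":
        raise KgmlError(f"expected <pathway> root element, found <{root.tag}>")

    map_id = root.get("number") or ""
    if not map_id:
        m = MAP_ID_PATTERN.search(root.get("name", ""))
        if not m:
            raise KgmlError("pathway element lacks a map number")
        map_id = m.group(1)
    map_id = f"{int(map_id):05d}"

    entries: list[Entry] = []
    for el in root.findall("entry"):
        etype = el.get("type", "")
        eid = el.get("id", "")
        name = el.get("name", "")
        if etype == "ortholog":
            kos = tuple(KO_PATTERN.findall(name))
            entries.append(Entry(eid, "ortholog", ko_ids=kos))
        elif etype == "compound":
            m = COMPOUND_PATTERN.search(name)
            entries.append(Entry(eid, "compound", compound_id=m.group(0) if m else None))
        elif etype == "map":
            m = MAP_ID_PATTERN.search(name)
            entries.append(Entry(eid, "map", target_map=m.group(1) if m else None))
        # gene/group/enzyme entries ignored

    index = {e.entry_id: e for e in entries}
    relations: list[Relation] = []
    for el in root.findall("relation"):
        rtype_raw = (el.get("type") or "").lower()
        if rtype_raw == "ecrel":
            rtype = "ecrel"
        elif rtype_raw == "maplink":
            rtype = "maplink"
        else:
            rtype = "other"
        compound_entry = None
        compound_id = None
        for sub in el.findall("subtype"):
            if sub.get("name") == "compound":
                compound_entry = sub.get("value")
                ref = index.get(compound_entry or "")
                if ref is not None and ref.entry_type == "compound":
                    compound_id = ref.compound_id
                break
        relations.append(
            Relation(el.get("entry1", ""), el.get("entry2", ""), rtype, compound_entry, compound_id)
        )
    return KgmlDocument(map_id=map_id, entries=entries, relations=relations)


def read_kgml_dir(path: str | Path, glob: str = "*.xml") -> list[KgmlDocument]:
    return [parse_kgml(p.read_text()) for p in sorted(Path(path).glob(glob))]


def _is_overview(map_id: str, overview_map_ids: Optional[set[str]]) -> bool:
    if overview_map_ids is not None:
        return map_id in overview_map_ids
    return map_id.startswith(DEFAULT_OVERVIEW_PREFIXES)


def _add_edge(graph: nx.Graph, ko1: str, ko2: str, compound: Optional[str], map_ids: Iterable[str]) -> None:
    if ko1 == ko2:
        return
    a, b = sorted((ko1, ko2))
    if not graph.has_edge(a, b):
        graph.add_edge(a, b, compounds=set(), maps=set())
    data = graph.edges[a, b]
    if compound is not None:
        data["compounds"].add(compound)
    data["maps"].update(map_ids)


def build_graph(
    documents: Sequence[KgmlDocument],
    overview_map_ids: Optional[set[str]] = None,
    nonmetabolic_map_ids: frozenset[str] | set[str] = DEFAULT_NONMETABOLIC_MAPS,
) -> PathwayGraph:
    """Merge KGML documents into one KO network.

    Overview maps contribute nothing.  ECrel relations between ortholog
    entries become edges labelled with the relation's compound; entries
    carrying several KO ids expand to all cross combinations (never
    self-pairs).  maplink relations between an ortholog entry and a map entry
    are joined across documents: KO1 on map A linking towards map B and KO2
    on map B linking towards map A produce an edge (KO1, KO2) when their
    linking compounds agree.  A maplink directly between two ortholog entries
    is treated like an ECrel edge.

    When ``overview_map_ids`` is None, maps with the KEGG global-map prefixes
    011/012 are treated as overviews.
    """
    graph = nx.Graph()
    map_category: dict[str, str] = {}
    # cross-map maplink stubs: (compound_id or None) -> list of (ko, source, target)
    stubs: list[tuple[str, str, str, Optional[str]]] = []
    seen_maps: set[str] = set()

    for doc in documents:
        if _is_overview(doc.map_id, overview_map_ids):
            map_category[doc.map_id] = "overview"
            continue
        if doc.map_id in seen_maps:
            warnings.warn(f"duplicate map id {doc.map_id}; merging relations from later file", stacklevel=2)
        seen_maps.add(doc.map_id)
        map_category[doc.map_id] = (
            "non_metabolic" if doc.map_id in nonmetabolic_map_ids else "metabolic"
        )
        index = doc._index()
        for e in doc.entries:
            for ko in e.ko_ids:
                if ko not in graph:
                    graph.add_node(ko, maps=set())
                graph.nodes[ko]["maps"].add(doc.map_id)
        for rel in doc.relations:
            if rel.relation_type == "other":
                continue
            e1 = index.get(rel.entry1)
            e2 = index.get(rel.entry2)
            if e1 is None or e2 is None:
                continue
            if e1.entry_type == "ortholog" and e2.entry_type == "ortholog":
                for ko1 in e1.ko_ids:
                    for ko2 in e2.ko_ids:
                        _add_edge(graph, ko1, ko2, rel.compound_id, [doc.map_id])
            elif rel.relation_type == "maplink":
                ortho, mapent = (e1, e2) if e1.entry_type == "ortholog" else (e2, e1)
                if ortho.entry_type != "ortholog" or mapent.entry_type != "map":
                    continue
                if mapent.target_map is None:
                    continue
                for ko in ortho.ko_ids:
                    stubs.append((ko, doc.map_id, mapent.target_map, rel.compound_id))

    # join reciprocal maplink stubs across maps
    for i, (ko1, src1, tgt1, c1) in enumerate(stubs):
        for ko2, src2, tgt2, c2 in stubs[i + 1 :]:
            if src1 == tgt2 and tgt1 == src2 and c1 == c2 and ko1 != ko2:
                _add_edge(graph, ko1, ko2, c1, [src1, src2])

    return PathwayGraph(graph=graph, map_category=map_category)


def enumerate_pairs(graph: PathwayGraph, require_compounds: bool = False) -> list[AdjacentPair]:
    """Enumerate adjacent KO pairs, canonically ordered.

    With ``require_compounds=True`` only pairs mediated by at least one
    intermediate compound are returned — the scored universe.
    """
    pairs = []
    for a, b, compounds, _maps in graph.edge_records():
        if require_compounds and not compounds:
            continue
        pairs.append(AdjacentPair(a, b, compounds=compounds))
    return pairs


def derive_transporter_relations(
    graph: PathwayGraph,
) -> list[tuple[str, str, str]]:
    """Find (uptake_ko, compound, producer_ko) triples from graph edges.

    An uptake KO sits on a non-metabolic (transporter/signalling) map; the
    producer is a metabolic-map KO connected to it through a shared edge
    compound.
    """
    cat = graph.map_category
    triples = []
    for a, b, compounds, _maps in graph.edge_records():
        for uptake, producer in ((a, b), (b, a)):
            u_maps = graph.ko_maps(uptake)
            p_maps = graph.ko_maps(producer)
            if not any(cat.get(m) == "non_metabolic" for m in u_maps):
                continue
            if not any(cat.get(m) == "metabolic" for m in p_maps):
                continue
            for c in compounds:
                triples.append((uptake, c, producer))
    return triples


def classify_boundary(
    pairs: Sequence[AdjacentPair],
    graph: PathwayGraph,
    transporter_relations: Optional[Sequence[tuple[str, str, str]]] = None,
) -> list[AdjacentPair]:
    """Assign each pair a metabolic/boundary class.

    A pair is ``metabolic_nonmetabolic`` when it matches a
    (uptake, compound, producer) transporter relation through one of its own
    compounds; ``metabolic_metabolic`` when both KOs appear exclusively on
    metabolic-category maps; ``unclassified`` otherwise.
    """
    if transporter_relations is None:
        transporter_relations = derive_transporter_relations(graph)
    boundary: dict[tuple[str, str], set[str]] = {}
    for uptake, compound, producer in transporter_relations:
        if uptake == producer:
            continue
        key = tuple(sorted((uptake, producer)))
        boundary.setdefault(key, set()).add(compound)

    cat = graph.map_category
    out = []
    for pair in pairs:
        cls = PAIR_CLASS_UNCLASSIFIED
        shared = boundary.get(pair.key, set()) & pair.compounds
        if shared:
            cls = PAIR_CLASS_BOUNDARY
        else:
            maps_a = graph.ko_maps(pair.ko_a)
            maps_b = graph.ko_maps(pair.ko_b)
            if (
                maps_a
                and maps_b
                and all(cat.get(m) == "metabolic" for m in maps_a)
                and all(cat.get(m) == "metabolic" for m in maps_b)
            ):
                cls = PAIR_CLASS_METABOLIC
        out.append(replace(pair, pair_class=cls))
    return out


def module_edge_lookup(pair: AdjacentPair, modules: Sequence[ModuleDefinition]) -> str:
    """Classify a pair's compounds against module termini.

    Returns ``"edge"`` if any compound is a terminal (edge) compound of any
    module, else ``"non_edge"`` if any compound is internal to a module, else
    ``"absent"``.  A compound that is a terminus in one module and internal
    in another counts as edge: any module terminus can link modules.
    """
    any_edge = any(c in m.edge_compounds for m in modules for c in pair.compounds)
    if any_edge:
        return "edge"
    any_internal = any(c in m.internal_compounds for m in modules for c in pair.compounds)
    return "non_edge" if any_internal else "absent"


# ---------------------------------------------------------------------------
# Tabular I/O

EDGE_LIST_COLUMNS = ["ko_a", "ko_b", "compounds", "maps", "pair_class"]


def write_edge_list(graph: PathwayGraph, path: str | Path, pairs: Optional[Sequence[AdjacentPair]] = None) -> None:
    """Write the graph as a TSV edge list (compounds/maps semicolon-joined)."""
    classes = {p.key: p.pair_class for p in pairs} if pairs else {}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(EDGE_LIST_COLUMNS)
        for a, b, compounds, maps in graph.edge_records():
            w.writerow(
                [a, b, ";".join(sorted(compounds)), ";".join(sorted(maps)),
                 classes.get((a, b), PAIR_CLASS_UNCLASSIFIED)]
            )


def read_edge_list(path: str | Path, map_category: Optional[Mapping[str, str]] = None) -> PathwayGraph:
    """Re-read a TSV edge list into a PathwayGraph.

    Node map membership is recovered as the union of incident edge maps.
    """
    graph = nx.Graph()
    with open(path, newline="") as fh:
        r = csv.DictReader(fh, delimiter="\t")
        for row in r:
            a, b = row["ko_a"], row["ko_b"]
            compounds = {c for c in row["compounds"].split(";") if c}
            maps = {m for m in row["maps"].split(";") if m}
            for ko in (a, b):
                if ko not in graph:
                    graph.add_node(ko, maps=set())
                graph.nodes[ko]["maps"].update(maps)
            graph.add_edge(a, b, compounds=compounds, maps=maps)
    return PathwayGraph(graph=graph, map_category=dict(map_category or {}))


def read_modules_tsv(path: str | Path) -> list[ModuleDefinition]:
    """Read module definitions (columns: module_id, compound_id, role)."""
    edge: dict[str, set[str]] = {}
    internal: dict[str, set[str]] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            mid, cid, role = row["module_id"], row["compound_id"], row["role"]
            if mid not in edge:
                order.append(mid)
                edge[mid] = set()
                internal[mid] = set()
            if role == "edge":
                edge[mid].add(cid)
            elif role == "internal":
                internal[mid].add(cid)
            else:
                raise ValueError(f"unknown module compound role {role!r}")
    return [
        ModuleDefinition(mid, frozenset(edge[mid]), frozenset(internal[mid])) for mid in order
    ]


def write_modules_tsv(modules: Sequence[ModuleDefinition], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["module_id", "compound_id", "role"])
        for m in modules:
            for c in sorted(m.edge_compounds):
                w.writerow([m.module_id, c, "edge"])
            for c in sorted(m.internal_compounds):
                w.writerow([m.module_id, c, "internal"])
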