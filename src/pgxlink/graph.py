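"""Typed linked-data graph for pharmacogenomics: loading, identifier
mappings, equivalence merging, pair-node augmentation and edge-direction
normalization.

The graph holds three entity types (Gene, Drug, Phenotype), attribute-value
nodes (ATC-like drug classes, pathway-like gene annotations), artificial
gene-drug pair nodes, and the two class nodes (``associated`` /
``not_associated``) used to phrase link prediction as node classification.
Entities of the same type coming from different sources are related by
equivalence mappings inferred from shared identifiers.
"""

from __future__ import annotations

import json
import re
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import rdflib

from .labels import (
    ATTRIBUTE,
    CLASS,
    CLASS_ASSOCIATED,
    CLASS_NOT_ASSOCIATED,
    GENERIC,
    LITERAL_NS,
    PRED_HAS_CLASS,
    PRED_MAPPED_TO,
    PRED_PAIR_DRUG,
    PRED_PAIR_GENE,
    PAIR,
    URI_BASE,
    Label,
    Triple,
    pair_label,
)

Schema = Mapping[str, str]  # namespace -> node type


@dataclass(frozen=True)
class EntityMapping:
    """A declared equivalence between two same-type nodes from different
    namespaces. Stored with endpoints in sorted order so the relation is
    symmetric by construction."""

    left: Label
    right: Label
    method: str = "shared_identifier"

    def __post_init__(self) -> None:
        if self.right < self.left:
            left, right = self.right, self.left
            object.__setattr__(self, "left", left)
            object.__setattr__(self, "right", right)


@dataclass
class LoadReport:
    node_counts: Dict[str, int] = field(default_factory=dict)
    n_edges: int = 0
    n_untyped: int = 0
    n_mappings: int = 0
    warnings: List[str] = field(default_factory=list)

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


class PGxGraph:
    """Edge-labeled directed multigraph with typed nodes.

    ``edges`` is a multiset (parallel edges allowed); ``mappings`` records
    declared equivalences between nodes.
    """

    def __init__(self) -> None:
        self.node_types: Dict[Label, str] = {}
        self.edges: List[Triple] = []
        self.mappings: Set[EntityMapping] = set()
        self._out: Optional[Dict[Label, List[Triple]]] = None
        self._in: Optional[Dict[Label, List[Triple]]] = None

    # -- construction -------------------------------------------------

    def add_node(self, label: Label, node_type: str = GENERIC) -> None:
        existing = self.node_types.get(label)
        if existing is None or existing == GENERIC:
            self.node_types[label] = node_type
        elif node_type not in (GENERIC, existing):
            raise ValueError(f"node {label} already typed {existing}, refusing {node_type}")

    def add_edge(self, subject: Label, predicate: Label, obj: Union[Label, str]) -> None:
        """Add one edge. A literal object becomes an attribute-value node."""
        if isinstance(obj, str):
            obj = Label(LITERAL_NS, obj)
            self.add_node(obj, ATTRIBUTE)
        if subject not in self.node_types:
            self.add_node(subject)
        if obj not in self.node_types:
            self.add_node(obj)
        self.edges.append(Triple(subject, predicate, obj))
        self._out = self._in = None

    def remove_edges(self, keep) -> None:
        self.edges = [e for e in self.edges if keep(e)]
        self._out = self._in = None

    def remove_node(self, label: Label) -> None:
        self.remove_edges(lambda e: e.subject != label and e.obj != label)
        self.node_types.pop(label, None)

    # -- queries -------------------------------------------------------

    def _index(self) -> None:
        out: Dict[Label, List[Triple]] = defaultdict(list)
        inn: Dict[Label, List[Triple]] = defaultdict(list)
        for e in self.edges:
            out[e.subject].append(e)
            inn[e.obj].append(e)
        self._out, self._in = out, inn

    def out_edges(self, node: Label) -> List[Triple]:
        if self._out is None:
            self._index()
        return self._out.get(node, [])

    def in_edges(self, node: Label) -> List[Triple]:
        if self._in is None:
            self._index()
        return self._in.get(node, [])

    def nodes_of_type(self, node_type: str) -> List[Label]:
        return sorted(l for l, t in self.node_types.items() if t == node_type)

    def type_counts(self) -> Dict[str, int]:
        return dict(Counter(self.node_types.values()))

    @property
    def n_nodes(self) -> int:
        return len(self.node_types)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def equivalence_class(self, node: Label) -> Set[Label]:
        """Closure of ``node`` under declared mappings and mapped_to edges."""
        neigh: Dict[Label, Set[Label]] = defaultdict(set)
        for m in self.mappings:
            neigh[m.left].add(m.right)
            neigh[m.right].add(m.left)
        for e in self.edges:
            if e.predicate == PRED_MAPPED_TO and isinstance(e.obj, Label):
                neigh[e.subject].add(e.obj)
                neigh[e.obj].add(e.subject)
        seen = {node}
        stack = [node]
        while stack:
            for nxt in neigh[stack.pop()]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return seen

    # -- copying / equality -------------------------------------------

    def copy(self) -> "PGxGraph":
        g = PGxGraph()
        g.node_types = dict(self.node_types)
        g.edges = list(self.edges)
        g.mappings = set(self.mappings)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PGxGraph):
            return NotImplemented
        return (
            self.node_types == other.node_types
            and sorted(self.edges) == sorted(other.edges)
            and self.mappings == other.mappings
        )


# -- serialization -----------------------------------------------------


def uri_to_label(uri: str) -> Label:
    """Extract a ``namespace:local_id`` label from a resource URI.

    The namespace is the second-to-last path segment, the local id the
    last; this convention covers both the package's own URI base and
    typical source-style URIs (``.../clinvar/1956``).
    """
    m = re.match(r"^.*?([^/#]+)[/#]([^/#]+)$", uri)
    if not m:
        raise ValueError(f"cannot derive a namespace:local_id label from URI {uri!r}")
    return Label(m.group(1), m.group(2))


_RDF_FORMATS = {".nt": "nt", ".ttl": "turtle"}

RDF_TYPE_URI = "http://www.w3.org/1999/02/22-rdf-syntax-ns#type"
TYPE_NS = "nodetype"  # rdf:type objects live under <URI_BASE>nodetype/<Type>


def load_graph(paths: Sequence[Union[str, Path]], schema: Schema) -> Tuple[PGxGraph, LoadReport]:
    """Parse N-Triples / Turtle files into a typed graph.

    Nodes are typed by matching their namespace against ``schema``;
    namespaces absent from the schema are kept with the generic type and
    counted in the report. Blank nodes are rejected: the schema has no
    use for them.
    """
    g = PGxGraph()
    report = LoadReport()
    unknown_ns: Counter = Counter()
    for path in paths:
        path = Path(path)
        fmt = _RDF_FORMATS.get(path.suffix.lower(), "nt")
        rg = rdflib.Graph()
        try:
            rg.parse(str(path), format=fmt)
        except Exception as exc:  # rdflib reports the offending line
            raise ValueError(f"unparseable triple file {path}: {exc}") from exc
        for s, p, o in rg:
            if isinstance(s, rdflib.BNode) or isinstance(o, rdflib.BNode):
                raise ValueError(f"blank node in {path}; the data schema does not use blank nodes")
            subj = uri_to_label(str(s))
            if str(p) == RDF_TYPE_URI:
                # explicit node-type declaration, not a data edge
                g.add_node(subj, uri_to_label(str(o)).local_id)
                continue
            pred = uri_to_label(str(p))
            _type_node(g, subj, schema, unknown_ns)
            if isinstance(o, rdflib.Literal):
                g.add_edge(subj, pred, str(o))
            else:
                obj = uri_to_label(str(o))
                _type_node(g, obj, schema, unknown_ns)
                g.add_edge(subj, pred, obj)
    for ns, n in sorted(unknown_ns.items()):
        report.warnings.append(f"namespace {ns!r} not in schema: {n} node(s) kept generic")
        warnings.warn(f"namespace {ns!r} not declared in schema; nodes kept generic")
    report.node_counts = g.type_counts()
    report.n_edges = g.n_edges
    report.n_untyped = report.node_counts.get(GENERIC, 0)
    return g, report


def _type_node(g: PGxGraph, label: Label, schema: Schema, unknown: Counter) -> None:
    node_type = schema.get(label.namespace)
    if node_type is None:
        if label not in g.node_types:
            unknown[label.namespace] += 1
        g.add_node(label, GENERIC)
    else:
        g.add_node(label, node_type)


def write_graph(g: PGxGraph, path: Union[str, Path]) -> None:
    """Serialize to N-Triples (sorted, deterministic).

    Node types are written as rdf:type statements so isolated nodes and
    their typing survive the round trip; :func:`load_graph` reads them
    back without counting them as data edges."""
    lines = []
    for e in sorted(g.edges):
        if isinstance(e.obj, Label) and e.obj.namespace == LITERAL_NS:
            obj = rdflib.Literal(e.obj.local_id).n3()
        else:
            obj = f"<{e.obj.uri()}>"
        lines.append(f"<{e.subject.uri()}> <{e.predicate.uri()}> {obj} .")
    for node, t in sorted(g.node_types.items()):
        lines.append(f"<{node.uri()}> <{RDF_TYPE_URI}> <{URI_BASE}{TYPE_NS}/{t}> .")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# -- mappings ----------------------------------------------------------


def infer_mappings(g: PGxGraph, extractors: Mapping[str, str]) -> Set[EntityMapping]:
    """Infer equivalences from shared identifiers.

    ``extractors`` maps a namespace to a regular expression with one
    capture group; the expression is applied to each node's rendered
    label. Two same-type nodes from different namespaces whose extracted
    identifiers are string-equal are declared equivalent.
    """
    by_id: Dict[Tuple[str, str], List[Label]] = defaultdict(list)
    hits: Counter = Counter()
    for node in sorted(g.node_types):
        pattern = extractors.get(node.namespace)
        if pattern is None:
            continue
        hits.setdefault(node.namespace, 0)
        m = re.search(pattern, str(node))
        if m is None:
            continue
        hits[node.namespace] += 1
        by_id[(g.node_types[node], m.group(1))].append(node)
    for ns, n in hits.items():
        if n == 0:
            warnings.warn(f"extractor for namespace {ns!r} matched 0 nodes")
    out: Set[EntityMapping] = set()
    for nodes in by_id.values():
        for i, a in enumerate(nodes):
            for b in nodes[i + 1 :]:
                if a.namespace != b.namespace:
                    out.add(EntityMapping(a, b))
    return out


IDENTITY_EXTRACTOR = r":(.+)$"  # whole local id is the shared identifier


def merge_equivalents(g: PGxGraph, mappings: Iterable[EntityMapping], mode: str = "edge") -> PGxGraph:
    """Apply equivalence mappings.

    mode="edge" (default): add a symmetric ``mapped_to`` edge per pair,
    preserving provenance so kernel walks can traverse the mapping.
    mode="contract": replace each equivalence class by its canonical
    (smallest) member and rewire all edges; the multiset of non-mapping
    edges is conserved.
    """
    mappings = list(mappings)
    missing = sorted(
        {m.left for m in mappings if m.left not in g.node_types}
        | {m.right for m in mappings if m.right not in g.node_types}
    )
    if missing:
        raise ValueError(f"mappings reference missing nodes: {', '.join(map(str, missing))}")
    for m in mappings:
        if g.node_types[m.left] != g.node_types[m.right]:
            raise ValueError(f"mapping {m.left}~{m.right} joins different node types")
    out = g.copy()
    if mode == "edge":
        for m in sorted(mappings, key=lambda m: (m.left, m.right)):
            out.add_edge(m.left, PRED_MAPPED_TO, m.right)
            out.add_edge(m.right, PRED_MAPPED_TO, m.left)
            out.mappings.add(m)
        return out
    if mode != "contract":
        raise ValueError(f"unknown merge mode {mode!r}")

    parent: Dict[Label, Label] = {}

    def find(x: Label) -> Label:
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    for m in mappings:
        ra, rb = find(m.left), find(m.right)
        if ra != rb:
            lo, hi = sorted((ra, rb))
            parent[hi] = lo
    canon = {n: find(n) for n in g.node_types}
    merged = PGxGraph()
    for n, t in sorted(g.node_types.items()):
        merged.add_node(canon[n], t)
    for e in g.edges:
        if e.predicate == PRED_MAPPED_TO:
            continue
        merged.add_edge(canon[e.subject], e.predicate, canon[e.obj])
    return merged


# -- pair nodes and directions ----------------------------------------


def add_pair_nodes(g: PGxGraph, pairs: Sequence) -> PGxGraph:
    """Augment the graph with one artificial node per gene-drug pair.

    Each pair node carries two outgoing structural edges, to its gene and
    to its drug; labeled training pairs get a third edge to the matching
    class node. Re-adding an existing pair is a no-op.
    """
    out = g.copy()
    for p in pairs:
        if p.gene not in out.node_types or p.drug not in out.node_types:
            raise ValueError(f"pair {p.gene}-{p.drug} references absent gene or drug")
        node = pair_label(p.gene, p.drug)
        if node in out.node_types:
            continue
        out.add_node(node, PAIR)
        out.add_edge(node, PRED_PAIR_GENE, p.gene)
        out.add_edge(node, PRED_PAIR_DRUG, p.drug)
        label = getattr(p, "label", "unknown")
        if label == "associated":
            out.add_node(CLASS_ASSOCIATED, CLASS)
            out.add_edge(node, PRED_HAS_CLASS, CLASS_ASSOCIATED)
        elif label == "not_associated":
            out.add_node(CLASS_NOT_ASSOCIATED, CLASS)
            out.add_edge(node, PRED_HAS_CLASS, CLASS_NOT_ASSOCIATED)
    return out


def remove_pair_nodes(g: PGxGraph) -> PGxGraph:
    """Inverse of :func:`add_pair_nodes` (also drops orphaned class nodes)."""
    out = g.copy()
    pair_nodes = {n for n, t in out.node_types.items() if t == PAIR}
    out.remove_edges(lambda e: e.subject not in pair_nodes and e.obj not in pair_nodes)
    for n in pair_nodes:
        del out.node_types[n]
    for cls in (CLASS_ASSOCIATED, CLASS_NOT_ASSOCIATED):
        if cls in out.node_types and not out.out_edges(cls) and not out.in_edges(cls):
            del out.node_types[cls]
    return out


def normalize_directions(g: PGxGraph, inversion_rules: Iterable[Label]) -> PGxGraph:
    """Reverse every edge whose predicate is listed, renaming the
    predicate ``<p>_inv``; all other edges are untouched. Applying twice
    (with the renamed predicates) restores an isomorphic graph."""
    rules = set(inversion_rules)
    out = g.copy()
    new_edges = []
    for e in out.edges:
        if e.predicate in rules:
            if not isinstance(e.obj, Label):
                raise ValueError(f"cannot invert literal-valued edge {e}")
            inv = Label(e.predicate.namespace, e.predicate.local_id + "_inv")
            new_edges.append(Triple(e.obj, inv, e.subject))
        else:
            new_edges.append(e)
    out.edges = new_edges
    out._out = out._in = None
    return out
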