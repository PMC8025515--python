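"""Ontology snapshots, gene annotations, and DAG closure queries.

The central objects are :class:`OntologyGraph` — a versioned, typed DAG of
terms connected by ``is_a`` / ``part_of`` edges, with obsolete terms retained
but excluded from traversal — and :class:`AnnotationTable`, which stores
*direct* gene-to-term annotations only.  Annotation propagation along the
true-path rule (a gene annotated to a term is implicitly annotated to every
ancestor; equivalently a term's gene set includes the genes of all its
descendants) happens at query time via :func:`annotated_genes`, which keeps
swapping ontology versions cheap.

Edges point child -> parent, the convention used by ``obonet``.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, TextIO

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: Relations traversed by default.  part_of is included because standard
#: descendant-closure services (e.g. QuickGO) include it in their default
#: closure; every query accepts an explicit relation set.
DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})

NAMESPACES = ("biological_process", "molecular_function", "cellular_component", "other")


class OboParseError(ValueError):
    """Raised for malformed OBO input; carries the offending line number."""


class OntologyIntegrityError(ValueError):
    """Raised when a parsed ontology violates structural invariants (e.g. a cycle)."""


class ObsoleteTermError(KeyError):
    """Raised when a closure query is anchored on an obsolete term."""


@dataclass(frozen=True)
class OntologyTerm:
    """A single ontology term.

    Parameters
    ----------
    term_id : accession string, e.g. ``"GO:0045786"``.
    name : human-readable label.
    namespace : one of biological_process / molecular_function /
        cellular_component / other.
    obsolete : retired terms are kept in the graph (version diffing needs
        them) but carry no edges and are refused as query anchors.
    replaced_by : accession of the replacement term, if any.
    """

    term_id: str
    name: str = ""
    namespace: str = "biological_process"
    obsolete: bool = False
    replaced_by: str | None = None

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            object.__setattr__(self, "namespace", "other")


class OntologyGraph:
    """A versioned DAG of ontology terms with typed child->parent edges."""

    def __init__(self, version_label: str = "unversioned") -> None:
        self.version_label = version_label
        self.terms: dict[str, OntologyTerm] = {}
        self.alt_ids: dict[str, str] = {}
        # MultiDiGraph keyed by relation; holds only non-obsolete terms.
        self._g = nx.MultiDiGraph()

    # -- construction -------------------------------------------------

    def add_term(self, term: OntologyTerm) -> None:
        if term.term_id in self.terms:
            raise OntologyIntegrityError(f"duplicate term id {term.term_id!r}")
        self.terms[term.term_id] = term
        if not term.obsolete:
            self._g.add_node(term.term_id)

    def add_edge(self, child: str, parent: str, relation: str = "is_a") -> None:
        if child == parent:
            raise OntologyIntegrityError(f"self-edge on {child!r}")
        for t in (child, parent):
            if t not in self.terms:
                raise OntologyIntegrityError(f"edge endpoint {t!r} is not a known term")
            if self.terms[t].obsolete:
                raise OntologyIntegrityError(f"edge endpoint {t!r} is obsolete")
        self._g.add_edge(child, parent, key=relation)

    def validate(self) -> None:
        """Check acyclicity; raise :class:`OntologyIntegrityError` naming one cycle."""
        if not nx.is_directed_acyclic_graph(self._g):
            cycle = nx.find_cycle(self._g)
            path = " -> ".join(str(e[0]) for e in cycle) + f" -> {cycle[-1][1]}"
            raise OntologyIntegrityError(f"ontology contains a cycle: {path}")

    # -- queries ------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def term(self, term_id: str) -> OntologyTerm:
        return self.terms[term_id]

    def resolve(self, term_id: str) -> str | None:
        """Map a (possibly merged alt_id) accession to its primary id, or None."""
        if term_id in self.terms:
            return term_id
        return self.alt_ids.get(term_id)

    def is_active(self, term_id: str) -> bool:
        return term_id in self.terms and not self.terms[term_id].obsolete

    @property
    def active_terms(self) -> set[str]:
        return {t for t, term in self.terms.items() if not term.obsolete}

    def edges(self) -> Iterator[tuple[str, str, str]]:
        """Yield (child, parent, relation) triples."""
        for child, parent, rel in self._g.edges(keys=True):
            yield child, parent, rel

    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def parent_edges(self, term_id: str) -> Iterator[tuple[str, str]]:
        """Yield (parent, relation) pairs for a term's outgoing edges."""
        for _, p, r in self._g.out_edges(term_id, keys=True):
            yield p, r

    def parents(self, term_id: str, relations: Iterable[str] = DEFAULT_RELATIONS) -> set[str]:
        rels = set(relations)
        return {p for _, p, r in self._g.out_edges(term_id, keys=True) if r in rels}

    def children(self, term_id: str, relations: Iterable[str] = DEFAULT_RELATIONS) -> set[str]:
        rels = set(relations)
        return {c for c, _, r in self._g.in_edges(term_id, keys=True) if r in rels}

    def roots(self) -> set[str]:
        return {t for t in self._g.nodes if self._g.out_degree(t) == 0}

    def copy(self, version_label: str | None = None) -> "OntologyGraph":
        out = OntologyGraph(version_label or self.version_label)
        out.terms = dict(self.terms)
        out.alt_ids = dict(self.alt_ids)
        out._g = self._g.copy()
        return out


@dataclass
class AnnotationTable:
    """Direct gene -> term annotations built against one graph version.

    ``entries`` holds only the direct annotations; the true-path closure is
    applied by :func:`annotated_genes` at query time.  Term ids that do not
    exist in the companion graph are kept aside in ``unknown_terms``.
    """

    entries: dict[str, set[str]] = field(default_factory=dict)
    graph_version: str = "unversioned"
    unknown_terms: set[str] = field(default_factory=set)
    _term_index: dict[str, set[str]] | None = field(default=None, repr=False, compare=False)

    def add(self, gene_id: str, term_id: str) -> None:
        if not gene_id:
            raise ValueError("empty gene id")
        self.entries.setdefault(gene_id, set()).add(term_id)
        self._term_index = None

    @property
    def genes(self) -> set[str]:
        return set(self.entries)

    def term_index(self) -> Mapping[str, set[str]]:
        """Inverted index term -> directly annotated genes (cached)."""
        if self._term_index is None:
            idx: dict[str, set[str]] = {}
            for g, terms in self.entries.items():
                for t in terms:
                    idx.setdefault(t, set()).add(g)
            self._term_index = idx
        return self._term_index

    def validate_against(self, graph: OntologyGraph) -> None:
        """Flag annotated term ids absent from the companion graph."""
        self.unknown_terms = {
            t for terms in self.entries.values() for t in terms if t not in graph
        }
        if self.unknown_terms:
            logger.warning(
                "%d annotated term id(s) are unknown in graph %s",
                len(self.unknown_terms), graph.version_label,
            )

    @classmethod
    def from_tsv(cls, source: str | TextIO, graph: OntologyGraph | None = None) -> "AnnotationTable":
        """Read a two-column (gene_id, term_id) TSV; '#' lines are comments."""
        table = cls(graph_version=graph.version_label if graph else "unversioned")
        with _opened(source) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2 or not parts[0] or not parts[1]:
                    raise ValueError(f"annotation TSV line {lineno}: expected gene_id<TAB>term_id")
                table.add(parts[0], parts[1])
        if graph is not None:
            table.validate_against(graph)
        return table

    @classmethod
    def from_gaf(cls, source: str | TextIO, graph: OntologyGraph | None = None) -> "AnnotationTable":
        """Read the (DB Object ID, GO ID) columns of a GAF 2.x file."""
        table = cls(graph_version=graph.version_label if graph else "unversioned")
        with _opened(source) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("!"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 5:
                    raise ValueError(f"GAF line {lineno}: fewer than 5 columns")
                table.add(parts[1], parts[4])
        if graph is not None:
            table.validate_against(graph)
        return table


def _opened(source: str | TextIO):
    if isinstance(source, str) and "\n" not in source:
        return open(source, "r", encoding="utf-8")
    if isinstance(source, str):
        return io.StringIO(source)
    # Already a file-like object; wrap so the caller's handle is not closed.
    return _NoCloseWrapper(source)


class _NoCloseWrapper:
    def __init__(self, fh: TextIO) -> None:
        self._fh = fh

    def __enter__(self) -> TextIO:
        return self._fh

    def __exit__(self, *exc) -> None:
        pass


# ---------------------------------------------------------------------------
# OBO parsing / writing
# ---------------------------------------------------------------------------

def _prescan_obo(text: str) -> None:
    """Light syntactic check so malformed stanza lines fail with a line number."""
    in_term = False
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("!")[0].strip()
        if not line:
            continue
        if line.startswith("["):
            if not line.endswith("]"):
                raise OboParseError(f"line {lineno}: unterminated stanza header {raw!r}")
            in_term = line == "[Term]"
            continue
        if in_term and ":" not in line:
            raise OboParseError(f"line {lineno}: malformed tag-value line {raw!r}")


def parse_obo(source: str | TextIO, version_label: str | None = None) -> OntologyGraph:
    """Parse OBO 1.2/1.4 text into an :class:`OntologyGraph`.

    Non-obsolete terms get their ``is_a`` and ``relationship: part_of`` edges;
    obsolete terms are retained with ``obsolete=True`` and zero edges.
    Acyclicity is verified; a cycle raises :class:`OntologyIntegrityError`
    listing one offending cycle.
    """
    if isinstance(source, str) and "\n" not in source:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    _prescan_obo(text)

    raw = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)
    label = version_label or str(raw.graph.get("data-version", "unversioned"))
    graph = OntologyGraph(version_label=label)

    for node, data in raw.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        replaced = data.get("replaced_by")
        graph.add_term(
            OntologyTerm(
                term_id=node,
                name=data.get("name", ""),
                namespace=data.get("namespace", "biological_process"),
                obsolete=obsolete,
                replaced_by=replaced[0] if replaced else None,
            )
        )
        for alt in data.get("alt_id", []):
            graph.alt_ids[alt] = node

    for child, parent, rel in raw.edges(keys=True):
        if rel not in ("is_a", "part_of"):
            continue  # regulates/occurs_in semantics are out of scope
        if graph.terms[child].obsolete or graph.terms[parent].obsolete:
            continue
        graph.add_edge(child, parent, rel)

    graph.validate()
    return graph


def write_obo(graph: OntologyGraph, stream: TextIO) -> None:
    """Serialize a graph back to OBO text (round-trips terms and typed edges)."""
    stream.write("format-version: 1.2\n")
    stream.write(f"data-version: {graph.version_label}\n")
    stream.write("ontology: hallmap\n\n")
    for term_id in sorted(graph.terms):
        term = graph.terms[term_id]
        stream.write("[Term]\n")
        stream.write(f"id: {term.term_id}\n")
        stream.write(f"name: {term.name or term.term_id}\n")
        stream.write(f"namespace: {term.namespace}\n")
        for alt, primary in sorted(graph.alt_ids.items()):
            if primary == term_id:
                stream.write(f"alt_id: {alt}\n")
        if term.obsolete:
            stream.write("is_obsolete: true\n")
            if term.replaced_by:
                stream.write(f"replaced_by: {term.replaced_by}\n")
        else:
            for child, parent, rel in sorted(graph.edges()):
                if child != term_id:
                    continue
                if rel == "is_a":
                    stream.write(f"is_a: {parent}\n")
                else:
                    stream.write(f"relationship: {rel} {parent}\n")
        stream.write("\n")


def write_node_edge_tsv(graph: OntologyGraph, node_stream: TextIO, edge_stream: TextIO) -> None:
    """Write a node table and an edge table for downstream network viewers."""
    node_stream.write("term_id\tname\tnamespace\tobsolete\treplaced_by\n")
    for term_id in sorted(graph.terms):
        t = graph.terms[term_id]
        node_stream.write(
            f"{t.term_id}\t{t.name}\t{t.namespace}\t{int(t.obsolete)}\t{t.replaced_by or ''}\n"
        )
    edge_stream.write("child\tparent\trelation\n")
    for child, parent, rel in sorted(graph.edges()):
        edge_stream.write(f"{child}\t{parent}\t{rel}\n")


# ---------------------------------------------------------------------------
# Closure queries
# ---------------------------------------------------------------------------

def descendants(
    graph: OntologyGraph,
    root: str,
    relations: Iterable[str] = DEFAULT_RELATIONS,
) -> set[str]:
    """All terms reachable from *root* against edge direction (its sub-hierarchy).

    The result is the transitive closure over the given relation set, root
    excluded.  Obsolete roots are refused: a retired term has no active
    sub-hierarchy and silently returning an empty set would mask the retirement.
    """
    if root not in graph:
        raise KeyError(f"unknown term {root!r} in graph {graph.version_label}")
    if graph.terms[root].obsolete:
        raise ObsoleteTermError(
            f"term {root!r} is obsolete in graph {graph.version_label}; "
            "closure queries require an active anchor"
        )
    rels = set(relations)
    out: set[str] = set()
    stack = [root]
    while stack:
        node = stack.pop()
        for child in graph.children(node, rels):
            if child not in out:
                out.add(child)
                stack.append(child)
    out.discard(root)
    return out


def annotated_genes(
    graph: OntologyGraph,
    annotations: AnnotationTable,
    term: str,
    relations: Iterable[str] = DEFAULT_RELATIONS,
) -> set[str]:
    """Genes annotated to *term* or any descendant (true-path rule at query time)."""
    if term not in graph:
        raise KeyError(f"unknown term {term!r} in graph {graph.version_label}")
    closure = {term} | descendants(graph, term, relations)
    idx = annotations.term_index()
    genes: set[str] = set()
    for t in closure:
        genes |= idx.get(t, set())
    return genes


def first_neighbor_subgraph(graph: OntologyGraph, seeds: Iterable[str]) -> OntologyGraph:
    """Subgraph induced on the seeds plus their direct parents and children.

    Edge types are retained and every edge of the parent graph between two
    included nodes is kept.  Unknown seeds are reported with a warning, not
    fatal; an empty seed set yields an empty graph with a warning.
    """
    seeds = set(seeds)
    unknown = {s for s in seeds if not graph.is_active(s)}
    if unknown:
        warnings.warn(f"{len(unknown)} seed term(s) absent from active graph: "
                      f"{sorted(unknown)[:5]}...", stacklevel=2)
    seeds -= unknown
    if not seeds:
        warnings.warn("empty seed set: returning an empty subgraph", stacklevel=2)
        return OntologyGraph(version_label=graph.version_label)

    keep = set(seeds)
    for s in seeds:
        keep |= graph.parents(s)
        keep |= graph.children(s)

    sub = OntologyGraph(version_label=graph.version_label)
    for t in keep:
        sub.add_term(graph.terms[t])
    for child, parent, rel in graph.edges():
        if child in keep and parent in keep:
            sub.add_edge(child, parent, rel)
    return sub
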