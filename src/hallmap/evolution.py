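"""Ontology version comparison: node classification and annotation drift.

Two ontology snapshots are compared through the lens of the term selections
made against each: around each selection a first-neighbour subgraph is built
in its own version, and every node of the combined view is classified into
exactly one category — selected in both, selected only by the older or only
by the newer scheme while available in both versions, obsoleted between the
versions, created after the older version, or an unselected neighbour.
Edge additions/removals within the compared subgraphs and per-term
annotation-count drift (with true-path closure inside each version) complete
the picture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import pandas as pd

from .ontology import (
    AnnotationTable,
    OntologyGraph,
    annotated_genes,
    first_neighbor_subgraph,
    DEFAULT_RELATIONS,
)

CATEGORIES = (
    "shared_selected_both",
    "shared_selected_only_old",
    "shared_selected_only_new",
    "obsoleted_in_new",
    "created_after_old",
    "neighbor_unselected",
)


@dataclass
class VersionDiff:
    """Per-term category assignment plus the typed edge diff of the subgraphs."""

    old_label: str
    new_label: str
    categories: dict[str, str] = field(default_factory=dict)
    edges_added: set[tuple[str, str, str]] = field(default_factory=set)
    edges_removed: set[tuple[str, str, str]] = field(default_factory=set)
    unresolved: set[str] = field(default_factory=set)

    def count(self, category: str) -> int:
        return sum(1 for c in self.categories.values() if c == category)

    def counts(self) -> dict[str, int]:
        return {cat: self.count(cat) for cat in CATEGORIES}


def _resolve_selection(graph_old: OntologyGraph, graph_new: OntologyGraph,
                       selected: Iterable[str], unresolved: set[str]) -> set[str]:
    """Map merged alt_ids to primary ids; ids unknown to both versions are reported."""
    out: set[str] = set()
    for term in selected:
        primary = graph_new.resolve(term) or graph_old.resolve(term)
        if primary is None:
            unresolved.add(term)
        else:
            out.add(primary)
    return out


def diff_versions(
    graph_old: OntologyGraph,
    graph_new: OntologyGraph,
    selected_old: Iterable[str],
    selected_new: Iterable[str],
) -> VersionDiff:
    """Classify the terms of two selections' first-neighbour subgraphs.

    A term counts as *available* in a version when it is present and not
    obsolete there; neighbours are taken from each version's active graph.
    The categories are mutually exclusive and cover the union node set.
    """
    if graph_old.version_label == graph_new.version_label:
        raise ValueError(
            f"both graphs carry version label {graph_old.version_label!r}; "
            "version diffing needs distinct labels"
        )
    diff = VersionDiff(old_label=graph_old.version_label, new_label=graph_new.version_label)
    sel_old = _resolve_selection(graph_old, graph_new, selected_old, diff.unresolved)
    sel_new = _resolve_selection(graph_old, graph_new, selected_new, diff.unresolved)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sub_old = first_neighbor_subgraph(graph_old, sel_old & graph_old.active_terms)
        sub_new = first_neighbor_subgraph(graph_new, sel_new & graph_new.active_terms)

    nodes = set(sub_old.terms) | set(sub_new.terms) | sel_old | sel_new
    for term in nodes:
        in_old = graph_old.is_active(term)
        in_new = graph_new.is_active(term)
        if term in sel_old and not in_new:
            category = "obsoleted_in_new"
        elif term in sel_new and not in_old:
            category = "created_after_old"
        elif term in sel_old and term in sel_new:
            category = "shared_selected_both"
        elif term in sel_old:
            category = "shared_selected_only_old"
        elif term in sel_new:
            category = "shared_selected_only_new"
        else:
            category = "neighbor_unselected"
        diff.categories[term] = category

    edges_old = set(sub_old.edges())
    edges_new = set(sub_new.edges())
    diff.edges_added = edges_new - edges_old
    diff.edges_removed = edges_old - edges_new
    return diff


def annotation_count_drift(
    graph_old: OntologyGraph,
    annotations_old: AnnotationTable,
    graph_new: OntologyGraph,
    annotations_new: AnnotationTable,
    terms: Sequence[str],
    relations: Iterable[str] = DEFAULT_RELATIONS,
) -> pd.DataFrame:
    """Per-term annotated-gene counts in each version, with descendant closure.

    Terms missing or obsolete in a version get a null count there (not zero:
    absence of the term is not absence of annotation); ``delta`` is null
    whenever either side is.
    """
    rows = []
    for term in terms:
        row: dict[str, object] = {"term_id": term}
        for tag, graph, ann in (("old", graph_old, annotations_old),
                                ("new", graph_new, annotations_new)):
            primary = graph.resolve(term)
            if primary is None or not graph.is_active(primary):
                row[f"count_{tag}"] = pd.NA
            else:
                row[f"count_{tag}"] = len(annotated_genes(graph, ann, primary, relations))
        if pd.isna(row["count_old"]) or pd.isna(row["count_new"]):
            row["delta"] = pd.NA
        else:
            row["delta"] = row["count_new"] - row["count_old"]
        rows.append(row)
    return pd.DataFrame(rows, columns=["term_id", "count_old", "count_new", "delta"]).astype(
        {"count_old": "Int64", "count_new": "Int64", "delta": "Int64"}
    )


def write_diff_tsv(diff: VersionDiff, node_stream: TextIO, edge_stream: TextIO) -> None:
    """Node-classification and edge-diff tables for generic network viewers."""
    node_stream.write("term_id\tcategory\n")
    for term in sorted(diff.categories):
        node_stream.write(f"{term}\t{diff.categories[term]}\n")
    edge_stream.write("child\tparent\trelation\tchange\n")
    for child, parent, rel in sorted(diff.edges_added):
        edge_stream.write(f"{child}\t{parent}\t{rel}\tadded\n")
    for child, parent, rel in sorted(diff.edges_removed):
        edge_stream.write(f"{child}\t{parent}\t{rel}\tremoved\n")
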