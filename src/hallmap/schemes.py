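"""Hallmark vocabulary, mapping schemes, and hallmark gene-set construction.

A *mapping scheme* is a published association between the ten hallmarks of
cancer (Hanahan & Weinberg 2011) and either ontology terms (GO-style schemes)
or biological-pathway gene lists (pathway-style schemes).  The genes annotated
— directly or through descendant terms — to any term a scheme selects form
that scheme's *hallmark genes*.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import pandas as pd

from .ontology import AnnotationTable, OntologyGraph, annotated_genes, DEFAULT_RELATIONS

logger = logging.getLogger(__name__)

#: The ten canonical hallmarks, in their conventional order.
HALLMARKS: tuple[str, ...] = (
    "sustaining proliferative signaling",
    "evading growth suppressor",
    "resisting cell death",
    "enabling replicative immortality",
    "inducing angiogenesis",
    "activating invasion and metastasis",
    "genome instability and mutation",
    "tumor promoting inflammation",
    "deregulating cellular energetic",
    "avoiding immune destruction",
)

# Spelling variants seen across publications, already in normalized form.
_EXTRA_ALIASES = {
    "evading growth suppressors": "evading growth suppressor",
    "sustained proliferative signaling": "sustaining proliferative signaling",
    "sustaining proliferative signalling": "sustaining proliferative signaling",
    "enabling replicative signaling": "enabling replicative immortality",
    "replicative immortality": "enabling replicative immortality",
    "angiogenesis": "inducing angiogenesis",
    "inducing angiogenesis": "inducing angiogenesis",
    "invasion and metastasis": "activating invasion and metastasis",
    "genome instability": "genome instability and mutation",
    "genomic instability and mutation": "genome instability and mutation",
    "tumour promoting inflammation": "tumor promoting inflammation",
    "deregulating cellular energetics": "deregulating cellular energetic",
    "deregulated cellular energetics": "deregulating cellular energetic",
    "avoiding immune destruction": "avoiding immune destruction",
    "evading immune destruction": "avoiding immune destruction",
}


class UnknownHallmarkError(ValueError):
    pass


def _normalize(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", " ", name.lower()).strip()


def canonical_hallmark(name: str) -> str:
    """Resolve a hallmark spelling variant to its canonical form.

    Matching is case/punctuation-insensitive, consults an alias table, and
    falls back to per-word singularization (``suppressors`` -> ``suppressor``)
    so trivially pluralized variants resolve without an explicit alias entry.
    """
    norm = _normalize(name)
    if norm in HALLMARKS:
        return norm
    if norm in _EXTRA_ALIASES:
        return _EXTRA_ALIASES[norm]
    singular = " ".join(w[:-1] if w.endswith("s") and len(w) > 3 else w for w in norm.split())
    if singular in HALLMARKS:
        return singular
    if singular in _EXTRA_ALIASES:
        return _EXTRA_ALIASES[singular]
    raise UnknownHallmarkError(f"unresolvable hallmark name {name!r}")


@dataclass
class MappingScheme:
    """One published hallmark mapping.

    ``ontology_terms`` schemes map hallmarks to term accessions; a
    ``pathway_genes`` scheme carries a hallmark-independent gene list (pathway
    schemes participate only in union-level comparisons unless a separate
    pathway-to-term correspondence converts them).
    """

    scheme_id: str
    source_kind: str = "ontology_terms"  # or "pathway_genes"
    selections: dict[str, set[str]] = field(default_factory=dict)
    gene_list: set[str] = field(default_factory=set)

    @property
    def hallmarks_covered(self) -> set[str]:
        return {h for h, terms in self.selections.items() if terms}

    @property
    def all_terms(self) -> set[str]:
        out: set[str] = set()
        for terms in self.selections.values():
            out |= terms
        return out


@dataclass
class HallmarkGeneSets:
    """Per-hallmark gene sets for one scheme, plus their union (hallmark genes)."""

    scheme_id: str
    per_hallmark: dict[str, set[str]] = field(default_factory=dict)
    union: set[str] = field(default_factory=set)
    skipped_terms: list[tuple[str, str, str]] = field(default_factory=list)  # (hallmark, term, reason)


def load_scheme(
    table: pd.DataFrame | Iterable[Sequence[str]] | str | TextIO,
    scheme_id: str | None = None,
) -> MappingScheme:
    """Build an ontology-kind scheme from (hallmark, term_id) rows.

    Accepts a DataFrame with columns ``hallmark``/``term_id`` (an optional
    ``scheme_id`` column is honoured), an iterable of rows, or TSV text/path
    with those columns.  Duplicate rows are deduplicated with a warning;
    unresolvable hallmark names raise, naming the offending row.
    """
    df = _coerce_table(table, ("hallmark", "term_id"))
    if scheme_id is None:
        scheme_id = str(df["scheme_id"].iloc[0]) if "scheme_id" in df.columns and len(df) else "scheme"

    scheme = MappingScheme(scheme_id=scheme_id, source_kind="ontology_terms")
    seen: set[tuple[str, str]] = set()
    dups = 0
    for i, row in df.iterrows():
        try:
            hallmark = canonical_hallmark(str(row["hallmark"]))
        except UnknownHallmarkError as exc:
            raise UnknownHallmarkError(f"row {i}: {exc}") from exc
        term = str(row["term_id"]).strip()
        if (hallmark, term) in seen:
            dups += 1
            continue
        seen.add((hallmark, term))
        scheme.selections.setdefault(hallmark, set()).add(term)
    if dups:
        logger.warning("scheme %s: %d duplicate (hallmark, term) row(s) dropped", scheme_id, dups)
    return scheme


def pathway_scheme_genes(
    table: pd.DataFrame | Iterable[Sequence[str]] | str | TextIO,
    scheme_id: str = "PW1",
) -> HallmarkGeneSets:
    """Hallmark genes of a pathway-kind scheme: union only, one gene per row.

    Pathway schemes whose authors did not state which pathway maps to which
    hallmark deliberately get no per-hallmark sets — inferring the assignment
    would be an interpretation, not a reuse, of the published mapping.
    """
    df = _coerce_table(table, ("gene_id",))
    genes = {str(g).strip() for g in df["gene_id"] if str(g).strip()}
    if not genes:
        raise ValueError(f"pathway scheme {scheme_id}: empty gene list")
    return HallmarkGeneSets(scheme_id=scheme_id, per_hallmark={}, union=genes)


def build_hallmark_gene_sets(
    scheme: MappingScheme,
    graph: OntologyGraph,
    annotations: AnnotationTable,
    relations: Iterable[str] = DEFAULT_RELATIONS,
) -> HallmarkGeneSets:
    """Per-hallmark gene sets: union over selected terms of the descendant-closed
    annotation sets.  Obsolete or unknown selected terms are skipped and
    reported, never silently dropped."""
    if scheme.source_kind != "ontology_terms":
        raise ValueError(f"scheme {scheme.scheme_id} is not ontology-kind")
    result = HallmarkGeneSets(scheme_id=scheme.scheme_id)
    rels = set(relations)
    for hallmark, terms in scheme.selections.items():
        genes: set[str] = set()
        for term in sorted(terms):
            resolved = graph.resolve(term)
            if resolved is None:
                result.skipped_terms.append((hallmark, term, "unknown"))
                continue
            if graph.terms[resolved].obsolete:
                result.skipped_terms.append((hallmark, term, "obsolete"))
                continue
            genes |= annotated_genes(graph, annotations, resolved, rels)
        result.per_hallmark[hallmark] = genes
        result.union |= genes
    if result.skipped_terms:
        logger.warning(
            "scheme %s: skipped %d selected term(s): %s",
            scheme.scheme_id, len(result.skipped_terms), result.skipped_terms[:5],
        )
    return result


def _coerce_table(
    table: pd.DataFrame | Iterable[Sequence[str]] | str | TextIO,
    columns: tuple[str, ...],
) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        df = table
    elif isinstance(table, str) or hasattr(table, "read"):
        import io as _io

        src = _io.StringIO(table) if isinstance(table, str) and "\n" in table else table
        df = pd.read_csv(src, sep="\t", dtype=str, comment="#")
    else:
        df = pd.DataFrame(list(table))
        if df.shape[1] == len(columns):
            df.columns = list(columns)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"table is missing required column(s): {missing}")
    return df
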