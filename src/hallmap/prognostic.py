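"""Prognostic-hallmark genes, cancer-type subgroup partitions, and Jaccard comparisons.

A gene that is both prognostic for a cancer type and in a scheme's hallmark
gene union is a *prognostic-hallmark gene*.  Genes are partitioned by the
exact combination of cancer types where they carry that label (a gene
prognostic-hallmark in three cancers belongs only to that three-cancer
combination, not to its sub-combinations); small subgroups are excluded; and
schemes are compared subgroup-by-subgroup with the Jaccard index, scoring 0
when a subgroup exists in only one of the two schemes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

logger = logging.getLogger(__name__)

#: cancer_type -> set of prognostic gene ids
PrognosticTable = dict[str, set[str]]


def load_prognostic_tsv(source: str | TextIO) -> PrognosticTable:
    """Read a (cancer_type, gene_id) TSV into a PrognosticTable."""
    import io

    src = io.StringIO(source) if isinstance(source, str) and "\n" in source else source
    df = pd.read_csv(src, sep="\t", dtype=str, comment="#")
    missing = [c for c in ("cancer_type", "gene_id") if c not in df.columns]
    if missing:
        raise ValueError(f"prognostic table is missing column(s): {missing}")
    table: PrognosticTable = {}
    for cancer, sub in df.groupby("cancer_type"):
        table[str(cancer)] = set(sub["gene_id"].astype(str))
    return table


@dataclass
class SubgroupTable:
    """Per-scheme partition of prognostic-hallmark genes by cancer-type combination."""

    scheme_id: str
    groups: dict[frozenset[str], set[str]] = field(default_factory=dict)
    min_size: int = 5
    excluded: dict[frozenset[str], int] = field(default_factory=dict)

    @property
    def combinations(self) -> set[frozenset[str]]:
        return set(self.groups)


def prognostic_hallmark_genes(
    hallmark_union: Iterable[str],
    prognostic: PrognosticTable,
) -> dict[str, set[str]]:
    """Per cancer type, the prognostic genes that are also hallmark genes."""
    union = set(hallmark_union)
    if not union or not prognostic:
        raise ValueError("hallmark union and prognostic table must be non-empty")
    return {cancer: genes & union for cancer, genes in prognostic.items()}


def subgroup_partition(
    per_cancer: Mapping[str, Iterable[str]],
    min_size: int = 5,
    scheme_id: str = "scheme",
) -> SubgroupTable:
    """Assign each gene to the combination equal to its exact cancer-type signature.

    Combinations with fewer than ``min_size`` genes are dropped and logged
    (their sizes are retained in ``excluded`` for the report).
    """
    if not per_cancer:
        raise ValueError("need at least one cancer type")
    signature: dict[str, set[str]] = {}
    for cancer, genes in per_cancer.items():
        for g in genes:
            signature.setdefault(g, set()).add(cancer)
    groups: dict[frozenset[str], set[str]] = {}
    for gene, cancers in signature.items():
        groups.setdefault(frozenset(cancers), set()).add(gene)
    table = SubgroupTable(scheme_id=scheme_id, min_size=min_size)
    for combo, genes in groups.items():
        if len(genes) >= min_size:
            table.groups[combo] = genes
        else:
            table.excluded[combo] = len(genes)
    if table.excluded:
        logger.info(
            "scheme %s: excluded %d subgroup(s) below min_size=%d",
            scheme_id, len(table.excluded), min_size,
        )
    return table


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """|a ∩ b| / |a ∪ b|; undefined (error) when both sets are empty."""
    sa, sb = set(a), set(b)
    if not sa and not sb:
        raise ValueError("Jaccard index is undefined for two empty sets")
    return len(sa & sb) / len(sa | sb)


def pairwise_scheme_similarity(tables: Sequence[SubgroupTable]) -> pd.DataFrame:
    """Jaccard of each cancer-type combination across every scheme pair.

    Every combination retained by at least one scheme is included; a pair in
    which one scheme lacks the combination scores 0.  Returns a long-format
    frame with columns (combination, scheme_a, scheme_b, jaccard).
    """
    if len(tables) < 2:
        raise ValueError("need subgroup tables for at least 2 schemes")
    combos: set[frozenset[str]] = set()
    for t in tables:
        combos |= t.combinations
    rows = []
    for combo in sorted(combos, key=lambda c: (len(c), sorted(c))):
        label = "&".join(sorted(combo))
        for i, ta in enumerate(tables):
            for tb in tables[i + 1:]:
                ga = ta.groups.get(combo)
                gb = tb.groups.get(combo)
                score = jaccard(ga, gb) if ga and gb else 0.0
                rows.append(
                    {"combination": label, "scheme_a": ta.scheme_id,
                     "scheme_b": tb.scheme_id, "jaccard": score}
                )
    return pd.DataFrame(rows, columns=["combination", "scheme_a", "scheme_b", "jaccard"])
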