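"""Reproduce the published comparison counts from the study's own tables.

The original comparison of hallmark mapping schemes distributed its inputs
as supplementary tables: the per-scheme term selections, the per-scheme
hallmark gene lists, the pathway scheme's gene list, the prognostic gene
lists for 17 cancer types, and a pathway-to-term correspondence table.
Given a directory holding those tables in the TSV dialects this package
reads, :func:`reproduce_study_counts` recomputes the headline numbers
(core gene intersection, per-scheme unique genes and unique-term fractions,
full-agreement terms, prognostic-hallmark totals, consensus term count)
with the same set operations the synthetic pipeline is tested on.

Expected files under the data directory::

    scheme_terms.tsv      scheme_id, hallmark, term_id     (term selections)
    hallmark_genes.tsv    scheme_id, gene_id               (per-scheme unions)
    pathway_genes.tsv     gene_id                          (pathway scheme list)
    prognostic.tsv        cancer_type, gene_id             (17 cancer types)
    correspondence.tsv    hallmark, term_id                (pathway-derived terms)
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .prognostic import load_prognostic_tsv, prognostic_hallmark_genes
from .schemes import MappingScheme, load_scheme, pathway_scheme_genes
from .setcomp import (
    consensus_terms,
    exclusive_intersections,
    term_selection_frequency,
    unique_term_fraction,
)

REQUIRED_FILES = (
    "scheme_terms.tsv",
    "hallmark_genes.tsv",
    "pathway_genes.tsv",
    "prognostic.tsv",
    "correspondence.tsv",
)


def reproduce_study_counts(data_dir: str | Path) -> dict:
    """Headline counts of the mapping-scheme comparison, from its own tables."""
    data_dir = Path(data_dir)
    missing = [f for f in REQUIRED_FILES if not (data_dir / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"study tables missing under {data_dir}: {missing}; these are the "
            "published supplementary tables and are not redistributed here"
        )

    term_df = pd.read_csv(data_dir / "scheme_terms.tsv", sep="\t", dtype=str)
    schemes = [
        load_scheme(sub, scheme_id=str(sid))
        for sid, sub in term_df.groupby("scheme_id")
    ]

    gene_df = pd.read_csv(data_dir / "hallmark_genes.tsv", sep="\t", dtype=str)
    unions = {str(sid): set(sub["gene_id"]) for sid, sub in gene_df.groupby("scheme_id")}
    pw = pathway_scheme_genes(pd.read_csv(data_dir / "pathway_genes.tsv", sep="\t",
                                          dtype=str), scheme_id="PW1")

    freq = term_selection_frequency(schemes)
    n_go = len(schemes)
    counts: dict = {
        "n_go_schemes": n_go,
        "terms_selected_by_all_go_schemes": sum(
            1 for c in freq.overall.values() if c == n_go
        ),
        "unique_term_pct": {
            s.scheme_id: unique_term_fraction(s, schemes) for s in schemes
        },
        "pathway_union_size": len(pw.union),
    }

    all_sets = dict(unions)
    all_sets["PW1"] = pw.union
    profile = exclusive_intersections(all_sets)
    core = frozenset(all_sets)
    counts["core_intersection_size"] = len(profile.exclusive.get(core, set()))
    counts["unique_gene_counts"] = {
        name: len(profile.exclusive.get(frozenset({name}), set())) for name in unions
    }

    prognostic = load_prognostic_tsv(str(data_dir / "prognostic.tsv"))
    counts["prognostic_hallmark_totals"] = {}
    for scheme_id, union in unions.items():
        per_cancer = prognostic_hallmark_genes(union, prognostic)
        counts["prognostic_hallmark_totals"][scheme_id] = len(
            set().union(*per_cancer.values())
        )
        counts.setdefault("prognostic_hallmark_per_cancer", {})[scheme_id] = {
            c: len(g) for c, g in per_cancer.items()
        }

    pw_terms = load_scheme(
        pd.read_csv(data_dir / "correspondence.tsv", sep="\t", dtype=str),
        scheme_id="PW1",
    )
    voters: list[MappingScheme] = schemes + [pw_terms]
    _, overall, pairs = consensus_terms(voters, min_schemes=3)
    counts["consensus_terms_total"] = len(overall)
    counts["consensus_hallmark_term_pairs"] = len(pairs)
    return counts
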