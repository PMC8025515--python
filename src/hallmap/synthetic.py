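"""Synthetic inputs with known ground truth for every pipeline stage.

Every generator is a pure function of its parameters and a seed, drawing
from a named substream of the world seed so adding a generator never
perturbs existing fixtures.  The generated world emulates the structure of
the real study inputs — a multi-rooted ontology DAG with is_a/part_of
edges, leaf-biased gene annotations obeying the true-path rule, 4-5
term-selection schemes with tunable pairwise overlap, prognostic gene lists
over many cancer types, a pair of ontology versions related by stated churn
rates, and an FPKM-like expression matrix with planted correlated gene
modules — and records every planted quantity so each stage's output can be
scored without re-running the generators.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ontology import AnnotationTable, OntologyGraph, OntologyTerm, write_obo
from .prognostic import PrognosticTable
from .schemes import HALLMARKS, MappingScheme


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named substream: independent generator per (seed, stream name)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


def _term_id(i: int) -> str:
    return f"GO:{i:07d}"


def _gene_id(i: int) -> str:
    return f"ENSG{i:011d}"


# ---------------------------------------------------------------------------
# Ontology and annotations
# ---------------------------------------------------------------------------

def generate_ontology(
    n_terms: int,
    n_roots: int = 1,
    mean_parents: float = 1.5,
    p_part_of: float = 0.2,
    seed: int = 0,
    version_label: str = "synthetic-v1",
    namespace: str = "biological_process",
) -> OntologyGraph:
    """Layered random DAG: term *i*'s parents are drawn among terms < *i*.

    Each non-root draws ``max(1, Poisson(mean_parents))`` parents; each edge
    is part_of with probability ``p_part_of``, is_a otherwise.  Term ids are
    ordered topologically (parents precede children), which downstream
    version churn relies on to rewire edges without creating cycles.
    """
    if not (n_terms >= n_roots >= 1):
        raise ValueError(f"need n_terms >= n_roots >= 1, got {n_terms}, {n_roots}")
    if mean_parents < 0 or not (0.0 <= p_part_of <= 1.0):
        raise ValueError("mean_parents must be >= 0 and p_part_of in [0, 1]")
    rng = _rng(seed, "ontology")
    graph = OntologyGraph(version_label=version_label)
    for i in range(n_terms):
        graph.add_term(OntologyTerm(_term_id(i + 1), name=f"synthetic term {i + 1}",
                                    namespace=namespace))
    ids = [_term_id(i + 1) for i in range(n_terms)]
    for i in range(n_roots, n_terms):
        n_par = max(1, int(rng.poisson(mean_parents)))
        parents = rng.choice(i, size=min(n_par, i), replace=False)
        for p in np.sort(parents):
            rel = "part_of" if rng.random() < p_part_of else "is_a"
            graph.add_edge(ids[i], ids[int(p)], rel)
    graph.validate()
    return graph


def term_depths(graph: OntologyGraph) -> dict[str, int]:
    """Shortest distance of each active term from the nearest root."""
    depths: dict[str, int] = {r: 0 for r in graph.roots()}
    frontier = list(depths)
    while frontier:
        nxt = []
        for node in frontier:
            for child in graph.children(node):
                if child not in depths:
                    depths[child] = depths[node] + 1
                    nxt.append(child)
        frontier = nxt
    return depths


def generate_annotations(
    graph: OntologyGraph,
    n_genes: int,
    mean_terms_per_gene: float = 3.0,
    seed: int = 0,
    gene_ids: Sequence[str] | None = None,
) -> AnnotationTable:
    """Leaf-biased direct annotations: deeper terms are proportionally more
    likely, so true-path propagation is non-trivial.  Every gene gets >= 1 term."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = _rng(seed, "annotations")
    depths = term_depths(graph)
    terms = sorted(depths)
    weights = np.array([depths[t] + 1 for t in terms], dtype=float)
    weights /= weights.sum()
    genes = list(gene_ids) if gene_ids is not None else [_gene_id(i + 1) for i in range(n_genes)]
    table = AnnotationTable(graph_version=graph.version_label)
    for g in genes:
        n_t = max(1, int(rng.poisson(mean_terms_per_gene)))
        chosen = rng.choice(len(terms), size=min(n_t, len(terms)), replace=False, p=weights)
        for idx in chosen:
            table.add(g, terms[int(idx)])
    return table


# ---------------------------------------------------------------------------
# Mapping schemes
# ---------------------------------------------------------------------------

def generate_schemes(
    graph: OntologyGraph,
    n_schemes: int = 4,
    terms_per_hallmark: int = 10,
    coverage: Sequence[Sequence[str]] | None = None,
    overlap: float = 0.5,
    seed: int = 0,
    pool_size: int | None = None,
    min_term_depth: int = 0,
) -> tuple[list[MappingScheme], dict]:
    """Schemes with a planted per-hallmark consensus pool.

    Each scheme/hallmark selection of size ``terms_per_hallmark`` draws
    Binomial(terms_per_hallmark, overlap) terms from that hallmark's shared
    pool and the rest from a global stock of never-reused terms, so pairwise
    overlap is tunable and fully recorded.  ``coverage`` masks hallmarks per
    scheme (emulating schemes that define only 8 of the 10 hallmarks);
    ``min_term_depth`` keeps near-root terms (whose descendant closures span
    most of the genome) out of the selections, as real schemes select
    process-level, not root-level, terms.
    """
    if not (0.0 <= overlap <= 1.0):
        raise ValueError("overlap must be in [0, 1]")
    pool_size = pool_size or terms_per_hallmark
    if pool_size < terms_per_hallmark:
        raise ValueError("pool_size must be >= terms_per_hallmark")
    if coverage is None:
        coverage = [HALLMARKS] * n_schemes
    if len(coverage) != n_schemes:
        raise ValueError("coverage must list hallmarks for every scheme")
    rng = _rng(seed, "schemes")
    depths = term_depths(graph)
    stock = sorted(t for t in graph.active_terms if depths.get(t, 0) >= min_term_depth)
    rng.shuffle(stock)
    hallmarks = sorted({h for cov in coverage for h in cov})
    need_pool = pool_size * len(hallmarks)
    if need_pool > len(stock):
        raise ValueError(
            f"term stock too small: need {need_pool} pool terms, have {len(stock)}"
        )
    pools: dict[str, list[str]] = {}
    cursor = 0
    for h in hallmarks:
        pools[h] = stock[cursor:cursor + pool_size]
        cursor += pool_size

    schemes: list[MappingScheme] = []
    truth: dict = {
        "pool": {h: set(p) for h, p in pools.items()},
        "selections": {},
        "n_shared": {},
    }
    for s in range(n_schemes):
        scheme = MappingScheme(scheme_id=f"GO{s + 1}", source_kind="ontology_terms")
        for h in coverage[s]:
            n_shared = int(rng.binomial(terms_per_hallmark, overlap))
            shared = rng.choice(pools[h], size=n_shared, replace=False).tolist()
            n_unique = terms_per_hallmark - n_shared
            if cursor + n_unique > len(stock):
                raise ValueError("term stock exhausted; grow the ontology or shrink schemes")
            unique = stock[cursor:cursor + n_unique]
            cursor += n_unique
            scheme.selections[h] = set(shared) | set(unique)
            truth["n_shared"][(scheme.scheme_id, h)] = n_shared
        truth["selections"][scheme.scheme_id] = {
            h: set(t) for h, t in scheme.selections.items()
        }
        schemes.append(scheme)
    return schemes, truth


# ---------------------------------------------------------------------------
# Version churn
# ---------------------------------------------------------------------------

def generate_version_pair(
    graph: OntologyGraph,
    p_obsolete: float = 0.05,
    n_new_terms: int = 20,
    p_rewire: float = 0.05,
    seed: int = 0,
    labels: tuple[str, str] = ("synthetic-v-old", "synthetic-v-new"),
) -> tuple[OntologyGraph, OntologyGraph, dict]:
    """An (old, new) version pair with recorded churn.

    The new version obsoletes a random fraction of non-root terms, rewires a
    fraction of surviving edges to a different earlier term (term ids are
    topologically ordered, so acyclicity is preserved), and appends new terms
    attached to surviving ones.  Obsoletions, rewirings and creations are all
    returned as truth.
    """
    if not (0.0 <= p_obsolete < 1.0) or not (0.0 <= p_rewire <= 1.0) or n_new_terms < 0:
        raise ValueError("invalid churn parameters")
    rng = _rng(seed, "versions")
    old = graph.copy(version_label=labels[0])

    ids = sorted(old.terms)
    index = {t: i for i, t in enumerate(ids)}
    roots = old.roots()
    candidates = [t for t in ids if t not in roots and not old.terms[t].obsolete]
    n_obs = int(round(p_obsolete * len(candidates)))
    obsoleted = set(rng.choice(candidates, size=n_obs, replace=False).tolist()) if n_obs else set()

    new = OntologyGraph(version_label=labels[1])
    for t in ids:
        term = old.terms[t]
        if t in obsoleted:
            new.add_term(OntologyTerm(t, term.name, term.namespace, obsolete=True))
        else:
            new.add_term(term)
    new.alt_ids = dict(old.alt_ids)

    surviving = [t for t in ids if new.is_active(t)]
    rewired: list[tuple[str, str, str, str]] = []
    for child, parent, rel in sorted(old.edges()):
        if child in obsoleted or parent in obsoleted:
            continue
        if rng.random() < p_rewire and index[child] > 0:
            pool = [t for t in surviving if index[t] < index[child] and t != parent]
            if pool:
                new_parent = pool[int(rng.integers(len(pool)))]
                if not any(p == new_parent for p, _ in new.parent_edges(child)):
                    new.add_edge(child, new_parent, rel)
                    rewired.append((child, parent, new_parent, rel))
                    continue
        new.add_edge(child, parent, rel)

    created: set[str] = set()
    next_num = max(int(t.split(":")[1]) for t in ids) + 1
    anchor_pool = sorted(t for t in new.active_terms)
    for j in range(n_new_terms):
        t = _term_id(next_num + j)
        new.add_term(OntologyTerm(t, name=f"synthetic term {next_num + j}"))
        n_par = max(1, int(rng.poisson(1.2)))
        parents = rng.choice(len(anchor_pool), size=min(n_par, len(anchor_pool)), replace=False)
        for p in np.sort(parents):
            rel = "part_of" if rng.random() < 0.2 else "is_a"
            new.add_edge(t, anchor_pool[int(p)], rel)
        created.add(t)
    new.validate()

    churn = {"obsoleted": obsoleted, "created": created, "rewired": rewired,
             "labels": labels}
    return old, new, churn


def drift_annotations(
    annotations: AnnotationTable,
    graph_new: OntologyGraph,
    n_added: int = 200,
    seed: int = 0,
) -> tuple[AnnotationTable, dict]:
    """New-version annotation table: direct entries to obsoleted terms are
    dropped and ``n_added`` fresh (gene, active term) annotations injected;
    both recorded as truth."""
    rng = _rng(seed, "drift")
    new = AnnotationTable(graph_version=graph_new.version_label)
    dropped: list[tuple[str, str]] = []
    for gene, terms in annotations.entries.items():
        for t in sorted(terms):
            if graph_new.is_active(t):
                new.add(gene, t)
            else:
                dropped.append((gene, t))
    genes = sorted(new.entries)
    active = sorted(graph_new.active_terms)
    added: list[tuple[str, str]] = []
    while len(added) < n_added:
        g = genes[int(rng.integers(len(genes)))]
        t = active[int(rng.integers(len(active)))]
        if t not in new.entries.get(g, set()):
            new.add(g, t)
            added.append((g, t))
    return new, {"dropped": dropped, "added": added}


# ---------------------------------------------------------------------------
# Expression and prognostic lists
# ---------------------------------------------------------------------------

def generate_expression(
    n_genes: int,
    n_samples: int,
    module_sizes: Sequence[int],
    within_cor: float = 0.8,
    noise_sd: float = 1.0,
    seed: int = 0,
    gene_ids: Sequence[str] | None = None,
    base_mean: float = 6.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """FPKM-like matrix with planted correlated modules.

    Each module has a latent per-sample profile z; member genes follow
    sqrt(r)·z + sqrt(1-r)·ε with unit-variance Gaussian ε, so the expected
    within-module Pearson correlation is ``within_cor``.  Background genes
    are independent noise.  Log2-scale values (mean ``base_mean``, sd
    ``noise_sd``) are exponentiated to the FPKM-like scale, so the standard
    log2(x+1) preprocessing approximately recovers them.
    """
    if sum(module_sizes) > n_genes:
        raise ValueError("module sizes exceed the gene count")
    if not (0.0 <= within_cor <= 1.0):
        raise ValueError("within_cor must be in [0, 1]")
    rng = _rng(seed, "expression")
    genes = list(gene_ids) if gene_ids is not None else [_gene_id(i + 1) for i in range(n_genes)]
    if len(genes) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    x = rng.standard_normal((n_genes, n_samples))
    labels = np.zeros(n_genes, dtype=int)
    start = 0
    for m, size in enumerate(module_sizes, start=1):
        z = rng.standard_normal(n_samples)
        block = slice(start, start + size)
        x[block] = np.sqrt(within_cor) * z + np.sqrt(1.0 - within_cor) * x[block]
        labels[block] = m
        start += size
    log2_values = base_mean + noise_sd * x
    fpkm = np.maximum(np.exp2(log2_values) - 1.0, 0.0)
    samples = [f"sample_{j + 1:03d}" for j in range(n_samples)]
    expr = pd.DataFrame(fpkm, index=genes, columns=samples)
    return expr, pd.Series(labels, index=genes, name="module")


def generate_prognostic(
    gene_pool: Sequence[str],
    n_cancers: int = 17,
    per_cancer_rate: float = 0.02,
    planted_combinations: Sequence[tuple[Sequence[str], int]] | None = None,
    seed: int = 0,
) -> tuple[PrognosticTable, dict]:
    """Prognostic lists with planted exact cancer-combination signatures.

    Planted genes carry *exactly* their combination's cancer set; the
    remaining pool genes become background singletons (one random cancer
    with probability ``per_cancer_rate``), so exact-signature partitioning
    can be scored against the planted truth.
    """
    rng = _rng(seed, "prognostic")
    cancers = [f"cancer_{i + 1:02d}" for i in range(n_cancers)]
    table: PrognosticTable = {c: set() for c in cancers}
    pool = list(gene_pool)
    rng.shuffle(pool)
    planted_truth: dict[frozenset[str], set[str]] = {}
    cursor = 0
    for combo, size in planted_combinations or []:
        combo_set = frozenset(combo)
        if not combo_set <= set(cancers):
            raise ValueError(f"unknown cancer type(s) in {sorted(combo_set)}")
        members = set(pool[cursor:cursor + size])
        if len(members) < size:
            raise ValueError("gene pool too small for the planted combinations")
        cursor += size
        planted_truth[combo_set] = members
        for c in combo_set:
            table[c] |= members
    for g in pool[cursor:]:
        if rng.random() < per_cancer_rate:
            table[cancers[int(rng.integers(n_cancers))]].add(g)
    return table, {"planted": planted_truth, "cancers": cancers}


def plant_module_enrichment(
    graph: OntologyGraph,
    annotations: AnnotationTable,
    module_labels: pd.Series,
    seed: int = 0,
    fraction: float = 1.0,
) -> dict[int, str]:
    """Annotate each expression module's genes to a dedicated leaf term.

    The planted term must come out of a hypergeometric enrichment of its
    module as the uniquely most significant term, so the choice of leaf is
    constrained rather than uniform: the leaf carries no direct annotations
    of its own (its propagated gene set is exactly the planted module), and
    every parent's closure already contains an annotated gene outside the
    module.  Because any ancestor's propagated set then strictly contains
    the module plus at least one outside gene, every ancestor has a strictly
    larger tail probability than the planted term itself.  Returns the
    planted module -> term mapping (the enrichment truth).
    """
    from .ontology import annotated_genes

    rng = _rng(seed, "enrichment")
    idx = annotations.term_index()
    modules = sorted(set(module_labels) - {0})
    # Prefer leaves with the fewest direct annotations of their own; shuffle
    # within that preference so different seeds plant different terms.
    candidates = sorted(t for t in graph.active_terms if not graph.children(t))
    rng.shuffle(candidates)
    candidates.sort(key=lambda t: len(idx.get(t, ())))
    planted: dict[int, str] = {}
    for m in modules:
        genes = list(module_labels.index[module_labels == m])
        module_set = set(genes)
        term = None
        for t in candidates:
            if t in planted.values():
                continue
            own = module_set | idx.get(t, set())
            parents = graph.parents(t)
            if parents and all(
                annotated_genes(graph, annotations, p) - own
                for p in parents
            ):
                term = t
                break
        if term is None:
            raise ValueError(
                "no leaf term with independently annotated ancestors available "
                "to plant enrichment; grow the ontology or the annotation table"
            )
        take = max(1, int(round(fraction * len(genes))))
        picked = rng.choice(len(genes), size=take, replace=False)
        for gi in picked:
            annotations.add(genes[int(gi)], term)
        planted[m] = term
    return planted


# ---------------------------------------------------------------------------
# The assembled world
# ---------------------------------------------------------------------------

@dataclass
class SyntheticWorld:
    """Everything the pipeline consumes, plus the truth that scores it."""

    seed: int
    graph_old: OntologyGraph
    graph_new: OntologyGraph
    annotations_old: AnnotationTable
    annotations_new: AnnotationTable
    schemes: list[MappingScheme]
    prognostic: PrognosticTable
    expression: pd.DataFrame
    module_labels: pd.Series
    truth: dict = field(default_factory=dict)


def generate_world(seed: int = 0, scale: float = 1.0) -> SyntheticWorld:
    """One coherent world at the study's scale (scale=1: ~600 terms, ~10000
    genes, 4 schemes over 10 hallmarks with two 8-hallmark schemes, 17
    cancers, 100 samples with 3 planted 50-gene expression modules).

    ``scale`` shrinks term/gene/sample counts proportionally for desk-scale
    runs; planted structure sizes shrink with sqrt-like floors so every
    stage stays exercised.
    """
    n_terms = max(200, int(round(600 * scale)))
    n_genes = max(400, int(round(10000 * scale)))
    n_samples = max(40, int(round(100 * scale)))
    terms_per_hallmark = max(4, int(round(10 * min(1.0, scale * 2))))
    module_size = max(15, int(round(50 * min(1.0, scale * 2))))

    graph = generate_ontology(n_terms=n_terms, n_roots=2, mean_parents=1.5,
                              p_part_of=0.2, seed=seed, version_label="synthetic-v-old")
    annotations = generate_annotations(graph, n_genes=n_genes,
                                       mean_terms_per_gene=3.0, seed=seed)
    coverage = [HALLMARKS, HALLMARKS, HALLMARKS[:8], HALLMARKS[:8]]
    schemes, scheme_truth = generate_schemes(
        graph, n_schemes=4, terms_per_hallmark=terms_per_hallmark,
        coverage=coverage, overlap=0.5, seed=seed, min_term_depth=2,
    )
    old, new, churn = generate_version_pair(graph, p_obsolete=0.05,
                                            n_new_terms=max(5, n_terms // 30),
                                            p_rewire=0.05, seed=seed)
    annotations_new, drift = drift_annotations(annotations, new,
                                               n_added=max(50, n_genes // 50), seed=seed)

    genes = sorted(annotations.entries)
    module_sizes = [module_size] * 3
    n_expr_genes = min(len(genes), module_size * 3 + max(50, module_size * 2))
    rng = _rng(seed, "world")
    expr_genes = [genes[i] for i in rng.choice(len(genes), size=n_expr_genes, replace=False)]
    expression, module_labels = generate_expression(
        n_genes=n_expr_genes, n_samples=n_samples, module_sizes=module_sizes,
        within_cor=0.8, noise_sd=1.0, seed=seed, gene_ids=expr_genes,
    )
    planted_terms = plant_module_enrichment(old, annotations, module_labels, seed=seed)

    cancers = [f"cancer_{i + 1:02d}" for i in range(17)]
    planted_combinations = [
        ((cancers[0], cancers[1]), 8),
        ((cancers[2], cancers[3], cancers[4]), 6),
        ((cancers[0],), 10),
    ]
    prognostic, prognostic_truth = generate_prognostic(
        genes, n_cancers=17, per_cancer_rate=0.02,
        planted_combinations=planted_combinations, seed=seed,
    )

    return SyntheticWorld(
        seed=seed,
        graph_old=old, graph_new=new,
        annotations_old=annotations, annotations_new=annotations_new,
        schemes=schemes, prognostic=prognostic,
        expression=expression, module_labels=module_labels,
        truth={
            "schemes": scheme_truth,
            "churn": churn,
            "drift": drift,
            "prognostic": prognostic_truth,
            "module_labels": module_labels,
            "planted_enrichment": planted_terms,
        },
    )


def write_world(world: SyntheticWorld, outdir: str | Path) -> None:
    """Write the world in the same dialects the pipeline reads, plus truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, graph in (("ontology_old.obo", world.graph_old),
                        ("ontology_new.obo", world.graph_new)):
        with open(out / name, "w", encoding="utf-8") as fh:
            write_obo(graph, fh)
    for name, ann in (("annotations_old.tsv", world.annotations_old),
                      ("annotations_new.tsv", world.annotations_new)):
        with open(out / name, "w", encoding="utf-8") as fh:
            for gene in sorted(ann.entries):
                for term in sorted(ann.entries[gene]):
                    fh.write(f"{gene}\t{term}\n")
    with open(out / "schemes.tsv", "w", encoding="utf-8") as fh:
        fh.write("scheme_id\thallmark\tterm_id\n")
        for scheme in world.schemes:
            for hallmark in sorted(scheme.selections):
                for term in sorted(scheme.selections[hallmark]):
                    fh.write(f"{scheme.scheme_id}\t{hallmark}\t{term}\n")
    with open(out / "prognostic.tsv", "w", encoding="utf-8") as fh:
        fh.write("cancer_type\tgene_id\n")
        for cancer in sorted(world.prognostic):
            for gene in sorted(world.prognostic[cancer]):
                fh.write(f"{cancer}\t{gene}\n")
    world.expression.to_csv(out / "expression.tsv", sep="\t", index_label="gene_id")
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(_jsonable(world.truth), fh, indent=1)


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {_key(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.Series):
        return {str(k): int(v) for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _key(k) -> str:
    if isinstance(k, (tuple, frozenset)):
        return "|".join(sorted(str(x) for x in k))
    return str(k)
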