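"""Simplified weighted co-expression network analysis.

The classic WGCNA recipe at desk scale: log-transform an FPKM-like
expression matrix, optionally drop outlying samples by hierarchical
clustering, pick a soft-threshold power by the scale-free topology fit,
raise |Pearson correlation| to that power to obtain the adjacency, convert
to the topological overlap matrix (TOM), cluster 1 - TOM with average
linkage under a single static cut (blockwise processing and dynamic tree
cutting are unnecessary at a few hundred genes), rank genes by intramodular
connectivity to call hubs, and test modules for ontology-term enrichment
with a one-sided hypergeometric test plus Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .ontology import AnnotationTable, OntologyGraph, annotated_genes, DEFAULT_RELATIONS

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentRecord:
    module_id: int
    term_id: str
    p_raw: float
    p_adjusted: float
    k: int  # annotated genes in the module
    K: int  # annotated genes in the background
    n: int  # module size
    N: int  # background size


@dataclass
class CoexpressionResult:
    """Bundle of every artefact a co-expression run produces."""

    power: float
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    module_labels: pd.Series  # gene -> module id; 0 = unassigned
    k_within: pd.Series
    hubs: dict[int, list[str]] = field(default_factory=dict)
    enrichment: list[EnrichmentRecord] = field(default_factory=list)
    fit_table: pd.DataFrame | None = None


def preprocess(
    expr: pd.DataFrame,
    log_offset: float = 1.0,
    outlier_cut_height: float | None = None,
) -> pd.DataFrame:
    """log2(value + offset) transform, then optional outlier-sample removal.

    Samples (columns) are average-linkage clustered on Euclidean distance;
    cutting the dendrogram at ``outlier_cut_height`` keeps the largest branch
    and removes the rest, logging what was dropped.
    """
    values = expr.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)) or (values < 0).any():
        raise ValueError("expression values must be finite and non-negative")
    logged = pd.DataFrame(
        np.log2(values + log_offset), index=expr.index, columns=expr.columns
    )
    if outlier_cut_height is None:
        return logged
    if logged.shape[1] < 3:
        raise ValueError("outlier removal needs at least 3 samples")
    link = hierarchy.linkage(logged.to_numpy().T, method="average", metric="euclidean")
    labels = hierarchy.fcluster(link, t=outlier_cut_height, criterion="distance")
    keep_label = np.bincount(labels)[1:].argmax() + 1
    keep = labels == keep_label
    removed = [c for c, k in zip(logged.columns, keep) if not k]
    if removed:
        logger.info("outlier removal dropped %d sample(s): %s", len(removed), removed[:10])
    if keep.sum() == 0:
        raise ValueError("outlier cut removed every sample")
    return logged.loc[:, keep]


def _correlation(expr: pd.DataFrame) -> tuple[np.ndarray, pd.Index]:
    """|corr| matrix across genes (rows); constant genes dropped with a warning."""
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1)
    ok = sd > 0
    if not ok.all():
        logger.warning("dropping %d constant gene(s) before correlation", (~ok).sum())
    values = values[ok]
    idx = expr.index[ok]
    cor = np.corrcoef(values)
    np.fill_diagonal(cor, 1.0)
    return cor, idx


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R² of the log-log degree-distribution regression.

    Connectivities are binned on log10(k); within each occupied bin the mean
    log10(k) and the log10 relative frequency enter an ordinary least-squares
    line.  The sign convention is -sign(slope) * R², so a decaying (scale-free
    like) degree distribution scores positively.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2:
        return 0.0
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max() + 1e-9, n_bins + 1)
    which = np.clip(np.digitize(logk, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        xs.append(logk[mask].mean())
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 2:
        return 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * np.asarray(xs) + intercept
    ss_res = float(((np.asarray(ys) - pred) ** 2).sum())
    ss_tot = float(((np.asarray(ys) - np.mean(ys)) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(-np.sign(slope) * r2)


def pick_soft_threshold(
    expr: pd.DataFrame,
    powers: Sequence[int] = tuple(range(1, 21)),
    r2_cut: float = 0.8,
    signed: bool = False,
) -> tuple[int, pd.DataFrame]:
    """Smallest power whose scale-free fit reaches ``r2_cut`` (else the argmax).

    Returns the chosen power and the full per-power fit table
    (power, fit, mean_k, median_k, max_k).
    """
    if expr.shape[0] < 3 or expr.shape[1] < 4:
        raise ValueError("need at least 3 genes and 4 samples")
    cor, _ = _correlation(expr)
    base = cor if signed else np.abs(cor)
    np.fill_diagonal(base, 0.0)
    rows = []
    for beta in powers:
        a = np.power(base, beta)
        k = a.sum(axis=1)
        rows.append(
            {"power": beta, "fit": scale_free_fit(k),
             "mean_k": float(k.mean()), "median_k": float(np.median(k)),
             "max_k": float(k.max())}
        )
    table = pd.DataFrame(rows)
    passing = table[table["fit"] >= r2_cut]
    beta = int(passing["power"].iloc[0]) if len(passing) else int(table.loc[table["fit"].idxmax(), "power"])
    return beta, table


def adjacency(expr: pd.DataFrame, beta: float, signed: bool = False) -> pd.DataFrame:
    """Weighted network adjacency a_ij = |cor_ij|^beta (unsigned default).

    The signed variant uses ((1 + cor)/2)^beta.  The diagonal is set to 0 so
    connectivity sums never include self-edges.
    """
    if beta < 1:
        raise ValueError("soft-threshold power must be >= 1")
    cor, idx = _correlation(expr)
    base = (1.0 + cor) / 2.0 if signed else np.abs(cor)
    a = np.power(base, beta)
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=idx, columns=idx)


def tom(adj: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap: TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij)
    with l_ij = Σ_{u≠i,j} a_iu a_uj and k_i = Σ_{u≠i} a_iu; unit diagonal."""
    is_frame = isinstance(adj, pd.DataFrame)
    a = adj.to_numpy(dtype=float).copy() if is_frame else np.array(adj, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be a symmetric square matrix")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # u=i and u=j vanish because the diagonal is zero
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (shared + a) / denom
    t = np.nan_to_num(t, nan=0.0)
    np.fill_diagonal(t, 1.0)
    if is_frame:
        return pd.DataFrame(t, index=adj.index, columns=adj.columns)
    return t


def detect_modules(
    tom_matrix: pd.DataFrame,
    min_module_size: int = 20,
    cut_height: float = 0.995,
) -> pd.Series:
    """Average-linkage clustering of 1 - TOM under a single static cut.

    Clusters smaller than ``min_module_size`` are labelled 0 (unassigned);
    surviving modules are renumbered 1, 2, ... by decreasing size.
    """
    t = tom_matrix.to_numpy(dtype=float)
    if t.shape[0] != t.shape[1]:
        raise ValueError("TOM must be square")
    diss = 1.0 - t
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(diss, checks=False), method="average")
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_module_size].index
    order = sorted(keep, key=lambda lab: (-sizes[lab], lab))
    relabel = {lab: i + 1 for i, lab in enumerate(order)}
    labels = np.array([relabel.get(lab, 0) for lab in raw])
    return pd.Series(labels, index=tom_matrix.index, name="module")


def intramodular_connectivity(adj: pd.DataFrame, module_labels: pd.Series) -> pd.Series:
    """kWithin_i = Σ adjacency to same-module genes (unassigned genes get 0)."""
    a = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    labels = module_labels.reindex(adj.index).to_numpy()
    kw = np.zeros(len(adj.index))
    for module in np.unique(labels):
        if module == 0:
            continue
        mask = labels == module
        kw[mask] = a[np.ix_(mask, mask)].sum(axis=1)
    return pd.Series(kw, index=adj.index, name="kWithin")


def hub_genes(
    adj: pd.DataFrame,
    module_labels: pd.Series,
    n: int = 5,
) -> dict[int, list[str]]:
    """Top-``n`` genes per module by intramodular connectivity.

    Ties at the n-th value extend the hub set (all tied genes are included),
    so a module may report more than ``n`` hubs.  Modules smaller than ``n``
    return every member with a warning.  Output order is deterministic:
    decreasing kWithin, gene id as tie-break — independent of input order.
    """
    kw = intramodular_connectivity(adj, module_labels)
    hubs: dict[int, list[str]] = {}
    for module in sorted(set(module_labels) - {0}):
        genes = module_labels.index[module_labels == module]
        ranked = sorted(genes, key=lambda g: (-kw[g], g))
        if len(ranked) <= n:
            if len(ranked) < n:
                logger.warning("module %s has %d gene(s) < n=%d; returning all",
                               module, len(ranked), n)
            hubs[module] = ranked
            continue
        threshold = kw[ranked[n - 1]]
        hubs[module] = [g for g in ranked if kw[g] > threshold or np.isclose(kw[g], threshold)]
    return hubs


def enrich(
    module_genes: Iterable[str],
    background_genes: Iterable[str],
    graph: OntologyGraph,
    annotations: AnnotationTable,
    alpha: float = 0.05,
    namespace: str = "biological_process",
    relations: Iterable[str] = DEFAULT_RELATIONS,
    module_id: int = 0,
) -> list[EnrichmentRecord]:
    """One-sided hypergeometric enrichment of ontology terms in a module.

    For every term of the chosen namespace with at least one module gene
    after true-path propagation: the upper-tail probability of drawing >= k
    annotated genes in a module of n from a background of N with K annotated.
    Raw p-values are the primary significance criterion (threshold ``alpha``);
    Benjamini-Hochberg adjusted p-values are always reported alongside.
    Records are sorted by raw p, term id as tie-break.
    """
    module = set(module_genes)
    background = set(background_genes)
    if not background:
        raise ValueError("empty background")
    if not module <= background:
        raise ValueError("module genes must be a subset of the background")
    N, n = len(background), len(module)
    records: list[EnrichmentRecord] = []
    for term_id in sorted(graph.active_terms):
        if graph.terms[term_id].namespace != namespace:
            continue
        annotated = annotated_genes(graph, annotations, term_id, relations) & background
        k = len(annotated & module)
        if k == 0:
            continue
        K = len(annotated)
        p = float(hypergeom.sf(k - 1, N, K, n))
        records.append(EnrichmentRecord(module_id, term_id, p, np.nan, k, K, n, N))
    if records:
        adjusted = multipletests([r.p_raw for r in records], method="fdr_bh")[1]
        for rec, padj in zip(records, adjusted):
            rec.p_adjusted = float(padj)
    records.sort(key=lambda r: (r.p_raw, r.term_id))
    return records


def run_coexpression(
    expr: pd.DataFrame,
    graph: OntologyGraph | None = None,
    annotations: AnnotationTable | None = None,
    beta: int | None = None,
    signed: bool = False,
    log_offset: float = 1.0,
    outlier_cut_height: float | None = None,
    min_module_size: int = 20,
    cut_height: float = 0.995,
    hub_n: int = 5,
    alpha: float = 0.05,
    relations: Iterable[str] = DEFAULT_RELATIONS,
) -> CoexpressionResult:
    """End-to-end co-expression stage; enrichment runs only when an ontology
    and annotation table are supplied (background = expression ∩ annotation
    genes)."""
    logged = preprocess(expr, log_offset=log_offset, outlier_cut_height=outlier_cut_height)
    fit_table = None
    if beta is None:
        beta, fit_table = pick_soft_threshold(logged, signed=signed)
        logger.info("soft-threshold power selected automatically: %d", beta)
    adj = adjacency(logged, beta, signed=signed)
    t = tom(adj)
    labels = detect_modules(t, min_module_size=min_module_size, cut_height=cut_height)
    kw = intramodular_connectivity(adj, labels)
    hubs = hub_genes(adj, labels, n=hub_n)
    enrichment: list[EnrichmentRecord] = []
    if graph is not None and annotations is not None:
        background = set(adj.index) & annotations.genes
        logger.info("enrichment background: %d genes (expression ∩ annotations)", len(background))
        for module in sorted(set(labels) - {0}):
            module_members = set(labels.index[labels == module]) & background
            if not module_members:
                continue
            enrichment.extend(
                enrich(module_members, background, graph, annotations,
                       alpha=alpha, relations=relations, module_id=module)
            )
    return CoexpressionResult(
        power=beta, adjacency=adj, tom=t, module_labels=labels,
        k_within=kw, hubs=hubs, enrichment=enrichment, fit_table=fit_table,
    )
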