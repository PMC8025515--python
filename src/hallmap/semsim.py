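"""Wang-method semantic similarity and best-match-average set similarity.

The Wang measure scores two ontology terms by the semantic contributions
(S-values) of their shared ancestors.  For an anchor term A, S_A(A) = 1 and
for every ancestor t,

    S_A(t) = max over children c of t on a path from A:  w(rel(c, t)) * S_A(c)

with a per-relation contribution factor w (conventionally 0.8 for is_a and
0.6 for part_of).  With SV(A) = sum of all S_A values,

    sim(A, B) = sum over shared ancestors t of (S_A(t) + S_B(t))
                / (SV(A) + SV(B)).

Terms in disjoint rooted components (e.g. different namespaces) share no
ancestors and score 0.  Set-level similarity uses the best-match-average
(BMA) strategy: every term's best counterpart match, averaged in both
directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .ontology import ObsoleteTermError, OntologyGraph

logger = logging.getLogger(__name__)

#: Conventional Wang contribution factors per relation type.
WANG_WEIGHTS: dict[str, float] = {"is_a": 0.8, "part_of": 0.6}


@dataclass
class SValueMap:
    """Semantic contributions of an anchor term's ancestor closure."""

    anchor: str
    s: dict[str, float] = field(default_factory=dict)

    @property
    def sv(self) -> float:
        return float(sum(self.s.values()))


def _check_weights(weights: Mapping[str, float]) -> None:
    for rel, w in weights.items():
        if not (0.0 < w < 1.0):
            raise ValueError(f"contribution factor for {rel!r} must be in (0, 1), got {w}")


def s_values(
    graph: OntologyGraph,
    term: str,
    weights: Mapping[str, float] | None = None,
) -> SValueMap:
    """S-values of *term* and its ancestors under per-relation weights.

    Only relations present in *weights* are traversed.  Each ancestor's
    S-value is the maximum over its children on ancestor paths, which equals
    the maximum over all child->ancestor paths of the product of edge weights.
    """
    weights = dict(weights or WANG_WEIGHTS)
    _check_weights(weights)
    if term not in graph:
        raise KeyError(f"unknown term {term!r} in graph {graph.version_label}")
    if graph.terms[term].obsolete:
        raise ObsoleteTermError(f"term {term!r} is obsolete; S-values undefined")

    # Collect the anchor's ancestor closure over the weighted relations.
    nodes = {term}
    stack = [term]
    edges: list[tuple[str, str, str]] = []  # (child, parent, relation)
    while stack:
        node = stack.pop()
        for parent, rel in graph.parent_edges(node):
            if rel not in weights:
                continue
            edges.append((node, parent, rel))
            if parent not in nodes:
                nodes.add(parent)
                stack.append(parent)

    # Topological pass (children before parents) with max-relaxation.
    pending: dict[str, int] = {n: 0 for n in nodes}
    by_child: dict[str, list[tuple[str, str]]] = {n: [] for n in nodes}
    for child, parent, rel in edges:
        pending[parent] += 1
        by_child[child].append((parent, rel))

    s: dict[str, float] = {term: 1.0}
    ready = [n for n, deg in pending.items() if deg == 0]
    order: list[str] = []
    while ready:
        node = ready.pop()
        order.append(node)
        for parent, rel in by_child[node]:
            candidate = weights[rel] * s.get(node, 0.0)
            if candidate > s.get(parent, 0.0):
                s[parent] = candidate
            pending[parent] -= 1
            if pending[parent] == 0:
                ready.append(parent)
    if len(order) != len(nodes):  # pragma: no cover - graphs are validated acyclic
        raise RuntimeError("cycle encountered in ancestor closure")
    return SValueMap(anchor=term, s=s)


def term_similarity(
    graph: OntologyGraph,
    t1: str,
    t2: str,
    weights: Mapping[str, float] | None = None,
) -> float:
    """Wang similarity of two terms in [0, 1]; 1.0 iff the terms coincide."""
    sv1 = s_values(graph, t1, weights)
    sv2 = s_values(graph, t2, weights)
    shared = set(sv1.s) & set(sv2.s)
    if not shared:
        return 0.0
    num = sum(sv1.s[t] + sv2.s[t] for t in shared)
    return num / (sv1.sv + sv2.sv)


def set_similarity_bma(
    graph: OntologyGraph,
    set1: Iterable[str],
    set2: Iterable[str],
    weights: Mapping[str, float] | None = None,
) -> float:
    """Best-match-average similarity of two term sets.

    Terms absent from (or obsolete in) the graph version in use are dropped
    with a warning before comparison — annotations routinely drift relative
    to the ontology snapshot they were made against.
    """
    a = _valid_terms(graph, set1)
    b = _valid_terms(graph, set2)
    if not a or not b:
        raise ValueError("a term set is empty after dropping invalid terms")
    # Cache S-values: BMA touches every pair.
    smaps = {t: s_values(graph, t, weights) for t in a | b}
    sim = {}
    for t in a:
        for u in b:
            shared = set(smaps[t].s) & set(smaps[u].s)
            sim[(t, u)] = (
                sum(smaps[t].s[x] + smaps[u].s[x] for x in shared)
                / (smaps[t].sv + smaps[u].sv)
                if shared else 0.0
            )
    forward = sum(max(sim[(t, u)] for u in b) for t in a)
    backward = sum(max(sim[(t, u)] for t in a) for u in b)
    return (forward + backward) / (len(a) + len(b))


def module_similarity_matrix(
    modules: Mapping[str, Iterable[str]],
    graph: OntologyGraph,
    weights: Mapping[str, float] | None = None,
    min_terms: int = 3,
) -> pd.DataFrame:
    """Pairwise BMA similarity between modules' enriched term sets.

    Modules enriched in fewer than ``min_terms`` valid terms are excluded
    (with a log entry); the returned matrix is symmetric with unit diagonal.
    """
    kept: dict[str, set[str]] = {}
    for module_id, terms in modules.items():
        valid = _valid_terms(graph, terms)
        if len(valid) < min_terms:
            logger.warning(
                "module %s excluded: %d valid enriched term(s) < %d",
                module_id, len(valid), min_terms,
            )
            continue
        kept[module_id] = valid
    if not kept:
        raise ValueError("every module was excluded; nothing to compare")
    ids = sorted(kept)
    mat = np.eye(len(ids))
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            score = set_similarity_bma(graph, kept[a], kept[ids[j]], weights)
            mat[i, j] = mat[j, i] = score
    return pd.DataFrame(mat, index=ids, columns=ids)


def _valid_terms(graph: OntologyGraph, terms: Iterable[str]) -> set[str]:
    valid: set[str] = set()
    dropped: list[str] = []
    for t in terms:
        resolved = graph.resolve(t)
        if resolved is not None and graph.is_active(resolved):
            valid.add(resolved)
        else:
            dropped.append(t)
    if dropped:
        logger.warning(
            "dropped %d term(s) absent/obsolete in graph %s: %s",
            len(dropped), graph.version_label, dropped[:5],
        )
    return valid
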