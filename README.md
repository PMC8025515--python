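# hallmap

Comparative analysis of **cancer-hallmark mapping schemes** — the published
associations between the ten hallmarks of cancer (Hanahan & Weinberg 2011)
and Gene Ontology terms or biological pathways.  Different research groups
have mapped the same hallmark concepts to very different term selections,
and those choices propagate into every downstream result: the hallmark gene
sets, the prognostic genes they intersect, the co-expression modules built
from them, and the enrichment stories told about those modules.  `hallmap`
quantifies that consensus and divergence with a reusable, fully testable
pipeline.

For whom: bioinformaticians comparing or curating hallmark annotation
schemes, and anyone who needs the individual building blocks — ontology
closure queries, UpSet-style exclusive intersections, Wang semantic
similarity, a desk-scale weighted co-expression stage, or ontology-version
diffing.

## What it computes

* **Ontology core** — OBO parsing (via `obonet`) into a typed `is_a`/`part_of`
  DAG with obsolete-term bookkeeping; descendant closure; true-path
  annotation propagation at query time (`annotated_genes(t)` = genes
  annotated to `t` or any descendant); first-neighbour subgraphs.
* **Schemes** — hallmark vocabulary with alias resolution, per-hallmark term
  selections, and hallmark gene sets: per hallmark `h`,
  `G(h) = ⋃_{t ∈ S(h)} annotated_genes(t)`, with the scheme union
  ("hallmark genes") alongside.
* **Set comparison** — per-term selection frequencies across schemes,
  unique-term percentages, consensus terms (same hallmark, ≥ 3 schemes),
  and exclusive (UpSet) intersections: each gene assigned to the cell of its
  exact membership signature, so cells partition the union.
* **Prognostic subgroups** — prognostic ∩ hallmark genes per cancer type,
  exact cancer-type-signature partitioning (min subgroup size 5), and
  pairwise scheme comparison with the Jaccard index
  `J(A,B) = |A∩B| / |A∪B|`, scoring 0 when a subgroup exists in only one
  scheme of a pair.
* **Semantic similarity** — the Wang method: S-values
  `S_A(t) = max_{c ∈ children(t)} w(rel) · S_A(c)`, `S_A(A)=1`,
  `sim(A,B) = Σ_{t ∈ anc(A)∩anc(B)} (S_A(t)+S_B(t)) / (SV(A)+SV(B))`,
  with best-match-average (BMA) aggregation for term sets and module
  functional-similarity matrices.
* **Co-expression** — log2 preprocessing, scale-free soft-threshold scan,
  unsigned adjacency `a_ij = |cor_ij|^β`, topological overlap
  `TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)`,
  average-linkage module detection on `1 − TOM`, intramodular-connectivity
  hub genes (top 5 with tie extension), and one-sided hypergeometric
  enrichment with Benjamini–Hochberg correction.
* **Evolution** — two ontology snapshots diffed around their term
  selections: every node classified as selected-in-both / only-old /
  only-new / obsoleted / newly-created / unselected-neighbour, plus typed
  edge changes and per-term annotation-count drift.
* **Synthetic data** — seeded generators for every input above, with full
  ground-truth records (planted term overlaps, gene memberships, churn
  events, module labels, enriched terms), so every stage is testable
  without downloads.

## Worked example

```python
import hallmap as hm

world = hm.generate_world(seed=1, scale=0.1)      # ~200 terms, 1000 genes
gene_sets = [
    hm.build_hallmark_gene_sets(s, world.graph_old, world.annotations_old)
    for s in world.schemes
]
print([len(g.union) for g in gene_sets])
# [995, 992, 796, 992]        gene-set sizes of the four synthetic schemes

per_h, overall, _ = hm.consensus_terms(world.schemes, min_schemes=3)
print(len(overall))
# 16                          terms selected for one hallmark by >= 3 schemes

print(hm.unique_term_fraction(world.schemes[0], world.schemes))
# 60.0                        % of scheme GO1's terms no other scheme selected

profile = hm.exclusive_intersections({g.scheme_id: g.union for g in gene_sets})
core = frozenset(g.scheme_id for g in gene_sets)
print(len(profile.exclusive[core]))
# 795                         genes in every scheme's hallmark gene set
```

The same stages run from the shell (`hallmap synth`, `hallmap schemes`,
`hallmap setcomp`, `hallmap prognostic`, `hallmap semsim`, `hallmap coexpr`,
`hallmap evolve`, `hallmap run --config config.yaml`), all writing TSV/JSON
with a provenance record.

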