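# Methods

## Problem setting

A hallmark *mapping scheme* associates each of the ten hallmarks of cancer
with a set of ontology terms (GO-style schemes) or a list of pathway genes
(pathway-style schemes).  The package compares such schemes at three
levels: the term selections themselves, the gene sets they induce through
annotation, and the downstream analyses (prognostic overlap, co-expression
modules, enrichment) built on those gene sets.  A fourth axis — ontology
evolution — asks how much of the disagreement between schemes is explained
by the ontology changing underneath them.

## Ontology model

An ontology snapshot is a directed acyclic multigraph of terms with typed
edges (`is_a`, `part_of`), child pointing to parent.  Obsolete terms are
retained in the object (the evolution stage needs them) but carry no edges
and are refused as anchors of closure queries — silently treating a retired
term as an empty subtree would mask the retirement.  Multi-rooted graphs
are allowed; closure queries cannot cross between rooted components, so no
namespace filter is applied to traversal (enrichment filters by namespace
explicitly, defaulting to `biological_process`).

Annotations are stored **direct-only**; the true-path rule (a gene annotated
to a term is implicitly annotated to every ancestor) is applied at query
time by unioning direct annotations over the term's descendant closure.
This keeps swapping ontology versions cheap: the same annotation table can
be queried against any snapshot that contains its terms.

Relations traversed default to `{is_a, part_of}`, matching the default
closure of standard descendant services; every query takes an explicit
relation set.  `regulates`-family semantics are out of scope.

## Set statistics

* **Selection frequency** counts *schemes*, not hallmark slots: a term one
  scheme maps to two hallmarks counts once in the overall tally.
* **Consensus** is hallmark-scoped: a term is a consensus term for hallmark
  *h* when ≥ `min_schemes` (default 3) schemes selected it *for h*.  A term
  selected by three schemes for three different hallmarks is not consensus
  anywhere.  Because a term can reach consensus in two hallmarks, both
  tallies are emitted: the global union (each term once) and the
  (hallmark, term) pair count.  Pathway schemes vote only after their
  pathway-to-term correspondence table has been loaded as a term selection
  (`load_scheme` on (hallmark, term_id) rows).
* **Exclusive intersections** assign every element to the cell of its exact
  membership signature; the partition property (cell sizes sum to the union
  size) is asserted on every call.
* Percentages are rounded half-up to one decimal, the convention of the
  comparison reports these statistics feed.

## Prognostic subgroups

"Exclusively labelled" is interpreted as exact signature matching: a gene
prognostic-hallmark in cancers {C1, C2, C3} belongs to that three-cancer
combination only, not to its sub-combinations.  Subgroups under `min_size`
(default 5) are excluded but logged with their sizes.  In pairwise scheme
comparison, every combination retained by at least one scheme is scored for
every scheme pair, with 0 when one side lacks the combination — so the
score matrix reflects both overlap quality and coverage.

## Wang similarity

Per-relation semantic contribution factors default to 0.8 (`is_a`) and 0.6
(`part_of`), the convention of the Wang method; they are configurable and
must lie in (0, 1).  S-values are computed by a topological max-relaxation
over the anchor's ancestor closure, equivalent to maximising the product of
edge weights over all anchor-to-ancestor paths (the property the test
oracle enumerates exhaustively).  Terms in disjoint rooted components share
no ancestors and score 0 rather than raising.  Terms absent from or
obsolete in the graph version in use are dropped with a warning before BMA
— annotation-versus-version drift is normal, not exceptional.  Module
similarity excludes modules with fewer than three valid enriched terms; a
one- or two-term profile makes BMA uninformative.

## Co-expression stage

Desk-scale inputs (tens to a few hundred genes) do not need WGCNA's
block-wise processing or dynamic tree cutting, so the stage uses a single
average-linkage clustering of `1 − TOM` with a static cut (default height
0.995, minimum module size 20), modules renumbered by decreasing size and
small clusters labelled 0 (unassigned).

The soft-threshold scan computes, per power β, the connectivity
`k_i = Σ_{j≠i} |cor_ij|^β`, bins `log10 k` (10 bins), and regresses the log
relative frequency on the bin mean; the signed fit is `−sign(slope)·R²` and
the chosen β is the smallest reaching `r2_cut = 0.8`, else the argmax.
Planted-block synthetic networks are **not** scale-free, so on such data
the scan has no meaningful optimum; analyses of planted-module expression
in this package therefore fix β = 6, the conventional default power for
unsigned networks.  The scan itself is exposed and unit-tested on exact
power-law degree sequences.

Enrichment is a one-sided hypergeometric upper tail (`scipy`), per BP term
with ≥ 1 module gene after true-path propagation, with Benjamini–Hochberg
adjusted p-values (`statsmodels`) always reported alongside the raw ones.
Raw p < α (default 0.05) is the primary significance rule; the background
defaults to expression ∩ annotation genes and is logged, since published
enrichment services rarely state theirs.  Hub genes are the top 5 per
module by intramodular connectivity; genes tied at the fifth value are all
included, so a module can report six or more hubs.  Hub output order is
deterministic (decreasing connectivity, gene id tie-break) and invariant to
input ordering.

## Version diffing

Around each version's term selection a first-neighbour subgraph is built in
that version's *active* graph (obsolete terms cannot be neighbours — they
have no edges).  Every node of the combined view gets exactly one category;
"absent from the old snapshot" and "created after it" are identified, since
OBO snapshots encode availability, not creation dates.  Merged ids
(`alt_id`) resolve to their primary term before classification; ids unknown
to both versions are reported, not dropped.  Swapping the two versions
swaps the only-old/only-new and obsoleted/created categories symmetrically.
Annotation-count drift uses descendant closure within each version and
reports null (not zero) for terms a version lacks.

## Synthetic data: what it emulates, and what not

Every generator is a pure function of its parameters and a seed; each draws
from a named substream of the seed, so adding a generator never perturbs
existing fixtures.  Defaults at scale 1 approximate the study conditions:
~600 terms in a two-root layered DAG, ~10 000 annotated genes (leaf-biased,
so propagation is non-trivial), four schemes (two covering all ten
hallmarks, two covering eight) with a planted 50 % consensus-pool overlap,
17 cancer types with planted exact-combination subgroups plus background
singleton prognostic genes, 100 expression samples with three planted
50-gene modules at within-module Pearson 0.8, and a version pair with 5 %
obsoletion, 5 % edge rewiring and ~3 % new terms.  Tests and the acceptance
script run at 1/10 scale.

Scheme term selections draw from terms at depth ≥ 2, since real schemes
select process-level rather than root-level terms; near-root terms would
make every scheme's gene union the whole genome.

Expression is generated on the log2 scale (`m = 6 + sd·x`, FPKM-like values
`2^m − 1`), with module members `x = √r·z + √(1−r)·ε` for a shared latent
profile `z`, so the expected within-module correlation is exactly the
`within_cor` parameter and the standard `log2(x+1)` preprocessing recovers
the generating scale.

Planted enrichment is constructed so "the planted term" is well defined:
the term is a leaf annotated to the *whole* module, chosen so every parent
already has an annotated gene outside the module in its closure.  Any
ancestor then has the same module hit count with a strictly larger
annotated total, hence a strictly larger tail probability — the planted
term is provably the unique enrichment optimum, not merely a likely one.

What the generators do **not** emulate: real GO topology statistics beyond
layered-DAG shape, inter-module expression correlation structure, batch or
library-size effects, and realistic annotation-evidence biases.  Passing
the planted-structure tests therefore demonstrates correctness of the
algorithms under their stated models, not robustness to the messiness of
real transcriptome or annotation data.

## Numerical and degenerate-input choices

Constant genes are dropped (with a warning) before correlation; asymmetric
adjacency is rejected; TOM denominators of zero (isolated gene pairs) yield
0, and the TOM diagonal is fixed at 1.  Jaccard of two empty sets, an empty
enrichment background, a module set that filters to empty, and a scheme
with zero selected terms are all errors, not silent zeros.  Obsolete or
unknown selected terms in gene-set construction are skipped into an
explicit report.  Half-up decimal rounding is used for reported
percentages.  Seeds derived inside the acceptance script stay below 2³¹.

## Known limitations

* The static-cut module detector is not WGCNA; published module counts
  from full-scale TCGA runs are not expected to reproduce, and the package
  makes no attempt to.
* No OWL parsing, no `regulates` semantics, no identifier translation
  (gene ids are opaque strings), no survival modelling (prognostic status
  is consumed as given), and no network downloads of any kind.
* Reproducing the original study's published counts requires its
  supplementary tables (term selections, hallmark gene lists, prognostic
  lists), which are not redistributed; `hallmap.study` documents the
  expected layout and recomputes the counts when they are present.
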