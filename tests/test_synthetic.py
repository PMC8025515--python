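"""Determinism and planted-structure properties of the synthetic generators."""

import numpy as np
import pandas as pd
import pytest

from hallmap.ontology import annotated_genes, descendants
from hallmap.prognostic import subgroup_partition
from hallmap.setcomp import unique_term_fraction
from hallmap.synthetic import (
    generate_annotations,
    generate_expression,
    generate_ontology,
    generate_prognostic,
    generate_schemes,
    generate_version_pair,
    generate_world,
    write_world,
)


class TestGenerateOntology:
    def test_single_term_is_one_root_no_edges(self):
        g = generate_ontology(n_terms=1)
        assert len(g) == 1
        assert g.n_edges() == 0

    def test_zero_mean_parents_yields_forest(self):
        g = generate_ontology(n_terms=50, n_roots=3, mean_parents=0.0, seed=2)
        for t in g.active_terms - g.roots():
            assert len(list(g.parent_edges(t))) == 1

    def test_identical_seed_gives_identical_edge_lists(self):
        g1 = generate_ontology(n_terms=80, seed=5)
        g2 = generate_ontology(n_terms=80, seed=5)
        assert sorted(g1.edges()) == sorted(g2.edges())
        g3 = generate_ontology(n_terms=80, seed=6)
        assert sorted(g1.edges()) != sorted(g3.edges())

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_ontology(n_terms=2, n_roots=5)
        with pytest.raises(ValueError):
            generate_ontology(n_terms=5, p_part_of=2.0)


class TestGenerateSchemes:
    def test_full_overlap_makes_identical_schemes(self):
        g = generate_ontology(n_terms=300, seed=1)
        schemes, _ = generate_schemes(g, n_schemes=3, terms_per_hallmark=4,
                                      overlap=1.0, seed=1)
        assert schemes[0].selections == schemes[1].selections == schemes[2].selections
        for s in schemes:
            assert unique_term_fraction(s, schemes) == 0.0

    def test_zero_overlap_makes_disjoint_schemes(self):
        g = generate_ontology(n_terms=400, seed=1)
        schemes, _ = generate_schemes(g, n_schemes=3, terms_per_hallmark=4,
                                      overlap=0.0, seed=1)
        for i, a in enumerate(schemes):
            for b in schemes[i + 1:]:
                assert not (a.all_terms & b.all_terms)

    def test_truth_records_match_selections(self):
        g = generate_ontology(n_terms=300, seed=4)
        schemes, truth = generate_schemes(g, n_schemes=4, terms_per_hallmark=5,
                                          overlap=0.5, seed=4)
        for s in schemes:
            assert truth["selections"][s.scheme_id] == s.selections
            for h, terms in s.selections.items():
                shared = terms & truth["pool"][h]
                assert len(shared) == truth["n_shared"][(s.scheme_id, h)]

    def test_mean_overlap_tracks_binomial_expectation(self):
        """Planted sharing rate: per-scheme shared-term counts over many seeds
        land within 3 standard errors of the Binomial(m, p) expectation."""
        g = generate_ontology(n_terms=500, seed=0)
        p, m = 0.5, 20
        counts = []
        for seed in range(100):
            _, truth = generate_schemes(g, n_schemes=4, terms_per_hallmark=m,
                                        coverage=[["resisting cell death"]] * 4,
                                        overlap=p, seed=seed)
            counts.extend(truth["n_shared"].values())
        mean = np.mean(counts)
        se = np.sqrt(m * p * (1 - p) / len(counts))
        assert abs(mean - m * p) < 3 * se

    def test_small_stock_rejected(self):
        g = generate_ontology(n_terms=30, seed=0)
        with pytest.raises(ValueError, match="stock"):
            generate_schemes(g, n_schemes=5, terms_per_hallmark=10, seed=0)


class TestGenerateAnnotations:
    def test_every_gene_annotated_and_deterministic(self):
        g = generate_ontology(n_terms=60, seed=3)
        a1 = generate_annotations(g, n_genes=40, seed=3)
        a2 = generate_annotations(g, n_genes=40, seed=3)
        assert a1.entries == a2.entries
        assert all(terms for terms in a1.entries.values())

    def test_propagated_counts_match_per_gene_closure_oracle(self):
        g = generate_ontology(n_terms=60, seed=3)
        ann = generate_annotations(g, n_genes=40, seed=3)
        for term in sorted(g.active_terms)[:15]:
            closure = {term} | descendants(g, term)
            expected = {ge for ge, ts in ann.entries.items() if ts & closure}
            assert annotated_genes(g, ann, term) == expected


class TestGenerateVersionPair:
    def test_zero_churn_preserves_graph(self):
        g = generate_ontology(n_terms=50, seed=7)
        old, new, churn = generate_version_pair(g, p_obsolete=0, n_new_terms=0,
                                                p_rewire=0, seed=7)
        assert set(old.terms) == set(new.terms)
        assert sorted(old.edges()) == sorted(new.edges())
        assert not churn["obsoleted"] and not churn["created"] and not churn["rewired"]

    def test_churn_truth_consistent_with_graphs(self):
        g = generate_ontology(n_terms=100, seed=8)
        old, new, churn = generate_version_pair(g, p_obsolete=0.1, n_new_terms=7,
                                                p_rewire=0.1, seed=8)
        for t in churn["obsoleted"]:
            assert old.is_active(t) and not new.is_active(t)
        for t in churn["created"]:
            assert t not in old and new.is_active(t)
        assert len(churn["obsoleted"]) == round(0.1 * len([
            t for t in old.active_terms if t not in old.roots()
        ]))

    def test_deterministic_under_seed(self):
        g = generate_ontology(n_terms=100, seed=8)
        _, n1, c1 = generate_version_pair(g, 0.1, 5, 0.05, seed=8)
        _, n2, c2 = generate_version_pair(g, 0.1, 5, 0.05, seed=8)
        assert sorted(n1.edges()) == sorted(n2.edges())
        assert c1["obsoleted"] == c2["obsoleted"]


class TestGenerateExpression:
    def test_no_structure_when_within_cor_zero(self):
        from hallmap.coexpr import adjacency, detect_modules, preprocess, tom

        expr, _ = generate_expression(60, 40, [20, 20], within_cor=0.0, seed=1)
        adj = adjacency(preprocess(expr), beta=6)
        labels = detect_modules(tom(adj), min_module_size=15)
        assert set(labels) == {0}

    def test_realized_within_module_correlation_near_target(self):
        target = 0.9
        realized = []
        for seed in range(20):
            expr, labels = generate_expression(60, 80, [50], within_cor=target,
                                               seed=seed)
            logged = np.log2(expr.to_numpy() + 1)
            block = logged[(labels == 1).to_numpy()]
            cor = np.corrcoef(block)
            iu = np.triu_indices_from(cor, k=1)
            realized.append(cor[iu].mean())
        assert abs(np.mean(realized) - target) < 0.05

    def test_deterministic_under_seed(self):
        e1, l1 = generate_expression(30, 20, [10], seed=5)
        e2, l2 = generate_expression(30, 20, [10], seed=5)
        pd.testing.assert_frame_equal(e1, e2)
        pd.testing.assert_series_equal(l1, l2)


class TestGeneratePrognostic:
    def test_planted_combination_recovered_exactly(self):
        pool = [f"g{i}" for i in range(200)]
        table, truth = generate_prognostic(
            pool, n_cancers=5, per_cancer_rate=0.1,
            planted_combinations=[(("cancer_01", "cancer_02"), 8)], seed=2,
        )
        partition = subgroup_partition(table, min_size=5)
        combo = frozenset({"cancer_01", "cancer_02"})
        assert partition.groups[combo] == truth["planted"][combo]
        assert len(truth["planted"][combo]) == 8

    def test_zero_rate_and_no_planting_gives_empty_table(self):
        table, _ = generate_prognostic([f"g{i}" for i in range(50)],
                                       n_cancers=3, per_cancer_rate=0.0, seed=1)
        assert all(not genes for genes in table.values())

    def test_deterministic_under_seed(self):
        pool = [f"g{i}" for i in range(100)]
        t1, _ = generate_prognostic(pool, seed=9)
        t2, _ = generate_prognostic(pool, seed=9)
        assert t1 == t2


class TestWorld:
    def test_world_is_byte_identical_under_seed(self, tmp_path):
        w1 = generate_world(seed=3, scale=0.05)
        w2 = generate_world(seed=3, scale=0.05)
        assert sorted(w1.graph_old.edges()) == sorted(w2.graph_old.edges())
        assert w1.annotations_old.entries == w2.annotations_old.entries
        pd.testing.assert_frame_equal(w1.expression, w2.expression)
        assert w1.prognostic == w2.prognostic
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_world(w1, d1)
        write_world(w2, d2)
        for f in sorted(p.name for p in d1.iterdir()):
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes()

    def test_truth_scores_scheme_stage_without_regeneration(self):
        from hallmap.schemes import build_hallmark_gene_sets

        w = generate_world(seed=4, scale=0.05)
        scheme = w.schemes[0]
        gs = build_hallmark_gene_sets(scheme, w.graph_old, w.annotations_old)
        truth_sel = w.truth["schemes"]["selections"][scheme.scheme_id]
        assert set(gs.per_hallmark) == set(truth_sel)
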