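"""Co-expression preprocessing, network construction, modules, hubs, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from hallmap.coexpr import (
    adjacency,
    detect_modules,
    enrich,
    hub_genes,
    intramodular_connectivity,
    pick_soft_threshold,
    preprocess,
    scale_free_fit,
    tom,
)
from hallmap.ontology import AnnotationTable, OntologyGraph, OntologyTerm
from hallmap.synthetic import generate_expression


def frame(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=[f"{prefix}{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )


class TestPreprocess:
    def test_all_zero_matrix_with_unit_offset(self):
        out = preprocess(frame(np.zeros((3, 4))), log_offset=1)
        assert (out.to_numpy() == 0).all()

    def test_no_cut_keeps_all_samples(self):
        out = preprocess(frame(np.random.default_rng(0).random((5, 6))))
        assert out.shape[1] == 6

    def test_planted_extreme_sample_removed(self, rng):
        values = rng.random((20, 10)) * 4
        values[:, 3] += 10 * values.std()  # one sample far from the rest
        out = preprocess(frame(values), outlier_cut_height=5.0)
        assert out.shape[1] == 9
        assert "s3" not in out.columns

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            preprocess(frame([[-1.0, 2.0, 1.0, 1.0]]))


class TestSoftThreshold:
    def test_exact_power_law_degrees_fit_near_one(self):
        # freq(k) proportional to k^-1 on a log-spaced grid is exactly
        # log-log linear, so the binned regression must fit almost perfectly.
        k = np.concatenate([[2.0 ** j] * (2 ** (10 - j)) for j in range(10)])
        assert scale_free_fit(k) > 0.95

    def test_flat_degree_sequence_fits_poorly(self, rng):
        k = rng.uniform(10, 11, size=500)
        assert scale_free_fit(k) < 0.8

    def test_zero_cut_accepts_first_power(self, rng):
        expr = frame(rng.random((10, 8)))
        beta, table = pick_soft_threshold(expr, r2_cut=0.0)
        assert beta == 1
        assert list(table["power"]) == list(range(1, 21))

    def test_deterministic_for_fixed_seed(self):
        expr1, _ = generate_expression(60, 30, [20, 20], seed=5)
        expr2, _ = generate_expression(60, 30, [20, 20], seed=5)
        b1, _ = pick_soft_threshold(preprocess(expr1))
        b2, _ = pick_soft_threshold(preprocess(expr2))
        assert b1 == b2

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            pick_soft_threshold(frame(np.ones((2, 10))))


class TestAdjacency:
    def test_perfectly_correlated_pair_is_one(self):
        expr = frame([[1, 2, 3, 4], [2, 4, 6, 8]])
        adj = adjacency(expr, beta=7)
        assert adj.iloc[0, 1] == pytest.approx(1.0)

    def test_uncorrelated_pair_vanishes_at_large_beta(self, rng):
        expr = frame(rng.standard_normal((2, 200)))
        assert adjacency(expr, beta=20).iloc[0, 1] < 1e-6

    def test_matches_elementwise_formula(self, rng):
        expr = frame(rng.random((5, 12)))
        beta = 4
        adj = adjacency(expr, beta)
        cor = np.corrcoef(expr.to_numpy())
        for i in range(5):
            for j in range(5):
                expected = 0.0 if i == j else abs(cor[i, j]) ** beta
                assert adj.iloc[i, j] == pytest.approx(expected)

    def test_beta_below_one_rejected(self, rng):
        with pytest.raises(ValueError):
            adjacency(frame(rng.random((3, 5))), beta=0.5)


def tom_loop_oracle(a):
    """Triple-loop reference implementation of topological overlap."""
    a = np.array(a, dtype=float)
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


class TestTOM:
    def test_zero_adjacency_gives_zero_offdiagonal(self):
        t = tom(np.zeros((4, 4)))
        assert np.allclose(t, np.eye(4))

    def test_three_node_hand_value(self):
        a = np.array([[0, 0.5, 0.3], [0.5, 0, 0.4], [0.3, 0.4, 0]])
        t = tom(a)
        assert t[0, 1] == pytest.approx(0.62 / 1.3)

    def test_matches_loop_oracle_on_random_matrices(self, rng):
        for _ in range(5):
            a = rng.random((20, 20))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            assert np.allclose(tom(a), tom_loop_oracle(a))

    def test_range_and_symmetry(self, rng):
        a = rng.random((15, 15))
        a = (a + a.T) / 2
        t = tom(a)
        assert np.allclose(t, t.T)
        assert (t >= 0).all() and (t <= 1 + 1e-12).all()

    def test_asymmetric_input_rejected(self, rng):
        with pytest.raises(ValueError):
            tom(rng.random((5, 5)))


class TestDetectModules:
    def test_two_disconnected_blocks_recovered_exactly(self):
        n = 50
        a = np.zeros((2 * n, 2 * n))
        a[:n, :n] = 0.8
        a[n:, n:] = 0.8
        np.fill_diagonal(a, 0.0)
        t = tom(pd.DataFrame(a, index=[f"g{i}" for i in range(2 * n)],
                             columns=[f"g{i}" for i in range(2 * n)]))
        labels = detect_modules(t, min_module_size=20)
        assert set(labels) == {1, 2}
        assert len(set(labels.iloc[:n])) == 1
        assert len(set(labels.iloc[n:])) == 1

    def test_identical_profiles_form_single_module(self):
        a = np.full((30, 30), 1.0)
        np.fill_diagonal(a, 0.0)
        df = pd.DataFrame(a, index=[f"g{i}" for i in range(30)],
                          columns=[f"g{i}" for i in range(30)])
        labels = detect_modules(tom(df), min_module_size=20)
        assert set(labels) == {1}

    def test_planted_modules_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        expr, truth = generate_expression(150, 100, [50, 50, 50],
                                          within_cor=0.8, seed=11)
        adj = adjacency(preprocess(expr), beta=6)
        labels = detect_modules(tom(adj), min_module_size=20)
        assert adjusted_rand_score(truth, labels) > 0.9


class TestHubGenes:
    def _adj(self, values, genes):
        return pd.DataFrame(values, index=genes, columns=genes)

    def test_small_module_returns_everyone(self):
        genes = [f"g{i}" for i in range(5)]
        a = np.full((5, 5), 0.5)
        np.fill_diagonal(a, 0)
        labels = pd.Series([1] * 5, index=genes)
        assert hub_genes(self._adj(a, genes), labels, n=5)[1] == genes

    def test_tie_at_rank_five_extends_hub_set(self):
        genes = [f"g{i}" for i in range(7)]
        # star weights through g6 set kWithin: g6 highest, then g0..g2, and
        # g3/g4 tied at the 5th rank; g5 below the cut.
        star = np.array([10, 9, 8, 6, 6, 1], dtype=float)
        a = np.zeros((7, 7))
        for i, k in enumerate(star):
            a[i, 6] = a[6, i] = k
        labels = pd.Series([1] * 7, index=genes)
        hubs = hub_genes(self._adj(a, genes), labels, n=5)[1]
        assert len(hubs) == 6
        assert set(hubs) == {"g6", "g0", "g1", "g2", "g3", "g4"}

    def test_invariant_to_gene_ordering(self, rng):
        genes = [f"g{i}" for i in range(30)]
        a = rng.random((30, 30))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        labels = pd.Series([1] * 15 + [2] * 15, index=genes)
        adj = self._adj(a, genes)
        hubs = hub_genes(adj, labels)
        perm = rng.permutation(30)
        adj_shuffled = adj.iloc[perm, perm]
        hubs_shuffled = hub_genes(adj_shuffled, labels.iloc[perm])
        assert {m: set(h) for m, h in hubs.items()} == {
            m: set(h) for m, h in hubs_shuffled.items()
        }

    def test_matches_sort_then_threshold_brute_force(self, rng):
        genes = [f"g{i}" for i in range(40)]
        a = rng.random((40, 40))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        labels = pd.Series(rng.integers(1, 4, size=40), index=genes)
        adj = self._adj(a, genes)
        kw = intramodular_connectivity(adj, labels)
        hubs = hub_genes(adj, labels, n=5)
        for module, hub_list in hubs.items():
            members = [g for g in genes if labels[g] == module]
            ranked = sorted(members, key=lambda g: -kw[g])
            cutoff = kw[ranked[min(4, len(ranked) - 1)]]
            expected = {g for g in members if kw[g] >= cutoff - 1e-12}
            assert set(hub_list) == expected


def _enrichment_world():
    g = OntologyGraph("enrich")
    for t in ("ROOT", "T1", "T2"):
        g.add_term(OntologyTerm(t))
    g.add_edge("T1", "ROOT", "is_a")
    g.add_edge("T2", "ROOT", "is_a")
    return g


class TestEnrich:
    def test_term_annotating_whole_background_has_p_one(self):
        g = _enrichment_world()
        ann = AnnotationTable()
        background = {f"g{i}" for i in range(10)}
        for gene in background:
            ann.add(gene, "T1")
        records = enrich({"g0", "g1"}, background, g, ann)
        by_term = {r.term_id: r for r in records}
        assert by_term["T1"].p_raw == pytest.approx(1.0)

    def test_closed_form_tail_value(self):
        # N=10, K=5, n=3, k=3 -> C(5,3)/C(10,3) = 10/120
        g = _enrichment_world()
        ann = AnnotationTable()
        genes = [f"g{i}" for i in range(10)]
        for gene in genes[:5]:
            ann.add(gene, "T1")
        for gene in genes[5:]:
            ann.add(gene, "T2")
        records = enrich(set(genes[:3]), set(genes), g, ann)
        by_term = {r.term_id: r for r in records}
        assert by_term["T1"].p_raw == pytest.approx(10 / 120)

    def test_true_path_propagation_reaches_parent_terms(self):
        g = _enrichment_world()
        ann = AnnotationTable()
        ann.add("g0", "T1")
        records = enrich({"g0"}, {"g0", "g1"}, g, ann)
        assert {r.term_id for r in records} == {"T1", "ROOT"}

    def test_module_not_in_background_rejected(self):
        g = _enrichment_world()
        with pytest.raises(ValueError):
            enrich({"gX"}, {"g0"}, g, AnnotationTable())

    def test_planted_term_ranks_first(self):
        from hallmap.synthetic import (
            generate_annotations,
            generate_ontology,
            plant_module_enrichment,
        )

        graph = generate_ontology(n_terms=100, seed=3)
        ann = generate_annotations(graph, n_genes=200, seed=3)
        genes = sorted(ann.entries)
        labels = pd.Series([1] * 40 + [0] * 160, index=genes)
        planted = plant_module_enrichment(graph, ann, labels, seed=3)
        records = enrich(set(genes[:40]), set(genes), graph, ann)
        assert records[0].term_id == planted[1]

    def test_null_p_values_approximately_uniform(self, rng):
        """Random module membership -> hypergeometric p close to U(0,1)."""
        N, K, n = 500, 250, 100
        background = [f"g{i}" for i in range(N)]
        g = OntologyGraph("null")
        g.add_term(OntologyTerm("T"))
        ann = AnnotationTable()
        for gene in background[:K]:
            ann.add(gene, "T")
        pvals = []
        for _ in range(200):
            module = set(rng.choice(background, size=n, replace=False))
            recs = enrich(module, set(background), g, ann)
            if recs:
                pvals.append(recs[0].p_raw)
        assert kstest(pvals, "uniform").pvalue > 0.01
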