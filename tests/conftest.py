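import numpy as np
import pytest

from hallmap.ontology import OntologyGraph, OntologyTerm


def make_chain() -> OntologyGraph:
    """C is_a B is_a A (A is the root)."""
    g = OntologyGraph("chain")
    for t in ("A", "B", "C"):
        g.add_term(OntologyTerm(t))
    g.add_edge("B", "A", "is_a")
    g.add_edge("C", "B", "is_a")
    g.validate()
    return g


def make_two_term_chain() -> OntologyGraph:
    """A is_a B: the minimal parent/child pair."""
    g = OntologyGraph("pair")
    g.add_term(OntologyTerm("B"))
    g.add_term(OntologyTerm("A"))
    g.add_edge("A", "B", "is_a")
    g.validate()
    return g


def make_random_dag(
    n: int,
    rng: np.random.Generator,
    p_edge: float = 0.15,
    p_part_of: float = 0.3,
) -> OntologyGraph:
    """Random DAG on ids t0..t{n-1}; edges only from higher to lower index."""
    g = OntologyGraph(f"random-{n}")
    for i in range(n):
        g.add_term(OntologyTerm(f"t{i}"))
    for child in range(1, n):
        parents = [p for p in range(child) if rng.random() < p_edge]
        if not parents:
            parents = [int(rng.integers(child))]
        for p in parents:
            rel = "part_of" if rng.random() < p_part_of else "is_a"
            g.add_edge(f"t{child}", f"t{p}", rel)
    g.validate()
    return g


@pytest.fixture
def chain():
    return make_chain()


@pytest.fixture
def pair():
    return make_two_term_chain()


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
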