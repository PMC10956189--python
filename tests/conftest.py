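import numpy as np
import pytest

from varprio.ontology import Ontology, compute_ic
from varprio.phenosim import DiseaseEntry, SemanticSimilarity


@pytest.fixture(scope="session")
def diamond_ontology():
    """root <- A, root <- B, A <- C, B <- C, A <- L (unannotated leaf)."""
    return Ontology(
        {
            "root": set(),
            "A": {"root"},
            "B": {"root"},
            "C": {"A", "B"},
            "L": {"A"},
        }
    )


@pytest.fixture(scope="session")
def diamond_corpus():
    """Four diseases; propagated counts: C:1, A:2, B:3, L:0, root:4."""
    return {"d1": {"C"}, "d2": {"A"}, "d3": {"B"}, "d4": {"B"}}


@pytest.fixture(scope="session")
def diamond_ic(diamond_ontology, diamond_corpus):
    return compute_ic(diamond_ontology, diamond_corpus)


@pytest.fixture(scope="session")
def diamond_sim(diamond_ontology, diamond_ic):
    return SemanticSimilarity(diamond_ontology, diamond_ic)


def naive_ancestors(parents: dict, term: str) -> set:
    """Independent reflexive ancestor closure (oracle, no memoization)."""
    out = {term}
    frontier = [term]
    while frontier:
        t = frontier.pop()
        for p in parents.get(t, ()):
            if p not in out:
                out.add(p)
                frontier.append(p)
    return out


def naive_resnik(parents: dict, ic: dict, t1: str, t2: str) -> float:
    """Brute-force MICA: max IC over the explicit ancestor intersection."""
    return max(
        ic[a] for a in naive_ancestors(parents, t1) & naive_ancestors(parents, t2)
    )


def random_dag(rng: np.random.Generator, n_terms: int, max_parents: int = 3) -> dict:
    """Small random rooted DAG as a parents mapping (test-local generator)."""
    ids = [f"T{i}" for i in range(n_terms)]
    parents = {ids[0]: set()}
    for i in range(1, n_terms):
        k = int(rng.integers(1, min(max_parents, i) + 1))
        parents[ids[i]] = {ids[int(j)] for j in rng.choice(i, size=k, replace=False)}
    return parents


@pytest.fixture(scope="session")
def toy_disease_entries():
    return {
        "dis1": DiseaseEntry("dis1", frozenset({"C"}), frozenset({"G1"}), frozenset({"AD"})),
        "dis2": DiseaseEntry("dis2", frozenset({"A", "B"}), frozenset({"G1"}), frozenset({"AR"})),
        "dis3": DiseaseEntry("dis3", frozenset({"B"}), frozenset({"G2"}), frozenset({"XLR"})),
    }
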