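"""Phenotype ontology DAG, information content, and Resnik term similarity.

The ontology is a rooted DAG of phenotype terms (HPO-like) linked by is_a
edges.  Information content is annotation-propagated Resnik IC: a term's
probability is the fraction of corpus diseases annotated to the term or any
of its descendants, and ic(t) = -log p(t).  Term-level similarity is the IC
of the most informative common ancestor (MICA), taken over the reflexive
ancestor closure so that resnik_sim(t, t) = ic(t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

__all__ = ["Ontology", "ICTable", "compute_ic", "resnik_sim"]


class Ontology:
    """Rooted DAG of phenotype terms with memoized ancestor closure."""

    def __init__(self, parents: Mapping[str, Iterable[str]], root: str | None = None):
        self.parents: dict[str, frozenset[str]] = {
            t: frozenset(ps) for t, ps in parents.items()
        }
        # terms mentioned only as parents are still terms
        for ps in list(self.parents.values()):
            for p in ps:
                self.parents.setdefault(p, frozenset())
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for t, ps in self.parents.items():
            for p in ps:
                g.add_edge(t, p)  # child -> parent
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology contains a cycle")
        roots = sorted(t for t, ps in self.parents.items() if not ps)
        if root is not None:
            if root not in self.parents:
                raise KeyError(f"designated root {root!r} not among terms")
            self.root = root
        elif len(roots) == 1:
            self.root = roots[0]
        else:
            raise ValueError(
                f"ontology has {len(roots)} roots ({roots[:5]}...); supply root="
            )
        self._graph = g
        self._ancestors: dict[str, frozenset[str]] = {}
        self._children: dict[str, set[str]] | None = None

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.parents)

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def __len__(self) -> int:
        return len(self.parents)

    def ancestors(self, term: str) -> frozenset[str]:
        """Reflexive transitive closure over parent edges (includes term and root)."""
        if term not in self.parents:
            raise KeyError(f"unknown term: {term!r}")
        cached = self._ancestors.get(term)
        if cached is None:
            closure = {term}
            for p in self.parents[term]:
                closure |= self.ancestors(p)
            cached = self._ancestors[term] = frozenset(closure)
        return cached

    def children(self, term: str) -> set[str]:
        if self._children is None:
            ch: dict[str, set[str]] = {t: set() for t in self.parents}
            for t, ps in self.parents.items():
                for p in ps:
                    ch[p].add(t)
            self._children = ch
        return self._children[term]

    def descendants(self, term: str) -> frozenset[str]:
        """Reflexive descendant closure (terms whose ancestors include ``term``)."""
        if term not in self.parents:
            raise KeyError(f"unknown term: {term!r}")
        out = {term}
        stack = [term]
        while stack:
            for c in self.children(stack.pop()):
                if c not in out:
                    out.add(c)
                    stack.append(c)
        return frozenset(out)


@dataclass
class ICTable:
    """Per-term information content over an annotation corpus.

    ``ic`` is in units of the configured log base (nats by default);
    ``p`` is the propagated annotation frequency; ``corpus_size`` the number
    of annotated diseases.
    """

    ic: dict[str, float]
    p: dict[str, float]
    corpus_size: int
    log_base: float = field(default=math.e)

    def __getitem__(self, term: str) -> float:
        try:
            return self.ic[term]
        except KeyError:
            raise KeyError(f"term {term!r} has no information content") from None

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("term_id\tp\tic\n")
            for t in sorted(self.ic):
                fh.write(f"{t}\t{self.p[t]:.10g}\t{self.ic[t]:.10g}\n")


def compute_ic(
    ontology: Ontology,
    annotations: Mapping[str, Iterable[str]],
    log_base: float = math.e,
) -> ICTable:
    """Annotation-propagated information content.

    p(t) = |{diseases annotated to t or any descendant}| / |diseases|;
    ic(t) = -log p(t).  Terms with zero propagated annotations are smoothed
    to p = 1/(N+1) so their IC stays finite.
    """
    if not annotations:
        raise ValueError("annotation corpus is empty")
    n = len(annotations)
    counts: dict[str, int] = {t: 0 for t in ontology.terms}
    for terms in annotations.values():
        propagated: set[str] = set()
        for t in terms:
            propagated |= ontology.ancestors(t)
        for t in propagated:
            counts[t] += 1
    log = math.log if log_base == math.e else (lambda x: math.log(x, log_base))
    p: dict[str, float] = {}
    ic: dict[str, float] = {}
    for t, c in counts.items():
        pt = c / n if c > 0 else 1.0 / (n + 1)
        p[t] = pt
        ic[t] = -log(pt)
    # the root covers every annotated disease by propagation
    ic[ontology.root] = 0.0 if counts[ontology.root] == n else ic[ontology.root]
    return ICTable(ic=ic, p=p, corpus_size=n, log_base=log_base)


def resnik_sim(ontology: Ontology, ic: ICTable, t1: str, t2: str) -> float:
    """IC of the most informative common ancestor of two terms."""
    common = ontology.ancestors(t1) & ontology.ancestors(t2)
    return max(ic[a] for a in common)
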