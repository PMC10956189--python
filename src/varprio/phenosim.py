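"""Set-level phenotype similarity with gene-level softmax upweighting.

A patient's phenotype set Q is compared with a disease's annotation set D
through best-match averaging of Resnik term similarities:

    one_sided(Q -> D)  = mean over t1 in Q of max over t2 in D of sim(t1, t2)
    two_sided(Q, D)    = (one_sided(Q->D) + one_sided(D->Q)) / 2

Candidate diseases are additionally up-weighted by how well Q matches the
phenotype profile of the disease's gene relative to the other candidate
genes of the same patient:

    weight(g) = 1 + softmax over candidate genes of two_sided(Q, profile(g))
    upweighted(Q, D_k) = weight(gene of D_k) * two_sided(Q, D_k)

where profile(g) is the union of term sets over the gene's diseases.  The
softmax shares sum to 1 across the patient's candidate genes, so each
weight lies in (1, 2].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .ontology import ICTable, Ontology, resnik_sim

__all__ = [
    "PhenotypeProfile",
    "DiseaseEntry",
    "GeneContext",
    "SemanticSimilarity",
]

#: Recognised inheritance-pattern codes.
INHERITANCE_CODES = frozenset({"AD", "AR", "XLD", "XLR", "MT", "YL"})


@dataclass(frozen=True)
class PhenotypeProfile:
    """A set of ontology term ids (patient symptoms, disease or gene profile)."""

    terms: frozenset[str]

    def __init__(self, terms: Iterable[str]):
        object.__setattr__(self, "terms", frozenset(terms))

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class DiseaseEntry:
    """One disease: its phenotype annotation set, genes and inheritance modes."""

    disease_id: str
    phenotype_terms: frozenset[str]
    genes: frozenset[str]
    inheritance_patterns: frozenset[str]

    def __post_init__(self) -> None:
        unknown = self.inheritance_patterns - INHERITANCE_CODES
        if unknown:
            raise ValueError(f"unknown inheritance codes: {sorted(unknown)}")


@dataclass
class GeneContext:
    """A candidate gene within one patient's ranking context."""

    gene: str
    diseases: frozenset[str]
    profile: PhenotypeProfile
    weight: float = field(default=float("nan"))


class SemanticSimilarity:
    """Resnik term and set similarities over one ontology + IC table.

    Term-pair similarities are memoized; profiles in this pipeline are
    small sets, so best-match averaging stays cheap even across thousands
    of (variant, disease) pairs.
    """

    def __init__(self, ontology: Ontology, ic: ICTable):
        self.ontology = ontology
        self.ic = ic
        self._cache: dict[tuple[str, str], float] = {}

    def term_sim(self, t1: str, t2: str) -> float:
        if t1 > t2:
            t1, t2 = t2, t1
        key = (t1, t2)
        val = self._cache.get(key)
        if val is None:
            val = self._cache[key] = resnik_sim(self.ontology, self.ic, t1, t2)
        return val

    def one_sided(self, q: PhenotypeProfile, d: PhenotypeProfile) -> float:
        """Mean over terms of q of their best Resnik match in d; 0 on empty sets."""
        if not q.terms or not d.terms:
            return 0.0
        total = 0.0
        for t1 in q.terms:
            total += max(self.term_sim(t1, t2) for t2 in d.terms)
        return total / len(q.terms)

    def two_sided(self, q: PhenotypeProfile, d: PhenotypeProfile) -> float:
        return 0.5 * self.one_sided(q, d) + 0.5 * self.one_sided(d, q)

    def gene_weights(
        self, q: PhenotypeProfile, genes: Sequence[GeneContext]
    ) -> dict[str, float]:
        """Softmax gene upweighting over a patient's candidate-gene context.

        Returns per-gene weights 1 + softmax(two_sided(Q, profile(g))); the
        shares sum to 1 across the context, and each weight lies in (1, 2].
        The ``weight`` field of each context is filled in place.
        """
        if not genes:
            raise ValueError("gene context is empty")
        sims = np.array([self.two_sided(q, g.profile) for g in genes], dtype=float)
        shifted = np.exp(sims - sims.max())  # stable softmax
        shares = shifted / shifted.sum()
        weights: dict[str, float] = {}
        for g, share in zip(genes, shares):
            g.weight = 1.0 + float(share)
            weights[g.gene] = g.weight
        return weights

    def upweighted(
        self,
        q: PhenotypeProfile,
        disease: DiseaseEntry,
        gene_ctx: GeneContext,
    ) -> float:
        """Gene-upweighted disease similarity: weight(g) * two_sided(Q, D)."""
        if disease.disease_id not in gene_ctx.diseases:
            raise ValueError(
                f"disease {disease.disease_id} is not associated with gene "
                f"{gene_ctx.gene}"
            )
        if not np.isfinite(gene_ctx.weight):
            raise ValueError(
                "gene context has no weight; call gene_weights() for the "
                "patient's candidate genes first"
            )
        return gene_ctx.weight * self.two_sided(
            q, PhenotypeProfile(disease.phenotype_terms)
        )


def build_gene_contexts(
    genes: Iterable[str],
    diseases: Mapping[str, DiseaseEntry],
) -> list[GeneContext]:
    """Assemble per-gene contexts (member diseases and union profile)."""
    by_gene: dict[str, set[str]] = {}
    for d in diseases.values():
        for g in d.genes:
            by_gene.setdefault(g, set()).add(d.disease_id)
    out = []
    for gene in sorted(set(genes)):
        ids = by_gene.get(gene, set())
        union: set[str] = set()
        for did in ids:
            union |= diseases[did].phenotype_terms
        out.append(GeneContext(gene=gene, diseases=frozenset(ids), profile=PhenotypeProfile(union)))
    return out
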