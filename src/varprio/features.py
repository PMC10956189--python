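"""Candidate-variant filtering and assembly of the six-feature vector.

Each (variant, disease) pair is described by exactly six features, in this
canonical order:

    bayes        ACMG Bayesian posterior of pathogenicity (0, 1)
    symsim       gene-upweighted phenotype similarity (>= 0)
    insilico     in-silico pathogenicity score [0, 1], fallback-imputed
    vaf          variant allele fraction, alt reads / total reads
    qual         Phred-scaled variant-call quality
    inh_mismatch 1 if the disease inheritance mode is incompatible with the
                 observed zygosity, else 0

Variants are filtered before scoring: common alleles (population AF > 5%),
benign/likely-benign classifications, BA1-flagged variants, and variants in
genes with no known disease association are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .acmg import BayesParams, CriteriaAssignment, classify_tier, posterior
from .phenosim import (
    DiseaseEntry,
    GeneContext,
    PhenotypeProfile,
    SemanticSimilarity,
)

__all__ = [
    "FEATURE_NAMES",
    "RawVariant",
    "VariantRecord",
    "FeatureVector",
    "filter_candidates",
    "inheritance_mismatch",
    "assemble_features",
    "phred_error_probability",
]

#: Canonical feature order; every model consumes a subset of these columns.
FEATURE_NAMES: tuple[str, ...] = (
    "bayes",
    "symsim",
    "insilico",
    "vaf",
    "qual",
    "inh_mismatch",
)

#: Fallback in-silico score for variants the upstream predictor cannot
#: evaluate (cohort-average constant).
INSILICO_FALLBACK = 0.206

#: Population allele-frequency cutoff above which variants are discarded.
MAX_POPULATION_AF = 0.05

ZYGOSITIES = ("het", "hom", "hemi")


def phred_error_probability(qual: float) -> float:
    """Probability that no variant exists at the site, from the Phred QUAL.

    QUAL = 20 corresponds to an error probability of 1%; QUAL = 50 to 1e-5.
    """
    if qual < 0:
        raise ValueError("QUAL must be non-negative")
    return 10.0 ** (-qual / 10.0)


@dataclass(frozen=True)
class RawVariant:
    """One biallelic called variant as read from a VCF sample column."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float | None = None
    genotype: str = "./."
    allele_depths: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be 1-based (>= 1)")
        if min(self.allele_depths) < 0:
            raise ValueError("allele depths must be non-negative")

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}-{self.pos}-{self.ref}-{self.alt}"

    @property
    def vaf(self) -> float:
        ref_d, alt_d = self.allele_depths
        total = ref_d + alt_d
        return alt_d / total if total > 0 else 0.0

    @property
    def zygosity(self) -> str:
        """Zygosity of the alt allele implied by the genotype call."""
        alleles = [a for a in self.genotype.replace("|", "/").split("/") if a != "."]
        alt_count = sum(a == "1" for a in alleles)
        if len(alleles) == 1:
            return "hemi" if alt_count == 1 else "ref"
        if alt_count >= 2:
            return "hom"
        if alt_count == 1:
            return "het"
        return "ref"


@dataclass(frozen=True)
class VariantRecord:
    """A candidate variant with all per-variant annotations attached."""

    raw: RawVariant
    gene: str
    criteria: CriteriaAssignment
    zygosity: str = "het"
    population_af: float | None = None
    insilico_score: float | None = None
    bayes_params: BayesParams = field(default=BayesParams())

    def __post_init__(self) -> None:
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"unknown zygosity: {self.zygosity!r}")

    @property
    def variant_id(self) -> str:
        return self.raw.variant_id

    @property
    def bayes_score(self) -> float:
        return posterior(self.criteria, self.bayes_params)

    @property
    def tier(self) -> str:
        return classify_tier(self.bayes_score, ba1=self.criteria.ba1)

    @property
    def vaf(self) -> float:
        return self.raw.vaf

    @property
    def qual(self) -> float:
        """QUAL with missing values imputed to 0 (most conservative)."""
        return self.raw.qual if self.raw.qual is not None else 0.0


@dataclass(frozen=True)
class FeatureVector:
    """The six model features for one (variant, disease) pair."""

    bayes: float
    symsim: float
    insilico: float
    vaf: float
    qual: float
    inh_mismatch: bool

    def as_tuple(self) -> tuple[float, ...]:
        return (
            self.bayes,
            self.symsim,
            self.insilico,
            self.vaf,
            self.qual,
            float(self.inh_mismatch),
        )


def filter_candidates(
    variants: Sequence[VariantRecord],
    gene_disease_map: Mapping[str, object],
) -> list[VariantRecord]:
    """Apply the candidate filters, preserving input order.

    Removes variants with population AF > 5%, benign/likely-benign tier,
    a BA1 flag, or a gene absent from the disease-association map.
    Missing population AF is treated as 0 (rare until proven common).
    """
    out = []
    for v in variants:
        af = v.population_af if v.population_af is not None else 0.0
        if af > MAX_POPULATION_AF:
            continue
        if v.criteria.ba1:
            continue
        if v.tier in ("B", "LB"):
            continue
        if v.gene not in gene_disease_map:
            continue
        out.append(v)
    return out


# zygosity states compatible with each inheritance mode; a lone heterozygous
# variant is treated as incompatible with AR (per-variant view, no phasing).
_COMPATIBLE: dict[str, frozenset[str]] = {
    "AD": frozenset({"het", "hom"}),
    "AR": frozenset({"hom"}),
    "XLR": frozenset(),  # sex-dependent, handled below
    "XLD": frozenset({"het", "hom", "hemi"}),
    "MT": frozenset({"hom", "hemi"}),
    "YL": frozenset({"hom", "hemi"}),
}


def inheritance_mismatch(
    zygosity: str,
    patient_sex: str,
    patterns: Iterable[str],
) -> bool:
    """True when no inheritance mode of the disease fits the observed zygosity.

    An empty pattern set yields False (no evidence of mismatch).  With
    unknown patient sex, X-linked patterns are evaluated leniently (any
    zygosity compatible) to avoid false mismatches.
    """
    if zygosity not in ZYGOSITIES:
        raise ValueError(f"unknown zygosity: {zygosity!r}")
    if patient_sex not in ("male", "female", "unknown"):
        raise ValueError(f"unknown patient sex: {patient_sex!r}")
    patterns = list(patterns)
    if not patterns:
        return False
    for pat in patterns:
        if pat == "XLR":
            if patient_sex == "male" and zygosity == "hemi":
                return False
            if patient_sex == "female" and zygosity == "hom":
                return False
            if patient_sex == "unknown":
                return False
        elif pat == "XLD" and patient_sex == "unknown":
            return False
        else:
            compatible = _COMPATIBLE.get(pat)
            if compatible is None:
                raise ValueError(f"unknown inheritance pattern: {pat!r}")
            if zygosity in compatible:
                return False
    return True


def assemble_features(
    patient_terms: PhenotypeProfile,
    variant: VariantRecord,
    disease: DiseaseEntry,
    gene_ctx: GeneContext,
    sim: SemanticSimilarity,
    patient_sex: str = "unknown",
    insilico_fallback: float = INSILICO_FALLBACK,
) -> FeatureVector:
    """Compose the six features for one (variant, disease) pair.

    The in-silico score falls back to the cohort-average constant when the
    upstream predictor could not evaluate the variant; missing QUAL maps
    to 0 via :class:`VariantRecord`.
    """
    if disease.disease_id not in gene_ctx.diseases:
        raise ValueError(
            f"disease {disease.disease_id} not associated with gene {gene_ctx.gene}"
        )
    insilico = (
        variant.insilico_score
        if variant.insilico_score is not None
        else insilico_fallback
    )
    return FeatureVector(
        bayes=variant.bayes_score,
        symsim=sim.upweighted(patient_terms, disease, gene_ctx),
        insilico=insilico,
        vaf=variant.vaf,
        qual=variant.qual,
        inh_mismatch=inheritance_mismatch(
            variant.zygosity, patient_sex, disease.inheritance_patterns
        ),
    )


def variant_id_key(variant_id: str) -> tuple:
    """Sort key for variant ids: genomic order, then alleles."""
    chrom, pos, ref, alt = variant_id.split("-", 3)
    order = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25, "M": 25}
    c = chrom.removeprefix("chr")
    return (order.get(c, 99), c, int(pos), ref, alt)
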