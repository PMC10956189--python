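"""Self-contained synthetic cohort generation.

Everything the pipeline consumes — a phenotype ontology, a disease/gene
database, and patient cohorts with planted causative variants — is
generated from a single seed, with the statistical structure the method
assumes:

* ~122 candidate variants per patient surviving the filters, of which 1-3
  are causative (mixture 0.88 / 0.11 / 0.01);
* causative variants carry enriched pathogenic ACMG evidence, zygosity
  consistent with the disease inheritance mode, high VAF and QUAL;
* background variants carry weak evidence; a configurable fraction are
  sequencing artifacts with low VAF (< 0.3) and low QUAL (< 20), half of
  which mimic pathogenic evidence — the false positives the QC features
  exist to catch;
* patient phenotypes are the disease's annotation set thinned by a dropout
  probability plus random distractor terms;
* a fraction of background and causative variants recur across patients
  (shared polymorphisms and founder alleles), so leakage exclusion between
  folds removes real rows.

QUAL values are generated as whole numbers so that the VCF round trip
through float32 storage is exact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .acmg import BayesParams, CriteriaAssignment
from .features import RawVariant, VariantRecord
from .ontology import Ontology, compute_ic
from .phenosim import DiseaseEntry

__all__ = [
    "CohortConfig",
    "DiseaseDatabase",
    "PatientCase",
    "Cohort",
    "generate_ontology",
    "generate_database",
    "generate_cohort",
    "ground_truth",
    "write_cohort",
]

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for synthetic cohort generation.

    The defaults are the noisy configuration: phenotype dropout 0.3, two
    distractor terms, 10% artifact variants.  ``strong_signal()`` switches
    every noise source off and guarantees very strong pathogenic evidence
    on causative variants, for identifiability checks.
    """

    seed: int
    n_patients: int = 100
    variants_per_patient_mean: float = 122.0
    causative_probs: tuple[float, float, float] = (0.88, 0.11, 0.01)
    phenotype_dropout: float = 0.3
    n_distractor_terms: int = 2
    fp_fraction: float = 0.1
    fp_pathogenic_like: float = 0.5
    evidence_enrichment: str = "default"  # "default" | "strong"
    decoy_fraction: float = 0.05
    shared_background_fraction: float = 0.2
    causative_shared_fraction: float = 0.3
    insilico_missing_rate: float = 0.1
    n_ontology_terms: int = 200
    max_parents: int = 3
    n_genes: int = 150

    def __post_init__(self) -> None:
        for name in (
            "phenotype_dropout",
            "fp_fraction",
            "fp_pathogenic_like",
            "decoy_fraction",
            "shared_background_fraction",
            "causative_shared_fraction",
            "insilico_missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if abs(sum(self.causative_probs) - 1.0) > 1e-9:
            raise ValueError("causative_probs must sum to 1")
        if self.evidence_enrichment not in ("default", "strong"):
            raise ValueError("evidence_enrichment must be 'default' or 'strong'")

    @classmethod
    def strong_signal(cls, seed: int, **kw) -> "CohortConfig":
        """Noise-free configuration with guaranteed strong planted signal."""
        kw.setdefault("phenotype_dropout", 0.0)
        kw.setdefault("n_distractor_terms", 0)
        kw.setdefault("fp_fraction", 0.0)
        kw.setdefault("evidence_enrichment", "strong")
        return cls(seed=seed, **kw)


@dataclass
class DiseaseDatabase:
    """Synthetic ontology plus disease/gene annotation tables."""

    ontology: Ontology
    diseases: dict[str, DiseaseEntry]
    gene_info: dict[str, tuple[str, int]]  # gene -> (chrom, locus start)

    @property
    def gene_to_diseases(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for d in self.diseases.values():
            for g in d.genes:
                out.setdefault(g, []).append(d.disease_id)
        return out

    @property
    def annotations(self) -> dict[str, frozenset[str]]:
        return {d.disease_id: d.phenotype_terms for d in self.diseases.values()}


@dataclass
class PatientCase:
    patient_id: str
    sex: str
    date: str
    phenotype_terms: frozenset[str]
    variants: list[VariantRecord]
    causative_ids: frozenset[str]
    true_diseases: tuple[str, ...]

    @property
    def causal_genes(self) -> frozenset[str]:
        return frozenset(
            v.gene for v in self.variants if v.variant_id in self.causative_ids
        )


@dataclass
class Cohort:
    config: CohortConfig
    db: DiseaseDatabase
    patients: list[PatientCase]


# ---------------------------------------------------------------------------
# Ontology and database


def generate_ontology(
    n_terms: int, max_parents: int = 3, seed: int | np.random.Generator = 0
) -> Ontology:
    """Random rooted DAG: term i draws 1..max_parents parents among 0..i-1."""
    if n_terms < 3:
        raise ValueError("need at least 3 terms")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = [f"SP:{i:06d}" for i in range(n_terms)]
    parents: dict[str, set[str]] = {ids[0]: set()}
    for i in range(1, n_terms):
        k = int(rng.integers(1, min(max_parents, i) + 1))
        # bias toward recent terms for depth
        weights = np.arange(1, i + 1, dtype=float) ** 1.5
        weights /= weights.sum()
        choice = rng.choice(i, size=k, replace=False, p=weights)
        parents[ids[i]] = {ids[int(j)] for j in choice}
    return Ontology(parents)


def generate_database(config: CohortConfig) -> DiseaseDatabase:
    """Ontology, gene loci, and leaf-biased disease annotations.

    Roughly 10% of genes sit on the X chromosome and get X-linked disease
    modes; autosomal genes get AD or AR.  Each gene carries 1-2 diseases
    with 3-10 annotation terms biased toward deep (informative) terms.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    onto = generate_ontology(config.n_ontology_terms, config.max_parents, rng)
    terms = sorted(onto.terms - {onto.root})
    depth = np.array([len(onto.ancestors(t)) for t in terms], dtype=float)
    term_w = depth**2
    term_w /= term_w.sum()

    gene_info: dict[str, tuple[str, int]] = {}
    diseases: dict[str, DiseaseEntry] = {}
    n_x = max(2, config.n_genes // 10)
    disease_idx = 0
    for gi in range(config.n_genes):
        gene = f"GENE{gi:04d}"
        on_x = gi < n_x
        chrom = "X" if on_x else str(1 + gi % 22)
        start = 1_000_000 + 200_000 * gi
        gene_info[gene] = (chrom, start)
        n_dis = 1 + int(rng.random() < 0.3)
        for _ in range(n_dis):
            did = f"DIS:{disease_idx:05d}"
            disease_idx += 1
            n_t = int(rng.integers(3, 11))
            chosen = rng.choice(len(terms), size=n_t, replace=False, p=term_w)
            if on_x:
                inh = rng.choice(["XLR", "XLD"], p=[0.7, 0.3])
            else:
                inh = rng.choice(["AD", "AR"], p=[0.55, 0.45])
            diseases[did] = DiseaseEntry(
                disease_id=did,
                phenotype_terms=frozenset(terms[int(i)] for i in chosen),
                genes=frozenset({gene}),
                inheritance_patterns=frozenset({str(inh)}),
            )
    return DiseaseDatabase(ontology=onto, diseases=diseases, gene_info=gene_info)


# ---------------------------------------------------------------------------
# Criteria distributions

_STRONG_CAUSATIVE = [("PVS1", "PM2"), ("PVS1", "PM1", "PM2"), ("PVS1", "PS1", "PM2")]
_MODERATE_CAUSATIVE = [
    ("PS1", "PM2", "PP3"),
    ("PS4", "PM2", "PP3", "PP5"),
    ("PS1", "PM1", "PM2"),
]
_WEAK_CAUSATIVE = [("PM1", "PM2", "PP3"), ("PM2", "PP3", "PP5"), ("PM1", "PM2")]
_BACKGROUND = [(), ("PM2",), ("PP3",), ("PM2", "PP3"), ("BP4",), ("PP3", "BP1")]
_BACKGROUND_P = np.array([0.40, 0.22, 0.18, 0.10, 0.06, 0.04])


def _draw_causative_criteria(rng, enrichment: str) -> tuple[str, ...]:
    if enrichment == "strong":
        return _STRONG_CAUSATIVE[int(rng.integers(len(_STRONG_CAUSATIVE)))]
    u = rng.random()
    if u < 0.55:
        pool = _STRONG_CAUSATIVE
    elif u < 0.90:
        pool = _MODERATE_CAUSATIVE
    else:
        pool = _WEAK_CAUSATIVE
    return pool[int(rng.integers(len(pool)))]


def _draw_background_criteria(rng, enrichment: str) -> tuple[str, ...]:
    if enrichment == "strong":
        return () if rng.random() < 0.5 else ("PP3",)
    return _BACKGROUND[int(rng.choice(len(_BACKGROUND), p=_BACKGROUND_P))]


# ---------------------------------------------------------------------------
# Cohort generation


def _zygosity_for(inh: str, sex: str) -> str:
    if inh == "AD":
        return "het"
    if inh == "AR":
        return "hom"
    if inh == "XLR":
        return "hemi" if sex == "male" else "hom"
    if inh == "XLD":
        return "hemi" if sex == "male" else "het"
    return "hom"


def _sample_read_support(rng, zygosity: str, artifact: bool) -> tuple[int, int, int]:
    """(ref_depth, alt_depth, qual) for one called variant."""
    depth = max(20, int(rng.poisson(100)))
    if artifact:
        vaf = rng.uniform(0.05, 0.29)
        qual = int(rng.integers(2, 20))
    else:
        if zygosity == "het":
            vaf = rng.beta(40, 40)
        else:
            vaf = rng.beta(60, 3)
        qual = int(rng.integers(50, 150))
    alt = int(np.clip(rng.binomial(depth, vaf), 1, depth))
    return depth - alt, alt, qual


def _genotype_for(zygosity: str) -> str:
    return {"het": "0/1", "hom": "1/1", "hemi": "1"}[zygosity]


def _make_variant(
    rng,
    gene: str,
    db: DiseaseDatabase,
    *,
    zygosity: str,
    criteria_codes: tuple[str, ...],
    artifact: bool = False,
    population_af: float = 0.0,
    used_positions: set[tuple[str, int]],
    fixed_site: tuple[str, int, str, str] | None = None,
) -> VariantRecord:
    chrom, start = db.gene_info.get(gene, ("0", 1))
    if fixed_site is not None:
        chrom, pos, ref, alt = fixed_site
    else:
        while True:
            pos = start + int(rng.integers(0, 50_000))
            if (chrom, pos) not in used_positions:
                break
        ref, alt = (str(b) for b in rng.choice(_BASES, size=2, replace=False))
    used_positions.add((chrom, pos))
    ref_d, alt_d, qual = _sample_read_support(rng, zygosity, artifact)
    raw = RawVariant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        qual=float(qual),
        genotype=_genotype_for(zygosity),
        allele_depths=(ref_d, alt_d),
    )
    return VariantRecord(
        raw=raw,
        gene=gene,
        criteria=CriteriaAssignment.from_codes(criteria_codes),
        zygosity=zygosity,
        population_af=population_af,
        insilico_score=None,  # filled by caller
        bayes_params=BayesParams(),
    )


def _insilico(rng, causative_like: bool, missing_rate: float) -> float | None:
    if rng.random() < missing_rate:
        return None
    score = rng.beta(8, 3) if causative_like else rng.beta(2, 5)
    return round(float(score), 4)


def generate_cohort(config: CohortConfig, db: DiseaseDatabase | None = None) -> Cohort:
    """Generate a cohort of patients with planted causative variants."""
    if db is None:
        db = generate_database(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 29]))
    genes = sorted(db.gene_info)
    gene_to_dis = db.gene_to_diseases
    disease_ids = sorted(db.diseases)
    all_terms = sorted(db.ontology.terms - {db.ontology.root})

    # recurrent-site pools: founder pathogenic alleles per disease, and a
    # shared polymorphism pool for background variants
    founder_sites: dict[str, tuple] = {}
    founder_criteria: dict[str, tuple[str, ...]] = {}
    poly_pool: list[tuple] = []
    poly_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 31]))
    for _ in range(300):
        gene = genes[int(poly_rng.integers(len(genes)))]
        chrom, start = db.gene_info[gene]
        pos = start + int(poly_rng.integers(0, 50_000))
        ref, alt = (str(b) for b in poly_rng.choice(_BASES, size=2, replace=False))
        codes = _draw_background_criteria(poly_rng, "default")
        poly_pool.append((gene, (chrom, pos, ref, alt), codes))

    dates = sorted(
        f"{d.year:04d}-{d.month:02d}-{d.day:02d}"
        for d in pd.to_datetime("2021-09-01")
        + pd.to_timedelta(rng.integers(0, 731, size=config.n_patients), unit="D")
    )
    rng.shuffle(date_arr := np.array(dates, dtype=object))

    patients: list[PatientCase] = []
    for pi in range(config.n_patients):
        pid = f"P{pi:05d}"
        sex = "male" if rng.random() < 0.5 else "female"
        n_caus = 1 + int(rng.choice(3, p=config.causative_probs))
        true_dis = [
            disease_ids[int(i)]
            for i in rng.choice(len(disease_ids), size=n_caus, replace=False)
        ]
        used_positions: set[tuple[str, int]] = set()
        variants: list[VariantRecord] = []
        causative_ids: set[str] = set()

        # phenotypes: union over causative diseases, thinned by dropout
        terms: set[str] = set()
        for did in true_dis:
            d_terms = sorted(db.diseases[did].phenotype_terms)
            kept = [t for t in d_terms if rng.random() >= config.phenotype_dropout]
            if not kept:
                kept = [d_terms[int(rng.integers(len(d_terms)))]]
            terms.update(kept)
        for _ in range(config.n_distractor_terms):
            terms.add(all_terms[int(rng.integers(len(all_terms)))])

        # causative variants
        for did in true_dis:
            entry = db.diseases[did]
            gene = sorted(entry.genes)[0]
            inh = sorted(entry.inheritance_patterns)[0]
            zyg = _zygosity_for(inh, sex)
            fixed = None
            if rng.random() < config.causative_shared_fraction:
                if did not in founder_sites:
                    chrom, start = db.gene_info[gene]
                    f_rng = np.random.default_rng(
                        np.random.SeedSequence([config.seed, 37, int(did[4:])])
                    )
                    pos = start + int(f_rng.integers(0, 50_000))
                    ref, alt = (
                        str(b) for b in f_rng.choice(_BASES, size=2, replace=False)
                    )
                    founder_sites[did] = (chrom, pos, ref, alt)
                    founder_criteria[did] = _draw_causative_criteria(
                        f_rng, config.evidence_enrichment
                    )
                fixed = founder_sites[did]
                codes = founder_criteria[did]
                if fixed[:2] in used_positions:  # rare clash with another site
                    fixed = None
            else:
                codes = _draw_causative_criteria(rng, config.evidence_enrichment)
            v = _make_variant(
                rng,
                gene,
                db,
                zygosity=zyg,
                criteria_codes=codes,
                population_af=round(float(rng.uniform(0, 0.001)), 6),
                used_positions=used_positions,
                fixed_site=fixed,
            )
            v = dataclasses.replace(
                v, insilico_score=_insilico(rng, True, config.insilico_missing_rate)
            )
            variants.append(v)
            causative_ids.add(v.variant_id)

        # background variants (survivors of the filters)
        n_bg = max(0, int(rng.poisson(config.variants_per_patient_mean)) - n_caus)
        for _ in range(n_bg):
            artifact = rng.random() < config.fp_fraction
            if not artifact and rng.random() < config.shared_background_fraction:
                gene, site, codes = poly_pool[int(rng.integers(len(poly_pool)))]
                if site[:2] in used_positions:
                    continue
                fixed = site
            else:
                gene = genes[int(rng.integers(len(genes)))]
                fixed = None
                if artifact and rng.random() < config.fp_pathogenic_like:
                    codes = _draw_causative_criteria(rng, config.evidence_enrichment)
                else:
                    codes = _draw_background_criteria(
                        rng, config.evidence_enrichment
                    )
            on_x = db.gene_info[gene][0] == "X"
            if artifact:
                zyg = "het"
            elif on_x and sex == "male":
                zyg = "hemi"
            else:
                zyg = "hom" if rng.random() < 0.1 else "het"
            v = _make_variant(
                rng,
                gene,
                db,
                zygosity=zyg,
                criteria_codes=codes,
                artifact=artifact,
                population_af=round(float(rng.uniform(0, 0.04)), 6),
                used_positions=used_positions,
                fixed_site=fixed,
            )
            v = dataclasses.replace(
                v,
                insilico_score=_insilico(rng, False, config.insilico_missing_rate),
            )
            variants.append(v)

        # decoys exercising each filter rule (removed before scoring)
        n_decoy = int(round(config.decoy_fraction * n_bg))
        for _ in range(n_decoy):
            kind = rng.choice(["common", "benign", "orphan"])
            gene = genes[int(rng.integers(len(genes)))]
            af = 0.0
            codes: tuple[str, ...] = ()
            if kind == "common":
                af = round(float(rng.uniform(0.06, 0.5)), 4)
            elif kind == "benign":
                codes = ("BA1",) if rng.random() < 0.5 else ("BS1", "BS2", "BP4")
            else:
                gene = f"ORPHAN{int(rng.integers(100)):03d}"
            v = _make_variant(
                rng,
                gene,
                db,
                zygosity="het",
                criteria_codes=codes,
                population_af=af,
                used_positions=used_positions,
            )
            v = dataclasses.replace(v, insilico_score=_insilico(rng, False, 0.0))
            variants.append(v)

        patients.append(
            PatientCase(
                patient_id=pid,
                sex=sex,
                date=str(date_arr[pi]),
                phenotype_terms=frozenset(terms),
                variants=variants,
                causative_ids=frozenset(causative_ids),
                true_diseases=tuple(true_dis),
            )
        )
    return Cohort(config=config, db=db, patients=patients)


def ground_truth(cohort: Cohort) -> pd.DataFrame:
    """(patient_id, variant_id, is_causative, true_disease) label table."""
    rows = []
    for p in cohort.patients:
        for v in p.variants:
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "variant_id": v.variant_id,
                    "is_causative": int(v.variant_id in p.causative_ids),
                    "true_disease": ";".join(p.true_diseases),
                }
            )
    return pd.DataFrame(rows)


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write all cohort inputs in the pipeline's file dialects."""
    from . import io as vio

    outdir = Path(outdir)
    (outdir / "patients").mkdir(parents=True, exist_ok=True)
    vio.write_obo(outdir / "ontology.obo", cohort.db.ontology)
    vio.write_disease_annotations(
        outdir / "disease_annotations.tsv", cohort.db.diseases
    )
    ground_truth(cohort).to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    meta = pd.DataFrame(
        [
            {"patient_id": p.patient_id, "sex": p.sex, "date": p.date}
            for p in cohort.patients
        ]
    )
    meta.to_csv(outdir / "patients.tsv", sep="\t", index=False)
    for p in cohort.patients:
        pdir = outdir / "patients"
        vio.write_vcf(pdir / f"{p.patient_id}.vcf", [v.raw for v in p.variants],
                      sample=p.patient_id)
        with open(pdir / f"{p.patient_id}.phenotypes.txt", "w") as fh:
            for t in sorted(p.phenotype_terms):
                fh.write(t + "\n")
        crit = pd.DataFrame(
            [
                {
                    "variant_id": v.variant_id,
                    "gene": v.gene,
                    "zygosity": v.zygosity,
                    "population_af": v.population_af,
                    "criteria": ";".join(v.criteria.codes),
                }
                for v in sorted(p.variants, key=lambda v: v.variant_id)
            ]
        )
        crit.to_csv(pdir / f"{p.patient_id}.criteria.tsv", sep="\t", index=False)
        scores = pd.DataFrame(
            [
                {"variant_id": v.variant_id, "insilico_score": v.insilico_score}
                for v in sorted(p.variants, key=lambda v: v.variant_id)
                if v.insilico_score is not None
            ],
            columns=["variant_id", "insilico_score"],
        )
        scores.to_csv(pdir / f"{p.patient_id}.scores.tsv", sep="\t", index=False)


def database_ic(db: DiseaseDatabase, log_base: float = np.e):
    """Information content of the database's own annotation corpus."""
    return compute_ic(db.ontology, db.annotations, log_base=log_base)
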