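"""End-to-end glue: cohort → pair-level feature table → rankings → outcomes.

The pair-level feature table is the single interchange format between the
feature layer, the models, and the evaluation: one row per surviving
(variant, disease) pair with columns

    patient_id, variant_id, disease_id, gene,
    bayes, symsim, insilico, vaf, qual, inh_mismatch, label
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .cohort import Cohort, DiseaseDatabase, database_ic
from .evaluate import PatientOutcome
from .features import FeatureVector, assemble_features, filter_candidates
from .models import VariantPrioritizer, score_and_rank
from .ontology import ICTable
from .phenosim import PhenotypeProfile, SemanticSimilarity, build_gene_contexts

__all__ = [
    "patient_feature_table",
    "cohort_feature_table",
    "patient_outcomes",
]

PAIR_COLUMNS = [
    "patient_id",
    "variant_id",
    "disease_id",
    "gene",
    "bayes",
    "symsim",
    "insilico",
    "vaf",
    "qual",
    "inh_mismatch",
    "label",
]


def patient_feature_table(
    patient,
    db: DiseaseDatabase,
    sim: SemanticSimilarity,
    causative_ids: frozenset[str] | None = None,
) -> pd.DataFrame:
    """Filter one patient's candidates and assemble all pair-level rows.

    The softmax gene context is the set of genes carrying the patient's
    post-filter candidate variants.  A pair row is labeled positive iff its
    variant is one of the patient's confirmed causative variants.
    """
    gene_to_dis = db.gene_to_diseases
    survivors = filter_candidates(patient.variants, gene_to_dis)
    if not survivors:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    q = PhenotypeProfile(patient.phenotype_terms)
    contexts = build_gene_contexts((v.gene for v in survivors), db.diseases)
    sim.gene_weights(q, contexts)
    ctx_by_gene = {c.gene: c for c in contexts}
    if causative_ids is None:
        causative_ids = getattr(patient, "causative_ids", frozenset())
    rows = []
    for v in survivors:
        ctx = ctx_by_gene[v.gene]
        for did in sorted(ctx.diseases):
            fv: FeatureVector = assemble_features(
                q, v, db.diseases[did], ctx, sim, patient_sex=patient.sex
            )
            rows.append(
                {
                    "patient_id": patient.patient_id,
                    "variant_id": v.variant_id,
                    "disease_id": did,
                    "gene": v.gene,
                    "bayes": fv.bayes,
                    "symsim": fv.symsim,
                    "insilico": fv.insilico,
                    "vaf": fv.vaf,
                    "qual": fv.qual,
                    "inh_mismatch": int(fv.inh_mismatch),
                    "label": int(v.variant_id in causative_ids),
                }
            )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def cohort_feature_table(
    cohort: Cohort,
    sim: SemanticSimilarity | None = None,
    ic: ICTable | None = None,
) -> pd.DataFrame:
    """Pair-level feature table for every patient of a cohort.

    The IC corpus is the cohort's own disease-annotation table unless an
    ``ic`` table (or prebuilt ``sim``) is supplied.
    """
    if sim is None:
        if ic is None:
            ic = database_ic(cohort.db)
        sim = SemanticSimilarity(cohort.db.ontology, ic)
    tables = [patient_feature_table(p, cohort.db, sim) for p in cohort.patients]
    tables = [t for t in tables if len(t)]
    if not tables:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    return pd.concat(tables, ignore_index=True)


def patient_outcomes(
    model: VariantPrioritizer,
    pair_table: pd.DataFrame,
    causative: Mapping[str, frozenset[str]],
    patients: Sequence[str] | None = None,
) -> list[PatientOutcome]:
    """Rank each patient's candidates and pair with the causative labels.

    ``causative`` maps patient id to the confirmed causative variant ids;
    causative variants missing from the ranking (filtered out or unscored)
    count as misses at infinite rank.
    """
    outcomes = []
    ids = patients if patients is not None else sorted(causative)
    by_patient = dict(tuple(pair_table.groupby("patient_id", sort=True)))
    for pid in ids:
        pairs = by_patient.get(pid)
        ranked = score_and_rank(model, pairs) if pairs is not None else []
        outcomes.append(
            PatientOutcome(
                patient_id=pid,
                ranked=tuple(ranked),
                causative_ids=frozenset(causative[pid]),
            )
        )
    return outcomes
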