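"""Readers and writers for every format the pipeline touches.

All tables are tab-delimited UTF-8 with a header row.  VCF positions stay
1-based throughout; variant identity is the normalized
``chrom-pos-ref-alt`` tuple after multiallelic splitting, which also keys
the criteria and in-silico score tables.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from cyvcf2 import VCF

from .acmg import ACMG_CRITERIA, CriteriaAssignment
from .features import RawVariant, variant_id_key
from .models import RankedVariant
from .ontology import Ontology
from .phenosim import INHERITANCE_CODES, DiseaseEntry

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_obo",
    "write_obo",
    "read_disease_annotations",
    "write_disease_annotations",
    "read_patient_inputs",
    "write_ranked_report",
    "read_ranked_report",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path, sample: str | None = None) -> list[RawVariant]:
    """Read one sample's biallelic records, splitting multiallelic sites.

    Per split record, the alt allele depth is the named allele's AD entry
    and the genotype is re-expressed against that allele alone (other alt
    alleles count as reference).  QUAL "." maps to missing.
    """
    vcf = VCF(str(path))
    try:
        if not vcf.samples:
            raise ValueError(f"{path}: VCF has no sample columns")
        if sample is None:
            idx = 0
        else:
            try:
                idx = vcf.samples.index(sample)
            except ValueError:
                raise KeyError(
                    f"sample {sample!r} not in {path} (has {vcf.samples})"
                ) from None
        out: list[RawVariant] = []
        for rec in vcf:
            ad = rec.format("AD")
            gt = rec.genotypes[idx]
            alleles = gt[:-1]  # last entry is the phasing flag
            for j, alt in enumerate(rec.ALT):
                if ad is not None:
                    ref_d = max(int(ad[idx][0]), 0)
                    alt_d = max(int(ad[idx][j + 1]), 0)
                else:
                    ref_d, alt_d = 0, 0
                gt_str = "/".join(
                    "." if a < 0 else ("1" if a == j + 1 else "0") for a in alleles
                )
                out.append(
                    RawVariant(
                        chrom=rec.CHROM,
                        pos=rec.POS,
                        ref=rec.REF,
                        alt=alt,
                        qual=rec.QUAL,
                        genotype=gt_str,
                        allele_depths=(ref_d, alt_d),
                    )
                )
        return out
    finally:
        vcf.close()


def write_vcf(path, variants: Sequence[RawVariant], sample: str = "SAMPLE") -> None:
    """Write biallelic records as a minimal single-sample VCF v4.2."""
    variants = sorted(variants, key=lambda v: variant_id_key(v.variant_id))
    contigs = []
    for v in variants:
        if v.chrom not in contigs:
            contigs.append(v.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for v in variants:
            qual = "." if v.qual is None else f"{v.qual:g}"
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{qual}\t.\t.\t"
                f"GT:AD\t{v.genotype}:{v.allele_depths[0]},{v.allele_depths[1]}\n"
            )


# ---------------------------------------------------------------------------
# Ontology (OBO)


def read_obo(path, root: str | None = None) -> Ontology:
    """Load an OBO ontology into the internal DAG (is_a edges only).

    Obsolete terms are excluded.  A cycle raises; multiple roots raise
    unless a root id is supplied.
    """
    import obonet

    graph = obonet.read_obo(str(path))
    parents: dict[str, set[str]] = {t: set() for t in graph.nodes}
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents[child].add(parent)
    return Ontology(parents, root=root)


def write_obo(path, ontology: Ontology, name: str = "synthetic-phenotype") -> None:
    """Dump an Ontology as OBO 1.2 (is_a edges only)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write(f"ontology: {name}\n")
        for term in sorted(ontology.terms):
            fh.write(f"\n[Term]\nid: {term}\nname: {term}\n")
            for p in sorted(ontology.parents[term]):
                fh.write(f"is_a: {p}\n")


# ---------------------------------------------------------------------------
# Disease annotations


def read_disease_annotations(
    path,
    ontology: Ontology | None = None,
    strict: bool = False,
) -> dict[str, DiseaseEntry]:
    """Group a (disease_id, term_id, gene, inheritance) table into entries.

    Duplicate rows collapse under set semantics.  Terms missing from the
    ontology are dropped with a warning (or raise under ``strict``).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"disease_id", "term_id", "gene", "inheritance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df[~df["inheritance"].isin(INHERITANCE_CODES)]
    if len(bad):
        raise ValueError(
            f"{path}: unknown inheritance codes in rows "
            f"{bad.index.tolist()[:10]}: {sorted(bad['inheritance'].unique())}"
        )
    entries: dict[str, DiseaseEntry] = {}
    for disease_id, grp in df.groupby("disease_id", sort=True):
        terms = set(grp["term_id"])
        if ontology is not None:
            unresolved = {t for t in terms if t not in ontology}
            if unresolved:
                msg = f"disease {disease_id}: unresolved terms {sorted(unresolved)}"
                if strict:
                    raise ValueError(msg)
                logger.warning(msg)
                terms -= unresolved
        entries[disease_id] = DiseaseEntry(
            disease_id=disease_id,
            phenotype_terms=frozenset(terms),
            genes=frozenset(grp["gene"]),
            inheritance_patterns=frozenset(grp["inheritance"]),
        )
    return entries


def write_disease_annotations(path, entries: Mapping[str, DiseaseEntry]) -> None:
    rows = []
    for d in entries.values():
        for term in sorted(d.phenotype_terms):
            for gene in sorted(d.genes):
                for inh in sorted(d.inheritance_patterns):
                    rows.append((d.disease_id, term, gene, inh))
    df = pd.DataFrame(
        sorted(rows), columns=["disease_id", "term_id", "gene", "inheritance"]
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Patient inputs (phenotypes, criteria, in-silico scores)


def read_phenotype_list(
    path, ontology: Ontology | None = None, strict: bool = False
) -> set[str]:
    """One ontology term per line; unknown terms dropped with a warning."""
    terms = [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    out: set[str] = set()
    for t in terms:
        if ontology is not None and t not in ontology:
            if strict:
                raise ValueError(f"{path}: unknown phenotype term {t!r}")
            logger.warning("%s: dropping unknown phenotype term %r", path, t)
            continue
        out.add(t)
    return out


def parse_criteria_field(field: str) -> CriteriaAssignment:
    """Parse a semicolon-joined criteria string (empty → no criteria)."""
    codes = [c.strip() for c in str(field).split(";") if c.strip()] if field else []
    unknown = [c for c in codes if c not in ACMG_CRITERIA]
    if unknown:
        raise ValueError(f"criteria tokens not among the 28 ACMG codes: {unknown}")
    return CriteriaAssignment.from_codes(codes)


def read_patient_inputs(
    pheno_path,
    criteria_path,
    scores_path,
    ontology: Ontology | None = None,
    strict: bool = False,
) -> tuple[set[str], dict[str, dict]]:
    """Join per-variant criteria and in-silico scores; load phenotype set Q.

    Variants absent from the scores table carry ``fallback=True`` and a
    missing score, to be imputed at feature assembly.
    """
    q = read_phenotype_list(pheno_path, ontology=ontology, strict=strict)
    crit = pd.read_csv(criteria_path, sep="\t", dtype=str, keep_default_na=False)
    if not {"variant_id", "criteria"} <= set(crit.columns):
        raise ValueError(f"{criteria_path}: needs columns variant_id, criteria")
    scores = pd.read_csv(scores_path, sep="\t", dtype={"variant_id": str})
    if not {"variant_id", "insilico_score"} <= set(scores.columns):
        raise ValueError(f"{scores_path}: needs columns variant_id, insilico_score")
    score_map = dict(zip(scores["variant_id"], scores["insilico_score"].astype(float)))
    annotations: dict[str, dict] = {}
    for row in crit.itertuples():
        vid = row.variant_id
        score = score_map.get(vid)
        if score is not None and pd.isna(score):
            score = None
        annotations[vid] = {
            "criteria": parse_criteria_field(row.criteria),
            "insilico_score": score,
            "fallback": score is None,
        }
    return q, annotations


# ---------------------------------------------------------------------------
# Ranked report

_REPORT_COLUMNS = [
    "rank",
    "variant_id",
    "score",
    "best_disease",
    "criteria",
    "bayes",
    "symsim",
    "insilico",
    "vaf",
    "qual",
    "inh_mismatch",
]


def write_ranked_report(
    path,
    ranking: Sequence[RankedVariant],
    pair_features: pd.DataFrame,
    criteria: Mapping[str, CriteriaAssignment] | None = None,
    json_path=None,
) -> pd.DataFrame:
    """Write a per-variant report (TSV + optional JSON mirror).

    One row per ranked variant: rank, score, the six feature values of the
    best-matching disease, and the assigned criteria codes.  A variant with
    no disease match gets zero features and an empty criteria field.
    """
    indexed = (
        pair_features.set_index(["variant_id", "disease_id"])
        if len(pair_features)
        else None
    )
    rows = []
    for rv in ranking:
        feats = {f: 0.0 for f in ("bayes", "symsim", "insilico", "vaf", "qual")}
        feats["inh_mismatch"] = 0
        if indexed is not None and (rv.variant_id, rv.best_disease) in indexed.index:
            rec = indexed.loc[(rv.variant_id, rv.best_disease)]
            for f in feats:
                feats[f] = rec[f]
        codes = ""
        if criteria and rv.variant_id in criteria:
            codes = ";".join(criteria[rv.variant_id].codes)
        rows.append(
            {
                "rank": rv.rank,
                "variant_id": rv.variant_id,
                "score": round(float(rv.score), 6),
                "best_disease": rv.best_disease,
                "criteria": codes,
                "bayes": round(float(feats["bayes"]), 6),
                "symsim": round(float(feats["symsim"]), 6),
                "insilico": round(float(feats["insilico"]), 6),
                "vaf": round(float(feats["vaf"]), 6),
                "qual": round(float(feats["qual"]), 6),
                "inh_mismatch": int(feats["inh_mismatch"]),
            }
        )
    df = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(rows, indent=1))
    return df


def read_ranked_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"criteria": str}, keep_default_na=False).astype(
        {
            "rank": int,
            "score": float,
            "bayes": float,
            "symsim": float,
            "insilico": float,
            "vaf": float,
            "qual": float,
            "inh_mismatch": int,
        }
    )
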