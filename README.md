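# varprio

Explainable, phenotype-driven prioritization of candidate variants for
rare Mendelian disease diagnosis.

A patient referred for genetic diagnosis typically carries on the order of
a hundred candidate variants after standard filtering, of which only 1–3
are causative. `varprio` ranks those candidates by combining four kinds of
evidence into a six-feature description of every (variant, candidate
disease) pair, scoring the pairs with either a rule-based baseline or a
trained classifier, and explaining every ranking by per-feature
contribution. It is aimed at clinical-genetics pipelines and at method
developers who need a fully self-contained, simulatable test bed for
phenotype-driven ranking.

## The model

**ACMG/AMP Bayesian score.** Assigned evidence criteria (PVS1, PS1–4,
PM1–6, PP1–5, BS1–4, BP1–7, BA1) are tallied per strength class and
combined into a posterior probability of pathogenicity via the
naive-Bayes reading of the guidelines:

```
OddsPath = O_PVS ^ (NPP/8 + NPM/4 + NPS/2 + NPVS − NBP/8 − NBS/2)
Post_P   = OddsPath · Prior_P / ((OddsPath − 1) · Prior_P + 1)
```

with `Prior_P = 0.1`, `O_PVS = 350`. Zero criteria give exactly the prior;
BA1 (stand-alone benign) excludes the variant outright.

**Gene-upweighted symptom similarity.** Patient phenotypes Q and disease
annotations D_k are sets of ontology terms (HPO-like DAG). Term similarity
is Resnik's information content of the most informative common ancestor;
set similarity is symmetrized best-match averaging:

```
one_sided(Q→D) = mean_{t∈Q} max_{t'∈D} IC(MICA(t, t'))
two_sided(Q,D) = ½ one_sided(Q→D) + ½ one_sided(D→Q)
```

Each candidate gene g of the patient gets a weight
`1 + softmax_g two_sided(Q, profile(g))` over the patient's candidate
genes, where `profile(g)` is the union of term sets of the gene's
diseases; the final similarity feature is `weight(g) · two_sided(Q, D_k)`.

**False-positive-risk features.** Variant allele fraction (alt reads /
total reads), Phred-scaled call quality QUAL (QUAL 20 ⇒ 1% probability of
no variant), and a boolean flag for inheritance-pattern/zygosity mismatch
(e.g. a lone heterozygote against an autosomal-recessive disease).

**Models.** The untrained baseline scores
`bayes · σ(symsim − 2) · σ(insilico)`; trained variants are logistic
regression (`class_weight="balanced"`, `max_iter=500`) and random forest
(`n_estimators=500`, `class_weight="balanced"`) over three nested feature
sets (`lr`/`rf`: the three scores; `*_qc`: + VAF and QUAL; `*_all`: + the
inheritance flag). A variant's score is the maximum over its candidate
diseases; patients are ranked by descending score.

**Evaluation and explanation.** Per-patient top-k recall with the revised
denominator `min(#causative, k)`, averaged over patients; fold-averaged
ROC/PR curves; three cross-validation schemes (random patient folds, a
date-based external split, gene-disjoint folds) with exclusion of variants
shared between training and test patients; permutation importance (mean
decrease in accuracy) and exact Shapley attributions computed by full
coalition enumeration over the six features.

A synthetic-cohort generator (`varprio.cohort`) produces the ontology,
disease/gene database, per-patient VCFs, criteria/score tables and ground
truth from a single seed, with planted causative variants and injected
low-VAF/low-QUAL artifacts — everything is testable offline.

## Worked example

```python
import varprio as vp

cohort = vp.generate_cohort(vp.CohortConfig(seed=42, n_patients=60))
table = vp.cohort_feature_table(cohort)          # pair-level features
causative = {p.patient_id: p.causative_ids for p in cohort.patients}
vids = {p.patient_id: frozenset(v.variant_id for v in p.variants)
        for p in cohort.patients}

plan = vp.make_folds(list(causative), "random_patient", seed=0,
                     variant_ids=vids)
test = set(plan.test_patients(0)); train = set(plan.train_patients(0))
leak = plan.leakage_removed[0]
train_tbl = table[table.patient_id.isin(train) & ~table.variant_id.isin(leak)]
test_tbl = table[table.patient_id.isin(test)]

model = vp.train_model("rf_all", train_tbl, seed=0)
outs = vp.patient_outcomes(model, test_tbl, {p: causative[p] for p in test})
for k in (1, 3, 5, 10):
    print(f"top-{k} recall: {vp.cohort_topk(outs, k):.3f}")
```

prints (training on 6,453 pair rows after excluding 164 leaked variant ids):

```
top-1 recall: 1.000
top-3 recall: 1.000
top-5 recall: 1.000
top-10 recall: 1.000
```

— on this small noisy synthetic cohort the forest recovers every planted
causative variant at rank 1. Ranking one held-out patient and explaining
the top pair:

```
patient P00009 — top 5 of 126 candidates:
  1. 18-22048478-C-A        score=0.9480 best=DIS:00132 *causative*
  2. 22-18414715-A-T        score=0.4900 best=DIS:00107 *causative*
  3. 4-10402019-T-A         score=0.0500 best=DIS:00056
  4. 2-10022365-G-A         score=0.0360 best=DIS:00053
  5. 18-22040311-C-G        score=0.0340 best=DIS:00132

Shapley attribution of the top-ranked pair (base 0.0178):
{'bayes': 0.5287, 'symsim': -0.0927, 'insilico': 0.0336,
 'vaf': -0.0467, 'qual': 0.0306, 'inh_mismatch': 0.0186}
```

The attribution reads: relative to the average score 0.018, the strong
ACMG evidence contributes +0.53 and the good call quality +0.03, while a
below-average phenotype match subtracts 0.09 — the attributions plus the
base value reproduce the model score exactly.

The same pipeline is scriptable from the shell:

```sh
varprio simulate --seed 42 --n-patients 60 --out cohort/
varprio features cohort/ --out pairs.tsv
varprio train pairs.tsv --model rf_all --seed 0 --out model.joblib
varprio rank model.joblib pairs.tsv --out report.tsv
varprio evaluate model.joblib pairs.tsv cohort/ground_truth.tsv
varprio explain model.joblib pairs.tsv --out-prefix explain
```

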