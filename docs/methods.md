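# Methods

This note records the model, the choices made where the design was open,
the defaults of the synthetic-data generator, and the limits of what the
test suite demonstrates.

## Evidence combination

Criteria are mapped to strength classes by code prefix (PVS/PS/PM/PP/BS/BP);
BA1 is a stand-alone exclusion flag, not an exponent term, because the
odds formula has no stand-alone slot and variants with common alleles are
removed outright. Strength-modified assignments (e.g. PP3 applied at
strong level) are supported through an explicit per-code override map,
since annotation pipelines weigh criteria without publishing their
override tables.

The posterior is evaluated in log-odds space,
`logit(Post_P) = exponent·ln(O_PVS) + logit(Prior_P)`, so large criteria
stacks cannot overflow; when the exponent is exactly zero the prior is
returned verbatim rather than round-tripped through logs. The five-tier
map uses the Bayesian-framework cut-points 0.99 / 0.90 / 0.10 / 0.001
(configurable); these are a convention of the quantitative framework, not
a fitted quantity.

## Phenotype similarity

Information content is computed from the loaded disease-annotation corpus
itself: `p(t)` is the fraction of diseases annotated to `t` or any
descendant, `ic(t) = −log p(t)` in natural log by default. The base is
configurable because it rescales every similarity uniformly; nothing
downstream depends on it beyond the baseline model's `symsim − 2` shift,
which assumes nats. Terms with zero propagated annotations are smoothed to
`p = 1/(N+1)` so their IC stays finite. Disease-level (not gene-level)
annotation frequencies are used; a gene-level corpus would be a
configuration extension, not a code change.

The one-sided set similarity is the mean over query terms of the best
Resnik match in the target set; empty sets score 0, which lets the
pipeline run on patients with no usable phenotype terms (ranking then
rests on the pathogenicity and QC features alone).

The gene profile entering the softmax weight is the union of term sets
over the gene's diseases — the simplest set-level construction consistent
with the two-sided similarity machinery. The softmax runs over the genes
carrying the patient's post-filter candidate variants, i.e. it is a
per-patient re-ranking device: over all genes in the database every weight
would collapse to ≈1 and the feature would carry no signal. Weights
therefore lie in (1, 2] and their softmax shares sum to 1 per patient.

## Feature layer

The inheritance-compatibility table is a declared convention (the feature
definition names the comparison but not the matrix): AD↔{het, hom};
AR↔{hom} — a lone heterozygote mismatches a recessive disease because
compound-heterozygote pairing across alleles is out of scope for a
per-variant feature; XLR↔{hemi (male), hom (female)}; XLD↔{het, hom,
hemi}; MT/YL↔{hom, hemi}. An empty pattern set is "no evidence of
mismatch" (False), and with unknown patient sex the X-linked patterns are
evaluated leniently to avoid false mismatches.

Missing values: in-silico score → 0.206 (the upstream predictor's
cohort-average constant; a config value, never recomputed from data);
QUAL → 0 (the most conservative reading — the call looks risky and a
trained model can down-weight it); population AF → 0 (rare until proven
common, matching standard clinical filtering).

## Models and ranking

The baseline score is `bayes · σ(symsim − 2) · σ(insilico)`; the shift of
2 soft-gates diseases with weak phenotype support. Trained models use the
scikit-learn implementations with the stated hyperparameters and defaults
otherwise; training rows are pair-level, a pair being positive iff its
variant is causative for that patient (the label choice dual to the
max-over-diseases reduction at inference). Ranking ties break by ascending
variant id so rankings are reproducible. The known random-forest
pathology — most pairs scored at the minimum, so a few causative variants
become unrankable — is accepted as a property of the algorithm; blending
with a logistic model for the tail is deliberately not enabled by default.

## Evaluation

Top-k recall uses the revised denominator `min(#causative, k)`. One
consequence worth stating: the revised metric is **not** monotone in k
below the causative count — a patient with causatives at ranks 1 and 100
scores 1.0 at k=1 (1 hit / min(2,1)) but 0.5 at k=2. The property tests
assert monotonicity only where the metric is ordered (single-causative
patients everywhere; k ≥ #causative otherwise) and pin the counterexample
explicitly. Causative variants absent from a ranking (filtered out, or
unscored) count as misses at infinite rank and are logged.

Fold-averaged ROC and PR curves interpolate each fold onto a uniform
1001-point grid (recorded in the result dict) before averaging; areas use
the trapezoid rule. PR averaging mirrors the ROC interpolation. Fold
construction supports random patient folds, a date split (external set =
patients on/after 2022-09-01), and gene-disjoint folds built by union-find
over patients sharing causal genes with greedy largest-component-first
packing — the constraint (no gene spans folds) is the specification, the
packing algorithm is ours. In every scheme, variant ids shared between a
fold's training patients and its test patients are recorded and must be
dropped from training tables; the suite asserts the post-exclusion
intersection is empty.

MDA uses probability-threshold-0.5 classification accuracy by default
(AUROC available via `metric="auroc"`); permuting a constant column leaves
the table bit-identical, so its importance is exactly 0.

## Shapley attributions

With six features, exact Shapley values are computed by full coalition
enumeration (64 coalitions) against an interventional value function
`v(S) = mean_b f(x_S, b_−S)` over a background sample (default: the
explained table, subsampled to 64 rows). This satisfies efficiency
exactly — attributions sum to `f(x) − base` up to float error — for any
model exposing a probability-like score, and is cross-checked in the tests
against an independent factorial-permutation enumeration. Sampling
approximations are unnecessary at this dimensionality and are not
implemented; more than 12 features raises.

## Synthetic cohort: what it emulates, and what it does not

Defaults (chosen once; the noisy configuration is the default):

| parameter | default | rationale |
|---|---|---|
| variants/patient (post-filter mean) | 122 | candidate load the method assumes |
| causative count mixture on {1,2,3} | 0.88 / 0.11 / 0.01 | observed dual/triple-diagnosis rates |
| phenotype dropout | 0.3 | clinicians record a subset of disease phenotypes |
| distractor terms | 2 | unrelated/incidental findings |
| artifact fraction (low VAF < 0.3, QUAL < 20) | 0.1 | sequencing false positives |
| artifact pathogenic-like criteria prob. | 0.5 | recurrent artifacts often mimic LoF evidence |
| shared background / founder causative fraction | 0.2 / 0.3 | recurrent variants across patients, so leakage exclusion removes real rows |
| in-silico score missing rate | 0.1 | variants outside the predictor's scope |
| ontology / genes | 200 terms, 150 genes (~10% X-linked) | desk-scale database |

Causative variants draw zygosity consistent with the disease inheritance
mode, VAF concentrated near 0.5 (het) or 1.0 (hom/hemi), integer QUAL in
[50, 150), and criteria from an enriched mixture (55% very-strong, 35%
moderate, 10% weak stacks); background variants draw mostly empty or
supporting-level criteria. Decoy variants violating each filter rule
(common allele, benign classification, orphan gene) are added so the
filters are exercised end to end. QUALs are whole numbers so the VCF
round trip through float32 is exact; all files are byte-identical across
runs with the same seed.

The generator emulates the *statistical* structure the ranking method
relies on — evidence enrichment, phenotype overlap, QC contrast,
inheritance consistency, variant recurrence. It does not emulate
sequence-level reality: no read simulation, no linkage or haplotype
structure, no transcript-level annotation ambiguity, no shared ancestry
between diseases' phenotype profiles beyond the random DAG, and the
separation between causative and background evidence is cleaner than in
real exomes. Passing recovery tests therefore demonstrates that the
pipeline ranks correctly *when its feature assumptions hold*, not that it
attains any particular recall on real patients; cohort-scale recalls
printed by the tests (e.g. forest top-1 near 1.0 on small cohorts) are
properties of the simulation, not clinical estimates.

Problem sizes used by the test suite — 1,000-patient cohorts for the
recovery checks, 100 random toy DAGs (≤ 50 terms) for the similarity
oracles, exhaustive criteria-count enumeration with entries ≤ 3 — keep the
full suite within a few minutes on one CPU while leaving the statistical
assertions well-powered.

## Known limitations

* Compound-heterozygote phasing, trio de-novo logic and penetrance are out
  of scope; the inheritance feature is strictly per-variant.
* The criteria table is keyed by normalized variant tuple; transcript
  choice is upstream.
* Probability calibration of trained models is not attempted; scores are
  ranking devices.
* The gene-disjoint fold packer warns (rather than fails) when one
  patient–gene component exceeds 20% of patients, reporting the achieved
  balance.
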