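# socsmut

Severity subtyping and cohort statistics for single-gene coding-mutation
screens, with a SOCS1-like gene model as the packaged default.

## The problem

In diffuse large B-cell lymphoma (DLBCL), the tumor-suppressor *SOCS1* — a
636-bp single-ORF gene encoding an inhibitor of JAK/STAT signaling — is
mutated in roughly 16% of cases, largely through aberrant somatic
hypermutation (SHM).  The prognostic meaning of those mutations depends on
their *severity*: cases whose truncating or frame-altering events destroy
or displace the C-terminal effector domains (NLS, SOCS box) behave
differently from cases carrying only point mutations.  `socsmut` turns
that analysis into a reusable pipeline for anyone working with per-case
mutation catalogs of a small gene:

* **consequence annotation** of HGVS-style `c.` mutations (substitution,
  deletion, duplication, insertion) against a domain-annotated gene model;
* the **intact coding length** severity statistic — per case,
  `min{ c_start − 1 : frame-disrupting indels } ∪ { 3(s−1) : stop at codon s } ∪ { L_c }`
  — and per-domain impact under a *conservative* (complete loss only) and
  an *aggressive* (partial loss or position shift) weighting;
* the case-level subtype call: **wild_type**, **minor** (only
  non-foreshortening point mutations) or **major** (≥1 foreshortening
  event whose aggressive impact reaches a C-terminal domain);
* **SHM hotspot-motif** scanning (RGYW/WRCY, DGYW/WRCH, WA/TW on both
  strands via the six-pattern forward scan), mutable-position targeting
  flags, deletion-flank checks, and a permutation enrichment test;
* **cohort statistics**: crosstabs with pairwise missing exclusion,
  two-sided Fisher exact tests (2×2 and Freeman–Halton r×c with exact
  enumeration or seeded Monte Carlo), domain frequency maps, Kaplan–Meier
  product-limit curves, and Cox proportional-hazards regression
  (Newton–Raphson, Breslow/Efron ties, Wald CIs) with the study-standard
  0/1 covariate encodings and the IPI missing→0 rule;
* a **synthetic-cohort generator** with planted truth (subtype, events,
  motif-targeting flags) for end-to-end validation.

See `docs/methods.md` for the full model description and numerical
choices.  The packaged CDS/exon-2 sequences are synthetic stand-ins with
the published geometry (start at transcript position 705, stop at
1340 = c.636, 761-bp amplicon from the published primer pair); drop in a
real transcript via the documented gene-model JSON schema to analyze real
data.

## Worked example

Simulate a 154-case cohort, call subtypes, and fit the survival models:

```sh
socsmut simulate --seed 11 --out demo
# simulated 154 cases (35 mutant: 18 major / 17 minor)

socsmut subtype --model demo/model.json --mutations demo/mutations.tsv --out demo/sub
# called 35 cases: {'major': 18, 'minor': 17}

socsmut shm --model demo/model.json --mutations demo/mutations.tsv --out demo/shm --seed 11
# 43/96 substitutions at hotspot motifs (enrichment p=0.02048975512243878)

socsmut survival --model demo/model.json --mutations demo/mutations.tsv \
    --clinical demo/clinical.tsv --out demo/surv
# fit 15 univariate models + 1 multivariate (converged)
```

`demo/surv/cox_multivariate.tsv` then contains (columns abridged):

```
covariate     log_hr   se     ci_low   ci_high  p
age60          0.256  0.204   -0.143    0.655   0.209
aas34          0.377  0.203   -0.020    0.774   0.063
non_gcb       -0.211  0.209   -0.621    0.199   0.313
socs1_major   -2.083  0.540   -3.142   -1.024   0.000115
socs1_minor    1.104  0.294    0.529    1.679   0.000169
```

Read: with planted log hazard ratios of −1.2 (major) and +1.0 (minor),
this draw recovers a strongly protective major subtype and a harmful
minor subtype, adjusted for age, stage and cell-of-origin — the
two-directional severity effect the subtype call is designed to expose.
The SHM line says 43 of 96 simulated substitutions (44.8%) sit on a
hotspot mutable base, against a θ = 0.41 planting, and the permutation
test flags the enrichment.  `demo/fm/freqmap.tsv` (from
`socsmut freqmap`) tabulates, per domain, the fraction of mutated cases
affected directly vs under the conservative/aggressive downstream
weightings — e.g. the SOCS box is hit directly in 31% of mutated cases
but lost or displaced in 69% once upstream truncations are propagated.

The same subcommands run on real tables: a mutation TSV
(`case_id`, `mutation` in `c.` notation), a clinical TSV (documented
column vocabulary, `.` = missing), and a gene-model JSON.

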