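# Methods

`socsmut` implements a single-gene mutation-severity analysis for coding
mutation screens of the kind performed on *SOCS1* in diffuse large B-cell
lymphoma (DLBCL): per-case consequence annotation against a domain-annotated
gene model, a two-tier severity subtype (*major* / *minor*), quantification
of somatic-hypermutation (SHM) hotspot-motif targeting, and the cohort-level
association and survival statistics that accompany such a screen.  This note
records the model, its assumptions, the numerical choices, and what the
synthetic cohorts do and do not establish.

## Coordinate frame and gene model

All positions are 1-based, fully closed, in HGVS-like `c.` coordinates on
the coding sequence (CDS).  A protein domain spanning amino acids
`[aa_start, aa_end]` occupies CDS nucleotides `[3*(aa_start-1)+1, 3*aa_end]`.
Domains may overlap or nest (KIR and SH2 lie inside the broader JAK
interaction region) and are never merged; frequency maps report each named
domain independently.

The packaged default is a SOCS1-like model: a 636-bp CDS (211-aa protein
plus stop), domains SH3 / KIR / SH2 / JAK / NLS / SOCS box, and C-terminal
set {NLS, SOCS box} — the domains whose loss or displacement defines the
*major* subtype.  The exact amino-acid boundaries of the SOCS1 domains are
not published to single-residue precision; the JSON fixture carries
literature-style stand-in boundaries and is explicitly editable.  The
packaged CDS and exon-2 template are synthetic stand-in sequences (the
fixture files say so): they reproduce the published geometry — translation
start at transcript position 705, stop codon ending at 1340 (= c.636), the
printed primer pair capturing a 761-bp amplicon — without being the real
SOCS1 sequence.  Users with the real transcript can drop it into the same
JSON schema.

Primer placement is exact-match only (the published primers are plain
sequence); the forward primer is matched on the given strand and the
reverse primer as its reverse complement, leftmost-forward paired with the
nearest downstream reverse match, with a warning on multiple placements.

## Consequence model and intact coding length

Single-nucleotide substitutions are translated in the reference frame at
the affected codon: silent, missense, or nonsense.  Indels are frameshift
when the net inserted-minus-deleted length is not a multiple of 3,
otherwise in-frame deletion / duplication / insertion.  Duplications are
modeled as tandem (the duplicated slice re-inserted immediately after its
3' end); insertions are anchored between `c_start` and `c_start + 1`.

The severity axis is the **intact coding length**: the number of 5'
reference nucleotides still encoded in frame ahead of the first truncating
event.  Per case it is the minimum over

* `c_start - 1` for every frame-disrupting indel,
* `3*(s - 1)` for every stop-gain substitution creating a stop at codon `s`,
* a codon-granular bound for a premature in-frame stop introduced inside
  in-frame inserted or duplicated material (see below),
* the full CDS length when no such event exists.

Silent and missense substitutions never shorten it, and neither do purely
in-frame indels that introduce no stop: an in-frame deletion shifts and
locally damages the protein but leaves the downstream sequence in sense,
which is exactly the distinction the two weighting schemes encode.  When a
case carries several truncating events the most severe (5'-most bound)
governs.

Stops arising inside in-frame inserted material are found by translating
the mutant CDS while carrying a mutant-to-reference coordinate tag for
every base; if the first in-frame stop codon contains newly inserted
(untagged) bases, the bound is `3*floor(a/3)` where `a` is the last
reference position preserved before that stop — whole reference codons,
mirroring the `3*(s-1)` stop-gain convention.  Events are applied to the
reference 3'→5' so stored coordinates never need re-mapping; repeated
substitutions at one position are applied in file order (last wins, with a
warning), and overlapping deletion intervals within one case are rejected
as conflicting.

## Domain impact: conservative vs aggressive weighting

Three nested readings of "affected domain" are computed per case:

* **direct** — an event footprint intersects the domain interval (for
  insertions, the anchor gap lies inside it);
* **conservative** — additionally counts a domain only when it is entirely
  lost: its whole interval lies beyond the intact coding length, or a
  deletion removes it completely;
* **aggressive** — additionally counts partial loss (any part of the
  interval beyond the intact length, or partially deleted) and position
  shifts (any net-length-changing event upstream of the domain start).

Conservative ⊆ aggressive holds by construction and is property-tested.
The two schemes bracket the plausible functional reading of a truncating
or frame-altering event's downstream consequences.

## Severity subtype

* **wild_type** — no coding mutation.
* **major** — at least one foreshortening event (stop-gain, frameshift,
  deletion, or frame-disrupting duplication/insertion) whose
  aggressive-scheme impact reaches a C-terminal domain.  The aggressive
  scheme operationalizes "affects presence **or position**" of those
  domains; each candidate event is evaluated in isolation, consistent with
  the most-severe-event-governs convention.
* **minor** — all events are non-foreshortening point substitutions
  (silent or missense).

Edge cases that the published material never exhibits — foreshortening
events strictly 3' of every C-terminal domain (only possible in the final
codons), or cases consisting solely of in-frame indels — are called
**major with an `ambiguous` flag**: they are deleterious but local, and
"minor" would be textually wrong since they are not point mutations.  This
severity-conservative default avoids inventing a third mutated class.

Figure-style severity ordering sorts by ascending intact coding length,
then descending mutation count, then case id — a stable total order.

Mono- vs biallelic assignment is out of scope (not determinable from bulk
tumor sequencing with stromal admixture).

## SHM hotspot motifs

The scanner covers the three classic AID hotspot families and their
reverse-complement partners: RGYW/WRCY and DGYW/WRCH (mutable G:C, offsets
1 and 2 respectively) and WA/TW (mutable A:T, offsets 1 and 0), with IUPAC
codes R=A/G, Y=C/T, W=A/T, D=A/G/T, H=A/C/T.  Because each family's
partner is its reverse complement, scanning the forward strand for all six
patterns is mathematically identical to scanning both strands; this avoids
coordinate mirroring entirely and the equivalence is property-tested
exactly.  All occurrences are reported, overlapping and nested, without
deduplication (every RGYW hit is also a DGYW hit; R ⊂ D).

A substitution is "at a motif" only when it sits on the **mutable** base of
at least one hit — not merely inside a motif.  Scanning uses flanking
context sequence so motifs straddling the CDS edges are seen; positions
within 3 nt of an edge with no context available carry a
`boundary_uncertain` flag.  Deletion flanks are tested against a window of
4 nt (one motif length) immediately outside each breakpoint; the window is
a tunable because no published convention exists.

The enrichment test is a permutation test: the observed number of
substitutions on mutable positions is compared against `B` uniform
repositionings of the same number of substitutions over the CDS, with the
add-one correction `p = (r + 1)/(B + 1)`.  Its null is exact uniformity,
which the synthetic generator can reproduce exactly (below).

## Cohort statistics

**Crosstabs** use pairwise missing-data exclusion, so denominators vary by
variable pair — the convention visible in published characteristics tables.

**Exact tests** follow the minimum-likelihood two-sided rule: the p-value
sums the probabilities of all tables with the observed margins whose point
probability does not exceed the observed table's, with a relative tie
tolerance of 1e-12.  The 2×2 case enumerates the hypergeometric range
directly; the r×c case (Freeman–Halton) enumerates all tables by a
row-wise recursion with incrementally accumulated log-factorials when the
table count fits under a cap (default 5×10⁶), and otherwise falls back to
seeded Monte Carlo over Patefield-sampled tables, reporting which path
ran.  Enumerated probability mass is checked to sum to 1 (±1e-6 hard
error; ±1e-9 in tests), and the p-value is normalized by that mass so the
degenerate all-tables case is exactly 1.

**Kaplan–Meier** is the standard product-limit estimator; subjects
censored exactly at an event time are counted at risk at that time.

**Cox proportional hazards** is fit by Newton–Raphson on the partial
likelihood from β = 0 with step-halving, Breslow tie handling by default
and Efron behind a flag.  Convergence requires max |score| < 1e-8 or a
log-likelihood change < 1e-10, within 50 iterations.  Standard errors are
Wald (observed information); 95% CIs are β ± 1.96·SE.  Constant covariates
are a hard error naming the column; monotone likelihood (complete
separation, detected as |β| > 15 at the stationarity stop) yields a
non-converged fit with a diagnostic rather than silent output.  Subjects
with any missing included covariate are dropped per model (complete-case),
logged.  Covariate encodings follow the screening study's conventions:
age ≥ 60, LDH > ULN, ECOG > 1, Ann Arbor III/IV, extranodal sites > 1,
B-symptoms, immunoblastic morphology, non-GCB, non-mBL, non-PAP-1,
non-BCR, IPI ≥ 2, and the mutation-status triplet.  The IPI is the only
derived value where missingness is converted: a missing factor scores 0
(the "pessimistic" published rule).  The default multivariate model is
age60 + aas34 + non_gcb + socs1_major + socs1_minor.

The published survival p-values cannot be re-derived — individual-level
survival times were never released — so survival correctness is
established by construction: grid-search oracles on small fixtures,
cross-checks against an independent survival library on tie-free data
(where Breslow and Efron coincide), and planted-parameter recovery on
synthetic cohorts.

## Synthetic cohorts

The generator emulates the screening study's statistical skeleton with
these defaults: 154 cases; mutant prevalence 0.16; an even major/minor
split among mutants; 1–18 point mutations per mutated case, truncated
geometric with success probability 0.25 (mean ≈ 4, right-skewed — the
published range is 1–18 with most cases carrying a handful); substitution
positions landing on a hotspot mutable position with probability
θ = 0.41; signature labels (COO, mBL, PAP, CC) drawn conditionally on
subtype with probabilities proportional to the published per-subtype
tallies (in particular, generated major cases are GCB with probability 1);
survival exponential with baseline hazard 0.02/month and subtype log
hazard ratios −1.2 (major) and +1.0 (minor) — free simulation parameters
chosen to mirror the direction and rough magnitude of the reported
divergence, not literature estimates — under independent uniform censoring
calibrated to ~30% censored.

Two generator details matter for the tests.  First, a substitution is
drawn from the mutable-position set with probability θ and from the
complement otherwise, so θ equal to the reference's mutable-position
density reduces exactly to the uniform null of the enrichment test — that
makes the calibration property exact rather than approximate.  Second,
every generated major case contains, by construction, at least one
frame-disrupting or stop-gain event 5' of the C-terminal domains, and
minor cases contain only non-stop-gain substitutions, so the planted
subtype is recoverable from the catalog alone and generator/classifier
agreement is an exact end-to-end invariant.

What the synthetic cohorts do **not** emulate: sequencing noise, tumor
purity and allele fractions, linkage between clinical covariates and
subtype (beyond the signature conditionals), non-exponential baselines,
and informative censoring.  Passing recovery tests therefore demonstrates
internal consistency of the pipeline and correct frequentist behavior of
the estimators at the study's scale — not that real cohorts will show the
published effect sizes.

## Problem sizes used in validation

Simulation-based checks run at: subtype agreement on 2 000 simulated
cases; conservative-⊆-aggressive on 1 000 random cases; Cox CI coverage
over 100 replicates of 1 000 subjects (coverage asserted per planted
coefficient against a ≥90% floor for nominal-95% intervals); SHM
enrichment power (θ = 0.8) and calibration (θ = background density) over
50 replicates of 50 substitutions with B = 500; exact-test equivalence and
conservation over 500 random tables.  These sizes give the binomial slack
each assertion needs while keeping the default suite fast.

## Known limitations

* Domain boundaries in the packaged model are stand-ins; analyses that
  depend on exact boundary placement should supply curated coordinates.
* The HGVS dialect is the four event kinds only; complex delins are
  rejected, not coerced.
* Whether the published 40.8% at-motif fraction counted boundary positions
  or used extra-CDS context is unknowable from the text; both variants are
  computable here (context-padded scanning is the default, and
  boundary-uncertain positions are flagged).
* The r×c exact test's enumeration/Monte-Carlo decision is made by
  attempting enumeration under the cap, not by a closed-form count; very
  large tables pay the aborted-enumeration cost once before falling back.
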