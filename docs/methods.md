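# Methods

`fedpipe` implements a federated, three-stream analysis pipeline for
harmonized clinical-registry data, in the setting of COVID-19 severity in
people with multiple sclerosis (MS). This note documents the models and
procedures, the parameters that matter, what the synthetic generator does
and does not emulate, and the numerical and design choices that were
genuinely open.

## The pipeline

Patient-level data arrive through three sharing streams with different
privacy contracts:

* **direct entry** — individual records submitted through a validated
  form (patient-level CSV);
* **core data set sharing** — a registry uploads patient-level CSV mapped
  to the shared data dictionary;
* **federated model sharing** — a registry runs validation, quality
  control and bucketization on its own infrastructure and shares only a
  multivariate contingency table ("buckets"); raw values never leave.

Central processing is: validate → QC → categorize → bucketize (per
source) → aggregate → expand → model. Federated sources enter at the
aggregation step.

## Data dictionary and validation

A `DataDictionary` is an ordered list of variable specifications (name,
format, optional choice set, rule dependencies), serialized as YAML. The
shipped default covers the core variable subset used by the quality rules
and the severity analysis; real deployments extend the document. Ordering
is canonical and fixes column order in every artifact.

Missingness uses an explicit `NA` token, deliberately distinct from the
empty string: a blank cell is a conformance violation, a declared missing
value is not. Unknown variables are violations rather than silently
dropped, because the harmonization contract is that sources map *to* the
dictionary. Validation reports violations as data (a list), never as
exceptions; unparseable values are set missing with a logged warning at
I/O time.

## Quality control

Each non-missing variable gets a `PASS` or `FAIL` flag; missing inputs are
`EMPTY`. A `FAIL` sets the value to missing and keeps the row — the
engine never drops records; downstream stages decide what to do with
missingness. Rules evaluate in a single pass in a fixed kind order,

    range → temporal → interdependency → derivation,

so later stages see values already blanked by earlier failures, and
derivations act on the post-QC ("for analysis") state. The shipped rules:

* reporting date must be 2019 or later; age in [0, 110]; EDSS in [0, 10];
* no date may exceed the reporting date; no date's calendar *year* may
  precede reporting year − age (year granularity only, since the age is
  in whole years — no birth date exists in the data);
* MS onset may not follow MS diagnosis or the suspected infection onset;
  COVID-19 dates may not precede the MS baseline dates (the earlier-side
  variable of the violated comparison is the one flagged);
* hospital admission with an explicitly unconfirmed case fails;
* a claimed ongoing therapy with no therapy named fails. The flagged
  variable is `current_dmt`: it is the inconsistent *non-missing* value,
  and flagging an already-null field would conflate FAIL with EMPTY;
* derivations: an EMPTY `covid19_has_symptoms` is filled from the nine
  symptom indicators (any yes → yes; all nine observed no → no; partial
  information leaves it EMPTY); an EMPTY `has_comorbidities` becomes yes
  when any comorbidity indicator is yes (only the yes direction is
  defined). Derivations never overwrite an observed value.

Rules whose anchors are missing (no reporting date, no age) are skipped:
an undefined comparison flags nothing, and the anchor's own EMPTY flag
already records the gap.

**Strict symptom mode** (off by default) additionally fails an explicit
"no symptoms" contradicted by a named symptom. This creates the one place
where QC is not a projection: the failed value is blanked, and a
*re-evaluation* of the cleaned record would re-derive it from the
symptoms. We therefore guarantee idempotence (identical cleaned output,
no new FAILs) for the default engine, and the weaker no-new-FAILs
guarantee in strict mode; derivations never fill a variable FAILed in the
same pass.

Only the printed core checks ship. The engine accepts additional
user-defined rules in a small declarative YAML dialect (conditions over
variables with comparison operators; undefined conditions flag nothing),
and verifies every referenced variable against the dictionary when the
engine is built, never at evaluation time.

## Integration: buckets, aggregation, expansion

Each analysis variable `k` has an ordered partition Σ_k of its domain
into bins; a cleaned record maps to a tuple of bin labels, with a reserved
`EMPTY` label per variable for missing or out-of-domain values. The
default scheme is: age bands 18–50 / 50–70 / >70, sex, MS phenotype
(relapsing-remitting vs progressive), EDSS dichotomized at 6, the 12 DMT
categories (untreated, ten named therapies, other), and the four severity
outcomes (hospitalization, ICU admission, ventilation, death) as yes/no
indicators.

Interval closure is lower-inclusive (ages [18,50), [50,70), [70,∞); EDSS
[0,6), [6,10]): the conventional epidemiological half-open convention,
with EDSS ≥ 6 as the standard high-disability group. Ages below 18 are
out of the analysis domain and map to EMPTY (QC admits 0–110; the
analysis scheme starts at adulthood; the analysis scheme wins here).

A `BucketTable` stores only observed tuples with strictly positive
integer counts. Aggregation across sources is tuple-wise count addition
and requires scheme equality *by value*; it is commutative, associative,
and exactly equivalent to bucketizing the pooled records — the pipeline's
central correctness property, tested against brute-force tallies over
random partitions. Expansion repeats each tuple count-many times in a
deterministic order (sources sorted, tuples in canonical bin order), so
equal tables expand bit-identically and `bucketize ∘ expand` is the
identity.

Aggregated tables keep a per-source count breakdown as provenance.
Equality and CSV serialization use only the summed view; the provenance
exists so that expansion can label each row with its source — the
grouping factor the downstream random-intercept model needs. Optional
small-cell suppression (drop buckets below a count threshold, reporting
the suppressed total) supports pre-release privacy review; no formal
privacy guarantee (differential privacy, k-anonymity) is claimed.

## Severity model

For a binary severity outcome of patient *i* in source *j*:

    logit P(y_ij = 1) = x_ij' β + b_j,    b_j ~ N(0, σ²)

with fixed effects for age band, sex, phenotype, EDSS group and DMT
category (reference levels: 18–50, female, relapsing-remitting, EDSS
0–6, untreated), and a source-level random intercept. Rows with EMPTY in
the outcome or any modelled variable are excluded (complete-case) and
counted; missing-category modelling is out of scope.

The marginal likelihood integrates b_j by Gauss–Hermite quadrature
(25 nodes by default) after collapsing the expanded table to unique
(source, covariate-pattern) cells with binomial counts — the collapse
makes the fit row-order invariant by construction and fast at any N. The
optimizer is BFGS (scipy) started from the pooled logistic fit, with σ on
the log scale; standard errors come from the inverse of the
finite-difference observed information at the optimum, and 95% CIs are
Wald (the CI method was an open choice; Wald is the default and the only
one implemented). Adjusted odds ratios are `exp(β̂)`. The fit agrees with
`lme4::glmer` (nAGQ=25) to ~1e-3 on shared designs, which is tested.

Two DMT parameterizations are provided, because "compared with all other
DMTs" contrasts and untreated-reference contrasts are both in use: the
default reference coding (11 coefficients against untreated) and a
one-vs-rest indicator for a chosen therapy. With fewer than two sources
the mixed model is degenerate and the fit falls back to ordinary logistic
regression with a warning; non-convergence or a singular information
matrix marks the result non-converged and withholds odds-ratio reporting.

## Synthetic generator

The generator emulates the *statistical structure* the pipeline and model
assume: categorical covariates from configurable prevalences, a Normal
per-source intercept (SD 0.25 by default), outcomes from the logistic
model above, internally consistent dates built backwards from a reporting
date in 2020-03 – 2021-06 (onset ≤ diagnosis ≤ suspected onset ≤
reporting, all consistent with age), per-variable missingness (5–10% on
dates, EDSS and comorbidity status by default), and optional injected
errors (future date, pre-birth date, onset after diagnosis, symptom
contradiction, out-of-range age/EDSS), each recorded in a ground-truth
ledger. At most one error is injected per record so every injection stays
independently detectable; clean-mode output passes every shipped rule by
construction. The default effect configuration elevates rituximab (log-OR
1.0) and ocrelizumab (0.55) on hospitalization so recovery tests are
directional — these are test fixtures, not clinical estimates.

What it does **not** emulate: realistic MS epidemiology (DMT market
shares, true severity rates), correlated outcomes (the four severity
indicators are drawn independently rather than as a progression),
informative missingness, within-source covariate drift, or free-text
noise. Passing tests therefore demonstrate the pipeline's algebra and the
model's statistical correctness under its own assumptions — not
robustness to every pathology of real registry exports.

One global seed determines everything; per-source substreams are derived
from (seed, source index), so a source's draw does not depend on the
sizes of the others.

## Problem sizes and verification scale

Defaults were chosen so the full verification battery runs on a laptop:
federated equivalence over 100 random partitions of 5,000 records;
round trips over 50 random tables; effect recovery at n=8,000 over 8
sources; null CI coverage over 50 replicates of n=4,000 (pooled over the
550 DMT coefficient CIs, expected ≈95% coverage, required ≥90%). The
reference acquisition scenario uses stream totals 1383 / 6374 / 3527
across 1 + 14 + 4 sources (N=11,284). Percentages in summaries are
computed from exact integer counts and rounded half-up at presentation
(two decimals for record shares, whole percent for registry shares).

## Known limitations

* The shipped rule set is the printed core subset; production deployments
  carry far larger rule inventories via the declarative dialect.
* The bucket scheme covers the severity-analysis variables only; other
  research questions require their own `BinningScheme`.
* Aggregation trusts federated sources to have run QC locally; the
  central side cannot audit record-level quality it never sees.
* Small-cell suppression is a reporting aid, not a privacy proof.
* Wald intervals can undercover for rare categories (few events per DMT
  cell); profile or bootstrap intervals are not implemented.
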