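# Methods

## Setting

Spontaneous-reporting databases such as FAERS collect individual case
safety reports (ICSRs): demographics, drugs with reporter-assigned roles,
reaction Preferred Terms (PTs) and regulatory outcomes. Disproportionality
analysis asks whether a drug–event pair is reported more (or less) often
than expected relative to a comparator. This package implements that
analysis for paediatric eye disorders after prenatal opioid exposure —
methadone vs buprenorphine head-to-head, and each against a pooled group of
non-opioid psychotropics — together with the case-selection and
deduplication machinery such a study needs.

## Reporting odds ratio and confidence interval

For cells (a, b, c, d) — exposure with/without event, comparator
with/without event — the reporting odds ratio is ROR = (a/b)/(c/d). The
confidence interval is Woolf's log-normal interval,
exp(ln ROR ± z·√(1/a + 1/b + 1/c + 1/d)) with z = 1.96 for 95%. This
interval reproduces, at two-decimal display precision, all published CI
bounds of the source analysis when applied to its printed cells, which is
how the (unnamed) published method was identified. Signals: CI entirely
above 1 → higher reporting; entirely below 1 → lower reporting; otherwise
not significant. Signal classification uses the unrounded interval.

Zero cells make the interval undefined; the optional Haldane–Anscombe
correction adds 0.5 to all four cells. It is off by default — the target
analyses never hit a zero cell — and requesting an uncorrected ROR on a
degenerate table is an error that names the flag rather than a silent
adjustment.

Rounding for display is banker's rounding (round-half-even) at 2 decimals;
full precision is kept internally and all invariant checks (reciprocity,
log-symmetry of the CI) run on unrounded values.

### Denominator convention

`b` and `d` are each drug's *total* paediatric ADR count minus its
validated event cases, while `a` and `c` are de-duplicated, taxonomy-vetted
survivors. The numerator and denominator are therefore cleaned to different
standards. This mirrors the source analysis deliberately and is a property
of the reporting-odds convention used there, not an incidence estimate; the
package keeps the convention rather than "fixing" it so that published and
recomputed numbers are commensurable.

## Case selection

A report is includable when it names an exposure substance (set
intersection on canonical constituents, so buprenorphine/naloxone counts as
buprenorphine), its age lies in the configured range (default 0–17 years),
it carries at least one eye-disorder PT (general or congenital), and its
exposure context classifies as in-utero.

Context classification is exact-string, case-insensitive PT matching
against an ordered exclusion taxonomy — no fuzzy matching, trading recall
for reproducibility. Categories are evaluated in declared order and a
report is counted once, under the first matching category; the
abuse/dependence rule is "rescued" by in-utero evidence (abuse PTs exclude
only *without* mention of in-utero exposure), while the other categories
(accidental exposure, toxicity/poisoning/overdose, suicide, substance use
disorder, anaesthesia-related, indication-only) exclude outright. Reports
with no context PT at all are excluded as unclassified. The shipped
taxonomy (`faerspv/data/default_taxonomy.yaml`) lists the eye-disorder PTs
named in the study's case listings plus a congenital set, and is explicitly
user-editable, since "eye disorders" is a System-Organ-Class label whose
full PT expansion is licensed MedDRA content.

Context exclusions run before duplicate removal and both are tallied in one
audit, so the flow-chart arithmetic is single-counted and conserving:
n_input = n_survivors + Σ excluded, on every input. Structural removals
(wrong drug, out-of-range or missing age, no event term, unclassifiable
context) get their own audit buckets. Missing-age reports are excluded from
the paediatric subset by default (configurable), a conservative choice the
source data leave open.

## Deduplication

Two reports are duplicates when they share a case ID, or when they agree on
sex, have identical canonical drug multisets, ages within ±1 of the coarser
report's age unit, and reaction-set Jaccard similarity at or above the
overlap threshold (default 0.5, exposed as a parameter). Both-missing ages
are treated as compatible, one-missing as incompatible. Clusters are the
transitive closure (single linkage) of the pairwise relation — a chain of
near-copies collapses to one case, matching how removed-duplicate counts
are reported. Within a cluster the retained report is the highest version,
ties broken by earliest report year then lexicographic case ID. The
"overlapping clinical information" rule is a declared convention: the
source describes its deduplication only as matching case IDs and
overlapping clinical information, so the exact predicate here is this
package's own, documented choice.

Candidate pairs are generated within (sex, drug-multiset) blocks, which
leaves the result identical to the exhaustive O(n²) comparison (verified
against a brute-force oracle in the tests) while scaling to larger cohorts.
Version supersession at load time (keeping the highest version per case ID)
is distinct from, and precedes, this stage.

## Synthetic cohorts

The generator emulates FAERS-like line listings with exact ground truth.
Per-drug blocks set a report count, an event probability and an
exposure-context mix; a duplication rate emits near-copies, half as
same-case-ID revisions and half as distinct-ID clinical near-copies (one
extra "Somnolence" term keeps them above the overlap threshold), so both
dedup pathways are exercised. Fractional duplicate quotas are apportioned
by the largest-remainder method, conserving counts exactly. In-utero
reports skew young: 60% fall in the 1–12-month bin, echoing the age
distribution of the validated cases; other ages are uniform over 0–17
years.

Each base report carries three "detail" PTs forming a distance-2 parity
codeword over three term pools, so two distinct base reports share at most
one detail term and their reaction Jaccard stays below the default
threshold. "Duplicate" is therefore an exact generator-controlled label,
not a statistical tendency — a deliberate departure from real FAERS data,
where independent reports can genuinely look like near-copies and
deduplication has a false-positive rate. Passing tests consequently show
the pipeline recovers the generator's truth, not that the overlap rule has
any particular operating characteristic on real data.

Two deterministic fixtures reproduce the published flow charts exactly: 190
methadone reports (9 abuse/dependence, 37 accidental exposure, 13
toxicity/poisoning/overdose, 1 indication-only, 113 duplicates, 17 valid
cases with the published 6 F / 4 M / 7 unspecified sex split) and 79
buprenorphine reports (1 toxicity, 22 accidental poisoning, 1 overdose, 1
suicide, 2 substance use disorder, 1 anaesthesia-related, 36 duplicates, 15
valid cases). Fixture ages are explicit (no missing values), so flow-chart
counts do not depend on the missing-age policy.

The two-arm study generator draws events Bernoulli per arm with the
comparator probability fixed and the exposure probability solved from the
requested true odds ratio θ. The comparator event probability defaults to
0.05, a realistic fraction of reports carrying the target event class, and
large enough that at the study's arm sizes (2,297 and 1,199) the expected
event counts (~60 per arm at θ = 1) keep the finite-sample bias of the
empirical odds ratio (≈ 1/a + 1/c) near 3%, comfortably inside the 10%
recovery band; at the real study's much rarer event probabilities that bias
alone approaches 13%, which is a small-counts property of the estimator,
not an implementation artefact. A θ whose implied exposure probability is
degenerate (≥ 1 − 1e-9) is a configuration error. Parameter-recovery runs
use 200 replicates per θ ∈ {0.5, 1, 2}; coverage of the 95% CI is checked
against a 3σ binomial band around 0.95. Recovery cohorts are generated
without duplicates and their RORs are computed from per-arm event tallies
(selection by exposure, age and event class); the dedup stage is exercised
separately by the fixtures and its own oracle-equivalence property.

## Rankings and class summaries

Medication rankings count *reports* per canonical substance for an event
class (general vs congenital): a report naming several substances counts
once for each, and combination products count once per constituent.
Ordering is descending count with alphabetical tie-break, making rankings
independent of input order. Per-class summaries compute three nested counts
per substance — all-ages event reports, the paediatric subset, validated
cases after selection and dedup — with the nesting enforced by the type.

The per-substance dashboard snapshot counts shipped in
`faerspv.reference` (paediatric totals summing to 1,591 and validated cases
to 42 across the 13 non-opioid psychotropics; 25 for benzodiazepines, 11
for antipsychotics) are study inputs transcribed from the published
analysis, used as comparator denominators and fixture parameters. They are
never recomputed: the live dashboard query behind them is not reproducible
bit-for-bit, and top-20 ranking counts from that external snapshot are
likewise treated as shapes, not targets.

## Numerical and design notes

- Age conversion: value/365.25 (days), /52.18 (weeks), /12 (months) years;
  deterministic and documented rather than calendar-exact.
- Manifests serialize with sorted keys; identical config + seed reproduces
  the manifest byte-for-byte.
- Delimited tables default to tab and accept `$`, the delimiter of the real
  quarterly files; neither matches the dashboard export exactly, which is
  unspecified in the source.
- `select_cases` sorts survivors by (case_id, version) before dedup so the
  retained representative is order-independent.
- Problem sizes in the shipped tests: fixtures at their natural sizes
  (190/79), property tests on cohorts of ≤ 100, dedup oracle equivalence on
  ≤ 50, recovery at the study's arm sizes with 200 replicates per θ —
  chosen as the smallest sizes at which each property is meaningfully
  exercised.

## Limitations

- The exclusion-taxonomy PT lists are a reconstruction at PT-label level;
  no MedDRA hierarchy traversal is performed, and real dashboard queries
  resolve SOC-level labels that this package approximates with editable
  lists.
- The clinical-overlap predicate is a convention; real-world record linkage
  (probabilistic weights, name matching) is out of scope.
- Reporting odds ratios quantify reporting behaviour, not risk: no
  denominator of exposed children exists, and confounding (polydrug
  exposure, maternal comorbidity, differential reporting) is untouched by
  the statistic.
- The generator does not model longitudinal reporting dynamics,
  drug–drug interactions, or realistic PT co-occurrence beyond what the
  ground-truth design requires.
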