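# faerspv

Disproportionality analysis of FAERS-like spontaneous adverse-event reports,
built around one question from paediatric pharmacovigilance: are eye
disorders reported more or less often for children exposed in utero to
methadone than for those exposed to buprenorphine (or to other psychotropic
drugs)?

The package is a tested, reusable implementation of the full analysis chain
for that kind of study:

- an individual-case-safety-report (ICSR) data model with readers/writers
  for FAERS-dialect delimited tables and JSON-lines line listings;
- deterministic drug-name normalization (salts, synonyms, combination
  products such as buprenorphine/naloxone);
- case selection by a Preferred-Term (PT) taxonomy: paediatric age filter,
  exposure match, eye-disorder event requirement, and an ordered
  exclusion taxonomy (abuse/dependence without in-utero mention, accidental
  exposure, toxicity/poisoning/overdose, suicide, substance use disorder,
  anaesthesia-related, indication-only) with full flow-chart audits;
- duplicate-report removal by case-ID match and clinical-information
  overlap (same sex, same canonical drugs, compatible age, reaction-set
  Jaccard similarity), clustered by transitive closure;
- reporting odds ratios with Woolf confidence intervals, head-to-head
  ("relative ROR") and against a pooled comparator group;
- medication rankings and per-class descriptive summaries;
- a synthetic ICSR cohort generator with exact ground truth, including
  deterministic fixtures reproducing the study's published case-selection
  flow charts.

## The statistic

For an exposure drug and a comparator, the 2×2 table is

|                | event (eye disorders) | no event |
|----------------|----------------------|----------|
| exposure drug  | a                    | b        |
| comparator     | c                    | d        |

with the reporting odds ratio and its 95% Woolf (log-normal) interval

    ROR = (a/b) / (c/d),
    CI  = exp( ln ROR ± z · sqrt(1/a + 1/b + 1/c + 1/d) ),  z = 1.96.

A CI entirely above 1 flags higher reporting, entirely below 1 lower
reporting, otherwise the comparison is not significant. Following the
source study's convention, `b` and `d` are each drug's total paediatric ADR
count minus its validated event cases: numerators are de-duplicated
survivors of case selection, denominators are raw report totals.

## Worked example

```python
from faerspv.pipeline import default_study_config, run_study

manifest = run_study(default_study_config(seed=17))
print(manifest.arms[0].flow_chart)
for name, result in manifest.results.items():
    print(result)
```

prints

```
Case selection: methadone
  reports identified: 190
  excluded - abuse dependence: 9
  excluded - accidental exposure: 37
  excluded - toxicity poisoning overdose: 13
  excluded - indication only: 1
  excluded - duplicate: 113
  unique and relevant cases remaining: 17
methadone vs buprenorphine: ROR 0.59 (95% CI 0.29-1.18; not_significant)
methadone vs all other psychotropic drugs: ROR 0.27 (95% CI 0.16-0.48; lower_reporting)
buprenorphine vs all other psychotropic drugs: ROR 0.47 (95% CI 0.26-0.85; lower_reporting)
```

Reading the output: of 190 methadone-exposed paediatric eye-disorder
reports, 17 unique in-utero cases survive selection and deduplication.
Against 15 buprenorphine survivors (of 79), the relative ROR of 0.59 has a
CI straddling 1 — no reporting-odds difference between the two opioids can
be claimed. Both opioids show significantly *lower* reporting odds than the
pooled non-opioid psychotropic comparator (42 validated cases among 1,591
paediatric reports): no disproportionality signal for eye disorders under
prenatal opioid exposure. A ROR below 1 is lower *reporting*, not evidence
of protection — spontaneous-reporting data carry no denominators and much
confounding.

The same run is available from the shell:

```sh
faerspv run-all --seed 17 --out results/
faerspv ror --a 17 --b 2280 --c 15 --d 1184
```

## Layout

| module | contents |
|---|---|
| `faerspv.model` | `CaseReport`, `DrugEntry`, `ReactionTerm` |
| `faerspv.substances` | drug-name normalization |
| `faerspv.taxonomy` | PT categories and exposure-context rules (editable YAML) |
| `faerspv.io` | jsonl / delimited-table readers and writers |
| `faerspv.synthetic` | cohort generator, fixtures, two-arm studies |
| `faerspv.selection` | inclusion filter, exclusion taxonomy, audits |
| `faerspv.dedup` | duplicate clustering and removal |
| `faerspv.disproportionality` | 2×2 tables, ROR, Woolf CI, pooling |
| `faerspv.ranking` | top-N medications, per-class summaries |
| `faerspv.reference` | published dashboard snapshot counts (inputs) |
| `faerspv.pipeline` | end-to-end study runner and manifest |
| `faerspv.cli` | `faerspv` command-line interface |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
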