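"""Published FAERS-dashboard snapshot counts used as study inputs.

These per-substance totals are transcribed from the public-dashboard query
the analysis is built around (queried September 2025).  They are *inputs* —
comparator denominators and fixture parameters — never computed targets: the
live dashboard is not reproducible bit-for-bit, so the package treats the
printed counts as the study conditions.

Columns per substance: total eye-disorder reports (all ages), eye-disorder
reports in the 0-17-year group, and final validated cases after case
selection and deduplication.
"""

from __future__ import annotations

from dataclasses import dataclass

from .disproportionality import CohortSummary

#: Paediatric (0-17 y) ADR totals for the two exposure drugs.
METHADONE_PAEDIATRIC_TOTAL = 2297
BUPRENORPHINE_PAEDIATRIC_TOTAL = 1199

#: Validated case counts after selection + dedup for the exposure drugs.
METHADONE_VALIDATED_CASES = 17
BUPRENORPHINE_VALIDATED_CASES = 15

#: Initial flow-chart report counts.
METHADONE_INITIAL_REPORTS = 190
BUPRENORPHINE_INITIAL_REPORTS = 79


@dataclass(frozen=True)
class ReferenceRow:
    substance: str
    drug_class: str
    n_total_eye: int
    n_paediatric: int
    n_validated: int


#: Non-opioid psychotropic comparator drugs (snapshot counts).
PSYCHOTROPIC_REFERENCE_ROWS: tuple[ReferenceRow, ...] = (
    ReferenceRow("diazepam", "benzodiazepine", 2791, 240, 7),
    ReferenceRow("alprazolam", "benzodiazepine", 2999, 97, 5),
    ReferenceRow("clonazepam", "benzodiazepine", 2862, 242, 7),
    ReferenceRow("lorazepam", "benzodiazepine", 2246, 117, 5),
    ReferenceRow("bromazepam", "benzodiazepine", 580, 27, 1),
    ReferenceRow("biperiden", "anticholinergic", 35, 6, 0),
    ReferenceRow("benztropine", "anticholinergic", 91, 15, 0),
    ReferenceRow("trihexyphenidyl", "anticholinergic", 166, 31, 1),
    ReferenceRow("pregabalin", "gabapentinoid", 12170, 200, 0),
    ReferenceRow("gabapentin", "gabapentinoid", 3501, 89, 5),
    ReferenceRow("quetiapine", "antipsychotic", 2054, 156, 3),
    ReferenceRow("olanzapine", "antipsychotic", 3973, 326, 7),
    ReferenceRow("clozapine", "antipsychotic", 1354, 45, 1),
)

#: substance -> pharmacological class for the comparator drugs.
PSYCHOTROPIC_CLASS_MAP: dict[str, str] = {
    r.substance: r.drug_class for r in PSYCHOTROPIC_REFERENCE_ROWS
}


def comparator_summaries() -> list[CohortSummary]:
    """The 13 comparator drugs as :class:`CohortSummary` records."""
    return [
        CohortSummary(
            substance=r.substance,
            n_total_adr_paediatric=r.n_paediatric,
            n_event_validated=r.n_validated,
        )
        for r in PSYCHOTROPIC_REFERENCE_ROWS
    ]


def exposure_summary(substance: str) -> CohortSummary:
    """Snapshot summary for one of the two exposure drugs."""
    table = {
        "methadone": (METHADONE_PAEDIATRIC_TOTAL, METHADONE_VALIDATED_CASES),
        "buprenorphine": (BUPRENORPHINE_PAEDIATRIC_TOTAL, BUPRENORPHINE_VALIDATED_CASES),
    }
    try:
        total, validated = table[substance.lower()]
    except KeyError:
        raise KeyError(f"no reference summary for {substance!r}") from None
    return CohortSummary(
        substance=substance.lower(),
        n_total_adr_paediatric=total,
        n_event_validated=validated,
    )
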