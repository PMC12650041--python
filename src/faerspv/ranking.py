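"""Medication rankings and per-class descriptive summaries.

``rank_top_medications`` tallies, per canonical substance, the number of
*reports* carrying an event of the requested class (general vs congenital
eye disorders).  Counting is report-level: a report naming several ranked
substances contributes one count to each, and a combination product counts
once per constituent.  Ordering is descending count with alphabetical
tie-break, so rankings are reproducible.

``summarize_classes`` produces the three nested counts per substance —
total event reports (all ages), the paediatric subset, and the final
validated cases after selection + deduplication.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .model import CaseReport
from .selection import SelectionCriteria, select_cases
from .taxonomy import Taxonomy

EVENT_CLASS_CATEGORIES = {
    "general": frozenset({"eye_disorder_general"}),
    "congenital": frozenset({"eye_disorder_congenital"}),
}


@dataclass(frozen=True)
class ClassSummary:
    """Nested counts for one substance: validated <= paediatric <= total."""

    substance: str
    drug_class: str
    n_total_eye: int
    n_paediatric: int
    n_validated: int

    def __post_init__(self) -> None:
        if not self.n_validated <= self.n_paediatric <= self.n_total_eye:
            raise ValueError(
                f"{self.substance}: counts not nested "
                f"({self.n_validated} <= {self.n_paediatric} <= {self.n_total_eye})"
            )


def rank_top_medications(
    reports: list[CaseReport],
    event_class: str = "general",
    n: int = 20,
) -> pd.DataFrame:
    """Top-``n`` substances by event-report count.

    Returns a DataFrame with columns ``substance``, ``n_reports``,
    ``event_class``, sorted by descending count then substance name.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    try:
        categories = EVENT_CLASS_CATEGORIES[event_class]
    except KeyError:
        raise ValueError(
            f"unknown event class {event_class!r}; expected one of "
            f"{sorted(EVENT_CLASS_CATEGORIES)}"
        ) from None
    counts: Counter[str] = Counter()
    for r in reports:
        if r.has_category(categories):
            counts.update(r.substances())
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
    return pd.DataFrame(
        [
            {"substance": s, "n_reports": c, "event_class": event_class}
            for s, c in rows
        ],
        columns=["substance", "n_reports", "event_class"],
    )


def summarize_classes(
    reports: list[CaseReport],
    class_map: dict[str, str],
    criteria_template: SelectionCriteria | None = None,
    *,
    taxonomy: Taxonomy | None = None,
    overlap_threshold: float = 0.5,
) -> list[ClassSummary]:
    """Nested event/paediatric/validated counts for every mapped substance.

    ``criteria_template`` supplies the age range and event categories; the
    exposure set is overridden per substance.  Substances absent from
    ``class_map`` cannot be requested (mapping error).
    """
    taxonomy = taxonomy or (criteria_template.taxonomy if criteria_template else Taxonomy.default())
    if criteria_template is None:
        criteria_template = SelectionCriteria(
            exposure_substances=frozenset(class_map) or frozenset({"placeholder"}),
            taxonomy=taxonomy,
        )
    if not class_map:
        raise ValueError("class_map must be non-empty")
    out = []
    for substance in sorted(class_map):
        drug_class = class_map[substance]
        group = frozenset({substance.lower()})
        event_cats = criteria_template.event_categories
        named = [r for r in reports if r.names_substance(group)]
        with_event = [r for r in named if r.has_category(event_cats)]
        lo, hi = criteria_template.age_range_years
        paediatric = [
            r
            for r in with_event
            if (
                (r.age_years is None and criteria_template.include_missing_age)
                or (r.age_years is not None and lo <= r.age_years <= hi)
            )
        ]
        crit = SelectionCriteria(
            exposure_substances=group,
            age_range_years=criteria_template.age_range_years,
            event_categories=event_cats,
            include_missing_age=criteria_template.include_missing_age,
            taxonomy=taxonomy,
        )
        survivors, _audit = select_cases(
            named, crit, overlap_threshold=overlap_threshold
        )
        out.append(
            ClassSummary(
                substance=substance.lower(),
                drug_class=drug_class,
                n_total_eye=len(with_event),
                n_paediatric=len(paediatric),
                n_validated=len(survivors),
            )
        )
    return out


def class_totals(summaries: list[ClassSummary]) -> dict[str, int]:
    """Validated-case rollup per pharmacological class."""
    totals: dict[str, int] = {}
    for s in summaries:
        totals[s.drug_class] = totals.get(s.drug_class, 0) + s.n_validated
    return totals


def summaries_to_frame(summaries: list[ClassSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "substance": s.substance,
                "class": s.drug_class,
                "total_eye_disorders": s.n_total_eye,
                "total_eye_disorders_0_17": s.n_paediatric,
                "final_validated_cases": s.n_validated,
            }
            for s in summaries
        ]
    )
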