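"""Case selection: inclusion filter plus PT-based exclusion taxonomy.

A report survives selection when it (1) names an exposure substance, (2) has
a reported age inside the paediatric range, (3) carries at least one
eye-disorder reaction, and (4) classifies as an in-utero exposure under the
context taxonomy.  Everything removed is tallied in a
:class:`SelectionAudit`, whose categories mirror a case-selection flow chart:
the published-style context categories first (abuse/dependence without
in-utero mention, accidental exposure, toxicity/poisoning/overdose, suicide,
substance use disorder, anaesthesia-related, indication-only), then
duplicates.  Structural removals (wrong drug, wrong age, no event term,
unclassifiable context) get their own buckets so the audit always conserves
counts: ``n_input == n_survivors + sum(excluded.values())``.

Context exclusions are evaluated before duplicate removal, and a report
matching several categories is counted once under the first in taxonomy
order — this keeps the flow-chart arithmetic single-counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .dedup import dedup as _dedup
from .model import CaseReport
from .taxonomy import IN_UTERO, Taxonomy

#: Audit buckets for structural (non-taxonomy) removals.
STRUCTURAL_CATEGORIES = (
    "no_exposure_match",
    "missing_age",
    "age_out_of_range",
    "no_event_term",
    "unclassified_context",
)

DEFAULT_EVENT_CATEGORIES = frozenset({"eye_disorder_general", "eye_disorder_congenital"})


class CriteriaError(ValueError):
    pass


@dataclass
class SelectionCriteria:
    """What counts as an includable case."""

    exposure_substances: frozenset[str]
    age_range_years: tuple[float, float] = (0.0, 17.0)
    event_categories: frozenset[str] = DEFAULT_EVENT_CATEGORIES
    include_missing_age: bool = False
    taxonomy: Taxonomy = field(default_factory=Taxonomy.default)

    def __post_init__(self) -> None:
        if not self.exposure_substances:
            raise CriteriaError("exposure_substances must be non-empty")
        lo, hi = self.age_range_years
        if lo > hi:
            raise CriteriaError(f"empty age range: {self.age_range_years}")
        self.exposure_substances = frozenset(s.lower() for s in self.exposure_substances)


@dataclass
class SelectionAudit:
    """Flow-chart accounting: input, per-category exclusions, survivors."""

    n_input: int = 0
    excluded: dict[str, int] = field(default_factory=dict)
    n_survivors: int = 0

    def check_conservation(self) -> None:
        total = self.n_survivors + sum(self.excluded.values())
        if total != self.n_input:
            raise AssertionError(
                f"audit does not conserve counts: {self.n_input} input vs "
                f"{self.n_survivors} survivors + {sum(self.excluded.values())} excluded"
            )

    def flow_chart(self, title: str = "Case selection") -> str:
        """Human-readable flow-chart text block."""
        lines = [title, f"  reports identified: {self.n_input}"]
        for cat, n in self.excluded.items():
            if n:
                lines.append(f"  excluded - {cat.replace('_', ' ')}: {n}")
        lines.append(f"  unique and relevant cases remaining: {self.n_survivors}")
        return "\n".join(lines)


def classify_exposure_context(report: CaseReport, taxonomy: Taxonomy) -> str:
    """Exposure-context category of one report (``in_utero`` when includable)."""
    if not report.reactions:
        raise ValueError(f"report {report.case_id} has no reactions")
    return taxonomy.classify_context(report.pts())


def _age_bucket(report: CaseReport, criteria: SelectionCriteria) -> Optional[str]:
    age = report.age_years
    if age is None:
        return None if criteria.include_missing_age else "missing_age"
    lo, hi = criteria.age_range_years
    return None if lo <= age <= hi else "age_out_of_range"


def select_cases(
    reports: list[CaseReport],
    criteria: SelectionCriteria,
    *,
    overlap_threshold: float = 0.5,
    apply_dedup: bool = True,
) -> tuple[list[CaseReport], SelectionAudit]:
    """Apply inclusion filter, exclusion taxonomy and (optionally) dedup.

    Returns the surviving unique cases and the conserving audit.  The
    survivor set and audit are independent of the input order (duplicate
    clusters retain a deterministic representative).
    """
    taxonomy = criteria.taxonomy
    categories = taxonomy.exclusion_categories()
    excluded: dict[str, int] = {c: 0 for c in categories}
    excluded.update({c: 0 for c in STRUCTURAL_CATEGORIES})
    excluded["duplicate"] = 0

    kept: list[CaseReport] = []
    for r in reports:
        if not r.drugs or not r.names_substance(criteria.exposure_substances):
            excluded["no_exposure_match"] += 1
            continue
        bucket = _age_bucket(r, criteria)
        if bucket:
            excluded[bucket] += 1
            continue
        if not r.has_category(criteria.event_categories):
            excluded["no_event_term"] += 1
            continue
        context = classify_exposure_context(r, taxonomy)
        if context != IN_UTERO:
            excluded[context] = excluded.get(context, 0) + 1
            continue
        kept.append(r)

    if apply_dedup:
        kept = sorted(kept, key=lambda r: (r.case_id, r.version))  # order-invariance
        kept, _clusters, n_removed = _dedup(kept, overlap_threshold)
        excluded["duplicate"] = n_removed

    audit = SelectionAudit(
        n_input=len(reports),
        excluded={c: n for c, n in excluded.items()},
        n_survivors=len(kept),
    )
    audit.check_conservation()
    return kept, audit
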