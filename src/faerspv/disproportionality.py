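"""Reporting odds ratios with Woolf (log-normal) confidence intervals.

The disproportionality statistic is the reporting odds ratio

    ROR = (a/b) / (c/d)

on the 2x2 table of event vs non-event reports for an exposure drug against
a comparator (another drug, or a pooled group).  The 95% CI is the Woolf
log-normal interval exp(ln ROR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).  A CI
entirely above 1 is read as a higher-reporting signal, entirely below 1 as
lower reporting, otherwise not significant.

Following the source convention for this analysis, ``b`` and ``d`` are the
drug's total paediatric ADR count minus its validated event cases: the
numerator is de-duplicated while the denominator is the raw report total.
This mirrors the published arithmetic deliberately; it is a reporting-odds
convention, not an incidence estimate.
"""

from __future__ import annotations

import math
from typing import Literal, Optional

from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .model import CaseReport

Signal = Literal["higher_reporting", "lower_reporting", "not_significant"]


class DegenerateTableError(ValueError):
    """A zero cell makes the Woolf interval undefined; enable the
    Haldane-Anscombe correction (``correction="haldane"``) to proceed."""


class CohortSummary(BaseModel):
    """Per-drug paediatric totals feeding one arm of a 2x2 table."""

    substance: str
    n_total_adr_paediatric: int = Field(ge=0)
    n_event_validated: int = Field(ge=0)

    @model_validator(mode="after")
    def _nested(self) -> "CohortSummary":
        if self.n_event_validated > self.n_total_adr_paediatric:
            raise ValueError(
                f"{self.substance}: validated events ({self.n_event_validated}) exceed "
                f"paediatric total ({self.n_total_adr_paediatric})"
            )
        return self


class ContingencyTable(BaseModel):
    """The 2x2 cells: a/b exposure with/without event, c/d comparator."""

    a: float = Field(ge=0)
    b: float = Field(ge=0)
    c: float = Field(ge=0)
    d: float = Field(ge=0)
    exposure_label: str = "exposure"
    comparator_label: str = "comparator"
    event_label: str = "event"


class DisproportionalityResult(BaseModel):
    """ROR point estimate, Woolf CI and signal classification.

    ``ror``/``ci_low``/``ci_high`` carry full precision; the ``*_rounded``
    fields apply banker's rounding at the configured display precision.
    log(ror) is always the midpoint of [log(ci_low), log(ci_high)].
    """

    table: ContingencyTable
    ror: float = Field(gt=0)
    ci_low: float = Field(gt=0)
    ci_high: float = Field(gt=0)
    z: float
    signal: Signal
    rounding: int = 2

    @model_validator(mode="after")
    def _ci_sane(self) -> "DisproportionalityResult":
        if not (self.ci_low <= self.ror <= self.ci_high):
            raise ValueError("point estimate outside its own CI")
        mid = 0.5 * (math.log(self.ci_low) + math.log(self.ci_high))
        if abs(mid - math.log(self.ror)) > 1e-9:
            raise ValueError("CI not log-symmetric around the estimate")
        return self

    @property
    def ror_rounded(self) -> float:
        return round(self.ror, self.rounding)

    @property
    def ci_rounded(self) -> tuple[float, float]:
        return round(self.ci_low, self.rounding), round(self.ci_high, self.rounding)

    def __str__(self) -> str:
        lo, hi = self.ci_rounded
        return (
            f"{self.table.exposure_label} vs {self.table.comparator_label}: "
            f"ROR {self.ror_rounded:.{self.rounding}f} "
            f"(95% CI {lo:.{self.rounding}f}-{hi:.{self.rounding}f}; {self.signal})"
        )


def z_from_confidence(confidence: float = 0.95) -> float:
    """Two-sided normal quantile, e.g. 0.95 -> 1.959964."""
    return float(stats.norm.ppf(0.5 + confidence / 2.0))


def build_contingency(
    exposure: CohortSummary,
    comparator: CohortSummary,
    event_label: str = "eye disorders",
) -> ContingencyTable:
    """a = exposure events, b = exposure total - a; likewise c, d."""
    return ContingencyTable(
        a=exposure.n_event_validated,
        b=exposure.n_total_adr_paediatric - exposure.n_event_validated,
        c=comparator.n_event_validated,
        d=comparator.n_total_adr_paediatric - comparator.n_event_validated,
        exposure_label=exposure.substance,
        comparator_label=comparator.substance,
        event_label=event_label,
    )


def ror(
    table: ContingencyTable,
    z: float = 1.96,
    correction: Literal["none", "haldane"] = "none",
    rounding: int = 2,
) -> DisproportionalityResult:
    """Reporting odds ratio with Woolf CI on ``table``.

    With ``correction="haldane"`` 0.5 is added to every cell (use for zero
    cells); otherwise any zero cell raises :class:`DegenerateTableError`.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if correction == "haldane":
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    elif min(a, b, c, d) <= 0:
        raise DegenerateTableError(
            f"zero cell in table ({table.a}, {table.b}, {table.c}, {table.d}); "
            'rerun with correction="haldane" to add 0.5 to all cells'
        )
    estimate = (a / b) / (c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci_low = estimate * math.exp(-z * se)
    ci_high = estimate * math.exp(z * se)
    if ci_low > 1.0:
        signal: Signal = "higher_reporting"
    elif ci_high < 1.0:
        signal = "lower_reporting"
    else:
        signal = "not_significant"
    return DisproportionalityResult(
        table=table,
        ror=estimate,
        ci_low=ci_low,
        ci_high=ci_high,
        z=z,
        signal=signal,
        rounding=rounding,
    )


def relative_ror(
    drug_a: CohortSummary,
    drug_b: CohortSummary,
    z: float = 1.96,
    correction: Literal["none", "haldane"] = "none",
    rounding: int = 2,
    event_label: str = "eye disorders",
) -> DisproportionalityResult:
    """Head-to-head ROR between two drugs (swapping them inverts the estimate)."""
    return ror(
        build_contingency(drug_a, drug_b, event_label=event_label),
        z=z,
        correction=correction,
        rounding=rounding,
    )


def summarize_arm(
    reports: list[CaseReport],
    substance: str,
    event_categories: frozenset[str] = frozenset(
        {"eye_disorder_general", "eye_disorder_congenital"}
    ),
    age_range_years: tuple[float, float] = (0.0, 17.0),
) -> CohortSummary:
    """Tally one exposure arm of a cohort into a :class:`CohortSummary`.

    The denominator is every paediatric report naming the substance; the
    numerator is the subset carrying an event-category reaction.  Used for
    parameter-recovery studies on simulated cohorts, where duplication is
    controlled by the generator rather than re-detected.
    """
    group = frozenset({substance.lower()})
    lo, hi = age_range_years
    total = 0
    events = 0
    for r in reports:
        if not r.names_substance(group):
            continue
        age = r.age_years
        if age is None or not (lo <= age <= hi):
            continue
        total += 1
        if r.has_category(event_categories):
            events += 1
    return CohortSummary(
        substance=substance.lower(),
        n_total_adr_paediatric=total,
        n_event_validated=events,
    )


def pooled_comparator(
    summaries: list[CohortSummary],
    label: str = "all other psychotropic drugs",
    exclude_substances: Optional[frozenset[str]] = None,
) -> CohortSummary:
    """Component-wise sum over a comparator drug list.

    ``exclude_substances`` guards against exposure-drug leakage into the
    pooled group (raises if any listed substance appears).
    """
    if not summaries:
        raise ValueError("comparator list must be non-empty")
    if exclude_substances:
        banned = {s.lower() for s in exclude_substances}
        leaked = [s.substance for s in summaries if s.substance.lower() in banned]
        if leaked:
            raise ValueError(f"exposure substances present in comparator list: {leaked}")
    return CohortSummary(
        substance=label,
        n_total_adr_paediatric=sum(s.n_total_adr_paediatric for s in summaries),
        n_event_validated=sum(s.n_event_validated for s in summaries),
    )
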