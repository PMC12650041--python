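"""Core data model for individual case safety reports (ICSRs).

A report bundles the demographics, the drug list (with reporter-assigned
roles), the reaction Preferred Terms and the regulatory outcomes of one
spontaneous adverse-event report, in the shape of a FAERS public-dashboard
line listing.  Fields that FAERS leaves blank are genuinely missing
(``None``), never zero-filled.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, Field, field_validator, model_validator

from .substances import normalize_substance

AgeUnit = Literal["day", "week", "month", "year"]
Sex = Literal["F", "M", "unspecified"]
DrugRole = Literal["suspect", "concomitant"]

#: Days/weeks/months per year used when converting reported ages to years.
AGE_UNIT_YEARS: dict[str, float] = {
    "day": 1.0 / 365.25,
    "week": 1.0 / 52.18,
    "month": 1.0 / 12.0,
    "year": 1.0,
}

#: Regulatory outcome codes, FAERS dashboard vocabulary.
OUTCOME_CODES = frozenset(
    {"died", "life-threatening", "hospitalised", "disabled", "congenital anomaly", "other"}
)

#: Reaction categories assigned by the taxonomy (see :mod:`faerspv.taxonomy`).
REACTION_CATEGORIES = (
    "eye_disorder_general",
    "eye_disorder_congenital",
    "exposure_context",
    "withdrawal_neonatal",
    "other",
)


class DrugEntry(BaseModel):
    """One drug row of a report.

    ``canonical_substances`` is derived deterministically from the verbatim
    name: lower-cased, salt suffixes stripped, combination products split into
    their constituents (so ``"Buprenorphine/Naloxone"`` yields
    ``("buprenorphine", "naloxone")`` and counts as buprenorphine exposure
    under set-intersection membership).
    """

    verbatim_name: str = Field(min_length=1)
    canonical_substances: tuple[str, ...] = ()
    role: DrugRole = "suspect"

    @model_validator(mode="after")
    def _derive_canonical(self) -> "DrugEntry":
        derived = normalize_substance(self.verbatim_name)
        if not self.canonical_substances:
            object.__setattr__(self, "canonical_substances", derived)
        elif tuple(self.canonical_substances) != derived:
            raise ValueError(
                f"canonical_substances {self.canonical_substances!r} does not match "
                f"normalize_substance({self.verbatim_name!r}) = {derived!r}"
            )
        return self

    def names_substance(self, group: frozenset[str] | set[str]) -> bool:
        """True if any constituent belongs to ``group`` (exposure membership)."""
        return bool(set(self.canonical_substances) & set(group))


class ReactionTerm(BaseModel, frozen=True):
    """A reaction coded as a Preferred-Term-like string.

    ``category`` is a pure function of ``pt`` given a taxonomy; unknown terms
    carry ``other``.
    """

    pt: str = Field(min_length=1)
    category: Literal[REACTION_CATEGORIES] = "other"  # type: ignore[valid-type]


class CaseReport(BaseModel):
    """One individual case safety report."""

    case_id: str = Field(min_length=1)
    version: int = Field(default=0, ge=0)
    age_value: Optional[float] = Field(default=None, ge=0)
    age_unit: Optional[AgeUnit] = None
    sex: Sex = "unspecified"
    reporter: Optional[str] = None
    report_year: Optional[int] = None
    country: Optional[str] = None
    drugs: tuple[DrugEntry, ...] = ()
    reactions: frozenset[ReactionTerm] = frozenset()
    outcomes: frozenset[str] = frozenset()

    @field_validator("outcomes")
    @classmethod
    def _known_outcomes(cls, v: frozenset[str]) -> frozenset[str]:
        unknown = v - OUTCOME_CODES
        if unknown:
            raise ValueError(f"unknown outcome codes: {sorted(unknown)}")
        return v

    @model_validator(mode="after")
    def _age_unit_required(self) -> "CaseReport":
        if self.age_value is not None and self.age_unit is None:
            raise ValueError("age_value present but age_unit missing")
        return self

    @property
    def age_years(self) -> Optional[float]:
        """Age converted to years, or None when not reported."""
        if self.age_value is None:
            return None
        return self.age_value * AGE_UNIT_YEARS[self.age_unit]

    def substances(self) -> frozenset[str]:
        """Union of canonical constituents over all drug rows."""
        out: set[str] = set()
        for d in self.drugs:
            out.update(d.canonical_substances)
        return frozenset(out)

    def names_substance(self, group: frozenset[str] | set[str]) -> bool:
        return bool(self.substances() & set(group))

    def pts(self) -> frozenset[str]:
        """Lower-cased reaction PT strings (the dedup comparison key)."""
        return frozenset(r.pt.strip().lower() for r in self.reactions)

    def has_category(self, categories: set[str] | frozenset[str]) -> bool:
        return any(r.category in categories for r in self.reactions)
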