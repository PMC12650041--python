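"""Synthetic FAERS-like cohort generation with known ground truth.

Two generators are provided:

* :func:`generate_cohort` — per-drug blocks with a report count, a target
  event probability, an exposure-context mix and a duplication rate.
  Duplicates are emitted half as same-case-ID revisions and half as
  distinct-ID clinical near-copies, so both deduplication pathways (ID match
  and clinical overlap) are exercised.  Fractional duplicate quotas are
  resolved by the largest-remainder method so report counts are conserved
  exactly.
* :func:`generate_two_drug_study` — two exposure arms whose event
  probabilities are chosen so the true reporting odds ratio equals a given
  theta; the ground truth is returned alongside the cohort, supporting
  parameter-recovery studies of the downstream ROR estimator.

Deterministic fixture cohorts (``methadone_fig1``, ``buprenorphine_fig2``)
reproduce the published flow-chart category mixes exactly: 190 methadone
reports partitioned 9 abuse/dependence, 37 accidental exposure, 13
toxicity/poisoning/overdose, 1 indication-only, 113 duplicates, 17 valid
in-utero cases; 79 buprenorphine reports partitioned 1 toxicity, 22
accidental poisoning, 1 overdose, 1 suicide, 2 substance use disorder, 1
anaesthesia-related, 36 duplicates, 15 valid in-utero cases.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .model import CaseReport, DrugEntry, ReactionTerm
from .substances import normalize_substance
from .taxonomy import Taxonomy

CONTEXT_CATEGORIES = (
    "in_utero",
    "accidental",
    "abuse_dependence",
    "toxicity_overdose",
    "suicide",
    "substance_use_disorder",
    "anaesthesia",
    "indication_only",
)

#: One representative context PT per generator category (default-taxonomy terms).
_CONTEXT_PTS = {
    "in_utero": (
        "Foetal exposure during pregnancy",
        "Maternal exposure during pregnancy",
        "Drug withdrawal syndrome neonatal",
    ),
    "accidental": ("Accidental exposure to product", "Accidental poisoning"),
    "abuse_dependence": ("Drug abuse", "Drug dependence"),
    "toxicity_overdose": ("Toxicity to various agents", "Overdose", "Poisoning"),
    "suicide": ("Suicide attempt",),
    "substance_use_disorder": ("Substance use disorder",),
    "anaesthesia": ("Anaesthetic complication",),
    "indication_only": ("Pain",),
}

_EYE_PTS_GENERAL = (
    "Strabismus",
    "Nystagmus",
    "Visual impairment",
    "Amblyopia",
    "Miosis",
    "Visual acuity reduced",
    "Refraction disorder",
    "Eye movement disorder",
)
_EYE_PTS_CONGENITAL = (
    "Optic nerve hypoplasia",
    "Microphthalmia",
    "Cataract congenital",
    "Coloboma",
)
# Detail-PT pools for the distance-2 code below; "Somnolence" is reserved as
# the near-copy marker and must never appear here.
_DETAIL_POOLS = (
    (
        "Irritability", "Feeding disorder neonatal", "Respiratory distress",
        "Hypotonia", "Low birth weight baby", "Premature baby", "Vomiting",
        "Diarrhoea", "Rash", "Pyrexia", "Insomnia", "Crying",
    ),
    (
        "Agitation neonatal", "Hypertonia", "Tachycardia", "Bradycardia",
        "Apnoea", "Cyanosis", "Seizure", "Jitteriness", "Poor weight gain",
        "Dehydration", "Jaundice neonatal", "Sneezing",
    ),
    (
        "Small for dates baby", "Developmental delay", "Failure to thrive",
        "Hyperreflexia", "Excoriation", "Yawning", "Nasal congestion",
        "Mottling", "Hypoglycaemia", "Feeding intolerance", "Restlessness",
        "High-pitched crying",
    ),
)


def _detail_pool(j: int, q: int) -> list[str]:
    base = _DETAIL_POOLS[j]
    pool = list(base[:q])
    k = 0
    while len(pool) < q:
        pool.append(f"{base[k % len(base)]} (variant {k // len(base) + 2})")
        k += 1
    return pool


def _detail_code(i: int, pools: tuple[list[str], ...], q: int) -> tuple[str, str, str]:
    """Detail PTs for base report ``i``: a length-3 parity codeword over three
    pools.  Distinct codewords agree in at most one position, so two distinct
    base reports share at most one detail PT — together with at most one
    shared context PT their reaction Jaccard stays below the 0.5 overlap
    threshold, and "duplicate" remains an exact generator-controlled label."""
    c1, c2 = i % q, (i // q) % q
    c3 = (c1 + c2) % q
    return pools[0][c1], pools[1][c2], pools[2][c3]

FIXTURES = ("methadone_fig1", "buprenorphine_fig2")


class ConfigError(ValueError):
    """Invalid cohort configuration."""


class DrugBlock(BaseModel):
    """Simulation parameters for one exposure drug."""

    substance: str
    n_reports: int = Field(ge=0)
    p_event: float = Field(default=0.05, ge=0.0, le=1.0)
    context_mix: dict[str, float] = Field(default_factory=lambda: {"in_utero": 1.0})

    @model_validator(mode="after")
    def _check_mix(self) -> "DrugBlock":
        unknown = set(self.context_mix) - set(CONTEXT_CATEGORIES)
        if unknown:
            raise ConfigError(f"unknown context categories: {sorted(unknown)}")
        if any(not (0.0 <= p <= 1.0) for p in self.context_mix.values()):
            raise ConfigError("context_mix proportions must lie in [0, 1]")
        if abs(sum(self.context_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("context_mix must sum to 1")
        return self


class CohortConfig(BaseModel):
    """Full cohort recipe; identical config + seed gives identical output."""

    drugs: list[DrugBlock] = Field(default_factory=list)
    duplication_rate: float = Field(default=0.0, ge=0.0)
    seed: int = 0
    fixture: Optional[str] = None

    @model_validator(mode="after")
    def _check_fixture(self) -> "CohortConfig":
        if self.fixture is not None and self.fixture not in FIXTURES:
            raise ConfigError(f"unknown fixture {self.fixture!r}; available: {FIXTURES}")
        return self


def largest_remainder(quotas: list[float], total: int) -> list[int]:
    """Integer apportionment of ``total`` proportional to ``quotas``.

    Floors each quota, then hands remaining units to the largest fractional
    remainders (ties by position).  Sum of the result is exactly ``total``.
    """
    floors = [math.floor(q) for q in quotas]
    short = total - sum(floors)
    remainders = sorted(
        range(len(quotas)), key=lambda i: (-(quotas[i] - floors[i]), i)
    )
    for i in remainders[:short]:
        floors[i] += 1
    return floors


# ---------------------------------------------------------------------------
# random cohorts

def _draw_age(rng: np.random.Generator, context: str) -> tuple[float, str]:
    # in-utero reports skew to infancy (most cases present in the first year)
    if context == "in_utero" and rng.random() < 0.6:
        return float(np.round(rng.uniform(1, 12), 1)), "month"
    return float(np.round(rng.uniform(0, 17), 2)), "year"


def _make_report(
    rng: np.random.Generator,
    case_id: str,
    substance: str,
    context: str,
    has_event: bool,
    detail_pts: tuple[str, ...],
    taxonomy: Taxonomy,
) -> CaseReport:
    age_value, age_unit = _draw_age(rng, context)
    pts: set[str] = {_CONTEXT_PTS[context][int(rng.integers(len(_CONTEXT_PTS[context])))]}
    if has_event:
        if rng.random() < 0.1:
            pts.add(_EYE_PTS_CONGENITAL[int(rng.integers(len(_EYE_PTS_CONGENITAL)))])
        else:
            pts.add(_EYE_PTS_GENERAL[int(rng.integers(len(_EYE_PTS_GENERAL)))])
    pts.update(detail_pts)
    outcomes = {"other"}
    if rng.random() < 0.3:
        outcomes.add("hospitalised")
    return CaseReport(
        case_id=case_id,
        version=0,
        age_value=age_value,
        age_unit=age_unit,
        sex=("F", "M", "unspecified")[int(rng.integers(3))],
        reporter=("consumer", "physician", "other health professional")[int(rng.integers(3))],
        report_year=int(rng.integers(2005, 2026)),
        country="US",
        drugs=(DrugEntry(verbatim_name=substance),),
        reactions=frozenset(
            ReactionTerm(pt=p, category=taxonomy.categorize(p)) for p in pts
        ),
        outcomes=frozenset(outcomes),
    )


def _near_copy(
    rng: np.random.Generator, base: CaseReport, idx: int, taxonomy: Taxonomy
) -> CaseReport:
    """A duplicate of ``base``: same-ID revision (even idx) or distinct-ID
    clinical near-copy (odd idx) whose reaction set stays Jaccard-similar."""
    if idx % 2 == 0:
        return base.model_copy(update={"version": base.version + 1 + idx // 2})
    extra = ReactionTerm(pt="Somnolence", category=taxonomy.categorize("Somnolence"))
    return base.model_copy(
        update={
            "case_id": f"{base.case_id}-D{idx}",
            "version": 0,
            "reactions": base.reactions | {extra},
            "reporter": "consumer",
        }
    )


def generate_cohort(config: CohortConfig, taxonomy: Optional[Taxonomy] = None) -> list[CaseReport]:
    """Generate a cohort per ``config`` (or a named deterministic fixture).

    Emitted count is sum over blocks of ``n_reports`` base reports plus
    ``round_LR(n_reports * duplication_rate)`` duplicates, where ``round_LR``
    is the largest-remainder apportionment of the total duplicate quota
    across blocks.
    """
    taxonomy = taxonomy or Taxonomy.default()
    if config.fixture == "methadone_fig1":
        return methadone_fig1_fixture(taxonomy)
    if config.fixture == "buprenorphine_fig2":
        return buprenorphine_fig2_fixture(taxonomy)

    rng = np.random.default_rng(config.seed)
    reports: list[CaseReport] = []
    block_reports: list[list[CaseReport]] = []
    for bi, block in enumerate(config.drugs):
        cats = sorted(block.context_mix)
        probs = np.array([block.context_mix[c] for c in cats])
        tag = "".join(w[0] for w in block.substance.upper().split())[:3] or "X"
        q = max(3, math.isqrt(max(block.n_reports - 1, 0)) + 1)
        pools = tuple(_detail_pool(j, q) for j in range(3))
        mine: list[CaseReport] = []
        for i in range(block.n_reports):
            context = cats[int(rng.choice(len(cats), p=probs))]
            mine.append(
                _make_report(
                    rng,
                    case_id=f"{tag}{bi}-{config.seed}-{i:06d}",
                    substance=block.substance,
                    context=context,
                    has_event=bool(rng.random() < block.p_event),
                    detail_pts=_detail_code(i, pools, q),
                    taxonomy=taxonomy,
                )
            )
        block_reports.append(mine)
        reports.extend(mine)

    dup_quotas = [b.n_reports * config.duplication_rate for b in config.drugs]
    n_dup_total = int(round(sum(dup_quotas)))
    for block_mine, n_dup in zip(block_reports, largest_remainder(dup_quotas, n_dup_total)):
        if not block_mine:
            continue
        for j in range(n_dup):
            base = block_mine[int(rng.integers(len(block_mine)))]
            reports.append(_near_copy(rng, base, j, taxonomy))
    return reports


# ---------------------------------------------------------------------------
# two-arm parameter-recovery studies

class TwoDrugStudyConfig(BaseModel):
    """Two exposure arms with a known true reporting odds ratio.

    The comparator arm reports the target event with probability
    ``p_event_comparator``; the exposure arm's probability is derived so the
    true odds ratio equals ``theta``.
    """

    exposure_substance: str = "drug A"
    comparator_substance: str = "drug B"
    n_exposure: int = Field(ge=1)
    n_comparator: int = Field(ge=1)
    theta: float = Field(gt=0.0)
    p_event_comparator: float = Field(default=0.05, gt=0.0, lt=1.0)
    seed: int = 0

    @property
    def p_event_exposure(self) -> float:
        odds = self.theta * self.p_event_comparator / (1.0 - self.p_event_comparator)
        p = odds / (1.0 + odds)
        if not (0.0 < p < 1.0 - 1e-9):
            raise ConfigError(
                f"infeasible theta={self.theta}: implied exposure p_event={p} is "
                "degenerate (essentially every exposure report would carry the event)"
            )
        return p


class TwoDrugStudy(BaseModel):
    """A generated two-arm cohort plus its ground truth."""

    model_config = {"arbitrary_types_allowed": True}

    reports: list[CaseReport]
    true_theta: float
    p_event_exposure: float
    p_event_comparator: float
    n_exposure: int
    n_comparator: int


def generate_two_drug_study(config: TwoDrugStudyConfig) -> TwoDrugStudy:
    """Generate both arms; every report is a paediatric in-utero exposure.

    Uses a lean construction path (validation is done once on the config);
    ages are uniform over 0–17 years and each report carries one in-utero
    context PT plus, with the arm's event probability, one eye-disorder PT.
    """
    p_exp = config.p_event_exposure  # raises on infeasible theta
    rng = np.random.default_rng(config.seed)
    reports: list[CaseReport] = []
    for arm, substance, n, p in (
        ("A", config.exposure_substance, config.n_exposure, p_exp),
        ("B", config.comparator_substance, config.n_comparator, config.p_event_comparator),
    ):
        canon = normalize_substance(substance)
        drug = DrugEntry.model_construct(
            verbatim_name=substance, canonical_substances=canon, role="suspect"
        )
        events = rng.random(n) < p
        ages = rng.uniform(0, 17, size=n)
        ctx_idx = rng.integers(0, len(_CONTEXT_PTS["in_utero"]), size=n)
        eye_idx = rng.integers(0, len(_EYE_PTS_GENERAL), size=n)
        sexes = rng.integers(0, 3, size=n)
        for i in range(n):
            pts = [
                ReactionTerm.model_construct(
                    pt=_CONTEXT_PTS["in_utero"][ctx_idx[i]], category="exposure_context"
                )
            ]
            if events[i]:
                pts.append(
                    ReactionTerm.model_construct(
                        pt=_EYE_PTS_GENERAL[eye_idx[i]], category="eye_disorder_general"
                    )
                )
            reports.append(
                CaseReport.model_construct(
                    case_id=f"{arm}-{config.seed}-{i:06d}",
                    version=0,
                    age_value=float(ages[i]),
                    age_unit="year",
                    sex=("F", "M", "unspecified")[sexes[i]],
                    reporter=None,
                    report_year=2020,
                    country="US",
                    drugs=(drug,),
                    reactions=frozenset(pts),
                    outcomes=frozenset(),
                )
            )
    return TwoDrugStudy(
        reports=reports,
        true_theta=config.theta,
        p_event_exposure=p_exp,
        p_event_comparator=config.p_event_comparator,
        n_exposure=config.n_exposure,
        n_comparator=config.n_comparator,
    )


# ---------------------------------------------------------------------------
# deterministic paper-shaped fixtures

def _fixture_report(
    taxonomy: Taxonomy,
    case_id: str,
    drug: str,
    pts: tuple[str, ...],
    age: tuple[float, str],
    sex: str,
    version: int = 0,
    year: int = 2015,
    outcomes: tuple[str, ...] = ("other",),
) -> CaseReport:
    return CaseReport(
        case_id=case_id,
        version=version,
        age_value=age[0],
        age_unit=age[1],
        sex=sex,
        reporter="physician",
        report_year=year,
        country="US",
        drugs=(DrugEntry(verbatim_name=drug),),
        reactions=frozenset(
            ReactionTerm(pt=p, category=taxonomy.categorize(p)) for p in pts
        ),
        outcomes=frozenset(outcomes),
    )


def _valid_cases(
    taxonomy: Taxonomy,
    prefix: str,
    drugs: list[str],
    sexes: list[str],
    ages: list[tuple[float, str]],
) -> list[CaseReport]:
    """Distinct in-utero base cases.

    Each case carries exactly one in-utero context PT and one eye PT, chosen
    so any two cases share at most one term (pairwise reaction Jaccard <= 1/3,
    below the default clinical-overlap threshold) — bases never merge with
    each other during deduplication.
    """
    utero = _CONTEXT_PTS["in_utero"]
    out = []
    for i, (sex, age) in enumerate(zip(sexes, ages)):
        pts = (utero[i % len(utero)], _EYE_PTS_GENERAL[i % len(_EYE_PTS_GENERAL)])
        out.append(
            _fixture_report(
                taxonomy,
                case_id=f"{prefix}-V{i:03d}",
                drug=drugs[i % len(drugs)],
                pts=pts,
                age=age,
                sex=sex,
                year=2010 + i % 10,
            )
        )
    return out


def _duplicates(
    taxonomy: Taxonomy, bases: list[CaseReport], n: int
) -> list[CaseReport]:
    """n duplicates spread cyclically over bases: even ones same-case-ID
    revisions, odd ones distinct-ID near-copies (extra Somnolence PT)."""
    extra = ReactionTerm(pt="Somnolence", category=taxonomy.categorize("Somnolence"))
    revision_count: dict[str, int] = {}
    out = []
    for j in range(n):
        base = bases[j % len(bases)]
        if j % 2 == 0:
            k = revision_count.get(base.case_id, 0) + 1
            revision_count[base.case_id] = k
            out.append(base.model_copy(update={"version": k}))
        else:
            out.append(
                base.model_copy(
                    update={
                        "case_id": f"{base.case_id}-D{j:03d}",
                        "reactions": base.reactions | {extra},
                        "reporter": "consumer",
                    }
                )
            )
    return out


def _excluded_cases(
    taxonomy: Taxonomy, prefix: str, drug: str, spec: list[tuple[str, int]]
) -> list[CaseReport]:
    """Context-excluded reports: paediatric, eye PT present, plus the
    category's context PT (so only the exposure-context rule removes them)."""
    out = []
    i = 0
    for context_pt, count in spec:
        for _ in range(count):
            out.append(
                _fixture_report(
                    taxonomy,
                    case_id=f"{prefix}-X{i:03d}",
                    drug=drug,
                    pts=(context_pt, _EYE_PTS_GENERAL[i % len(_EYE_PTS_GENERAL)]),
                    age=(float(1 + i % 16), "year"),
                    sex=("F", "M", "unspecified")[i % 3],
                )
            )
            i += 1
    return out


def methadone_fig1_fixture(taxonomy: Optional[Taxonomy] = None) -> list[CaseReport]:
    """190 methadone reports: 9 abuse/dependence, 37 accidental, 13
    toxicity/overdose, 1 indication-only, 113 duplicates, 17 valid cases."""
    taxonomy = taxonomy or Taxonomy.default()
    sexes = ["F"] * 6 + ["M"] * 4 + ["unspecified"] * 7
    ages: list[tuple[float, str]] = (
        [(float(2 + m), "month") for m in range(9)]          # 1–12 months
        + [(15.0, "month"), (20.0, "month")]                 # 13–24 months
        + [(3.0, "year"), (4.0, "year")]                     # 2–5 years
        + [(6.0, "year"), (8.0, "year"), (10.0, "year"), (12.0, "year")]
    )
    valid = _valid_cases(
        taxonomy, "MET", ["Methadone", "METHADONE HYDROCHLORIDE"], sexes, ages
    )
    assert len(valid) == 17
    excluded = _excluded_cases(
        taxonomy,
        "MET",
        "Methadone",
        [
            ("Drug abuse", 5),
            ("Drug dependence", 4),
            ("Accidental exposure to product", 37),
            ("Toxicity to various agents", 7),
            ("Overdose", 6),
            ("Pain", 1),
        ],
    )
    dups = _duplicates(taxonomy, valid, 113)
    cohort = excluded + valid + dups
    assert len(cohort) == 190
    return cohort


def buprenorphine_fig2_fixture(taxonomy: Optional[Taxonomy] = None) -> list[CaseReport]:
    """79 buprenorphine reports: 1 toxicity, 22 accidental poisoning, 1
    overdose, 1 suicide, 2 substance use disorder, 1 anaesthesia-related,
    36 duplicates, 15 valid cases."""
    taxonomy = taxonomy or Taxonomy.default()
    sexes = ["M"] * 7 + ["F"] * 2 + ["unspecified"] * 6
    ages: list[tuple[float, str]] = (
        [(float(1 + m), "month") for m in range(11)]         # 0–12 months
        + [(15.0, "month")]                                  # 13–24 months
        + [(3.0, "year")]                                    # 2–5 years
        + [(5.0, "year"), (7.0, "year")]
    )
    valid = _valid_cases(
        taxonomy, "BUP", ["Buprenorphine", "Buprenorphine/Naloxone"], sexes, ages
    )
    assert len(valid) == 15
    excluded = _excluded_cases(
        taxonomy,
        "BUP",
        "Buprenorphine",
        [
            ("Toxicity to various agents", 1),
            ("Accidental poisoning", 22),
            ("Overdose", 1),
            ("Suicide attempt", 1),
            ("Substance use disorder", 2),
            ("Anaesthetic complication", 1),
        ],
    )
    dups = _duplicates(taxonomy, valid, 36)
    cohort = excluded + valid + dups
    assert len(cohort) == 79
    return cohort
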