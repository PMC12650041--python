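"""End-to-end study runner: simulate/load -> select -> dedup -> ROR -> rank.

A :class:`StudyConfig` names the exposure arms (each a fixture or cohort
recipe plus its paediatric ADR denominator), the comparator (the built-in
psychotropic reference list or explicit summaries), and thresholds.
:func:`run_study` executes every stage and returns a :class:`RunManifest`
holding the config snapshot, the per-arm flow-chart audits, all contingency
tables and disproportionality results, and the medication rankings.
Re-running with the same config and seed reproduces the manifest
byte-for-byte (``RunManifest.to_json`` is sorted and stable).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field

from . import __version__
from .disproportionality import (
    CohortSummary,
    DisproportionalityResult,
    pooled_comparator,
    relative_ror,
)
from .model import CaseReport
from .ranking import rank_top_medications
from .reference import comparator_summaries, exposure_summary
from .selection import SelectionAudit, SelectionCriteria, select_cases
from .synthetic import CohortConfig, generate_cohort
from .taxonomy import Taxonomy


class ArmConfig(BaseModel):
    """One exposure arm: its cohort source and its ADR denominator."""

    name: str
    substances: list[str]
    cohort: CohortConfig
    n_total_adr_paediatric: int = Field(ge=0)


class StudyConfig(BaseModel):
    """Reproducible study recipe."""

    arms: list[ArmConfig]
    comparator: str | list[CohortSummary] = "reference_psychotropics"
    taxonomy_path: Optional[str] = None
    age_range_years: tuple[float, float] = (0.0, 17.0)
    overlap_threshold: float = Field(default=0.5, ge=0.0, le=1.0)
    z: float = 1.96
    rounding: int = 2
    seed: int = 0
    top_n: int = 20


class ArmResult(BaseModel):
    name: str
    n_input: int
    audit_excluded: dict[str, int]
    n_survivors: int
    summary: CohortSummary
    flow_chart: str


class RunManifest(BaseModel):
    """Machine-readable record of one full study run."""

    tool_version: str
    config: StudyConfig
    arms: list[ArmResult]
    comparator_summary: CohortSummary
    results: dict[str, DisproportionalityResult]
    rankings: dict[str, list[dict]]

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.model_dump(mode="json"), indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls.model_validate(json.loads(text))

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json(), encoding="utf-8")
        return path


def default_study_config(seed: int = 0) -> StudyConfig:
    """The published-study configuration: both flow-chart fixtures against
    the 13-drug psychotropic reference comparator."""
    return StudyConfig(
        arms=[
            ArmConfig(
                name="methadone",
                substances=["methadone"],
                cohort=CohortConfig(fixture="methadone_fig1", seed=seed),
                n_total_adr_paediatric=exposure_summary("methadone").n_total_adr_paediatric,
            ),
            ArmConfig(
                name="buprenorphine",
                substances=["buprenorphine"],
                cohort=CohortConfig(fixture="buprenorphine_fig2", seed=seed),
                n_total_adr_paediatric=exposure_summary("buprenorphine").n_total_adr_paediatric,
            ),
        ],
        seed=seed,
    )


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _run_arm(
    arm: ArmConfig, config: StudyConfig, taxonomy: Taxonomy
) -> tuple[ArmResult, list[CaseReport]]:
    cohort = generate_cohort(arm.cohort, taxonomy=taxonomy)
    criteria = SelectionCriteria(
        exposure_substances=frozenset(arm.substances),
        age_range_years=config.age_range_years,
        taxonomy=taxonomy,
    )
    survivors, audit = select_cases(
        cohort, criteria, overlap_threshold=config.overlap_threshold
    )
    if arm.n_total_adr_paediatric < len(survivors):
        raise StageError(
            "contingency",
            f"arm {arm.name}: denominator {arm.n_total_adr_paediatric} smaller "
            f"than {len(survivors)} validated cases",
        )
    summary = CohortSummary(
        substance=arm.name,
        n_total_adr_paediatric=arm.n_total_adr_paediatric,
        n_event_validated=len(survivors),
    )
    result = ArmResult(
        name=arm.name,
        n_input=audit.n_input,
        audit_excluded=audit.excluded,
        n_survivors=audit.n_survivors,
        summary=summary,
        flow_chart=audit.flow_chart(f"Case selection: {arm.name}"),
    )
    return result, survivors


def run_study(config: StudyConfig) -> RunManifest:
    """Execute all stages; deterministic under fixed config + seed."""
    taxonomy = (
        Taxonomy.from_yaml(config.taxonomy_path)
        if config.taxonomy_path
        else Taxonomy.default()
    )

    arm_results: list[ArmResult] = []
    survivor_pool: list[CaseReport] = []
    for arm in config.arms:
        result, survivors = _run_arm(arm, config, taxonomy)
        arm_results.append(result)
        survivor_pool.extend(survivors)

    if config.comparator == "reference_psychotropics":
        comparator = pooled_comparator(
            comparator_summaries(),
            exclude_substances=frozenset(
                s for arm in config.arms for s in arm.substances
            ),
        )
    else:
        comparator = pooled_comparator(list(config.comparator))

    results: dict[str, DisproportionalityResult] = {}
    if len(arm_results) >= 2:
        first, second = arm_results[0], arm_results[1]
        results[f"{first.name}_vs_{second.name}"] = relative_ror(
            first.summary, second.summary, z=config.z, rounding=config.rounding
        )
    for arm in arm_results:
        results[f"{arm.name}_vs_pooled"] = relative_ror(
            arm.summary, comparator, z=config.z, rounding=config.rounding
        )

    rankings = {
        cls: rank_top_medications(survivor_pool, event_class=cls, n=config.top_n).to_dict(
            orient="records"
        )
        for cls in ("general", "congenital")
    }

    return RunManifest(
        tool_version=__version__,
        config=config,
        arms=arm_results,
        comparator_summary=comparator,
        results=results,
        rankings=rankings,
    )
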