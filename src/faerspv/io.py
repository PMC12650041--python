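"""Reading and writing FAERS-dialect line listings.

Two dialects are supported:

* ``jsonl`` — one JSON object per report (the package's native schema;
  lossless round-trip including missing-value markers).
* ``faers_tables`` — four delimited tables sharing a case-ID key column,
  mirroring quarterly-extract style line listings: ``demographics``,
  ``drugs``, ``reactions``, ``outcomes``.  Delimiter is configurable
  (default tab; ``$`` accepted, as in the real quarterly files).

Loading keeps the highest ``version`` per case ID (regulatory latest-version
practice); superseded revisions are counted, not silently dropped.  Drug or
reaction rows whose case ID has no demographic row are collected into a
rejects list.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional

import pandas as pd

from .model import CaseReport, DrugEntry, ReactionTerm
from .taxonomy import Taxonomy

log = logging.getLogger(__name__)

Dialect = Literal["jsonl", "faers_tables"]

TABLE_COLUMNS = {
    "demographics": [
        "case_id",
        "version",
        "age_value",
        "age_unit",
        "sex",
        "reporter",
        "report_year",
        "country",
    ],
    "drugs": ["case_id", "drug_name", "role"],
    "reactions": ["case_id", "pt"],
    "outcomes": ["case_id", "outcome_code"],
}


class FormatError(ValueError):
    """A table is missing a mandatory column or is otherwise malformed."""


@dataclass
class LoadAudit:
    """Accounting for one load: parsed, superseded and rejected rows."""

    n_reports: int = 0
    n_version_superseded: int = 0
    rejects: list[dict] = field(default_factory=list)


def load_reports(
    path: str | Path,
    dialect: Dialect = "jsonl",
    *,
    delimiter: str = "\t",
    taxonomy: Optional[Taxonomy] = None,
    audit: Optional[LoadAudit] = None,
) -> list[CaseReport]:
    """Load case reports from ``path``.

    For ``faers_tables`` the path is a directory containing the four tables
    as ``<name>.tsv``.  Pass a :class:`LoadAudit` to collect reject rows and
    supersession counts; otherwise they are logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    audit = audit if audit is not None else LoadAudit()
    taxonomy = taxonomy or Taxonomy.default()
    if dialect == "jsonl":
        reports = _load_jsonl(path)
    elif dialect == "faers_tables":
        reports = _load_tables(path, delimiter, taxonomy, audit)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    reports = _keep_latest_versions(reports, audit)
    audit.n_reports = len(reports)
    if audit.rejects:
        log.warning("load_reports: %d dangling rows rejected", len(audit.rejects))
    return reports


def write_reports(
    reports: Iterable[CaseReport],
    path: str | Path,
    dialect: Dialect = "jsonl",
    *,
    delimiter: str = "\t",
) -> Path:
    """Serialize reports; ``load_reports`` on the result is the identity."""
    path = Path(path)
    reports = list(reports)
    if dialect == "jsonl":
        _write_jsonl(reports, path)
    elif dialect == "faers_tables":
        _write_tables(reports, path, delimiter)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    return path


# ---------------------------------------------------------------------------
# jsonl dialect

def report_to_dict(report: CaseReport) -> dict:
    """JSON-serializable dict with deterministic ordering of collections."""
    d = report.model_dump(mode="json")
    d["reactions"] = sorted(
        (dict(r) for r in d["reactions"]), key=lambda r: (r["pt"], r["category"])
    )
    d["outcomes"] = sorted(d["outcomes"])
    return d


def report_from_dict(d: dict) -> CaseReport:
    return CaseReport.model_validate(d)


def _load_jsonl(path: Path) -> list[CaseReport]:
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(report_from_dict(json.loads(line)))
    return out


def _write_jsonl(reports: list[CaseReport], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in reports:
            fh.write(json.dumps(report_to_dict(r), sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# faers_tables dialect

def _read_table(directory: Path, name: str, delimiter: str) -> pd.DataFrame:
    fp = directory / f"{name}.tsv"
    if not fp.exists():
        raise FormatError(f"missing table file: {fp}")
    df = pd.read_csv(fp, sep=delimiter, dtype=str, keep_default_na=False)
    for col in TABLE_COLUMNS[name]:
        if col not in df.columns:
            raise FormatError(f"table {name!r} is missing mandatory column {col!r}")
    return df


def _opt(v: str) -> Optional[str]:
    return v if v != "" else None


def _load_tables(
    directory: Path, delimiter: str, taxonomy: Taxonomy, audit: LoadAudit
) -> list[CaseReport]:
    if not directory.is_dir():
        raise FormatError(f"faers_tables dialect expects a directory, got {directory}")
    demo = _read_table(directory, "demographics", delimiter)
    drugs = _read_table(directory, "drugs", delimiter)
    reactions = _read_table(directory, "reactions", delimiter)
    outcomes = _read_table(directory, "outcomes", delimiter)

    known_ids = set(demo["case_id"])
    drug_rows: dict[str, list] = {}
    for row in drugs.itertuples(index=False):
        if row.case_id not in known_ids:
            audit.rejects.append({"table": "drugs", **row._asdict()})
            continue
        drug_rows.setdefault(row.case_id, []).append(
            DrugEntry(verbatim_name=row.drug_name, role=row.role or "suspect")
        )
    reaction_rows: dict[str, set] = {}
    for row in reactions.itertuples(index=False):
        if row.case_id not in known_ids:
            audit.rejects.append({"table": "reactions", **row._asdict()})
            continue
        reaction_rows.setdefault(row.case_id, set()).add(
            ReactionTerm(pt=row.pt, category=taxonomy.categorize(row.pt))
        )
    outcome_rows: dict[str, set] = {}
    for row in outcomes.itertuples(index=False):
        if row.case_id not in known_ids:
            audit.rejects.append({"table": "outcomes", **row._asdict()})
            continue
        outcome_rows.setdefault(row.case_id, set()).add(row.outcome_code)

    out = []
    for row in demo.itertuples(index=False):
        age_value = _opt(row.age_value)
        out.append(
            CaseReport(
                case_id=row.case_id,
                version=int(row.version or 0),
                age_value=float(age_value) if age_value is not None else None,
                age_unit=_opt(row.age_unit),
                sex=row.sex or "unspecified",
                reporter=_opt(row.reporter),
                report_year=int(row.report_year) if _opt(row.report_year) else None,
                country=_opt(row.country),
                drugs=tuple(drug_rows.get(row.case_id, [])),
                reactions=frozenset(reaction_rows.get(row.case_id, set())),
                outcomes=frozenset(outcome_rows.get(row.case_id, set())),
            )
        )
    return out


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float) and v == int(v):
        return str(int(v))
    return str(v)


def _write_tables(reports: list[CaseReport], directory: Path, delimiter: str) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    demo, drugs, reactions, outcomes = [], [], [], []
    for r in reports:
        demo.append(
            {
                "case_id": r.case_id,
                "version": r.version,
                "age_value": _fmt(r.age_value),
                "age_unit": _fmt(r.age_unit),
                "sex": r.sex,
                "reporter": _fmt(r.reporter),
                "report_year": _fmt(r.report_year),
                "country": _fmt(r.country),
            }
        )
        for d in r.drugs:
            drugs.append({"case_id": r.case_id, "drug_name": d.verbatim_name, "role": d.role})
        for t in sorted(r.reactions, key=lambda t: t.pt):
            reactions.append({"case_id": r.case_id, "pt": t.pt})
        for o in sorted(r.outcomes):
            outcomes.append({"case_id": r.case_id, "outcome_code": o})
    for name, rows in (
        ("demographics", demo),
        ("drugs", drugs),
        ("reactions", reactions),
        ("outcomes", outcomes),
    ):
        pd.DataFrame(rows, columns=TABLE_COLUMNS[name]).to_csv(
            directory / f"{name}.tsv", sep=delimiter, index=False
        )


def _keep_latest_versions(reports: list[CaseReport], audit: LoadAudit) -> list[CaseReport]:
    latest: dict[str, CaseReport] = {}
    order: list[str] = []
    superseded = 0
    for r in reports:
        prev = latest.get(r.case_id)
        if prev is None:
            latest[r.case_id] = r
            order.append(r.case_id)
        elif r.version > prev.version:
            latest[r.case_id] = r
            superseded += 1
        else:
            superseded += 1
    audit.n_version_superseded = superseded
    return [latest[cid] for cid in order]
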