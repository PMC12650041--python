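"""Preferred-Term taxonomy: reaction categories and exposure-context rules.

The package works at the PT-label level (no MedDRA hierarchy traversal).  Two
structures are carried:

* ``reaction_categories`` — ordered mapping category -> PT strings, used to
  tag each :class:`~faerspv.model.ReactionTerm` (first listing wins; unknown
  terms are ``other``).
* ``exposure_context`` — an in-utero evidence set plus an ordered list of
  exclusion categories, each a PT pattern list.  Matching is exact-string and
  case-insensitive; no fuzzy matching, so classification is reproducible.

The default taxonomy ships as an editable YAML file
(``faerspv/data/default_taxonomy.yaml``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

IN_UTERO = "in_utero"
UNCLASSIFIED = "unclassified_context"


@dataclass(frozen=True)
class ExclusionRule:
    category: str
    patterns: frozenset[str]
    rescued_by_in_utero: bool = False


@dataclass
class Taxonomy:
    """PT classification rules; all patterns stored lower-cased."""

    reaction_categories: dict[str, frozenset[str]] = field(default_factory=dict)
    category_order: tuple[str, ...] = ()
    in_utero_patterns: frozenset[str] = frozenset()
    exclusions: tuple[ExclusionRule, ...] = ()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_dict(cls, raw: dict) -> "Taxonomy":
        cats = {
            name: frozenset(p.strip().lower() for p in pts)
            for name, pts in (raw.get("reaction_categories") or {}).items()
        }
        ctx = raw.get("exposure_context") or {}
        rules = tuple(
            ExclusionRule(
                category=r["category"],
                patterns=frozenset(p.strip().lower() for p in r.get("patterns", [])),
                rescued_by_in_utero=bool(r.get("rescued_by_in_utero", False)),
            )
            for r in ctx.get("exclusions", [])
        )
        return cls(
            reaction_categories=cats,
            category_order=tuple(cats),
            in_utero_patterns=frozenset(p.strip().lower() for p in ctx.get("in_utero", [])),
            exclusions=rules,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Taxonomy":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "Taxonomy":
        ref = resources.files("faerspv").joinpath("data/default_taxonomy.yaml")
        return cls.from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))

    # -- classification ---------------------------------------------------

    def categorize(self, pt: str) -> str:
        """Reaction category of a PT; ``other`` when unlisted."""
        key = pt.strip().lower()
        for name in self.category_order:
            if key in self.reaction_categories[name]:
                return name
        return "other"

    def exclusion_categories(self) -> tuple[str, ...]:
        return tuple(r.category for r in self.exclusions)

    def classify_context(self, pts: frozenset[str]) -> str:
        """Exposure context of a report's (lower-cased) PT set.

        Exclusion rules are evaluated in declared order; the first match wins
        unless the rule is rescued by in-utero evidence and such evidence is
        present.  Reports with in-utero evidence and no applicable exclusion
        are ``in_utero``; reports matching nothing are ``unclassified_context``
        (excluded by the default selection policy).
        """
        has_utero = bool(pts & self.in_utero_patterns)
        for rule in self.exclusions:
            if pts & rule.patterns:
                if rule.rescued_by_in_utero and has_utero:
                    continue
                return rule.category
        return IN_UTERO if has_utero else UNCLASSIFIED
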