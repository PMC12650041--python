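"""Deterministic drug-name normalization.

FAERS drug names arrive as free text: brand capitalisation, salt forms
("METHADONE HYDROCHLORIDE", "valproate sodium") and combination products
("Buprenorphine/Naloxone").  Normalization lower-cases, strips a configurable
salt-suffix list, resolves a small alias map (e.g. valproate -> valproic
acid), and splits combinations into their constituent substances.  Exposure
membership is then a set-intersection test, so a buprenorphine/naloxone
report counts as buprenorphine exposure.
"""

from __future__ import annotations

import re

#: Trailing tokens removed (repeatedly) from each constituent name.
SALT_SUFFIXES: frozenset[str] = frozenset(
    {
        "hydrochloride",
        "dihydrochloride",
        "hcl",
        "sodium",
        "disodium",
        "potassium",
        "calcium",
        "sulfate",
        "sulphate",
        "tartrate",
        "bitartrate",
        "maleate",
        "mesylate",
        "besylate",
        "fumarate",
        "hemifumarate",
        "succinate",
        "citrate",
        "phosphate",
        "acetate",
        "lactate",
        "salt",
    }
)

#: Synonyms collapsed to one canonical substance after salt stripping.
ALIASES: dict[str, str] = {
    "valproate": "valproic acid",
    "valproate semisodium": "valproic acid",
    "divalproex": "valproic acid",
    "levomethadone": "methadone",
    "buprenorfine": "buprenorphine",
}

_SPLIT_RE = re.compile(r"\s*[/+;]\s*|\s+\bwith\b\s+")


def _normalize_one(name: str) -> str:
    tokens = name.strip().strip(".").lower().split()
    while len(tokens) > 1 and tokens[-1] in SALT_SUFFIXES:
        tokens.pop()
    out = " ".join(tokens)
    return ALIASES.get(out, out)


def normalize_substance(verbatim_name: str) -> tuple[str, ...]:
    """Map a verbatim drug name to its canonical constituent substances.

    Returns a sorted tuple; single-ingredient products yield a 1-tuple.
    Unknown names pass through lower-cased and salt-stripped.  Idempotent:
    re-normalizing the joined canonical label returns the same tuple.
    """
    if not verbatim_name or not verbatim_name.strip():
        raise ValueError("empty drug name")
    parts = [p for p in _SPLIT_RE.split(verbatim_name) if p.strip()]
    constituents = {_normalize_one(p) for p in parts}
    constituents.discard("")
    return tuple(sorted(constituents))


def canonical_label(verbatim_name: str) -> str:
    """Single-string form of the canonical constituents, "/"-joined."""
    return "/".join(normalize_substance(verbatim_name))
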