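"""Duplicate-report detection and removal.

Spontaneous-reporting databases carry the same clinical case several times:
resubmitted revisions sharing a case ID, and independent submissions (e.g.
consumer + physician) with distinct IDs but overlapping clinical content.
Two reports are considered duplicates when either

* their case IDs are equal, or
* they agree on sex, have identical canonical drug multisets, their ages lie
  within +/-1 of the coarser report's age unit, and their reaction-PT sets
  have Jaccard similarity >= ``overlap_threshold``.

Clusters are the transitive closure (single linkage) of this pairwise
relation; one representative per cluster is retained (highest version, then
earliest report year, then lexicographically smallest case ID).

Candidate pairs for the clinical rule are generated within blocks keyed by
(sex, canonical drug multiset), which keeps the comparison count far below
n^2 on heterogeneous cohorts without changing the result.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import AGE_UNIT_YEARS, CaseReport


@dataclass(frozen=True)
class DuplicateCluster:
    """Indices (into the input list) of one group of mutual duplicates."""

    members: tuple[int, ...]
    match_basis: str  # "case_id" | "clinical_overlap"
    retained: int

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a duplicate cluster needs at least 2 members")
        if self.retained not in self.members:
            raise ValueError("retained member must belong to the cluster")


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def ages_compatible(r1: CaseReport, r2: CaseReport) -> bool:
    """Ages within +/-1 of the coarser report's unit; both-missing matches,
    one-missing does not."""
    if r1.age_value is None and r2.age_value is None:
        return True
    if r1.age_value is None or r2.age_value is None:
        return False
    coarse = max(AGE_UNIT_YEARS[r1.age_unit], AGE_UNIT_YEARS[r2.age_unit])
    return abs(r1.age_years - r2.age_years) <= coarse * (1.0 + 1e-9)


def clinically_overlapping(r1: CaseReport, r2: CaseReport, threshold: float) -> bool:
    return (
        r1.sex == r2.sex
        and sorted(d.canonical_substances for d in r1.drugs)
        == sorted(d.canonical_substances for d in r2.drugs)
        and ages_compatible(r1, r2)
        and jaccard(r1.pts(), r2.pts()) >= threshold
    )


def find_duplicates(
    reports: list[CaseReport], overlap_threshold: float = 0.5
) -> list[DuplicateCluster]:
    """Cluster duplicate reports; see module docstring for the rule."""
    if not 0.0 <= overlap_threshold <= 1.0:
        raise ValueError(f"overlap_threshold must lie in [0, 1], got {overlap_threshold}")
    n = len(reports)
    uf = _UnionFind(n)
    id_matched: set[int] = set()

    by_case_id: dict[str, int] = {}
    for i, r in enumerate(reports):
        j = by_case_id.setdefault(r.case_id, i)
        if j != i:
            uf.union(j, i)
            id_matched.update((j, i))

    blocks: dict[tuple, list[int]] = {}
    for i, r in enumerate(reports):
        key = (r.sex, tuple(sorted(d.canonical_substances for d in r.drugs)))
        blocks.setdefault(key, []).append(i)
    for members in blocks.values():
        for x in range(len(members)):
            i = members[x]
            for y in range(x + 1, len(members)):
                j = members[y]
                if ages_compatible(reports[i], reports[j]) and jaccard(
                    reports[i].pts(), reports[j].pts()
                ) >= overlap_threshold:
                    uf.union(i, j)

    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(uf.find(i), []).append(i)

    clusters = []
    for members in components.values():
        if len(members) < 2:
            continue
        members = tuple(sorted(members))
        basis = "case_id" if any(m in id_matched for m in members) else "clinical_overlap"
        retained = min(
            members,
            key=lambda m: (
                -reports[m].version,
                reports[m].report_year if reports[m].report_year is not None else 10**6,
                reports[m].case_id,
            ),
        )
        clusters.append(DuplicateCluster(members=members, match_basis=basis, retained=retained))
    clusters.sort(key=lambda c: c.members[0])
    return clusters


def remove_duplicates(
    reports: list[CaseReport], clusters: list[DuplicateCluster]
) -> tuple[list[CaseReport], int]:
    """Drop all non-retained cluster members; returns (unique, n_removed).

    Idempotent: running find/remove again on the output changes nothing.
    """
    n = len(reports)
    drop: set[int] = set()
    for c in clusters:
        if any(m >= n or m < 0 for m in c.members):
            raise ValueError(f"cluster references unknown report index: {c.members}")
        drop.update(m for m in c.members if m != c.retained)
    unique = [r for i, r in enumerate(reports) if i not in drop]
    return unique, len(drop)


def dedup(
    reports: list[CaseReport], overlap_threshold: float = 0.5
) -> tuple[list[CaseReport], list[DuplicateCluster], int]:
    """Convenience: find then remove; returns (unique, clusters, n_removed)."""
    clusters = find_duplicates(reports, overlap_threshold)
    unique, n_removed = remove_duplicates(reports, clusters)
    return unique, clusters, n_removed
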