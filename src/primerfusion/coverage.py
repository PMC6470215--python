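"""Coverage, overlap and abundance accounting across primer sets.

All set arithmetic is done on *canonical* taxon keys: an affiliated or
candidate taxon keeps its lineage label; every unassigned label at a rank is
pooled into the single ``Unassigned`` bucket, so the bucket is counted once per
primer set and once in any union or intersection.  Percentages are computed in
exact rational arithmetic and rounded to one decimal, ties away from zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from ._util import percentage
from .merge import MergedProfile
from .taxonomy import (
    DEFAULT_RULES,
    AffiliationStatus,
    CandidateRules,
    TaxonProfile,
    UNASSIGNED_LABEL,
    classify_affiliation,
)


@dataclass(frozen=True)
class StatusCounts:
    n_affiliated: int
    n_candidate: int
    n_unassigned: int

    @property
    def n_unaffiliated(self) -> int:
        return self.n_candidate + self.n_unassigned

    @property
    def total(self) -> int:
        return self.n_affiliated + self.n_candidate + self.n_unassigned


@dataclass
class CoverageSummary:
    """Per-primer and combined taxon counts partitioned by affiliation status."""

    rank: str
    per_primer: dict[str, StatusCounts]
    combined: StatusCounts
    shared_all_primers: tuple[int, int]  # (n_unaffiliated, n_affiliated)
    per_primer_unique: dict[str, int]
    unaffiliated_fraction: float

    def as_dict(self) -> dict:
        return {
            "rank": self.rank,
            "per_primer": {
                ps: {
                    "affiliated": sc.n_affiliated,
                    "candidate": sc.n_candidate,
                    "unassigned": sc.n_unassigned,
                    "unaffiliated": sc.n_unaffiliated,
                    "total": sc.total,
                }
                for ps, sc in self.per_primer.items()
            },
            "combined": {
                "affiliated": self.combined.n_affiliated,
                "candidate": self.combined.n_candidate,
                "unassigned": self.combined.n_unassigned,
                "unaffiliated": self.combined.n_unaffiliated,
                "total": self.combined.total,
            },
            "shared_all_primers": {
                "unaffiliated": self.shared_all_primers[0],
                "affiliated": self.shared_all_primers[1],
            },
            "per_primer_unique": dict(self.per_primer_unique),
            "unaffiliated_fraction_pct": self.unaffiliated_fraction,
        }


def canonical_taxa(
    labels: Iterable[str], rank: str, rules: CandidateRules = DEFAULT_RULES
) -> dict[str, AffiliationStatus]:
    """Map labels to canonical keys with statuses; unassigned pools to one key."""
    out: dict[str, AffiliationStatus] = {}
    for lab in labels:
        status = classify_affiliation(lab, rank, rules)
        key = UNASSIGNED_LABEL if status is AffiliationStatus.UNASSIGNED else lab
        out[key] = status
    return out


def _status_counts(keyed: Mapping[str, AffiliationStatus]) -> StatusCounts:
    n_a = sum(1 for s in keyed.values() if s is AffiliationStatus.AFFILIATED)
    n_c = sum(1 for s in keyed.values() if s is AffiliationStatus.CANDIDATE)
    n_u = sum(1 for s in keyed.values() if s is AffiliationStatus.UNASSIGNED)
    return StatusCounts(n_a, n_c, n_u)


def tally_by_status(
    profiles: Mapping[str, TaxonProfile],
    rank: str,
    candidate_rules: CandidateRules = DEFAULT_RULES,
) -> CoverageSummary:
    """Count affiliated/candidate/unassigned taxa per primer set and combined.

    ``profiles`` maps primer set -> profile at ``rank`` for the same sample (or
    pooled group).  The Unassigned bucket contributes at most one taxon per
    primer set and one to the union.
    """
    if not profiles:
        raise ValueError("no profiles given")
    per_primer_keyed = {
        ps: canonical_taxa(p.taxa, rank, candidate_rules)
        for ps, p in profiles.items()
    }
    per_primer = {ps: _status_counts(k) for ps, k in per_primer_keyed.items()}
    union: dict[str, AffiliationStatus] = {}
    for keyed in per_primer_keyed.values():
        union.update(keyed)
    combined = _status_counts(union)
    key_sets = {ps: set(k) for ps, k in per_primer_keyed.items()}
    shared = set.intersection(*key_sets.values())
    shared_statuses = {k: union[k] for k in shared}
    sc = _status_counts(shared_statuses)
    uniques = unique_taxa(key_sets) if len(key_sets) >= 2 else {
        ps: len(k) for ps, k in key_sets.items()
    }
    frac = unaffiliated_fraction(combined.n_unaffiliated, combined.n_affiliated)
    return CoverageSummary(
        rank=rank,
        per_primer=per_primer,
        combined=combined,
        shared_all_primers=(sc.n_unaffiliated, sc.n_affiliated),
        per_primer_unique=uniques,
        unaffiliated_fraction=frac,
    )


def unique_taxa(sets: Mapping[str, set[str]]) -> dict[str, int]:
    """Per primer set, the number of taxa found in that set and no other."""
    if len(sets) < 2:
        raise ValueError("unique-taxon accounting needs at least two sets")
    out = {}
    for ps, s in sets.items():
        others = set().union(*(o for q, o in sets.items() if q != ps))
        out[ps] = len(s - others)
    return out


def shared_fraction(sets: Mapping[str, set[str]]) -> tuple[int, int, float]:
    """(intersection size, union size, |∩|/|∪| as a one-decimal percentage)."""
    if len(sets) < 2:
        raise ValueError("shared-fraction needs at least two sets")
    values = list(sets.values())
    inter = set.intersection(*values)
    union = set.union(*values)
    pct = percentage(len(inter), len(union)) if union else 0.0
    return len(inter), len(union), pct


@dataclass
class VennPartition:
    """Disjoint membership cells over 2-5 primer sets."""

    primer_sets: tuple[str, ...]
    cells: dict[frozenset[str], int]

    @property
    def union_size(self) -> int:
        return sum(self.cells.values())

    def set_size(self, primer_set: str) -> int:
        return sum(n for cell, n in self.cells.items() if primer_set in cell)


def venn_partition(sets: Mapping[str, set[str]]) -> VennPartition:
    """Partition the union into the 2^k - 1 exclusive membership cells."""
    k = len(sets)
    if not 2 <= k <= 5:
        raise ValueError("venn partition supports 2-5 sets")
    names = tuple(sets)
    cells: dict[frozenset[str], int] = {
        frozenset(c): 0
        for r in range(1, k + 1)
        for c in itertools.combinations(names, r)
    }
    union = set().union(*sets.values())
    for t in union:
        members = frozenset(ps for ps, s in sets.items() if t in s)
        cells[members] += 1
    return VennPartition(primer_sets=names, cells=cells)


def unaffiliated_fraction(n_unaffiliated: int, n_affiliated: int) -> float:
    """100 * U / (U + A), one decimal."""
    if n_unaffiliated + n_affiliated <= 0:
        raise ValueError("no taxa to compute unaffiliated fraction over")
    return percentage(n_unaffiliated, n_unaffiliated + n_affiliated)


def missed_fraction(combined_total: int, single_total: int) -> float:
    """Percent of taxa a single primer set misses relative to its own tally."""
    if not combined_total >= single_total > 0:
        raise ValueError("need combined_total >= single_total > 0")
    return percentage(combined_total - single_total, single_total)


def increase_vs_best_single(
    combined_count: int, per_primer_counts: Sequence[int]
) -> float:
    """Percent gain of the combined tally over the best single primer set."""
    if not per_primer_counts:
        raise ValueError("no per-primer counts")
    best = max(per_primer_counts)
    if best <= 0:
        raise ValueError("best single-primer count must be positive")
    return percentage(combined_count - best, best)


def abundance_by_status(
    merged: MergedProfile, candidate_rules: CandidateRules = DEFAULT_RULES
) -> dict[AffiliationStatus, dict[str, float]]:
    """Total and mean relative abundance (%) per affiliation status.

    Abundances are computed over the representative reads of the merged
    profile; per-status totals sum to 100% and mean = total / taxon count.
    The Unassigned bucket is pooled before averaging.
    """
    total_reads = sum(merged.representative.values())
    if total_reads <= 0:
        raise ValueError("merged profile has no reads")
    pooled: dict[str, tuple[AffiliationStatus, int]] = {}
    for t, reads in merged.representative.items():
        status = classify_affiliation(t, merged.rank, candidate_rules)
        key = UNASSIGNED_LABEL if status is AffiliationStatus.UNASSIGNED else t
        prev = pooled.get(key)
        pooled[key] = (status, (prev[1] if prev else 0) + reads)
    out: dict[AffiliationStatus, dict[str, float]] = {}
    for status in AffiliationStatus:
        members = {k: r for k, (s, r) in pooled.items() if s is status}
        n = len(members)
        total_pct = Fraction(100) * Fraction(sum(members.values()), total_reads)
        out[status] = {
            "n_taxa": n,
            "total_pct": float(total_pct),
            "mean_pct": float(total_pct / n) if n else 0.0,
        }
    return out


def cross_group_shared(groups: Mapping[str, set[str]]) -> int:
    """Size of the taxon intersection across groups (e.g. host species)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    return len(set.intersection(*groups.values()))
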