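"""Combine per-primer taxon profiles for one sample under the representative-throughput rule.

Different hypervariable regions cannot share sequence-level OTUs, so profiles
are merged on the rank-collapsed taxonomy label.  A taxon detected by a single
primer set contributes its read count directly; a taxon shared by several
primer sets is represented by the highest read count any of them achieved.
Summing representatives therefore realises both the unique-addition and the
shared-maximum rule at once, and gives the combined sequencing throughput the
multi-primer design can deliver.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from ._util import percentage
from .taxonomy import TaxonProfile


@dataclass
class MergedProfile:
    """Union of per-primer profiles for one sample at one rank.

    ``representative[t]`` is the maximum read count over the primer sets that
    detected ``t``; ``provenance[t]`` is the argmax set (ties kept whole);
    ``member_primers[t]`` every primer set that detected ``t``.
    """

    sample_id: str
    rank: str
    per_primer: dict[str, dict[str, int]]
    representative: dict[str, int]
    provenance: dict[str, frozenset[str]]
    member_primers: dict[str, frozenset[str]]

    @property
    def taxa(self) -> set[str]:
        return set(self.representative)

    def unique_to(self, primer_set: str) -> set[str]:
        """Taxa detected by exactly one primer set, that one."""
        return {
            t for t, members in self.member_primers.items()
            if members == frozenset({primer_set})
        }


def merge_profiles(
    profiles: Sequence[TaxonProfile], min_reads: int = 1
) -> MergedProfile:
    """Merge >= 1 same-sample, same-rank integer-count profiles.

    ``min_reads`` is the detection floor applied before merging (default 1:
    any positive count counts as detection, no abundance filtering).

    Raises
    ------
    ValueError
        On mixed samples/ranks, duplicate primer sets, or fractional profiles.
    """
    if not profiles:
        raise ValueError("need at least one profile to merge")
    samples = {p.sample_id for p in profiles}
    ranks = {p.rank for p in profiles}
    if len(samples) != 1:
        raise ValueError(f"profiles span multiple samples: {sorted(samples)}")
    if len(ranks) != 1:
        raise ValueError(f"profiles span multiple ranks: {sorted(ranks)}")
    per_primer: dict[str, dict[str, int]] = {}
    for p in profiles:
        if p.is_fractional:
            raise ValueError(
                f"profile {p.primer_set}/{p.sample_id} is fractional; "
                "throughput merging needs integer read counts"
            )
        if p.primer_set in per_primer:
            raise ValueError(f"duplicate primer set {p.primer_set!r}")
        per_primer[p.primer_set] = {
            t: c for t, c in p.counts.items() if c >= min_reads
        }

    representative: dict[str, int] = {}
    provenance: dict[str, frozenset[str]] = {}
    member_primers: dict[str, frozenset[str]] = {}
    union: set[str] = set()
    for counts in per_primer.values():
        union |= set(counts)
    for t in union:
        detecting = {ps: counts[t] for ps, counts in per_primer.items() if t in counts}
        best = max(detecting.values())
        representative[t] = best
        provenance[t] = frozenset(ps for ps, c in detecting.items() if c == best)
        member_primers[t] = frozenset(detecting)
    return MergedProfile(
        sample_id=profiles[0].sample_id,
        rank=profiles[0].rank,
        per_primer=per_primer,
        representative=representative,
        provenance=provenance,
        member_primers=member_primers,
    )


def combined_throughput(merged: MergedProfile) -> int:
    """Total representative reads over the union taxon set."""
    if not merged.representative:
        raise ValueError("merged profile is empty")
    return sum(merged.representative.values())


def throughput_increase(combined: int, baseline: int) -> float:
    """Percent increase of the combined throughput over a single-primer baseline.

    One decimal, ties away from zero — the convention of the reported tables.
    """
    if baseline <= 0:
        raise ValueError("baseline throughput must be positive")
    return percentage(combined - baseline, baseline)


def per_primer_totals(merged: MergedProfile) -> dict[str, int]:
    """Read totals of each contributing primer set (after the detection floor)."""
    return {ps: sum(c.values()) for ps, c in merged.per_primer.items()}
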