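"""Greengenes-style lineage parsing, affiliation status, and taxa-table I/O.

A lineage string like ``k__Bacteria;p__Proteobacteria`` carries one segment per
taxonomic rank, each tagged with a single-letter prefix.  Closed-reference OTU
picking against a Greengenes-style database emits taxa summaries keyed by such
strings; everything downstream (merging, coverage accounting, mock evaluation)
consumes the :class:`TaxonProfile` objects produced here.

Affiliation status partitions taxa three ways:

* AFFILIATED — a validly named taxon at the rank considered;
* CANDIDATE — a provisional candidate division (TM7, OD1, WS3, ...);
* UNASSIGNED — no name at that rank, or no database match at all.

"Unaffiliated" means CANDIDATE or UNASSIGNED.  All unassigned sequences are
conventionally counted as a single bucket per rank.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

RANKS: tuple[str, ...] = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

_PREFIX_TO_RANK = {
    "k": "kingdom",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}
_RANK_TO_PREFIX = {v: k for k, v in _PREFIX_TO_RANK.items()}

EMPTY = ""

#: Label under which every unassigned taxon is pooled at a given rank.
UNASSIGNED_LABEL = "Unassigned"

PRIMER_SETS: tuple[str, ...] = ("V1V3", "V4", "V4V5", "V5V8", "V6V9")


class LineageParseError(ValueError):
    """Raised for a lineage segment that cannot be interpreted."""


class AffiliationStatus(enum.Enum):
    AFFILIATED = "affiliated"
    CANDIDATE = "candidate"
    UNASSIGNED = "unassigned"

    @property
    def unaffiliated(self) -> bool:
        return self is not AffiliationStatus.AFFILIATED


@dataclass(frozen=True)
class Lineage:
    """A parsed rank-qualified taxonomy path.

    ``ranks`` maps every canonical rank name to a taxon name or ``EMPTY``;
    ``n_segments`` records how many segments the raw string carried so that
    formatting round-trips; ``unassigned`` marks the literal ``Unassigned``
    token produced when a read matches nothing in the reference database.
    """

    ranks: Mapping[str, str]
    raw: str
    n_segments: int
    unassigned: bool = False

    def name_at(self, rank: str) -> str:
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return self.ranks[rank]

    def format(self) -> str:
        """Re-serialize; reproduces ``raw`` for well-formed prefixed input."""
        if self.unassigned:
            return UNASSIGNED_LABEL
        parts = [
            f"{_RANK_TO_PREFIX[r]}__{self.ranks[r]}"
            for r in RANKS[: self.n_segments]
        ]
        return ";".join(parts)


def parse_lineage(raw: str) -> Lineage:
    """Parse a Greengenes-dialect lineage string.

    Segments are semicolon-delimited, optionally with single-letter rank
    prefixes (``k__``, ``p__``, ...).  A blank segment (``p__`` or empty) leaves
    that rank EMPTY.  The literal token ``Unassigned`` yields a lineage with
    every rank EMPTY and the unassigned flag set.

    Raises
    ------
    LineageParseError
        If a segment carries an unknown rank prefix or ranks arrive out of
        order.
    """
    text = raw.strip()
    if not text:
        raise LineageParseError("empty lineage string")
    ranks = {r: EMPTY for r in RANKS}
    if text == UNASSIGNED_LABEL:
        return Lineage(ranks=ranks, raw=raw, n_segments=0, unassigned=True)

    segments = [s.strip() for s in text.split(";")]
    if len(segments) > len(RANKS):
        raise LineageParseError(
            f"lineage has {len(segments)} segments; at most {len(RANKS)} ranks supported: {raw!r}"
        )
    for i, seg in enumerate(segments):
        expected_rank = RANKS[i]
        if "__" in seg:
            prefix, _, name = seg.partition("__")
            rank = _PREFIX_TO_RANK.get(prefix)
            if rank is None:
                raise LineageParseError(
                    f"segment {seg!r} in {raw!r}: unknown rank prefix {prefix!r}"
                )
            if rank != expected_rank:
                raise LineageParseError(
                    f"segment {seg!r} in {raw!r}: rank {rank!r} out of order "
                    f"(expected {expected_rank!r} at position {i})"
                )
        else:
            name = seg
        ranks[expected_rank] = name
    return Lineage(ranks=ranks, raw=raw, n_segments=len(segments))


# Candidate divisions appearing in Greengenes phylum-level lineages. Seeds the
# default rules; user-extensible because no authoritative complete list exists.
DEFAULT_CANDIDATE_NAMES: frozenset[str] = frozenset(
    {
        "BRC1",
        "GN02",
        "OD1",
        "OP3",
        "OP11",
        "SR1",
        "TM6",
        "TM7",
        "WS3",
        "WWE1",
        "SAR406",
        "NKB19",
        "ZB3",
        "GN04",
        "WS2",
        "OP8",
        "PAUC34f",
        "SBR1093",
        "WPS-2",
        "AncK6",
        "FBP",
        "Kazan-3B-28",
        "LD1",
        "MVP-21",
        "NC10",
        "OctSpA1-106",
        "WS4",
        "WS6",
        "GOUTA4",
        "Hyd24-12",
        "LCP-89",
        "SC4",
        "TPD-58",
        "Caldithrix",
    }
)

# Fallback: an all-capitals/digit code of >= 2 characters (candidate divisions
# have no naming grammar; codes like "TM7", "OP11", "ZZ9" follow this shape,
# validly published names never do).
_CANDIDATE_CODE = re.compile(r"[A-Z][A-Z0-9]+")


@dataclass(frozen=True)
class CandidateRules:
    """Configurable recognition of candidate (provisional) taxon names."""

    names: frozenset[str] = DEFAULT_CANDIDATE_NAMES
    pattern_enabled: bool = True

    def is_candidate(self, name: str) -> bool:
        if name in self.names:
            return True
        return bool(self.pattern_enabled and _CANDIDATE_CODE.fullmatch(name))

    @classmethod
    def from_config(cls, cfg: Mapping) -> "CandidateRules":
        """Build from a ``candidate_rules:`` config block (``names``, ``pattern_enabled``)."""
        names = frozenset(cfg.get("names", DEFAULT_CANDIDATE_NAMES))
        return cls(names=names, pattern_enabled=bool(cfg.get("pattern_enabled", True)))


DEFAULT_RULES = CandidateRules()


def classify_affiliation(
    lineage: Lineage | str,
    rank: str,
    candidate_rules: CandidateRules = DEFAULT_RULES,
) -> AffiliationStatus:
    """Classify one taxon at ``rank`` as affiliated, candidate, or unassigned."""
    if isinstance(lineage, str):
        lineage = parse_lineage(lineage)
    name = lineage.name_at(rank)  # raises KeyError for unknown rank
    if lineage.unassigned or name == EMPTY:
        return AffiliationStatus.UNASSIGNED
    if candidate_rules.is_candidate(name):
        return AffiliationStatus.CANDIDATE
    return AffiliationStatus.AFFILIATED


@dataclass
class TaxonProfile:
    """One primer-set x sample x rank abundance table.

    ``counts`` holds integer read counts per taxon label (a lineage string
    collapsed at ``rank``); ``relative`` optionally holds fractions.  Profiles
    read from fractional tables carry ``relative`` only and are refused by
    read-count arithmetic (merging, throughput).
    """

    sample_id: str
    primer_set: str
    rank: str
    counts: dict[str, int] = field(default_factory=dict)
    relative: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")
        for label, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for {label!r}: {c}")
        if self.relative is not None and self.relative:
            total = sum(self.relative.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"relative abundances sum to {total}, not 1")

    @property
    def is_fractional(self) -> bool:
        return not self.counts and self.relative is not None

    @property
    def taxa(self) -> set[str]:
        return set(self.counts) if self.counts else set(self.relative or {})

    @property
    def total_reads(self) -> int:
        if self.is_fractional:
            raise ValueError("fractional profile has no read total")
        return sum(self.counts.values())

    def as_relative(self) -> dict[str, float]:
        """Relative abundances, from counts when present."""
        if self.counts:
            total = self.total_reads
            if total == 0:
                raise ValueError("profile has zero reads")
            return {t: c / total for t, c in self.counts.items()}
        if self.relative is None:
            raise ValueError("empty profile")
        return dict(self.relative)


def exclude_and_renormalize(
    profile: TaxonProfile, predicate: Callable[[Lineage], bool]
) -> TaxonProfile:
    """Drop taxa whose lineage satisfies ``predicate`` and recompute fractions.

    Used e.g. to remove eukaryote-derived taxa picked up by a primer set before
    relative abundances are reported.  Count ratios among retained taxa are
    untouched; ``relative`` is recomputed to sum to 1 over what remains.
    """
    drop = {t for t in profile.taxa if predicate(parse_lineage(t))}
    keep = profile.taxa - drop
    if not keep:
        raise ValueError("predicate excluded every taxon in the profile")
    if profile.counts:
        counts = {t: c for t, c in profile.counts.items() if t in keep}
        total = sum(counts.values())
        rel = {t: c / total for t, c in counts.items()} if total else None
        return replace(profile, counts=counts, relative=rel)
    rel = {t: v for t, v in (profile.relative or {}).items() if t in keep}
    total = sum(rel.values())
    if total == 0:
        raise ValueError("retained taxa carry zero abundance")
    rel = {t: v / total for t, v in rel.items()}
    return replace(profile, counts={}, relative=rel)


def read_taxa_table(path, primer_set: str, rank: str) -> list[TaxonProfile]:
    """Read a tab-separated taxa summary into one :class:`TaxonProfile` per sample.

    Layout: header row; first column the lineage string; one column of counts
    or fractions per sample.  Tables whose values are non-integral are treated
    as fractional (stored in ``relative``; no counts).
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    lineage_col = df.columns[0]
    lineages = df[lineage_col].astype(str)
    dup = lineages[lineages.duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate lineage row(s): {sorted(set(dup))}")
    for raw in lineages:
        parse_lineage(raw)  # validates; raises naming the segment
    values = df.set_index(lineage_col)
    if (values.values < 0).any():
        raise ValueError("negative abundance values in table")
    fractional = not (values.values == values.values.round()).all()
    profiles = []
    for sample in values.columns:
        col = values[sample]
        if fractional:
            rel = {t: float(v) for t, v in col.items() if v > 0}
            total = sum(rel.values())
            if total > 0:  # tolerate tables normalised over more taxa than kept
                rel = {t: v / total for t, v in rel.items()}
            profiles.append(
                TaxonProfile(sample_id=str(sample), primer_set=primer_set,
                             rank=rank, counts={}, relative=rel)
            )
        else:
            counts = {t: int(v) for t, v in col.items() if v > 0}
            profiles.append(
                TaxonProfile(sample_id=str(sample), primer_set=primer_set,
                             rank=rank, counts=counts)
            )
    return profiles


def write_taxa_table(profiles: Sequence[TaxonProfile], path) -> None:
    """Write profiles (same rank, distinct sample ids) back to a taxa table."""
    if not profiles:
        raise ValueError("no profiles to write")
    ranks = {p.rank for p in profiles}
    if len(ranks) != 1:
        raise ValueError(f"profiles span multiple ranks: {sorted(ranks)}")
    taxa: list[str] = []
    seen = set()
    for p in profiles:
        for t in (p.counts or p.relative or {}):
            if t not in seen:
                seen.add(t)
                taxa.append(t)
    data = {}
    for p in profiles:
        source = p.counts if p.counts else (p.relative or {})
        data[p.sample_id] = [source.get(t, 0) for t in taxa]
    df = pd.DataFrame(data, index=pd.Index(taxa, name="Taxon"))
    df.to_csv(path, sep="\t")


def iter_statuses(
    labels: Iterable[str], rank: str, rules: CandidateRules = DEFAULT_RULES
) -> dict[str, AffiliationStatus]:
    """Classify a collection of lineage labels at ``rank``."""
    return {lab: classify_affiliation(lab, rank, rules) for lab in labels}
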