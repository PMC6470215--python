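"""Degenerate-primer matching and in-silico PCR coverage over reference 16S sequences.

Primers are written in the IUPAC nucleotide alphabet; a primer base matches a
reference base when the reference base is one of the primer code's concrete
nucleotides.  An ``N`` in the *reference* matches nothing under the default
strict policy (it counts as a mismatch), because an uncalled base gives no
evidence of an annealing site.  Match stringency follows common in-silico PCR
practice: a global mismatch budget plus a 3'-terminal anchor that must pair
exactly (polymerase elongation starts at the 3' end, so mismatches there are
the ones that kill amplification).

Coordinates are 0-based half-open.  Amplicons are reported primer-exclusive
(the inner insert) as the canonical interval, with the primer-inclusive outer
interval alongside.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement

from .taxonomy import Lineage, parse_lineage

#: concrete nucleotides each IUPAC code stands for
IUPAC: dict[str, frozenset[str]] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items()
}

_VALID_PRIMER = frozenset(IUPAC)


@dataclass(frozen=True)
class DegeneratePrimer:
    """A named oligo over the IUPAC alphabet."""

    name: str
    sequence: str
    orientation: str = "forward"  # forward | reverse

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"primer {self.name!r} has empty sequence")
        bad = set(seq) - _VALID_PRIMER
        if bad:
            raise ValueError(
                f"primer {self.name!r}: invalid IUPAC code(s) {sorted(bad)}"
            )
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward/reverse, got {self.orientation!r}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def degeneracy(self) -> int:
        d = 1
        for b in self.sequence:
            d *= len(IUPAC[b])
        return d


@dataclass(frozen=True)
class MatchPolicy:
    """Stringency for a single primer-site search."""

    max_mismatch: int = 0
    anchor_3prime: int = 3  # terminal bases that must match exactly


@dataclass(frozen=True)
class PrimerPair:
    forward: DegeneratePrimer
    reverse: DegeneratePrimer
    max_mismatch: int = 0
    anchor_3prime: int = 3
    min_amplicon: int = 1  # inner (primer-exclusive) length bounds
    max_amplicon: int = 2000

    def __post_init__(self) -> None:
        if self.min_amplicon <= 0 or self.max_amplicon < self.min_amplicon:
            raise ValueError("amplicon length bounds must be positive and ordered")
        if self.anchor_3prime > min(len(self.forward), len(self.reverse)):
            raise ValueError("3' anchor longer than a primer")

    @property
    def policy(self) -> MatchPolicy:
        return MatchPolicy(self.max_mismatch, self.anchor_3prime)


@dataclass(frozen=True)
class MatchResult:
    """One predicted amplicon on a reference sequence."""

    reference_id: str
    forward_site: tuple[int, int]
    reverse_site: tuple[int, int]
    amplicon: tuple[int, int]  # inner, primer-exclusive (canonical)
    amplicon_outer: tuple[int, int]  # primer-inclusive
    forward_mismatches: int
    reverse_mismatches: int


def expand_degenerate(primer: DegeneratePrimer, cap: int = 4096) -> set[str]:
    """All concrete sequences a degenerate primer stands for.

    Serves as the independent brute-force oracle for :func:`match_primer`;
    refuses degeneracies beyond ``cap``.
    """
    if primer.degeneracy > cap:
        raise ValueError(
            f"degeneracy {primer.degeneracy} exceeds cap {cap} for {primer.name!r}"
        )
    pools = [sorted(IUPAC[b]) for b in primer.sequence]
    return {"".join(combo) for combo in itertools.product(*pools)}


def _mismatches(pattern: str, window: str, limit: int, anchor_tail: int) -> int | None:
    """Mismatch count if the window passes the policy, else None.

    ``anchor_tail`` > 0 demands exact (mismatch-free) pairing over the last
    ``anchor_tail`` pattern positions; ``anchor_tail`` < 0 anchors the first
    ``-anchor_tail`` positions instead (a 3' anchor on the minus strand).
    """
    n = len(pattern)
    if anchor_tail >= 0:
        anchored = range(n - anchor_tail, n)
    else:
        anchored = range(-anchor_tail)
    anchored = set(anchored)
    mm = 0
    for i, (p, r) in enumerate(zip(pattern, window)):
        if r not in IUPAC[p] or r == "N":
            if i in anchored:
                return None
            mm += 1
            if mm > limit:
                return None
    return mm


def match_primer(
    primer: DegeneratePrimer,
    reference: str,
    policy: MatchPolicy = MatchPolicy(),
) -> list[tuple[int, str, int]]:
    """All annealing sites of ``primer`` on ``reference``, both strands.

    Returns ``(position, strand, mismatches)`` with ``position`` the 0-based
    start of the site on the forward strand.  ``'+'`` sites match the primer
    as written; ``'-'`` sites match its reverse complement (the primer anneals
    to the forward strand, pointing leftward, so its 3' anchor sits at the
    window start).
    """
    if not reference:
        raise ValueError("empty reference sequence")
    ref = reference.upper()
    n = len(primer)
    if n > len(ref):
        return []
    fwd = primer.sequence
    rev = reverse_complement(fwd)
    hits = []
    for pos in range(len(ref) - n + 1):
        window = ref[pos : pos + n]
        mm = _mismatches(fwd, window, policy.max_mismatch, policy.anchor_3prime)
        if mm is not None:
            hits.append((pos, "+", mm))
        mm = _mismatches(rev, window, policy.max_mismatch, -policy.anchor_3prime)
        if mm is not None:
            hits.append((pos, "-", mm))
    return hits


def find_amplicons(pair: PrimerPair, reference: str, reference_id: str = "ref") -> list[MatchResult]:
    """Predicted amplicons: forward site upstream of a reverse-complemented reverse site.

    Each forward site is paired with the nearest downstream reverse site whose
    inner product length falls within the pair's bounds; paired sites are
    consumed so tandem target cassettes yield non-overlapping amplicons.
    """
    policy = pair.policy
    f_hits = [h for h in match_primer(pair.forward, reference, policy) if h[1] == "+"]
    r_hits = [h for h in match_primer(pair.reverse, reference, policy) if h[1] == "-"]
    if not f_hits or not r_hits:
        return []
    nf, nr = len(pair.forward), len(pair.reverse)
    results: list[MatchResult] = []
    used_r: set[int] = set()
    for f_pos, _, f_mm in sorted(f_hits):
        f_end = f_pos + nf
        best = None
        for r_pos, _, r_mm in sorted(r_hits):
            if r_pos in used_r or r_pos < f_end:
                continue
            inner = r_pos - f_end
            if pair.min_amplicon <= inner <= pair.max_amplicon:
                best = (r_pos, r_mm)
                break
        if best is None:
            continue
        r_pos, r_mm = best
        used_r.add(r_pos)
        results.append(
            MatchResult(
                reference_id=reference_id,
                forward_site=(f_pos, f_end),
                reverse_site=(r_pos, r_pos + nr),
                amplicon=(f_end, r_pos),
                amplicon_outer=(f_pos, r_pos + nr),
                forward_mismatches=f_mm,
                reverse_mismatches=r_mm,
            )
        )
    return results


@dataclass
class CoverageResult:
    """Per-taxon amplification coverage at one rank."""

    rank: str
    per_taxon: dict[str, tuple[int, int, float]]  # taxon -> (amplified, total, fraction)
    n_amplified: int
    n_total: int

    @property
    def overall(self) -> float:
        return self.n_amplified / self.n_total if self.n_total else 0.0


def rank_coverage(
    pair: PrimerPair,
    references: Mapping[str, str],
    lineages: Mapping[str, Lineage | str],
    rank: str,
) -> CoverageResult:
    """Fraction of reference sequences each taxon at ``rank`` that amplify.

    ``references`` maps id -> sequence; ``lineages`` maps the same ids to
    parsed lineages or raw lineage strings.  References with no name at the
    rank are grouped under ``"(unclassified)"``.
    """
    tallies: dict[str, list[int]] = {}
    n_amp = 0
    for ref_id, seq in references.items():
        if ref_id not in lineages:
            raise KeyError(f"reference {ref_id!r} has no lineage")
        lin = lineages[ref_id]
        if isinstance(lin, str):
            lin = parse_lineage(lin)
        taxon = lin.name_at(rank) or "(unclassified)"
        amplified = bool(find_amplicons(pair, seq, ref_id))
        n_amp += amplified
        bucket = tallies.setdefault(taxon, [0, 0])
        bucket[0] += amplified
        bucket[1] += 1
    per_taxon = {
        t: (a, n, a / n) for t, (a, n) in sorted(tallies.items())
    }
    return CoverageResult(
        rank=rank, per_taxon=per_taxon, n_amplified=n_amp, n_total=len(references)
    )


def read_fasta(path) -> dict[str, str]:
    """Minimal FASTA loader returning id -> uppercase sequence."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_taxonomy_map(path) -> dict[str, str]:
    """Two-column TSV: sequence id -> lineage string."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            ref_id, _, lineage = line.partition("\t")
            out[ref_id] = lineage
    return out
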