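"""Synthetic multi-primer taxon profiles with planted ground truth.

The generator emulates the structure of a multi-primer 16S survey of a
host-associated community: a pool of affiliated and candidate taxa plus a
pooled unassigned bucket; per-region detection bias (each primer set sees a
status-dependent random subset of the pool); heavy-tailed (log-normal)
abundances scaled to realistic per-dataset read budgets (tens of thousands to
several hundred thousand reads); and an optional marginal-constrained fixture
builder that reproduces published per-primer set sizes, all-primer
intersection and union exactly.

Every statistic downstream (unique/shared/status counts, merged throughput)
can be checked against the planted truth returned alongside the profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .mock import MockComposition
from .taxonomy import (
    AffiliationStatus,
    TaxonProfile,
    UNASSIGNED_LABEL,
    classify_affiliation,
)

# Validly named phyla observed in marine-sponge 16S surveys; affiliated pool vocabulary.
AFFILIATED_VOCAB: tuple[str, ...] = (
    "Proteobacteria", "Chloroflexi", "Acidobacteria", "Actinobacteria",
    "Bacteroidetes", "Cyanobacteria", "Firmicutes", "Planctomycetes",
    "Spirochaetes", "Verrucomicrobia", "Nitrospirae", "Gemmatimonadetes",
    "Lentisphaerae", "Fusobacteria", "Chlamydiae", "Chlorobi",
    "Armatimonadetes", "Tenericutes", "Synergistetes", "Thermotogae",
    "Aquificae", "Crenarchaeota", "Euryarchaeota", "Deferribacteres",
    "Dictyoglomi", "Elusimicrobia", "Fibrobacteres", "Caldiserica",
    "Chrysiogenetes", "Thermodesulfobacteria",
)

# Candidate-division vocabulary plus synthetic codes exercising the
# pattern fallback of the affiliation classifier.
CANDIDATE_VOCAB: tuple[str, ...] = (
    "TM7", "OD1", "WS3", "OP11", "OP3", "SR1", "BRC1", "GN02", "WWE1",
    "SAR406", "NKB19", "ZB3", "GN04", "WS2", "OP8", "TM6", "NC10",
    "WS6", "WS4", "LD1", "ZZ9", "QX12", "KB7", "RF3", "AD3", "PB19",
    "EC214", "MAT9", "SC3", "HY1", "UX88", "GAL15", "JL37", "VR2",
)


@dataclass
class GeneratorSpec:
    """Study conditions for the profile generator.

    Defaults mirror a four-sponge, five-primer phylum-level survey: 27
    affiliated and 29 candidate taxa in the combined pool, an unassigned
    bucket carrying ~10.8% of reads, candidate taxa collectively rare
    (a few percent of reads), per-dataset read budgets between ~5x10^4 and
    6.5x10^5, and region-specific detection bias.
    """

    n_affiliated: int = 27
    n_candidate: int = 29
    unassigned_mass: float = 0.108
    candidate_abundance_scale: float = 0.03
    detection_prob: Mapping[str, Mapping[AffiliationStatus, float]] = field(
        default_factory=lambda: {
            "V1V3": {AffiliationStatus.AFFILIATED: 0.70, AffiliationStatus.CANDIDATE: 0.35},
            "V4": {AffiliationStatus.AFFILIATED: 0.65, AffiliationStatus.CANDIDATE: 0.80},
            "V4V5": {AffiliationStatus.AFFILIATED: 0.75, AffiliationStatus.CANDIDATE: 0.45},
            "V5V8": {AffiliationStatus.AFFILIATED: 0.90, AffiliationStatus.CANDIDATE: 0.60},
            "V6V9": {AffiliationStatus.AFFILIATED: 0.55, AffiliationStatus.CANDIDATE: 0.20},
        }
    )
    read_budget: Mapping[str, int] = field(
        default_factory=lambda: {
            "V1V3": 75_000,
            "V4": 100_000,
            "V4V5": 90_000,
            "V5V8": 300_000,
            "V6V9": 55_000,
        }
    )
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 2.0
    rank: str = "phylum"
    n_samples: int = 1
    seed: int = 0
    forced_unique: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        for ps, probs in self.detection_prob.items():
            for st, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"detection prob {p} for {ps}/{st} outside [0,1]")
        if any(b <= 0 for b in self.read_budget.values()):
            raise ValueError("read budgets must be positive")
        if not 0.0 <= self.unassigned_mass < 1.0:
            raise ValueError("unassigned_mass must be in [0, 1)")


def simulate_pool(spec: GeneratorSpec) -> list[tuple[str, AffiliationStatus]]:
    """Draw the combined taxon pool: lineage strings plus planted statuses.

    Names come from real vocabularies first and deterministic synthetic names
    after; every planted status is recoverable by the affiliation classifier
    (round-trip property).
    """
    rng = np.random.default_rng(spec.seed)
    pool: list[tuple[str, AffiliationStatus]] = []
    aff = list(AFFILIATED_VOCAB)
    rng.shuffle(aff)
    for i in range(spec.n_affiliated):
        name = aff[i] if i < len(aff) else f"Synthobacteria{i - len(aff) + 1}"
        pool.append((f"k__Bacteria;p__{name}", AffiliationStatus.AFFILIATED))
    cand = list(CANDIDATE_VOCAB)
    rng.shuffle(cand)
    for i in range(spec.n_candidate):
        name = cand[i] if i < len(cand) else f"SX{100 + i}"
        pool.append((f"k__Bacteria;p__{name}", AffiliationStatus.CANDIDATE))
    for lineage, status in pool:
        assert classify_affiliation(lineage, spec.rank) is status
    return pool


@dataclass
class GroundTruth:
    """What the generator planted, for exact downstream verification."""

    pool: list[tuple[str, AffiliationStatus]]
    detected: dict[str, set[str]]  # primer set -> taxon labels (excl. Unassigned)
    unique_counts: dict[str, int]
    union: set[str]
    shared_all: set[str]
    status_of: dict[str, AffiliationStatus]


def simulate_profiles(
    pool: Sequence[tuple[str, AffiliationStatus]],
    spec: GeneratorSpec,
) -> tuple[dict[str, list[TaxonProfile]], GroundTruth]:
    """Per-primer, per-sample profiles with status-biased detection.

    Returns ``(profiles, truth)`` where ``profiles[primer_set]`` holds one
    profile per sample (detection is drawn once; read noise per sample) and
    ``truth`` records the planted detection sets.

    With ``spec.forced_unique`` set, that many pool taxa per primer set are
    reserved as detected by that set alone, and the remaining taxa are
    prevented from being singletons, so planted unique counts are exact.
    """
    if not pool:
        raise ValueError("empty taxon pool")
    rng = np.random.default_rng(spec.seed + 1)
    primers = list(spec.detection_prob)
    status_of = {lab: st for lab, st in pool}
    labels = [lab for lab, _ in pool]

    base = rng.lognormal(spec.lognormal_mu, spec.lognormal_sigma, size=len(labels))
    weight = {
        lab: w * (spec.candidate_abundance_scale
                  if status_of[lab] is AffiliationStatus.CANDIDATE else 1.0)
        for lab, w in zip(labels, base)
    }

    detected: dict[str, set[str]] = {ps: set() for ps in primers}
    remaining = list(labels)
    if spec.forced_unique:
        idx = 0
        for ps, n in spec.forced_unique.items():
            if ps not in detected:
                raise ValueError(f"forced_unique names unknown primer set {ps!r}")
            block = labels[idx : idx + n]
            if len(block) < n:
                raise ValueError("pool too small for the forced unique blocks")
            detected[ps].update(block)
            idx += n
        remaining = labels[idx:]
    for lab in remaining:
        st = status_of[lab]
        members = [
            ps for ps in primers
            if rng.random() < spec.detection_prob[ps].get(st, 0.5)
        ]
        if spec.forced_unique is not None:
            # planted-unique mode: non-block taxa must not be singletons
            if len(members) == 1:
                others = [ps for ps in primers if ps not in members]
                members.append(others[rng.integers(len(others))])
        for ps in members:
            detected[ps].add(lab)
    if all(not s for s in detected.values()):
        raise ValueError("zero detection everywhere; raise detection probabilities")

    profiles: dict[str, list[TaxonProfile]] = {ps: [] for ps in primers}
    for ps in primers:
        taxa = sorted(detected[ps])
        budget = spec.read_budget.get(ps, 100_000)
        for s in range(spec.n_samples):
            sample_id = f"S{s + 1}"
            counts: dict[str, int] = {}
            if taxa:
                w = np.array([weight[t] for t in taxa])
                w = w * rng.lognormal(0.0, 0.1, size=len(taxa))  # per-sample noise
                taxon_budget = budget * (1.0 - spec.unassigned_mass)
                reads = np.maximum(1, np.round(taxon_budget * w / w.sum())).astype(int)
                counts = dict(zip(taxa, (int(r) for r in reads)))
            if spec.unassigned_mass > 0:
                counts[UNASSIGNED_LABEL] = max(1, round(budget * spec.unassigned_mass))
            profiles[ps].append(
                TaxonProfile(sample_id=sample_id, primer_set=ps,
                             rank=spec.rank, counts=counts)
            )

    union = set().union(*detected.values())
    shared_all = set.intersection(*detected.values()) if detected else set()
    unique_counts = {
        ps: sum(
            1 for t in s
            if all(t not in o for q, o in detected.items() if q != ps)
        )
        for ps, s in detected.items()
    }
    truth = GroundTruth(
        pool=list(pool),
        detected=detected,
        unique_counts=unique_counts,
        union=union,
        shared_all=shared_all,
        status_of=status_of,
    )
    return profiles, truth


def fixture_from_marginals(
    set_sizes: Mapping[str, int] | Sequence[int],
    intersection: int,
    union: int,
    seed: int = 0,
    label_prefix: str = "t",
) -> dict[str, set[str]]:
    """Deterministic taxon-label sets matching published marginals exactly.

    Satisfies: each set's size, the all-set intersection, and the union size.
    Pairwise overlaps beyond those constraints are whatever the greedy
    construction produces (allocate the common core, then give every non-core
    label one home, then fill remaining slots reusing labels kept out of at
    least one set).

    Raises
    ------
    ValueError
        Naming the violated inequality when the constraints are infeasible.
    """
    if not isinstance(set_sizes, Mapping):
        set_sizes = {f"P{i + 1}": n for i, n in enumerate(set_sizes)}
    names = list(set_sizes)
    sizes = list(set_sizes.values())
    k = len(names)
    if k < 2:
        raise ValueError("need at least two sets")
    if intersection > min(sizes):
        raise ValueError(
            f"infeasible: intersection {intersection} > smallest set size {min(sizes)}"
        )
    if union < max(sizes):
        raise ValueError(f"infeasible: union {union} < largest set size {max(sizes)}")
    extras = [s - intersection for s in sizes]
    n_extra_labels = union - intersection
    total_slots = sum(extras)
    if n_extra_labels > total_slots:
        raise ValueError(
            f"infeasible: union {union} > intersection + sum of per-set surplus "
            f"({intersection} + {total_slots})"
        )
    if total_slots > n_extra_labels * (k - 1):
        raise ValueError(
            "infeasible: per-set surplus slots exceed what non-core labels can "
            "absorb without all of them being shared by every set "
            f"({total_slots} > {n_extra_labels} * (k-1))"
        )

    rng = np.random.default_rng(seed)
    width = len(str(union))
    core = [f"{label_prefix}{i:0{width}d}" for i in range(intersection)]
    extra_labels = [
        f"{label_prefix}{i:0{width}d}" for i in range(intersection, union)
    ]
    sets: dict[str, set[str]] = {n: set(core) for n in names}
    rem = dict(zip(names, extras))

    order = list(extra_labels)
    rng.shuffle(order)
    for lab in order:  # one home per non-core label, most-starved set first
        target = max((n for n in names if rem[n] > 0), key=lambda n: (rem[n], n))
        sets[target].add(lab)
        rem[target] -= 1

    for n in names:  # fill remaining slots, capping multiplicity at k-1
        while rem[n] > 0:
            membership = {
                lab: sum(lab in sets[q] for q in names) for lab in extra_labels
            }
            candidates = [
                lab for lab in extra_labels
                if lab not in sets[n] and membership[lab] < k - 1
            ]
            if not candidates:
                raise ValueError("greedy fill deadlocked; constraints too tight")
            lab = min(candidates, key=lambda c: (membership[c], c))
            sets[n].add(lab)
            rem[n] -= 1

    for n, target in zip(names, sizes):
        assert len(sets[n]) == target
    assert len(set.union(*sets.values())) == union
    assert len(set.intersection(*sets.values())) == intersection
    return sets


def simulate_mock(
    expected: MockComposition, noise: float, seed: int = 0,
    primer_set: str = "V4", sample_id: str = "mock",
) -> TaxonProfile:
    """Observed mock-community profile under multiplicative log-normal noise.

    ``noise`` is the log-scale standard deviation; zero noise returns the
    expected fractions exactly, and concordance with the expected composition
    decreases monotonically in expectation as noise grows.
    """
    if noise < 0:
        raise ValueError("noise must be non-negative")
    labels = sorted(expected.fractions)
    frac = np.array([expected.fractions[t] for t in labels], dtype=float)
    if noise > 0:
        rng = np.random.default_rng(seed)
        frac = frac * np.exp(rng.normal(0.0, noise, size=len(frac)))
        frac = frac / frac.sum()
    else:
        frac = frac / frac.sum()
    return TaxonProfile(
        sample_id=sample_id, primer_set=primer_set, rank="genus",
        counts={}, relative=dict(zip(labels, (float(f) for f in frac))),
    )
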