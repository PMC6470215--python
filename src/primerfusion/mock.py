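"""Mock-community concordance: measured profiles vs a known input composition.

A defined microbial community standard (here defaulting to the widely used
eight-genus cellular/DNA standard: *Bacillus*, *Enterococcus*, *Escherichia*,
*Lactobacillus*, *Listeria*, *Pseudomonas*, *Salmonella*, *Staphylococcus*)
is sequenced alongside the samples; agreement between the expected and the
observed relative abundances validates the whole wet-lab + informatics chain.
Agreement is scored by the Pearson correlation coefficient, complemented by
the total-variation distance (half the L1 distance between the two
compositions), which unlike r is bounded in [0, 1] and sensitive to
systematic scale distortion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .taxonomy import TaxonProfile

#: Vendor-stated theoretical 16S relative abundances (%) of the eight-genus
#: community standard, normalised to fractions.
ZYMO_THEORETICAL: dict[str, float] = {
    "Bacillus": 0.174,
    "Enterococcus": 0.099,
    "Escherichia": 0.101,
    "Lactobacillus": 0.184,
    "Listeria": 0.141,
    "Pseudomonas": 0.042,
    "Salmonella": 0.104,
    "Staphylococcus": 0.155,
}


@dataclass(frozen=True)
class MockComposition:
    """Expected genus-level fractions of a defined community."""

    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"expected fractions sum to {total}, not 1")

    @classmethod
    def zymo(cls) -> "MockComposition":
        return cls(dict(ZYMO_THEORETICAL))

    @classmethod
    def read(cls, path) -> "MockComposition":
        """Two-column TSV (label, fraction), header optional."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if isinstance(df.iloc[0, 1], str):  # header row
            df = df.iloc[1:]
        fractions = {str(r): float(v) for r, v in zip(df[0], df[1])}
        return cls(fractions)


def _aligned_vectors(
    expected: MockComposition, observed: TaxonProfile
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    obs_rel = observed.as_relative()
    labels = sorted(set(expected.fractions) | set(obs_rel))
    e = np.array([expected.fractions.get(t, 0.0) for t in labels])
    o = np.array([obs_rel.get(t, 0.0) for t in labels])
    return e, o, labels


def pearson_concordance(expected: MockComposition, observed: TaxonProfile) -> float:
    """Pearson r between expected and observed relative abundances.

    The label union is taken, absent taxa imputed as zero.  Invariant to any
    uniform rescaling of the observed counts.

    Raises
    ------
    ValueError
        If either vector has zero variance (r undefined).
    """
    e, o, _ = _aligned_vectors(expected, observed)
    if np.ptp(e) == 0 or np.ptp(o) == 0:
        raise ValueError("zero variance: Pearson correlation undefined")
    return float(pearsonr(e, o).statistic)


def total_variation(expected: MockComposition, observed: TaxonProfile) -> float:
    """Total-variation distance between the two compositions, in [0, 1]."""
    e, o, _ = _aligned_vectors(expected, observed)
    return float(0.5 * np.abs(e - o).sum())


def recovery_report(
    expected: MockComposition, observed: Mapping[str, TaxonProfile]
) -> pd.DataFrame:
    """Rank primer sets by how faithfully they recover the mock community.

    Returns a DataFrame (primer_set, pearson_r, tv_distance) sorted by
    descending r with TV distance as the deterministic tiebreak.
    """
    if not observed:
        raise ValueError("no observed profiles")
    rows = [
        {
            "primer_set": ps,
            "pearson_r": pearson_concordance(expected, prof),
            "tv_distance": total_variation(expected, prof),
        }
        for ps, prof in observed.items()
    ]
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["pearson_r", "tv_distance", "primer_set"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return df
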