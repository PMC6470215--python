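"""Shared numeric helpers."""

from __future__ import annotations

from fractions import Fraction


def round_half_away(x: float | Fraction, ndigits: int = 1) -> float:
    """Round with ties going away from zero (the convention of the reported tables).

    Exact for ``Fraction`` inputs; floats are converted through ``Fraction`` so the
    decision is made on the exact binary value, not on a second rounding.
    """
    f = Fraction(x) * 10**ndigits
    n, d = f.numerator, f.denominator
    q, r = divmod(abs(n), d)
    if 2 * r >= d:
        q += 1
    if n < 0:
        q = -q
    return q / 10**ndigits


def percentage(num: int | Fraction, den: int | Fraction, ndigits: int = 1) -> float:
    """100 * num / den, rounded half away from zero; exact rational arithmetic first."""
    if den == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    return round_half_away(Fraction(100) * Fraction(num) / Fraction(den), ndigits)
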