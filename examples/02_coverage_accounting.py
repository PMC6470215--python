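"""Affiliation accounting and overlap statistics across primer sets.

Classifies every taxon as affiliated (validly named), candidate (provisional
division such as TM7) or unassigned, then reports per-primer and combined
counts, the unaffiliated fraction, and how much a single primer set misses.
"""

from primerfusion import (
    TaxonProfile, missed_fraction, shared_fraction, tally_by_status,
    unaffiliated_fraction,
)

labels = {
    "V4": ["k__Bacteria;p__Proteobacteria", "k__Bacteria;p__Chloroflexi",
           "k__Bacteria;p__TM7", "Unassigned"],
    "V5V8": ["k__Bacteria;p__Proteobacteria", "k__Bacteria;p__Acidobacteria",
             "k__Bacteria;p__OD1", "k__Bacteria;p__TM7", "Unassigned"],
}
profiles = {
    ps: TaxonProfile("sponge1", ps, "phylum", {t: 10 for t in ls})
    for ps, ls in labels.items()
}

summary = tally_by_status(profiles, "phylum")
for ps, sc in summary.per_primer.items():
    print(f"{ps:5s} affiliated={sc.n_affiliated} candidate={sc.n_candidate} "
          f"unassigned={sc.n_unassigned}")
c = summary.combined
print(f"combined: affiliated={c.n_affiliated} candidate={c.n_candidate} "
      f"unassigned={c.n_unassigned}")
print(f"unaffiliated fraction: "
      f"{unaffiliated_fraction(c.n_unaffiliated, c.n_affiliated)}% "
      "(candidate + unassigned share of all taxa)")

sets = {ps: set(ls) for ps, ls in labels.items()}
inter, union, pct = shared_fraction(sets)
print(f"shared between the two primer sets: {inter}/{union} = {pct}%")
print(f"V4 alone misses {missed_fraction(c.total, summary.per_primer['V4'].total)}% "
      "of the combined taxon count")
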