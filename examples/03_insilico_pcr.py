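"""In-silico PCR: degenerate-primer coverage over a small reference panel.

Builds a synthetic panel of 16S-like templates, knocks the forward primer
site out of some of them, and measures per-phylum amplification coverage.
The primer pair used here is the widely published 515F/806R V4 pair, given
purely as a worked example; real evaluations should supply their own oligos
(see primers.yaml).
"""

from Bio.Seq import reverse_complement

from primerfusion import (
    DegeneratePrimer, PrimerPair, expand_degenerate, find_amplicons, rank_coverage,
)

FWD = DegeneratePrimer("515F", "GTGYCAGCMGCCGCGGTAA", "forward")
REV = DegeneratePrimer("806R", "GGACTACNVGGGTWTCTAAT", "reverse")
pair = PrimerPair(FWD, REV, max_mismatch=0, anchor_3prime=3,
                  min_amplicon=100, max_amplicon=500)

insert = "ACGT" * 60  # 240 nt stand-in for the amplified region
# templates carry one concrete realization of each degenerate site
fwd_site = min(expand_degenerate(FWD))
rev_site = reverse_complement(min(expand_degenerate(REV)))
good = "TTTTT" + fwd_site + insert + rev_site + "TTTTT"
broken = good.replace(fwd_site[:8], "T" * 8, 1)  # primer site mutated away

references, lineages = {}, {}
for i in range(6):
    references[f"chloro{i}"] = good if i < 4 else broken
    lineages[f"chloro{i}"] = "k__Bacteria;p__Chloroflexi"
for i in range(4):
    references[f"proteo{i}"] = good
    lineages[f"proteo{i}"] = "k__Bacteria;p__Proteobacteria"

(hit,) = find_amplicons(pair, good, "chloro0")
print(f"amplicon on an intact template: inner interval {hit.amplicon}, "
      f"{hit.amplicon[1] - hit.amplicon[0]} nt")

cov = rank_coverage(pair, references, lineages, "phylum")
for taxon, (n_amp, n_tot, frac) in cov.per_taxon.items():
    print(f"{taxon:16s} {n_amp}/{n_tot} amplified ({frac:.0%})")
print(f"overall coverage: {cov.overall:.0%}")
# Chloroflexi drops to 4/6 because two templates lost the forward site; a
# primer pair's coverage is exactly this per-taxon amplifiable fraction.
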