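# Primer-pair configuration for `primerfusion insilico`.
#
# One named slot per primer set. The region slots below are intentionally
# blank: supply the oligos used in your own study. The commented candidates
# are well-known published primers often used for these regions — they are
# EXAMPLES, not an endorsement of any particular study's choices.
#
# Optional per-pair policy keys: max_mismatch (default 0), anchor_3prime
# (default 3), min_amplicon, max_amplicon (inner, primer-exclusive bounds).

V1V3:
  forward:   # e.g. 27F  AGAGTTTGATCMTGGCTCAG
  reverse:   # e.g. 534R ATTACCGCGGCTGCTGG

V4:
  forward:   # e.g. 515F GTGYCAGCMGCCGCGGTAA
  reverse:   # e.g. 806R GGACTACNVGGGTWTCTAAT

V4V5:
  forward:   # e.g. 515F GTGYCAGCMGCCGCGGTAA
  reverse:   # e.g. 926R CCGYCAATTYMTTTRAGTTT

V5V8:
  forward:   # e.g. 784F AGGATTAGATACCCTGGTA
  reverse:   # e.g. 1346R TGACGGGCGGTGTGTACAAG

V6V9:
  forward:   # e.g. 928F TAAAACTYAAAKGAATTGACGGG
  reverse:   # e.g. 1492R TACGGYTACCTTGTTACGACTT
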