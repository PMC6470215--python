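"""Published per-primer tallies for the four-sponge, five-primer survey.

A bundled example dataset: phylum- and class-level affiliated/unaffiliated OTU
counts per primer set and per sponge species, the all-primer combined counts,
the all-primer shared counts and unions, and the per-dataset sequencing read
totals with their combined (representative) throughput.  These are observed
study results, usable as inputs for the coverage and throughput operations —
the lineage-level identities behind the counts are not part of the dataset.
"""

from __future__ import annotations

PRIMER_SETS = ("V1V3", "V4", "V4V5", "V5V8", "V6V9")
SPECIES = (
    "Aplysina archeri",
    "Halichondria okadai",
    "Igernella notabilis",
    "Tedania tubulifera",
)

#: per species: {primer -> (n_unaffiliated, n_affiliated)}, plus combined,
#: all-primer shared count and union size. Phylum level.
PHYLUM_OTUS = {
    "Aplysina archeri": {
        "per_primer": {
            "V1V3": (4, 15),
            "V4": (6, 14),
            "V4V5": (6, 15),
            "V5V8": (12, 16),
            "V6V9": (5, 13),
        },
        "combined": (16, 17),
        "shared": 11,
        "union": 33,
    },
    "Halichondria okadai": {
        "per_primer": {
            "V1V3": (9, 20),
            "V4": (24, 15),
            "V4V5": (11, 18),
            "V5V8": (10, 24),
            "V6V9": (5, 13),
        },
        "combined": (26, 25),
        "shared": 10,
        "union": 51,
    },
    "Igernella notabilis": {
        "per_primer": {
            "V1V3": (9, 19),
            "V4": (12, 14),
            "V4V5": (8, 18),
            "V5V8": (10, 19),
            "V6V9": (4, 14),
        },
        "combined": (18, 22),
        "shared": 10,
        "union": 40,
    },
    "Tedania tubulifera": {
        "per_primer": {
            "V1V3": (6, 14),
            "V4": (11, 12),
            "V4V5": (8, 16),
            "V5V8": (10, 18),
            "V6V9": (2, 14),
        },
        "combined": (13, 22),
        "shared": 10,
        "union": 35,
    },
}

#: four-species pooled phylum tallies: per primer and combined
#: (n_unaffiliated, n_affiliated); all-primer shared and union.
PHYLUM_TOTAL = {
    "per_primer": {
        "V1V3": (11, 21),
        "V4": (26, 18),
        "V4V5": (14, 22),
        "V5V8": (21, 24),
        "V6V9": (5, 17),
    },
    "combined": (30, 27),
    "shared": 27,
    "union": 57,
}

CLASS_OTUS = {
    "Aplysina archeri": {
        "per_primer": {
            "V1V3": (17, 24),
            "V4": (24, 20),
            "V4V5": (25, 24),
            "V5V8": (35, 26),
            "V6V9": (13, 25),
        },
        "combined": (51, 38),
        "shared": 11,
        "union": 89,
    },
    "Halichondria okadai": {
        "per_primer": {
            "V1V3": (27, 39),
            "V4": (76, 32),
            "V4V5": (36, 34),
            "V5V8": (31, 51),
            "V6V9": (13, 27),
        },
        "combined": (81, 56),
        "shared": 22,
        "union": 137,
    },
    "Igernella notabilis": {
        "per_primer": {
            "V1V3": (19, 33),
            "V4": (36, 28),
            "V4V5": (28, 33),
            "V5V8": (23, 34),
            "V6V9": (15, 28),
        },
        "combined": (52, 45),
        "shared": 20,
        "union": 97,
    },
    "Tedania tubulifera": {
        "per_primer": {
            "V1V3": (20, 28),
            "V4": (36, 23),
            "V4V5": (22, 27),
            "V5V8": (24, 34),
            "V6V9": (4, 23),
        },
        "combined": (42, 46),
        "shared": 10,
        "union": 88,
    },
}

CLASS_TOTAL = {
    "per_primer": {
        "V1V3": (38, 41),
        "V4": (86, 38),
        "V4V5": (53, 42),
        "V5V8": (57, 55),
        "V6V9": (18, 35),
    },
    "combined": (103, 65),
    "shared": 65,
    "union": 168,
}

#: per-dataset sequencing read totals and the combined representative
#: throughput after shared-OTU deduplication.
READ_TOTALS = {
    "Aplysina archeri": {
        "V1V3": 96_338, "V4": 100_584, "V4V5": 172_013,
        "V5V8": 298_920, "V6V9": 57_184, "combined": 327_208,
    },
    "Halichondria okadai": {
        "V1V3": 69_573, "V4": 100_280, "V4V5": 55_452,
        "V5V8": 641_381, "V6V9": 47_892, "combined": 651_704,
    },
    "Igernella notabilis": {
        "V1V3": 80_920, "V4": 100_166, "V4V5": 96_798,
        "V5V8": 162_256, "V6V9": 66_088, "combined": 194_240,
    },
    "Tedania tubulifera": {
        "V1V3": 49_392, "V4": 42_069, "V4V5": 44_587,
        "V5V8": 129_829, "V6V9": 46_002, "combined": 162_805,
    },
}

#: combined candidate-phylum abundance summary: 29 candidate OTUs carrying
#: 2.3% of reads in total; the pooled unassigned bucket 10.8%.
CANDIDATE_SUMMARY = {
    "n_candidate": 29,
    "candidate_total_pct": 2.3,
    "affiliated_total_pct": 87.62,
    "unassigned_total_pct": 10.8,
}
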