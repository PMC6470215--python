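# Methods

## Scope and data model

The pipeline starts from per-primer-set taxa summaries — the table shape
produced by closed-reference OTU picking against a Greengenes-style
reference followed by rank collapsing: one lineage string per row
(`k__Bacteria;p__Chloroflexi;…`), one column of read counts (or fractions)
per sample. Read-level processing (demultiplexing, trimming, chimera
removal, OTU picking) is upstream and out of scope. The canonical internal
unit is the integer read count; fractional tables are accepted for
concordance and comparison work but refused by throughput arithmetic, which
is only meaningful on reads.

Merging operates on rank-collapsed taxonomy labels, not sequence-level
OTUs: amplicons from different 16S regions cannot be identical sequences,
so cross-primer comparison is only defined at taxonomy ranks
(phylum … genus).

## Affiliation status

Each taxon at a rank is exactly one of AFFILIATED, CANDIDATE, UNASSIGNED
(the statuses partition any taxon set; "unaffiliated" = candidate ∪
unassigned):

* UNASSIGNED — the literal `Unassigned` token, or an empty name at the
  rank (`p__`). All unassigned taxa at a rank are pooled into a single
  bucket, counted once per primer set and once in any union or
  intersection: individually they are indistinguishable no-match reads,
  and counting them per orphan label would inflate taxon tallies with
  processing artifacts.
* CANDIDATE — the name appears on a configurable candidate-division list
  (seeded with the divisions that occur in Greengenes phylum strings: TM7,
  OD1, OP11, WS3, BRC1, GN02, SR1, WWE1, SAR406, …), or — as a fallback,
  separately switchable — is an all-capitals letters-and-digits code of ≥ 2
  characters. Candidate names have no grammar, so an explicit, overridable
  list with an auditable pattern fallback is preferred over any attempt at
  a complete rule. The shipped list is deliberately not claimed complete.
* AFFILIATED — everything else with a name at the rank.

## Merging and throughput

A taxon is *detected* by a primer set iff its reads are ≥ `min_reads`
(default 1 — no abundance floor). The merged profile is the union of
detected taxa; each taxon's representative read count is the maximum over
the primer sets that detected it, so summing representatives realises both
the unique-taxon addition rule and the shared-taxon maximum rule at once.
Ties keep the whole argmax set in the provenance (the value is unaffected;
reporting an arbitrary single winner would discard information).
Consequences used as test invariants: adding a primer set never decreases
union size or combined throughput, and the combined throughput is bounded
below by the best single-primer total.

## Percentage arithmetic

All reported percentages (unaffiliated fraction 100·U/(U+A), missed
fraction, increase over best single primer set, shared fraction |∩|/|∪|,
throughput increase) are computed in exact rational arithmetic
(`fractions.Fraction`) and rounded once, to one decimal, ties away from
zero. This convention reproduces every published footer value checked
(52.6, 61.3, 29.5, 35.5, 33.3, 47.4, 38.7, 50.0, 45.7, 549.9, 90.2);
banker's rounding does not.

In the published totals column, the "shared OTUs" numerator (27/57 phylum,
65/168 class) is sharing across the four host species' combined taxon sets
— it exceeds the smallest per-primer tally, so it cannot be cross-primer
sharing. The fixture-based checks therefore build species-level marginals
for those two quantities and per-primer marginals for the per-species rows.

## In-silico PCR

Primers are IUPAC-degenerate; a primer position matches a reference base
iff the base belongs to the code's set. An `N` in the reference counts as a
mismatch (an uncalled base is no evidence of an annealing site). Stringency
is a global mismatch budget plus an exact 3′-terminal anchor, defaulting to
0 mismatches / 3 anchored bases — elongation-blocking 3′ mismatches are the
ones that kill amplification, which is the behaviour of the standard
reference-database primer-evaluation tools; both knobs are configurable.
Matching is implemented as a direct positional window scan (per-position
set membership), which is provably equivalent to expanding the primer into
all concrete variants and scanning each — that expansion is kept as the
independent test oracle, never the implementation. Reverse primers are
matched as their reverse complement on the forward strand with the anchor
mirrored to the window start. Amplicons pair each forward site with the
nearest downstream reverse site within length bounds, consuming sites so
tandem cassettes yield disjoint amplicons; coordinates are 0-based
half-open and the primer-exclusive (inner) interval is canonical. Coverage
at a rank is the amplifiable fraction of reference sequences per taxon. No
melting-temperature or thermodynamic modelling is attempted. Primer oligos
are user-supplied configuration; the package ships no default oligos, only
a commented example file.

## Mock-community evaluation

Expected and observed genus compositions are aligned on the label union
with absent taxa as zero; concordance is the Pearson correlation of the two
fraction vectors (undefined — and rejected — when either vector is
constant). Pearson r is the field's reporting convention; the
total-variation distance (half the L1 distance, in [0, 1]) is added as a
bounded complement and as the deterministic tiebreak when ranking primer
sets. The default expected composition is the vendor-stated theoretical
16S profile of the widely used eight-genus standard (Bacillus 17.4% …
Pseudomonas 4.2%). Comparison defaults to genus rank; any rank present in
the profiles works.

## Profile comparison

Row scaling: `unit_variance` maps each row to mean 0, sample variance 1
(ddof = 1); constant rows are dropped with a warning since they cannot be
scaled (their correlation is likewise undefined). Rows or columns missing
more than 99.99% of cells are rejected. Missing cells are imputed by
iterative low-rank SVD approximation (default rank 2 — the plotted
components; tol 1e-6 on the max-abs change of imputed cells; max 100
iterations), never altering observed cells; a rank-1 matrix with masked
cells is recovered to numerical precision, which the tests exploit as an
exact oracle. PCA treats columns (profiles) as observations, centres them,
and decomposes by SVD; scores × loadingsᵀ reconstructs the centred matrix
exactly. Clustering uses correlation distance d = 1 − r in [0, 2] with
average linkage (UPGMA), serialised to Newick; the test oracle is a
hand-computed UPGMA on a 4-item distance table.

## Synthetic data

The generator's defaults describe the study conditions it emulates: a
combined pool of 27 affiliated and 29 candidate phyla; a pooled unassigned
bucket carrying 10.8% of each dataset's reads; candidate taxa collectively
rare (abundance scale 0.03, putting their joint share at a few percent);
per-dataset read budgets of 55 000–300 000 reads; per-region detection
probabilities between 0.2 and 0.9, status-dependent, so that each primer
set sees a substantially different subset (V5V8 broadest among affiliated
taxa, V4 strongest on candidates, V6V9 narrowest). Abundances are
log-normal (σ = 2), matching the few-dominant/many-rare structure of real
communities; per-sample multiplicative noise is σ = 0.1. All randomness
flows from a single integer seed.

What the generator does not emulate: read-level error, chimeras, copy-number
variation, compositional coupling between primer sets beyond shared base
abundances, or genuine taxonomy (names are drawn from real vocabulary but
assignments are arbitrary). Passing ground-truth-recovery tests therefore
demonstrates the *accounting* is exact, not that the biology of any real
survey is reproduced.

`fixture_from_marginals` builds label sets satisfying published marginals
(per-set sizes, all-set intersection, union) exactly: allocate the common
core, give each non-core label one home (most-starved set first, shuffled
deterministically by seed), then fill remaining slots with labels kept out
of at least one set (multiplicity capped at k−1 so the planted intersection
is preserved). Infeasible constraint combinations raise errors naming the
violated inequality. Only the stated constraints are honoured; pairwise
overlaps beyond them are unconstrained.

`simulate_mock` perturbs expected fractions multiplicatively
(log-normal, σ = `noise`) and renormalises; zero noise returns the expected
fractions exactly.

## Problem sizes

The test-suite and reproduction-script problem sizes are desk scale by
construction — the survey statistics are footer arithmetic over printed
tallies, and the property checks use 25 random merge instances (≤ 5 primer
sets × 50 taxa), 10 degenerate-matcher instances (300 nt references,
degeneracy ≤ 256), a 56-taxon synthetic survey, and 60-replicate mock
noise grids. Everything runs in seconds on one CPU.

## Known limitations

* Greengenes 7-rank lineage dialect only; SILVA/RDP dialects are not
  parsed.
* The candidate-name list is configurable but necessarily incomplete.
* Merging by taxonomy label cannot resolve taxa that different regions
  assign to different names; the combined tallies are therefore
  conservative at lower ranks.
* The in-silico engine predicts annealing by sequence identity only.
* Heatmap/PCA plotting is out of scope; the comparison module returns the
  matrices, scores and trees for any plotting front end.
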