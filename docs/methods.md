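# Methods

## Scope and model

`ssrmine` treats an SSR as a *perfect* tandem repeat: a maximal run of a
primitive motif (1–6 bp by default, longer allowed) with no interrupting
substitutions, indels or ambiguous bases. A *candidate polymorphic SSR
marker* between two assemblies is a pair of loci, one per assembly, with
the same motif, mutually conserved flanking sequences, and flanks that are
single-copy within their own assembly. Polymorphism is defined purely by
repeat-count difference; with equal motifs this is equivalent to an SSR
length difference, which is what a PCR product-length assay detects.

## Mining

The scanner compiles one regular expression alternating over all enabled
classes, shortest motif first, e.g. `([ACGT]{1})\1{9,}|([ACGT]{2})\2{6,}|…`
for the defaults. Shortest-first branch order plus a primitivity filter
guarantees a run is attributed to its primitive period: a match whose
motif is itself a repetition of a shorter unit (e.g. `AA`, `ATAT`) is
discarded — reducing it to the shorter unit would either duplicate a locus
already reported by the shorter class or report a locus that fails the
shorter class's repeat threshold.

After each successful match the scan position backtracks by *B* bases
(formula in the README) so that an adjacent repeat sharing boundary bases
with the previous match is still seen. Backtracked rescans can land
*inside* a run rather than at its start (runs of different periods may
overlap by a few bases more than *B* in rare double-periodicity
configurations), so each match is re-extended in both directions along its
period before reporting; together with deduplication by
`(seq_id, start, end, motif)` and removal of same-period nested intervals,
the reported set equals the set of maximal runs. The test suite verifies
this equivalence against an independent run-enumeration oracle on
thousands of repeat-rich random sequences.

Trailing partial units are trimmed (`AGAGA` is `AG`×2), `N` breaks every
run, and coordinates are 1-based inclusive. Loci separated by at most
`compound_gap` bp (default 0, i.e. directly adjacent or overlapping by a
shared boundary base) share a compound id.

### Fragmentation

Sequences longer than `frag_size + overlap` (defaults 500 kb + 5 kb) are
scanned in windows of `frag_size` plus an `overlap` lookahead. A window
owns the loci starting within its first `frag_size` bases. A locus
reported at an interior window start whose run continues leftward in the
full sequence is a partial re-detection owned by the previous window and
is dropped. A locus that cannot be proven right-maximal inside its window
is checked against the full sequence; if its run truly continues past the
window, it is reported truncated with a `RuntimeWarning` — this happens
only when a locus is longer than the overlap, which is the documented
limit of the fragmentation scheme (raise `--overlap` for extreme repeats).

### Parallel work allocation

Sequences are distributed over workers with the longest-processing-time
greedy: sort by length descending (stable, so equal lengths keep input
order), seed each worker with one of the longest sequences, then always
hand the next sequence to the least-loaded worker (lowest index on ties).
Ties are fixed deterministically because the plan feeds reproducible
output. Workers are OS processes; results are re-sorted afterwards, so
output is bit-identical to a serial run for any worker count. The suite
checks the greedy's makespan against an exhaustive-partition optimum
(within the classic 4/3 factor) on small instances.

## Flank conservation

Flanks of `flank_len` bp (*f*, default 100) are taken immediately left and
right of each locus. Loci whose flank would run past a sequence end or
contain `N` are excluded from marker development: such flanks cannot
anchor a primer nor be matched reliably.

* **Stage 1 (exact):** the concatenation `left+right` keyed with the motif
  is hashed; keys occurring once in each assembly form pairs with identity
  1.0. A key occurring more than once within either assembly is ambiguous
  and falls through to the later stages (and ultimately to the uniqueness
  filter).
* **Stage 2 (pre-alignment):** only the `p = ceil(f·x/100)` bp nearest the
  SSR on each side (default 5% → 5 bp; 8 bp at f=150) are compared,
  allowing at most 2 mismatches in total. The implementation indexes every
  masked variant of each near-key with up to 2 wildcard positions; two
  keys at Hamming distance d share the variant masking exactly their d
  differing positions, so the output provably equals the all-pairs Hamming
  filter (tested against that oracle) at hash-join cost.
* **Stage 3 (verification):** each side is scored with the full-table
  Levenshtein distance (`LD/f ≤ threshold`, default 0.05) or
  Needleman–Wunsch identity (`matches/columns ≥ 1 − threshold`, default
  scheme +1/−1/−2). Both sides must pass individually — a single divergent
  side would break a primer site, and scoring the concatenation would
  dilute it. `N` matches nothing, not even another `N`. The NW traceback
  breaks ties diagonal > up > left so the reported identity is
  deterministic. If a locus survives in several pairs, only its best pair
  (highest mean identity) is kept; exact ties are ambiguous and drop all
  of that locus's pairs. The suite checks both programs exhaustively
  against independent DP oracles on all two-letter strings up to length 8,
  and Levenshtein against edlib on flank-sized strings.

## Flank uniqueness

Every substring of length *f* of an assembly (step 1 bp, forward strand;
`--check-revcomp` adds reverse-complement counting) is counted. A pair is
kept only if its four flanks each occur exactly once in their own
assembly. `time_saving` materialises the full count table; `memory_saving`
keeps only the sequences and answers query batches by streaming one pass
per 2-bp-prefix partition of the query set. The two modes return identical
counts by construction and byte-identical pipelines by test.

## Synthetic assembly pairs

The generator is the package's test bed and a first-class module. Each
sequence is laid out as alternating background gaps and planted repeats.
Defaults model a small but realistic marker-development experiment: one
200-kb sequence, 50 loci, motif lengths weighted toward di-/tri-/tetra-
(5/30/25/20/10/10%), repeat counts 1–7 above the mining threshold, 40%
polymorphic with repeat-count edits of 1–3 units, and a 1%-per-bp flank
substitution rate in the second assembly — below the 5% conservation
threshold in expectation, so nearly all planted markers should survive.

Construction guarantees, by rejection sampling and explicit border
breaking, that planted coordinates are exact and flanks are repeat-free:
gaps are regenerated if they contain any run within one repeat of the
default thresholds, and the bases bordering each planted repeat are forced
to break it. Confounder classes are planted on disjoint loci: a copy of
the left flank pasted into shared background (must fail uniqueness), more
substitutions than the threshold allows placed outside the pre-alignment
window (must fail verification), and exactly 3 substitutions inside the
pre-alignment windows with otherwise identical flanks (must fail
pre-alignment). Every truth record's expected fate is derived from the
realized edits — verified with the same Levenshtein definition the
alignment tests validate independently — so the truth table is exact
regardless of the random draws.

What the generator does *not* emulate: indels in flanks, structural
variation, transposable-element landscapes, sequencing error, or
base-composition heterogeneity. Passing the end-to-end tests therefore
shows the pipeline implements its stated filters exactly on substitution-
divergent assemblies, not that real assemblies of a given divergence will
yield any particular marker rate. Accidental repeats can still arise in
background far from planted loci; they flow through the pipeline normally
but are outside the truth table, so evaluation counts them separately and
scores sensitivity/precision over planted loci only.

## Numerical and design choices

* Canonical motif = the primitive unit as it appears at the locus start;
  no reverse-complement or rotational normalisation on loci themselves
  (orientation is needed for flank extraction). Statistics pool motifs by
  lexicographically smallest rotation; reverse-complement pooling is
  opt-in, keeping AG and CT distinct by default.
* Non-ACGTN input characters (IUPAC codes) are mapped to `N` with a
  warning rather than aborting; `N` is already excluded from repeats and
  flanks downstream.
* Pairing requires identical motifs (`--require-same-motif`, default on):
  a marker amplifies the same locus in both genotypes, and the repeat
  count difference is the polymorphism signal.
* Summary rates are percentages of all SSRs mined in assembly 1:
  candidate rate = candidates/total₁·100, polymorphic rate =
  polymorphic/total₁·100.
* Stage-3 threshold comparisons use a 1e-12 slack so identities like
  0.95 computed as 1 − 5/100 are not lost to floating-point rounding.
* Problem sizes in the tests and acceptance script (sequences up to 5 kb
  for oracle equivalence, a 1.2-Mb fragmentation fixture, 120–200-kb
  synthetic assemblies with 30–50 loci) are chosen so each property is
  exercised at the scale where its failure modes appear — fragment
  boundaries, overlapping runs, confounder classes — while the whole suite
  stays quick to run.

## Known limitations

* Imperfect/interrupted SSRs are out of scope by design.
* A locus longer than the fragmentation overlap is truncated (warned).
* The uniqueness index counts the forward strand by default; a flank whose
  reverse complement occurs elsewhere passes unless `--check-revcomp`.
* The backtracking scan's equivalence to the maximal-run oracle relies on
  the re-extension step; the raw resume heuristic alone can clip a run's
  first base in rare double-periodicity overlaps.
* Primer design, e-PCR simulation, and >2-assembly comparisons are not
  implemented.
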