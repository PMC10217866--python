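# Methods

## The detection model

Imprinting control regions (ICRs) that depend on ZFP57 carry clusters of
its binding hexamer, and in the large majority of characterized loci those
hexamers occur inside composite elements in which the binding site
(ZFBS, `TGCCGC`) overlaps a CpG-rich MLL1/MLL2 morpheme ("ZFBS-morph
overlaps", ≥ 2 CpGs per word). The hexamer alone is short (k = 6,
expected once per 4⁶ ≈ 4 kb per strand in random DNA) and therefore
uninformative on its own; the composite words are both longer and
CpG-dense, so they are rare in bulk DNA — clusters of them mark candidate
ICRs.

`icrscan` implements the resulting decision rule:

- scan for exact occurrences of the word sets on both strands;
- count overlap-element occurrences in a sliding window of **850 bases**;
- **discard isolated occurrences** (density suppression of count-1
  windows);
- report each surviving cluster as a peak classified **robust** when it
  encompasses ≥ 3 elements and **weak** at exactly 2. Weak peaks may be
  true or false positives; robust peaks are the candidate-ICR calls.

No statistical significance is attached to peaks; the method is a
deterministic rule whose constants (850-base window, ≥ 2 CpG motif class,
robust threshold 3) are part of its definition.

## Scanning semantics

- Exact string match over {A, C, G, T}; any IUPAC ambiguity code becomes
  `N` at FASTA ingestion and never matches. Soft-masked (lowercase) bases
  are uppercased and scanned: the method defines no repeat-masking rule,
  and isolated-hit suppression is its noise filter.
- Both strands are covered by one forward pass over a
  complement-expanded motif set; a complement-origin motif match is a
  minus-strand hit. This is provably equivalent to scanning both sequence
  orientations and is tested by a coordinate-mirror property.
- All overlapping and self-overlapping occurrences are reported.
- A word and its reverse complement can match the identical interval
  (palindromes); `dedupe_hits` collapses identical intervals so one
  genomic element counts once in the density. The collapse is on by
  default and can be disabled (`--no-dedupe`) for raw per-motif track
  parity.

## Composite-word generation

`generate_overlap_motifs` enumerates every placement of a morpheme
against a ZFBS word whose overlap spans ≥ `min_overlap` bases (default 1
— any overlap qualifies; containment counts as overlap with length equal
to the contained word) and whose overlapping letters agree, emitting the
shortest superstring of each compatible placement. Merged words with
fewer than two CpGs are excluded: the ≥ 2-CpG property is the definition
of the class, so even a degenerate full self-overlap of the 1-CpG hexamer
yields nothing. Distinct derivations of the same word are kept as
provenance in the motif id. Correctness is checked against an exhaustive
superstring-construction oracle on random word pairs.

The packaged word lists under `src/icrscan/data/` are **synthetic
stand-ins** (the published composite-element list is not redistributed
here); they are plain editable text files, and every pipeline entry point
accepts user-supplied lists. No test depends on their membership.

## Density, suppression and peak calling

Two equivalent formulations are used:

- `window_counts` produces the exportable density: windows at starts
  0, step, 2·step, … (trailing partial window included), counting hit
  *start* positions per window, with per-window counts of exactly 1 set
  to 0. The default export step is 85 bases (window/10), a compromise
  between wiggle file size and positional resolution; counts use hit
  starts so each hit belongs to exactly one window per placement.
- `call_peaks` realizes the step-1 limit directly by chaining: sorted
  hits whose consecutive starts differ by ≤ window join one cluster;
  singleton clusters are the isolated occurrences and are discarded;
  a cluster may chain across more than one window length in total span
  and is kept as a single peak. Peak extent is the hull of member hits,
  so "a peak encompasses k elements" is literally true of the reported
  interval.

Boundary note: two hits whose starts differ by *exactly* the window
length are chained into one peak, although no single window of that
length contains both starts. The chaining definition ("within `window`
bases") was chosen as the contract; the equivalence between suppression
in step-1 window counts and singleton clusters therefore holds everywhere
except at that one-base boundary, and the property test excludes exactly
that tie. Enlarging the window can also *create* peaks by chaining
previously isolated hits — cluster count is monotone in the window, peak
count is not.

## Synthetic genomes

`simulate_genome` emulates only what the tests need: i.i.d. background at
a chosen GC fraction with planted exact word copies — clusters of
n ≥ 2 copies inside a span ≤ window, and isolated single copies — all
pairwise separated by more than `min_separation` bases (default 5001,
i.e. > 5 kb of background between element hulls; it must exceed the
window so distinct elements cannot chain). Background is
rejection-scrubbed: any chance occurrence of the planted word or its
reverse complement outside the planted intervals is resampled until none
remain, so the ground truth is exact and a seeded run is bit-identical.
All randomness flows from one explicit seed.

What it deliberately does not model: isochore/GC heterogeneity, CpG
islands, repeats, and co-occurrence of *different* overlap words.
Passing end-to-end tests therefore demonstrate the correctness of the
scanning/suppression/classification logic, not the biological error rate
of the method on real chromosomes — on real DNA, weak (2-element) peaks
in particular may be false positives, as the rule itself acknowledges.

## Defaults and tunables

| parameter | default | meaning |
|---|---|---|
| `window` | 850 b | sliding-window length; the method's constant |
| `wig_step` | 85 b | window start spacing in the exported wiggle |
| `robust_min` | 3 | minimum elements for a robust peak |
| `min_overlap` | 1 b | minimum ZFBS/morpheme overlap in generation |
| `radius` | 10 kb | gene-annotation radius around a peak hull ("vicinity" is not quantified by the rule; 10 kb spans typical promoter-proximal regulatory distance and is configurable) |
| `dedupe` | on | collapse identical-interval strand duplicates |
| `min_separation` | 5001 b | background gap between planted elements |

Coordinates are 0-based half-open internally; BED output is 0-based
half-open and wiggle 1-based, per UCSC conventions, with the conversions
confined to the writers and covered by round-trip tests.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run on synthetic chromosomes
of 60–250 kb with 1–5 planted clusters (sizes 2–6) plus isolated sites,
20 replicate seeded end-to-end runs, 200-pair scanner-vs-oracle and
peak-caller-vs-oracle randomized suites, and one 1 Mb uniform-sequence
hit-frequency sanity check. These sizes exercise every code path —
scanning is linear in sequence length, so behaviour at chromosome scale
(~10⁸ b) differs only in runtime; the CLI streams one chromosome at a
time to keep memory flat.

## Known limitations

- Exact-match words only; no PWM or mismatch tolerance, and methylation
  state is represented only implicitly (the words are the unmethylated
  forms).
- Peak calls carry no significance estimate or truth-set benchmark.
- The shipped composite-word list is a stand-in; genome-scale results
  depend on supplying a published list.
- GFF3 gene extraction reads `gene` features and the `Name`/`ID`
  attributes only; exotic GFF3 dialects may need pre-processing.
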