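# Methods

## Model and procedure

`tilecall` assumes the targeted-resequencing regime: reads and references
are short (~100–5000 bp), each read derives from one known reference
amplicon, and differences between read and reference are sparse — isolated
substitutions and block indels, occasionally clustered. Under these
assumptions exact string matching over a sparse word tiling is both a
filter and a locator: identical sequence is excluded from further analysis,
and what remains provably contains every mutation.

### Index

Both strands of each reference are tiled with words of length `w` starting
at offsets 0, δ, 2δ, …. The spacing is uniform (δ between consecutive
starts); with δ ≤ w the word intervals cover every base, which is the
guarantee that any mutation breaks at least one word. If the final tiling
position would leave a tail shorter than `w`, the tail is appended to the
previous word, producing one longer terminal word rather than an
unreliable short probe. A word whose sequence occurs at more than one
position of its strand is repeat-flagged. Word count is bounded by
l − w + 1, attained at δ = 1. Coordinates are 0-based half-open
internally; reported mutation positions are 1-based.

The reverse-complement index stores offsets in the rc-strand frame. It is
used only to decide read orientation: a read assigned to the reverse
strand is reverse-complemented and analyzed against the forward index, so
every reported coordinate is forward-frame.

### Read screening

Demultiplexing is exact: a read is accepted only with an intact,
mismatch-free MID — as a 5′ prefix, or (reverse-strand reads) its reverse
complement as a 3′ suffix; paired mode requires both MIDs of one sample
row in either orientation. Exactness is deliberate: barcodes identify
patients, and the cost of a dropped read is far below the cost of a
misassigned one. Reads are kept when strictly longer than
`min_read_length` (default 80 bp) and sharing at least `min_shared_words`
(default 5) indexed words with the best (reference, strand) pair; ties go
to reference input order, forward strand first.

### Region location

Every indexed word is searched in the read with a recursive-restart exact
substring scan that reports all (possibly overlapping) occurrences.
Choosing *which* occurrence represents each word matters in repeats: a
mutation inside the second copy of a repeat must not be masked by the
first copy still matching (and a deletion of one repeat unit makes two
reference copies compete for one read copy). The locator therefore solves
a small weighted longest-increasing-subsequence problem over all
(word, occurrence) candidates: chained words must have strictly increasing
read offsets, words whose reference intervals overlap must agree on the
same offset shift, disjoint words need a non-negative read gap, and among
maximal chains the one with the least total |shift change| wins. For
non-repetitive references (every word unique, one occurrence each) the
chain is trivial and the solver short-circuits.

Each maximal run of unmatched words between chained words becomes one
polymorphic region; runs at the read's ends become unanchored regions.
Inconsistent evidence (a region whose paired intervals invert) marks the
read unalignable rather than forcing a call.

### Calling

For each region, the longest common prefix *p* and suffix *s* of the
paired segments are computed (with p + s capped at the shorter length;
trimming the overlap at the suffix side is equivalent to left-alignment).
Equal-length segments with one mismatch are a substitution; a length
difference fully explained by p + s is one block deletion or insertion,
with no size limit. Any residual mismatch within `w` bases of a simple
mutation makes the region complex (for two adjacent substitutions the
region spans up to 2w + δ — 35 bp at the defaults — which keeps the DP
cheap). Mismatches farther apart than `w` in one region are called as
independent substitutions.

Complex interior regions are aligned with affine-gap Needleman–Wunsch
(Gotoh; a gap of length L costs open + L·extend). Default scores are the
EMBOSS-style match 8 / mismatch −2 / open −7 / extend −1, configurable.
Tie-breaking is deterministic: substitution columns over gaps, gaps in the
read over gaps in the reference, resolved along the high road.

Terminal (unanchored) regions would be misserved by both plain global and
plain local alignment: global alignment turns a truncated read's missing
reference into a giant spurious deletion, while purely local
(Smith–Waterman) alignment may trim a genuine substitution at the read's
first base or wander off-diagonal and fabricate indel pairs. The pipeline
instead aligns terminal regions semiglobally — the read fully aligned, the
reference overhang at the unanchored edge free — and reports the overhang
as truncation, never as a mutation. A Smith–Waterman implementation is
retained in the library (`align_sw`) for local-alignment use. On the
simple path the same principle applies: a deletion whose equivalent
placements reach the unanchored reference edge has no read support
distinguishing it from truncation and is reported as truncation.

All indels are left-aligned (shifted to the smallest reference coordinate
yielding the same alternate sequence), the dominant normalization
convention; within one alignment the shift is floored at the previous
call's end so calls never overlap. Names follow the amplicon-local
HGVS-style forms `<pos><ref>><alt>`, `<pos>del<seq>`, `<pos>ins<seq>`;
complex regions are reported as their constituent edits joined in
coordinate order. (Strict HGVS would write a multi-base deletion as a
range, e.g. `137_152del`; the spelled-out form matches diagnostic
reporting practice and is kept deliberately.)

### Reporting

The aggregate table has one row per distinct (sample, reference, mutation):
percent of the pair's assigned reads carrying it, forward/reverse tallies
(their sum is the mutation count — a read with k mutations contributes to
k rows), total reads, and an annotation column carrying the full name when
the variant sequence exceeds 5 nt and the mutation column shows only its
length. Wild-type reads enter the denominators but get no row.

## Synthetic data

The generator emulates the evaluation conditions end to end:

- **Exon-like references**: seeded random 225 bp sequences, regenerated
  until all w-mers are unique, so the index carries no repeat flags — the
  typical diagnostic amplicon. A variant plants the worked-example hotspot
  layout (C at position 128; `GGAATTAAGAGAAGCA` at 137–152 with a non-A
  base before it so the deletion name cannot shift).
- **Planted mutations**: substitutions are uniform over positions and
  always change the base (alternate drawn from the three other bases);
  block indels are uniform over valid interior positions. Ground truth is
  emitted in the caller's own convention (1-based, left-aligned) and reads
  are produced by applying the truth to the reference, so truth fidelity
  holds by construction.
- **Complex clusters**: two substitutions plus a 4 bp deletion inside one
  15 nt window, guaranteeing the DP path.
- **Repeat region**: a ~200 bp analog of the prion octapeptide repeat —
  five 24 bp units R1-R2-R2-R3-R4 with R2 in two identical copies and
  R1/R3/R4 each one substitution from R2, inside 40 bp unique flanks —
  plus a 24 bp-deletion allele (one R2 removed) and a 48 bp-insertion
  allele R1-R2-R2′-R2-R2′-R3-R4 with R2′ one substitution from R2. Because
  R2′ differs from R2, the minimal representation of the insertion allele
  against the wild type is two 24 bp unit insertions (net +48), and that
  is what the caller reports.
- **Barcoding**: optional MID prefixes and a configurable
  reverse-complement fraction (reverse reads carry the MID's reverse
  complement at the 3′ end).

Three deliberate restrictions, and what they mean for interpreting green
tests: indels are planted only where *every* equivalent (left/right-
shifted) placement keeps at least one flanking reference base — an indel
flush with an amplicon terminus is observationally identical to a
truncated or shorter amplicon, so "detection" there is undefined; complex
windows keep a full word length of intact flank for the same reason; and
no sequencing-error model is simulated (the evaluation datasets contain
only planted mutations). Detection rates of 100% on this data therefore
demonstrate the algorithm's exactness on clean reads of the stated mutation
classes; they say nothing about homopolymer noise, PCR chimeras or
quality-dependent errors in real instrument data.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `w` | 15 bp | word length; also the complex-mutation window flank |
| `delta` | 5 bp | tiling shift; δ ≤ w guarantees coverage |
| `min_shared_words` | 5 | minimum indexed words shared with a reference |
| `min_read_length` | 80 bp | reads must be strictly longer |
| DP scores | 8 / −2 / −7 / −1 | match / mismatch / gap open / gap extend |

`w` and δ trade index size against region length; the defaults suit
~200 bp exon reads and remain sound up to a few kb. Detection accuracy is
insensitive to them — every mutation still breaks a word as long as δ ≤ w.

## Problem sizes and determinism

The evaluation suites and `scripts/acceptance.py` use 10,000 reads per
dataset — detection rate is a per-read property, so it is scale-invariant
— and complete in seconds on one CPU. All randomness flows from explicit
seeds (numpy `default_rng`); the analysis path itself contains none, and
re-running a pipeline on identical inputs is byte-identical.

## Known limitations

- Mutations inside the MID itself reject the read (exact barcoding).
- An insertion before the first reference base cannot be expressed in the
  `<pos>ins` convention and is reported as an unaligned tail.
- Reference-assignment ties are resolved by input order, which is
  arbitrary for duplicated references.
- Very repetitive references (dominant homopolymer runs) inflate the
  occurrence lists and the chain-selection cost; amplicon-scale inputs
  keep this negligible.
- SAM/BAM and VCF output are out of scope; the tabular per-read and
  aggregate formats are the interface.
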