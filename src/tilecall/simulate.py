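"""Synthetic amplicon data generation with exact ground truth.

The generator emulates the evaluation conditions of targeted amplicon
resequencing: short (~225 bp) non-repetitive exon-like references carrying
randomly placed substitutions and single/block indels; a ~200 bp repeat
region built from five 24 bp near-perfect repeat units (structure
R1-R2-R2-R3-R4, with R2 in two identical copies) together with its 24 bp
deletion and 48 bp insertion alleles; and optionally barcoded read sets with
a configurable reverse-complement fraction.

Reads are produced by applying the ground-truth edits to the reference, so
ground-truth fidelity (truth applied to reference == read) holds by
construction.  Truth calls use the same normalized convention as the caller:
1-based forward coordinates, left-aligned indels.  Indels are planted
strictly inside the amplicon (at least one flanking reference base), since an
indel flush with an amplicon end is indistinguishable from a shorter or
truncated amplicon.  No sequencing-error model is added: the simulated data
contain only the planted mutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .calling import MutationCall, apply_calls, left_normalize
from .dna import revcomp

BASES = "ACGT"

IndelKind = Literal["insertion", "deletion"]
Placement = int | None  # fixed 1-based position, or None for random


@dataclass(frozen=True)
class IndelSpec:
    kind: IndelKind
    length: int
    position: Placement = None  # 1-based ref position (see MutationCall)
    sequence: str | None = None  # fixed inserted sequence (insertions only)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("indel length must be >= 1")


@dataclass(frozen=True)
class MutationSpec:
    """What to plant in each simulated read."""

    n_substitutions: int = 0
    indels: tuple[IndelSpec, ...] = ()
    substitution_positions: tuple[int, ...] | None = None  # fixed, 1-based
    substitution_alts: tuple[str, ...] | None = None


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _has_repeated_words(seq: str, w: int) -> bool:
    words = [seq[i : i + w] for i in range(len(seq) - w + 1)]
    return len(set(words)) != len(words)


def make_reference(
    length: int = 225,
    seed: int | np.random.Generator = 0,
    *,
    name: str = "amplicon",
    w: int = 15,
) -> "ReferenceRecord":
    """A seeded random non-repetitive reference (all w-mers unique).

    Emulates a typical exon amplicon, where the tiling index contains no
    repeat-flagged words.
    """
    from .index import ReferenceRecord

    rng = _rng(seed)
    for _ in range(100):
        seq = _random_seq(rng, length)
        if not _has_repeated_words(seq, w):
            return ReferenceRecord(name, seq)
    raise RuntimeError("could not generate a non-repetitive reference")


def make_egfr_like_reference(
    seed: int | np.random.Generator = 0, *, name: str = "exon_amplicon"
) -> "ReferenceRecord":
    """A 225 bp reference carrying the worked-example mutation context.

    Position 128 (1-based) is a C, and the 16-mer GGAATTAAGAGAAGCA sits at
    positions 137-152 with a non-A base at 136 so that deleting it yields the
    unambiguous left-aligned call 137delGGAATTAAGAGAAGCA.  This mirrors the
    EGFR exon 20 point-mutation / exon 19 deletion hotspot layout used in
    lung-cancer amplicon panels.
    """
    from .index import ReferenceRecord

    rng = _rng(seed)
    motif = "GGAATTAAGAGAAGCA"
    for _ in range(100):
        seq = list(_random_seq(rng, 225))
        seq[127] = "C"  # 1-based 128
        seq[136 : 136 + len(motif)] = motif  # 1-based 137..152
        if seq[135] == motif[-1]:  # would left-shift the deletion call
            seq[135] = "C"
        candidate = "".join(seq)
        if not _has_repeated_words(candidate, 15):
            return ReferenceRecord(name, candidate)
    raise RuntimeError("could not generate the worked-example reference")


def _deletion_interior(ref: str, d: int, k: int) -> bool:
    """True if no equivalent placement of deleting ref[d:d+k] touches an end.

    A deletion inside a repeat slides left/right over equivalent positions;
    if any equivalent placement is flush with the amplicon terminus the read
    is indistinguishable from a truncated or shorter amplicon, so such
    placements are not planted.
    """
    lo = d
    while lo > 0 and ref[lo - 1] == ref[lo + k - 1]:
        lo -= 1
    hi = d
    while hi + k < len(ref) and ref[hi + k] == ref[hi]:
        hi += 1
    return lo >= 1 and hi + k <= len(ref) - 1


def _insertion_interior(ref: str, g: int, seq: str) -> bool:
    """True if no equivalent placement of the insertion reaches an end."""
    lo, s = g, seq
    while lo > 0 and s[-1] == ref[lo - 1]:
        s = ref[lo - 1] + s[:-1]
        lo -= 1
    hi, s = g, seq
    while hi < len(ref) and s[0] == ref[hi]:
        s = s[1:] + ref[hi]
        hi += 1
    return lo >= 1 and hi <= len(ref) - 1


def _call_interval(call: MutationCall) -> tuple[int, int]:
    """0-based half-open reference interval occupied by a call."""
    p = call.ref_position - 1
    if call.kind == "substitution":
        return (p, p + 1)
    if call.kind == "deletion":
        return (p, p + len(call.ref_allele))
    return (p + 1, p + 1)  # insertion sits between p and p+1


def _intervals_clear(intervals: list[tuple[int, int]], margin: int = 1) -> bool:
    """True if 0-based intervals are pairwise separated by >= margin bases."""
    ordered = sorted(intervals)
    return all(
        b_start - a_end >= margin
        for (_, a_end), (b_start, _) in zip(ordered, ordered[1:])
    )


def mutate_read(
    reference: "ReferenceRecord",
    spec: MutationSpec,
    seed: int | np.random.Generator = 0,
) -> tuple[str, list[MutationCall]]:
    """Plant the specified mutations into one read.

    Substitutions always change the base (drawn uniformly from the three
    non-identical bases); random placements are uniform over the valid
    positions.  Planted edits are pairwise separated by at least one matching
    base so that each keeps its own identity in the ground truth.

    Returns ``(read, truth_calls)`` with truth in the normalized (1-based,
    left-aligned) convention.
    """
    rng = _rng(seed)
    ref = reference.sequence
    l = len(ref)
    for indel in spec.indels:
        if indel.length >= l:
            raise ValueError("indel longer than the reference")
    for _ in range(1000):
        calls: list[MutationCall] = []
        intervals: list[tuple[int, int]] = []
        if spec.substitution_positions is not None:
            positions = [p - 1 for p in spec.substitution_positions]
        else:
            positions = sorted(
                int(p) for p in rng.choice(l, size=spec.n_substitutions, replace=False)
            )
        for idx, p in enumerate(positions):
            if spec.substitution_alts is not None:
                alt = spec.substitution_alts[idx]
            else:
                alt = rng.choice([b for b in BASES if b != ref[p]])
            calls.append(MutationCall("substitution", p + 1, ref[p], str(alt)))
            intervals.append((p, p + 1))
        placement_ok = True
        for indel in spec.indels:
            k = indel.length
            if indel.kind == "deletion":
                if indel.position is not None:
                    d = indel.position - 1
                else:
                    d = int(rng.integers(1, l - k))  # strict interior
                if not _deletion_interior(ref, d, k):
                    placement_ok = False
                    break
                call = MutationCall("deletion", d + 1, ref[d : d + k], "")
                intervals.append((d, d + k))
            else:
                if indel.position is not None:
                    g = indel.position
                else:
                    g = int(rng.integers(1, l))  # after base g, 1 <= g <= l-1
                seq = indel.sequence or _random_seq(rng, k)
                if not _insertion_interior(ref, g, seq):
                    placement_ok = False
                    break
                call = MutationCall("insertion", g, "", seq)
                intervals.append((g, g))
            calls.append(call)
        if not (placement_ok and _intervals_clear(intervals)):
            continue
        truth = [left_normalize(c, ref) for c in calls]
        # left-normalization may slide an indel onto another edit; resample
        if _intervals_clear([_call_interval(c) for c in truth]):
            break
    else:
        raise RuntimeError("could not place non-overlapping mutations")
    read = apply_calls(ref, calls)
    return read, truth


def make_complex_read(
    reference: "ReferenceRecord",
    seed: int | np.random.Generator = 0,
    *,
    window: int = 15,
) -> tuple[str, list[MutationCall]]:
    """Two random substitutions plus a 4 bp deletion within a 15 nt window.

    The three edits fall inside one randomly placed window, guaranteeing the
    region is classified complex and resolved by dynamic programming.  The
    window is placed so that reference sequence of at least one word length
    flanks it on both sides: a complex cluster flush with a read terminus is
    confounded with read truncation and is not an interior complex mutation.
    """
    rng = _rng(seed)
    ref = reference.sequence
    l = len(ref)
    if l < 50:
        raise ValueError("reference must be at least 50 bp")
    margin = 15  # keep >= one word length of intact flank on both sides
    for _ in range(1000):
        start = int(rng.integers(margin, l - window - margin + 1))
        d = int(rng.integers(start, start + window - 4 + 1))
        subs = sorted(
            int(p) for p in rng.choice(range(start, start + window), 2, replace=False)
        )
        intervals = [(d, d + 4), (subs[0], subs[0] + 1), (subs[1], subs[1] + 1)]
        if not _intervals_clear(intervals, margin=2):
            continue
        calls = [
            MutationCall("deletion", d + 1, ref[d : d + 4], ""),
        ]
        for p in subs:
            alt = rng.choice([b for b in BASES if b != ref[p]])
            calls.append(MutationCall("substitution", p + 1, ref[p], str(alt)))
        truth = [left_normalize(c, ref) for c in calls]
        if not _intervals_clear([_call_interval(c) for c in truth]):
            continue
        spans = [_call_interval(c) for c in truth]
        if max(e for _, e in spans) - min(s for s, _ in spans) > window:
            continue  # normalization drifted an edit out of the window
        read = apply_calls(ref, calls)
        return read, truth
    raise RuntimeError("could not place a complex mutation window")


@dataclass(frozen=True)
class RepeatRegionSpec:
    """The prion-like octapeptide repeat region analog.

    Five 24 bp near-perfect repeat units in structure R1-R2-R2-R3-R4 with R2
    in two identical copies and R1/R3/R4 each one substitution away from R2,
    flanked by short unique sequence.  Alleles: the wild type, a 24 bp
    deletion of one R2 copy, and a 48 bp insertion giving
    R1-R2-R2'-R2-R2'-R3-R4 where R2' differs from R2 by one substitution.
    """

    unit_length: int = 24
    flank_length: int = 40
    allele: Literal["wild_type", "deletion_24bp", "insertion_48bp"] = "wild_type"
    seed: int = 0


def make_repeat_reference(spec: RepeatRegionSpec) -> "ReferenceRecord":
    from .index import ReferenceRecord

    rng = np.random.default_rng(spec.seed)
    u = spec.unit_length

    def variant_of(unit: str, pos: int) -> str:
        alt = str(rng.choice([b for b in BASES if b != unit[pos]]))
        return unit[:pos] + alt + unit[pos + 1 :]

    r2 = _random_seq(rng, u)
    # divergent positions distinct so the variants are pairwise distinct
    pos = rng.choice(u, size=4, replace=False)
    r1 = variant_of(r2, int(pos[0]))
    r3 = variant_of(r2, int(pos[1]))
    r4 = variant_of(r2, int(pos[2]))
    r2p = variant_of(r2, int(pos[3]))
    flank5 = _random_seq(rng, spec.flank_length)
    flank3 = _random_seq(rng, spec.flank_length)
    structures = {
        "wild_type": [r1, r2, r2, r3, r4],
        "deletion_24bp": [r1, r2, r3, r4],
        "insertion_48bp": [r1, r2, r2p, r2, r2p, r3, r4],
    }
    units = structures[spec.allele]
    seq = flank5 + "".join(units) + flank3
    return ReferenceRecord(f"repeat_region_{spec.allele}", seq)


@dataclass(frozen=True)
class SimulatedDataset:
    reads: list[tuple[str, str]]  # (read_id, sequence)
    truth: dict[str, frozenset[str]]  # read_id -> mutation names
    truth_calls: dict[str, tuple[MutationCall, ...]] = field(repr=False, default=None)


def make_dataset(
    reference: "ReferenceRecord",
    n_reads: int,
    spec: MutationSpec,
    seed: int | np.random.Generator = 0,
    *,
    mids: Sequence[tuple[str, str]] | None = None,
    reverse_fraction: float = 0.0,
    read_prefix: str = "read",
) -> SimulatedDataset:
    """Simulate ``n_reads`` independent mutated copies of the reference.

    When ``mids`` (a list of (mid_name, mid_sequence)) is given, each read is
    prefixed with a randomly chosen MID; reverse-strand reads (a
    ``reverse_fraction`` share) are emitted as the reverse complement of the
    barcoded read, i.e. with the MID's reverse complement at the 3' end.
    """
    rng = _rng(seed)
    reads: list[tuple[str, str]] = []
    truth: dict[str, frozenset[str]] = {}
    truth_calls: dict[str, tuple[MutationCall, ...]] = {}
    for i in range(n_reads):
        read_id = f"{read_prefix}_{i:06d}"
        seq, calls = mutate_read(reference, spec, rng)
        if mids is not None:
            _, mid_seq = mids[int(rng.integers(0, len(mids)))]
            seq = mid_seq + seq
        if reverse_fraction > 0 and rng.random() < reverse_fraction:
            seq = revcomp(seq)
        reads.append((read_id, seq))
        truth[read_id] = frozenset(c.name for c in calls)
        truth_calls[read_id] = tuple(calls)
    return SimulatedDataset(reads, truth, truth_calls)
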