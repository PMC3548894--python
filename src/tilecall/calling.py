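"""Mutation calling inside polymorphic regions.

A region is first analyzed by character-by-character comparison
(:func:`call_simple`): a single substitution or a single block indel of any
size is identified exactly from the longest common prefix and suffix of the
reference and read segments.  If a further mismatch lies within a window of
``w`` bases of a simple mutation the region is *complex* and is handed to
dynamic programming (:func:`tilecall.align.align_nw` for interior regions,
:func:`tilecall.align.align_sw` at read termini).

All calls are reported in HGVS-style amplicon-local nomenclature with 1-based
forward-reference coordinates; indels are left-aligned (normalized to the
smallest reference coordinate yielding the same alternate sequence).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

from .align import Alignment
from .index import IndexParams

Kind = Literal["substitution", "deletion", "insertion"]

#: Sentinel returned by :func:`call_simple` when a region needs DP analysis.
COMPLEX = "complex"


@dataclass(frozen=True)
class MutationCall:
    """A typed variant call on the forward reference strand.

    ``ref_position`` is 1-based: for a substitution or deletion it is the
    first affected base; for an insertion it is the base *after which* the
    new sequence is inserted.  ``strand_observed`` records the strand of the
    read the call came from; coordinates are always forward-frame.
    ``complex_region`` marks calls recovered by dynamic programming.
    """

    kind: Kind
    ref_position: int
    ref_allele: str
    alt_allele: str
    strand_observed: Literal["forward", "reverse"] = "forward"
    complex_region: bool = False

    @property
    def name(self) -> str:
        return format_hgvs(self)

    def __post_init__(self) -> None:
        if self.ref_position < 1:
            raise ValueError("ref_position is 1-based and must be >= 1")
        if self.kind == "substitution":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("substitution alleles must be single bases")
        elif self.kind == "deletion":
            if not self.ref_allele or self.alt_allele:
                raise ValueError("deletion must have ref allele only")
        elif self.kind == "insertion":
            if self.ref_allele or not self.alt_allele:
                raise ValueError("insertion must have alt allele only")
        else:
            raise ValueError(f"unknown mutation kind {self.kind!r}")


def format_hgvs(call: MutationCall) -> str:
    """HGVS-style amplicon-local name, e.g. ``128C>T``, ``137delGGAATTAAGAGAAGCA``.

    Deletions spell out the deleted bases after ``del`` (and insertions after
    ``ins``) rather than using range syntax; this matches the tabular output
    convention of amplicon diagnostics reports.
    """
    if call.kind == "substitution":
        return f"{call.ref_position}{call.ref_allele}>{call.alt_allele}"
    if call.kind == "deletion":
        return f"{call.ref_position}del{call.ref_allele}"
    return f"{call.ref_position}ins{call.alt_allele}"


def format_calls(calls: Sequence[MutationCall]) -> str:
    """Join per-edit names in coordinate order (the name of a complex region)."""
    ordered = sorted(calls, key=lambda c: (c.ref_position, c.kind, c.alt_allele))
    return ",".join(c.name for c in ordered)


def complex_window_span(params: IndexParams) -> int:
    """Maximum span of a polymorphic region holding two adjacent simple
    mutations: ``2*w + delta`` (35 bp at the defaults w=15, delta=5).

    Two mutations closer than this end up in one region and trigger the
    dynamic-programming path.
    """
    return 2 * params.w + params.delta


def left_normalize(
    call: MutationCall, reference: str, floor: int = 0
) -> MutationCall:
    """Shift an ambiguous indel to its smallest reference coordinate.

    Standard variant normalization: a deletion (insertion) inside a repeat
    can be placed at several coordinates producing the same alternate
    sequence; the leftmost placement is canonical.  Substitutions are
    returned unchanged.  ``floor`` (0-based) stops the shift from crossing
    into a preceding call's span.
    """
    if call.kind == "substitution":
        return call
    if call.kind == "deletion":
        d = call.ref_position - 1  # 0-based start of deleted block
        k = len(call.ref_allele)
        while d > floor and reference[d - 1] == reference[d + k - 1]:
            d -= 1
        return replace(
            call, ref_position=d + 1, ref_allele=reference[d : d + k]
        )
    # insertion after 1-based position p == before 0-based offset p
    g = call.ref_position
    seq = call.alt_allele
    while g > max(floor, 0) and seq[-1] == reference[g - 1]:
        seq = reference[g - 1] + seq[:-1]
        g -= 1
    if g == 0:
        # cannot anchor an insertion before the first base; undo last shift
        g = 1
        seq = seq[1:] + reference[0]
    return replace(call, ref_position=g, alt_allele=seq)


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _common_suffix(a: str, b: str, max_len: int) -> int:
    i = 0
    while i < max_len and a[len(a) - 1 - i] == b[len(b) - 1 - i]:
        i += 1
    return i


def call_simple(
    ref_segment: str,
    read_segment: str,
    *,
    reference: str,
    ref_offset: int,
    w: int = 15,
) -> list[MutationCall] | str:
    """Character-by-character analysis of one polymorphic region.

    Parameters
    ----------
    ref_segment, read_segment
        The paired region sequences (reference side / read side).
    reference
        Full forward reference sequence, used for indel left-normalization.
    ref_offset
        0-based offset of ``ref_segment`` within ``reference``.
    w
        Word length; a further mismatch within ``w`` bases of a simple
        mutation makes the region complex.

    Returns
    -------
    list of MutationCall, or the string ``"complex"`` when the region needs
    dynamic-programming analysis.
    """
    m, n = len(ref_segment), len(read_segment)
    if m == 0 and n == 0:
        raise ValueError("empty polymorphic region: nothing to compare")
    if m == n:
        mismatches = [
            i for i in range(m) if ref_segment[i] != read_segment[i]
        ]
        if not mismatches:
            return []
        # window rule: substitutions within w of each other -> complex
        for a, b in zip(mismatches, mismatches[1:]):
            if b - a <= w:
                return COMPLEX
        return [
            MutationCall(
                "substitution",
                ref_offset + i + 1,
                ref_segment[i],
                read_segment[i],
            )
            for i in mismatches
        ]
    p = _common_prefix(ref_segment, read_segment)
    shorter = min(m, n)
    s = _common_suffix(ref_segment, read_segment, shorter)
    if p + s < shorter:
        # indel plus at least one extra mismatch inside the region; the
        # region length bounds the distance below w + delta, so treat as
        # complex and let dynamic programming resolve it
        return COMPLEX
    if p + s > shorter:
        # ambiguous placement inside a repeat: trimming the suffix is
        # equivalent to choosing the leftmost placement
        s = shorter - p
    if m > n:
        deleted = ref_segment[p : p + (m - n)]
        call = MutationCall("deletion", ref_offset + p + 1, deleted, "")
    else:
        inserted = read_segment[p : p + (n - m)]
        # inserted after the last matching prefix base (1-based ref_offset+p)
        pos = ref_offset + p
        if pos < 1:
            return COMPLEX  # insertion before the first reference base
        call = MutationCall("insertion", pos, "", inserted)
    return [left_normalize(call, reference)]


def alignment_to_calls(
    alignment: Alignment,
    ref_offset: int,
    reference: str,
) -> list[MutationCall]:
    """Convert an alignment of (reference segment, read segment) to calls.

    Mismatch columns become substitutions; each run of gaps in the read
    becomes one deletion, each run of gaps in the reference one insertion.
    Coordinates are shifted by ``ref_offset`` into the full-reference 1-based
    frame and indels are left-normalized.
    """
    a, b = alignment.aligned_a, alignment.aligned_b
    calls: list[MutationCall] = []
    ref_pos = ref_offset + alignment.a_start  # 0-based, next reference base
    floor = 0  # 0-based end of the previous call; bounds left-normalization
    i = 0
    length = len(a)
    while i < length:
        if a[i] != "-" and b[i] != "-":
            if a[i] != b[i]:
                calls.append(
                    MutationCall(
                        "substitution",
                        ref_pos + 1,
                        a[i],
                        b[i],
                        complex_region=True,
                    )
                )
                floor = ref_pos + 1
            ref_pos += 1
            i += 1
        elif b[i] == "-":
            j = i
            while j < length and b[j] == "-":
                j += 1
            deleted = a[i:j]
            call = left_normalize(
                MutationCall(
                    "deletion", ref_pos + 1, deleted, "", complex_region=True
                ),
                reference,
                floor,
            )
            calls.append(call)
            floor = call.ref_position - 1 + len(call.ref_allele)
            ref_pos += j - i
            i = j
        else:
            j = i
            while j < length and a[j] == "-":
                j += 1
            inserted = b[i:j]
            if ref_pos >= 1:
                call = left_normalize(
                    MutationCall(
                        "insertion", ref_pos, "", inserted, complex_region=True
                    ),
                    reference,
                    floor,
                )
                calls.append(call)
                floor = call.ref_position
            i = j
    return calls


def apply_calls(reference: str, calls: Sequence[MutationCall]) -> str:
    """Apply a set of calls to the reference, reconstructing the read.

    Calls must be mutually non-overlapping; they are applied right-to-left so
    coordinates stay valid.  This is the round-trip inverse of calling and is
    used both by the simulator and by consistency tests.
    """
    seq = reference
    for call in sorted(calls, key=lambda c: c.ref_position, reverse=True):
        p = call.ref_position - 1
        if call.kind == "substitution":
            if seq[p] != call.ref_allele:
                raise ValueError(f"reference mismatch applying {call.name}")
            seq = seq[:p] + call.alt_allele + seq[p + 1 :]
        elif call.kind == "deletion":
            k = len(call.ref_allele)
            if seq[p : p + k] != call.ref_allele:
                raise ValueError(f"reference mismatch applying {call.name}")
            seq = seq[:p] + seq[p + k :]
        else:  # insertion after 1-based ref_position
            seq = seq[: p + 1] + call.alt_allele + seq[p + 1 :]
    return seq
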