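"""Read screening: barcode demultiplexing and reference/strand assignment.

Multiplexed amplicon runs carry a sample-specific molecular identifier (MID)
ligated to the 5' end (single-end barcoding) or to both ends (paired).  A
read is kept only if it carries an intact -- exact, mismatch-free -- MID; the
MID bases are trimmed before alignment.  The trimmed read is then assigned to
the (reference, strand) pair sharing the most indexed words with it, and
discarded if that count falls below ``min_shared_words`` or if the read is
not longer than ``min_read_length``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

from .dna import revcomp
from .index import SubwordIndex, count_matching_words

BarcodeMode = Literal["single", "paired"]

DEFAULT_MIN_SHARED_WORDS = 5
DEFAULT_MIN_READ_LENGTH = 80


class ReadRejected(ValueError):
    """Base class for per-read screening rejections."""

    reason = "rejected"


class NoIntactMID(ReadRejected):
    reason = "no intact MID"


class ReadTooShort(ReadRejected):
    reason = "read too short"


class TooFewSharedWords(ReadRejected):
    reason = "too few shared words"


@dataclass(frozen=True)
class MultiplexTable:
    """Sample-to-barcode associations.

    ``entries`` maps sample ID to one MID name (single-end) or a
    (5' MID, 3' MID) pair from the same row (paired-end).  ``mids`` maps MID
    names to their sequences.
    """

    entries: Mapping[str, tuple[str, ...]]
    mids: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("multiplex table has no samples")
        for sample, names in self.entries.items():
            if len(names) not in (1, 2):
                raise ValueError(
                    f"sample {sample!r}: expected 1 or 2 MID names, got {names}"
                )
            for name in names:
                if name not in self.mids:
                    raise ValueError(
                        f"sample {sample!r} references unknown MID {name!r}"
                    )
        seqs = list(self.mids.values())
        if len(set(seqs)) != len(seqs):
            raise ValueError("MID sequences must be mutually distinct")


@dataclass(frozen=True)
class ReadAssignment:
    """A screened read: sample, best-matching reference and strand.

    ``trimmed`` is the read with MID bases removed, in its original
    orientation; ``strand`` is ``"reverse"`` when the read matches the
    reverse-complement strand of the reference.
    """

    read_id: str
    sample_id: str
    reference: str
    strand: Literal["forward", "reverse"]
    matched_word_count: int
    trimmed: str


def demultiplex(
    read: str, table: MultiplexTable, mode: BarcodeMode = "single"
) -> tuple[str, str]:
    """Assign a read to a sample by exact MID match and trim the MID bases.

    Single-end mode accepts the MID as an exact 5' prefix (forward-strand
    read) or its reverse complement as an exact 3' suffix (reverse-strand
    read).  Paired mode requires both MIDs of one sample row, in either
    orientation.

    Returns ``(sample_id, trimmed_read)``.

    Raises
    ------
    NoIntactMID
        If no sample's barcode(s) match exactly.
    """
    if mode == "single":
        for sample, names in table.entries.items():
            mid = table.mids[names[0]]
            if len(read) <= len(mid):
                continue
            if read.startswith(mid):
                return sample, read[len(mid) :]
            if read.endswith(revcomp(mid)):
                return sample, read[: -len(mid)]
        raise NoIntactMID("no intact MID at either read end")
    for sample, names in table.entries.items():
        if len(names) != 2:
            raise ValueError(
                f"sample {sample!r} lacks a 3' MID required in paired mode"
            )
        m5, m3 = table.mids[names[0]], table.mids[names[1]]
        if len(read) <= len(m5) + len(m3):
            continue
        if read.startswith(m5) and read.endswith(revcomp(m3)):
            return sample, read[len(m5) : -len(m3)]
        if read.startswith(m3) and read.endswith(revcomp(m5)):
            return sample, read[len(m3) : -len(m5)]
    raise NoIntactMID("no intact MID pair at the read ends")


def filter_and_assign(
    read_id: str,
    trimmed: str,
    indexes: Mapping[str, tuple[SubwordIndex, SubwordIndex]],
    *,
    sample_id: str = "all",
    min_shared_words: int = DEFAULT_MIN_SHARED_WORDS,
    min_read_length: int = DEFAULT_MIN_READ_LENGTH,
) -> ReadAssignment:
    """Assign a trimmed read to the (reference, strand) with most shared words.

    Reads are retained only if strictly longer than ``min_read_length``
    (default 80 bp) and sharing at least ``min_shared_words`` indexed words
    with the winning reference strand.  Ties are broken by reference input
    order, then forward strand first.

    Raises
    ------
    ReadTooShort, TooFewSharedWords
        On the corresponding rejection.
    ValueError
        If ``indexes`` is empty (configuration error).
    """
    if not indexes:
        raise ValueError("no reference indexes configured")
    if len(trimmed) <= min_read_length:
        raise ReadTooShort(
            f"read {read_id!r}: {len(trimmed)} bp, need > {min_read_length} bp"
        )
    best: tuple[int, str, str] | None = None  # (count, ref, strand)
    for ref_name, (fwd, rev) in indexes.items():
        for strand, ix in (("forward", fwd), ("reverse", rev)):
            count = count_matching_words(trimmed, ix)
            if best is None or count > best[0]:
                best = (count, ref_name, strand)
    assert best is not None
    count, ref_name, strand = best
    if count < min_shared_words:
        raise TooFewSharedWords(
            f"read {read_id!r}: best reference shares {count} words, "
            f"need >= {min_shared_words}"
        )
    return ReadAssignment(read_id, sample_id, ref_name, strand, count, trimmed)


def screen_reads(
    reads: Sequence[tuple[str, str]],
    indexes: Mapping[str, tuple[SubwordIndex, SubwordIndex]],
    table: MultiplexTable | None = None,
    mode: BarcodeMode = "single",
    *,
    min_shared_words: int = DEFAULT_MIN_SHARED_WORDS,
    min_read_length: int = DEFAULT_MIN_READ_LENGTH,
) -> tuple[list[ReadAssignment], list[tuple[str, str]]]:
    """Demultiplex and assign a batch of reads.

    When ``table`` is None the run is treated as unbarcoded: every read is
    assigned to the sample ``"all"`` untrimmed.

    Returns ``(assignments, rejections)`` where each rejection is
    ``(read_id, reason)``.
    """
    assignments: list[ReadAssignment] = []
    rejections: list[tuple[str, str]] = []
    for read_id, seq in reads:
        sample = "all"
        trimmed = seq
        if table is not None:
            try:
                sample, trimmed = demultiplex(seq, table, mode)
            except NoIntactMID as exc:
                rejections.append((read_id, exc.reason))
                continue
        try:
            assignment = filter_and_assign(
                read_id,
                trimmed,
                indexes,
                sample_id=sample,
                min_shared_words=min_shared_words,
                min_read_length=min_read_length,
            )
        except ReadRejected as exc:
            rejections.append((read_id, exc.reason))
            continue
        assignments.append(assignment)
    return assignments, rejections
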