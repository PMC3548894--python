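"""Sparse subword tiling index over amplicon reference sequences.

The reference is tiled with words of length ``w`` whose start positions are
spaced ``delta`` apart, on both the forward and the reverse-complement strand.
With ``delta <= w`` every reference base is covered by at least one word, so
any mutation in a read breaks at least one word and the non-matching words
localize it.  Words whose sequence occurs at more than one position of their
strand carry a repeat flag: their occurrences in a read must all be
enumerated, because the first occurrence alone can mask a mutation inside a
later repeat copy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

from .dna import find_all_occurrences, normalize, revcomp

Strand = Literal["forward", "reverse_complement"]


@dataclass(frozen=True)
class ReferenceRecord:
    """A named reference amplicon sequence (uppercase, {A,C,G,T,N})."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("reference name must be non-empty")
        object.__setattr__(self, "sequence", normalize(self.sequence))
        if not self.sequence:
            raise ValueError(f"reference {self.name!r}: sequence is empty")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class IndexParams:
    """Tiling parameters: word length ``w`` and tiling shift ``delta``.

    Defaults (w=15, delta=5) are suitable for ~100-5000 bp amplicon reads.
    ``delta <= w`` is required so that word intervals cover every base.
    """

    w: int = 15
    delta: int = 5

    def __post_init__(self) -> None:
        if not (1 <= self.delta <= self.w):
            raise ValueError(
                f"require 1 <= delta <= w, got w={self.w}, delta={self.delta}"
            )


@dataclass(frozen=True)
class IndexedWord:
    """One tiled subword: start offset on its strand, sequence, repeat flag."""

    start: int
    sequence: str
    repeat_flag: bool = False

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


@dataclass
class SubwordIndex:
    """The word list for one strand of one reference."""

    reference: ReferenceRecord
    strand: Strand
    params: IndexParams
    words: list[IndexedWord] = field(default_factory=list)

    @property
    def strand_sequence(self) -> str:
        seq = self.reference.sequence
        return seq if self.strand == "forward" else revcomp(seq)

    def __len__(self) -> int:
        return len(self.words)


def _tile_starts(length: int, params: IndexParams) -> list[int]:
    """Word start offsets 0, delta, 2*delta, ... with full-length words only."""
    return list(range(0, length - params.w + 1, params.delta))


def _tile_strand(sequence: str, params: IndexParams) -> list[IndexedWord]:
    l, w = len(sequence), params.w
    starts = _tile_starts(l, params)
    words = [IndexedWord(s, sequence[s : s + w]) for s in starts]
    # A tail shorter than w is appended to the previous word, making one
    # longer terminal word instead of a short unreliable probe.
    last_end = starts[-1] + w
    if last_end < l:
        tail_word = IndexedWord(starts[-1], sequence[starts[-1] :])
        words[-1] = tail_word
    # Repeat flagging: exact sequence occurring at >1 position on this strand.
    flagged = []
    for word in words:
        n_occ = len(find_all_occurrences(sequence, word.sequence))
        flagged.append(
            IndexedWord(word.start, word.sequence, repeat_flag=n_occ > 1)
        )
    return flagged


def build_index(
    reference: ReferenceRecord, params: IndexParams | None = None
) -> tuple[SubwordIndex, SubwordIndex]:
    """Build the (forward, reverse-complement) subword indexes of a reference.

    Reverse-complement words are stored with offsets in the rc-strand frame;
    the caller converts coordinates back to the forward frame when reporting.

    Raises
    ------
    ValueError
        If the reference is shorter than the word length ``w``.
    """
    params = params or IndexParams()
    if reference.length < params.w:
        raise ValueError(
            f"reference {reference.name!r} is shorter ({reference.length} bp) "
            f"than the word length w={params.w}"
        )
    fwd = SubwordIndex(
        reference, "forward", params, _tile_strand(reference.sequence, params)
    )
    rev = SubwordIndex(
        reference,
        "reverse_complement",
        params,
        _tile_strand(revcomp(reference.sequence), params),
    )
    return fwd, rev


def match_words(read: str, index: SubwordIndex) -> list[list[int]]:
    """Occurrence offsets of every indexed word in ``read``.

    Returns one list per indexed word (same order as ``index.words``); an
    empty list marks a non-matching word.  All occurrences are reported, not
    just the first: a repeat-flagged word legitimately occurs several times,
    and a mutation can duplicate a word that is unique in the reference.
    """
    return [find_all_occurrences(read, word.sequence) for word in index.words]


def count_matching_words(read: str, index: SubwordIndex) -> int:
    """Number of indexed words with at least one occurrence in ``read``."""
    return sum(1 for word in index.words if read.find(word.sequence) != -1)


def index_stats(indexes: Iterable[SubwordIndex]) -> list[dict]:
    """Summary rows (reference, strand, word count, repeat count) per index."""
    rows = []
    for ix in indexes:
        rows.append(
            {
                "reference": ix.reference.name,
                "strand": ix.strand,
                "length": ix.reference.length,
                "words": len(ix.words),
                "repeat_words": sum(w.repeat_flag for w in ix.words),
            }
        )
    return rows
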