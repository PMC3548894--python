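"""Locating polymorphic regions from the matched/non-matched word pattern.

Every mutation breaks the words covering it, so a maximal run of
non-matching words brackets each mutated site: the region spans from the end
of the last matching word before the run to the start of the first matching
word after it, with the corresponding read span inferred from the flanking
words' occurrence offsets.

Repeat-flagged words (and words duplicated by the mutation itself) can occur
at several read offsets; a consistent assignment is chosen by a small
dynamic program that maximizes the number of matched words subject to
strictly increasing read offsets, preferring assignments with the least
change in reference-to-read shift.  This keeps a mutation inside the second
copy of a repeat from being masked by the first copy.
"""

from __future__ import annotations

from dataclasses import dataclass

from .index import SubwordIndex


class UnalignableReadError(ValueError):
    """Raised when matched words give mutually inconsistent coordinates."""


@dataclass(frozen=True)
class PolymorphicRegion:
    """Paired reference/read intervals (0-based, half-open) around mutations.

    A side not bounded by a matching word is unanchored; unanchored regions
    touch a read terminus (truncated or mutated read end).
    """

    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    anchored_left: bool = True
    anchored_right: bool = True

    @property
    def ref_length(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def read_length(self) -> int:
        return self.read_end - self.read_start

    @property
    def anchored(self) -> bool:
        return self.anchored_left and self.anchored_right


def _select_occurrences(
    words, occ_lists: list[list[int]]
) -> dict[int, int]:
    """Choose one read offset per matching word, mutually consistent.

    Weighted longest-increasing-subsequence over all (word, occurrence)
    candidates.  Consecutive chained words must be mutually consistent:
    strictly increasing read offsets; identical shift when their reference
    intervals overlap (no mutation can fit between overlapping words); a
    non-negative read gap when disjoint.  Among maximal chains the one with
    the least total |shift change| wins (least-surprise placement, which
    keeps repeat copies from masking each other).
    """

    def compatible(i_start: int, i_len: int, i_occ: int, j_start: int, j_occ: int) -> bool:
        dref = j_start - i_start
        docc = j_occ - i_occ
        if docc <= 0:
            return False
        if dref < i_len:  # overlapping reference intervals: same shift only
            return docc == dref
        return docc >= i_len

    single = all(len(o) <= 1 for o in occ_lists)
    if single:
        chosen = {i: o[0] for i, o in enumerate(occ_lists) if o}
        matched = sorted(chosen)
        if all(
            compatible(
                words[a].start,
                len(words[a].sequence),
                chosen[a],
                words[b].start,
                chosen[b],
            )
            for a, b in zip(matched, matched[1:])
        ):
            return chosen
    cands: list[tuple[int, int, int]] = []  # (word_idx, occ, shift)
    for i, occs in enumerate(occ_lists):
        start = words[i].start
        for o in occs:
            cands.append((i, o, o - start))
    n = len(cands)
    count = [1] * n
    penalty = [0] * n
    parent = [-1] * n
    for j in range(n):
        wj, oj, sj = cands[j]
        for i in range(j):
            wi, oi, si = cands[i]
            if wi >= wj:
                continue
            if not compatible(
                words[wi].start, len(words[wi].sequence), oi, words[wj].start, oj
            ):
                continue
            c = count[i] + 1
            p = penalty[i] + abs(sj - si)
            if c > count[j] or (c == count[j] and p < penalty[j]):
                count[j], penalty[j], parent[j] = c, p, i
    if not cands:
        return {}
    best = 0
    for j in range(1, n):
        if (count[j], -penalty[j]) > (count[best], -penalty[best]):
            best = j
    chosen = {}
    j = best
    while j != -1:
        chosen[cands[j][0]] = cands[j][1]
        j = parent[j]
    return chosen


def locate_regions(
    read: str, index: SubwordIndex, occurrences: list[list[int]]
) -> list[PolymorphicRegion]:
    """Turn the word occurrence pattern of a read into polymorphic regions.

    Parameters
    ----------
    read
        Trimmed read sequence, oriented like the index strand.
    index
        The subword index of the assigned (reference, strand).
    occurrences
        Output of :func:`tilecall.index.match_words` for this read/index.

    Returns
    -------
    Ordered regions; empty when the read matches the reference word-for-word
    at consistent offsets (no mutation).

    Raises
    ------
    UnalignableReadError
        If flanking words give inverted intervals (inconsistent evidence).
    """
    words = index.words
    ref_len = index.reference.length
    chosen = _select_occurrences(words, occurrences)
    if not chosen:
        raise UnalignableReadError("no consistently matching words")
    matched = sorted(chosen)
    regions: list[PolymorphicRegion] = []

    first = matched[0]
    if words[first].start > 0 or chosen[first] > 0:
        regions.append(
            PolymorphicRegion(
                0,
                words[first].start,
                0,
                chosen[first],
                anchored_left=False,
            )
        )
    for left, right in zip(matched, matched[1:]):
        if right == left + 1 and chosen[right] - chosen[left] == (
            words[right].start - words[left].start
        ):
            continue  # consecutive matching words at a consistent shift
        ref_a, ref_b = words[left].end, words[right].start
        read_a = chosen[left] + len(words[left].sequence)
        read_b = chosen[right]
        if ref_b < ref_a or read_b < read_a:
            raise UnalignableReadError(
                "flanking words give inverted region intervals"
            )
        if ref_b == ref_a and read_b == read_a:
            continue  # nothing between the anchors
        regions.append(PolymorphicRegion(ref_a, ref_b, read_a, read_b))
    last = matched[-1]
    tail_ref = words[last].end
    tail_read = chosen[last] + len(words[last].sequence)
    if tail_ref < ref_len or tail_read < len(read):
        regions.append(
            PolymorphicRegion(
                tail_ref,
                ref_len,
                tail_read,
                len(read),
                anchored_right=False,
            )
        )
    return regions
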