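"""Small DNA string helpers shared across the package.

Sequences are plain uppercase Python strings over the alphabet {A, C, G, T, N}.
Exact string matching is the correctness guarantee of the whole pipeline, so
``N`` is treated literally: it never matches anything but itself.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def normalize(sequence: str) -> str:
    """Uppercase a sequence and validate its alphabet."""
    seq = sequence.strip().upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"invalid characters in DNA sequence: {sorted(bad)!r}")
    return seq


def revcomp(sequence: str) -> str:
    """Reverse complement of a DNA string."""
    return sequence.translate(_COMPLEMENT)[::-1]


def find_all_occurrences(haystack: str, needle: str) -> list[int]:
    """All 0-based offsets of ``needle`` in ``haystack``, in ascending order.

    This is the recursive-restart exact substring search at the heart of the
    aligner: after a hit at offset ``p`` the search resumes at ``p + 1``, so
    overlapping occurrences are all reported.

    >>> find_all_occurrences("ACGTACGT", "ACGT")
    [0, 4]
    >>> find_all_occurrences("AAAA", "AA")
    [0, 1, 2]
    """
    if not needle:
        raise ValueError("needle must be non-empty")
    hits: list[int] = []
    p = haystack.find(needle)
    while p != -1:
        hits.append(p)
        p = haystack.find(needle, p + 1)
    return hits
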