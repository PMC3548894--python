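"""Affine-gap dynamic programming alignment (Needleman-Wunsch / Smith-Waterman).

Only polymorphic regions classified as *complex* reach these routines, so the
inputs are short (typically 2w + delta, i.e. a few dozen bp) and a plain
Python Gotoh implementation is fast enough.

Scoring follows the EMBOSS-style convention the package defaults to
(match +8, mismatch -2, gap open -7, gap extend -1): a gap of length L costs
``gap_open + L * gap_extend``.

Tie-breaking is deterministic: substitution columns are preferred over gaps,
and gaps in the read (deletions) over gaps in the reference (insertions).
"""

from __future__ import annotations

from dataclasses import dataclass

NEG_INF = float("-inf")


@dataclass(frozen=True)
class DPScoring:
    """Alignment scoring parameters (affine gaps)."""

    match: int = 8
    mismatch: int = -2
    gap_open: int = -7
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")

    def gap_cost(self, length: int) -> int:
        return self.gap_open + length * self.gap_extend


@dataclass(frozen=True)
class Alignment:
    """A pairwise alignment: gapped strings of equal length plus the score.

    ``aligned_a`` is the reference side, ``aligned_b`` the read side; ``-``
    marks a gap.  For local alignments the half-open aligned spans on each
    input are recorded so the caller can see the unaligned overhangs.
    """

    aligned_a: str
    aligned_b: str
    score: float
    a_start: int = 0
    a_end: int = 0
    b_start: int = 0
    b_end: int = 0


# DP states: M = substitution column, X = gap in b (consumes a),
# Y = gap in a (consumes b).  Preference on ties: M > X > Y.
_M, _X, _Y = 0, 1, 2


def _matrices(a: str, b: str, scoring: DPScoring, local: bool):
    n, m = len(a), len(b)
    open_ext = scoring.gap_open + scoring.gap_extend
    ext = scoring.gap_extend
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0
    for i in range(1, n + 1):
        X[i][0] = 0 if local else scoring.gap_cost(i)
    for j in range(1, m + 1):
        Y[0][j] = 0 if local else scoring.gap_cost(j)
    if local:
        for i in range(n + 1):
            M[i][0] = 0
        for j in range(m + 1):
            M[0][j] = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = scoring.match if ai == b[j - 1] else scoring.mismatch
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = diag + s
            X[i][j] = max(
                X[i - 1][j] + ext,
                M[i - 1][j] + open_ext,
                Y[i - 1][j] + open_ext,
            )
            Y[i][j] = max(
                Y[i][j - 1] + ext,
                M[i][j - 1] + open_ext,
                X[i][j - 1] + open_ext,
            )
            if local and M[i][j] < 0:
                M[i][j] = 0
    return M, X, Y


def _best_state(M, X, Y, i, j):
    best, state = M[i][j], _M
    if X[i][j] > best:
        best, state = X[i][j], _X
    if Y[i][j] > best:
        best, state = Y[i][j], _Y
    return best, state


def align_nw(a: str, b: str, scoring: DPScoring | None = None) -> Alignment:
    """Optimal global alignment of ``a`` (reference) and ``b`` (read)."""
    scoring = scoring or DPScoring()
    if not a and not b:
        return Alignment("", "", 0)
    if not a:
        return Alignment("-" * len(b), b, scoring.gap_cost(len(b)), 0, 0, 0, len(b))
    if not b:
        return Alignment(a, "-" * len(a), scoring.gap_cost(len(a)), 0, len(a), 0, 0)
    M, X, Y = _matrices(a, b, scoring, local=False)
    n, m = len(a), len(b)
    score, state = _best_state(M, X, Y, n, m)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    open_ext = scoring.gap_open + scoring.gap_extend
    ext = scoring.gap_extend
    while i > 0 or j > 0:
        if state == _M:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            _, state = _best_state(M, X, Y, i, j)
        elif state == _X:
            out_a.append(a[i - 1])
            out_b.append("-")
            target = X[i][j]
            i -= 1
            if i == 0 and j == 0:
                break
            # prefer ending the gap (coming from M, then Y) over extending
            if M[i][j] + open_ext == target:
                state = _M
            elif Y[i][j] + open_ext == target:
                state = _Y
            else:
                state = _X
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            target = Y[i][j]
            j -= 1
            if i == 0 and j == 0:
                break
            if M[i][j] + open_ext == target:
                state = _M
            elif X[i][j] + open_ext == target:
                state = _X
            else:
                state = _Y
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    return Alignment(aligned_a, aligned_b, score, 0, n, 0, m)


def align_semiglobal(
    a: str,
    b: str,
    scoring: DPScoring | None = None,
    *,
    free_prefix: bool = False,
    free_suffix: bool = False,
) -> Alignment:
    """Global in the read ``b``, free reference overhang at chosen ends.

    Used for polymorphic regions touching a read terminus: the read bases
    must all be aligned (a substitution at the first read base stays a
    substitution), while reference sequence beyond the read's reach at the
    unanchored edge is skipped without penalty -- that overhang is a
    truncation, not a deletion.  ``a_start``/``a_end`` delimit the aligned
    reference span.
    """
    scoring = scoring or DPScoring()
    if not b:
        return Alignment("", "", 0, 0, 0, 0, 0)
    if not a:
        return Alignment("-" * len(b), b, scoring.gap_cost(len(b)), 0, 0, 0, len(b))
    n, m = len(a), len(b)
    open_ext = scoring.gap_open + scoring.gap_extend
    ext = scoring.gap_extend
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0
    for i in range(1, n + 1):
        X[i][0] = 0 if free_prefix else scoring.gap_cost(i)
    for j in range(1, m + 1):
        Y[0][j] = scoring.gap_cost(j)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = scoring.match if ai == b[j - 1] else scoring.mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                X[i - 1][j] + ext, M[i - 1][j] + open_ext, Y[i - 1][j] + open_ext
            )
            Y[i][j] = max(
                Y[i][j - 1] + ext, M[i][j - 1] + open_ext, X[i][j - 1] + open_ext
            )
    # end cell: the full read is consumed; reference may end early
    end_i = n
    score, state = _best_state(M, X, Y, n, m)
    if free_suffix:
        for i in range(n - 1, -1, -1):
            cand, cstate = _best_state(M, X, Y, i, m)
            if cand > score:
                score, state, end_i = cand, cstate, i
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = end_i, m
    while i > 0 or j > 0:
        if free_prefix and j == 0:
            break  # remaining reference prefix is unaligned overhang
        if state == _M:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            _, state = _best_state(M, X, Y, i, j)
        elif state == _X:
            out_a.append(a[i - 1])
            out_b.append("-")
            target = X[i][j]
            i -= 1
            if i == 0 and j == 0:
                break
            if j > 0 and M[i][j] + open_ext == target:
                state = _M
            elif j > 0 and Y[i][j] + open_ext == target:
                state = _Y
            else:
                state = _X
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            target = Y[i][j]
            j -= 1
            if i == 0 and j == 0:
                break
            if M[i][j] + open_ext == target:
                state = _M
            elif X[i][j] + open_ext == target:
                state = _X
            else:
                state = _Y
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    return Alignment(aligned_a, aligned_b, score, i, end_i, 0, m)


def align_sw(a: str, b: str, scoring: DPScoring | None = None) -> Alignment:
    """Best local alignment of ``a`` and ``b``.

    Used for regions at a read terminus, where part of the reference may be
    uncovered: the unaligned overhang is a truncation, not a mutation.  An
    empty alignment (score 0) means the sequences share nothing alignable.
    """
    scoring = scoring or DPScoring()
    if not a or not b:
        return Alignment("", "", 0)
    M, X, Y = _matrices(a, b, scoring, local=True)
    n, m = len(a), len(b)
    best, bi, bj = 0, 0, 0
    for i in range(n + 1):
        Mi = M[i]
        for j in range(m + 1):
            if Mi[j] > best:
                best, bi, bj = Mi[j], i, j
    if best <= 0:
        return Alignment("", "", 0)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = bi, bj
    state = _M
    open_ext = scoring.gap_open + scoring.gap_extend
    ext = scoring.gap_extend
    while i > 0 and j > 0:
        if state == _M:
            if M[i][j] == 0:
                break
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            s = scoring.match if a[i - 1] == b[j - 1] else scoring.mismatch
            target = M[i][j] - s
            i, j = i - 1, j - 1
            if M[i][j] == target:
                state = _M
            elif X[i][j] == target:
                state = _X
            elif Y[i][j] == target:
                state = _Y
            else:  # local start (diag max was clamped 0)
                break
        elif state == _X:
            out_a.append(a[i - 1])
            out_b.append("-")
            target = X[i][j]
            i -= 1
            if M[i][j] + open_ext == target:
                state = _M
            elif Y[i][j] + open_ext == target:
                state = _Y
            else:
                state = _X
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            target = Y[i][j]
            j -= 1
            if M[i][j] + open_ext == target:
                state = _M
            elif X[i][j] + open_ext == target:
                state = _X
            else:
                state = _Y
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    a_start = i
    b_start = j
    return Alignment(aligned_a, aligned_b, best, a_start, bi, b_start, bj)
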