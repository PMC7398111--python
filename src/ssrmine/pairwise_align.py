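"""Exact Levenshtein distance and Needleman-Wunsch global alignment.

Both are classic dynamic programs over the full (|a|+1) x (|b|+1) table:

    LD(i,j) = max(i,j)                                  if min(i,j) == 0
            = min( LD(i-1,j) + 1,
                   LD(i,j-1) + 1,
                   LD(i-1,j-1) + [a_i != b_j] )         otherwise

    NW(i,j) = 0                                         at i = j = 0
            = max( NW(i-1,j) + S_gap,
                   NW(i,j-1) + S_gap,
                   NW(i-1,j-1) + S_match/mismatch )     otherwise

Levenshtein needs no traceback and is the faster way to put a number on
flank similarity; Needleman-Wunsch reports the identity of one optimal
global alignment (matches / alignment columns) under an explicit scoring
scheme. N never matches anything, including another N.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ScoringScheme:
    """Match / mismatch / gap scores for global alignment."""

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0

    def __post_init__(self) -> None:
        if not self.match > self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if not self.gap < self.match:
            raise ValueError("gap score must be below match score")


def _same(x: str, y: str) -> bool:
    # N is ambiguous: it matches nothing, not even another N
    return x == y and x != "N"


def levenshtein(a: str, b: str) -> int:
    """Minimum number of single-character edits turning ``a`` into ``b``."""
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(
                prev[j] + 1,                          # delete from a
                cur[j - 1] + 1,                       # insert into a
                prev[j - 1] + (0 if _same(ca, cb) else 1),
            ))
        prev = cur
    return prev[-1]


def ld_identity(a: str, b: str) -> float:
    """1 - LD/max(|a|,|b|): an edit-distance proxy for percent identity."""
    m = max(len(a), len(b))
    if m == 0:
        raise ValueError("both strings are empty")
    return 1.0 - levenshtein(a, b) / m


def nw_align(a: str, b: str,
             scheme: ScoringScheme | None = None) -> tuple[float, int, int]:
    """Optimal global alignment of ``a`` and ``b``.

    Returns ``(score, matches, alignment_length)`` where matches and length
    come from one optimal traceback with deterministic tie-breaking:
    diagonal is preferred over a gap in ``b`` (up), which is preferred over
    a gap in ``a`` (left).
    """
    if not a or not b:
        raise ValueError("nw_align requires non-empty strings")
    scheme = scheme or ScoringScheme()
    n, m = len(a), len(b)
    score = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        score[i][0] = i * scheme.gap
    for j in range(1, m + 1):
        score[0][j] = j * scheme.gap
    for i in range(1, n + 1):
        row, prev = score[i], score[i - 1]
        ca = a[i - 1]
        for j in range(1, m + 1):
            sub = scheme.match if _same(ca, b[j - 1]) else scheme.mismatch
            row[j] = max(prev[j - 1] + sub, prev[j] + scheme.gap,
                         row[j - 1] + scheme.gap)
    matches = 0
    length = 0
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            sub = scheme.match if _same(a[i - 1], b[j - 1]) else scheme.mismatch
            if score[i][j] == score[i - 1][j - 1] + sub:
                matches += _same(a[i - 1], b[j - 1])
                i, j = i - 1, j - 1
                length += 1
                continue
        if i > 0 and score[i][j] == score[i - 1][j] + scheme.gap:
            i -= 1
            length += 1
            continue
        j -= 1
        length += 1
    return score[n][m], matches, length


def nw_identity(a: str, b: str, scheme: ScoringScheme | None = None) -> float:
    """Matches / alignment columns of one optimal global alignment."""
    _, matches, length = nw_align(a, b, scheme)
    return matches / length
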