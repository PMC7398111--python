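"""Independent brute-force oracles used only by the test suite.

These deliberately use different algorithms and data paths from the
package: maximal-run enumeration over boolean period masks instead of the
backtracking regex scan, full-table recursive DP instead of rolling-row DP,
all-pairs comparison instead of masked-variant indexing, and exhaustive
partition enumeration instead of the greedy scheduler.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np


def _primitive_len(s: str) -> int:
    n = len(s)
    for p in range(1, n):
        if n % p == 0 and s == s[:p] * (n // p):
            return p
    return n


def oracle_scan(seq: str, min_repeats: dict[int, int]) -> set[tuple]:
    """Every maximal perfect repeat meeting its class threshold, as a set of
    (start, end, motif, repeats) with 1-based inclusive coordinates.

    For each enabled period, positions where seq[i] == seq[i+l] (both
    non-N) form boolean runs; each maximal run is one repeat region, trimmed
    at the tail to a whole number of motif units. Regions whose motif is a
    repetition of a shorter unit belong to that shorter period and are
    skipped, so each repeat is reported exactly once.
    """
    n = len(seq)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = arr != ord("N")
    out: set[tuple] = set()
    for l, rmin in min_repeats.items():
        if n < 2 * l:
            continue
        eq = (arr[:-l] == arr[l:]) & valid[:-l] & valid[l:]
        edges = np.flatnonzero(np.diff(np.concatenate(
            ([0], eq.astype(np.int8), [0]))))
        for a, e in zip(edges[::2], edges[1::2]):
            a, e = int(a), int(e)          # eq true on [a, e)
            reps = (e - a + l) // l        # chars span [a, e + l)
            if reps < rmin:
                continue
            motif = seq[a:a + l]
            if _primitive_len(motif) != l:
                continue
            out.add((a + 1, a + l * reps, motif, reps))
    return out


def oracle_levenshtein(a: str, b: str) -> int:
    """Plain full-table edit distance."""
    n, m = len(a), len(b)
    d = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        d[i][0] = i
    for j in range(m + 1):
        d[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = 0 if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else 1
            d[i][j] = min(d[i - 1][j] + 1, d[i][j - 1] + 1,
                          d[i - 1][j - 1] + cost)
    return d[n][m]


def oracle_nw_score(a: str, b: str, match: float, mismatch: float,
                    gap: float) -> float:
    """Recursive-with-memo global alignment score."""

    @lru_cache(maxsize=None)
    def f(i: int, j: int) -> float:
        if i == 0 and j == 0:
            return 0.0
        best = -float("inf")
        if i > 0:
            best = max(best, f(i - 1, j) + gap)
        if j > 0:
            best = max(best, f(i, j - 1) + gap)
        if i > 0 and j > 0:
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
            best = max(best, f(i - 1, j - 1) + s)
        return best

    return f(len(a), len(b))


def oracle_hamming_pairs(keys_a: list[tuple[str, str]],
                         keys_b: list[tuple[str, str]],
                         max_mm: int) -> set[tuple[int, int]]:
    """All-pairs Hamming filter: indices (ia, ib) with equal motif and at
    most max_mm mismatching positions between equal-length keys."""
    out = set()
    for ia, (motif_a, ka) in enumerate(keys_a):
        for ib, (motif_b, kb) in enumerate(keys_b):
            if motif_a != motif_b or len(ka) != len(kb):
                continue
            if sum(x != y for x, y in zip(ka, kb)) <= max_mm:
                out.add((ia, ib))
    return out


def oracle_optimal_makespan(lengths: list[int], k: int) -> int:
    """Minimum possible makespan by exhaustive assignment (tiny inputs)."""
    best = sum(lengths)
    for assignment in itertools.product(range(k), repeat=len(lengths)):
        loads = [0] * k
        for length, w in zip(lengths, assignment):
            loads[w] += length
        best = min(best, max(loads))
    return best


def random_dna(rng: np.random.Generator, length: int,
               probs=(0.25, 0.25, 0.25, 0.25), n_rate: float = 0.0) -> str:
    bases = np.array(list("ACGT"))
    seq = bases[rng.choice(4, size=length, p=list(probs))]
    if n_rate > 0:
        mask = rng.random(length) < n_rate
        seq[mask] = "N"
    return "".join(seq)


def repeat_rich_sequence(rng: np.random.Generator, length: int) -> str:
    """Random sequence interleaved with planted repeats of all motif sizes,
    including directly adjacent (compound) repeats — the stress input for
    scanner/oracle equivalence."""
    bases = "ACGT"
    parts: list[str] = []
    total = 0
    while total < length:
        roll = rng.random()
        if roll < 0.45:
            chunk = random_dna(rng, int(rng.integers(20, 120)),
                               n_rate=0.01 if rng.random() < 0.2 else 0.0)
        elif roll < 0.85:
            l = int(rng.integers(1, 7))
            motif = "".join(bases[i] for i in rng.integers(0, 4, size=l))
            reps = int(rng.integers(2, 15))
            chunk = motif * reps
        else:  # adjacent compound block
            chunk = ""
            for _ in range(int(rng.integers(2, 4))):
                l = int(rng.integers(1, 7))
                motif = "".join(bases[i] for i in rng.integers(0, 4, size=l))
                chunk += motif * int(rng.integers(4, 12))
        parts.append(chunk)
        total += len(chunk)
    return "".join(parts)[:length]
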