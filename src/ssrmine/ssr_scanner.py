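"""Single-pass mining of perfect SSR loci.

All enabled motif classes are folded into one alternation pattern (shortest
motif first), so a sequence is traversed once regardless of how many motif
lengths are enabled. After each successful match the scan position backtracks
by B bases so that adjacent (compound) repeats sharing boundary bases are not
missed; B is derived from the enabled thresholds:

    B = l - 1                       if only one motif class is enabled
    B = max{L_1..L_n}               if min{S_1..S_n} > max{L_1..L_n}
    B = min{S_1..S_n} - 1           otherwise

where L_i is the motif length of class i and S_i = L_i * r_i is the minimum
total SSR length of class i. Long sequences are processed in 500-kb fragments
with a 5-kb overlap so memory stays bounded; results are identical to an
unfragmented scan as long as no locus is longer than the overlap.
"""

from __future__ import annotations

import functools
import re
import warnings
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from ssrmine.fasta_io import SequenceRecord
from ssrmine.workload import allocate_sequences

DEFAULT_MIN_REPEATS: dict[int, int] = {1: 10, 2: 7, 3: 6, 4: 5, 5: 4, 6: 4}

LOCUS_COLUMNS = (
    "id", "seq_id", "motif", "motif_len", "repeats", "start", "end",
    "length", "compound_id",
)


@dataclass(frozen=True)
class MotifThresholds:
    """Minimum repeat count per enabled motif length.

    Stored as a sorted tuple of ``(motif_length, min_repeats)`` pairs so the
    object is hashable (scan patterns are cached per threshold set).
    """

    classes: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("at least one motif class must be enabled")
        lengths = [l for l, _ in self.classes]
        if len(set(lengths)) != len(lengths):
            raise ValueError("motif lengths must be distinct")
        for l, r in self.classes:
            if l < 1:
                raise ValueError(f"motif length must be >= 1, got {l}")
            if r < 2:
                raise ValueError(f"minimum repeat count must be >= 2, got {r}")
        if list(self.classes) != sorted(self.classes):
            object.__setattr__(self, "classes", tuple(sorted(self.classes)))

    @classmethod
    def from_dict(cls, min_repeats: Mapping[int, int]) -> "MotifThresholds":
        return cls(tuple(sorted(min_repeats.items())))

    @classmethod
    def default(cls) -> "MotifThresholds":
        return cls.from_dict(DEFAULT_MIN_REPEATS)

    @classmethod
    def parse(cls, text: str) -> "MotifThresholds":
        """Parse a ``"1=10,2=7,..."`` threshold string."""
        pairs = {}
        try:
            for chunk in text.split(","):
                l, r = chunk.split("=")
                pairs[int(l)] = int(r)
        except ValueError as exc:
            raise ValueError(f"invalid thresholds string {text!r}") from exc
        return cls.from_dict(pairs)

    def as_dict(self) -> dict[int, int]:
        return dict(self.classes)

    @property
    def motif_lengths(self) -> tuple[int, ...]:
        """L_i: the enabled motif lengths."""
        return tuple(l for l, _ in self.classes)

    @property
    def min_ssr_lengths(self) -> tuple[int, ...]:
        """S_i = L_i * r_i: the minimum total SSR length per class."""
        return tuple(l * r for l, r in self.classes)

    def __str__(self) -> str:
        return ",".join(f"{l}={r}" for l, r in self.classes)


@dataclass(frozen=True)
class SSRLocus:
    """One perfect repeat locus, 1-based inclusive coordinates."""

    seq_id: str
    motif: str
    repeats: int
    start: int
    end: int
    compound_id: int | None = None

    @property
    def motif_length(self) -> int:
        return len(self.motif)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def key(self) -> tuple[str, int, int, str]:
        return (self.seq_id, self.start, self.end, self.motif)

    def to_row(self, locus_id: int | str = ".") -> dict[str, object]:
        return {
            "id": locus_id,
            "seq_id": self.seq_id,
            "motif": self.motif,
            "motif_len": self.motif_length,
            "repeats": self.repeats,
            "start": self.start,
            "end": self.end,
            "length": self.length,
            "compound_id": self.compound_id,
        }


def primitive_period(motif: str) -> int:
    """Smallest p such that the motif is a whole number of repeats of its
    first p characters."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return p
    return n


def backtrack_size(thresholds: MotifThresholds) -> int:
    """Backtracking distance B applied after each successful match."""
    lengths = thresholds.motif_lengths
    if len(lengths) == 1:
        return lengths[0] - 1
    s_min = min(thresholds.min_ssr_lengths)
    l_max = max(lengths)
    if s_min > l_max:
        return l_max
    return s_min - 1


@functools.lru_cache(maxsize=32)
def _pattern(classes: tuple[tuple[int, int], ...]) -> re.Pattern[str]:
    # one branch per class, shortest motif first; group i+1 captures the motif
    branches = []
    for i, (l, r) in enumerate(classes):
        branches.append(f"([ACGT]{{{l}}})\\{i + 1}{{{r - 1},}}")
    return re.compile("|".join(branches))


def _scan_string(seq: str, thresholds: MotifThresholds,
                 seq_id: str, offset: int = 0) -> list[SSRLocus]:
    """Scan a raw string; coordinates are 1-based after adding ``offset``."""
    pattern = _pattern(thresholds.classes)
    b = backtrack_size(thresholds)
    n_classes = len(thresholds.classes)
    n = len(seq)
    min_reps = thresholds.as_dict()
    loci: list[SSRLocus] = []
    pos = 0
    while True:
        m = pattern.search(seq, pos)
        if m is None:
            break
        start0, end0 = m.start(), m.end()
        motif = next(m.group(g) for g in range(1, n_classes + 1)
                     if m.group(g) is not None)
        l = len(motif)
        if primitive_period(motif) == l:
            # a backtracked rescan can land inside a run; re-extend to the
            # full maximal run so partial nested runs are never reported
            ts, te = start0, end0
            while ts > 0 and seq[ts - 1] == seq[ts - 1 + l] \
                    and seq[ts - 1] != "N":
                ts -= 1
            while te < n and seq[te] == seq[te - l] and seq[te] != "N":
                te += 1
            reps = (te - ts) // l
            if reps >= min_reps[l]:
                loci.append(SSRLocus(
                    seq_id=seq_id,
                    motif=seq[ts:ts + l],
                    repeats=reps,
                    start=offset + ts + 1,
                    end=offset + ts + l * reps,
                ))
        # resume B bases before the match end; always make progress
        pos = max(end0 - b, start0 + 1)
    return _dedup(loci)


def _dedup(loci: list[SSRLocus]) -> list[SSRLocus]:
    """Drop exact duplicates and loci nested inside a longer locus of the
    same motif length (maximal runs of one period are disjoint, so any such
    nesting is a rescan artifact)."""
    seen: set[tuple[str, int, int, str]] = set()
    unique: list[SSRLocus] = []
    for loc in sorted(loci, key=lambda x: (x.start, x.end, x.motif)):
        if loc.key() not in seen:
            seen.add(loc.key())
            unique.append(loc)
    kept: list[SSRLocus] = []
    max_end_per_len: dict[int, int] = {}
    for loc in unique:  # sorted by start: containment -> end <= running max
        if loc.end <= max_end_per_len.get(loc.motif_length, 0):
            continue
        max_end_per_len[loc.motif_length] = loc.end
        kept.append(loc)
    return kept


def scan_sequence(record: SequenceRecord,
                  thresholds: MotifThresholds | None = None) -> list[SSRLocus]:
    """Mine every maximal perfect repeat in one record, leftmost first.

    Runs containing N are never reported (N is outside the match alphabet),
    and a motif that is itself a repetition of a shorter unit is never
    reported as a separate locus.
    """
    thresholds = thresholds or MotifThresholds.default()
    return _scan_string(record.sequence, thresholds, record.id)


def fragment_positions(seq_length: int, frag_size: int = 500_000,
                       overlap: int = 5_000) -> list[tuple[int, int]]:
    """1-based inclusive fragment windows covering ``[1, seq_length]``.

    Each window spans ``frag_size`` new bases plus ``overlap`` bases of
    lookahead so repeats straddling a boundary are still seen whole.
    """
    if overlap < 0 or frag_size <= overlap:
        raise ValueError("frag_size must exceed overlap and overlap be >= 0")
    windows = []
    start = 1
    while start <= seq_length:
        windows.append((start, min(start + frag_size + overlap - 1, seq_length)))
        start += frag_size
    return windows


def scan_fragmented(record: SequenceRecord,
                    thresholds: MotifThresholds | None = None,
                    frag_size: int = 500_000,
                    overlap: int = 5_000) -> list[SSRLocus]:
    """Fragmented scan, identical to :func:`scan_sequence` whenever no locus
    is longer than ``overlap`` (a longer locus is truncated with a warning).

    A window owns the loci that start within its first ``frag_size`` bases;
    loci that begin exactly at an interior window start and whose run
    continues leftward in the full sequence are partial re-detections of a
    locus owned by the previous window and are discarded.
    """
    thresholds = thresholds or MotifThresholds.default()
    seq = record.sequence
    n = len(seq)
    if n <= frag_size + overlap:
        return scan_sequence(record, thresholds)
    loci: list[SSRLocus] = []
    for win_start, win_end in fragment_positions(n, frag_size, overlap):
        sub = seq[win_start - 1:win_end]
        for loc in _scan_string(sub, thresholds, record.id, offset=win_start - 1):
            if loc.start > win_start + frag_size - 1:
                continue  # owned by the next window
            g0 = loc.start - 1
            l = loc.motif_length
            if win_start > 1 and loc.start == win_start \
                    and g0 >= 1 and seq[g0 - 1] == seq[g0 - 1 + l]:
                continue  # left-truncated continuation; previous window owns it
            if loc.end + l > win_end:
                # window could not prove right-maximality; check the full seq
                e0 = loc.end - 1
                ext = e0
                while ext + 1 < n and seq[ext + 1] == seq[ext + 1 - l]:
                    ext += 1
                if (ext - g0 + 1) // l > loc.repeats:
                    warnings.warn(
                        f"locus {loc.seq_id}:{loc.start}-{loc.end} ({loc.motif}) "
                        f"extends beyond its fragment; reported truncated — "
                        f"increase overlap above the longest expected SSR",
                        RuntimeWarning, stacklevel=2,
                    )
            loci.append(loc)
    return _dedup(loci)


def annotate_compound(loci: Sequence[SSRLocus],
                      max_gap: int = 0) -> list[SSRLocus]:
    """Label chains of adjacent loci (gap <= ``max_gap`` bp) with a shared
    compound id; singletons keep ``compound_id=None``."""
    out: list[SSRLocus] = []
    next_id = 0
    by_seq: dict[str, list[SSRLocus]] = {}
    for loc in sorted(loci, key=lambda x: (x.seq_id, x.start, x.end)):
        by_seq.setdefault(loc.seq_id, []).append(loc)
    for seq_id in sorted(by_seq):
        group: list[SSRLocus] = []
        group_end = None
        for loc in by_seq[seq_id]:
            if group and loc.start - group_end - 1 <= max_gap:
                group.append(loc)
                group_end = max(group_end, loc.end)
            else:
                next_id = _flush_compound(group, next_id, out)
                group = [loc]
                group_end = loc.end
        next_id = _flush_compound(group, next_id, out)
    return out


def _flush_compound(group: list[SSRLocus], next_id: int,
                    out: list[SSRLocus]) -> int:
    if len(group) >= 2:
        out.extend(replace(loc, compound_id=next_id) for loc in group)
        return next_id + 1
    out.extend(group)
    return next_id


def _scan_worker(args: tuple[list[SequenceRecord], tuple[tuple[int, int], ...],
                             int, int]) -> list[SSRLocus]:
    records, classes, frag_size, overlap = args
    thresholds = MotifThresholds(classes)
    out: list[SSRLocus] = []
    for rec in records:
        out.extend(scan_fragmented(rec, thresholds, frag_size, overlap))
    return out


def mine_records(records: Iterable[SequenceRecord],
                 thresholds: MotifThresholds | None = None,
                 threads: int = 1,
                 frag_size: int = 500_000,
                 overlap: int = 5_000,
                 compound_gap: int = 0) -> list[SSRLocus]:
    """Mine all records, optionally in parallel workers balanced by total
    sequence length. Output is deterministic and identical for any thread
    count: loci are re-sorted by (seq_id, start) and compound-annotated at
    the end.
    """
    thresholds = thresholds or MotifThresholds.default()
    recs = list(records)
    loci: list[SSRLocus] = []
    if threads <= 1 or len(recs) <= 1:
        for rec in recs:
            loci.extend(scan_fragmented(rec, thresholds, frag_size, overlap))
    else:
        plan = allocate_sequences([(r.id, r.length) for r in recs], threads)
        by_id = {r.id: r for r in recs}
        jobs = [
            ([by_id[i] for i in ids], thresholds.classes, frag_size, overlap)
            for ids in plan.assignments.values() if ids
        ]
        with ProcessPoolExecutor(max_workers=threads) as pool:
            for chunk in pool.map(_scan_worker, jobs):
                loci.extend(chunk)
    loci.sort(key=lambda x: (x.seq_id, x.start, x.end, x.motif))
    return annotate_compound(loci, max_gap=compound_gap)


def loci_to_rows(loci: Sequence[SSRLocus]) -> list[dict[str, object]]:
    """Rows for the locus TSV, ids assigned in (seq_id, start) order."""
    ordered = sorted(loci, key=lambda x: (x.seq_id, x.start, x.end))
    return [loc.to_row(i + 1) for i, loc in enumerate(ordered)]
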