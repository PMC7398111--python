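"""Candidate polymorphic SSR discovery between two assemblies.

A locus becomes a candidate marker when its flanking sequences are both
*conserved* across the assemblies and *unique* within each assembly:

1. exact stage — flank concatenations that are byte-identical between the
   two assemblies are paired immediately via a hash lookup;
2. pre-alignment stage — only the x% of each flank nearest the SSR (default
   5%, i.e. 5 bp per side at f=100) is compared, tolerating up to 2
   mismatched bases in total; this cheap Hamming filter discards pairs whose
   near-SSR flanks already disagree;
3. verification stage — surviving pairs are scored per side with either the
   Levenshtein distance ratio (LD/f <= threshold) or Needleman-Wunsch
   identity (>= 1 - threshold).

Uniqueness is then assessed with a sliding-window index (window = flank
length, step 1 bp): all four flanks must occur exactly once in their own
assembly. Finally pairs are classified monomorphic or polymorphic by
comparing repeat counts.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from ssrmine.fasta_io import SequenceRecord
from ssrmine.pairwise_align import ScoringScheme, levenshtein, nw_identity
from ssrmine.ssr_scanner import MotifThresholds, SSRLocus, mine_records

logger = logging.getLogger(__name__)

MARKER_COLUMNS = (
    "marker_id", "seq_id_a", "motif", "repeats_a", "start_a", "end_a",
    "repeats_b", "start_b", "end_b", "seq_id_b", "left_identity",
    "right_identity", "stage", "unique", "classification",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PolymorphismConfig:
    """Tunables for candidate marker discovery.

    flank_len
        f, the flank length in bp on each side of the SSR (default 100; the
        published large-genome benchmarks use 150).
    prealign_pct
        x, percent of f nearest the SSR used in the pre-alignment stage;
        the per-side window is p = max(ceil(f*x/100), 1).
    prealign_max_mismatch
        mismatches tolerated across both near-SSR windows combined (<= 2).
    method
        "ld" (Levenshtein ratio) or "nw" (Needleman-Wunsch identity).
    conservation_threshold
        maximum LD/f per side, equivalently 1 - minimum NW identity.
    mode
        "time_saving" keeps the full sliding-window index in memory;
        "memory_saving" streams the assembly once per key partition.
    """

    flank_len: int = 100
    prealign_pct: float = 5.0
    prealign_max_mismatch: int = 2
    method: Literal["ld", "nw"] = "ld"
    conservation_threshold: float = 0.05
    mode: Literal["time_saving", "memory_saving"] = "time_saving"
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    require_same_motif: bool = True
    check_revcomp: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.prealign_pct <= 100:
            raise ValueError("prealign_pct must be in (0, 100]")
        if self.prealign_max_mismatch not in (0, 1, 2):
            raise ValueError("prealign_max_mismatch must be 0, 1 or 2")
        if self.flank_len < 1:
            raise ValueError("flank_len must be >= 1")

    @property
    def prealign_len(self) -> int:
        """p: per-side near-SSR window length."""
        return max(math.ceil(self.flank_len * self.prealign_pct / 100), 1)


@dataclass(frozen=True)
class FlankPair:
    """Left/right flanks of fixed length f around one locus."""

    locus: SSRLocus
    left: str
    right: str
    prealign_len: int

    @property
    def key_full(self) -> str:
        return self.left + self.right

    @property
    def key_near(self) -> str:
        p = self.prealign_len
        return self.left[-p:] + self.right[:p]


@dataclass(frozen=True)
class CandidateMarker:
    """A conserved, unique locus pair across the two assemblies."""

    locus_a: SSRLocus
    locus_b: SSRLocus
    stage: Literal["exact", "prealign"]
    left_identity: float
    right_identity: float
    unique_a: bool = True
    unique_b: bool = True

    @property
    def classification(self) -> str:
        return ("polymorphic" if self.locus_a.repeats != self.locus_b.repeats
                else "monomorphic")

    def to_row(self, marker_id: int | str = ".") -> dict[str, object]:
        a, b = self.locus_a, self.locus_b
        return {
            "marker_id": marker_id,
            "seq_id_a": a.seq_id, "motif": a.motif, "repeats_a": a.repeats,
            "start_a": a.start, "end_a": a.end,
            "repeats_b": b.repeats, "start_b": b.start, "end_b": b.end,
            "seq_id_b": b.seq_id,
            "left_identity": self.left_identity,
            "right_identity": self.right_identity,
            "stage": self.stage,
            "unique": "yes" if self.unique_a and self.unique_b else "no",
            "classification": self.classification,
        }


def extract_flanks(locus: SSRLocus, record: SequenceRecord,
                   flank_len: int, prealign_len: int = 5) -> FlankPair | None:
    """Flanks of ``flank_len`` bp on each side, or None when a flank is
    truncated by a sequence end or contains N (such loci cannot anchor a
    marker and are excluded)."""
    seq = record.sequence
    if locus.start - flank_len < 1 or locus.end + flank_len > len(seq):
        return None
    left = seq[locus.start - 1 - flank_len:locus.start - 1]
    right = seq[locus.end:locus.end + flank_len]
    if "N" in left or "N" in right:
        return None
    return FlankPair(locus=locus, left=left, right=right,
                     prealign_len=prealign_len)


def extract_all_flanks(loci: Iterable[SSRLocus],
                       records: Sequence[SequenceRecord],
                       config: PolymorphismConfig) -> list[FlankPair]:
    by_id = {r.id: r for r in records}
    out = []
    skipped = 0
    for locus in loci:
        pair = extract_flanks(locus, by_id[locus.seq_id], config.flank_len,
                              config.prealign_len)
        if pair is None:
            skipped += 1
        else:
            out.append(pair)
    if skipped:
        logger.info("%d loci excluded (flank truncated by sequence end or "
                    "containing N)", skipped)
    return out


def _pair_motif(fp: FlankPair) -> str:
    return fp.locus.motif


def stage1_exact_match(
    flanks_a: Sequence[FlankPair], flanks_b: Sequence[FlankPair],
    require_same_motif: bool = True,
) -> tuple[list[tuple[FlankPair, FlankPair]], list[FlankPair], list[FlankPair]]:
    """Pair loci whose full flank concatenation (and motif) is identical.

    The first assembly's keys act as the lookup library. A key occurring
    more than once within either assembly is ambiguous; all its loci fall
    through to the later stages where uniqueness filtering resolves them.
    """
    def keyed(flanks: Sequence[FlankPair]) -> dict[tuple, list[FlankPair]]:
        lib: dict[tuple, list[FlankPair]] = defaultdict(list)
        for fp in flanks:
            motif = _pair_motif(fp) if require_same_motif else ""
            lib[(motif, fp.key_full)].append(fp)
        return lib

    lib_a, lib_b = keyed(flanks_a), keyed(flanks_b)
    matched: list[tuple[FlankPair, FlankPair]] = []
    rest_a: list[FlankPair] = []
    rest_b: list[FlankPair] = []
    matched_keys = set()
    for key, group_a in lib_a.items():
        group_b = lib_b.get(key, [])
        if len(group_a) == 1 and len(group_b) == 1:
            matched.append((group_a[0], group_b[0]))
            matched_keys.add(key)
    for fp in flanks_a:
        motif = _pair_motif(fp) if require_same_motif else ""
        if (motif, fp.key_full) not in matched_keys:
            rest_a.append(fp)
    for fp in flanks_b:
        motif = _pair_motif(fp) if require_same_motif else ""
        if (motif, fp.key_full) not in matched_keys:
            rest_b.append(fp)
    return matched, rest_a, rest_b


def _masked_variants(key: str, max_mm: int) -> Iterable[str]:
    """The key with up to ``max_mm`` positions replaced by a wildcard."""
    yield key
    positions = range(len(key))
    for k in range(1, max_mm + 1):
        for combo in itertools.combinations(positions, k):
            chars = list(key)
            for pos in combo:
                chars[pos] = "*"
            yield "".join(chars)


def stage2_prealign(
    remainder_a: Sequence[FlankPair], remainder_b: Sequence[FlankPair],
    p: int, max_mm: int = 2, require_same_motif: bool = True,
) -> list[tuple[FlankPair, FlankPair]]:
    """Pairs whose near-SSR keys (last p bp of left + first p bp of right)
    differ by at most ``max_mm`` bases.

    Implemented by indexing every masked variant (up to ``max_mm`` wildcard
    positions) of each library key; two keys at Hamming distance d share the
    variant masking exactly their d mismatch positions, so the output equals
    the all-pairs Hamming filter.
    """
    lib: dict[tuple, list[int]] = defaultdict(list)
    for ia, fp in enumerate(remainder_a):
        motif = _pair_motif(fp) if require_same_motif else ""
        for variant in _masked_variants(fp.key_near, max_mm):
            lib[(motif, variant)].append(ia)
    pairs: set[tuple[int, int]] = set()
    for ib, fp in enumerate(remainder_b):
        motif = _pair_motif(fp) if require_same_motif else ""
        for variant in _masked_variants(fp.key_near, max_mm):
            for ia in lib.get((motif, variant), ()):
                pairs.add((ia, ib))
    out = []
    for ia, ib in sorted(pairs):
        ka, kb = remainder_a[ia].key_near, remainder_b[ib].key_near
        if sum(x != y for x, y in zip(ka, kb)) <= max_mm:
            out.append((remainder_a[ia], remainder_b[ib]))
    return out


def stage3_verify(
    candidates: Sequence[tuple[FlankPair, FlankPair]],
    method: Literal["ld", "nw"] = "ld",
    scheme: ScoringScheme | None = None,
    threshold: float = 0.05,
) -> list[tuple[FlankPair, FlankPair, float, float]]:
    """Score each candidate pair per side and keep pairs conserved on both.

    LD: LD(side_a, side_b)/f <= threshold, identity reported as 1 - LD/f.
    NW: identity >= 1 - threshold.
    A locus surviving in several pairs keeps only its best pair by mean
    identity; ties are ambiguous and drop all of that locus's pairs.
    """
    scored: list[tuple[FlankPair, FlankPair, float, float]] = []
    for fa, fb in candidates:
        f = len(fa.left)
        if method == "ld":
            li = 1.0 - levenshtein(fa.left, fb.left) / f
            ri = 1.0 - levenshtein(fa.right, fb.right) / f
        else:
            li = nw_identity(fa.left, fb.left, scheme)
            ri = nw_identity(fa.right, fb.right, scheme)
        if li >= 1.0 - threshold - 1e-12 and ri >= 1.0 - threshold - 1e-12:
            scored.append((fa, fb, li, ri))
    return _resolve_one_to_one(scored)


def _resolve_one_to_one(
    scored: list[tuple[FlankPair, FlankPair, float, float]],
) -> list[tuple[FlankPair, FlankPair, float, float]]:
    best_a: dict[tuple, tuple[float, list[int]]] = {}
    best_b: dict[tuple, tuple[float, list[int]]] = {}
    for idx, (fa, fb, li, ri) in enumerate(scored):
        mean = (li + ri) / 2
        for best, fp in ((best_a, fa), (best_b, fb)):
            key = fp.locus.key()
            if key not in best or mean > best[key][0] + 1e-12:
                best[key] = (mean, [idx])
            elif abs(mean - best[key][0]) <= 1e-12:
                best[key][1].append(idx)
    kept = []
    for idx, (fa, fb, li, ri) in enumerate(scored):
        wa = best_a[fa.locus.key()][1]
        wb = best_b[fb.locus.key()][1]
        if wa == [idx] and wb == [idx]:
            kept.append((fa, fb, li, ri))
    return kept


class UniquenessIndex:
    """Occurrence counts of fixed-length windows in one assembly.

    Window size equals the flank length; windows slide with step 1 bp over
    the forward strand (optionally also counting reverse-complement hits),
    so overlapping occurrences are counted. ``time_saving`` materialises the
    full window -> count table; ``memory_saving`` keeps only the sequences
    and answers queries by streaming passes over prefix partitions.
    """

    def __init__(self, records: Sequence[SequenceRecord], window: int,
                 mode: str = "time_saving", check_revcomp: bool = False,
                 prefix_len: int = 2):
        if window < 1:
            raise ValueError("window must be >= 1")
        self.window = window
        self.mode = mode
        self.check_revcomp = check_revcomp
        self._records = list(records)
        self._prefix_len = min(prefix_len, window)
        self._counts: Counter[str] | None = None
        self._partial: dict[str, int] = {}
        self._partial_keys: set[str] = set()
        if mode == "time_saving":
            self._counts = Counter()
            for win in self._iter_windows():
                self._counts[win] += 1
        elif mode != "memory_saving":
            raise ValueError(f"unknown mode {mode!r}")

    def _iter_windows(self):
        w = self.window
        for rec in self._records:
            seqs = [rec.sequence]
            if self.check_revcomp:
                seqs.append(revcomp(rec.sequence))
            for seq in seqs:
                for i in range(len(seq) - w + 1):
                    yield seq[i:i + w]

    def count(self, s: str) -> int:
        if len(s) != self.window:
            return 0
        if self._counts is not None:
            return self._counts.get(s, 0)
        if s not in self._partial_keys:
            self.count_many([s])
        return self._partial.get(s, 0)

    def count_many(self, queries: Iterable[str]) -> dict[str, int]:
        """Batch counting; in memory_saving mode the assembly is streamed
        once per first-``prefix_len``-bases partition of the query set."""
        queries = [q for q in queries if len(q) == self.window]
        if self._counts is not None:
            return {q: self._counts.get(q, 0) for q in queries}
        todo = [q for q in queries if q not in self._partial_keys]
        by_prefix: dict[str, set[str]] = defaultdict(set)
        for q in todo:
            by_prefix[q[:self._prefix_len]].add(q)
        for prefix, qs in sorted(by_prefix.items()):
            found = {q: 0 for q in qs}
            for win in self._iter_windows():
                if win.startswith(prefix) and win in found:
                    found[win] += 1
            self._partial.update(found)
            self._partial_keys.update(qs)
        return {q: self._partial.get(q, 0) for q in queries}


def build_uniqueness_index(records: Sequence[SequenceRecord], window: int,
                           mode: str = "time_saving",
                           check_revcomp: bool = False) -> UniquenessIndex:
    return UniquenessIndex(records, window, mode, check_revcomp)


def assess_uniqueness(
    pairs: Sequence[tuple[FlankPair, FlankPair, float, float, str]],
    index_a: UniquenessIndex, index_b: UniquenessIndex,
) -> list[CandidateMarker]:
    """Keep a pair only if all four flanks are single-copy in their own
    assembly (count == 1 via the sliding-window index)."""
    queries_a = {fp.left for fp, *_ in pairs} | {fp.right for fp, *_ in pairs}
    queries_b = {t[1].left for t in pairs} | {t[1].right for t in pairs}
    counts_a = index_a.count_many(sorted(queries_a))
    counts_b = index_b.count_many(sorted(queries_b))
    markers = []
    for fa, fb, li, ri, stage in pairs:
        unique_a = counts_a[fa.left] == 1 and counts_a[fa.right] == 1
        unique_b = counts_b[fb.left] == 1 and counts_b[fb.right] == 1
        if unique_a and unique_b:
            markers.append(CandidateMarker(
                locus_a=fa.locus, locus_b=fb.locus, stage=stage,
                left_identity=li, right_identity=ri,
                unique_a=True, unique_b=True,
            ))
    return markers


@dataclass(frozen=True)
class PolymorphismSummary:
    """The headline counts for a two-assembly comparison."""

    total_ssrs_a: int
    total_ssrs_b: int
    candidate_markers: int
    monomorphic: int
    polymorphic: int

    @property
    def candidate_marker_rate(self) -> float:
        """Candidate markers as a percentage of all SSRs mined in assembly 1."""
        if self.total_ssrs_a == 0:
            return 0.0
        return self.candidate_markers / self.total_ssrs_a * 100

    @property
    def polymorphic_rate(self) -> float:
        """Polymorphic markers as a percentage of all SSRs mined in assembly 1."""
        if self.total_ssrs_a == 0:
            return 0.0
        return self.polymorphic / self.total_ssrs_a * 100


def classify(markers: Sequence[CandidateMarker], total_ssrs_a: int,
             total_ssrs_b: int = 0) -> PolymorphismSummary:
    poly = sum(1 for m in markers if m.classification == "polymorphic")
    return PolymorphismSummary(
        total_ssrs_a=total_ssrs_a,
        total_ssrs_b=total_ssrs_b,
        candidate_markers=len(markers),
        monomorphic=len(markers) - poly,
        polymorphic=poly,
    )


def discover_polymorphic(
    records_a: Sequence[SequenceRecord], records_b: Sequence[SequenceRecord],
    config: PolymorphismConfig | None = None,
    thresholds: MotifThresholds | None = None,
    threads: int = 1,
    loci_a: Sequence[SSRLocus] | None = None,
    loci_b: Sequence[SSRLocus] | None = None,
) -> tuple[list[CandidateMarker], PolymorphismSummary]:
    """Run the full two-assembly pipeline.

    Mines SSRs in both assemblies (unless pre-mined loci are supplied),
    extracts flanks, runs the three conservation stages, filters by flank
    uniqueness, and classifies the surviving markers. Markers are returned
    sorted by assembly-1 coordinates.
    """
    config = config or PolymorphismConfig()
    thresholds = thresholds or MotifThresholds.default()
    if loci_a is None:
        loci_a = mine_records(records_a, thresholds, threads=threads)
    if loci_b is None:
        loci_b = mine_records(records_b, thresholds, threads=threads)
    flanks_a = extract_all_flanks(loci_a, records_a, config)
    flanks_b = extract_all_flanks(loci_b, records_b, config)

    exact, rest_a, rest_b = stage1_exact_match(
        flanks_a, flanks_b, config.require_same_motif)
    prealign = stage2_prealign(
        rest_a, rest_b, config.prealign_len, config.prealign_max_mismatch,
        config.require_same_motif)
    verified = stage3_verify(
        prealign, config.method, config.scheme, config.conservation_threshold)

    staged = [(fa, fb, 1.0, 1.0, "exact") for fa, fb in exact]
    staged += [(fa, fb, li, ri, "prealign") for fa, fb, li, ri in verified]

    index_a = build_uniqueness_index(
        records_a, config.flank_len, config.mode, config.check_revcomp)
    index_b = build_uniqueness_index(
        records_b, config.flank_len, config.mode, config.check_revcomp)
    markers = assess_uniqueness(staged, index_a, index_b)
    markers.sort(key=lambda m: (m.locus_a.seq_id, m.locus_a.start))
    summary = classify(markers, len(loci_a), len(loci_b))
    return markers, summary


def markers_to_rows(markers: Sequence[CandidateMarker]) -> list[dict[str, object]]:
    ordered = sorted(markers, key=lambda m: (m.locus_a.seq_id, m.locus_a.start))
    return [m.to_row(i + 1) for i, m in enumerate(ordered)]
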