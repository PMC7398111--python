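"""Synthetic assembly pairs with planted SSRs and a truth table.

The generator lays each sequence out as alternating clean background gaps
and planted perfect repeats, then derives the second assembly from the
first by editing repeat counts (the polymorphism signal), substituting
bases in the flanks at a configurable per-bp rate, and planting confounders:

* duplicated flanks — a copy of a locus's left flank pasted elsewhere, so
  the uniqueness filter must reject it;
* over-divergence — more flank substitutions than the conservation
  threshold allows, placed away from the SSR so the pre-alignment stage
  passes and the verification stage must reject;
* near-SSR heavy mismatch — three substitutions inside the pre-alignment
  windows with otherwise identical flanks, so the pre-alignment stage must
  reject.

Background gaps are rejection-sampled so no repeat within one unit of the
default thresholds occurs near a planted locus, and the bases bordering
each planted repeat are forced to break the repeat so planted coordinates
are exact. Every truth record's expected fate is computed from the realized
edits (verified with the same Levenshtein definition the pipeline is tested
against), so the truth table is exact by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ssrmine.fasta_io import SequenceRecord
from ssrmine.pairwise_align import levenshtein
from ssrmine.polymorphism_pipeline import CandidateMarker, PolymorphismConfig
from ssrmine.ssr_scanner import (
    DEFAULT_MIN_REPEATS,
    MotifThresholds,
    backtrack_size,
    primitive_period,
    scan_sequence,
)

_BASES = "ACGT"

DEFAULT_MOTIF_LENGTH_WEIGHTS: dict[int, float] = {
    1: 0.05, 2: 0.30, 3: 0.25, 4: 0.20, 5: 0.10, 6: 0.10,
}

PAIR_FATES = ("exact_pair", "prealign_pair")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic assembly pair."""

    seed: int
    n_sequences: int = 1
    seq_length: int = 200_000
    n_ssrs: int = 50
    motif_length_weights: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_MOTIF_LENGTH_WEIGHTS))
    repeat_range: Mapping[int, tuple[int, int]] | None = None
    fraction_polymorphic: float = 0.4
    flank_snp_rate: float = 0.01
    fraction_duplicated_flanks: float = 0.0
    fraction_over_divergence: float = 0.0
    fraction_near_ssr_heavy_mismatch: float = 0.0
    min_spacing: int = 300
    config: PolymorphismConfig = field(default_factory=PolymorphismConfig)

    def resolved_repeat_range(self) -> dict[int, tuple[int, int]]:
        if self.repeat_range is not None:
            return dict(self.repeat_range)
        return {l: (r + 1, r + 7) for l, r in DEFAULT_MIN_REPEATS.items()}


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted locus."""

    seq_id: str
    motif: str
    repeats_a: int
    repeats_b: int
    start_a: int
    end_a: int
    start_b: int
    end_b: int
    expected_fate: str    # exact_pair | prealign_pair | dropped_conservation
                          # | dropped_uniqueness | dropped_flank_N_or_edge
    drop_stage: str       # "" | prealign | verify | uniqueness
    expected_classification: str  # monomorphic | polymorphic

    def key_a(self) -> tuple[str, int, int]:
        return (self.seq_id, self.start_a, self.end_a)


def _random_primitive_motif(rng: np.random.Generator, length: int) -> str:
    while True:
        motif = "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
        if primitive_period(motif) == length:
            return motif


def _relaxed_thresholds() -> MotifThresholds:
    # one repeat below the defaults: a single later substitution cannot
    # join two sub-threshold runs into a reportable one except via runs
    # this margin already rejects
    return MotifThresholds.from_dict(
        {l: max(r - 1, 2) for l, r in DEFAULT_MIN_REPEATS.items()})


def _clean_gap(rng: np.random.Generator, length: int,
               forbid_first: str = "", forbid_last: str = "") -> str:
    relaxed = _relaxed_thresholds()
    for _ in range(200):
        arr = rng.integers(0, 4, size=length)
        chars = [_BASES[i] for i in arr]
        if forbid_first and chars[0] in forbid_first:
            chars[0] = rng.choice([b for b in _BASES if b not in forbid_first])
        if forbid_last and chars[-1] in forbid_last:
            chars[-1] = rng.choice([b for b in _BASES if b not in forbid_last])
        gap = "".join(chars)
        probe = SequenceRecord(id="gap", sequence=gap)
        if not scan_sequence(probe, relaxed):
            return gap
    raise RuntimeError("could not generate a repeat-free background gap")


def _draw_snps(rng: np.random.Generator, flank: str, n: int,
               allowed_positions: Sequence[int],
               forbidden_at: Mapping[int, str]) -> dict[int, str]:
    """Choose n substitution positions/bases; the alt base always differs
    from the reference and avoids per-position forbidden bases (used to keep
    the planted repeat's borders broken)."""
    n = min(n, len(allowed_positions))
    positions = rng.choice(len(allowed_positions), size=n, replace=False)
    edits: dict[int, str] = {}
    for idx in sorted(int(i) for i in positions):
        pos = allowed_positions[idx]
        banned = set(flank[pos]) | set(forbidden_at.get(pos, ""))
        alt = rng.choice([b for b in _BASES if b not in banned])
        edits[pos] = alt
    return edits


def _apply_edits(flank: str, edits: Mapping[int, str]) -> str:
    chars = list(flank)
    for pos, alt in edits.items():
        chars[pos] = alt
    return "".join(chars)


@dataclass
class _PlantedLocus:
    motif: str
    repeats_a: int
    repeats_b: int
    role: str  # regular | duplicated | over_divergence | near_heavy


def generate_pair(
    spec: FixtureSpec,
) -> tuple[list[SequenceRecord], list[SequenceRecord], list[TruthRecord]]:
    """Build (assembly_a, assembly_b, truth), deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    cfg = spec.config
    f = cfg.flank_len
    p = cfg.prealign_len
    max_mm = cfg.prealign_max_mismatch
    thr_edits = int(math.floor(cfg.conservation_threshold * f))
    b = backtrack_size(MotifThresholds.default())
    repeat_range = spec.resolved_repeat_range()

    weights_items = sorted(spec.motif_length_weights.items())
    lengths = np.array([l for l, _ in weights_items])
    probs = np.array([w for _, w in weights_items], dtype=float)
    probs /= probs.sum()

    n_dup = math.ceil(spec.fraction_duplicated_flanks * spec.n_ssrs)
    n_div = math.ceil(spec.fraction_over_divergence * spec.n_ssrs)
    n_near = math.ceil(spec.fraction_near_ssr_heavy_mismatch * spec.n_ssrs)
    if n_dup + n_div + n_near > spec.n_ssrs:
        raise ValueError("confounder fractions exceed the number of loci")

    # plan loci: motifs, repeat counts, polymorphism, confounder roles
    n_poly = round(spec.fraction_polymorphic * spec.n_ssrs)
    poly_idx = set(rng.choice(spec.n_ssrs, size=n_poly, replace=False).tolist())
    roles = (["duplicated"] * n_dup + ["over_divergence"] * n_div
             + ["near_heavy"] * n_near)
    roles += ["regular"] * (spec.n_ssrs - len(roles))
    planted: list[_PlantedLocus] = []
    for i in range(spec.n_ssrs):
        l = int(rng.choice(lengths, p=probs))
        motif = _random_primitive_motif(rng, l)
        lo, hi = repeat_range[l]
        r_a = int(rng.integers(lo, hi + 1))
        if i in poly_idx:
            delta = int(rng.integers(1, 4))
            r_b = r_a + delta if (r_a + delta <= hi or r_a - delta < lo) \
                else r_a - delta
            r_b = max(r_b, DEFAULT_MIN_REPEATS[l])
            if r_b == r_a:
                r_b = r_a + 1
        else:
            r_b = r_a
        planted.append(_PlantedLocus(motif, r_a, r_b, roles[i]))

    # distribute loci over sequences round-robin
    per_seq: list[list[_PlantedLocus]] = [[] for _ in range(spec.n_sequences)]
    for i, pl in enumerate(planted):
        per_seq[i % spec.n_sequences].append(pl)

    records_a: list[SequenceRecord] = []
    records_b: list[SequenceRecord] = []
    truth: list[TruthRecord] = []
    for s, loci in enumerate(per_seq):
        seq_id = f"seq{s + 1}"
        rec_a, rec_b, seq_truth = _build_sequence(
            rng, seq_id, loci, spec, f, p, max_mm, thr_edits, b)
        records_a.append(rec_a)
        records_b.append(rec_b)
        truth.extend(seq_truth)
    return records_a, records_b, truth


def _build_sequence(rng, seq_id, loci, spec, f, p, max_mm, thr_edits, b):
    m = len(loci)
    edge_min = max(spec.min_spacing, f + b + 20)
    n_dup = sum(1 for pl in loci if pl.role == "duplicated")
    final_min = edge_min + (f + 20) * n_dup + (f + 20 if n_dup else 0)
    gap_min = [edge_min] + [max(spec.min_spacing, 2 * f + 20)] * max(m - 1, 0) \
        + [final_min]
    if m == 0:
        gap_min = [max(spec.seq_length, 1)]
    ssr_total = sum(len(pl.motif) * pl.repeats_a for pl in loci)
    slack = spec.seq_length - ssr_total - sum(gap_min)
    if slack < 0:
        raise ValueError(
            f"spec infeasible: {m} loci need {ssr_total + sum(gap_min)} bp "
            f"but seq_length is {spec.seq_length}")
    shares = rng.random(len(gap_min))
    extras = np.floor(slack * shares / shares.sum()).astype(int)
    extras[-1] += slack - int(extras.sum())
    gap_lens = [int(g + e) for g, e in zip(gap_min, extras)]

    gaps: list[str] = []
    for i in range(m + 1):
        forbid_first = loci[i - 1].motif[0] if i > 0 else ""
        forbid_last = loci[i].motif[-1] if i < m else ""
        gaps.append(_clean_gap(rng, gap_lens[i], forbid_first, forbid_last))
    if m == 0:
        seq = gaps[0]
        rec = SequenceRecord(id=seq_id, sequence=seq)
        return rec, rec, []

    # paste duplicated-flank copies into the final gap (shared background,
    # so the copy exists in both assemblies)
    dup_slots = iter(range(n_dup))
    dup_paste_at: dict[int, int] = {}
    for i, pl in enumerate(loci):
        if pl.role == "duplicated":
            slot = next(dup_slots)
            dup_paste_at[i] = f + 20 + slot * (f + 20)

    left_a = [gaps[i][-f:] for i in range(m)]
    right_a = [gaps[i + 1][:f] for i in range(m)]
    for i, off in dup_paste_at.items():
        tail = gaps[m]
        gaps[m] = tail[:off] + left_a[i] + tail[off + f:]
        right_a = [gaps[j + 1][:f] for j in range(m)]  # gap m may hold flank m-1

    # derive assembly-B flank edits per locus
    edits_left: list[dict[int, str]] = []
    edits_right: list[dict[int, str]] = []
    for i, pl in enumerate(loci):
        la, ra = left_a[i], right_a[i]
        # keep the repeat borders broken in assembly B too
        forbid_l = {f - 1: pl.motif[-1]}
        forbid_r = {0: pl.motif[0]}
        far_left = list(range(0, f - p))     # outside the near-SSR window
        near_left = list(range(f - p, f))
        near_right = list(range(0, p))
        far_right = list(range(p, f))
        if pl.role == "duplicated":
            el, er = {}, {}
        elif pl.role == "near_heavy":
            el = _draw_snps(rng, la, 2, near_left, forbid_l)
            er = _draw_snps(rng, ra, 1, near_right, forbid_r)
        elif pl.role == "over_divergence":
            for _ in range(50):
                el = _draw_snps(rng, la, thr_edits + 3, far_left, forbid_l)
                if levenshtein(la, _apply_edits(la, el)) > thr_edits:
                    break
            er = {}
        else:
            nl = int(rng.binomial(f, spec.flank_snp_rate))
            nr = int(rng.binomial(f, spec.flank_snp_rate))
            el = _draw_snps(rng, la, nl, list(range(f)), forbid_l)
            er = _draw_snps(rng, ra, nr, list(range(f)), forbid_r)
        edits_left.append(el)
        edits_right.append(er)

    # assemble both sequences and the truth table
    b_gaps = list(gaps)
    for i in range(m):
        if edits_left[i]:
            g = b_gaps[i]
            b_gaps[i] = g[:-f] + _apply_edits(g[-f:], edits_left[i])
        if edits_right[i]:
            g = b_gaps[i + 1]
            b_gaps[i + 1] = _apply_edits(g[:f], edits_right[i]) + g[f:]

    parts_a, parts_b = [gaps[0]], [b_gaps[0]]
    pos_a, pos_b = len(gaps[0]), len(b_gaps[0])
    truth: list[TruthRecord] = []
    for i, pl in enumerate(loci):
        len_a = len(pl.motif) * pl.repeats_a
        len_b = len(pl.motif) * pl.repeats_b
        start_a, end_a = pos_a + 1, pos_a + len_a
        start_b, end_b = pos_b + 1, pos_b + len_b
        parts_a.append(pl.motif * pl.repeats_a)
        parts_b.append(pl.motif * pl.repeats_b)
        parts_a.append(gaps[i + 1])
        parts_b.append(b_gaps[i + 1])
        pos_a = end_a + len(gaps[i + 1])
        pos_b = end_b + len(b_gaps[i + 1])

        la, ra = left_a[i], right_a[i]
        lb = _apply_edits(la, edits_left[i])
        rb = _apply_edits(ra, edits_right[i])
        fate, stage = _expected_fate(
            pl, la, ra, lb, rb, p, max_mm, thr_edits)
        truth.append(TruthRecord(
            seq_id=seq_id, motif=pl.motif,
            repeats_a=pl.repeats_a, repeats_b=pl.repeats_b,
            start_a=start_a, end_a=end_a, start_b=start_b, end_b=end_b,
            expected_fate=fate, drop_stage=stage,
            expected_classification=(
                "polymorphic" if pl.repeats_a != pl.repeats_b
                else "monomorphic"),
        ))
    rec_a = SequenceRecord(id=seq_id, sequence="".join(parts_a))
    rec_b = SequenceRecord(id=seq_id, sequence="".join(parts_b))
    return rec_a, rec_b, truth


def _expected_fate(pl: _PlantedLocus, la: str, ra: str, lb: str, rb: str,
                   p: int, max_mm: int, thr_edits: int) -> tuple[str, str]:
    if pl.role == "duplicated":
        return "dropped_uniqueness", "uniqueness"
    near_mm = sum(x != y for x, y in zip(la[-p:], lb[-p:])) \
        + sum(x != y for x, y in zip(ra[:p], rb[:p]))
    if la == lb and ra == rb:
        return "exact_pair", ""
    if near_mm > max_mm:
        return "dropped_conservation", "prealign"
    if levenshtein(la, lb) <= thr_edits and levenshtein(ra, rb) <= thr_edits:
        return "prealign_pair", ""
    return "dropped_conservation", "verify"


@dataclass(frozen=True)
class EvaluationResult:
    """Pipeline output scored against a fixture's truth table.

    Accidental background repeats are not in the truth table; markers formed
    from them are counted separately as ``extra_markers`` and do not enter
    sensitivity or precision over the planted set.
    """

    n_expected: int
    n_recovered: int
    n_planted_markers: int
    n_correct_markers: int
    extra_markers: int
    stage_mismatches: int

    @property
    def sensitivity(self) -> float:
        return self.n_recovered / self.n_expected if self.n_expected else 1.0

    @property
    def precision(self) -> float:
        return (self.n_correct_markers / self.n_planted_markers
                if self.n_planted_markers else 1.0)


def evaluate_markers(markers: Sequence[CandidateMarker],
                     truth: Sequence[TruthRecord]) -> EvaluationResult:
    by_key = {t.key_a(): t for t in truth}
    expected = [t for t in truth if t.expected_fate in PAIR_FATES]
    recovered = 0
    planted_markers = 0
    correct = 0
    stage_mismatch = 0
    seen_keys = set()
    for mk in markers:
        key = (mk.locus_a.seq_id, mk.locus_a.start, mk.locus_a.end)
        t = by_key.get(key)
        if t is None:
            continue
        planted_markers += 1
        seen_keys.add(key)
        ok = (t.expected_fate in PAIR_FATES
              and mk.classification == t.expected_classification
              and mk.locus_b.repeats == t.repeats_b
              and mk.locus_b.start == t.start_b
              and mk.locus_b.end == t.end_b)
        if ok:
            correct += 1
        expected_stage = "exact" if t.expected_fate == "exact_pair" else "prealign"
        if t.expected_fate in PAIR_FATES and mk.stage != expected_stage:
            stage_mismatch += 1
    recovered = sum(1 for t in expected if t.key_a() in seen_keys)
    return EvaluationResult(
        n_expected=len(expected),
        n_recovered=recovered,
        n_planted_markers=planted_markers,
        n_correct_markers=correct,
        extra_markers=len(markers) - planted_markers,
        stage_mismatches=stage_mismatch,
    )


TRUTH_COLUMNS = (
    "seq_id", "motif", "repeats_a", "repeats_b", "start_a", "end_a",
    "start_b", "end_b", "expected_fate", "drop_stage",
    "expected_classification",
)


def truth_to_rows(truth: Sequence[TruthRecord]) -> list[dict[str, object]]:
    return [
        {c: getattr(t, c) for c in TRUTH_COLUMNS}
        for t in sorted(truth, key=lambda t: (t.seq_id, t.start_a))
    ]
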