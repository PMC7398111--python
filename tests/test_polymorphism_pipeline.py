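from __future__ import annotations

import numpy as np
import pytest

from oracles import oracle_hamming_pairs, random_dna
from ssrmine.fasta_io import SequenceRecord
from ssrmine.polymorphism_pipeline import (
    CandidateMarker,
    FlankPair,
    PolymorphismConfig,
    PolymorphismSummary,
    assess_uniqueness,
    build_uniqueness_index,
    classify,
    discover_polymorphic,
    extract_flanks,
    markers_to_rows,
    stage1_exact_match,
    stage2_prealign,
    stage3_verify,
)
from ssrmine.ssr_scanner import SSRLocus


def _locus(start, end, motif, seq_id="s"):
    return SSRLocus(seq_id, motif, (end - start + 1) // len(motif), start, end)


def _fp(left, right, motif="AG", start=1000, p=5, seq_id="s"):
    end = start + len(motif) * 7 - 1
    return FlankPair(locus=_locus(start, end, motif, seq_id),
                     left=left, right=right, prealign_len=p)


class TestConfig:
    def test_prealign_window_default(self):
        assert PolymorphismConfig().prealign_len == 5      # 5% of 100 bp

    def test_prealign_window_benchmark_flank(self):
        cfg = PolymorphismConfig(flank_len=150)
        assert cfg.prealign_len == 8                       # ceil(150*0.05)

    def test_invalid(self):
        with pytest.raises(ValueError):
            PolymorphismConfig(prealign_pct=0)
        with pytest.raises(ValueError):
            PolymorphismConfig(prealign_max_mismatch=3)


class TestExtractFlanks:
    rec = SequenceRecord("s", "A" * 0 + random_dna(np.random.default_rng(1), 400))

    def test_boundary_fit(self):
        rng = np.random.default_rng(2)
        seq = random_dna(rng, 100) + "AG" * 7 + random_dna(rng, 100)
        rec = SequenceRecord("s", seq)
        fp = extract_flanks(_locus(101, 114, "AG"), rec, flank_len=100)
        assert fp.left == seq[:100] and fp.right == seq[114:214]
        assert fp.key_full == fp.left + fp.right
        assert fp.key_near == fp.left[-5:] + fp.right[:5]

    def test_truncated_flank_excluded(self):
        fp = extract_flanks(_locus(50, 63, "AG"), self.rec, flank_len=100)
        assert fp is None

    def test_n_in_flank_excluded(self):
        seq = "N" + random_dna(np.random.default_rng(3), 99) + "AG" * 7 \
            + random_dna(np.random.default_rng(4), 100)
        fp = extract_flanks(_locus(101, 114, "AG"),
                            SequenceRecord("s", seq), flank_len=100)
        assert fp is None


class TestStage1:
    def test_identical_flanks_pair(self):
        a = _fp("A" * 20, "C" * 20)
        b = _fp("A" * 20, "C" * 20, start=5000)
        matched, ra, rb = stage1_exact_match([a], [b])
        assert matched == [(a, b)] and ra == [] and rb == []

    def test_different_motifs_do_not_pair(self):
        a = _fp("A" * 20, "C" * 20, motif="AG")
        b = _fp("A" * 20, "C" * 20, motif="AC")
        matched, ra, rb = stage1_exact_match([a], [b])
        assert matched == [] and ra == [a] and rb == [b]

    def test_ambiguous_key_goes_to_remainder(self):
        a1 = _fp("A" * 20, "C" * 20, start=100)
        a2 = _fp("A" * 20, "C" * 20, start=900)
        b = _fp("A" * 20, "C" * 20, start=5000)
        matched, ra, rb = stage1_exact_match([a1, a2], [b])
        assert matched == [] and ra == [a1, a2] and rb == [b]


class TestStage2:
    def test_near_key_distance_boundaries(self):
        left_a, right_a = "G" * 20, "T" * 20
        a = _fp(left_a, right_a)
        # distance 2 in the near windows -> kept
        b2 = _fp("G" * 15 + "GGGCC", "T" * 20, start=5000)
        # distance 3 -> dropped
        b3 = _fp("G" * 15 + "GCCCG", "T" * 20, start=6000)
        out = stage2_prealign([a], [b2, b3], p=5, max_mm=2)
        assert out == [(a, b2)]

    def test_full_flanks_may_differ(self):
        a = _fp("A" * 15 + "GCGCG", "TATAC" + "A" * 15)
        b = _fp("C" * 15 + "GCGCG", "TATAC" + "G" * 15, start=5000)
        out = stage2_prealign([a], [b], p=5, max_mm=0)
        assert out == [(a, b)]

    def test_equals_all_pairs_hamming_oracle(self):
        rng = np.random.default_rng(42)
        motifs = ["AG", "AC", "AT"]
        fa = [_fp(random_dna(rng, 20), random_dna(rng, 20),
                  motif=motifs[i % 3], start=100 * (i + 1))
              for i in range(10)]
        fb = [_fp(random_dna(rng, 20), random_dna(rng, 20),
                  motif=motifs[i % 3], start=100 * (i + 1), seq_id="t")
              for i in range(10)]
        # plant one guaranteed collision; the rest collide (or not) at random
        fb[0] = _fp(fa[0].left, fa[0].right, motif="AG", start=100, seq_id="t")
        for max_mm in (0, 1, 2):
            got = stage2_prealign(fa, fb, p=5, max_mm=max_mm)
            got_idx = {(fa.index(x), fb.index(y)) for x, y in got}
            want = oracle_hamming_pairs(
                [(f.locus.motif, f.key_near) for f in fa],
                [(f.locus.motif, f.key_near) for f in fb], max_mm)
            assert got_idx == want


class TestStage3:
    def _diverged(self, base, n, rng):
        chars = list(base)
        pos = rng.choice(len(base), size=n, replace=False)
        for i in pos:
            chars[i] = "T" if chars[i] != "T" else "G"
        return "".join(chars)

    def test_threshold_boundary_ld(self):
        rng = np.random.default_rng(9)
        left = random_dna(rng, 100)
        right = random_dna(rng, 100)
        a = _fp(left, right)
        b_ok = _fp(self._diverged(left, 5, rng), right, start=5000)
        b_bad = _fp(self._diverged(left, 6, rng), right, start=6000)
        kept = stage3_verify([(a, b_ok)], method="ld", threshold=0.05)
        assert len(kept) == 1
        _, _, li, ri = kept[0]
        assert li == pytest.approx(0.95) and ri == 1.0
        assert stage3_verify([(a, b_bad)], method="ld", threshold=0.05) == []

    def test_best_pair_wins(self):
        rng = np.random.default_rng(10)
        left = random_dna(rng, 100)
        right = random_dna(rng, 100)
        a = _fp(left, right)
        b1 = _fp(left, right, start=5000)
        b2 = _fp(self._diverged(left, 4, rng), self._diverged(right, 4, rng),
                 start=6000)
        kept = stage3_verify([(a, b1), (a, b2)], method="ld", threshold=0.05)
        assert [(x.locus.start, y.locus.start) for x, y, *_ in kept] == [(1000, 5000)]

    def test_ambiguous_tie_drops_all(self):
        rng = np.random.default_rng(11)
        left = random_dna(rng, 100)
        right = random_dna(rng, 100)
        a = _fp(left, right)
        b1 = _fp(left, right, start=5000)
        b2 = _fp(left, right, start=6000)
        assert stage3_verify([(a, b1), (a, b2)], method="ld") == []

    def test_nw_method(self):
        rng = np.random.default_rng(12)
        left = random_dna(rng, 100)
        right = random_dna(rng, 100)
        a = _fp(left, right)
        b = _fp(self._diverged(left, 5, rng), right, start=5000)
        kept = stage3_verify([(a, b)], method="nw", threshold=0.05)
        assert len(kept) == 1 and kept[0][2] >= 0.95


class TestUniquenessIndex:
    def test_enumerated_window_counts(self):
        rec = SequenceRecord("s", "ACGTACGT")
        idx = build_uniqueness_index([rec], window=4)
        assert idx.count("ACGT") == 2
        assert idx.count("CGTA") == 1
        assert idx.count("AAAA") == 0

    def test_overlapping_occurrences(self):
        idx = build_uniqueness_index([SequenceRecord("s", "AAAA")], window=2)
        assert idx.count("AA") == 3

    def test_window_longer_than_sequences(self):
        idx = build_uniqueness_index([SequenceRecord("s", "ACG")], window=10)
        assert idx.count("ACGACGACGA") == 0

    def test_modes_agree(self):
        rng = np.random.default_rng(13)
        recs = [SequenceRecord("s1", random_dna(rng, 3000)),
                SequenceRecord("s2", random_dna(rng, 2000))]
        queries = [recs[0].sequence[i:i + 20] for i in (0, 100, 999)] \
            + [random_dna(rng, 20) for _ in range(5)]
        t = build_uniqueness_index(recs, 20, mode="time_saving")
        m = build_uniqueness_index(recs, 20, mode="memory_saving")
        assert t.count_many(queries) == m.count_many(queries)
        assert all(m.count(q) == t.count(q) for q in queries)

    def test_revcomp_counting(self):
        rec = SequenceRecord("s", "ACGTTTTT")
        idx = build_uniqueness_index([rec], window=4, check_revcomp=True)
        # ACGT occurs forward once and its reverse complement is itself
        assert idx.count("ACGT") == 2


class TestAssessUniqueness:
    def _pairs(self, rng, dup_left=False):
        flank = random_dna(rng, 30)
        left_a = random_dna(rng, 30)
        seq_a = left_a + "AG" * 7 + flank + (left_a if dup_left else random_dna(rng, 30))
        seq_b = left_a + "AG" * 9 + flank + random_dna(rng, 30)
        rec_a = SequenceRecord("a", seq_a)
        rec_b = SequenceRecord("b", seq_b)
        fa = FlankPair(_locus(31, 44, "AG", "a"), left_a, flank, 2)
        fb = FlankPair(_locus(31, 48, "AG", "b"), left_a, flank, 2)
        ia = build_uniqueness_index([rec_a], 30)
        ib = build_uniqueness_index([rec_b], 30)
        return [(fa, fb, 1.0, 1.0, "exact")], ia, ib

    def test_single_copy_kept(self):
        pairs, ia, ib = self._pairs(np.random.default_rng(21))
        markers = assess_uniqueness(pairs, ia, ib)
        assert len(markers) == 1 and markers[0].classification == "polymorphic"

    def test_duplicated_left_flank_dropped(self):
        pairs, ia, ib = self._pairs(np.random.default_rng(22), dup_left=True)
        assert assess_uniqueness(pairs, ia, ib) == []

    def test_cross_assembly_duplication_dropped(self):
        rng = np.random.default_rng(23)
        pairs, ia, _ = self._pairs(rng)
        fa, fb, li, ri, stage = pairs[0]
        dup_b = SequenceRecord("b", fb.left + "AG" * 9 + fb.right
                               + "T" + fb.right)
        ib = build_uniqueness_index([dup_b], 30)
        assert assess_uniqueness(pairs, ia, ib) == []


class TestClassify:
    def test_published_rice_rates(self):
        """Rate formula applied to the published rice comparison counts."""
        summary = PolymorphismSummary(
            total_ssrs_a=111_960, total_ssrs_b=0,
            candidate_markers=68_242, monomorphic=50_895, polymorphic=17_347)
        assert summary.candidate_markers == summary.monomorphic + summary.polymorphic
        assert round(summary.polymorphic_rate, 2) == 15.49
        assert round(summary.candidate_marker_rate, 2) == 60.95

    def test_repeat_count_rule(self):
        rng = np.random.default_rng(30)
        left, right = random_dna(rng, 100), random_dna(rng, 100)
        same = CandidateMarker(_locus(101, 114, "AG", "a"),
                               _locus(101, 114, "AG", "b"), "exact", 1.0, 1.0)
        diff = CandidateMarker(_locus(101, 114, "AG", "a"),
                               _locus(101, 118, "AG", "b"), "exact", 1.0, 1.0)
        assert same.classification == "monomorphic"
        assert diff.classification == "polymorphic"
        summary = classify([same, diff], total_ssrs_a=4)
        assert (summary.candidate_markers, summary.monomorphic,
                summary.polymorphic) == (2, 1, 1)
        assert summary.polymorphic_rate == pytest.approx(25.0)


class TestEndToEnd:
    def test_stage1_pairs_would_pass_later_stages(self, clean_fixture):
        """Stage monotonicity: every exact pair also clears pre-alignment
        and verification with identity 1."""
        spec, ra, rb, _ = clean_fixture
        from ssrmine.polymorphism_pipeline import extract_all_flanks
        from ssrmine.ssr_scanner import mine_records
        cfg = spec.config
        fa = extract_all_flanks(mine_records(ra), ra, cfg)
        fb = extract_all_flanks(mine_records(rb), rb, cfg)
        exact, _, _ = stage1_exact_match(fa, fb)
        assert exact
        again = stage2_prealign([x for x, _ in exact], [y for _, y in exact],
                                cfg.prealign_len, cfg.prealign_max_mismatch)
        assert len(again) >= len(exact)
        verified = stage3_verify(again, "ld", threshold=cfg.conservation_threshold)
        kept_keys = {(x.locus.key(), y.locus.key()) for x, y, li, ri in verified
                     if li == 1.0 and ri == 1.0}
        assert {(x.locus.key(), y.locus.key()) for x, y in exact} <= kept_keys

    def test_mode_equivalence_end_to_end(self, clean_fixture, clean_pipeline_result):
        spec, ra, rb, _ = clean_fixture
        markers_time, _ = clean_pipeline_result
        cfg_mem = PolymorphismConfig(mode="memory_saving")
        markers_mem, _ = discover_polymorphic(ra, rb, cfg_mem)
        assert markers_to_rows(markers_time) == markers_to_rows(markers_mem)

    def test_candidate_counts_are_consistent(self, clean_pipeline_result):
        markers, summary = clean_pipeline_result
        assert summary.candidate_markers == len(markers)
        assert summary.candidate_markers == summary.monomorphic + summary.polymorphic
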