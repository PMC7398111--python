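"""Distribution statistics for a mined SSR set.

Three views, mirroring the tool's statistics file: (a) SSR count and
density (loci per Mb, 2 decimals) per assembled sequence; (b) count and
proportion per motif length; (c) count per repeat number within each motif
group, where motifs are pooled by their lexicographically smallest rotation
(so AG and GA count together; reverse complements stay separate unless
requested).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence, TextIO

from ssrmine.polymorphism_pipeline import revcomp
from ssrmine.ssr_scanner import SSRLocus


def canonical_rotation(motif: str, pool_revcomp: bool = False) -> str:
    """Lexicographically smallest rotation of the motif (optionally also
    considering rotations of the reverse complement)."""
    rotations = [motif[i:] + motif[:i] for i in range(len(motif))]
    if pool_revcomp:
        rc = revcomp(motif)
        rotations += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(rotations)


@dataclass(frozen=True)
class StatsSummary:
    per_sequence: list[tuple[str, int, float]]          # (seq_id, count, per-Mb)
    per_motif_length: list[tuple[int, int, float]]      # (l, count, proportion)
    repeat_distribution: dict[tuple[str, int], int]     # (motif group, repeats)

    @property
    def total(self) -> int:
        return sum(n for _, n, _ in self.per_sequence)


def summarize(loci: Sequence[SSRLocus], seq_lengths: Mapping[str, int],
              pool_revcomp: bool = False) -> StatsSummary:
    unknown = {loc.seq_id for loc in loci} - set(seq_lengths)
    if unknown:
        raise ValueError(f"loci reference unknown sequence ids: {sorted(unknown)}")
    per_seq_counts = Counter(loc.seq_id for loc in loci)
    per_sequence = [
        (seq_id,
         per_seq_counts.get(seq_id, 0),
         round(per_seq_counts.get(seq_id, 0) / (length / 1e6), 2) if length else 0.0)
        for seq_id, length in seq_lengths.items()
    ]
    total = len(loci)
    len_counts = Counter(loc.motif_length for loc in loci)
    per_motif_length = [
        (l, n, n / total) for l, n in sorted(len_counts.items())
    ] if total else []
    repeat_distribution = Counter(
        (canonical_rotation(loc.motif, pool_revcomp), loc.repeats)
        for loc in loci
    )
    return StatsSummary(
        per_sequence=per_sequence,
        per_motif_length=per_motif_length,
        repeat_distribution=dict(repeat_distribution),
    )


def write_stats(summary: StatsSummary, fh: TextIO) -> None:
    """Plain-text statistics file with the three labelled TSV sections."""
    fh.write("# (a) SSR number and density in each assembled sequence\n")
    fh.write("seq_id\tssr_count\tdensity_per_Mb\n")
    for seq_id, n, dens in summary.per_sequence:
        fh.write(f"{seq_id}\t{n}\t{dens:.2f}\n")
    fh.write("\n# (b) SSR number and proportion per motif length\n")
    fh.write("motif_len\tssr_count\tproportion\n")
    for l, n, prop in summary.per_motif_length:
        fh.write(f"{l}\t{n}\t{prop:.4f}\n")
    fh.write("\n# (c) SSR number among different numbers of repeats per motif\n")
    fh.write("motif\trepeats\tssr_count\n")
    for (motif, reps), n in sorted(summary.repeat_distribution.items()):
        fh.write(f"{motif}\t{reps}\t{n}\n")
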