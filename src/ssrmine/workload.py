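"""Balanced distribution of sequences across parallel workers.

Work is partitioned by total sequence length (TOS) with the classic
longest-processing-time greedy: sort sequences by length descending, seed
each worker with one of the longest, then repeatedly hand the next sequence
to the least-loaded worker. Ties (equal lengths, equal loads) are broken by
input order / lowest worker index so the plan is deterministic.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Sequence


@dataclass(frozen=True)
class AllocationPlan:
    """Assignment of sequence ids to workers and the resulting loads (bp)."""

    assignments: dict[int, list[str]]
    loads: dict[int, int]

    @property
    def n_workers(self) -> int:
        return len(self.assignments)

    @property
    def makespan(self) -> int:
        return max(self.loads.values()) if self.loads else 0


def allocate_sequences(items: Sequence[tuple[str, int]], k: int) -> AllocationPlan:
    """Partition ``(id, length)`` items over ``k`` workers, balancing load.

    Steps: sort descending by length (stable, so equal lengths keep input
    order); give the i-th longest item to worker i for i < k; then assign
    each remaining item to the worker with the smallest current load
    (lowest index on load ties).
    """
    if k < 1:
        raise ValueError(f"worker count must be >= 1, got {k}")
    ids = [it[0] for it in items]
    if len(set(ids)) != len(ids):
        raise ValueError("sequence ids must be unique")
    if any(length < 0 for _, length in items):
        raise ValueError("sequence lengths must be >= 0")

    order = sorted(items, key=lambda it: -it[1])  # stable: ties keep input order
    assignments: dict[int, list[str]] = {w: [] for w in range(k)}
    loads: dict[int, int] = {w: 0 for w in range(k)}

    heap: list[tuple[int, int]] = []  # (load, worker index)
    for w, (seq_id, length) in enumerate(order[:k]):
        assignments[w].append(seq_id)
        loads[w] = length
    for w in range(k):
        heapq.heappush(heap, (loads[w], w))
    for seq_id, length in order[k:]:
        load, w = heapq.heappop(heap)
        assignments[w].append(seq_id)
        loads[w] = load + length
        heapq.heappush(heap, (loads[w], w))
    return AllocationPlan(assignments=assignments, loads=loads)
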