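"""FASTA input and tabular output.

Sequences are read record-by-record (memory bounded by the largest record,
not file size), upper-cased, and any character outside ``{A,C,G,T,N}`` is
mapped to ``N`` so that IUPAC ambiguity codes cannot seed a repeat or a
flank downstream.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID = frozenset("ACGTN")
# translate anything outside A/C/G/T/N (after upper-casing) to N
_TO_N = {c: "N" for c in map(chr, range(256)) if c.upper() not in _VALID}
_NORMALIZE = str.maketrans({**{c: c.upper() for c in "acgtn"}, **_TO_N})


@dataclass(frozen=True)
class SequenceRecord:
    """One assembled sequence: id (first header token) and its bases."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def _normalize(seq: str, seq_id: str) -> str:
    out = seq.translate(_NORMALIZE)
    if "N" in out:
        n_new = sum(1 for a, b in zip(seq.upper(), out) if a != "N" and b == "N")
        if n_new:
            logger.warning(
                "sequence %s: %d non-ACGTN character(s) mapped to N", seq_id, n_new
            )
    return out


def read_fasta(path: str | os.PathLike) -> Iterator[SequenceRecord]:
    """Stream :class:`SequenceRecord` objects from a FASTA file in file order.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` for a
    duplicate record id. Empty records are skipped with a warning.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"FASTA file not found: {path}")
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq_id = rec.id  # Biopython id = first whitespace-delimited token
        if seq_id in seen:
            raise ValueError(f"duplicate sequence id in {path}: {seq_id!r}")
        seen.add(seq_id)
        seq = str(rec.seq)
        if not seq:
            logger.warning("sequence %s is empty; skipped", seq_id)
            continue
        yield SequenceRecord(id=seq_id, sequence=_normalize(seq, seq_id))


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike,
                line_width: int = 60) -> None:
    """Write records as wrapped FASTA."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), line_width):
                fh.write(rec.sequence[i:i + line_width] + "\n")


def write_table(rows: Sequence[Mapping[str, object]], columns: Sequence[str],
                path: str | os.PathLike,
                sort_keys: tuple[str, str] | None = None) -> None:
    """Write rows as a TSV file with one header line.

    Rows are sorted by ``sort_keys`` for deterministic output; when
    ``sort_keys`` is not given and the columns include ``seq_id`` and
    ``start``, those are used.
    """
    for row in rows:
        missing = [c for c in columns if c not in row]
        if missing:
            raise ValueError(f"row missing columns {missing}")
    ordered = list(rows)
    if sort_keys is None and "seq_id" in columns and "start" in columns:
        sort_keys = ("seq_id", "start")
    if sort_keys is not None:
        k1, k2 = sort_keys
        ordered.sort(key=lambda r: (r[k1], r[k2]))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in ordered:
            fh.write("\t".join(_fmt(row[c]) for c in columns) + "\n")


def read_table(path: str | os.PathLike) -> list[dict[str, str]]:
    """Parse a TSV written by :func:`write_table` back into string-valued rows."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        return [dict(zip(header, line.rstrip("\n").split("\t"))) for line in fh]


def _fmt(value: object) -> str:
    if isinstance(value, float):
        return f"{value:.4f}"
    if value is None:
        return "."
    return str(value)
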