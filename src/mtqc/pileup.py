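"""Per-sample, per-position pileup counts from alignments or TSV.

The pileup unit is strand-resolved read depth plus the number of covering
reads whose alignment places a deletion gap at the position.  A read with
a deletion SPANS the deleted positions, so it contributes to total depth
there as well — this keeps the deletion ratio bounded by 1.  Insertions
carry no reference position and are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from .reference import CircularReference

__all__ = [
    "PositionPileup",
    "PileupTable",
    "pileup_from_alignments",
    "read_pileup_table",
    "write_pileup_table",
    "stack_tables",
]

TSV_HEADER = "sample\tref\tpos\tfwd\trev\tdel\ttotal"


@dataclass(frozen=True)
class PositionPileup:
    """Strand-resolved depth at one 1-based reference position."""

    position: int
    fwd_reads: int
    rev_reads: int
    del_reads: int = 0

    def __post_init__(self):
        if min(self.fwd_reads, self.rev_reads, self.del_reads) < 0:
            raise ValueError("read counts must be non-negative")
        if self.del_reads > self.total_reads:
            raise ValueError("del_reads cannot exceed total_reads")

    @property
    def total_reads(self) -> int:
        return self.fwd_reads + self.rev_reads


class PileupTable:
    """Pileup counts for one sample over every non-placeholder position.

    Columns are held as parallel numpy arrays sorted by position; the
    strand partition invariant (fwd + rev == total) and the deletion bound
    (del <= total) are enforced at construction.
    """

    def __init__(
        self,
        sample_id: str,
        reference_name: str,
        positions: np.ndarray,
        fwd: np.ndarray,
        rev: np.ndarray,
        dele: np.ndarray,
    ):
        positions = np.asarray(positions, dtype=np.int64)
        fwd = np.asarray(fwd, dtype=np.int64)
        rev = np.asarray(rev, dtype=np.int64)
        dele = np.asarray(dele, dtype=np.int64)
        if not (len(positions) == len(fwd) == len(rev) == len(dele)):
            raise ValueError("column length mismatch")
        if len(positions) and np.any(np.diff(positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(fwd < 0) or np.any(rev < 0) or np.any(dele < 0):
            raise ValueError("read counts must be non-negative")
        if np.any(dele > fwd + rev):
            bad = int(positions[np.argmax(dele > fwd + rev)])
            raise ValueError(f"del_reads exceeds total_reads at position {bad}")
        self.sample_id = sample_id
        self.reference_name = reference_name
        self.positions = positions
        self.fwd = fwd
        self.rev = rev
        self.dele = dele

    @property
    def total(self) -> np.ndarray:
        return self.fwd + self.rev

    def __len__(self) -> int:
        return len(self.positions)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PileupTable):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.reference_name == other.reference_name
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.fwd, other.fwd)
            and np.array_equal(self.rev, other.rev)
            and np.array_equal(self.dele, other.dele)
        )

    def at(self, position: int) -> PositionPileup:
        idx = int(np.searchsorted(self.positions, position))
        if idx >= len(self.positions) or self.positions[idx] != position:
            raise KeyError(f"position {position} not in table")
        return PositionPileup(
            position=position,
            fwd_reads=int(self.fwd[idx]),
            rev_reads=int(self.rev[idx]),
            del_reads=int(self.dele[idx]),
        )


def pileup_from_alignments(
    alignment_path: str | Path,
    ref: CircularReference,
    min_mapq: int = 0,
    min_baseq: int = 0,
    count_deletion_span: bool = True,
    sample_id: str | None = None,
) -> PileupTable:
    """Build a pileup table from a SAM/BAM file.

    A read contributes strand-resolved depth at every reference position
    its alignment covers with an aligned base or (when
    ``count_deletion_span`` is set) a deletion gap; it contributes to the
    deletion count exactly at the gap positions.  Disabling
    ``count_deletion_span`` makes gap reads invisible at the deleted
    positions (neither depth nor deletion count), which keeps the
    deletion ratio bounded.  Reads below ``min_mapq`` are skipped,
    aligned bases below ``min_baseq`` are not counted (deletion gaps
    carry no base quality and are unaffected).
    """
    L = ref.length
    fwd = np.zeros(L + 1, dtype=np.int64)
    rev = np.zeros(L + 1, dtype=np.int64)
    dele = np.zeros(L + 1, dtype=np.int64)
    n_mapped = 0
    with pysam.AlignmentFile(str(alignment_path), require_index=False) as af:
        for sq in af.header.get("SQ", []):
            if sq.get("LN") != L:
                raise ValueError(
                    f"alignment reference length {sq.get('LN')} does not match "
                    f"reference length {L}"
                )
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.mapping_quality < min_mapq:
                continue
            n_mapped += 1
            strand = rev if read.is_reverse else fwd
            quals = read.query_qualities
            rpos = read.reference_start  # 0-based
            qpos = 0
            for op, oplen in read.cigartuples or []:
                if op in (0, 7, 8):  # M, =, X
                    for k in range(oplen):
                        if quals is None or quals[qpos + k] >= min_baseq:
                            strand[rpos + k + 1] += 1
                    rpos += oplen
                    qpos += oplen
                elif op == 2:  # D
                    if count_deletion_span:
                        # gap reads span the deleted positions: depth + del
                        dele[rpos + 1 : rpos + oplen + 1] += 1
                        strand[rpos + 1 : rpos + oplen + 1] += 1
                    rpos += oplen
                elif op == 3:  # N
                    rpos += oplen
                elif op in (1, 4):  # I, S consume query only
                    qpos += oplen
                # H, P consume neither
    if n_mapped == 0:
        import warnings

        warnings.warn("no mapped reads; pileup table is all zeros", stacklevel=2)
    keep = np.array([p for p in range(1, L + 1) if p not in ref.placeholder_positions])
    return PileupTable(
        sample_id=sample_id or Path(alignment_path).stem,
        reference_name=ref.name,
        positions=keep,
        fwd=fwd[keep],
        rev=rev[keep],
        dele=dele[keep],
    )


def write_pileup_table(table: PileupTable, tsv_path: str | Path) -> None:
    """Write the bit-exact TSV dialect (LF-terminated, 1-based)."""
    with open(tsv_path, "w", newline="\n") as fh:
        fh.write(TSV_HEADER + "\n")
        total = table.total
        for i in range(len(table)):
            fh.write(
                f"{table.sample_id}\t{table.reference_name}\t{table.positions[i]}\t"
                f"{table.fwd[i]}\t{table.rev[i]}\t{table.dele[i]}\t{total[i]}\n"
            )


def read_pileup_table(
    tsv_path: str | Path, ref: CircularReference | None = None
) -> PileupTable:
    """Read the TSV dialect back; inverse of :func:`write_pileup_table`.

    Row invariants (strand partition, deletion bound) are always checked.
    When ``ref`` is given the position set must equal the reference's
    non-placeholder positions exactly; a gap is reported by position.
    """
    sample_id = reference_name = None
    positions, fwd, rev, dele = [], [], [], []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n")
        if header != TSV_HEADER:
            raise ValueError(f"bad header in {tsv_path}: {header!r}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                raise ValueError(f"line {lineno}: expected 7 fields, got {len(parts)}")
            s, r, pos, f, v, d, t = parts
            try:
                pos, f, v, d, t = int(pos), int(f), int(v), int(d), int(t)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer count field") from exc
            if t != f + v:
                raise ValueError(f"line {lineno}: total != fwd + rev at position {pos}")
            if d > t:
                raise ValueError(f"line {lineno}: del > total at position {pos}")
            if sample_id is None:
                sample_id, reference_name = s, r
            elif s != sample_id or r != reference_name:
                raise ValueError(f"line {lineno}: mixed sample or reference labels")
            positions.append(pos)
            fwd.append(f)
            rev.append(v)
            dele.append(d)
    if sample_id is None:
        raise ValueError(f"empty pileup table in {tsv_path}")
    table = PileupTable(sample_id, reference_name, positions, fwd, rev, dele)
    if ref is not None:
        expected = np.fromiter(ref.positions(), dtype=np.int64)
        if not np.array_equal(table.positions, expected):
            missing = sorted(set(expected.tolist()) - set(table.positions.tolist()))
            extra = sorted(set(table.positions.tolist()) - set(expected.tolist()))
            if missing:
                raise ValueError(f"missing position {missing[0]} in {tsv_path}")
            raise ValueError(f"unexpected position {extra[0]} in {tsv_path}")
    return table


def stack_tables(tables: list[PileupTable]):
    """Stack same-positioned tables into (positions, fwd, rev, dele, total).

    Matrices are samples x positions.  Raises if the position sets differ.
    """
    if not tables:
        raise ValueError("need at least one pileup table")
    positions = tables[0].positions
    for t in tables[1:]:
        if not np.array_equal(t.positions, positions):
            raise ValueError(
                f"position sets differ between samples "
                f"{tables[0].sample_id} and {t.sample_id}"
            )
    fwd = np.stack([t.fwd for t in tables])
    rev = np.stack([t.rev for t in tables])
    dele = np.stack([t.dele for t in tables])
    return positions, fwd, rev, dele, fwd + rev
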