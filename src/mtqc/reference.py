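"""Circular reference genomes and their sequence-motif annotations.

A mitochondrial reference is a single circular sequence addressed with
1-based coordinates.  One position may hold a placeholder character (for
the human rCRS, the historical spacer at position 3107); placeholders are
opaque to every scan — they terminate homopolymer runs and interrupted
C-tracts exactly as a mismatching base would, and they are excluded from
the count of surveyed positions.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from collections import Counter
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

BASES = frozenset("ACGT")

__all__ = [
    "CircularReference",
    "HomopolymerRun",
    "InterruptedCTract",
    "load_reference",
    "load_rcrs",
    "scan_homopolymers",
    "find_interrupted_c_tracts",
    "count_runs_by_type",
    "write_runs_tsv",
]


@dataclass(frozen=True)
class CircularReference:
    """A circular genome with 1-based coordinates.

    Attributes
    ----------
    name : str
        Record label from the FASTA header.
    sequence : str
        Upper-case base string; index ``i`` (0-based) is position ``i + 1``.
    placeholder_positions : frozenset[int]
        1-based positions holding a non-ACGT placeholder character.
    circular : bool
        Whether coordinate arithmetic wraps past the origin.
    """

    name: str
    sequence: str
    placeholder_positions: frozenset[int] = field(default_factory=frozenset)
    circular: bool = True

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def n_surveyed(self) -> int:
        """Number of real (non-placeholder) positions."""
        return self.length - len(self.placeholder_positions)

    def base(self, position: int) -> str:
        """Base at a 1-based position, wrapping circularly."""
        return self.sequence[(position - 1) % self.length]

    def wrap(self, position: int) -> int:
        """Map any integer onto [1, length] circularly."""
        return (position - 1) % self.length + 1

    def is_placeholder(self, position: int) -> bool:
        return self.wrap(position) in self.placeholder_positions

    def positions(self) -> Iterator[int]:
        """All non-placeholder positions in ascending order."""
        for p in range(1, self.length + 1):
            if p not in self.placeholder_positions:
                yield p


@dataclass(frozen=True)
class HomopolymerRun:
    """A maximal run of one repeated base.

    ``end`` may be numerically smaller than ``start`` when the run wraps
    past the origin of a circular genome; ``run_length`` always reflects
    the true span.
    """

    base: str
    start: int
    end: int
    run_length: int

    def positions(self, genome_length: int) -> list[int]:
        """1-based positions covered by the run, in run order."""
        return [(self.start - 1 + k) % genome_length + 1 for k in range(self.run_length)]

    def overlaps(self, lo: int, hi: int, genome_length: int) -> bool:
        """Whether any run position falls in the linear interval [lo, hi]."""
        return any(lo <= p <= hi for p in self.positions(genome_length))


@dataclass(frozen=True)
class InterruptedCTract:
    """Two maximal C runs separated by exactly one non-C base (CnXCn)."""

    left_run: HomopolymerRun
    interrupt_position: int
    interrupt_base: str
    right_run: HomopolymerRun

    def positions(self, genome_length: int) -> list[int]:
        return (
            self.left_run.positions(genome_length)
            + [self.interrupt_position]
            + self.right_run.positions(genome_length)
        )


def load_reference(
    fasta_path: str | Path,
    placeholder_chars: str = "N",
    circular: bool = True,
) -> CircularReference:
    """Load a single-record FASTA as a circular reference.

    Characters listed in ``placeholder_chars`` become placeholder
    positions; any other non-ACGT character is rejected (IUPAC ambiguity
    codes are not expanded).
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"expected a single-record FASTA, got {len(records)} records in {fasta_path}"
        )
    seq = str(records[0].seq).upper()
    if not seq:
        raise ValueError(f"empty sequence in {fasta_path}")
    allowed_placeholders = set(placeholder_chars.upper())
    placeholders = set()
    for i, c in enumerate(seq):
        if c in BASES:
            continue
        if c in allowed_placeholders:
            placeholders.add(i + 1)
        else:
            raise ValueError(f"unexpected character {c!r} at position {i + 1}")
    return CircularReference(
        name=records[0].id,
        sequence=seq,
        placeholder_positions=frozenset(placeholders),
        circular=circular,
    )


def load_rcrs() -> CircularReference:
    """Load the bundled rCRS (NC_012920.1; 16,569 bp, placeholder at 3107)."""
    path = importlib.resources.files("mtqc") / "data" / "rCRS.fasta"
    return load_reference(str(path))


def _linear_runs(seq: str, valid: set[int]) -> list[tuple[str, int, int]]:
    """Maximal runs on the linear sequence as (base, start0, end0).

    ``valid`` holds 0-based indices of real bases; anything else breaks a run.
    """
    runs: list[tuple[str, int, int]] = []
    n = len(seq)
    i = 0
    while i < n:
        if i not in valid:
            i += 1
            continue
        b = seq[i]
        j = i
        while j + 1 < n and j + 1 in valid and seq[j + 1] == b:
            j += 1
        runs.append((b, i, j))
        i = j + 1
    return runs


def scan_homopolymers(
    ref: CircularReference,
    min_len: int = 2,
    wrap: bool | None = None,
) -> list[HomopolymerRun]:
    """All maximal homopolymer runs with ``run_length >= min_len``.

    With ``wrap`` enabled (the default on a circular reference) a run
    spanning the origin is reported once with wrapped coordinates; pass
    ``wrap=False`` to reproduce the counting of linear-coordinate tools.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    if wrap is None:
        wrap = ref.circular
    L = ref.length
    valid = {i for i in range(L) if (i + 1) not in ref.placeholder_positions}
    raw = _linear_runs(ref.sequence, valid)
    if wrap and len(raw) >= 2:
        first, last = raw[0], raw[-1]
        if first[0] == last[0] and first[1] == 0 and last[2] == L - 1:
            # merge across the origin; end index runs past L
            raw = raw[1:-1] + [(last[0], last[1], last[2] + (first[2] - first[1] + 1))]
    runs = []
    for b, s, e in raw:
        length = e - s + 1
        if length < min_len:
            continue
        runs.append(
            HomopolymerRun(base=b, start=s + 1, end=e % L + 1, run_length=length)
        )
    runs.sort(key=lambda r: r.start)
    return runs


def find_interrupted_c_tracts(
    ref: CircularReference,
    min_arm: int = 2,
    wrap: bool | None = None,
) -> list[InterruptedCTract]:
    """Maximal C runs separated by exactly one non-C, non-placeholder base.

    Both arms must have ``run_length >= min_arm``.
    """
    if min_arm < 2:
        raise ValueError("min_arm must be >= 2")
    if wrap is None:
        wrap = ref.circular
    c_runs = [r for r in scan_homopolymers(ref, min_len=2, wrap=wrap) if r.base == "C"]
    c_runs = [r for r in c_runs if r.run_length >= min_arm]
    if len(c_runs) < 2:
        return []
    L = ref.length
    tracts = []
    pairs = list(zip(c_runs, c_runs[1:]))
    if wrap:
        pairs.append((c_runs[-1], c_runs[0]))
    for left, right in pairs:
        if left is right:
            continue
        gap = (right.start - left.end - 1) % L if wrap else right.start - left.end - 1
        if gap != 1:
            continue
        ipos = ref.wrap(left.end + 1)
        ibase = ref.base(ipos)
        if ibase == "C" or ref.is_placeholder(ipos):
            continue
        tracts.append(
            InterruptedCTract(
                left_run=left,
                interrupt_position=ipos,
                interrupt_base=ibase,
                right_run=right,
            )
        )
    return tracts


def count_runs_by_type(
    runs: Iterable[HomopolymerRun],
    classes: Iterable[tuple[str, int]] | None = None,
) -> dict[tuple[str, int], int]:
    """Count runs per (base, run_length) class.

    Classes are exact lengths — a GGG run does not count toward GG.  Pass
    ``classes`` to zero-fill a fixed class list; otherwise only observed
    classes appear.
    """
    counts = Counter((r.base, r.run_length) for r in runs)
    if classes is not None:
        out = {c: 0 for c in classes}
        for key, n in counts.items():
            out[key] = out.get(key, 0) + n
        return out
    return dict(counts)


def write_runs_tsv(runs: Iterable[HomopolymerRun], path: str | Path) -> None:
    """Persist runs as a 1-based inclusive TSV (base, start, end, length)."""
    with open(path, "w") as fh:
        fh.write("base\tstart\tend\tlength\n")
        for r in runs:
            fh.write(f"{r.base}\t{r.start}\t{r.end}\t{r.run_length}\n")
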