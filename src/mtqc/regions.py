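"""Coverage segmentation and motif/region association.

Positions whose across-sample mean coverage meets the high threshold form
HIGH regions, those at or below the low threshold form LOW regions;
everything in between is unassigned.  Same-class runs separated by a
small gap are merged, short regions are dropped, and homopolymer runs or
interrupted C-tracts are cross-tabulated against the resulting classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .metrics import AnalysisConfig
from .reference import HomopolymerRun, InterruptedCTract

__all__ = [
    "RegionClass",
    "CoverageRegion",
    "segment_coverage_regions",
    "homopolymer_region_contingency",
    "motif_coverage_association",
    "detect_coverage_gaps",
]


class RegionClass(str, Enum):
    HIGH = "HIGH"
    LOW = "LOW"


@dataclass(frozen=True)
class CoverageRegion:
    start: int
    end: int
    region_class: RegionClass
    mean_coverage: float
    n_positions: int


def _runs_of(mask: np.ndarray, positions: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, split where coordinates jump by more than 1."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if positions[i] != positions[prev] + 1:
            runs.append((int(positions[start]), int(positions[prev])))
            start = i
        prev = i
    runs.append((int(positions[start]), int(positions[prev])))
    return runs


def segment_coverage_regions(
    mean_cov: np.ndarray,
    cfg: AnalysisConfig = AnalysisConfig(),
    min_region_len: int | None = None,
    merge_gap: int | None = None,
    positions: np.ndarray | None = None,
) -> list[CoverageRegion]:
    """Segment per-position mean coverage into HIGH/LOW regions.

    ``positions`` defaults to 1..len(mean_cov); pass the real coordinate
    vector when placeholders were skipped.  Same-class runs separated by
    at most ``merge_gap`` positions are merged (qualifying positions only
    are counted and averaged); merged regions spanning fewer than
    ``min_region_len`` qualifying positions are dropped.
    """
    mean_cov = np.asarray(mean_cov, dtype=float)
    if positions is None:
        positions = np.arange(1, len(mean_cov) + 1)
    if min_region_len is None:
        min_region_len = cfg.min_region_len
    if merge_gap is None:
        merge_gap = cfg.merge_gap

    out: list[CoverageRegion] = []
    for cls, mask in (
        (RegionClass.HIGH, mean_cov >= cfg.high_cov_threshold),
        (RegionClass.LOW, mean_cov <= cfg.low_cov_threshold),
    ):
        raw = _runs_of(mask, positions)
        merged: list[tuple[int, int]] = []
        for s, e in raw:
            if merged and s - merged[-1][1] - 1 <= merge_gap:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        for s, e in merged:
            sel = mask & (positions >= s) & (positions <= e)
            n_qual = int(sel.sum())
            if n_qual < min_region_len:
                continue
            out.append(
                CoverageRegion(
                    start=s,
                    end=e,
                    region_class=cls,
                    mean_coverage=float(mean_cov[sel].mean()),
                    n_positions=n_qual,
                )
            )
    out.sort(key=lambda r: (r.start, r.region_class.value))
    return out


def _region_overlap(
    item_positions: list[int], region: CoverageRegion
) -> bool:
    return any(region.start <= p <= region.end for p in item_positions)


def homopolymer_region_contingency(
    runs: list[HomopolymerRun],
    regions: list[CoverageRegion],
    genome_length: int,
    fully_contained: bool = False,
) -> dict[tuple[str, int], dict[str, int]]:
    """Cross-tabulate run classes (base, length) by coverage region class.

    A run counts toward a class when it overlaps any region of that class
    (default) or only when fully contained (``fully_contained=True``).  A
    run overlapping both classes is counted in both and flagged via the
    ``"both"`` counter.
    """
    table: dict[tuple[str, int], dict[str, int]] = {}
    for r in runs:
        pos = r.positions(genome_length)
        hit = {RegionClass.HIGH: False, RegionClass.LOW: False}
        for region in regions:
            inside = [region.start <= p <= region.end for p in pos]
            ok = all(inside) if fully_contained else any(inside)
            if ok:
                hit[region.region_class] = True
        key = (r.base, r.run_length)
        row = table.setdefault(key, {"high": 0, "low": 0, "both": 0})
        if hit[RegionClass.HIGH]:
            row["high"] += 1
        if hit[RegionClass.LOW]:
            row["low"] += 1
        if hit[RegionClass.HIGH] and hit[RegionClass.LOW]:
            row["both"] += 1
    return table


@dataclass(frozen=True)
class MotifAssociation:
    n_tracts: int
    n_in_low: int
    fraction_in_low: float | None
    per_tract: tuple[tuple[int, bool], ...]  # (interrupt_position, in_low)


def motif_coverage_association(
    tracts: list[InterruptedCTract],
    regions: list[CoverageRegion],
    genome_length: int,
) -> MotifAssociation:
    """Fraction of interrupted C-tracts overlapping a LOW coverage region."""
    low = [r for r in regions if r.region_class is RegionClass.LOW]
    per_tract = []
    for t in tracts:
        pos = t.positions(genome_length)
        in_low = any(_region_overlap(pos, r) for r in low)
        per_tract.append((t.interrupt_position, in_low))
    n = len(tracts)
    n_in_low = sum(1 for _, ok in per_tract if ok)
    return MotifAssociation(
        n_tracts=n,
        n_in_low=n_in_low,
        fraction_in_low=(n_in_low / n) if n else None,
        per_tract=tuple(per_tract),
    )


def detect_coverage_gaps(
    mean_cov: np.ndarray,
    drop_factor: float = 0.2,
    window: int = 25,
    positions: np.ndarray | None = None,
    circular: bool = True,
) -> list[tuple[int, float, float]]:
    """Positions whose coverage drops below ``drop_factor`` x the flanking
    median (window of ``window`` bp on each side, centre excluded).

    Returns (position, coverage, flanking_median) triples for primer-site
    inspection.
    """
    if not 0 < drop_factor < 1:
        raise ValueError("drop_factor must be in (0, 1)")
    mean_cov = np.asarray(mean_cov, dtype=float)
    n = len(mean_cov)
    if positions is None:
        positions = np.arange(1, n + 1)
    out = []
    for i in range(n):
        if circular:
            idx = [(i + d) % n for d in range(-window, window + 1) if d != 0]
        else:
            idx = [i + d for d in range(-window, window + 1) if d != 0 and 0 <= i + d < n]
        med = float(np.median(mean_cov[idx]))
        if mean_cov[i] <= drop_factor * med:
            out.append((int(positions[i]), float(mean_cov[i]), med))
    return out


def write_regions_tsv(regions: list[CoverageRegion], path) -> None:
    """1-based inclusive region TSV."""
    with open(path, "w", newline="\n") as fh:
        fh.write("start\tend\tclass\tmean_coverage\tn_positions\n")
        for r in regions:
            fh.write(
                f"{r.start}\t{r.end}\t{r.region_class.value}\t"
                f"{r.mean_coverage:.6g}\t{r.n_positions}\n"
            )


def write_contingency_tsv(table: dict[tuple[str, int], dict[str, int]], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("homopolymer\thigh\tlow\tboth\n")
        for (base, length), row in sorted(
            table.items(), key=lambda kv: (kv[0][1], kv[0][0])
        ):
            fh.write(f"{base * length}\t{row['high']}\t{row['low']}\t{row['both']}\n")
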