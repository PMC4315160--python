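"""Per-position strand-bias and deletion-ratio statistics with
genome-wide, multi-sample summaries.

Strand bias at a position is min(fwd, rev) / max(fwd, rev): 1 means
perfect balance, 0 one-sided coverage, undefined at zero depth.  The
deletion ratio (DR) is deletion-bearing reads over total covering reads.
Multi-sample aggregation is the mean over samples of per-sample ratios;
undefined ratios are excluded from means and counts, never treated as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pileup import PileupTable, PositionPileup, stack_tables
from .reference import HomopolymerRun

__all__ = [
    "AnalysisConfig",
    "StrandBiasSummary",
    "FlaggedSite",
    "strand_bias_ratio",
    "deletion_ratio",
    "compute_site_metrics",
    "summarize_strand_bias",
    "flag_high_dr_sites",
    "coverage_summary",
]

# C-tract neighbourhoods excluded from concordance by default; widths are a
# free parameter, only the anchor positions (310, 16189) are fixed.
DEFAULT_EXCLUSION_ZONES = ((302, 316), (16180, 16195))
DEFAULT_REPEAT_ZONES = ((514, 524),)


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and zones for the whole analysis."""

    sb_balance_threshold: float = 0.5
    sb_extreme_threshold: float = 0.1
    dr_flag_threshold: float = 0.15
    high_cov_threshold: float = 810.0
    low_cov_threshold: float = 500.0
    exclusion_zones: tuple[tuple[int, int], ...] = DEFAULT_EXCLUSION_ZONES
    repeat_zones: tuple[tuple[int, int], ...] = DEFAULT_REPEAT_ZONES
    min_region_len: int = 5
    merge_gap: int = 2
    homopolymer_adjacency: int = 1
    gap_window: int = 25
    gap_drop_factor: float = 0.2

    def __post_init__(self):
        for name in ("sb_balance_threshold", "sb_extreme_threshold", "dr_flag_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.low_cov_threshold >= self.high_cov_threshold:
            raise ValueError("low_cov_threshold must be < high_cov_threshold")


def strand_bias_ratio(fwd: int, rev: int) -> float | None:
    """min/max strand coverage ratio; None at zero depth."""
    if fwd < 0 or rev < 0:
        raise ValueError("counts must be non-negative")
    if fwd + rev == 0:
        return None
    return min(fwd, rev) / max(fwd, rev)


def deletion_ratio(p: PositionPileup) -> float | None:
    """del_reads / total_reads; None at zero depth."""
    if p.total_reads == 0:
        return None
    return p.del_reads / p.total_reads


def _sb_matrix(fwd: np.ndarray, rev: np.ndarray) -> np.ndarray:
    """Per-sample strand-bias ratios, NaN where depth is zero."""
    lo = np.minimum(fwd, rev).astype(float)
    hi = np.maximum(fwd, rev).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(hi > 0, lo / hi, np.nan)


def _dr_matrix(dele: np.ndarray, total: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, dele / total, np.nan)


def compute_site_metrics(tables: list[PileupTable]) -> pd.DataFrame:
    """Per-position mean coverage, mean strand bias and mean DR.

    Returns a DataFrame with columns pos, mean_cov, mean_sb, mean_dr,
    n_samples_defined; means are over samples with non-zero depth.
    """
    positions, fwd, rev, dele, total = stack_tables(tables)
    sb = _sb_matrix(fwd, rev)
    dr = _dr_matrix(dele, total)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        return pd.DataFrame(
            {
                "pos": positions,
                "mean_cov": total.mean(axis=0),
                "mean_sb": np.nanmean(sb, axis=0),
                "mean_dr": np.nanmean(dr, axis=0),
                "n_samples_defined": (total > 0).sum(axis=0),
            }
        )


@dataclass(frozen=True)
class StrandBiasSummary:
    n_defined: int
    n_above_balance: int
    frac_above_balance: float | None
    n_extreme: int
    per_position: pd.DataFrame = field(repr=False)


def summarize_strand_bias(
    tables: list[PileupTable], cfg: AnalysisConfig = AnalysisConfig()
) -> StrandBiasSummary:
    """Genome-wide summary of per-position mean strand-bias ratios.

    Counts, over positions whose mean ratio is defined: how many exceed
    the balance threshold (strictly) and how many sit at or below the
    extreme threshold.
    """
    positions, fwd, rev, _, total = stack_tables(tables)
    sb = _sb_matrix(fwd, rev)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean_sb = np.nanmean(sb, axis=0)
    defined = ~np.isnan(mean_sb)
    n_defined = int(defined.sum())
    n_above = int((mean_sb[defined] > cfg.sb_balance_threshold).sum())
    n_extreme = int((mean_sb[defined] <= cfg.sb_extreme_threshold).sum())
    per_position = pd.DataFrame({"pos": positions, "mean_sb": mean_sb})
    return StrandBiasSummary(
        n_defined=n_defined,
        n_above_balance=n_above,
        frac_above_balance=(n_above / n_defined) if n_defined else None,
        n_extreme=n_extreme,
        per_position=per_position,
    )


@dataclass(frozen=True)
class FlaggedSite:
    position: int
    max_dr: float
    mean_dr: float
    samples_exceeding: tuple[str, ...]
    in_homopolymer: bool


def flag_high_dr_sites(
    tables: list[PileupTable],
    cfg: AnalysisConfig = AnalysisConfig(),
    runs: list[HomopolymerRun] | None = None,
    genome_length: int | None = None,
    min_total: int = 0,
) -> list[FlaggedSite]:
    """Sites where ANY sample's DR strictly exceeds the flag threshold.

    Samples with depth below ``min_total`` at a position do not
    contribute.  Each flagged site is annotated with whether it lies
    inside or within ``cfg.homopolymer_adjacency`` bp of a homopolymer
    run (when ``runs`` is supplied).
    """
    positions, _, _, dele, total = stack_tables(tables)
    dr = _dr_matrix(dele, total)
    dr = np.where(total >= max(min_total, 1), dr, np.nan)
    with np.errstate(invalid="ignore"):
        exceed = dr > cfg.dr_flag_threshold
    flagged_cols = np.flatnonzero(np.any(exceed, axis=0))

    hp_positions: set[int] = set()
    if runs is not None:
        if genome_length is None:
            genome_length = int(positions[-1])
        w = cfg.homopolymer_adjacency
        for r in runs:
            for p in r.positions(genome_length):
                for d in range(-w, w + 1):
                    hp_positions.add((p - 1 + d) % genome_length + 1)

    sample_ids = [t.sample_id for t in tables]
    out = []
    for col in flagged_cols:
        col_dr = dr[:, col]
        defined = ~np.isnan(col_dr)
        pos = int(positions[col])
        out.append(
            FlaggedSite(
                position=pos,
                max_dr=float(np.nanmax(col_dr)),
                mean_dr=float(np.nanmean(col_dr)),
                samples_exceeding=tuple(
                    sample_ids[i] for i in np.flatnonzero(exceed[:, col])
                ),
                in_homopolymer=pos in hp_positions if runs is not None else False,
            )
        )
    return out


def coverage_summary(
    tables: list[PileupTable],
) -> tuple[np.ndarray, float, float]:
    """Per-position mean coverage plus its grand mean and SD over positions."""
    _, _, _, _, total = stack_tables(tables)
    mean_cov = total.mean(axis=0)
    return mean_cov, float(mean_cov.mean()), float(mean_cov.std(ddof=1))


def write_site_metrics_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def write_flagged_sites_tsv(sites: list[FlaggedSite], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("position\tmax_dr\tmean_dr\tsamples_exceeding\tin_homopolymer\n")
        for s in sites:
            fh.write(
                f"{s.position}\t{s.max_dr:.6g}\t{s.mean_dr:.6g}\t"
                f"{','.join(s.samples_exceeding)}\t{int(s.in_homopolymer)}\n"
            )
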