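"""Ground-truth simulators for every pipeline stage.

All simulation is pileup-resolution: depth is drawn from an
overdispersed (gamma-Poisson) model around a planted coverage profile,
forward-strand counts are binomial in a per-position strand fraction, and
deletion-bearing reads are binomial in a context-dependent error
probability.  Read-level SAM emission is a thin extra layer used only to
exercise the alignment-file pileup builder.  Every generator takes a
seeded ``numpy`` Generator and is byte-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .concordance import Haplotype, Variant, canonicalize_variant
from .pileup import PileupTable
from .reference import (
    CircularReference,
    HomopolymerRun,
    InterruptedCTract,
    scan_homopolymers,
)

__all__ = [
    "PlantedRun",
    "PlantedTract",
    "DipSpec",
    "DrSite",
    "SimulationConfig",
    "ReferenceTruth",
    "PileupTruth",
    "HaplotypePairTruth",
    "simulate_reference",
    "simulate_pileups",
    "simulate_haplotype_pair",
    "simulate_sam",
]

BASES = "ACGT"


@dataclass(frozen=True)
class PlantedRun:
    base: str
    start: int
    length: int


@dataclass(frozen=True)
class PlantedTract:
    """CnXCn motif planted at ``start`` (left arm first position)."""

    start: int
    left_len: int
    interrupt_base: str
    right_len: int

    @property
    def span(self) -> int:
        return self.left_len + 1 + self.right_len


@dataclass(frozen=True)
class DipSpec:
    """Coverage multiplier over a closed 1-based interval."""

    start: int
    end: int
    factor: float


@dataclass(frozen=True)
class DrSite:
    position: int
    prob: float


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 16569
    n_samples: int = 24
    chip_size: int = 6
    coverage_mean: float = 810.0
    coverage_sd: float = 664.0
    dips: tuple[DipSpec, ...] = ()
    # strand-fraction mixture: balanced Beta(c, c) around 0.5 vs a skewed
    # Beta component flipped to either strand
    sb_balanced_frac: float = 0.75
    sb_balanced_conc: float = 30.0
    sb_skewed_alpha: float = 1.0
    sb_skewed_beta: float = 12.0
    # deletion-error probabilities by sequence context
    dr_baseline: float = 0.0
    dr_c_run: float = 0.0
    dr_gg: float = 0.0
    dr_sites: tuple[DrSite, ...] = ()
    # reference layout
    placeholder_position: int | None = None
    planted_runs: tuple[PlantedRun, ...] = ()
    planted_tracts: tuple[PlantedTract, ...] = ()
    # haplotypes
    n_shared_variants: tuple[int, int] = (31, 98)
    n_discordant: int = 0
    n_shifted_indels: int = 0
    avoid_zones: tuple[tuple[int, int], ...] = ((302, 316), (514, 524), (16180, 16195))

    def __post_init__(self):
        for p in (self.dr_baseline, self.dr_c_run, self.dr_gg, self.sb_balanced_frac):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        for d in self.dips:
            if not 0 < d.factor <= 1:
                raise ValueError("dip factors must be in (0, 1]")


@dataclass
class ReferenceTruth:
    runs: list[HomopolymerRun]
    tracts: list[InterruptedCTract]
    run_classes: dict


@dataclass
class PileupTruth:
    expected_depth: np.ndarray  # per non-placeholder position
    strand_fraction: np.ndarray
    del_prob: np.ndarray
    positions: np.ndarray
    dips: tuple[DipSpec, ...]
    dr_sites: tuple[DrSite, ...]
    chip_of_sample: dict


@dataclass
class HaplotypePairTruth:
    shared: list[Variant]
    discordant: list[tuple[Variant, str]]  # (variant, platform carrying it)
    shifted_pairs: list[tuple[Variant, Variant]]  # (form on A, form on B)


def _intervals_of_planted(cfg: SimulationConfig) -> list[tuple[int, int]]:
    iv = []
    if cfg.placeholder_position is not None:
        iv.append((cfg.placeholder_position, cfg.placeholder_position))
    for r in cfg.planted_runs:
        iv.append((r.start, r.start + r.length - 1))
    for t in cfg.planted_tracts:
        iv.append((t.start, t.start + t.span - 1))
    return sorted(iv)


def simulate_reference(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[CircularReference, ReferenceTruth]:
    """Build a circular reference holding exactly the planted motifs.

    Filler bases never repeat their neighbour (including across the
    origin and against planted motif edges), so no unplanned run of
    length >= 2 — and hence no unplanned tract — can arise.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    L = cfg.genome_length
    seq = [""] * L

    planted = _intervals_of_planted(cfg)
    for (s1, e1), (s2, e2) in zip(planted, planted[1:]):
        if s2 <= e1 + 1:
            raise ValueError(
                f"planted motifs at {s1}-{e1} and {s2}-{e2} overlap or touch"
            )
    if planted and planted[0][0] == 1 and planted[-1][1] == L:
        raise ValueError("planted motifs may not touch both genome ends")

    if cfg.placeholder_position is not None:
        seq[cfg.placeholder_position - 1] = "N"
    for r in cfg.planted_runs:
        if r.start + r.length - 1 > L:
            raise ValueError(f"planted run at {r.start} exceeds genome length")
        for k in range(r.length):
            seq[r.start - 1 + k] = r.base
    for t in cfg.planted_tracts:
        if t.start + t.span - 1 > L:
            raise ValueError(f"planted tract at {t.start} exceeds genome length")
        block = "C" * t.left_len + t.interrupt_base + "C" * t.right_len
        for k, b in enumerate(block):
            seq[t.start - 1 + k] = b

    for i in range(L):
        if seq[i]:
            continue
        prev_b = seq[i - 1]  # circular: i == 0 looks at the (possibly empty) end
        next_b = seq[(i + 1) % L]
        choices = [b for b in BASES if b != prev_b and b != next_b]
        seq[i] = choices[int(rng.integers(len(choices)))]

    ref = CircularReference(
        name="synthetic",
        sequence="".join(seq),
        placeholder_positions=frozenset(
            {cfg.placeholder_position} if cfg.placeholder_position else set()
        ),
        circular=True,
    )
    runs = scan_homopolymers(ref, min_len=2)
    from .reference import count_runs_by_type, find_interrupted_c_tracts

    truth = ReferenceTruth(
        runs=runs,
        tracts=find_interrupted_c_tracts(ref, min_arm=2),
        run_classes=count_runs_by_type(runs),
    )
    return ref, truth


def _depth_draw(
    rng: np.random.Generator, mean: np.ndarray, sd: float
) -> np.ndarray:
    """Gamma-Poisson depth with per-position mean and common dispersion.

    SD scales with the local mean (sd_pos = sd * mean_pos / global_mean is
    NOT used; instead sd applies where the dip factor is 1 and shrinks
    proportionally inside dips).  sd == 0 gives deterministic rounding.
    """
    if sd <= 0:
        return np.maximum(np.rint(mean).astype(np.int64), 1)
    base = mean.max()
    rel_sd = sd / base if base > 0 else 0.0
    var = (rel_sd * mean) ** 2
    out = np.empty_like(mean, dtype=np.int64)
    over = var > mean
    lam = np.array(mean, dtype=float)
    if over.any():
        r = mean[over] ** 2 / (var[over] - mean[over])
        theta = (var[over] - mean[over]) / mean[over]
        lam[over] = rng.gamma(shape=r, scale=theta)
    out = rng.poisson(lam).astype(np.int64)
    return np.maximum(out, 1)


def simulate_pileups(
    ref: CircularReference,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[PileupTable], PileupTruth]:
    """Draw per-sample pileup tables around the planted profile."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    positions = np.fromiter(ref.positions(), dtype=np.int64)
    n_pos = len(positions)

    factor = np.ones(ref.length + 1)
    for d in cfg.dips:
        factor[d.start : d.end + 1] = d.factor
    expected_depth = cfg.coverage_mean * factor[positions]

    # positional strand fraction, shared by all samples (it is a property
    # of local sequence context, not of the library)
    balanced = rng.random(n_pos) < cfg.sb_balanced_frac
    frac = np.where(
        balanced,
        rng.beta(cfg.sb_balanced_conc, cfg.sb_balanced_conc, size=n_pos),
        rng.beta(cfg.sb_skewed_alpha, cfg.sb_skewed_beta, size=n_pos),
    )
    flip = rng.random(n_pos) < 0.5
    frac = np.where(flip, 1.0 - frac, frac)

    del_prob = np.full(n_pos, cfg.dr_baseline)
    pos_index = {int(p): i for i, p in enumerate(positions)}
    for r in scan_homopolymers(ref, min_len=2):
        if r.base == "C" and cfg.dr_c_run > 0:
            for p in r.positions(ref.length):
                if p in pos_index:
                    del_prob[pos_index[p]] = cfg.dr_c_run
        if r.base == "G" and r.run_length == 2 and cfg.dr_gg > 0:
            for p in r.positions(ref.length):
                if p in pos_index:
                    del_prob[pos_index[p]] = cfg.dr_gg
    for site in cfg.dr_sites:
        if site.position not in pos_index:
            raise ValueError(f"dr site {site.position} is not a real position")
        del_prob[pos_index[site.position]] = site.prob

    tables = []
    for i in range(cfg.n_samples):
        depth = _depth_draw(rng, expected_depth, cfg.coverage_sd)
        fwd = rng.binomial(depth, frac)
        dele = rng.binomial(depth, del_prob)
        tables.append(
            PileupTable(
                sample_id=f"S{i + 1:02d}",
                reference_name=ref.name,
                positions=positions,
                fwd=fwd,
                rev=depth - fwd,
                dele=dele,
            )
        )
    truth = PileupTruth(
        expected_depth=expected_depth,
        strand_fraction=frac,
        del_prob=del_prob,
        positions=positions,
        dips=cfg.dips,
        dr_sites=cfg.dr_sites,
        chip_of_sample={
            f"S{i + 1:02d}": i // cfg.chip_size + 1 for i in range(cfg.n_samples)
        },
    )
    return tables, truth


def _right_shift(v: Variant, ref: CircularReference) -> Variant:
    """Rightmost equivalent representation of an indel (for exercising
    canonicalization; inverse direction of the canonical form)."""
    L = ref.length
    pos = v.position
    if v.var_type.value == "DEL":
        allele = v.ref_allele
        for _ in range(L):
            nxt = ref.wrap(pos + len(allele))
            if ref.base(nxt) != allele[0] or ref.is_placeholder(nxt):
                break
            allele = allele[1:] + ref.base(nxt)
            pos = ref.wrap(pos + 1)
        return Variant(position=pos, ref_allele=allele, alt_allele="")
    allele = v.alt_allele
    for _ in range(L):
        nxt = ref.wrap(pos + 1)
        if ref.base(nxt) != allele[0] or ref.is_placeholder(nxt):
            break
        allele = allele[1:] + allele[0]
        pos = nxt
    return Variant(position=pos, ref_allele="", alt_allele=allele)


def simulate_haplotype_pair(
    ref: CircularReference,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    sample_id: str = "S01",
    platforms: tuple[str, str] = ("A", "B"),
) -> tuple[Haplotype, Haplotype, HaplotypePairTruth]:
    """Emit two platforms' haplotypes with planted shared variants,
    planted discordances on alternating platforms, and a configurable
    number of shared deletions emitted right-shifted on platform B.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    L = ref.length

    def ok_position(p: int, used: set[int]) -> bool:
        if p in used or ref.is_placeholder(p):
            return False
        return not any(lo <= p <= hi for lo, hi in cfg.avoid_zones)

    used: set[int] = set()

    def draw_positions(n: int) -> list[int]:
        out = []
        while len(out) < n:
            p = int(rng.integers(1, L + 1))
            if ok_position(p, used):
                used.add(p)
                out.append(p)
        return out

    lo, hi = cfg.n_shared_variants
    n_shared = int(rng.integers(lo, hi + 1))
    shared = []
    for p in draw_positions(n_shared):
        refb = ref.base(p)
        alts = [b for b in BASES if b != refb]
        shared.append(
            Variant(position=p, ref_allele=refb, alt_allele=alts[int(rng.integers(3))])
        )

    shifted_pairs: list[tuple[Variant, Variant]] = []
    c_runs = [
        r
        for r in scan_homopolymers(ref, min_len=3)
        if r.start > 1 and not any(
            lo_ <= p <= hi_
            for p in r.positions(L)
            for lo_, hi_ in cfg.avoid_zones
        )
    ]
    rng.shuffle(c_runs)
    for r in c_runs[: cfg.n_shifted_indels]:
        left = canonicalize_variant(
            Variant(position=r.start, ref_allele=r.base, alt_allele=""), ref
        )
        left = Variant(left.position, left.ref_allele, left.alt_allele)  # drop flag
        right = _right_shift(left, ref)
        shifted_pairs.append((left, right))
        for p in range(left.position, right.position + 1):
            used.add(p)

    discordant: list[tuple[Variant, str]] = []
    for j, p in enumerate(draw_positions(cfg.n_discordant)):
        refb = ref.base(p)
        alts = [b for b in BASES if b != refb]
        v = Variant(position=p, ref_allele=refb, alt_allele=alts[int(rng.integers(3))])
        discordant.append((v, platforms[j % 2]))

    va = list(shared) + [lv for lv, _ in shifted_pairs] + [
        v for v, plat in discordant if plat == platforms[0]
    ]
    vb = list(shared) + [rv for _, rv in shifted_pairs] + [
        v for v, plat in discordant if plat == platforms[1]
    ]
    hap_a = Haplotype(sample_id=sample_id, platform_label=platforms[0],
                      variants=tuple(sorted(va, key=lambda v: v.position)))
    hap_b = Haplotype(sample_id=sample_id, platform_label=platforms[1],
                      variants=tuple(sorted(vb, key=lambda v: v.position)))
    return hap_a, hap_b, HaplotypePairTruth(
        shared=shared, discordant=discordant, shifted_pairs=shifted_pairs
    )


def simulate_sam(
    ref: CircularReference,
    path: str | Path,
    n_reads: int = 500,
    read_len: int = 100,
    del_read_frac: float = 0.1,
    max_del_len: int = 3,
    rng: np.random.Generator | None = None,
    sample_id: str = "sim",
) -> PileupTable:
    """Write a plain-text SAM of random gapless/one-deletion reads and
    return the truth pileup computed directly from the emitted records.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    L = ref.length
    fwd = np.zeros(L + 1, dtype=np.int64)
    rev = np.zeros(L + 1, dtype=np.int64)
    dele = np.zeros(L + 1, dtype=np.int64)
    lines = [
        "@HD\tVN:1.6\tSO:unknown",
        f"@SQ\tSN:{ref.name}\tLN:{L}",
    ]
    for i in range(n_reads):
        is_rev = bool(rng.integers(2))
        flag = 16 if is_rev else 0
        has_del = rng.random() < del_read_frac
        if has_del:
            dlen = int(rng.integers(1, max_del_len + 1))
            doff = int(rng.integers(10, read_len - 10))  # M-block split point
            span = read_len + dlen
            start = int(rng.integers(1, L - span + 1))
            cigar = f"{doff}M{dlen}D{read_len - doff}M"
            seq = ref.sequence[start - 1 : start - 1 + doff] + ref.sequence[
                start - 1 + doff + dlen : start - 1 + span
            ]
            strand = rev if is_rev else fwd
            strand[start : start + doff] += 1
            strand[start + doff : start + doff + dlen] += 1  # deletion span
            dele[start + doff : start + doff + dlen] += 1
            strand[start + doff + dlen : start + span] += 1
        else:
            start = int(rng.integers(1, L - read_len + 1))
            cigar = f"{read_len}M"
            seq = ref.sequence[start - 1 : start - 1 + read_len]
            strand = rev if is_rev else fwd
            strand[start : start + read_len] += 1
        lines.append(
            f"r{i:05d}\t{flag}\t{ref.name}\t{start}\t60\t{cigar}\t*\t0\t0\t"
            f"{seq}\t{'I' * len(seq)}"
        )
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
    keep = np.fromiter(ref.positions(), dtype=np.int64)
    return PileupTable(
        sample_id=sample_id,
        reference_name=ref.name,
        positions=keep,
        fwd=fwd[keep],
        rev=rev[keep],
        dele=dele[keep],
    )
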