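"""Variant canonicalization on a circular genome and cross-platform
haplotype comparison.

Different alignment pipelines can place the same indel at different
coordinates inside a repeat context (the classic mitochondrial example is
the 9-bp deletion reported both as positions 8280-8288 and 8281-8289).
Canonicalization left-aligns every indel — shifting it toward smaller
positions, across the circular origin if need be — so that equivalent
representations collapse onto one key before comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import pysam

from .metrics import AnalysisConfig
from .reference import CircularReference

__all__ = [
    "VarType",
    "Variant",
    "Haplotype",
    "ConcordanceReport",
    "canonicalize_variant",
    "compare_haplotypes",
    "read_variants",
    "write_diff_table",
    "write_concordance_report",
]


class VarType(str, Enum):
    SNP = "SNP"
    INS = "INS"
    DEL = "DEL"


@dataclass(frozen=True)
class Variant:
    """A difference from the reference.

    ``position`` is 1-based.  For a DEL it is the first deleted position
    and ``ref_allele`` the deleted bases (``alt_allele`` empty).  For an
    INS the inserted bases (``alt_allele``) sit immediately AFTER
    ``position`` (``ref_allele`` empty).  SNPs carry one base on each side.
    """

    position: int
    ref_allele: str
    alt_allele: str
    canonical: bool = False

    def __post_init__(self):
        t = self.var_type  # validates allele shape

    @property
    def var_type(self) -> VarType:
        if self.ref_allele and self.alt_allele:
            if len(self.ref_allele) == 1 and len(self.alt_allele) == 1:
                return VarType.SNP
            raise ValueError(
                f"unsupported allele pair {self.ref_allele!r}>{self.alt_allele!r}"
            )
        if self.ref_allele:
            return VarType.DEL
        if self.alt_allele:
            return VarType.INS
        raise ValueError("empty ref and alt")

    @property
    def end(self) -> int:
        """Last reference position touched (== position for SNP/INS)."""
        if self.var_type is VarType.DEL:
            return self.position + len(self.ref_allele) - 1
        return self.position

    def key(self) -> tuple[str, int, str, str]:
        return (self.var_type.value, self.position, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class Haplotype:
    """A sample's list of differences from the reference."""

    sample_id: str
    platform_label: str
    variants: tuple[Variant, ...]

    def __post_init__(self):
        seen = set()
        for v in self.variants:
            k = (v.position, v.ref_allele, v.alt_allele)
            if k in seen:
                raise ValueError(f"duplicate variant {k} in {self.sample_id}")
            seen.add(k)


def _check_ref_match(v: Variant, ref: CircularReference) -> None:
    if v.var_type is VarType.INS:
        return
    for k, b in enumerate(v.ref_allele):
        have = ref.base(v.position + k)
        if have != b:
            raise ValueError(
                f"ref allele mismatch at position {ref.wrap(v.position + k)}: "
                f"variant says {b!r}, reference has {have!r}"
            )


def canonicalize_variant(v: Variant, ref: CircularReference) -> Variant:
    """Left-align an indel to its smallest equivalent position.

    The indel is shifted one position left while the reference base
    preceding it equals its last base, wrapping across the circular
    origin; iteration is capped at one full genome turn to terminate on
    degenerate (periodic) sequences.  SNPs are returned unchanged apart
    from the canonical flag.
    """
    _check_ref_match(v, ref)
    if v.var_type is VarType.SNP:
        return replace(v, canonical=True)
    L = ref.length
    pos = v.position
    if v.var_type is VarType.DEL:
        allele = v.ref_allele
        for _ in range(L):
            if pos == 1 and not ref.circular:
                break
            prev = ref.wrap(pos - 1)
            if ref.base(prev) != allele[-1] or ref.is_placeholder(prev):
                break
            allele = ref.base(prev) + allele[:-1]
            pos = prev
        return Variant(position=pos, ref_allele=allele, alt_allele="", canonical=True)
    # INS anchored after `pos`; on a linear reference pos may reach 0,
    # meaning the insertion precedes the first base
    allele = v.alt_allele
    for _ in range(L):
        if pos < 1:
            break
        anchor = ref.wrap(pos)
        if ref.base(anchor) != allele[-1] or ref.is_placeholder(anchor):
            break
        allele = allele[-1] + allele[:-1]
        pos = ref.wrap(pos - 1) if ref.circular else pos - 1
    return Variant(position=pos, ref_allele="", alt_allele=allele, canonical=True)


def _in_zones(v: Variant, zones) -> bool:
    return any(not (v.end < lo or v.position > hi) for lo, hi in zones)


@dataclass(frozen=True)
class ConcordanceReport:
    sample_id: str
    platform_a: str
    platform_b: str
    n_concordant: int
    n_discordant: int
    n_excluded: int
    n_inconclusive: int
    per_platform: dict = field(default_factory=dict)
    discordant_detail: tuple[tuple[Variant, str], ...] = ()

    @property
    def n_total_pre_exclusion(self) -> int:
        """Distinct canonical variants before any zone filtering."""
        return self.n_concordant + self.n_discordant + self.n_excluded + self.n_inconclusive


def compare_haplotypes(
    a: Haplotype,
    b: Haplotype,
    ref: CircularReference,
    cfg: AnalysisConfig = AnalysisConfig(),
    repeat_zones=None,
) -> ConcordanceReport:
    """Bucket two platforms' variants: excluded / inconclusive /
    concordant / discordant.

    Variants are canonicalized, then routed: overlap with an exclusion
    zone -> excluded; overlap with a repeat zone (default the 514-524
    dinucleotide repeat) -> inconclusive; the rest are matched on the
    canonical key — present in both platforms means concordant, present
    in one means discordant with platform attribution.
    """
    if a.sample_id != b.sample_id:
        raise ValueError(f"sample mismatch: {a.sample_id} vs {b.sample_id}")
    if repeat_zones is None:
        repeat_zones = cfg.repeat_zones

    def buckets(h: Haplotype):
        # zone routing looks at the ORIGINAL span too: left alignment can
        # shift a repeat-context indel to just before its zone boundary
        comp, excl, inc = {}, 0, 0
        for v in h.variants:
            cv = canonicalize_variant(v, ref)
            if _in_zones(cv, cfg.exclusion_zones) or _in_zones(v, cfg.exclusion_zones):
                excl += 1
            elif _in_zones(cv, repeat_zones) or _in_zones(v, repeat_zones):
                inc += 1
            else:
                comp[cv.key()] = cv
        return comp, excl, inc

    comp_a, excl_a, inc_a = buckets(a)
    comp_b, excl_b, inc_b = buckets(b)
    shared = comp_a.keys() & comp_b.keys()
    only_a = comp_a.keys() - comp_b.keys()
    only_b = comp_b.keys() - comp_a.keys()
    detail = tuple(
        sorted(
            [(comp_a[k], a.platform_label) for k in only_a]
            + [(comp_b[k], b.platform_label) for k in only_b],
            key=lambda t: t[0].position,
        )
    )
    per_platform = {
        a.platform_label: {
            "n_variants": len(a.variants),
            "n_concordant": len(shared),
            "n_discordant": len(only_a),
            "n_excluded": excl_a,
            "n_inconclusive": inc_a,
        },
        b.platform_label: {
            "n_variants": len(b.variants),
            "n_concordant": len(shared),
            "n_discordant": len(only_b),
            "n_excluded": excl_b,
            "n_inconclusive": inc_b,
        },
    }
    return ConcordanceReport(
        sample_id=a.sample_id,
        platform_a=a.platform_label,
        platform_b=b.platform_label,
        n_concordant=len(shared),
        n_discordant=len(only_a) + len(only_b),
        n_excluded=excl_a + excl_b,
        n_inconclusive=inc_a + inc_b,
        per_platform=per_platform,
        discordant_detail=detail,
    )


def _variant_from_vcf_alleles(pos: int, ref_allele: str, alt_allele: str) -> Variant:
    """Reduce a VCF REF/ALT pair (anchor-base convention) to a Variant."""
    ref_allele, alt_allele = ref_allele.upper(), alt_allele.upper()
    # trim shared suffix, keeping at least one base on the longer side
    while len(ref_allele) > 1 and len(alt_allele) > 1 and ref_allele[-1] == alt_allele[-1]:
        ref_allele, alt_allele = ref_allele[:-1], alt_allele[:-1]
    # trim shared prefix, advancing the position
    while ref_allele and alt_allele and ref_allele[0] == alt_allele[0]:
        ref_allele, alt_allele = ref_allele[1:], alt_allele[1:]
        pos += 1
    if ref_allele and alt_allele:
        if len(ref_allele) == 1 and len(alt_allele) == 1:
            return Variant(position=pos, ref_allele=ref_allele, alt_allele=alt_allele)
        raise ValueError(f"complex substitution at {pos} not supported")
    if ref_allele:  # deletion: pos is the first deleted base
        return Variant(position=pos, ref_allele=ref_allele, alt_allele="")
    # insertion: inserted bases follow the base before the trimmed point
    return Variant(position=pos - 1, ref_allele="", alt_allele=alt_allele)


def read_variants(
    path: str | Path,
    fmt: str = "auto",
    sample_id: str = "",
    platform_label: str = "",
) -> Haplotype:
    """Read a VCF (4.x) or a diff-table (``pos<TAB>ref<TAB>alt``, "-" for
    an empty allele) into a Haplotype.  Multi-allelic VCF rows are split.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "vcf" if path.suffix.lower() == ".vcf" else "diff"
    variants: list[Variant] = []
    if fmt == "vcf":
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                for alt in rec.alts or ():
                    variants.append(
                        _variant_from_vcf_alleles(rec.pos, rec.ref, alt)
                    )
    elif fmt == "diff":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(f"line {lineno}: expected 3 fields")
                pos, r, alt = parts
                r = "" if r == "-" else r.upper()
                alt = "" if alt == "-" else alt.upper()
                variants.append(
                    Variant(position=int(pos), ref_allele=r, alt_allele=alt)
                )
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return Haplotype(
        sample_id=sample_id or path.stem,
        platform_label=platform_label or fmt,
        variants=tuple(variants),
    )


def write_diff_table(h: Haplotype, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for v in sorted(h.variants, key=lambda v: v.position):
            fh.write(f"{v.position}\t{v.ref_allele or '-'}\t{v.alt_allele or '-'}\n")


def write_concordance_report(report: ConcordanceReport, path: str | Path) -> None:
    """TSV summary plus per-discordance detail rows."""
    with open(path, "w", newline="\n") as fh:
        fh.write("sample\tconcordant\tdiscordant\texcluded\tinconclusive\n")
        fh.write(
            f"{report.sample_id}\t{report.n_concordant}\t{report.n_discordant}\t"
            f"{report.n_excluded}\t{report.n_inconclusive}\n"
        )
        fh.write("#discordant detail: position\tref\talt\tplatform\n")
        for v, platform in report.discordant_detail:
            fh.write(
                f"#{v.position}\t{v.ref_allele or '-'}\t{v.alt_allele or '-'}\t{platform}\n"
            )
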