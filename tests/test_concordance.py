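import pytest
from hypothesis import given, settings, strategies as st

from mtqc.concordance import (
    Haplotype,
    Variant,
    VarType,
    canonicalize_variant,
    compare_haplotypes,
    read_variants,
    write_concordance_report,
    write_diff_table,
)
from mtqc.metrics import AnalysisConfig

from conftest import make_ref


def apply_variant(seq: str, v: Variant) -> str:
    """Brute-force application of a variant to a linear sequence string."""
    p = v.position
    if v.var_type is VarType.SNP:
        assert seq[p - 1] == v.ref_allele
        return seq[: p - 1] + v.alt_allele + seq[p:]
    if v.var_type is VarType.DEL:
        assert seq[p - 1 : p - 1 + len(v.ref_allele)] == v.ref_allele
        return seq[: p - 1] + seq[p - 1 + len(v.ref_allele) :]
    return seq[:p] + v.alt_allele + seq[p:]  # INS after position p


class TestCanonicalizeVariant:
    def test_nine_bp_deletion_nomenclatures_agree(self, rcrs):
        a = canonicalize_variant(Variant(8280, "ACCCCCTCT", ""), rcrs)
        b = canonicalize_variant(Variant(8281, "CCCCCTCTA", ""), rcrs)
        assert a.key() == b.key()
        assert a.canonical and b.canonical

    def test_snp_unchanged(self, rcrs):
        v = Variant(1438, "A", "G")
        cv = canonicalize_variant(v, rcrs)
        assert (cv.position, cv.ref_allele, cv.alt_allele) == (1438, "A", "G")
        assert cv.canonical

    def test_insertion_placements_collapse(self):
        # "AACCCCGT": a C inserted after any of positions 3..7 is equivalent
        ref = make_ref("AACCCCGT", circular=False)
        keys = {
            canonicalize_variant(Variant(p, "", "C"), ref).key() for p in range(2, 7)
        }
        assert len(keys) == 1
        assert keys.pop()[1] == 2  # anchored after position 2 (before the Cs)

    def test_ref_mismatch_raises(self, rcrs):
        with pytest.raises(ValueError, match="position 1438"):
            canonicalize_variant(Variant(1438, "C", "G"), rcrs)

    def test_idempotence(self, rcrs):
        v = canonicalize_variant(Variant(8281, "CCCCCTCTA", ""), rcrs)
        assert canonicalize_variant(v, rcrs).key() == v.key()

    def test_shift_across_origin(self):
        # circular "CAAT": deleting the A at 3 shifts... run is 2-3, leftmost 2
        ref = make_ref("CAAT")
        v = canonicalize_variant(Variant(3, "A", ""), ref)
        assert v.position == 2
        # wrap case: genome "AATA", delete A at 4 -> run spans 4,1,2
        ref2 = make_ref("AATA")
        w = canonicalize_variant(Variant(4, "A", ""), ref2)
        assert w.position == 4  # leftmost via wrap: 4 precedes 1 on the circle

    def test_placeholder_blocks_shift(self):
        ref = make_ref("ANAAT")
        v = canonicalize_variant(Variant(4, "A", ""), ref)
        assert v.position == 3  # cannot shift past the N at 2

    @settings(max_examples=300, deadline=None)
    @given(data=st.data())
    def test_equivalence_class_soundness(self, data):
        # all equivalent sliding placements of an indel map to one key, and
        # the canonical form applies to the same edited sequence
        seq = data.draw(st.text(alphabet="ACGT", min_size=8, max_size=64))
        ref = make_ref(seq, circular=False)
        is_del = data.draw(st.booleans())
        if is_del:
            p = data.draw(st.integers(2, len(seq) - 2))
            k = data.draw(st.integers(1, min(4, len(seq) - p)))
            v = Variant(p, seq[p - 1 : p - 1 + k], "")
        else:
            p = data.draw(st.integers(1, len(seq) - 1))
            ins = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=4))
            v = Variant(p, "", ins)
        edited = apply_variant(seq, v)
        cv = canonicalize_variant(v, ref)
        assert cv.position >= (1 if v.var_type is VarType.DEL else 0)
        assert apply_variant(seq, cv) == edited
        # every representation that edits to the same string has the same key
        if v.var_type is VarType.DEL:
            k = len(v.ref_allele)
            for q in range(1, len(seq) - k + 2):
                w = Variant(q, seq[q - 1 : q - 1 + k], "")
                if apply_variant(seq, w) == edited:
                    assert canonicalize_variant(w, ref).key() == cv.key()
        else:
            for q in range(0, len(seq)):
                w = Variant(q, "", v.alt_allele)
                if apply_variant(seq, w) == edited:
                    assert canonicalize_variant(w, ref).key() == cv.key()


class TestCompareHaplotypes:
    def hap(self, variants, sample="S01", platform="A"):
        return Haplotype(sample_id=sample, platform_label=platform,
                         variants=tuple(variants))

    def test_identical_lists_concordant(self, rcrs):
        vs = [Variant(1438, "A", "G"), Variant(8280, "ACCCCCTCT", "")]
        r = compare_haplotypes(
            self.hap(vs), self.hap(vs, platform="B"), rcrs,
            AnalysisConfig(exclusion_zones=(), repeat_zones=()),
        )
        assert (r.n_concordant, r.n_discordant) == (2, 0)

    def test_c_tract_insertion_excluded(self, rcrs):
        a = self.hap([Variant(310, "", "C")])
        b = self.hap([Variant(310, "", "CC")], platform="B")
        r = compare_haplotypes(a, b, rcrs)
        assert r.n_discordant == 0
        assert r.n_excluded >= 1

    def test_ca_repeat_inconclusive(self, rcrs):
        a = self.hap([Variant(523, "", "CA")])
        b = self.hap([], platform="B")
        r = compare_haplotypes(a, b, rcrs)
        assert r.n_inconclusive == 1
        assert r.n_discordant == 0

    def test_discordant_attribution(self, rcrs):
        a = self.hap([Variant(1438, "A", "G"), Variant(2706, "A", "G")])
        b = self.hap([Variant(1438, "A", "G"), Variant(7028, "C", "T")], platform="B")
        r = compare_haplotypes(a, b, rcrs)
        assert r.n_concordant == 1
        assert r.n_discordant == 2
        plats = {v.position: p for v, p in r.discordant_detail}
        assert plats == {2706: "A", 7028: "B"}

    def test_shifted_nomenclatures_concordant(self, rcrs):
        a = self.hap([Variant(8280, "ACCCCCTCT", "")])
        b = self.hap([Variant(8281, "CCCCCTCTA", "")], platform="B")
        r = compare_haplotypes(a, b, rcrs)
        assert (r.n_concordant, r.n_discordant) == (1, 0)

    def test_bucket_conservation(self, rcrs):
        a = self.hap([Variant(310, "", "C"), Variant(523, "", "CA"),
                      Variant(1438, "A", "G"), Variant(2706, "A", "G")])
        b = self.hap([Variant(1438, "A", "G")], platform="B")
        r = compare_haplotypes(a, b, rcrs)
        for h in (a, b):
            pp = r.per_platform[h.platform_label]
            assert (
                pp["n_concordant"] + pp["n_discordant"]
                + pp["n_excluded"] + pp["n_inconclusive"]
            ) == len(h.variants)

    def test_sample_mismatch_rejected(self, rcrs):
        with pytest.raises(ValueError, match="sample mismatch"):
            compare_haplotypes(
                self.hap([], sample="S01"), self.hap([], sample="S02"), rcrs
            )


class TestReadVariants:
    VCF_HEADER = (
        "##fileformat=VCFv4.2\n"
        '##contig=<ID=chrM,length=16569>\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
    )

    def test_vcf_deletion_anchor_convention(self, tmp_path, rcrs):
        # anchor-base row for the 9-bp deletion: REF covers 8279-8288,
        # ALT is the anchor base at 8279
        p = tmp_path / "x.vcf"
        ref_allele = rcrs.sequence[8278:8288]
        p.write_text(
            self.VCF_HEADER
            + f"chrM\t8279\t.\t{ref_allele}\t{ref_allele[0]}\t.\tPASS\t.\n"
        )
        hap = read_variants(p)
        assert len(hap.variants) == 1
        v = hap.variants[0]
        assert v.var_type is VarType.DEL
        assert (v.position, v.ref_allele) == (8280, "ACCCCCTCT")
        cv = canonicalize_variant(v, rcrs)
        want = canonicalize_variant(Variant(8281, "CCCCCTCTA", ""), rcrs)
        assert cv.key() == want.key()

    def test_vcf_snp(self, tmp_path):
        p = tmp_path / "x.vcf"
        p.write_text(self.VCF_HEADER + "chrM\t1438\t.\tA\tG\t.\tPASS\t.\n")
        hap = read_variants(p)
        assert hap.variants[0].key() == ("SNP", 1438, "A", "G")

    def test_vcf_insertion(self, tmp_path):
        p = tmp_path / "x.vcf"
        p.write_text(self.VCF_HEADER + "chrM\t310\t.\tT\tTC\t.\tPASS\t.\n")
        v = read_variants(p).variants[0]
        assert v.var_type is VarType.INS
        assert (v.position, v.alt_allele) == (310, "C")

    def test_vcf_multiallelic_split(self, tmp_path):
        p = tmp_path / "x.vcf"
        p.write_text(self.VCF_HEADER + "chrM\t100\t.\tA\tG,T\t.\tPASS\t.\n")
        hap = read_variants(p)
        assert len(hap.variants) == 2

    def test_empty_vcf(self, tmp_path):
        p = tmp_path / "x.vcf"
        p.write_text(self.VCF_HEADER)
        assert read_variants(p).variants == ()

    def test_diff_table_round_trip(self, tmp_path):
        p = tmp_path / "h.tsv"
        hap = Haplotype("S01", "diff", (
            Variant(1438, "A", "G"),
            Variant(8280, "ACCCCCTCT", ""),
            Variant(310, "", "C"),
        ))
        write_diff_table(hap, p)
        back = read_variants(p, sample_id="S01")
        assert sorted(v.key() for v in back.variants) == sorted(
            v.key() for v in hap.variants
        )

    def test_diff_table_snp_row(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("1438\tA\tG\n")
        assert read_variants(p).variants[0].key() == ("SNP", 1438, "A", "G")

    def test_report_writer(self, tmp_path, rcrs):
        a = Haplotype("S01", "A", (Variant(1438, "A", "G"),))
        b = Haplotype("S01", "B", ())
        r = compare_haplotypes(a, b, rcrs)
        out = tmp_path / "report.tsv"
        write_concordance_report(r, out)
        text = out.read_text()
        assert "S01\t0\t1\t0\t0" in text
        assert "#1438\tA\tG\tA" in text
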