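"""I/O layer: VCF parsing/writing, multi-allelic splitting, BED masks."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from denovotrio import (
    GenomeMask,
    VariantRecord,
    overlaps_mask,
    read_intervals_bed,
    read_multisample_vcf,
    read_pedigree,
    read_sv_vcf,
    write_vcf,
)
from denovotrio.model import GenotypeCall
from denovotrio.variant_io import BedParseError, VcfParseError

from oracles import bf_mask_overlap

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##INFO=<ID=QD,Number=1,Type=Float,Description="x">
##INFO=<ID=FS,Number=1,Type=Float,Description="x">
##INFO=<ID=SOR,Number=1,Type=Float,Description="x">
##FORMAT=<ID=GT,Number=1,Type=String,Description="x">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="x">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="x">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tmum\tkid
"""


def _write(tmp_path, body, name="x.vcf"):
    p = tmp_path / name
    p.write_text(VCF_HEADER + body)
    return p


class TestReadVcf:
    def test_multiallelic_split_reslices_ad(self, tmp_path):
        body = "chr1\t100\t.\tA\tT,G\t.\t.\tQD=20\tGT:AD:DP\t0/1:50,4,6:60\t1/2:10,20,30:60\n"
        records, samples = read_multisample_vcf(_write(tmp_path, body))
        assert samples == ["mum", "kid"]
        assert len(records) == 2
        t, g = records
        assert (t.alt, g.alt) == ("T", "G")
        assert t.pos == g.pos == 100
        # AD re-sliced per alt allele
        assert (t.calls[0].ad_ref, t.calls[0].ad_alt) == (50, 4)
        assert (g.calls[0].ad_ref, g.calls[0].ad_alt) == (50, 6)
        # GT 1/2 carries one copy of each alt in the bi-allelic view
        assert t.calls[1].gt == "0/1"
        assert g.calls[1].gt == "0/1"

    def test_annotations_mapped_and_missing_stay_absent(self, tmp_path):
        body = "chr1\t5\t.\tC\tT\t.\t.\tQD=1.9;SOR=3.5\tGT:AD:DP\t0/0:30,0:30\t0/1:15,15:30\n"
        records, _ = read_multisample_vcf(_write(tmp_path, body))
        (rec,) = records
        assert rec.annotations == pytest.approx({"QD": 1.9, "SOR": 3.5})
        assert "FS" not in rec.annotations  # absent, not zero

    def test_empty_body_returns_sample_order(self, tmp_path):
        records, samples = read_multisample_vcf(_write(tmp_path, ""))
        assert records == []
        assert samples == ["mum", "kid"]

    def test_chrom_prefix_normalised(self, tmp_path):
        body = "1\t5\t.\tC\tT\t.\t.\t.\tGT:AD:DP\t0/0:30,0:30\t0/1:15,15:30\n"
        records, _ = read_multisample_vcf(_write(tmp_path, body))
        assert records[0].chrom == "chr1"

    def test_malformed_header_raises(self, tmp_path):
        p = tmp_path / "bad.vcf"
        p.write_text("not a vcf at all\n")
        with pytest.raises(VcfParseError):
            read_multisample_vcf(p)

    def test_split_conserves_site_alt_pairs(self, tmp_path):
        body = (
            "chr1\t100\t.\tA\tT,G\t.\t.\t.\tGT:AD:DP\t0/1:5,5,0:10\t0/0:9,0,0:9\n"
            "chr1\t200\t.\tC\tT\t.\t.\t.\tGT:AD:DP\t0/1:5,5:10\t0/0:9,0:9\n"
        )
        records, _ = read_multisample_vcf(_write(tmp_path, body))
        assert len({(r.chrom, r.pos, r.ref, r.alt) for r in records}) == 3


@st.composite
def _record_corpus(draw):
    n_samples = draw(st.integers(1, 4))
    n = draw(st.integers(1, 8))
    positions = draw(
        st.lists(st.integers(1, 10_000), min_size=n, max_size=n, unique=True)
    )
    records = []
    for pos in sorted(positions):
        ref = draw(st.text("ACGT", min_size=1, max_size=4))
        alt = draw(st.text("ACGT", min_size=1, max_size=4))
        if not ref or not alt or ref == alt:
            ref, alt = "A", "T"
        ann = {}
        if draw(st.booleans()):
            ann["QD"] = float(draw(st.integers(0, 40)))
        if draw(st.booleans()):
            ann["SOR"] = float(draw(st.integers(0, 10)))
        calls = []
        for _ in range(n_samples):
            gt = draw(st.sampled_from(["0/0", "0/1", "1/1", "./."]))
            dp = draw(st.one_of(st.none(), st.integers(0, 200)))
            if dp is None or draw(st.booleans()):
                ad_ref = ad_alt = None
            else:
                ad_ref = draw(st.integers(0, dp))
                ad_alt = dp - ad_ref
            calls.append(GenotypeCall(gt=gt, ad_ref=ad_ref, ad_alt=ad_alt, dp=dp))
        records.append(
            VariantRecord(
                chrom="chr1", pos=pos, ref=ref, alt=alt,
                annotations=ann, calls=tuple(calls),
            )
        )
    samples = [f"s{i}" for i in range(n_samples)]
    return records, samples


class TestRoundTrip:
    @given(_record_corpus())
    def test_write_read_preserves_fields(self, tmp_path_factory, corpus):
        records, samples = corpus
        path = tmp_path_factory.mktemp("rt") / "rt.vcf"
        write_vcf(records, samples, path, contigs=[("chr1", 20_000)])
        back, back_samples = read_multisample_vcf(path)
        assert back_samples == samples
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert (a.chrom, a.pos, a.ref, a.alt) == (b.chrom, b.pos, b.ref, b.alt)
            for ca, cb in zip(a.calls, b.calls):
                assert ca.gt == cb.gt
                assert ca.ad_ref == cb.ad_ref
                assert ca.ad_alt == cb.ad_alt
                assert ca.dp == cb.dp


class TestBed:
    def test_overlapping_lines_merge(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t20\nchr1\t15\t30\n")
        mask = read_intervals_bed(p)
        assert mask.intervals() == [("chr1", 10, 30)]

    def test_multiple_files_union(self, tmp_path):
        a, b = tmp_path / "a.bed", tmp_path / "b.bed"
        a.write_text("chr1\t0\t10\n")
        b.write_text("chr2\t5\t15\n")
        mask = read_intervals_bed([a, b])
        assert mask.intervals() == [("chr1", 0, 10), ("chr2", 5, 15)]

    def test_inverted_interval_raises(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t20\t10\n")
        with pytest.raises(BedParseError, match="start 20 >= end 10"):
            read_intervals_bed(p)


def _snv(chrom, pos, ref="A", alt="T"):
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt)


class TestOverlapsMask:
    @pytest.mark.parametrize(
        "pos,ref,expected",
        [
            (11, "A", True),  # 0-based base 10 in [10, 20)
            (10, "A", False),  # 0-based base 9 outside
            (8, "AAAAA", True),  # deletion REF spans 1-based 8..12
            (21, "A", False),  # 0-based 20 just past the half-open end
        ],
    )
    def test_boundary_cases(self, pos, ref, expected):
        mask = GenomeMask([("chr1", 10, 20)])
        alt = "T" if len(ref) == 1 else ref[0]
        v = _snv("chr1", pos, ref=ref, alt=alt)
        assert overlaps_mask(v, mask) is expected
        s, e = v.span0
        assert bf_mask_overlap("chr1", s, e, [("chr1", 10, 20)]) is expected

    def test_agrees_with_per_base_oracle_on_random_pairs(self):
        rng = np.random.default_rng(5)
        intervals = []
        for _ in range(30):
            s = int(rng.integers(0, 950))
            intervals.append(("chr1", s, s + int(rng.integers(1, 40))))
        mask = GenomeMask(intervals)
        for _ in range(1000):
            pos = int(rng.integers(1, 1000))
            ref_len = int(rng.integers(1, 6))
            ref = "A" * ref_len
            alt = "T" if ref_len == 1 else "A"
            v = _snv("chr1", pos, ref=ref, alt=alt)
            s, e = v.span0
            assert overlaps_mask(v, mask) == bf_mask_overlap("chr1", s, e, intervals)


class TestTables:
    def test_pedigree_round_trip(self, small_bundle):
        ped = read_pedigree(small_bundle.paths["pedigree"])
        assert ped.samples == small_bundle.pedigree.samples
        assert ped.group == small_bundle.pedigree.group
        assert ped.sire == small_bundle.pedigree.sire

    def test_sv_vcf_round_trip(self, small_bundle):
        back, samples = read_sv_vcf(small_bundle.paths["sv_vcf"])
        assert samples == small_bundle.samples
        orig = small_bundle.sv_records
        assert len(back) == len(orig)
        for a, b in zip(orig, back):
            assert a.key == b.key
            assert a.su == b.su
            assert a.qual == pytest.approx(b.qual)
            assert a.gts == b.gts
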