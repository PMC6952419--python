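"""Filter cascade: hard filters, sample-level filters, proximity and
SV-overlap exclusions, parental subtraction, and whole-cascade properties."""

import math

import numpy as np
import pytest

from denovotrio import (
    FilterConfig,
    VariantRecord,
    apply_indel_hard_filters,
    apply_snv_hard_filters,
    call_denovo_cohort,
    excessive_depth_cutoff,
    exclude_sv_overlapping_simple_indels,
    remove_near_indel,
    sample_level_filter,
    subtract_parental,
)
from denovotrio.denovo_filters import (
    ConfigError,
    complex_indel_steps,
    FAIL,
    PASS,
)
from denovotrio.model import ComplexIndelRecord, GenomeMask, GenotypeCall

from oracles import bf_denovo, random_mini_cohort

CFG = FilterConfig()


def _snv(pos=100, chrom="chr1", ref="C", alt="T", ann=None, calls=()):
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        annotations=ann or {}, calls=tuple(calls),
    )


class TestHardFilters:
    def test_low_qd_fails_with_reason(self):
        ok, reasons = apply_snv_hard_filters(_snv(ann={"QD": 1.9}), CFG)
        assert not ok and reasons == ("QD",)

    def test_all_annotations_absent_pass(self):
        ok, reasons = apply_snv_hard_filters(_snv(ann={}), CFG)
        assert ok and reasons == ()

    def test_good_annotations_pass_all_six(self):
        ann = {"QD": 30, "FS": 0.5, "MQ": 60, "MQRankSum": 0,
               "ReadPosRankSum": 0, "SOR": 1.0}
        ok, _ = apply_snv_hard_filters(_snv(ann=ann), CFG)
        assert ok

    def test_indel_fs_threshold_differs_from_snv(self):
        indel = _snv(ref="CAT", alt="C", ann={"FS": 250.0})
        ok, reasons = apply_indel_hard_filters(indel, CFG)
        assert not ok and reasons == ("FS",)
        # 150 would fail the SNV rule (>60) but passes the indel rule (>200)
        ok, _ = apply_indel_hard_filters(_snv(ref="CAT", alt="C", ann={"FS": 150.0}), CFG)
        assert ok

    def test_sor_boundary_is_strict(self):
        ok, _ = apply_indel_hard_filters(_snv(ref="CAT", alt="C", ann={"SOR": 10.0}), CFG)
        assert ok
        ok, _ = apply_snv_hard_filters(_snv(ann={"SOR": 3.0}), CFG)
        assert ok


class TestExcessiveDepth:
    def test_perfect_square(self):
        assert excessive_depth_cutoff(100) == 130.0
        assert excessive_depth_cutoff(1) == 4.0

    def test_default_depth(self):
        assert excessive_depth_cutoff(60) == pytest.approx(60 + 3 * math.sqrt(60), abs=1e-12)

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ConfigError):
            excessive_depth_cutoff(0)
        with pytest.raises(ConfigError):
            FilterConfig(d=-1)


def _steps_dict(steps):
    return dict(steps)


class TestSampleLevelFilter:
    def test_low_allele_fraction_fails(self):
        call = GenotypeCall(gt="0/1", ad_ref=58, ad_alt=6, dp=64)
        steps = _steps_dict(sample_level_filter(call, CFG))
        assert steps["allele_fraction"] == FAIL  # 6/64 < 0.10
        assert steps["genotype"] == PASS and steps["min_depth"] == PASS

    def test_homref_genotype_fails(self):
        call = GenotypeCall(gt="0/0", ad_ref=60, ad_alt=0, dp=60)
        assert _steps_dict(sample_level_filter(call, CFG))["genotype"] == FAIL

    def test_low_depth_fails(self):
        call = GenotypeCall(gt="0/1", ad_ref=5, ad_alt=4, dp=9)
        steps = _steps_dict(sample_level_filter(call, CFG))
        assert steps["min_depth"] == FAIL
        assert steps["allele_fraction"] == PASS  # 4/9 >= 0.10

    def test_excessive_depth_fails(self):
        call = GenotypeCall(gt="1/1", ad_ref=0, ad_alt=200, dp=200)
        assert _steps_dict(sample_level_filter(call, CFG))["max_depth"] == FAIL

    def test_undefined_af_fails_conservatively(self):
        call = GenotypeCall(gt="0/1", ad_ref=None, ad_alt=None, dp=60)
        assert _steps_dict(sample_level_filter(call, CFG))["allele_fraction"] == FAIL


class TestNearIndel:
    def test_border_distance_convention(self):
        deletion = _snv(pos=100, ref="ACTA", alt="A")  # REF spans 100..103
        near = _snv(pos=105)  # distance 2 to border 103
        far = _snv(pos=109)  # distance 6
        kept, removed = remove_near_indel([near, far], [deletion], CFG)
        assert [v.pos for v in removed] == [105]
        assert [v.pos for v in kept] == [109]

    def test_no_indel_on_chromosome_keeps_snv(self):
        other = _snv(pos=100, chrom="chr2", ref="ACTA", alt="A")
        kept, removed = remove_near_indel([_snv(pos=102)], [other], CFG)
        assert removed == [] and len(kept) == 1

    def test_insertion_borders_are_flanking_bases(self):
        ins = _snv(pos=200, ref="A", alt="ATTT")  # borders 200, 201
        kept, removed = remove_near_indel(
            [_snv(pos=206), _snv(pos=207)], [ins], CFG
        )
        assert [v.pos for v in removed] == [206]
        assert [v.pos for v in kept] == [207]


def _sv(start, end, gts=("0/1",), qual=500.0, su=20, dps=(60,)):
    return ComplexIndelRecord(
        chrom="chr1", start=start, end=end, svtype="DEL",
        qual=qual, su=su, gts=tuple(gts), dps=tuple(dps),
    )


class TestComplexIndelFilters:
    def test_low_quality_removed(self):
        steps = _steps_dict(complex_indel_steps(_sv(0, 100, qual=99.0), 0, CFG, GenomeMask()))
        assert steps["sv_quality"] == FAIL

    def test_low_su_removed(self):
        steps = _steps_dict(complex_indel_steps(_sv(0, 100, su=4), 0, CFG, GenomeMask()))
        assert steps["sv_su"] == FAIL

    def test_good_record_kept(self):
        steps = complex_indel_steps(_sv(0, 100), 0, CFG, GenomeMask())
        assert all(o == PASS for _, o in steps)

    def test_masked_span_removed(self):
        mask = GenomeMask([("chr1", 50, 60)])
        steps = _steps_dict(complex_indel_steps(_sv(0, 100), 0, CFG, mask))
        assert steps["sv_mask"] == FAIL


class TestSvOverlapExclusion:
    def test_contained_simple_indel_removed(self):
        simple = _snv(pos=150, ref="ACT", alt="A")
        kept, removed = exclude_sv_overlapping_simple_indels([simple], [_sv(100, 200)])
        assert removed == [simple] and kept == []

    def test_distant_indel_kept(self):
        simple = _snv(pos=1500, ref="A", alt="ACT")
        kept, removed = exclude_sv_overlapping_simple_indels([simple], [_sv(100, 200)])
        assert kept == [simple]

    def test_abutting_half_open_interval_kept(self):
        # REF span [200, 203) starts exactly where the SV interval ends
        simple = _snv(pos=201, ref="ACT", alt="A")
        kept, removed = exclude_sv_overlapping_simple_indels([simple], [_sv(100, 200)])
        assert kept == [simple] and removed == []


class TestParentalSubtraction:
    def test_allele_in_parent_excluded(self):
        child = _snv(pos=100)
        denovo, inherited = subtract_parental([child], set(), {child.key})
        assert denovo == [] and inherited == [child]

    def test_absent_from_both_parents_retained(self):
        child = _snv(pos=100)
        denovo, _ = subtract_parental([child], {("chr1", 5, "A", "T")}, set())
        assert denovo == [child]

    def test_different_alt_allele_does_not_exclude(self):
        child = _snv(pos=100, ref="C", alt="T")
        parent_key = ("chr1", 100, "C", "G")  # same site, different allele
        denovo, _ = subtract_parental([child], {parent_key}, set())
        assert denovo == [child]


class TestCascade:
    def test_planted_truth_recovered_exactly(self, small_bundle):
        b = small_bundle
        callsets = call_denovo_cohort(
            b.records, b.samples, b.sv_records, b.samples, b.mask, b.pedigree,
            FilterConfig(d=b.spec.depth_mean),
        )
        truth_pass = b.truth[b.truth.expected == "pass"]
        for child in b.pedigree.offspring:
            cs = callsets[child]
            sub = truth_pass[truth_pass["sample"] == child]
            want_small = {
                (r.chrom, int(r.pos), r.ref, r.alt)
                for r in sub[sub.vtype.isin(["snv", "indel"])].itertuples()
            }
            assert cs.snv_keys | cs.indel_keys == want_small
            want_cx = {
                (r.chrom, int(r.pos), int(r.end), "DEL")
                for r in sub[sub.vtype == "complex"].itertuples()
            }
            assert cs.complex_keys == want_cx

    def test_distractors_fail_their_named_filter(self, small_bundle):
        b = small_bundle
        callsets = call_denovo_cohort(
            b.records, b.samples, b.sv_records, b.samples, b.mask, b.pedigree,
            FilterConfig(d=b.spec.depth_mean),
        )
        distractors = b.truth[b.truth.category.str.startswith("distractor:")]
        assert len(distractors) > 0
        for row in distractors.itertuples():
            expected_filter = row.expected.split(":", 1)[1]
            if row.vtype == "complex":
                key = (row.chrom, int(row.pos), int(row.end), "DEL")
            else:
                key = (row.chrom, int(row.pos), row.ref, row.alt)
            trace = callsets[row.sample].traces[key]
            assert trace.final == FAIL
            assert trace.first_failed == expected_filter, (row.category, trace.steps)

    def test_matches_joint_bruteforce_oracle(self):
        rng = np.random.default_rng(20)
        for _ in range(60):
            records, samples, svs, sv_samples, mask_iv, ped = random_mini_cohort(rng)
            cfg = FilterConfig()
            got = call_denovo_cohort(
                records, samples, svs, sv_samples, GenomeMask(mask_iv), ped, cfg
            )
            want = bf_denovo(records, samples, svs, sv_samples, mask_iv, ped, cfg)
            for child in ped.offspring:
                cs = got[child]
                assert (cs.snv_keys, cs.indel_keys, cs.complex_keys) == want[child]

    def test_relaxing_af_threshold_never_shrinks_callsets(self, small_bundle):
        b = small_bundle
        strict = call_denovo_cohort(
            b.records, b.samples, b.sv_records, b.samples, b.mask, b.pedigree,
            FilterConfig(d=b.spec.depth_mean, af_min=0.10),
        )
        loose = call_denovo_cohort(
            b.records, b.samples, b.sv_records, b.samples, b.mask, b.pedigree,
            FilterConfig(d=b.spec.depth_mean, af_min=0.05),
        )
        for child in b.pedigree.offspring:
            assert strict[child].snv_keys <= loose[child].snv_keys
            assert strict[child].indel_keys <= loose[child].indel_keys

    def test_denovo_sets_disjoint_from_parental_alleles(self, small_bundle):
        b = small_bundle
        callsets = call_denovo_cohort(
            b.records, b.samples, b.sv_records, b.samples, b.mask, b.pedigree,
            FilterConfig(d=b.spec.depth_mean),
        )
        idx = {s: i for i, s in enumerate(b.samples)}
        for child in b.pedigree.offspring:
            parents = b.pedigree.parents_of(child)
            parental = {
                r.key
                for r in b.records
                for p in parents
                if r.calls[idx[p]].has_alt
            }
            cs = callsets[child]
            assert not (cs.snv_keys | cs.indel_keys) & parental

    def test_rerunning_cascade_on_its_output_is_noop(self, small_bundle):
        b = small_bundle
        cfg = FilterConfig(d=b.spec.depth_mean)
        first = call_denovo_cohort(
            b.records, b.samples, b.sv_records, b.samples, b.mask, b.pedigree, cfg
        )
        passing_keys = set()
        for cs in first.values():
            passing_keys |= cs.snv_keys | cs.indel_keys
        subset = [r for r in b.records if r.key in passing_keys]
        second = call_denovo_cohort(
            subset, b.samples, b.sv_records, b.samples, b.mask, b.pedigree, cfg
        )
        for child in b.pedigree.offspring:
            assert second[child].snv_keys == first[child].snv_keys
            assert second[child].indel_keys == first[child].indel_keys

    def test_offspring_missing_parent_in_vcf_raises(self, small_bundle):
        b = small_bundle
        trimmed = [
            VariantRecord(
                chrom=r.chrom, pos=r.pos, ref=r.ref, alt=r.alt,
                annotations=r.annotations, calls=r.calls[1:],
            )
            for r in b.records[:5]
        ]
        with pytest.raises(ConfigError, match="lacks both parents|absent"):
            call_denovo_cohort(
                trimmed, b.samples[1:], [], [], b.mask, b.pedigree,
                FilterConfig(),
            )
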