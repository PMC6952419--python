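"""The post-calling filter cascade that turns joint-genotyped variant calls
into per-offspring de novo callsets.

Stages, in the order they are applied to every candidate:

1. class-specific site hard filters (SNV vs indel annotation thresholds);
2. repeat/blacklist mask exclusion;
3. per-sample genotype, minimum-depth, excessive-depth and allele-fraction
   filters;
4. removal of SNVs within a window of a surviving indel border;
5. exclusion of simple indels overlapping SV-caller (complex) indels;
6. complex-indel filtering (genotype, quality, coverage, SU, mask);
7. trio parental subtraction.

Every (variant, offspring) pair gets a :class:`FilterTrace` recording each
filter outcome, so the funnel is fully auditable.  Missing site annotations
never fail a hard filter: the variant callers this pipeline consumes omit
rank-sum annotations at homozygous sites, and failing absent values would
discard most 1/1 calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .model import (
    DELETION,
    INSERTION,
    OTHER,
    SNV,
    ComplexIndelRecord,
    GenomeMask,
    GenotypeCall,
    PedigreeCohort,
    SvKey,
    VariantKey,
    VariantRecord,
)
from .variant_io import overlaps_mask


class ConfigError(ValueError):
    """Invalid filter or cohort configuration."""


@dataclass(slots=True)
class FilterConfig:
    """Every numeric threshold of the cascade.

    Hard-filter cutoffs follow the caller's recommended fixed-threshold
    values; ``d`` is the average per-sample read depth of the experiment
    (from sequencing coverage, not re-estimated from the VCF) and feeds the
    excessive-depth cutoff d + 3*sqrt(d).
    """

    # SNV site hard filters (a variant FAILS when the inequality holds)
    snv_qd_min: float = 2.0  # QD < 2.0
    snv_fs_max: float = 60.0  # FS > 60.0
    snv_mq_min: float = 40.0  # MQ < 40.0
    snv_mqranksum_min: float = -12.5  # MQRankSum < -12.5
    snv_readposranksum_min: float = -8.0  # ReadPosRankSum < -8.0
    snv_sor_max: float = 3.0  # SOR > 3
    # indel site hard filters
    indel_qd_min: float = 2.0
    indel_fs_max: float = 200.0
    indel_readposranksum_min: float = -20.0
    indel_sor_max: float = 10.0
    # per-sample filters
    dp_min: int = 10
    d: float = 60.0  # average read depth per sample
    af_min: float = 0.10
    # SNV-near-indel exclusion window (bp, inclusive distance to a border)
    indel_window: int = 5
    # complex (SV-caller) indel filters
    sv_qual_min: float = 100.0
    sv_su_min: int = 5

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ConfigError(f"average read depth d must be positive, got {self.d}")
        if self.indel_window < 0:
            raise ConfigError("indel_window must be >= 0")

    @property
    def dp_max(self) -> float:
        return excessive_depth_cutoff(self.d)


def excessive_depth_cutoff(d: float) -> float:
    """Excessive-depth threshold d + 3*sqrt(d).

    Calls with depth strictly greater than this cutoff fail the
    excess-depth filter (collapsed-repeat artefact guard).
    """
    if d <= 0:
        raise ConfigError(f"average read depth d must be positive, got {d}")
    return d + 3.0 * math.sqrt(d)


# canonical filter-stage names, in cascade order
F_HARD_SNV = "hard_snv"
F_HARD_INDEL = "hard_indel"
F_VCLASS = "variant_class"
F_MASK = "mask"
F_GENOTYPE = "genotype"
F_MIN_DEPTH = "min_depth"
F_MAX_DEPTH = "max_depth"
F_AF = "allele_fraction"
F_NEAR_INDEL = "near_indel"
F_SV_OVERLAP = "sv_overlap"
F_INHERITED = "inherited"
# complex-indel stages
F_SV_GENOTYPE = "sv_genotype"
F_SV_QUALITY = "sv_quality"
F_SV_COVERAGE = "sv_coverage"
F_SV_SU = "sv_su"
F_SV_MASK = "sv_mask"

PASS = "pass"
FAIL = "fail"


@dataclass(slots=True)
class FilterTrace:
    """Ordered filter outcomes for one (variant, sample) pair."""

    chrom: str
    pos: int  # 1-based for small variants; 0-based start for complex indels
    ref: str
    alt: str
    sample: str
    steps: list[tuple[str, str]] = field(default_factory=list)
    reasons: tuple[str, ...] = ()  # e.g. failing hard-filter annotation names
    flags: tuple[str, ...] = ()  # e.g. "parent_uncalled"

    @property
    def final(self) -> str:
        return PASS if all(o == PASS for _, o in self.steps) else FAIL

    @property
    def failed_filters(self) -> tuple[str, ...]:
        return tuple(name for name, o in self.steps if o == FAIL)

    @property
    def first_failed(self) -> str | None:
        for name, o in self.steps:
            if o == FAIL:
                return name
        return None


@dataclass(slots=True)
class DeNovoCallset:
    """Passing de novo variants of one offspring, plus the decision trace."""

    sample: str
    snvs: list[VariantRecord]
    indels: list[VariantRecord]
    complex: list[ComplexIndelRecord]
    traces: dict[tuple, FilterTrace]

    @property
    def snv_keys(self) -> set[VariantKey]:
        return {v.key for v in self.snvs}

    @property
    def indel_keys(self) -> set[VariantKey]:
        return {v.key for v in self.indels}

    @property
    def complex_keys(self) -> set[SvKey]:
        return {c.key for c in self.complex}


def apply_snv_hard_filters(v: VariantRecord, cfg: FilterConfig) -> tuple[bool, tuple[str, ...]]:
    """Evaluate the six SNV site hard filters.

    Returns ``(passed, failing_annotation_names)``.  Only annotations that
    are present can violate a threshold.
    """
    ann = v.annotations
    failing = []
    if ann.get("QD", math.inf) < cfg.snv_qd_min:
        failing.append("QD")
    if ann.get("FS", -math.inf) > cfg.snv_fs_max:
        failing.append("FS")
    if ann.get("MQ", math.inf) < cfg.snv_mq_min:
        failing.append("MQ")
    if ann.get("MQRankSum", math.inf) < cfg.snv_mqranksum_min:
        failing.append("MQRankSum")
    if ann.get("ReadPosRankSum", math.inf) < cfg.snv_readposranksum_min:
        failing.append("ReadPosRankSum")
    if ann.get("SOR", -math.inf) > cfg.snv_sor_max:
        failing.append("SOR")
    return (not failing, tuple(failing))


def apply_indel_hard_filters(v: VariantRecord, cfg: FilterConfig) -> tuple[bool, tuple[str, ...]]:
    """Evaluate the four indel site hard filters (strict inequalities)."""
    ann = v.annotations
    failing = []
    if ann.get("QD", math.inf) < cfg.indel_qd_min:
        failing.append("QD")
    if ann.get("FS", -math.inf) > cfg.indel_fs_max:
        failing.append("FS")
    if ann.get("ReadPosRankSum", math.inf) < cfg.indel_readposranksum_min:
        failing.append("ReadPosRankSum")
    if ann.get("SOR", -math.inf) > cfg.indel_sor_max:
        failing.append("SOR")
    return (not failing, tuple(failing))


def sample_level_filter(call: GenotypeCall, cfg: FilterConfig) -> list[tuple[str, str]]:
    """Genotype / depth / allele-fraction filters for one sample's call.

    All four conditions are evaluated and recorded (a call can fail more
    than one).  A call with undefined allele fraction fails the AF filter:
    the cascade removes calls below 10% alt fraction, so an unevaluable
    fraction cannot be shown to pass.
    """
    steps = []
    steps.append((F_GENOTYPE, PASS if call.has_alt else FAIL))
    dp = call.dp
    if dp is None and call.ad_ref is not None and call.ad_alt is not None:
        dp = call.ad_ref + call.ad_alt
    steps.append((F_MIN_DEPTH, PASS if dp is not None and dp >= cfg.dp_min else FAIL))
    steps.append((F_MAX_DEPTH, PASS if dp is not None and dp <= cfg.dp_max else FAIL))
    af = call.af
    steps.append((F_AF, PASS if af is not None and af >= cfg.af_min else FAIL))
    return steps


def indel_borders(v: VariantRecord) -> tuple[int, int]:
    """1-based border positions of an indel.

    For a deletion the borders are the first and last REF base
    (pos, pos + len(ref) - 1); for an insertion the two flanking bases
    (pos, pos + 1).
    """
    if v.vclass == DELETION:
        return (v.pos, v.pos + len(v.ref) - 1)
    if v.vclass == INSERTION:
        return (v.pos, v.pos + 1)
    raise ValueError(f"not an indel: {v.key}")


def remove_near_indel(
    snvs: Sequence[VariantRecord],
    indels: Sequence[VariantRecord],
    cfg: FilterConfig,
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Split SNVs into (kept, removed) by proximity to an indel border.

    An SNV is removed iff its position lies within ``indel_window`` bases
    (inclusive) of either border of any same-chromosome indel.
    """
    import bisect

    borders: dict[str, list[int]] = {}
    for ind in indels:
        bs = borders.setdefault(ind.chrom, [])
        bs.extend(indel_borders(ind))
    for bs in borders.values():
        bs.sort()
    kept, removed = [], []
    w = cfg.indel_window
    for snv in snvs:
        bs = borders.get(snv.chrom)
        near = False
        if bs:
            i = bisect.bisect_left(bs, snv.pos)
            for j in (i - 1, i):
                if 0 <= j < len(bs) and abs(snv.pos - bs[j]) <= w:
                    near = True
                    break
        (removed if near else kept).append(snv)
    return kept, removed


def _sv_tree(records: Iterable[ComplexIndelRecord]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for rec in records:
        trees.setdefault(rec.chrom, IntervalTree()).addi(rec.start, rec.end, rec)
    return trees


def exclude_sv_overlapping_simple_indels(
    simple: Sequence[VariantRecord],
    complex_recs: Sequence[ComplexIndelRecord],
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Split simple indels into (kept, removed) by overlap with complex indels.

    Overlap is half-open interval intersection of the simple indel's REF
    span with the complex record's [start, end); abutting intervals do not
    overlap.
    """
    trees = _sv_tree(complex_recs)
    kept, removed = [], []
    for ind in simple:
        start, end = ind.span0
        tree = trees.get(ind.chrom)
        if tree is not None and tree.overlap(start, end):
            removed.append(ind)
        else:
            kept.append(ind)
    return kept, removed


def complex_indel_steps(
    rec: ComplexIndelRecord,
    sample_index: int,
    cfg: FilterConfig,
    mask: GenomeMask,
) -> list[tuple[str, str]]:
    """Evaluate the complex-indel filters for one sample.

    A record with no per-sample depth passes the coverage check vacuously
    (only a present value can demonstrate excessive coverage).
    """
    gt = rec.gts[sample_index] if sample_index < len(rec.gts) else "./."
    dp = rec.dps[sample_index] if sample_index < len(rec.dps) else None
    steps = [
        (F_SV_GENOTYPE, PASS if gt in ("0/1", "1/1") else FAIL),
        (F_SV_QUALITY, PASS if rec.qual >= cfg.sv_qual_min else FAIL),
        (F_SV_COVERAGE, PASS if dp is None or dp <= cfg.dp_max else FAIL),
        (F_SV_SU, PASS if rec.su >= cfg.sv_su_min else FAIL),
        (F_SV_MASK, FAIL if mask.overlaps(rec.chrom, rec.start, rec.end) else PASS),
    ]
    return steps


def parental_carrier_keys(
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    parent: str,
) -> set[VariantKey]:
    """Keys of variants whose alt allele the given parent carries."""
    idx = samples.index(parent)
    return {r.key for r in records if r.calls[idx].has_alt}


def subtract_parental(
    offspring_variants: Sequence[VariantRecord],
    sire_keys: set[VariantKey],
    dam_keys: set[VariantKey],
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Split variants into (de novo, inherited) by allele-level parental match.

    A variant is inherited iff either parent carries the same alt allele at
    the same site (exact (chrom, pos, ref, alt) match).  A parent with a
    different alt allele at the site, or no call at all, does not exclude
    the child's variant.
    """
    parental = sire_keys | dam_keys
    denovo, inherited = [], []
    for v in offspring_variants:
        (inherited if v.key in parental else denovo).append(v)
    return denovo, inherited


def call_denovo_cohort(
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    sv_records: Sequence[ComplexIndelRecord],
    sv_samples: Sequence[str],
    mask: GenomeMask,
    pedigree: PedigreeCohort,
    cfg: FilterConfig,
) -> dict[str, DeNovoCallset]:
    """Run the full cascade and return one :class:`DeNovoCallset` per offspring.

    ``records`` must already be bi-allelic (see
    :func:`denovotrio.variant_io.read_multisample_vcf`).
    """
    sample_index = {s: i for i, s in enumerate(samples)}
    sv_index = {s: i for i, s in enumerate(sv_samples)}
    for child in pedigree.offspring:
        missing = [p for p in pedigree.parents_of(child) if p not in sample_index]
        if missing or len(pedigree.parents_of(child)) < 2:
            raise ConfigError(
                f"offspring {child!r} lacks both parents in the VCF "
                f"(missing: {missing or 'parent link'})"
            )
        if child not in sample_index:
            raise ConfigError(f"offspring {child!r} absent from the VCF")

    # site-level stages are sample-independent: evaluate once per record
    site_steps: list[list[tuple[str, str]]] = []
    site_reasons: list[tuple[str, ...]] = []
    for rec in records:
        vclass = rec.vclass
        if vclass == SNV:
            ok, reasons = apply_snv_hard_filters(rec, cfg)
            steps = [(F_HARD_SNV, PASS if ok else FAIL)]
        elif vclass in (INSERTION, DELETION):
            ok, reasons = apply_indel_hard_filters(rec, cfg)
            steps = [(F_HARD_INDEL, PASS if ok else FAIL)]
        else:  # OTHER: not analysable by this cascade
            reasons = (vclass,)
            steps = [(F_VCLASS, FAIL)]
        steps.append((F_MASK, FAIL if overlaps_mask(rec, mask) else PASS))
        site_steps.append(steps)
        site_reasons.append(reasons)

    # parental allele sets for subtraction
    parent_small: dict[str, set[VariantKey]] = {
        p: parental_carrier_keys(records, samples, p) for p in pedigree.parents
    }
    parent_sv: dict[str, set[SvKey]] = {}
    for p in pedigree.parents:
        i = sv_index.get(p)
        parent_sv[p] = (
            {r.key for r in sv_records if i < len(r.gts) and r.gts[i] in ("0/1", "1/1")}
            if i is not None
            else set()
        )

    callsets: dict[str, DeNovoCallset] = {}
    for child in pedigree.offspring:
        ci = sample_index[child]
        traces: dict[tuple, FilterTrace] = {}
        surviving_snvs: list[VariantRecord] = []
        surviving_indels: list[VariantRecord] = []

        for rec, steps0, reasons in zip(records, site_steps, site_reasons):
            trace = FilterTrace(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=rec.alt,
                sample=child,
                steps=list(steps0),
                reasons=reasons,
            )
            traces[rec.key] = trace
            if trace.final == FAIL:
                continue
            trace.steps.extend(sample_level_filter(rec.calls[ci], cfg))
            if trace.final == FAIL:
                continue
            if rec.vclass == SNV:
                surviving_snvs.append(rec)
            else:
                surviving_indels.append(rec)

        # SNVs near a surviving indel border (within-sample, pre-subtraction)
        kept_snvs, near = remove_near_indel(surviving_snvs, surviving_indels, cfg)
        for v in near:
            traces[v.key].steps.append((F_NEAR_INDEL, FAIL))
        for v in kept_snvs:
            traces[v.key].steps.append((F_NEAR_INDEL, PASS))

        # complex indels: the sample's raw carrier set drives the simple-indel
        # exclusion; the filtered set enters the callset
        svi = sv_index.get(child)
        carrier_complex: list[ComplexIndelRecord] = []
        passing_complex: list[ComplexIndelRecord] = []
        if svi is not None:
            for rec in sv_records:
                gt = rec.gts[svi] if svi < len(rec.gts) else "./."
                if gt in ("0/1", "1/1"):
                    carrier_complex.append(rec)
                trace = FilterTrace(
                    chrom=rec.chrom,
                    pos=rec.start,
                    ref=".",
                    alt=f"<{rec.svtype}>",
                    sample=child,
                    steps=complex_indel_steps(rec, svi, cfg, mask),
                )
                traces[rec.key] = trace
                if trace.final == PASS:
                    passing_complex.append(rec)

        kept_indels, sv_removed = exclude_sv_overlapping_simple_indels(
            surviving_indels, carrier_complex
        )
        for v in sv_removed:
            traces[v.key].steps.append((F_SV_OVERLAP, FAIL))
        for v in kept_indels:
            traces[v.key].steps.append((F_SV_OVERLAP, PASS))

        # parental subtraction
        sire = pedigree.sire[child]
        dam = pedigree.dam[child]
        sire_keys = parent_small[sire]
        dam_keys = parent_small[dam]
        denovo_snvs, inh_snvs = subtract_parental(kept_snvs, sire_keys, dam_keys)
        denovo_indels, inh_indels = subtract_parental(kept_indels, sire_keys, dam_keys)
        sire_i, dam_i = sample_index[sire], sample_index[dam]
        for v in inh_snvs + inh_indels:
            traces[v.key].steps.append((F_INHERITED, FAIL))
        for v in denovo_snvs + denovo_indels:
            trace = traces[v.key]
            trace.steps.append((F_INHERITED, PASS))
            if v.calls[sire_i].is_missing or v.calls[dam_i].is_missing:
                trace.flags = trace.flags + ("parent_uncalled",)

        sv_parental = parent_sv[sire] | parent_sv[dam]
        denovo_complex = []
        for rec in passing_complex:
            if rec.key in sv_parental:
                traces[rec.key].steps.append((F_INHERITED, FAIL))
            else:
                traces[rec.key].steps.append((F_INHERITED, PASS))
                denovo_complex.append(rec)

        callsets[child] = DeNovoCallset(
            sample=child,
            snvs=denovo_snvs,
            indels=denovo_indels,
            complex=denovo_complex,
            traces=traces,
        )
    return callsets


def funnel_counts(callsets: Mapping[str, DeNovoCallset]) -> dict[str, int]:
    """Aggregate first-failure counts per filter across all traces."""
    counts: dict[str, int] = {}
    for cs in callsets.values():
        for trace in cs.traces.values():
            name = trace.first_failed
            key = name if name is not None else PASS
            counts[key] = counts.get(key, 0) + 1
    return counts
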