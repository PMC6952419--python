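"""Synthetic trio-cohort generator.

Emits a complete, self-consistent input bundle for the pipeline — a
multi-sample small-variant VCF, an SV-dialect complex-indel VCF, a mask
BED, an off-target site table, a pedigree table — plus a machine-readable
truth table stating, for every planted variant, what the cascade must do
with it.  The default spec mirrors the study design the pipeline targets:
nine parents (one sire, eight dams), 13 control / 13 ABE / 9 BE4 offspring
at ~60X depth, per-group de novo SNV rates of 132 / 119 / 221 with a
BE4-specific C>T excess, occasional complex deletions in a subset of BE4
animals, and a small fraction (2%) of de novo SNVs placed inside predicted
off-target sites.

Planted variants fall into four categories:

* ``inherited`` — a parental germline allele transmitted Mendelian-style;
  the cascade must remove it at parental subtraction;
* ``denovo_pass`` — a de novo variant whose annotations, depth and allele
  fraction satisfy every filter; the cascade must keep it;
* ``offtarget_coincident`` — a ``denovo_pass`` SNV placed inside a
  predicted off-target site;
* ``distractor:<filter>`` — a variant violating exactly one named filter;
  the cascade must reject it for exactly that reason.

Generation is deterministic: the same spec and seed produce a byte-
identical bundle.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from intervaltree import IntervalTree

from .denovo_filters import FilterConfig, excessive_depth_cutoff
from .model import (
    ComplexIndelRecord,
    GenomeMask,
    GenotypeCall,
    PedigreeCohort,
    ROLE_OFFSPRING,
    ROLE_PARENT,
    VariantRecord,
)
from .offtarget import OffTargetSite, write_offtarget_table
from .spectrum_stats import DIRECTIONAL_CLASSES
from .variant_io import (
    write_intervals_bed,
    write_pedigree,
    write_sv_vcf,
    write_vcf,
)


class GenerationError(RuntimeError):
    """The requested cohort cannot be placed on the configured genome."""


#: filters a distractor can be aimed at, one spelled per cascade stage
DISTRACTOR_CATEGORIES = (
    "hard_snv",
    "hard_indel",
    "mask",
    "genotype",
    "min_depth",
    "max_depth",
    "allele_fraction",
    "near_indel",
    "sv_overlap",
    "inherited",
    "sv_quality",
    "sv_su",
)

_BASES = "ACGT"

_UNIFORM_WEIGHTS = {c: 1.0 / 12.0 for c in DIRECTIONAL_CLASSES}

#: BE4 cytosine-deaminase signature: C>T (and its reverse complement G>A)
#: dominate, with minor C>A / C>G components, over a uniform background.
_BE4_WEIGHTS = {
    "C>T": 0.32,
    "G>A": 0.32,
    "C>A": 0.04,
    "G>T": 0.04,
    "C>G": 0.03,
    "G>C": 0.03,
    "T>A": 0.22 / 6,
    "T>C": 0.22 / 6,
    "T>G": 0.22 / 6,
    "A>T": 0.22 / 6,
    "A>G": 0.22 / 6,
    "A>C": 0.22 / 6,
}


@dataclass
class SyntheticCohortSpec:
    """All knobs of the generator, with study-structure defaults."""

    chromosomes: list[tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 10_000_000), ("chr2", 10_000_000), ("chr3", 10_000_000)]
    )
    n_dams: int = 8  # plus one sire
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"control": 13, "ABE": 13, "BE4": 9}
    )
    snv_rates: dict[str, float] = field(
        default_factory=lambda: {"control": 132.0, "ABE": 119.0, "BE4": 221.0}
    )
    indel_rates: dict[str, float] = field(
        default_factory=lambda: {"control": 20.0, "ABE": 20.0, "BE4": 20.0}
    )
    spectrum_weights: dict[str, dict[str, float]] | None = None  # None -> defaults
    depth_mean: float = 60.0
    af_beta: tuple[float, float] = (50.0, 50.0)  # heterozygous AF ~ Beta(a, b)
    mosaic_fraction: float = 0.1  # of BE4 de novo SNVs
    mosaic_af: float = 0.25
    offtarget_fraction: float = 0.02
    n_offtarget_sites: int = 300
    site_length: int = 23
    n_inherited: int = 200  # germline het variants per parent
    germline_indel_fraction: float = 0.1
    mask_fraction: float = 0.45
    mask_tile: int = 10_000
    n_be4_complex_carriers: int = 4  # BE4 mice carrying a passing complex DEL
    distractors: list[str] = field(default_factory=lambda: list(DISTRACTOR_CATEGORIES))
    nb_dispersion: float | None = None  # None -> Poisson counts
    min_spacing: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.snv_rates.values()):
            raise ValueError("snv_rates must be non-negative")
        if not 0.0 <= self.offtarget_fraction <= 1.0:
            raise ValueError("offtarget_fraction must be in [0, 1]")
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")
        unknown = set(self.distractors) - set(DISTRACTOR_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown distractor categories: {sorted(unknown)}")
        if self.spectrum_weights is not None:
            for g, w in self.spectrum_weights.items():
                if abs(sum(w.values()) - 1.0) > 1e-6:
                    raise ValueError(f"spectrum weights for {g} must sum to 1")

    def weights_for(self, group: str) -> dict[str, float]:
        if self.spectrum_weights and group in self.spectrum_weights:
            return self.spectrum_weights[group]
        return _BE4_WEIGHTS if group == "BE4" else _UNIFORM_WEIGHTS

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chromosomes"] = [[n, int(l)] for n, l in self.chromosomes]
        d["af_beta"] = [float(x) for x in self.af_beta]
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticCohortSpec":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown spec keys: {sorted(unknown)}")
        data = dict(data)
        if "chromosomes" in data:
            data["chromosomes"] = [(str(n), int(l)) for n, l in data["chromosomes"]]
        if "af_beta" in data:
            data["af_beta"] = tuple(float(x) for x in data["af_beta"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SyntheticCohortSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


TRUTH_COLUMNS = ["sample", "vtype", "chrom", "pos", "end", "ref", "alt", "category", "expected"]


def write_truth(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write the truth table as TSV (one planted variant/sample per row)."""
    table.to_csv(path, sep="\t", index=False, columns=TRUTH_COLUMNS)


def read_truth(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"sample": str, "vtype": str, "chrom": str, "ref": str, "alt": str,
               "category": str, "expected": str},
    )
    return df[TRUTH_COLUMNS]


@dataclass
class CohortBundle:
    """Everything :func:`generate_cohort` produced, on disk and in memory."""

    outdir: Path
    spec: SyntheticCohortSpec
    paths: dict[str, Path]
    truth: pd.DataFrame
    samples: list[str]
    records: list[VariantRecord]
    sv_records: list[ComplexIndelRecord]
    mask: GenomeMask
    pedigree: PedigreeCohort
    sites: list[OffTargetSite]


class _Placer:
    """Rejection-samples variant positions under mask/spacing constraints."""

    def __init__(self, spec: SyntheticCohortSpec, mask: GenomeMask, rng: np.random.Generator):
        self.spec = spec
        self.mask = mask
        self.rng = rng
        self.occupied: dict[str, IntervalTree] = {n: IntervalTree() for n, _ in spec.chromosomes}
        self.sites: dict[str, IntervalTree] = {n: IntervalTree() for n, _ in spec.chromosomes}
        self.used_pos: set[tuple[str, int]] = set()
        names = [n for n, _ in spec.chromosomes]
        lengths = np.array([l for _, l in spec.chromosomes], dtype=float)
        self._names = names
        self._lengths = {n: int(l) for n, l in spec.chromosomes}
        self._probs = lengths / lengths.sum()

    def sample_span(
        self,
        span_len: int,
        in_mask: bool = False,
        max_tries: int = 20_000,
    ) -> tuple[str, int]:
        """Return (chrom, start0) for a fresh span of ``span_len`` bases."""
        pad = self.spec.min_spacing
        for _ in range(max_tries):
            chrom = self._names[self.rng.choice(len(self._names), p=self._probs)]
            length = self._lengths[chrom]
            if length <= span_len + 2 * pad:
                continue
            start = int(self.rng.integers(pad, length - span_len - pad))
            end = start + span_len
            if self.mask.overlaps(chrom, start, end) != in_mask:
                continue
            if self.occupied[chrom].overlap(start, end):
                continue
            if self.sites[chrom].overlap(start - pad, end + pad):
                continue
            self.reserve(chrom, start, end)
            return chrom, start
        raise GenerationError(
            f"could not place a {span_len} bp span after {max_tries} tries; "
            "genome too small or too densely packed"
        )

    def reserve(self, chrom: str, start: int, end: int) -> None:
        pad = self.spec.min_spacing
        self.occupied[chrom].addi(start - pad, end + pad)
        for p in range(start, end):
            self.used_pos.add((chrom, p))

    def add_site(self, site: OffTargetSite) -> None:
        self.sites[site.chrom].addi(site.start, site.end)


class _Synthesizer:
    """Draws calls that are guaranteed to pass (or fail) specific filters."""

    def __init__(self, spec: SyntheticCohortSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.cfg = FilterConfig(d=spec.depth_mean)
        self.dp_max = int(excessive_depth_cutoff(spec.depth_mean))

    def passing_depth(self) -> int:
        while True:
            dp = int(self.rng.poisson(self.spec.depth_mean))
            if self.cfg.dp_min <= dp <= self.dp_max:
                return dp

    def het_call(self, af_target: float | None = None) -> GenotypeCall:
        """A 0/1 call passing depth and AF filters."""
        dp = self.passing_depth()
        a, b = self.spec.af_beta
        while True:
            p = af_target if af_target is not None else float(self.rng.beta(a, b))
            ad_alt = int(self.rng.binomial(dp, p))
            if ad_alt < dp and ad_alt / dp >= 0.12:  # clear of the 10% cutoff
                return GenotypeCall(gt="0/1", ad_ref=dp - ad_alt, ad_alt=ad_alt, dp=dp)

    def good_annotations(self) -> dict[str, float]:
        r = self.rng
        return {
            "QD": round(float(r.uniform(15.0, 35.0)), 2),
            "FS": round(float(r.uniform(0.0, 5.0)), 3),
            "MQ": round(float(r.uniform(55.0, 60.0)), 2),
            "MQRankSum": round(float(r.uniform(-1.0, 1.0)), 3),
            "ReadPosRankSum": round(float(r.uniform(-1.0, 1.0)), 3),
            "SOR": round(float(r.uniform(0.4, 1.5)), 3),
        }


@dataclass
class _Row:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    annotations: dict[str, float]
    overrides: dict[str, GenotypeCall] = field(default_factory=dict)


@dataclass
class _SvRow:
    chrom: str
    start: int
    end: int
    svtype: str
    qual: float
    su: int
    overrides: dict[str, tuple[str, int]] = field(default_factory=dict)  # gt, dp


def _build_mask(spec: SyntheticCohortSpec, rng: np.random.Generator) -> GenomeMask:
    intervals = []
    for chrom, length in spec.chromosomes:
        n_tiles = length // spec.mask_tile
        masked = rng.random(n_tiles) < spec.mask_fraction
        for i in np.flatnonzero(masked):
            start = int(i) * spec.mask_tile
            intervals.append((chrom, start, start + spec.mask_tile))
    return GenomeMask(intervals)


def _build_pedigree(spec: SyntheticCohortSpec) -> PedigreeCohort:
    sire = "sire_01"
    dams = [f"dam_{i + 1:02d}" for i in range(spec.n_dams)]
    samples = [sire] + dams
    role = {s: ROLE_PARENT for s in samples}
    group: dict[str, str] = {}
    sire_of: dict[str, str] = {}
    dam_of: dict[str, str] = {}
    k = 0
    for g, size in spec.group_sizes.items():
        for i in range(size):
            name = f"{g}_{i + 1:02d}"
            samples.append(name)
            role[name] = ROLE_OFFSPRING
            group[name] = g
            sire_of[name] = sire
            dam_of[name] = dams[k % len(dams)]
            k += 1
    return PedigreeCohort(
        samples=tuple(samples), role=role, group=group, sire=sire_of, dam=dam_of
    )


def _substitution(rng: np.random.Generator, weights: dict[str, float]) -> tuple[str, str]:
    classes = list(DIRECTIONAL_CLASSES)
    p = np.array([weights[c] for c in classes])
    p = p / p.sum()
    cls = classes[int(rng.choice(len(classes), p=p))]
    return cls[0], cls[2]


def _random_indel(rng: np.random.Generator) -> tuple[str, str]:
    anchor = _BASES[int(rng.integers(4))]
    extra = "".join(_BASES[int(b)] for b in rng.integers(0, 4, size=int(rng.integers(1, 7))))
    if rng.random() < 0.5:
        return anchor + extra, anchor  # deletion
    return anchor, anchor + extra  # insertion


def _draw_count(rng: np.random.Generator, rate: float, dispersion: float | None) -> int:
    if rate <= 0:
        return 0
    if dispersion is None:
        return int(rng.poisson(rate))
    # negative binomial with mean `rate` and size (shape) `dispersion`
    p = dispersion / (dispersion + rate)
    return int(rng.negative_binomial(dispersion, p))


def generate_cohort(spec: SyntheticCohortSpec, outdir: str | os.PathLike) -> CohortBundle:
    """Generate the full synthetic bundle under ``outdir``.

    Returns a :class:`CohortBundle` holding both the written paths and the
    in-memory objects (records, mask, pedigree, sites, truth table).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    mask = _build_mask(spec, rng)
    pedigree = _build_pedigree(spec)
    placer = _Placer(spec, mask, rng)
    synth = _Synthesizer(spec, rng)
    cfg = synth.cfg

    rows: list[_Row] = []
    sv_rows: list[_SvRow] = []
    truth_rows: list[dict] = []

    def add_truth(sample, vtype, chrom, pos, end, ref, alt, category, expected):
        truth_rows.append(
            {
                "sample": sample,
                "vtype": vtype,
                "chrom": chrom,
                "pos": pos,
                "end": end,
                "ref": ref,
                "alt": alt,
                "category": category,
                "expected": expected,
            }
        )

    # ------------------------------------------------------------------
    # predicted off-target sites (placed first so variants can avoid them)
    sites: list[OffTargetSite] = []
    for _ in range(spec.n_offtarget_sites):
        chrom, start = placer_site_span(placer, spec)
        site = OffTargetSite(
            chrom=chrom,
            start=start,
            end=start + spec.site_length,
            mismatches=int(rng.integers(1, 5)),
        )
        placer.add_site(site)
        sites.append(site)
    site_used_offsets: dict[int, set[int]] = {i: set() for i in range(len(sites))}

    # ------------------------------------------------------------------
    # parental germline variants and Mendelian transmission
    children_of: dict[str, list[str]] = {p: [] for p in pedigree.parents}
    for child in pedigree.offspring:
        children_of[pedigree.sire[child]].append(child)
        children_of[pedigree.dam[child]].append(child)

    for parent in pedigree.parents:
        for _ in range(spec.n_inherited):
            if rng.random() < spec.germline_indel_fraction:
                ref, alt = _random_indel(rng)
                vtype = "indel"
            else:
                ref, alt = _substitution(rng, _UNIFORM_WEIGHTS)
                vtype = "snv"
            chrom, start = placer.sample_span(len(ref))
            pos = start + 1
            row = _Row(chrom, pos, ref, alt, synth.good_annotations())
            row.overrides[parent] = synth.het_call()
            for child in children_of[parent]:
                if rng.random() < 0.5:  # Mendelian transmission of a het allele
                    row.overrides[child] = synth.het_call()
                    add_truth(
                        child, vtype, chrom, pos, start + len(ref), ref, alt,
                        "inherited", "fail:inherited",
                    )
            rows.append(row)

    # ------------------------------------------------------------------
    # de novo SNVs and simple indels per offspring
    indels_by_child: dict[str, list[_Row]] = {c: [] for c in pedigree.offspring}
    for child in pedigree.offspring:
        group = pedigree.group_of(child)
        weights = spec.weights_for(group)
        n_snv = _draw_count(rng, spec.snv_rates[group], spec.nb_dispersion)
        for _ in range(n_snv):
            ref, alt = _substitution(rng, weights)
            coincident = rng.random() < spec.offtarget_fraction and sites
            if coincident:
                chrom, pos = _place_in_site(rng, sites, site_used_offsets, placer)
                if pos is None:  # all site bases exhausted; place outside
                    coincident = False
            if not coincident:
                chrom, start = placer.sample_span(1)
                pos = start + 1
            af = None
            if group == "BE4" and rng.random() < spec.mosaic_fraction:
                af = spec.mosaic_af  # sub-half AF from post-zygotic editing
            row = _Row(chrom, pos, ref, alt, synth.good_annotations())
            row.overrides[child] = synth.het_call(af_target=af)
            rows.append(row)
            add_truth(
                child, "snv", chrom, pos, pos, ref, alt,
                "offtarget_coincident" if coincident else "denovo_pass", "pass",
            )
        n_ind = _draw_count(rng, spec.indel_rates[group], spec.nb_dispersion)
        for _ in range(n_ind):
            ref, alt = _random_indel(rng)
            chrom, start = placer.sample_span(len(ref))
            pos = start + 1
            row = _Row(chrom, pos, ref, alt, synth.good_annotations())
            row.overrides[child] = synth.het_call()
            rows.append(row)
            indels_by_child[child].append(row)
            add_truth(
                child, "indel", chrom, pos, start + len(ref), ref, alt,
                "denovo_pass", "pass",
            )

    # ------------------------------------------------------------------
    # passing complex deletions in a subset of BE4 animals
    be4 = pedigree.offspring_in("BE4")
    for child in be4[: spec.n_be4_complex_carriers]:
        sv = _plant_complex(
            placer, rng, qual=round(float(rng.uniform(300, 900)), 1),
            su=int(rng.integers(8, 31)),
        )
        sv.overrides[child] = ("0/1", synth.passing_depth())
        sv_rows.append(sv)
        add_truth(
            child, "complex", sv.chrom, sv.start, sv.end, ".", f"<{sv.svtype}>",
            "denovo_pass", "pass",
        )

    # ------------------------------------------------------------------
    # distractors: each violates exactly the filter it is named after
    for child in pedigree.offspring:
        _plant_distractors(
            spec, rng, placer, synth, cfg, pedigree, child,
            rows, sv_rows, indels_by_child, add_truth,
        )

    # ------------------------------------------------------------------
    # materialise the VCFs
    rows.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    sv_rows.sort(key=lambda r: (r.chrom, r.start, r.end))
    samples = list(pedigree.samples)
    records = []
    for row in rows:
        base_dp = rng.poisson(spec.depth_mean, size=len(samples))
        calls = []
        for i, s in enumerate(samples):
            if s in row.overrides:
                calls.append(row.overrides[s])
            else:
                dp = int(base_dp[i])
                calls.append(GenotypeCall(gt="0/0", ad_ref=dp, ad_alt=0, dp=dp))
        records.append(
            VariantRecord(
                chrom=row.chrom, pos=row.pos, ref=row.ref, alt=row.alt,
                annotations=row.annotations, calls=tuple(calls),
            )
        )
    sv_records = []
    for row in sv_rows:
        base_dp = rng.poisson(spec.depth_mean, size=len(samples))
        gts, dps = [], []
        for i, s in enumerate(samples):
            if s in row.overrides:
                gt, dp = row.overrides[s]
            else:
                gt, dp = "0/0", int(base_dp[i])
            gts.append(gt)
            dps.append(dp)
        sv_records.append(
            ComplexIndelRecord(
                chrom=row.chrom, start=row.start, end=row.end, svtype=row.svtype,
                qual=row.qual, su=row.su, gts=tuple(gts), dps=tuple(dps),
            )
        )

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)

    paths = {
        "vcf": outdir / "cohort.vcf",
        "sv_vcf": outdir / "complex.vcf",
        "mask": outdir / "masks.bed",
        "offtargets": outdir / "offtargets.tsv",
        "pedigree": outdir / "pedigree.tsv",
        "truth": outdir / "truth.tsv",
        "spec": outdir / "spec.yaml",
    }
    write_vcf(records, samples, paths["vcf"], contigs=spec.chromosomes)
    write_sv_vcf(sv_records, samples, paths["sv_vcf"], contigs=spec.chromosomes)
    write_intervals_bed(mask, paths["mask"])
    write_offtarget_table(sites, paths["offtargets"])
    write_pedigree(pedigree, paths["pedigree"])
    write_truth(truth, paths["truth"])
    spec.to_yaml(paths["spec"])

    return CohortBundle(
        outdir=outdir, spec=spec, paths=paths, truth=truth, samples=samples,
        records=records, sv_records=sv_records, mask=mask, pedigree=pedigree,
        sites=sites,
    )


def placer_site_span(placer: _Placer, spec: SyntheticCohortSpec) -> tuple[str, int]:
    return placer.sample_span(spec.site_length)


def _place_in_site(rng, sites, site_used_offsets, placer):
    """Pick a fresh base inside a random off-target site (interior bases)."""
    for _ in range(200):
        i = int(rng.integers(len(sites)))
        site = sites[i]
        free = [
            o for o in range(2, site.end - site.start - 2)
            if o not in site_used_offsets[i]
        ]
        if not free:
            continue
        offset = free[int(rng.integers(len(free)))]
        site_used_offsets[i].add(offset)
        pos = site.start + offset + 1  # 1-based
        placer.used_pos.add((site.chrom, pos - 1))
        return site.chrom, pos
    return None, None


def _plant_complex(placer: _Placer, rng, qual: float, su: int) -> _SvRow:
    length = int(rng.integers(200, 801))
    chrom, start = placer.sample_span(length)
    return _SvRow(chrom=chrom, start=start, end=start + length, svtype="DEL",
                  qual=qual, su=su)


def _plant_distractors(
    spec, rng, placer, synth, cfg, pedigree, child,
    rows, sv_rows, indels_by_child, add_truth,
):
    sv_quality_row: _SvRow | None = None
    # sv_quality must precede sv_overlap: the low-quality complex record is
    # the overlap partner for the simple-indel distractor
    order = sorted(
        set(spec.distractors),
        key=lambda c: (c != "sv_quality", DISTRACTOR_CATEGORIES.index(c)),
    )
    for category in order:
        if category == "hard_snv":
            ref, alt = _substitution(rng, _UNIFORM_WEIGHTS)
            chrom, start = placer.sample_span(1)
            ann = synth.good_annotations()
            ann["QD"] = round(float(rng.uniform(0.2, 1.5)), 2)
            row = _Row(chrom, start + 1, ref, alt, ann)
            row.overrides[child] = synth.het_call()
            rows.append(row)
            add_truth(child, "snv", chrom, start + 1, start + 1, ref, alt,
                      "distractor:hard_snv", "fail:hard_snv")
        elif category == "hard_indel":
            ref, alt = _random_indel(rng)
            chrom, start = placer.sample_span(len(ref))
            ann = synth.good_annotations()
            ann["FS"] = round(float(rng.uniform(210.0, 300.0)), 2)
            row = _Row(chrom, start + 1, ref, alt, ann)
            row.overrides[child] = synth.het_call()
            rows.append(row)
            add_truth(child, "indel", chrom, start + 1, start + len(ref), ref, alt,
                      "distractor:hard_indel", "fail:hard_indel")
        elif category == "mask":
            ref, alt = _substitution(rng, _UNIFORM_WEIGHTS)
            chrom, start = placer.sample_span(1, in_mask=True)
            row = _Row(chrom, start + 1, ref, alt, synth.good_annotations())
            row.overrides[child] = synth.het_call()
            rows.append(row)
            add_truth(child, "snv", chrom, start + 1, start + 1, ref, alt,
                      "distractor:mask", "fail:mask")
        elif category == "genotype":
            ref, alt = _substitution(rng, _UNIFORM_WEIGHTS)
            chrom, start = placer.sample_span(1)
            dp = synth.passing_depth()
            ad_alt = max(2, round(0.25 * dp))  # alt evidence, but called 0/0
            row = _Row(chrom, start + 1, ref, alt, synth.good_annotations())
            row.overrides[child] = GenotypeCall(
                gt="0/0", ad_ref=dp - ad_alt, ad_alt=ad_alt, dp=dp
            )
            rows.append(row)
            add_truth(child, "snv", chrom, start + 1, start + 1, ref, alt,
                      "distractor:genotype", "fail:genotype")
        elif category == "min_depth":
            ref, alt = _substitution(rng, _UNIFORM_WEIGHTS)
            chrom, start = placer.sample_span(1)
            dp = int(rng.integers(4, cfg.dp_min))
            ad_alt = max(1, round(0.4 * dp))
            row = _Row(chrom, start + 1, ref, alt, synth.good_annotations())
            row.overrides[child] = GenotypeCall(
                gt="0/1", ad_ref=dp - ad_alt, ad_alt=ad_alt, dp=dp
            )
            rows.append(row)
            add_truth(child, "snv", chrom, start + 1, start + 1, ref, alt,
                      "distractor:min_depth", "fail:min_depth")
        elif category == "max_depth":
            ref, alt = _substitution(rng, _UNIFORM_WEIGHTS)
            chrom, start = placer.sample_span(1)
            dp = synth.dp_max + int(rng.integers(20, 60))
            ad_alt = round(0.5 * dp)
            row = _Row(chrom, start + 1, ref, alt, synth.good_annotations())
            row.overrides[child] = GenotypeCall(
                gt="0/1", ad_ref=dp - ad_alt, ad_alt=ad_alt, dp=dp
            )
            rows.append(row)
            add_truth(child, "snv", chrom, start + 1, start + 1, ref, alt,
                      "distractor:max_depth", "fail:max_depth")
        elif category == "allele_fraction":
            ref, alt = _substitution(rng, _UNIFORM_WEIGHTS)
            chrom, start = placer.sample_span(1)
            dp = int(rng.integers(40, 81))
            ad_alt = max(2, round(0.06 * dp))  # af in (0, 0.10)
            row = _Row(chrom, start + 1, ref, alt, synth.good_annotations())
            row.overrides[child] = GenotypeCall(
                gt="0/1", ad_ref=dp - ad_alt, ad_alt=ad_alt, dp=dp
            )
            rows.append(row)
            add_truth(child, "snv", chrom, start + 1, start + 1, ref, alt,
                      "distractor:allele_fraction", "fail:allele_fraction")
        elif category == "near_indel":
            partner = _near_indel_partner(
                spec, rng, placer, synth, child, rows, indels_by_child, add_truth
            )
            snv_pos = _near_indel_position(spec, rng, placer, partner)
            ref_base = "A" if partner.ref[0] != "A" else "C"
            alt_base = "G" if ref_base != "G" else "T"
            row = _Row(partner.chrom, snv_pos, ref_base, alt_base, synth.good_annotations())
            row.overrides[child] = synth.het_call()
            rows.append(row)
            add_truth(child, "snv", partner.chrom, snv_pos, snv_pos, ref_base, alt_base,
                      "distractor:near_indel", "fail:near_indel")
        elif category == "sv_quality":
            sv = _plant_complex(placer, rng, qual=round(float(rng.uniform(20, 90)), 1),
                                su=int(rng.integers(8, 31)))
            sv.overrides[child] = ("0/1", synth.passing_depth())
            sv_rows.append(sv)
            sv_quality_row = sv
            add_truth(child, "complex", sv.chrom, sv.start, sv.end, ".", "<DEL>",
                      "distractor:sv_quality", "fail:sv_quality")
        elif category == "sv_su":
            sv = _plant_complex(placer, rng, qual=round(float(rng.uniform(300, 900)), 1),
                                su=int(rng.integers(0, cfg.sv_su_min)))
            sv.overrides[child] = ("0/1", synth.passing_depth())
            sv_rows.append(sv)
            add_truth(child, "complex", sv.chrom, sv.start, sv.end, ".", "<DEL>",
                      "distractor:sv_su", "fail:sv_su")
        elif category == "sv_overlap":
            if sv_quality_row is None:
                sv_quality_row = _plant_complex(
                    placer, rng, qual=round(float(rng.uniform(300, 900)), 1),
                    su=int(rng.integers(8, 31)),
                )
                sv_quality_row.overrides[child] = ("0/1", synth.passing_depth())
                sv_rows.append(sv_quality_row)
                add_truth(child, "complex", sv_quality_row.chrom, sv_quality_row.start,
                          sv_quality_row.end, ".", "<DEL>", "denovo_pass", "pass")
            sv = sv_quality_row
            ref, alt = _random_indel(rng)
            lo = sv.start + 20
            hi = sv.end - 20 - len(ref)
            start = int(rng.integers(lo, hi))
            row = _Row(sv.chrom, start + 1, ref, alt, synth.good_annotations())
            row.overrides[child] = synth.het_call()
            rows.append(row)
            for p in range(start, start + len(ref)):
                placer.used_pos.add((sv.chrom, p))
            add_truth(child, "indel", sv.chrom, start + 1, start + len(ref), ref, alt,
                      "distractor:sv_overlap", "fail:sv_overlap")
        elif category == "inherited":
            ref, alt = _substitution(rng, _UNIFORM_WEIGHTS)
            chrom, start = placer.sample_span(1)
            row = _Row(chrom, start + 1, ref, alt, synth.good_annotations())
            row.overrides[child] = synth.het_call()
            row.overrides[pedigree.dam[child]] = synth.het_call()
            rows.append(row)
            add_truth(child, "snv", chrom, start + 1, start + 1, ref, alt,
                      "distractor:inherited", "fail:inherited")


def _near_indel_partner(spec, rng, placer, synth, child, rows, indels_by_child, add_truth):
    """A passing de novo indel of this child, planting one if necessary."""
    if indels_by_child[child]:
        return indels_by_child[child][0]
    ref, alt = _random_indel(rng)
    chrom, start = placer.sample_span(len(ref))
    row = _Row(chrom, start + 1, ref, alt, synth.good_annotations())
    row.overrides[child] = synth.het_call()
    rows.append(row)
    indels_by_child[child].append(row)
    add_truth(child, "indel", chrom, start + 1, start + len(ref), ref, alt,
              "denovo_pass", "pass")
    return row


def _near_indel_position(spec, rng, placer, partner: _Row) -> int:
    """A 1-based SNV position within the exclusion window of the partner indel."""
    if len(partner.ref) > len(partner.alt):  # deletion borders: first/last REF base
        left, right = partner.pos, partner.pos + len(partner.ref) - 1
    else:  # insertion borders: the two flanking bases
        left, right = partner.pos, partner.pos + 1
    candidates = []
    for off in range(2, 6):  # distance to the nearer border stays <= 5
        candidates.append(right + off)
        candidates.append(left - off)
    for pos in candidates:
        if pos < 1:
            continue
        if placer.mask.overlaps(partner.chrom, pos - 1, pos):
            continue
        if (partner.chrom, pos - 1) in placer.used_pos:
            continue
        if placer.sites[partner.chrom].overlap(pos - 1, pos):
            continue
        placer.used_pos.add((partner.chrom, pos - 1))
        return pos
    raise GenerationError("could not place a near-indel distractor SNV")
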