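"""Core data model shared by every stage of the pipeline.

Coordinate conventions, fixed here and nowhere else:

* small variants carry a VCF-style 1-based ``pos`` of the first REF base;
* interval types (masks, structural variants, off-target sites) use
  BED-style 0-based half-open ``[start, end)`` coordinates.

All conversions between the two live in :mod:`denovotrio.variant_io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from intervaltree import IntervalTree

BASES = frozenset("ACGT")

#: genotype strings the pipeline understands
GT_HOMREF = "0/0"
GT_HET = "0/1"
GT_HOMALT = "1/1"
GT_MISSING = "./."

CARRIER_GTS = frozenset({GT_HET, GT_HOMALT})

#: variant classes
SNV = "SNV"
INSERTION = "insertion"
DELETION = "deletion"
OTHER = "other"  # e.g. multi-nucleotide substitutions; parsed but not analysed


class PedigreeError(ValueError):
    """Inconsistent pedigree / cohort description."""


@dataclass(frozen=True, slots=True)
class GenotypeCall:
    """One sample's call at one bi-allelic site.

    ``af`` is derived from the allele depths (AD), not from DP, because DP
    also counts reads that were uninformative for either allele.  When the
    allele depths are absent or sum to zero the allele fraction is
    undefined and reported as ``None``.
    """

    gt: str = GT_MISSING
    ad_ref: int | None = None
    ad_alt: int | None = None
    dp: int | None = None

    def __post_init__(self) -> None:
        if self.gt not in (GT_HOMREF, GT_HET, GT_HOMALT, GT_MISSING):
            raise ValueError(f"unsupported genotype string: {self.gt!r}")
        for name in ("ad_ref", "ad_alt", "dp"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @property
    def af(self) -> float | None:
        """Allele fraction ad_alt / (ad_ref + ad_alt); None when undefined."""
        if self.ad_ref is None or self.ad_alt is None:
            return None
        total = self.ad_ref + self.ad_alt
        if total == 0:
            return None
        return self.ad_alt / total

    @property
    def has_alt(self) -> bool:
        return self.gt in CARRIER_GTS

    @property
    def is_missing(self) -> bool:
        return self.gt == GT_MISSING


#: site-level annotation keys recognised on small variants
ANNOTATION_KEYS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "SOR")

VariantKey = tuple[str, int, str, str]


@dataclass(slots=True)
class VariantRecord:
    """One normalised bi-allelic small variant.

    Multi-allelic VCF rows are split into one record per ALT allele before
    construction, with AD columns re-sliced per allele, so every threshold
    downstream is evaluated per allele.
    """

    chrom: str
    pos: int  # 1-based position of the first REF base
    ref: str
    alt: str
    annotations: dict[str, float] = field(default_factory=dict)
    calls: tuple[GenotypeCall, ...] = ()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if not (set(self.ref) <= BASES and set(self.alt) <= BASES):
            raise ValueError(f"non-ACGT allele: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        unknown = set(self.annotations) - set(ANNOTATION_KEYS)
        if unknown:
            raise ValueError(f"unknown annotation keys: {sorted(unknown)}")

    @property
    def vclass(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return SNV
        if len(self.alt) > len(self.ref):
            return INSERTION
        if len(self.ref) > len(self.alt):
            return DELETION
        return OTHER

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def span0(self) -> tuple[int, int]:
        """0-based half-open interval of the REF bases this record spans."""
        return (self.pos - 1, self.pos - 1 + len(self.ref))


SvKey = tuple[str, int, int, str]


@dataclass(slots=True)
class ComplexIndelRecord:
    """A structural-variant caller record (complex/large indel)."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    svtype: str  # DEL / DUP / INV / other
    qual: float
    su: int  # pieces of evidence supporting the variant across all samples
    gts: tuple[str, ...] = ()
    dps: tuple[int | None, ...] = ()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end must exceed start ({self.start}, {self.end})")
        if self.su < 0:
            raise ValueError("SU must be non-negative")
        if self.qual < 0:
            raise ValueError("qual must be non-negative")

    @property
    def key(self) -> SvKey:
        return (self.chrom, self.start, self.end, self.svtype)


class GenomeMask:
    """Union of excluded genomic intervals (repeats, blacklist regions).

    Intervals are merged per chromosome on construction, so membership
    queries see a sorted, non-overlapping set.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()) -> None:
        trees: dict[str, IntervalTree] = {}
        for chrom, start, end in intervals:
            if end <= start:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
        for tree in trees.values():
            tree.merge_overlaps(strict=False)  # also merge bookended intervals
        self._trees = trees

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) intersects any masked interval."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self._trees):
            for iv in sorted(self._trees[chrom]):
                out.append((chrom, iv.begin, iv.end))
        return out

    def total_length(self) -> int:
        return sum(e - s for _, s, e in self.intervals())

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


ROLE_PARENT = "parent"
ROLE_OFFSPRING = "offspring"
GROUPS = ("control", "ABE", "BE4")
NON_EDITED_GROUPS = frozenset({"control"})


@dataclass(slots=True)
class PedigreeCohort:
    """Sample roles, experimental groups and trio links for a cohort."""

    samples: tuple[str, ...]
    role: dict[str, str]
    group: dict[str, str]  # offspring -> control / ABE / BE4
    sire: dict[str, str]  # offspring -> sire id
    dam: dict[str, str]  # offspring -> dam id

    def __post_init__(self) -> None:
        for s in self.samples:
            if self.role.get(s) not in (ROLE_PARENT, ROLE_OFFSPRING):
                raise PedigreeError(f"sample {s!r} has no valid role")
        for s in self.offspring:
            if s not in self.group:
                raise PedigreeError(f"offspring {s!r} has no group label")
            if s not in self.sire and s not in self.dam:
                raise PedigreeError(f"offspring {s!r} has no resolvable parent")
            for p in self.parents_of(s):
                if self.role.get(p) != ROLE_PARENT:
                    raise PedigreeError(
                        f"parent {p!r} of {s!r} is not a parent sample"
                    )

    @property
    def parents(self) -> list[str]:
        return [s for s in self.samples if self.role[s] == ROLE_PARENT]

    @property
    def offspring(self) -> list[str]:
        return [s for s in self.samples if self.role[s] == ROLE_OFFSPRING]

    def parents_of(self, sample: str) -> list[str]:
        out = []
        if sample in self.sire:
            out.append(self.sire[sample])
        if sample in self.dam:
            out.append(self.dam[sample])
        return out

    def group_of(self, sample: str) -> str:
        return self.group[sample]

    def offspring_in(self, group: str) -> list[str]:
        return [s for s in self.offspring if self.group[s] == group]

    def is_edited(self, sample: str) -> bool:
        """True for offspring exposed to a base editor (ABE or BE4)."""
        return (
            self.role[sample] == ROLE_OFFSPRING
            and self.group[sample] not in NON_EDITED_GROUPS
        )

    def non_edited_samples(self) -> list[str]:
        """Parents plus non-edited (control) offspring."""
        return [
            s
            for s in self.samples
            if self.role[s] == ROLE_PARENT or not self.is_edited(s)
        ]
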