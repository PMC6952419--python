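"""Coincidence of de novo SNVs with in-silico predicted off-target sites.

Predicted protospacer+PAM intervals are first filtered with the same
repeat/blacklist mask used for variants.  Candidate de novo SNVs that also
occur in a non-edited animal (a control offspring or a parent) are
population-recurrent and excluded from coincidence accounting before the
fraction is computed: such variants cannot be attributed to base editing.
Coincidence itself is positional — the SNV's base falling inside a site
interval — not allele-aware.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .model import GenomeMask, PedigreeCohort, VariantKey
from .variant_io import normalize_chrom


@dataclass(frozen=True, slots=True)
class OffTargetSite:
    """One predicted off-target interval (protospacer + PAM)."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    mismatches: int

    def __post_init__(self) -> None:
        length = self.end - self.start
        if not 20 <= length <= 30:
            raise ValueError(
                f"off-target site length {length} outside [20, 30] "
                f"({self.chrom}:{self.start}-{self.end})"
            )
        if self.mismatches < 0:
            raise ValueError("mismatches must be non-negative")


@dataclass(slots=True)
class CoincidenceResult:
    """Coincidence accounting for a set of de novo SNVs."""

    n_denovo: int
    n_coincident: int
    matched: list[tuple[VariantKey, OffTargetSite]] = field(default_factory=list)

    @property
    def fraction(self) -> float | None:
        """n_coincident / n_denovo; None (not 0) when there are no SNVs."""
        if self.n_denovo == 0:
            return None
        return self.n_coincident / self.n_denovo


OFFTARGET_COLUMNS = ["chrom", "start", "end", "mismatches"]


def read_offtarget_table(path: str | os.PathLike) -> list[OffTargetSite]:
    """Read the tab-separated predicted off-target site table."""
    df = pd.read_csv(path, sep="\t")
    missing = set(OFFTARGET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"off-target table missing columns: {sorted(missing)}")
    return [
        OffTargetSite(
            chrom=normalize_chrom(str(row.chrom)),
            start=int(row.start),
            end=int(row.end),
            mismatches=int(row.mismatches),
        )
        for row in df.itertuples(index=False)
    ]


def write_offtarget_table(sites: Sequence[OffTargetSite], path: str | os.PathLike) -> None:
    pd.DataFrame(
        [(s.chrom, s.start, s.end, s.mismatches) for s in sites],
        columns=OFFTARGET_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def filter_sites(sites: Iterable[OffTargetSite], mask: GenomeMask) -> list[OffTargetSite]:
    """Drop sites overlapping any masked interval (any-overlap semantics)."""
    return [s for s in sites if not mask.overlaps(s.chrom, s.start, s.end)]


def population_recurrence_filter(
    candidates: Mapping[str, Iterable[VariantKey]],
    pedigree: PedigreeCohort,
    parent_keys: Mapping[str, Iterable[VariantKey]] | None = None,
) -> dict[str, set[VariantKey]]:
    """Exclude population-recurrent variants from per-sample candidate sets.

    A variant is dropped from a sample's set iff the same (chrom, pos, ref,
    alt) also occurs in a non-edited animal other than the sample itself —
    a control offspring's candidate set or a parent's carried alleles
    (``parent_keys``, optional).  Recurrence confined to base-edited
    animals does not exclude.
    """
    seen_in: dict[VariantKey, set[str]] = {}
    for sample, keys in candidates.items():
        for key in keys:
            seen_in.setdefault(key, set()).add(sample)
    if parent_keys:
        for parent, keys in parent_keys.items():
            for key in keys:
                seen_in.setdefault(key, set()).add(parent)

    non_edited = set(pedigree.non_edited_samples())
    out: dict[str, set[VariantKey]] = {}
    for sample, keys in candidates.items():
        kept = set()
        for key in keys:
            others = seen_in[key] - {sample}
            if not (others & non_edited):
                kept.add(key)
        out[sample] = kept
    return out


def coincidence(
    denovo: Iterable[VariantKey],
    sites: Sequence[OffTargetSite],
) -> CoincidenceResult:
    """Count de novo SNVs whose position lies inside a retained site.

    ``denovo`` is an iterable of (chrom, pos, ref, alt) keys with 1-based
    positions; each element counts once (pool per-sample sets upstream to
    weight recurrent variants by the number of carriers).
    """
    trees: dict[str, IntervalTree] = {}
    for site in sites:
        trees.setdefault(site.chrom, IntervalTree()).addi(site.start, site.end, site)
    n = 0
    n_hit = 0
    matched = []
    for key in denovo:
        chrom, pos = key[0], key[1]
        n += 1
        tree = trees.get(chrom)
        if tree is None:
            continue
        hits = tree.at(pos - 1)  # 0-based position of the SNV base
        if hits:
            n_hit += 1
            site = sorted(hits, key=lambda iv: (iv.begin, iv.end))[0].data
            matched.append((key, site))
    return CoincidenceResult(n_denovo=n, n_coincident=n_hit, matched=matched)
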