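"""Mutational-spectrum tabulation and nonparametric group statistics.

The group comparison follows the conventions of small-cohort mutation-rate
studies: per-group mean +/- SD summaries, a Kruskal-Wallis rank test across
all groups, and pairwise two-sided Wilcoxon rank-sum / Mann-Whitney U tests
(one test, two historical names).  The pairwise test is exact (full
enumeration of rank assignments) for small tie-free inputs and falls back
to the normal approximation with tie and continuity corrections otherwise,
matching the default behaviour of R's ``wilcox.test``.

Boxplot tuples use a mean-based convention: center = mean, box limits =
mean +/- SD, whiskers = min and max.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .model import BASES, PedigreeCohort

#: default size limit (n1 + n2) up to which the tie-free U test is exact,
#: matching R's wilcox.test convention (exact below 50 observations)
EXACT_LIMIT = 50

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: the 12 directional substitution classes, pyrimidine references first
DIRECTIONAL_CLASSES = (
    "C>A", "C>G", "C>T", "T>A", "T>C", "T>G",
    "G>T", "G>C", "G>A", "A>T", "A>G", "A>C",
)

#: the 6 pyrimidine-collapsed classes
COLLAPSED_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def classify_substitution(ref: str, alt: str, collapse: bool = False) -> str:
    """Substitution class label for a single-base change.

    With ``collapse=True`` purine-reference changes are mapped to the
    reverse-complement pyrimidine class (e.g. G>A becomes C>T), giving the
    6-class strand-symmetric spectrum.
    """
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"bases must be one of ACGT, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if collapse and ref in ("A", "G"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def spectrum_table(
    substitutions: Mapping[str, Sequence[tuple[str, str]]],
    collapse: bool = False,
):
    """Per-sample substitution-class count matrix.

    ``substitutions`` maps sample id to its (ref, alt) single-base changes.
    Returns a pandas DataFrame (rows = samples, columns = classes) whose
    row sums equal the per-sample SNV counts.
    """
    import pandas as pd

    classes = COLLAPSED_CLASSES if collapse else DIRECTIONAL_CLASSES
    data = {}
    for sample, subs in substitutions.items():
        counts = dict.fromkeys(classes, 0)
        for ref, alt in subs:
            counts[classify_substitution(ref, alt, collapse=collapse)] += 1
        data[sample] = counts
    df = pd.DataFrame.from_dict(data, orient="index", columns=list(classes))
    df.index.name = "sample"
    return df


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    exact_limit: int = EXACT_LIMIT,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (a.k.a. Wilcoxon rank-sum test).

    Returns ``(U, p)`` with U the statistic of ``x`` computed from
    midranks.  The p-value is exact (doubled smaller tail of the full
    permutation distribution, capped at 1) when ``len(x) + len(y) <=
    exact_limit`` and there are no ties; otherwise the normal approximation
    with tie correction and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        # all observations identical: maximal overlap, U at its null mean
        return (n1 * n2 / 2.0, 1.0)
    if n1 + n2 <= exact_limit and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return (float(res.statistic), min(float(res.pvalue), 1.0))


# the Wilcoxon rank-sum test is the same procedure under another name
wilcoxon_rank_sum = mann_whitney_u


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-squared p on k-1 df.

    The degenerate all-identical case (every observation equal) carries no
    rank information; it is reported as H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return (0.0, 1.0)
    h, p = stats.kruskal(*arrays)
    return (float(h), float(p))


@dataclass(slots=True)
class GroupSummary:
    """Mean +/- SD summary of one group's per-sample counts."""

    n: int
    mean: float
    sd: float
    min: float
    max: float

    @property
    def boxplot(self) -> dict[str, float]:
        """Boxplot tuple: center = mean, box = mean +/- SD, whiskers = min/max."""
        return {
            "center": self.mean,
            "box_low": self.mean - self.sd,
            "box_high": self.mean + self.sd,
            "whisker_low": self.min,
            "whisker_high": self.max,
        }


@dataclass(slots=True)
class GroupComparisonResult:
    """Full group comparison of per-sample counts."""

    groups: dict[str, GroupSummary]
    kruskal: tuple[float, float] | None  # (H, p)
    pairwise: dict[tuple[str, str], tuple[float, float]]  # (U, p)
    pairwise_adjusted: dict[tuple[str, str], float] | None = None
    warnings: list[str] = field(default_factory=list)


def summarize_groups(
    counts: Mapping[str, float],
    pedigree_or_groups: PedigreeCohort | Mapping[str, str],
    bonferroni: bool = False,
    exact_limit: int = EXACT_LIMIT,
) -> GroupComparisonResult:
    """Summarise per-sample counts by group and run the group tests.

    ``counts`` maps offspring sample id to its de novo count (SNVs or
    indels).  SD is the sample standard deviation (ddof = 1; 0 for a group
    of one).  With a single group only the summary is produced.  Pairwise
    p-values are reported raw; ``bonferroni=True`` adds adjusted values.
    """
    if isinstance(pedigree_or_groups, PedigreeCohort):
        group_of = {s: pedigree_or_groups.group_of(s) for s in counts}
    else:
        group_of = {s: pedigree_or_groups[s] for s in counts}

    by_group: dict[str, list[float]] = {}
    for sample, count in counts.items():
        by_group.setdefault(group_of[sample], []).append(float(count))
    if any(len(v) == 0 for v in by_group.values()) or not by_group:
        raise ValueError("every group must have at least one member")

    summaries = {}
    for name in sorted(by_group):
        vals = np.asarray(by_group[name])
        summaries[name] = GroupSummary(
            n=vals.size,
            mean=float(vals.mean()),
            sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            min=float(vals.min()),
            max=float(vals.max()),
        )

    warns: list[str] = []
    names = sorted(by_group)
    if len(names) < 2:
        warns.append("single group: omnibus and pairwise tests skipped")
        warnings.warn(warns[-1], stacklevel=2)
        return GroupComparisonResult(
            groups=summaries, kruskal=None, pairwise={}, warnings=warns
        )

    kw = kruskal_wallis([by_group[n] for n in names])
    pairwise = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            pairwise[(a, b)] = mann_whitney_u(
                by_group[a], by_group[b], exact_limit=exact_limit
            )
    adjusted = None
    if bonferroni:
        m = len(pairwise)
        adjusted = {pair: min(1.0, p * m) for pair, (_, p) in pairwise.items()}
    return GroupComparisonResult(
        groups=summaries,
        kruskal=kw,
        pairwise=pairwise,
        pairwise_adjusted=adjusted,
        warnings=warns,
    )
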