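"""End-to-end orchestration: load inputs, run the cascade, compute the
spectrum/group statistics and the off-target coincidence, write reports."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .denovo_filters import (
    DeNovoCallset,
    FilterConfig,
    call_denovo_cohort,
    funnel_counts,
    parental_carrier_keys,
)
from .model import PedigreeCohort
from .offtarget import (
    CoincidenceResult,
    coincidence,
    filter_sites,
    population_recurrence_filter,
    read_offtarget_table,
)
from .spectrum_stats import (
    GroupComparisonResult,
    spectrum_table,
    summarize_groups,
)
from .variant_io import (
    read_intervals_bed,
    read_multisample_vcf,
    read_pedigree,
    read_sv_vcf,
    write_vcf,
)

log = logging.getLogger("denovotrio")


@dataclass
class RunConfig:
    """Paths and options for one pipeline run."""

    vcf: str
    sv_vcf: str | None
    masks: list[str]
    pedigree: str
    offtargets: str | None
    out: str | None = None  # None: return results without writing files
    filters: FilterConfig = field(default_factory=FilterConfig)
    exact_limit: int = 50
    bonferroni: bool = False
    write_traces: bool = True
    write_denovo_vcfs: bool = True

    def validate_paths(self) -> None:
        required = [self.vcf, self.pedigree, *self.masks]
        if self.sv_vcf:
            required.append(self.sv_vcf)
        if self.offtargets:
            required.append(self.offtargets)
        missing = [p for p in required if not os.path.exists(p)]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")
        if not self.masks:
            raise FileNotFoundError("at least one mask BED is required")


@dataclass
class PipelineResult:
    callsets: dict[str, DeNovoCallset]
    snv_counts: dict[str, int]
    indel_counts: dict[str, int]  # simple + complex
    snv_stats: GroupComparisonResult | None
    indel_stats: GroupComparisonResult | None
    coincidence_overall: CoincidenceResult | None
    coincidence_by_group: dict[str, CoincidenceResult]
    funnel: dict[str, int]
    pedigree: PedigreeCohort


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full analysis described by ``cfg``."""
    cfg.validate_paths()
    log.info("reading inputs")
    records, samples = read_multisample_vcf(cfg.vcf)
    sv_records, sv_samples = ([], [])
    if cfg.sv_vcf:
        sv_records, sv_samples = read_sv_vcf(cfg.sv_vcf)
    mask = read_intervals_bed(cfg.masks)
    pedigree = read_pedigree(cfg.pedigree)

    unmatched = [s for s in pedigree.samples if s not in set(samples)]
    if unmatched:
        raise ValueError(f"pedigree samples absent from the VCF: {unmatched}")

    log.info(
        "loaded %d small variants, %d complex indels, %d mask intervals, "
        "%d samples", len(records), len(sv_records), len(mask), len(samples),
    )
    callsets = call_denovo_cohort(
        records, samples, sv_records, sv_samples, mask, pedigree, cfg.filters
    )
    funnel = funnel_counts(callsets)
    for name in sorted(funnel):
        log.info("funnel %-16s %d", name, funnel[name])

    snv_counts = {s: len(cs.snvs) for s, cs in callsets.items()}
    indel_counts = {
        s: len(cs.indels) + len(cs.complex) for s, cs in callsets.items()
    }

    groups = {pedigree.group_of(s) for s in pedigree.offspring}
    snv_stats = indel_stats = None
    if groups:
        snv_stats = summarize_groups(
            snv_counts, pedigree, bonferroni=cfg.bonferroni,
            exact_limit=cfg.exact_limit,
        )
        indel_stats = summarize_groups(
            indel_counts, pedigree, bonferroni=cfg.bonferroni,
            exact_limit=cfg.exact_limit,
        )

    coincidence_overall = None
    coincidence_by_group: dict[str, CoincidenceResult] = {}
    if cfg.offtargets:
        sites = filter_sites(read_offtarget_table(cfg.offtargets), mask)
        candidates = {s: cs.snv_keys for s, cs in callsets.items()}
        parent_keys = {
            p: parental_carrier_keys(records, samples, p) for p in pedigree.parents
        }
        retained = population_recurrence_filter(candidates, pedigree, parent_keys)
        pooled = [k for s in pedigree.offspring for k in sorted(retained[s])]
        coincidence_overall = coincidence(pooled, sites)
        for g in sorted(groups):
            keys = [
                k for s in pedigree.offspring_in(g) for k in sorted(retained[s])
            ]
            coincidence_by_group[g] = coincidence(keys, sites)

    result = PipelineResult(
        callsets=callsets,
        snv_counts=snv_counts,
        indel_counts=indel_counts,
        snv_stats=snv_stats,
        indel_stats=indel_stats,
        coincidence_overall=coincidence_overall,
        coincidence_by_group=coincidence_by_group,
        funnel=funnel,
        pedigree=pedigree,
    )
    if cfg.out is not None:
        write_outputs(result, cfg)
    return result


def _stats_dict(stats: GroupComparisonResult | None) -> dict | None:
    if stats is None:
        return None
    out = {
        "groups": {
            name: {**asdict(s), "boxplot": s.boxplot}
            for name, s in stats.groups.items()
        },
        "kruskal_wallis": (
            {"H": stats.kruskal[0], "p": stats.kruskal[1]} if stats.kruskal else None
        ),
        "pairwise": {
            f"{a}_vs_{b}": {"U": u, "p": p}
            for (a, b), (u, p) in stats.pairwise.items()
        },
        "warnings": stats.warnings,
    }
    if stats.pairwise_adjusted is not None:
        for (a, b), p in stats.pairwise_adjusted.items():
            out["pairwise"][f"{a}_vs_{b}"]["p_bonferroni"] = p
    return out


def _coincidence_dict(res: CoincidenceResult | None) -> dict | None:
    if res is None:
        return None
    return {
        "n_denovo": res.n_denovo,
        "n_coincident": res.n_coincident,
        "fraction": res.fraction,
    }


def write_outputs(result: PipelineResult, cfg: RunConfig) -> None:
    """Write the report bundle under ``cfg.out``."""
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)

    # config echo, sufficient to reproduce the run
    echo = {
        "vcf": cfg.vcf,
        "sv_vcf": cfg.sv_vcf,
        "masks": list(cfg.masks),
        "pedigree": cfg.pedigree,
        "offtargets": cfg.offtargets,
        "filters": asdict(cfg.filters),
        "exact_limit": cfg.exact_limit,
        "bonferroni": cfg.bonferroni,
    }
    with open(out / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(echo, fh, sort_keys=True)

    if cfg.write_denovo_vcfs:
        for sample, cs in result.callsets.items():
            variants = sorted(
                cs.snvs + cs.indels, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)
            )
            single = [
                type(v)(
                    chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                    annotations=v.annotations,
                    calls=(v.calls[result.pedigree.samples.index(sample)],),
                )
                for v in variants
            ]
            write_vcf(single, [sample], out / f"denovo_{sample}.vcf")

    if cfg.write_traces:
        with open(out / "traces.tsv", "w") as fh:
            fh.write("sample\tchrom\tpos\tref\talt\tsteps\tfinal\treasons\tflags\n")
            for sample in result.pedigree.offspring:
                cs = result.callsets[sample]
                for trace in cs.traces.values():
                    steps = ";".join(f"{n}={o}" for n, o in trace.steps)
                    fh.write(
                        f"{sample}\t{trace.chrom}\t{trace.pos}\t{trace.ref}\t"
                        f"{trace.alt}\t{steps}\t{trace.final}\t"
                        f"{','.join(trace.reasons)}\t{','.join(trace.flags)}\n"
                    )

    counts = pd.DataFrame(
        {
            "sample": list(result.snv_counts),
            "group": [
                result.pedigree.group.get(s, ".") for s in result.snv_counts
            ],
            "denovo_snvs": list(result.snv_counts.values()),
            "denovo_indels": [result.indel_counts[s] for s in result.snv_counts],
        }
    )
    counts.to_csv(out / "counts.tsv", sep="\t", index=False)

    subs = {
        s: [(v.ref, v.alt) for v in cs.snvs]
        for s, cs in result.callsets.items()
    }
    spectrum_table(subs, collapse=False).to_csv(out / "spectrum.tsv", sep="\t")
    spectrum_table(subs, collapse=True).to_csv(
        out / "spectrum_collapsed.tsv", sep="\t"
    )

    report = {
        "funnel": result.funnel,
        "snv_stats": _stats_dict(result.snv_stats),
        "indel_stats": _stats_dict(result.indel_stats),
        "coincidence": {
            "overall": _coincidence_dict(result.coincidence_overall),
            "by_group": {
                g: _coincidence_dict(r)
                for g, r in result.coincidence_by_group.items()
            },
        },
    }
    with open(out / "stats.json", "w") as fh:
        json.dump(report, fh, indent=2)

    with open(out / "summary.txt", "w") as fh:
        fh.write(render_summary(result))


def render_summary(result: PipelineResult) -> str:
    """Human-readable run summary."""
    lines = ["de novo mutation analysis summary", "=" * 34, ""]
    if result.snv_stats:
        lines.append("de novo SNVs per mouse (mean +/- SD [min, max]):")
        for name, s in result.snv_stats.groups.items():
            lines.append(
                f"  {name:8s} n={s.n:2d}  {s.mean:7.1f} +/- {s.sd:6.1f}"
                f"  [{s.min:.0f}, {s.max:.0f}]"
            )
        if result.snv_stats.kruskal:
            h, p = result.snv_stats.kruskal
            lines.append(f"  Kruskal-Wallis: H = {h:.3f}, p = {p:.3g}")
        for (a, b), (u, p) in result.snv_stats.pairwise.items():
            lines.append(f"  {a} vs {b}: U = {u:.1f}, p = {p:.3g}")
        lines.append("")
    if result.indel_stats:
        lines.append("de novo indels per mouse (simple + complex):")
        for name, s in result.indel_stats.groups.items():
            lines.append(
                f"  {name:8s} n={s.n:2d}  {s.mean:7.1f} +/- {s.sd:6.1f}"
                f"  [{s.min:.0f}, {s.max:.0f}]"
            )
        lines.append("")
    res = result.coincidence_overall
    if res is not None:
        frac = "NA" if res.fraction is None else f"{100 * res.fraction:.2f}%"
        lines.append(
            f"off-target coincidence: {res.n_coincident}/{res.n_denovo} "
            f"de novo SNVs inside predicted sites ({frac})"
        )
        lines.append("")
    return "\n".join(lines) + "\n"
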