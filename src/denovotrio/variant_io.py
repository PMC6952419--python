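"""Readers and writers for the standard formats the pipeline touches.

Small variants come from a joint-genotyped multi-sample VCF (v4.x) with
``GT:AD:DP`` per-sample fields and the usual site annotations (QD, FS, MQ,
MQRankSum, ReadPosRankSum, SOR).  Complex indels come from an SV-caller VCF
dialect carrying ``SVTYPE``/``END``/``SU``.  Masks are BED3.  Pedigree and
off-target site tables are plain TSV.

Multi-allelic rows are split into bi-allelic records on read, with the AD
column re-sliced per ALT allele; chromosome names are normalised to the
UCSC ``chr`` prefix.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .model import (
    ANNOTATION_KEYS,
    GT_HET,
    GT_HOMALT,
    GT_HOMREF,
    GT_MISSING,
    ComplexIndelRecord,
    GenomeMask,
    GenotypeCall,
    PedigreeCohort,
    ROLE_OFFSPRING,
    ROLE_PARENT,
    VariantRecord,
)


class VcfParseError(ValueError):
    """A VCF could not be parsed into the internal model."""


class BedParseError(ValueError):
    """A BED interval file is malformed."""


def normalize_chrom(chrom: str) -> str:
    """Canonicalise chromosome names to the UCSC 'chr' prefix."""
    return chrom if chrom.startswith("chr") else f"chr{chrom}"


def _gt_string(gt_tuple, alt_index: int) -> str:
    """Project a (possibly multi-allelic) GT tuple onto one ALT allele.

    Alleles other than the focal ALT are treated as reference in the
    bi-allelic view; any missing allele makes the whole call missing.
    """
    if gt_tuple is None or any(a is None for a in gt_tuple) or len(gt_tuple) == 0:
        return GT_MISSING
    n_alt = sum(1 for a in gt_tuple if a == alt_index)
    return (GT_HOMREF, GT_HET, GT_HOMALT)[min(n_alt, 2)]


def _int_or_none(value) -> int | None:
    if value is None:
        return None
    try:
        return int(value)
    except (TypeError, ValueError):
        return None


def read_multisample_vcf(path: str | os.PathLike) -> tuple[list[VariantRecord], list[str]]:
    """Read a multi-sample small-variant VCF.

    Returns ``(records, samples)``: one :class:`VariantRecord` per ALT
    allele of every data line (multi-allelic rows are split), with calls
    ordered like ``samples``.  Missing annotations stay absent — they are
    never coerced to zero.
    """
    try:
        vf = pysam.VariantFile(os.fspath(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot parse VCF header of {path}: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        records: list[VariantRecord] = []
        for line_no, rec in enumerate(vf, start=1):
            try:
                records.extend(_split_record(rec, samples))
            except (ValueError, KeyError) as exc:
                raise VcfParseError(
                    f"{path}: bad record #{line_no} at "
                    f"{rec.chrom}:{rec.pos}: {exc}"
                ) from exc
    return records, samples


def _split_record(rec: pysam.VariantRecord, samples: Sequence[str]) -> list[VariantRecord]:
    alts = rec.alts or ()
    annotations: dict[str, float] = {}
    for key in ANNOTATION_KEYS:
        if key in rec.info:
            value = rec.info[key]
            if isinstance(value, tuple):
                value = value[0]
            if value is not None:
                annotations[key] = float(value)
    out = []
    for i, alt in enumerate(alts):
        if alt is None or alt in (".", "*", "<NON_REF>"):
            continue
        alt_index = i + 1
        calls = []
        for s in samples:
            sample = rec.samples[s]
            ad = sample.get("AD")
            ad_ref = ad_alt = None
            if ad is not None and not all(a is None for a in ad):
                ad_ref = _int_or_none(ad[0])
                ad_alt = _int_or_none(ad[alt_index]) if alt_index < len(ad) else None
            calls.append(
                GenotypeCall(
                    gt=_gt_string(sample.get("GT"), alt_index),
                    ad_ref=ad_ref,
                    ad_alt=ad_alt,
                    dp=_int_or_none(sample.get("DP")),
                )
            )
        out.append(
            VariantRecord(
                chrom=normalize_chrom(rec.chrom),
                pos=rec.pos,
                ref=rec.ref,
                alt=alt,
                annotations=dict(annotations),
                calls=tuple(calls),
            )
        )
    return out


_VCF_HEADER_LINES = [
    '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
    '##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias (Phred)">',
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
    '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank-sum">',
    '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank-sum">',
    '##INFO=<ID=SOR,Number=1,Type=Float,Description="Symmetric odds ratio">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
]


def _format_info(annotations: dict[str, float]) -> str:
    if not annotations:
        return "."
    parts = [f"{k}={annotations[k]:g}" for k in ANNOTATION_KEYS if k in annotations]
    return ";".join(parts)


def _format_call(call: GenotypeCall) -> str:
    ad = (
        f"{call.ad_ref},{call.ad_alt}"
        if call.ad_ref is not None and call.ad_alt is not None
        else "."
    )
    dp = str(call.dp) if call.dp is not None else "."
    return f"{call.gt}:{ad}:{dp}"


def write_vcf(
    records: Iterable[VariantRecord],
    samples: Sequence[str],
    path: str | os.PathLike,
    contigs: Iterable[tuple[str, int]] | None = None,
) -> None:
    """Write bi-allelic records as an uncompressed VCF v4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=denovotrio\n")
        if contigs is not None:
            for name, length in contigs:
                fh.write(f"##contig=<ID={name},length={length}>\n")
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + list(samples)) + "\n")
        for rec in records:
            if len(rec.calls) != len(samples):
                raise ValueError(
                    f"record {rec.key} has {len(rec.calls)} calls for "
                    f"{len(samples)} samples"
                )
            row = [
                rec.chrom,
                str(rec.pos),
                ".",
                rec.ref,
                rec.alt,
                ".",
                ".",
                _format_info(rec.annotations),
                "GT:AD:DP",
            ] + [_format_call(c) for c in rec.calls]
            fh.write("\t".join(row) + "\n")


def read_sv_vcf(path: str | os.PathLike) -> tuple[list[ComplexIndelRecord], list[str]]:
    """Read an SV-caller VCF (SVTYPE/END/SU) into complex-indel records."""
    try:
        vf = pysam.VariantFile(os.fspath(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot parse SV VCF header of {path}: {exc}") from exc
    records: list[ComplexIndelRecord] = []
    with vf:
        samples = list(vf.header.samples)
        for rec in vf:
            svtype = rec.info.get("SVTYPE", "other")
            if isinstance(svtype, tuple):
                svtype = svtype[0]
            su = rec.info.get("SU", 0)
            if isinstance(su, tuple):
                su = su[0]
            gts = []
            dps = []
            for s in samples:
                sample = rec.samples[s]
                gts.append(_gt_string(sample.get("GT"), 1))
                dps.append(_int_or_none(sample.get("DP")))
            records.append(
                ComplexIndelRecord(
                    chrom=normalize_chrom(rec.chrom),
                    start=rec.start,  # pysam: 0-based inclusive
                    end=rec.stop,  # 0-based exclusive (from END)
                    svtype=str(svtype),
                    qual=float(rec.qual) if rec.qual is not None else 0.0,
                    su=int(su),
                    gts=tuple(gts),
                    dps=tuple(dps),
                )
            )
    return records, samples


def write_sv_vcf(
    records: Iterable[ComplexIndelRecord],
    samples: Sequence[str],
    path: str | os.PathLike,
    contigs: Iterable[tuple[str, int]] | None = None,
) -> None:
    """Write complex-indel records in the SVTYPE/END/SU VCF dialect."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=denovotrio\n")
        if contigs is not None:
            for name, length in contigs:
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n')
        fh.write(
            '##INFO=<ID=SU,Number=1,Type=Integer,'
            'Description="Pieces of evidence across all samples">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + list(samples)) + "\n")
        for i, rec in enumerate(records):
            info = f"SVTYPE={rec.svtype};END={rec.end};SU={rec.su}"
            row = [
                rec.chrom,
                str(rec.start + 1),
                f"sv{i + 1}",
                "N",
                f"<{rec.svtype}>",
                f"{rec.qual:g}",
                ".",
                info,
                "GT:DP",
            ]
            for gt, dp in zip(rec.gts, rec.dps):
                row.append(f"{gt}:{dp if dp is not None else '.'}")
            fh.write("\t".join(row) + "\n")


def read_intervals_bed(paths: Sequence[str | os.PathLike] | str | os.PathLike) -> GenomeMask:
    """Read one or more BED3+ files into a merged :class:`GenomeMask`."""
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    intervals: list[tuple[str, int, int]] = []
    for path in paths:
        with open(path) as fh:
            for line_no, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise BedParseError(f"{path}:{line_no}: fewer than 3 columns")
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise BedParseError(
                        f"{path}:{line_no}: non-integer coordinates"
                    ) from exc
                if start >= end:
                    raise BedParseError(
                        f"{path}:{line_no}: start {start} >= end {end}"
                    )
                intervals.append((normalize_chrom(fields[0]), start, end))
    return GenomeMask(intervals)


def write_intervals_bed(mask: GenomeMask, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in mask.intervals():
            fh.write(f"{chrom}\t{start}\t{end}\n")


def overlaps_mask(v: VariantRecord, mask: GenomeMask) -> bool:
    """True iff any REF base spanned by ``v`` intersects the mask."""
    start, end = v.span0
    return mask.overlaps(v.chrom, start, end)


PEDIGREE_COLUMNS = ["sample_id", "role", "group", "sire_id", "dam_id"]


def read_pedigree(path: str | os.PathLike) -> PedigreeCohort:
    """Read the tab-separated pedigree/group table."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(".")
    missing = set(PEDIGREE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pedigree table missing columns: {sorted(missing)}")
    samples = tuple(df["sample_id"])
    role: dict[str, str] = {}
    group: dict[str, str] = {}
    sire: dict[str, str] = {}
    dam: dict[str, str] = {}
    for row in df.itertuples(index=False):
        role[row.sample_id] = row.role
        if row.role == ROLE_OFFSPRING:
            group[row.sample_id] = row.group
            if row.sire_id != ".":
                sire[row.sample_id] = row.sire_id
            if row.dam_id != ".":
                dam[row.sample_id] = row.dam_id
    return PedigreeCohort(samples=samples, role=role, group=group, sire=sire, dam=dam)


def write_pedigree(cohort: PedigreeCohort, path: str | os.PathLike) -> None:
    rows = []
    for s in cohort.samples:
        rows.append(
            {
                "sample_id": s,
                "role": cohort.role[s],
                "group": cohort.group.get(s, "."),
                "sire_id": cohort.sire.get(s, "."),
                "dam_id": cohort.dam.get(s, "."),
            }
        )
    pd.DataFrame(rows, columns=PEDIGREE_COLUMNS).to_csv(path, sep="\t", index=False)
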