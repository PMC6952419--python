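"""Independent brute-force oracles used only by the test suite.

Each function re-derives a pipeline result by the most literal method
available (per-base loops, joint predicate evaluation, exhaustive
enumeration) and shares no code with the implementation it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

from denovotrio import FilterConfig, PedigreeCohort
from denovotrio.model import ComplexIndelRecord, GenotypeCall, VariantRecord

INF = math.inf


def bf_mask_overlap(chrom, start, end, intervals) -> bool:
    """Per-base membership check of [start, end) against raw intervals."""
    for c, s, e in intervals:
        if c != chrom:
            continue
        for b in range(start, end):
            if s <= b < e:
                return True
    return False


def _is_snv(r: VariantRecord) -> bool:
    return len(r.ref) == 1 and len(r.alt) == 1


def bf_denovo(records, samples, sv_records, sv_samples, mask_intervals, pedigree, cfg: FilterConfig):
    """Joint single-pass evaluation of every cascade predicate.

    Returns {offspring: (snv_keys, indel_keys, complex_keys)}.
    """
    cutoff = cfg.d + 3 * math.sqrt(cfg.d)
    idx = {s: i for i, s in enumerate(samples)}
    svx = {s: i for i, s in enumerate(sv_samples)}
    out = {}
    for child in pedigree.offspring:
        ci = idx[child]
        surv = []
        for r in records:
            ann = r.annotations
            if _is_snv(r):
                bad = (
                    ann.get("QD", INF) < cfg.snv_qd_min
                    or ann.get("FS", -INF) > cfg.snv_fs_max
                    or ann.get("MQ", INF) < cfg.snv_mq_min
                    or ann.get("MQRankSum", INF) < cfg.snv_mqranksum_min
                    or ann.get("ReadPosRankSum", INF) < cfg.snv_readposranksum_min
                    or ann.get("SOR", -INF) > cfg.snv_sor_max
                )
            else:
                bad = (
                    ann.get("QD", INF) < cfg.indel_qd_min
                    or ann.get("FS", -INF) > cfg.indel_fs_max
                    or ann.get("ReadPosRankSum", INF) < cfg.indel_readposranksum_min
                    or ann.get("SOR", -INF) > cfg.indel_sor_max
                )
            if bad:
                continue
            if bf_mask_overlap(r.chrom, r.pos - 1, r.pos - 1 + len(r.ref), mask_intervals):
                continue
            call = r.calls[ci]
            if call.gt not in ("0/1", "1/1"):
                continue
            dp = call.dp
            if dp is None and call.ad_ref is not None and call.ad_alt is not None:
                dp = call.ad_ref + call.ad_alt
            if dp is None or dp < cfg.dp_min or dp > cutoff:
                continue
            if call.ad_ref is None or call.ad_alt is None:
                continue
            tot = call.ad_ref + call.ad_alt
            if tot == 0 or call.ad_alt / tot < cfg.af_min:
                continue
            surv.append(r)
        snvs = [r for r in surv if _is_snv(r)]
        indels = [r for r in surv if not _is_snv(r)]

        kept_snvs = []
        for s in snvs:
            near = False
            for ind in indels:
                if ind.chrom != s.chrom:
                    continue
                if len(ind.ref) > len(ind.alt):
                    borders = (ind.pos, ind.pos + len(ind.ref) - 1)
                else:
                    borders = (ind.pos, ind.pos + 1)
                if min(abs(s.pos - b) for b in borders) <= cfg.indel_window:
                    near = True
                    break
            if not near:
                kept_snvs.append(s)

        child_sv = svx.get(child)
        carrier = [
            sv
            for sv in sv_records
            if child_sv is not None and sv.gts[child_sv] in ("0/1", "1/1")
        ]
        kept_indels = []
        for ind in indels:
            s0, e0 = ind.pos - 1, ind.pos - 1 + len(ind.ref)
            hit = any(
                sv.chrom == ind.chrom and not (e0 <= sv.start or sv.end <= s0)
                for sv in carrier
            )
            if not hit:
                kept_indels.append(ind)

        passing_cx = []
        for sv in carrier:
            dp = sv.dps[child_sv] if sv.dps else None
            if sv.qual < cfg.sv_qual_min:
                continue
            if dp is not None and dp > cutoff:
                continue
            if sv.su < cfg.sv_su_min:
                continue
            if bf_mask_overlap(sv.chrom, sv.start, sv.end, mask_intervals):
                continue
            passing_cx.append(sv)

        par_keys = set()
        sv_par = set()
        for p in (pedigree.sire[child], pedigree.dam[child]):
            pi = idx[p]
            for r in records:
                if r.calls[pi].gt in ("0/1", "1/1"):
                    par_keys.add(r.key)
            psv = svx.get(p)
            if psv is not None:
                for sv in sv_records:
                    if sv.gts[psv] in ("0/1", "1/1"):
                        sv_par.add(sv.key)

        out[child] = (
            {r.key for r in kept_snvs if r.key not in par_keys},
            {r.key for r in kept_indels if r.key not in par_keys},
            {sv.key for sv in passing_cx if sv.key not in sv_par},
        )
    return out


def mwu_exact_enum(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration of rank subsets.

    Tie-free inputs only.  Returns (U_of_x, p).
    """
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "enumeration oracle needs tie-free data"
    n1, n = len(x), len(pooled)

    def u_of(xs, ys):
        return sum(1 for xi in xs for yj in ys if xi > yj)

    u_obs = u_of(x, y)
    us = []
    for positions in combinations(range(n), n1):
        chosen = set(positions)
        xs = [pooled[i] for i in positions]
        ys = [pooled[i] for i in range(n) if i not in chosen]
        us.append(u_of(xs, ys))
    m = len(us)
    lo = sum(u <= u_obs for u in us) / m
    hi = sum(u >= u_obs for u in us) / m
    return u_obs, min(1.0, 2 * min(lo, hi))


def random_mini_cohort(rng: np.random.Generator):
    """A random 2-parent, 2-offspring cohort probing every filter boundary."""
    samples = ["p1", "p2", "c1", "c2"]
    pedigree = PedigreeCohort(
        samples=tuple(samples),
        role={"p1": "parent", "p2": "parent", "c1": "offspring", "c2": "offspring"},
        group={"c1": "BE4", "c2": "control"},
        sire={"c1": "p1", "c2": "p1"},
        dam={"c1": "p2", "c2": "p2"},
    )
    mask_intervals = []
    for _ in range(int(rng.integers(0, 4))):
        s = int(rng.integers(0, 4800))
        mask_intervals.append(("chr1", s, s + int(rng.integers(1, 120))))

    n = int(rng.integers(10, 26))
    positions = rng.choice(np.arange(1, 4900), size=n, replace=False)
    bases = "ACGT"
    records = []
    for pos in sorted(int(p) for p in positions):
        if rng.random() < 0.6:
            ref = bases[int(rng.integers(4))]
            alt = bases[int(rng.integers(4))]
            while alt == ref:
                alt = bases[int(rng.integers(4))]
        else:
            anchor = bases[int(rng.integers(4))]
            extra = "".join(bases[int(b)] for b in rng.integers(0, 4, size=int(rng.integers(1, 5))))
            ref, alt = (anchor + extra, anchor) if rng.random() < 0.5 else (anchor, anchor + extra)
        ann = {}
        spans = {
            "QD": (0.0, 10.0),
            "FS": (0.0, 250.0),
            "MQ": (30.0, 60.0),
            "MQRankSum": (-20.0, 5.0),
            "ReadPosRankSum": (-25.0, 5.0),
            "SOR": (0.0, 12.0),
        }
        for key, (lo, hi) in spans.items():
            if rng.random() < 0.7:
                ann[key] = float(np.round(rng.uniform(lo, hi), 3))
        calls = []
        for _ in samples:
            gt = str(rng.choice(["0/0", "0/1", "1/1", "./."], p=[0.25, 0.4, 0.25, 0.1]))
            dp = None if rng.random() < 0.1 else int(rng.integers(0, 140))
            if rng.random() < 0.1:
                ad_ref = ad_alt = None
            else:
                cap = dp if dp is not None else int(rng.integers(0, 140))
                tot = int(rng.integers(0, cap + 1))
                ad_alt = int(rng.integers(0, tot + 1))
                ad_ref = tot - ad_alt
            calls.append(GenotypeCall(gt=gt, ad_ref=ad_ref, ad_alt=ad_alt, dp=dp))
        records.append(
            VariantRecord(
                chrom="chr1", pos=pos, ref=ref, alt=alt,
                annotations=ann, calls=tuple(calls),
            )
        )

    sv_records = []
    for _ in range(int(rng.integers(0, 4))):
        start = int(rng.integers(0, 4500))
        end = start + int(rng.integers(40, 400))
        gts = tuple(
            str(rng.choice(["0/0", "0/1", "1/1", "./."], p=[0.3, 0.4, 0.2, 0.1]))
            for _ in samples
        )
        dps = tuple(
            None if rng.random() < 0.2 else int(rng.integers(0, 140)) for _ in samples
        )
        sv_records.append(
            ComplexIndelRecord(
                chrom="chr1", start=start, end=end, svtype="DEL",
                qual=float(np.round(rng.uniform(0, 400), 1)),
                su=int(rng.integers(0, 12)), gts=gts, dps=dps,
            )
        )
    return records, samples, sv_records, samples, mask_intervals, pedigree
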