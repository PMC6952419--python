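# Methods

## Problem and model

A trio design isolates mutations that arose in (or were introduced into)
an offspring's genome: sequence parents and offspring at matched coverage,
joint-genotype all samples, and call *de novo* any offspring variant whose
alt allele no parent carries. In a base-editor experiment the offspring
fall into three groups — unedited controls, adenine-base-editor (ABE)
founders and cytosine-base-editor (BE4) founders — and the per-mouse de
novo SNV count is the burden statistic. A genome-wide-active cytosine
deaminase shows up as (i) an elevated de novo SNV count in the edited
group, (ii) an excess of C>T (equivalently G>A) substitutions, and
(iii) little or no enrichment of those SNVs at sgRNA-predicted off-target
sites, since the activity is sgRNA-independent.

## Filter cascade

Candidates pass through fixed stages, in order; the first failing stage is
recorded per (variant, sample) in a trace, so the filtering funnel can be
reconstructed exactly from any run.

1. **Site hard filters** (fixed-threshold annotation cuts in lieu of
   statistical recalibration). SNVs fail on `QD < 2.0`, `FS > 60.0`,
   `MQ < 40.0`, `MQRankSum < -12.5`, `ReadPosRankSum < -8.0` or `SOR > 3`;
   indels on `QD < 2.0`, `FS > 200.0`, `ReadPosRankSum < -20.0` or
   `SOR > 10.0`. All inequalities are strict; a missing annotation never
   fails (callers omit rank-sum annotations at homozygous sites, and
   failing absent values would discard most 1/1 calls).
2. **Mask exclusion.** Any overlap of the REF span with the union of
   repeat masks and blacklist regions removes the variant. Variants use
   1-based VCF coordinates, intervals BED 0-based half-open; conversions
   live in `variant_io` only.
3. **Per-sample filters.** Genotype ∈ {0/1, 1/1}; DP ≥ 10 (AD sum is used
   if DP is absent); DP ≤ d + 3√d where `d` is the average per-sample
   sequencing depth (default 60, supplied in config — a VCF-derived mean
   would be biased toward called sites); allele fraction
   AF = AD_alt/(AD_ref+AD_alt) ≥ 0.10. An undefined AF fails: the cascade
   removes sub-10% calls, and an unevaluable fraction cannot be shown to
   pass. AD-based AF is preferred over AD_alt/DP because DP counts reads
   uninformative for either allele.
4. **SNV-near-indel removal.** An SNV within 5 bp (inclusive) of an indel
   border is discarded as a likely alignment artefact. Borders: first and
   last REF base for a deletion; the two flanking bases for an insertion.
   The indel set used is the same sample's indels surviving stages 1–3,
   before parental subtraction (an inherited indel still distorts
   alignment around it).
5. **Simple-vs-complex exclusion.** Simple indels whose REF span
   intersects (half-open semantics; abutting ≠ overlap) a complex indel
   carried by the same sample are removed. The comparison set is the
   SV caller's raw carrier records, not the post-filter set: a true event
   that fails, say, the SU cut still explains the conflicting simple call.
6. **Complex-indel filters.** Carrier genotype, QUAL ≥ 100, per-sample
   coverage ≤ d + 3√d (vacuously true when the record has no DP), SU ≥ 5
   (pieces of supporting evidence across samples), and mask exclusion.
7. **Parental subtraction.** Allele-exact: a variant is inherited iff a
   parent carries the identical (chrom, pos, ref, alt); a different alt at
   the same site does not exclude. A missing parental genotype does not
   exclude either — only variants demonstrably present in a parent are
   subtracted — but such calls are flagged `parent_uncalled` in the trace
   for downstream scrutiny.

Multi-allelic records are split into bi-allelic records (AD re-sliced per
allele; alleles other than the focal one count as reference in the
genotype projection) before any filtering, because every threshold is
per-allele. Input is assumed left-normalised by the caller. The cascade is
idempotent and monotone in its thresholds (relaxing any one threshold can
only grow the passing set); both properties are asserted in the tests.

## Group statistics

Per-group summaries are mean ± sample SD (ddof = 1) with min/max; boxplot
tuples deliberately follow the mean-based convention (center = mean, box =
mean ± SD, whiskers = min/max) rather than quartiles. The omnibus test is
Kruskal–Wallis with tie correction and a χ²(k−1) p-value; all-identical
input degenerates to H = 0, p = 1. Pairwise comparisons use the two-sided
Mann–Whitney U test (identically, the Wilcoxon rank-sum test — one
implementation, both names). The p-value is exact — twice the smaller tail
of the permutation distribution, capped at 1 — whenever the pooled sample
is tie-free and n₁+n₂ ≤ 50, matching R's `wilcox.test` default; otherwise
the normal approximation with tie correction and continuity correction is
used. Both regimes are served by `scipy.stats`; the test suite checks the
exact branch against full enumeration of all rank arrangements up to
n₁+n₂ = 12 and the identities p = 1 for identical samples and
p = 2/C(n₁+n₂, n₁) under complete separation. Pairwise p-values are
reported raw (no multiplicity correction), with an optional Bonferroni
flag for reuse.

Spectra are tabulated over the 12 directional substitution classes or,
collapsed, the 6 pyrimidine-reference classes (purine-reference changes
mapped through reverse complement); collapsed spectra are invariant under
reverse-complementing every input, and row sums equal per-sample SNV
counts.

## Off-target coincidence

Predicted off-target intervals (protospacer + PAM, 20–30 bp) are filtered
with the same genome mask as variants. A candidate de novo SNV present in
any non-edited animal (control offspring or parent) other than the sample
itself is population-recurrent and excluded before accounting — such a
variant cannot be attributed to base editing; recurrence confined to
edited animals does not exclude. Coincidence is positional (the SNV base
inside a site interval, half-open), not allele-aware. The fraction is
reported with explicit numerator and denominator; an empty denominator is
reported as not-available rather than zero.

## Synthetic cohorts

The generator emulates the study conditions: a toy genome (3 × 10 Mb —
all logic is coordinate-generic, and this keeps a full cohort under ten
seconds), 45% of it masked in 10 kb tiles to mimic mouse repeat density;
one sire and eight dams each carrying 200 germline het variants
transmitted to each child with probability ½; per-mouse de novo counts
Poisson around group means 132 / 119 / 221 (the minimal dispersion model
given that only means and between-mouse variation are reported; a
negative-binomial option is exposed); a BE4 spectrum with 64% C>T/G>A
weight plus minor C>A/C>G, uniform elsewhere; depths Poisson(60) and
heterozygous allele fractions Beta(50, 50), resampled into the passing
region for variants that must pass; a 10% BE4 mosaic component at AF 0.25
(post-zygotic editing) to exercise the AF boundary; complex deletions in
4 of 9 BE4 founders; and 2% of each mouse's de novo SNVs placed inside
predicted off-target sites (300 sites of 23 bp). Indel rates default to 20
per mouse, equal across groups, since no group difference is modelled.

Each offspring also receives one distractor per filter category — a
variant constructed to violate exactly that filter (e.g. QD = 1.0 for the
SNV hard filter, AF ≈ 0.06 for the allele-fraction filter, a simple indel
inside a carried complex deletion for the SV-overlap filter, a variant
shared with the dam for parental subtraction). A 20 bp spacing constraint
keeps planted variants from interacting except where a distractor demands
it. The truth table records every planted (sample, variant) with its
category and intended outcome, so truth recovery — zero false positives,
zero false negatives, every distractor failing its named filter — is
checkable without trusting the pipeline, and is asserted both on a small
cohort and on the full default design.

Generation is deterministic: one seeded generator, fixed draw order, fixed
file formatting — identical spec + seed gives a byte-identical bundle.

**What passing does and does not show.** The generator plants variants
whose annotations are drawn inside or outside the acceptance region by
construction; real callers produce correlated, boundary-hugging
annotations, mapping artefacts, multi-allelic complexity beyond simple
splitting, and reference errors that no synthetic bundle reproduces.
Passing tests demonstrate that the decision logic is implemented exactly
as specified and recovers planted structure at realistic scale — not that
the thresholds themselves are optimal for any particular dataset.

## Numerical and design choices

- Excess-depth comparison is strict (`DP > d + 3√d` fails), symmetric with
  the other strict inequalities.
- `d` defaults to per-sample average depth; whether a cohort-wide value is
  used instead is a config choice.
- Exact-test size limit defaults to 50 (R convention) and is configurable;
  the all-ties degenerate case returns U = n₁n₂/2, p = 1 rather than a
  division-by-zero in the variance.
- Ties in the coincidence site lookup (an SNV inside two overlapping
  sites) attribute the hit to the left-most site; the count is per SNV, so
  the fraction is unaffected.
- Chromosome names are normalised to the UCSC `chr` prefix on read.

## Known limitations

- No gVCF or BAM/CRAM handling; the pipeline starts at joint-genotyped
  VCFs and consumes the SV caller's output as given.
- No phasing, mosaicism deconvolution, or trinucleotide-context (96-class)
  signature analysis.
- Parental subtraction is exact-allele; a parent mosaic below calling
  sensitivity will leak an inherited variant into the de novo set (the
  `parent_uncalled` flag covers only missing genotypes).
- The synthetic genome has no sequence context, so REF/ALT strings are
  arbitrary labels; spectrum tests rely on planted class weights, not on
  sequence realism.
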