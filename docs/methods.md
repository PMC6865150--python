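# Methods

## The two-stage procedure

`medipdmr` implements a discovery/confirmation design for finding genomic
regions whose methylation distinguishes fetal tissue (chorionic villus
samples, CVS) from the maternal background circulating in plasma (whole
blood from non-pregnant females, WBF, and non-pregnant plasma, PL). MeDIP
enrichment sequencing converts methylation into read depth: a region's
depth grows with its methylated CpG content, so depth differences between
sample groups stand in for methylation differences.

**Discovery.** The genome (autosomes only) is tiled into fixed 100-bp
windows. For each window and each of the two pairwise comparisons
(CVS vs WBF, CVS vs PL), reads-per-million-normalized depths are compared
with Welch's unequal-variance t-test,

t = (x̄_a − x̄_b) / √(s²_a/n_a + s²_b/n_b),

with Welch–Satterthwaite degrees of freedom and per-group variances floored
at ε_v = 1e-8 rpm² so all-equal groups stay finite. Two-sided p-values are
Bonferroni-adjusted over the tested windows (windows whose summed raw count
is below `min_total = 10` contribute no hypothesis and carry p = 1), and
windows with adjusted p < 0.10 (strict) are kept. Significant windows are
merged into maximal same-direction runs of adjacent bins (`max_gap = 0` by
default; configurable because the merging gap tolerance is a genuinely open
choice). A merged candidate survives selection only if it

1. contains ≥ 3 CpG dinucleotides,
2. overlaps no copy-number-variable region,
3. lies ≥ 200 bp from the nearest repetitive element (edge-to-edge;
   overlap counts as distance 0; exactly 200 bp passes), and
4. retains Bonferroni significance (minimum member p_adj < 0.10).

Candidates from the two comparisons are intersected: one common DMR per
same-direction pair overlapping by ≥ 1 bp, reported as the interval
intersection (union available). Common DMRs are annotated against gene
body / exon / promoter / CpG-island tracks, multi-label (a DMR inside an
exon inside a gene carries both labels), and summarized (length median and
IQR under the linear-interpolation quantile convention, counts per
direction, label and provenance). An optional final narrowing keeps DMRs
with at least one regulatory label, ranks them by minimum adjusted p, and
takes the top K; this rank-and-take is a deterministic stand-in for a
curation step that has no fully specified operational rule, and reports
flag it as such.

**Confirmation.** Targeted-panel read depths for the selected DMRs in an
independent cohort (8 CVS / 8 WBF / 8 PL) are first *vertically
normalized*: each sample column is scaled by f_s = T̄/T_s, where T_s is the
sample's cumulative panel depth and T̄ the mean of the totals. This makes
all column totals equal while conserving the grand total, and reapplying it
is the identity. The normalized depths y_{d,s} then enter a mixed-effects
analysis of variance,

y_{d,s} = μ + τ_tissue(s) + b_d + ε_{d,s},  b_d ~ N(0, σ_b²),  ε ~ N(0, σ²),

with a random DMR intercept absorbing region-to-region differences in
capture efficiency and methylation variability. The model is fitted by
REML (statsmodels `MixedLM`); the tissue effect is tested with a
likelihood-ratio test of the ML fits with and without τ against chi-square
with (#tissues − 1) df — the standard caveat that LRTs compare ML, not
REML, likelihoods is observed. Post-hoc, the three tissue pairs are
compared with Welch t-tests on the pooled per-DMR-per-sample normalized
depths (observation unit: one DMR in one sample; a per-sample-mean mode is
available behind a flag) and corrected with the Holm–Bonferroni step-down
rule adj_(i) = max_{j≤i} min(1, (m−j+1) p_(j)).

### Normalization and panel composition

Equalizing panel totals has a consequence worth stating plainly: if every
panel region were hypermethylated in CVS, the normalization would force
every sample's mean panel depth to the same value and no tissue contrast
could survive it. A capture panel therefore needs non-differential anchor
regions, and the simulated panel includes background *control regions*
(default 200) that take part in normalization but are excluded from the
tissue statistics. With controls present, equal totals no longer imply
equal DMR-row means, and the planted contrast passes through attenuated
but intact.

### Open choices resolved here

- The original window-level test is described only as a package's
  methylation-difference test; the variant is unrecoverable. Welch's t on
  rpm values was adopted as the closest simple two-group test for the tiny
  group sizes (3 vs 3, 3 vs 2), and the comparison against a reference
  implementation is part of the test suite.
- Bonferroni's m is the number of *tested* windows: untested windows
  contribute no hypothesis.
- "More than two CpGs" is enforced as a hard n_cpg ≥ 3 filter
  (configurable, since the source phrasing is preferential).
- Whether group-mean direction suffices for "consistent" hypermethylation
  or every fetal sample must exceed every maternal sample is ambiguous; the
  default uses group-mean direction, and a per-sample sign-consistency mode
  exists behind a flag.
- Depths are analyzed on the raw scale by default (depth is the
  methylation proxy); a log1p mode is available for variance stabilization.
  Neither is asserted to be the original analysis.

## The synthetic study

The generator plants ground truth so every stage is testable end to end.
One global seed drives independent named substreams (annotation, truth,
counts, panel), so any stage can be regenerated in isolation and all
outputs are byte-identical for a fixed configuration.

**Genome and annotation.** Two 2.5-Mb chromosomes (≈50,000 windows) carry
300 CpG islands (0.08 CpG/bp inside, 0.01/bp outside; sites drawn by
per-bp Bernoulli at the local rate), 300 repeats (200–1500 bp), 8 CNVs
(3–8 kb), and 120 genes with promoters (1 kb upstream) and exons. A few
repeats are deliberately placed 20–60 bp from CpG islands and a few CNVs
anchored over islands so that hosts for every decoy class exist for every
seed; the remaining features are placed uniformly.

**Planted truth.** 40 compliant fetal DMRs (lengths drawn uniform on
100–2300 bp, clipped to the host island) live inside CpG islands ≥ 300 bp
from repeats and clear of CNVs, with planted methylation CVS 0.85,
WBF 0.05, PL 0.10 against a common background of 0.05. Each decoy class
violates exactly one criterion: *in_cnv* (island fully inside a CNV),
*near_repeat* (short, ≤ 120 bp, anchored at the repeat-proximal island
edge so any bin-snapped fragment stays < 200 bp from the repeat),
*low_cpg* (a single background window holding ≤ 2 CpGs), and
*single_comparison* (PL methylation equal to CVS, so the region is
differential against WBF only and must fall at the intersection step).

**Count model.** Window counts are negative binomial with mean
proportional to L_s · b · (1 + α · m · c(w)), where L_s is the sample's
library-size factor, b the baseline window depth, α the enrichment effect
scale, m the tissue methylation and c(w) the window CpG count; windows in
a CNV are additionally multiplied by the sample's copy ratio. Because a
sequencer yields the library's read total regardless of genome
composition, each sample's intensity vector is rescaled to a common
reference sum — enrichment and copy-number changes redistribute reads
rather than create them. With α = 0 and no CNVs the rescaling factor is
exactly 1, so the generator embeds the no-signal null exactly (equal
expectations in all tissues), which the family-wise-error calibration
relies on.

**Panel model.** Each panel region receives a capture efficiency
g_d ~ LogNormal(0, σ_d) shared across samples (the physical motivation for
the random DMR effect), and depths are negative binomial with mean
L_s · b_panel · g_d · (1 + α · m · c(d)).

### What the defaults do and do not represent

The defaults (α = 0.6, giving a per-window CVS/WBF mean ratio ≈ 4 at the
mean island CpG count; baseline depth 25,000 reads/window; NB size 1e6,
i.e. counts 5–30 % above Poisson variance at these depths; library sizes
1.0–1.5 × 10⁹) put the study in a deep-coverage, technical-noise-dominated
regime. That choice is forced by arithmetic, not biology: with three
samples per group and an n = 2 plasma group, the Welch degrees of freedom
sit near 2–3, so Bonferroni significance over 50,000 windows needs
t ≳ 110–220, which only near-Poisson counts at high depth can reach.
Real MeDIP cohorts have substantial biological replicate variability
(dispersion orders of magnitude larger), and nothing here should be read
as an estimate of the original study's data; passing the synthetic
recovery tests demonstrates the correctness of the pipeline's logic, not
window-level power on real cohorts. The CNV defaults (kb-scale, 20 %
carrier probability) also matter: because rpm is purely relative, large
CNVs shift a carrier's genome-wide read composition and put a floor under
the between-sample variance at every window; kb-scale CNVs keep that
composition effect an order of magnitude below counting noise while still
exercising the CNV exclusion filter.

Other things the generator does not emulate: read-level sequence (no
FASTQ/alignment), fragment-length effects, GC bias, CpG-coupling
normalization, batch effects, or fetal fraction in plasma (the plasma
group is non-pregnant by design).

## Numerical choices

- Variance floor ε_v = 1e-8 rpm²; log2 ratios use a 1e-6 rpm offset.
- Quantiles (median, IQR) use numpy's linear-interpolation convention.
- Vertical normalization targets the mean of the totals, conserving the
  grand total; any common target yields the same test statistics.
- The mixed-model fit retries with alternative optimizers and accepts a
  boundary fit when the random-effect variance collapses to zero (reported
  as σ_b = 0 with a boundary flag); genuine non-convergence raises.
- A common DMR's joint adjusted p is the maximum of the two
  per-comparison minima (both comparisons must clear the threshold).
- Merging, intersection and BED output are deterministic: ties break by
  genomic position, and floats serialize with a fixed format, so manifests
  reproduce byte-identically for a fixed seed.

## Problem sizes used by the test suite

The acceptance-style checks run the full synthetic study (50,000 windows,
40 planted DMRs, 12 decoys), 50 null replicates for the family-wise error
calibration, 1000 random cases for each oracle comparison, and 20 recovery
plus 50 null mixed-model fits (300 DMRs × 24 samples each). Unit tests use
a 400–500 kb genome; at that scale the kb-sized CNVs would occupy a
proportionally large genome share, so the small pipeline fixtures omit
them (the composition effect above is why).

## Known limitations

- The window test treats windows independently; no spatial smoothing or
  CpG-coupling correction is applied.
- The 1453→331-style regulatory narrowing is a deterministic
  approximation of an editorial step; its output should not be compared
  region-for-region against any curated list.
- With n = 2 in one group the Welch test's degrees of freedom are
  unstable; on real data a count-model test with information sharing
  across windows would be preferable. The module boundary makes swapping
  the per-window test straightforward.
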