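# Methods

## Scope and data model

The package analyses gene × sample matrices of linear-scale intensities
(gene-level, as produced by oligonucleotide arrays or summarised RNA
quantification).  No normalisation is applied beyond an intensity floor:
non-positive or missing cells are raised to a configurable floor (default
1.0 on the linear scale) so that log2 is always defined.  All logarithms in
the package are base 2.  How a given platform normalises raw intensities
upstream is out of scope; the floor+log2 convention is a documented
stand-in, and results on real platform data depend on that upstream
pipeline.

## Maturity grouping and biometrics

GSI = gonad weight / body weight × 100 (%), CF = W/L³ × 100 (W in g, L in
cm).  Fish partition into immature (GSI < 0.08 %, strict), pubertal
(GSI ≥ 0.23 %, inclusive) and indeterminate (the gap).  Indeterminate fish
are excluded from all two-group statistics but retained in reports: the gap
between thresholds is deliberately left unpopulated rather than forced into
either group, because endocrine state and testis histology can disagree
there (endocrine-primed fish with immature histology are exactly the
interesting intermediate cases, and the candidate screen exists to study
them on hand-picked sample splits).

## Differential specific activity

Effect size: log2-ER = mean(log2 intensities, pubertal) − mean(log2
intensities, immature), i.e. the log2 ratio of geometric means — the
standard effect size for log-scale intensity data.  A linear-means variant
(`log2_ratio_of_linear_means`) exists for sensitivity analysis.

Test: Welch's two-sample t-test on log2 intensities (group sizes are
unbalanced at 14 vs 6; a pooled-variance switch exists).  Zero-variance
degeneracies: two constant, equal groups give p = 1 (no evidence, never
NaN); constant, unequal groups give p = 0.

Classification uses strict inequalities at both cutoffs (log2-ER > 0.8,
p < 0.05).  No multiple-testing correction is applied by default — the
criteria are the study-wide raw thresholds; Benjamini–Hochberg is available
behind `multiple_testing: bh` and is clearly non-default behaviour.

Signed folds for presentation: fold = 2^m for m ≥ 0 and −2^(−m) for m < 0,
so magnitudes are symmetric and sign encodes direction (log2-ER −3.036
prints as −8.2).  The map is antisymmetric away from zero; exactly zero
prints as fold 1.

The candidate screen selects genes whose log2 intensity exceeds the
baseline-group mean by the log2-ER cutoff in *every* include-sample and in
*no* exclude-sample.  The reuse of the study-wide 0.8 cutoff is a choice
(no separate threshold is defined for the screen) and is configurable.

## Gonad-specific genes

Score: max expression over the target tissues (testis and/or ovary)
divided by the arithmetic mean over all tissues, targets included (a config
switch excludes them).  The 8-fold threshold is inclusive (≥ 8).  Note the
score is bounded above by the number of tissues, so a compendium must have
more than `margin × 8` tissues for high-margin genes to exist; the bundled
generator uses 20 named salmon tissues.

"Not expressed in any other tissue" is operationalised as: every non-target
tissue below max(absolute floor 2.0, 0.1 × the gene's maximum gonadal
expression).  A relative rule keeps the criterion robust to platform scale;
anchoring it to the gene's own gonadal level (rather than, say, a
background median across tissues) makes the call *monotone* — raising a
non-target tissue's expression can only push a gene towards "expressed
elsewhere", never rescue a rejected gene — which a per-gene
median-referenced threshold cannot guarantee (raising one tissue can shift
the median, lift the threshold, and flip a different tissue to "absent").
Both constants are configurable.

## Functional-group shifts

Per annotated group with ≥ 10 members present in the data (the smallest
meaningful group size; configurable), the member log2-ERs are tested for a
mean deviating from zero with a one-sample t-test, and summarised by the
signed fold of the mean log2-ER (an option reports the mean of per-gene
signed folds instead, which is systematically larger in magnitude under
dispersion).  Because inter-gene correlation inflates the t-test's type-I
error on real arrays, a seeded gene-label permutation test (default 10 000
permutations) is available behind `set_test: permutation`; on the
independent-gene synthetic data the t-test is calibrated and is the
default.  Groups whose members all share one identical log2-ER have an
undefined (NaN) p.  Ranking within a direction orders by |mean fold|
descending with ties broken alphabetically by group label.

## Hormone statistics

Pearson product–moment correlation per analyte against a per-fish index
(GSI), requiring ≥ 3 pairs; constant analytes are reported as undefined,
not errors.  Group folds are ratios of arithmetic means on the linear
concentration scale (matching how fold increases are conventionally
reported for hormone panels); a geometric-mean option exists.  Group
differences use the same Welch t-test machinery as the expression tests.

## Synthetic-data generator

The generator's defaults *are* the study conditions: 20 fish (14 immature
with GSI uniform on 0.01–0.08 %, 6 pubertal on 0.23–0.60 %), body weight
N(1017, 82²) g, CF N(1.44, 0.08²) with fork length derived, three oocyte
observations planted only among immature fish, and advanced germ-cell
stages (SPC/SPT/SZ) only in pubertal fish.

Testis expression follows the two-compartment mixture
E[I] = π·G·r + (1−π)·S with multiplicative log-normal noise (log2-scale SD
0.25).  Per-fish germinative proportions π are truncated-normal around 0.3
(immature) and 0.8 (pubertal) with SD 0.05 — drawn per fish rather than
deterministic in GSI so composition-confound tests face realistic sampling
variation.  The 0.3/0.8 means are illustrative round values consistent with
"small" vs "large" germinative compartments; ordinal histology grades give
no quantitative proportions, so these are fixed package conventions, not
measured quantities.  Gene categories: 25 % germinative-exclusive (S = 0),
25 % interstitial-exclusive (G = 0), 50 % shared with G = S, so shared
unregulated genes are exactly composition-invariant.  Regulation (default:
5 % of genes at +2.0 log2) multiplies the germinative term of pubertal
samples and is planted only on germinative-expressed genes — transcription
change during puberty is modelled where spermatogenesis happens, and a
multiplier on a G = 0 gene would be unrecoverable by construction.

The tissue compendium plants gonad-specific genes at an exact
gonad-over-average score of margin × 8 (their non-gonad tissues are
noise-free, and the default background level 24 makes the boundary case
margin = 1.0 land exactly on the inclusive threshold in floating point),
alongside ubiquitously-high decoys, gonad-plus-liver decoys, and log-normal
background genes.

Hormones: androgen-like analytes are linear in GSI, anchored so the
pubertal/immature group-mean fold equals the configured value, with
additive Gaussian noise whose SD is proportional to the noise-free level
(constant CV).  The CV is solved from r² = var(signal)/var(total) with
var(noise) = cv²·E[signal²], so the requested population correlation
(default 0.83) holds by construction; GSI mixture moments are computed
analytically from the group ranges.  Two caveats are intrinsic to this
model and documented rather than patched:

- a linear-in-GSI model with nonnegative concentrations bounds the
  attainable group fold by mean(GSI, pubertal)/mean(GSI, immature) ≈ 9.2
  at the default ranges, so the default planted folds span 7.5–9.0 (the
  attainable lower part of the empirically observed 7.5–17.5 range);
  requesting more is a hard error rather than a silent distortion;
- rare negative draws (~2 % at r = 0.83) are clipped to zero, and the
  heteroscedastic noise plus clipping biases the *sample* correlation at
  n = 20 slightly upward (mean sample r ≈ 0.85 for a population r of
  0.83); homoscedastic noise would remove the bias but put ~40 % of
  immature-fish draws below zero, so nonnegativity wins.

Cortisol-like analytes are log-normal and independent of GSI.  An
`anchor="sample"` mode re-anchors the fold on the realized group-mean GSI
of a particular cohort, so with `noise_scale=0` the recovered fold is
exact — used for round-trip contracts.

Determinism: one global seed fans out through `SeedSequence.spawn` with
fixed child indices (cohort 0, testis 1, compendium 2, hormones 3); every
generator is byte-reproducible under a fixed seed, and any generator can be
re-run in isolation.

## What passing tests do and do not show

The simulator draws genes independently (no inter-gene correlation, no
probe structure, no array spatial artefacts), uses exactly two
compartments, and makes noise homoscedastic on the log2 scale.  Recovery
results (null false-classification ≤ α, planted-regulation sensitivity
≥ 0.9, perfect GSG precision/recall at 2× margin) therefore validate the
*pipeline logic and calibration*, not performance on real arrays, where
correlated genes inflate gene-set t-tests (hence the permutation option)
and upstream normalisation changes per-gene variances.  Accession-specific
gene counts and per-gene folds from any real data set are consequently not
reproduced by design.

## Problem sizes and runtime defaults

Simulation-backed checks use 2000-gene matrices, 500-replicate hormone
panels, 1000-group null ensembles, and 5-cohort averages for
composition-confound means (a single 20-fish cohort carries ~0.08 MC SD on
the mean shift through π jitter).  These sizes keep every Monte-Carlo
standard error several times smaller than the asserted tolerance while the
full suite runs in well under a minute.

## Degenerate inputs and numerical conventions

Duplicate gene/sample/tissue identifiers, non-numeric cells, overlapping
screen sample sets, missing GSG flags and unknown stage labels are hard
errors naming the offender.  Undefined-but-valid statistics (constant
analyte correlation, zero immature mean fold, < 2 fish per group,
zero-variance gene sets) are NaN, never exceptions.  `alpha` must lie
strictly inside (0, 1); passing a denormal-small alpha (e.g. 1e-300)
reproduces the "classify nothing" limit.  Percentages and folds in
presentation tables are rounded to one decimal; underlying columns keep
full precision.
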