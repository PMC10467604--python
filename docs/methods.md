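# Methods

## The differential methylation model

Tile-level methylated counts are modelled as beta-binomial: given coverage
`n_ij`, the methylated count `m_ij` for tile `i`, sample `j` has mean
`n_ij * p_ig(j)` and variance inflated by an intraclass dispersion
`phi_i`, so `Var(m/n) = p(1-p) * (1 + (n-1) phi) / n`. `phi` captures
between-sample biological variability beyond binomial counting noise;
`phi -> 0` recovers the binomial, `phi -> 1` maximal overdispersion.

**Dispersion estimation.** Per tile, a method-of-moments estimate pools
squared within-group residuals of the per-sample fractions over both
groups (with an `n/(n-1)` small-sample correction per group) and solves
the moment identity above for `phi`. Raw estimates at 18 samples are very
noisy, so each is shrunk toward the across-tile median with weight
`w = m / (m + k)`, where `m` is the tile's total coverage and `k` (default
1000) sets how much coverage a tile needs to keep its own estimate; with
typical 100-bp tiles at 24–45x over 36 samples, `m ~ 900–1600`, so
shrinkage is moderate. `phi` is clipped to `[1e-6, 0.999]`.

**Testing.** The smoothed fraction `(m + 0.5)/(n + 1)` is mapped through
`y = arcsin(2p - 1)`, whose delta-method variance `~(1 + (n-1)phi)/n` is
free of `p` — the same stabilisation used by the dispersion-shrinkage
family of WGBS tests. A weighted least-squares fit of `y` on
`[intercept, group, covariates]` with inverse-variance weights yields a
Wald statistic for the group coefficient, referred to N(0,1). The normal
reference (rather than a t) was chosen because the plugged-in shrunken
dispersion already behaves like a known variance at these sample sizes:
simulation (the acceptance suite) puts the empirical type-I error at
p < 0.05 between 0.044 and 0.053 for `phi` in {0.05, 0.1, 0.2} with 8 vs
10 samples at 24x. Singular covariate designs fall back to the
covariate-free two-group fit, flagged per record.

This is a re-derivation of the model family, not a port of any existing
implementation; its acceptance is calibration and power on synthetic data
with known truth, not numeric equality with another tool.

**Selection rules.** Tiles enter a contrast when covered (usable counts)
in at least 80% of each group's samples, with a ceiling at fractional
thresholds (8 samples -> 7 required), the stricter of the two readings.
DMRs require BH FDR < 0.05 within the contrast and an absolute
coverage-weighted group difference of at least 20 percentage points on
the fraction scale. "Hyper" always refers to the first-named group.

## Tiling and coordinates

All internal intervals are 0-based half-open; 1-based cytosine-report
positions are converted at the reader boundary. CpGs reported on the
minus strand are collapsed onto the plus-strand cytosine (symmetric CpG
methylation assumed). Tiles are anchored on the fixed genome grid
(`floor(pos0/100)*100`) rather than at the first CpG of a run — the two
anchorings differ only by sub-tile phase, and the fixed grid makes tiles
comparable across samples by construction. Coverage bounds are inclusive
on both ends (a 10x and a 500x site are both kept). Filtering masks a
site per sample rather than deleting the row, so the 80% group-coverage
rule downstream operates on honest per-sample missingness.

## cis-eQTM scan

Candidate pairs are (tile, gene) with tile midpoint within 1 Mb of the
TSS, boundary inclusive, signed distance negative upstream relative to
the gene's strand. Three filters guard against outlier-driven hits:
coverage in >= 80% of samples; coefficient of variation above the lowest
5th percentile of coverage-eligible tiles (CV is scale-invariant, so
fraction vs percent is immaterial; an all-zero tile has CV treated as 0
and drops out); and fewer than a configured number of fully unmethylated
samples (33/36 as a fraction, generalising the cohort-specific rule).
Each pair is fit by OLS with a t-test on the methylation slope; BH runs
across all candidate pairs genome-wide (pooled, not per-gene). The slope
is expression (log2-CPM) per methylation-fraction unit.

For differential methylation the default covariate set is sex, age,
smoking and stage; HPV expression (CPM) is available but excluded by
default because it is structurally collinear with group in any HPV(+) vs
HPV(−) contrast (zero for every HPV(−) sample) and absorbs the group
effect — the pipeline additionally drops any covariate whose correlation
with the group indicator exceeds 0.95. The eQTM scan uses the four-
covariate set (sex, age, stage, smoking).

## Genomic instability

Segments are intersected with arm definitions (splitting
centromere-spanning segments), then each piece with `|CN - 2| >= 0.3`
and length strictly greater than 10 Mb contributes `|CN - 2|` if it
covers at least 90% of its arm (the conventional arm-call threshold;
configurable) and a binary 1 otherwise. Copy numbers are taken as
reported (real-valued); the 0.3 neutral band absorbs segmentation noise
around CN 2. Binary terms are counted per segment, not merged across
adjacent segments.

## Region-set scores and deconvolution

MIRA-style profiles anchor each region at its center, pool
coverage-weighted tile methylation into an odd number of equal bins over
`center ± flank`, and aggregate over the set; minus-strand regions are
flipped. The score is `log2(shoulder/center)` with the shoulder at
`floor(B/2)` bins from the center (B = flank bins per side) — zero for a
flat profile, monotone in dip depth, with the center floored at 1e-3 if
it reaches zero. The original MIRA publication's exact flank/bin choices
are not restated here; both are parameters with the defaults documented
above, so absolute scores are comparable only within a fixed setting.

Deconvolution solves non-negative least squares of a sample's per-region
methylation on the atlas rows and normalises the weights to the simplex.
The atlas is expected to include a tumour reference row, as
signature-matrix approaches do: a "free" tumour component with no
reference (tumour = 1 − Σ normal weights) is unidentifiable whenever the
tumour methylome has any appreciable projection onto the normal
references — a short orthogonal-marker calculation shows the normal
weights then absorb most of the tumour signal — so that mode exists only
as `deconvolve_free_tumor` for sensitivity analyses. The
cancer-cell-specific methylome is recovered from the residual,
`(x − Σ w_i ref_i)/w_t`, clipped to [0, 1] with clip events counted, and
reported missing when `w_t < 0.05` (unstable division). Pathway scores
are per-sample means of cohort z-scored log2-CPM over a gene set.

## The synthetic cohort

The generator emulates the study conditions end to end: 36 samples
(8 IMU, 10 KRT, 18 HPV(−)) with group global methylation means
0.62 / 0.51 / 0.52; exponential CpG spacing (default mean 1200 bp) with
dense hypomethylated island hotspots so island/shore/shelf annotations
are non-degenerate; negative-binomial per-CpG coverage with mean 24 and
dispersion 0.3 (tile coverage lands higher where tiles hold several
CpGs; the calibration and power studies impose 24x at the tile level
directly); and beta-binomial counts with intraclass dispersion
`phi = 0.05` by default. The default `phi` is the one parameter the
design space left genuinely open: tile-level within-group dispersions in
WGBS cohorts are typically a few percent, so 0.05 is the realistic
center, and the suite sweeps {0.05, 0.1, 0.2}. Within a tile, all CpGs of
a sample share one beta quantile, so tile-level counts stay beta-binomial
with the same `phi` — the simulation is closed under the test's model,
which is what makes the calibration checks meaningful.

Planted structure, all recorded as ground truth: DMR blocks (default 60,
±30 pp, island placement at 2x odds, direction mix hyper-in-IMU-dominated
for the IMU contrasts and mixed for KRT vs HPV(−)); methylation-coupled
genes whose TSS-proximal tile gets a bimodal across-sample shift (the
high-variability pattern the CV filter selects for) and whose expression
follows the realized tile fraction with slope ±2 and noise SD 0.5;
group-specific methylation dips at TF/enhancer region sets (deeper in
KRT/HPV(−) than IMU); copy-number segment sets whose event counts rise
from IMU to HPV(−) and anti-track a per-sample latent methylation factor
(centered within groups so the configured group means stay exact); and
cell mixtures over a marker-structured atlas with a subtype-shifted
tumour methylome. Expression additionally carries keratinisation / T-cell
/ EMT gene-set structure.

What the generator does **not** emulate: read-level data (no FASTQ, no
bisulfite-conversion errors), sequence content, spatial correlation of
methylation beyond the tile, mappability or coverage biases, and any
relationship between the CNA genome and local methylation (instability
couples to methylation only through the per-sample latent factor).
Passing tests therefore demonstrate correctness and calibration of the
statistical machinery under the stated model, not robustness to
alignment artefacts or reference mismatch in real tumours. In the same
spirit, the cohort's deconvolution panel deliberately includes a
subtype-shifted tumour profile, so recovered tumour *fractions* carry a
reference-mismatch bias of up to ~0.1 there, while the recovered
cancer-specific methylome stays accurate — the controlled mixture study
(atlas-faithful tumour, noise SD 0.03) is the clean recovery benchmark.

## Problem sizes and numerical choices

The suite and the acceptance script use scaled-down genomes chosen as the
smallest that keep every feature non-degenerate: 1–3 chromosomes of
6–30 Mb (arms must exceed 10 Mb for instability to be exercised),
5,000-tile null calibration per dispersion value, 400 replicate tiles for
the power estimate, 100 replicate pairs for eQTM recovery, 100 random
fixtures for the instability oracle and 100 mixtures for deconvolution.
Fisher p-values are checked against direct hypergeometric enumeration on
all small tables (cells ≤ 6) plus random tables up to total 200.
Tie-breaks and degenerate inputs: tiles with identical p keep stable
input order; zero-DMR summaries report 0% with a flag; zero-variance
inputs to the correlation are errors rather than NaNs; Haldane's 0.5
correction is applied to odds ratios only when a cell is zero. All
simulation randomness flows from a single `numpy` Generator per run, and
pipeline outputs are written with fixed float formatting so reruns under
one seed are byte-identical (verified by manifest checksums).
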