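# Methods

## The scoring model

A sample's IFN score is the median over the ISG panel of the comparative-Ct
fold change RQ = 2^−ΔΔCt. The package's conventions, where the underlying
assay leaves room for choice:

- **Housekeeper aggregation.** ΔCt = Ct_target − mean(Ct over measured
  housekeepers). Averaging Cts equals taking the geometric mean of the
  housekeeper quantities, the standard multi-reference rule. If exactly one
  housekeeper is measured it is used alone (warning logged; the sample is
  kept rather than discarded); with none, the sample's ΔCt are all missing.
- **Virtual calibrator.** Pooling controls in software averages their ΔCt
  (log2) profiles — the analogue of mixing equal amounts of cDNA, and the
  choice that makes a pool of n identical samples equal each of them.
  Scoring the calibrator's own profile yields exactly 1 for every gene.
- **Undetermined reactions** are missing, never imputed: imputing a
  limit-of-detection Ct would inflate scores precisely in the high-IFN
  samples whose ISGs are never undetermined. An optional `--lod-ct` flag
  substitutes a fixed Ct for labs that prefer imputation.
- **Median with an even gene count** is the mean of the two central order
  statistics. A sample with fewer than `min_genes_for_score` (default 4)
  measurable genes gets a missing score plus a reason, never a score from
  too few genes, and never zero.

Useful invariants that the tests verify: adding a constant to all of a
sample's Cts leaves everything unchanged; lowering a target Ct never lowers
the score; the score equals a brute-force sorted median under every
missingness pattern.

## Pool adequacy and the λ criterion

The inter-laboratory comparability question is recast as a power
calculation on each gene's coefficient of variation in healthy controls.
With effect size d = mean/SD = 1/CV, a pool of n controls gives the
one-sample two-tailed t-test noncentrality

    λ = (mean/SD)·√n = √n/CV,

which is compared against the reference λref(n): the noncentrality at which
that test with df = n − 1 attains power 1 − β (default 0.8) at level α
(default 0.05). λref solves power(λ) = 1 − β by bracketed root-finding
(Brent, |Δpower| < 1e−8) on

    power(λ) = 1 − F(t_crit; df, λ) + F(−t_crit; df, λ),

with F the noncentral-t CDF and t_crit the central two-tailed critical
value. A gene passes when λ > λref strictly (a tie fails); a cohort passes
when all genes do. A zero SD yields λ = ∞ and passes with a warning.
`project_lambda` evaluates λ at a larger n with mean and SD held fixed —
i.e. assuming the CV does not change as the cohort grows.

Numerical note: scipy's noncentral-t CDF (Boost backend) returns NaN in a
region around df = 1 with moderate λ. Where the library value is
non-finite, the CDF is evaluated by quadrature of the scale-mixture
representation E_V[Φ(t√(V/df) − λ)], V ~ χ²_df, which agrees with the
library to < 1e−9 where both are finite.

## Pool-size planning

λref(n) falls steeply at small n and flattens toward the normal-theory
limit z_{1−α/2} + z_{1−β} ≈ 2.8016. The planner computes λref on
n = n_min..n_max (defaults 2..40), fits the one-phase decay

    y(n) = plateau + (y₀ − plateau)·exp(−k·(n − n_min))

by unweighted least squares (initialized at y₀ = λref(n_min),
plateau = λref(n_max), k = 0.2; the exponential is anchored at n_min to
decouple y₀ from k), and recommends the grid n whose λref is closest in
absolute value to the fitted plateau, ties to the smaller n. With defaults
this gives plateau 3.013 and a recommended pool of 15.

A limitation worth knowing: λref(n) is *not* a single exponential — it
decays fast initially and then approaches its asymptote much more slowly —
so the fitted plateau depends on the fit's lower bound. Including n = 2
(λref = 16.3) forces a fast rate whose plateau averages the flat tail
(3.01); starting at n = 4 or 5 lets the fit chase the slow tail
(plateau ≈ 2.92–2.90). The default n_min = 2 is the convention this
package standardizes on; `--n-min` exposes the choice, and the recommended
n should be read as a convention-dependent operating point on a genuinely
asymptoting curve, not a sharp optimum.

## RNA-seq side

- **FPKM**: counts·10⁹/(libsize·length), with library size the sum of
  counted reads in the table (the default of the usual `rpkm`
  implementations); per sample Σ fpkm·length = 10⁹ exactly.
- **Size factors**: DESeq-style median-of-ratios over genes with nonzero
  counts in every sample, reported unscaled (defined up to a shared
  constant). Dispersion estimation, shrinkage and differential-expression
  testing are deliberately out of scope; the per-patient fold change is the
  size-factor-normalized value divided by the mean of the controls'
  normalized values. A gene whose control mean is zero gets a missing fold
  change, never ±∞. Only the ratio's trend feeds the median score, so this
  naive fold change is an adequate stand-in for a shrunken estimate.
- **PCA screening**: per-gene log2(fpkm + 1), centered and unit-scaled
  across samples, SVD-based PCA; a sample is flagged when its median/MAD
  robust z (MAD scaled by 1.4826) on PC1 or PC2 exceeds the threshold
  (default 3.0). The input transform and the outlier rule are this
  package's explicit conventions — the screening idea (excluding rare
  high-variance donors before pooling) does not by itself fix either, and
  the threshold is a CLI parameter. Because a robust z is scale-invariant,
  an iid cohort of any noise amplitude has a fixed, non-negligible chance
  of containing genuine > 3-MAD samples; excluding a few of ~20 candidate
  donors is the expected behaviour, not a malfunction.

## Concordance

Two platforms' scores on shared subjects are banded at user-chosen
thresholds (left-closed half-open bins; a score exactly at a break goes
up), cross-tabulated, and tested with Pearson χ² (no continuity correction
for r×c; optional Yates for 2×2). Categories empty on both margins are
dropped before testing. Banding thresholds are a required argument: no
default bands are claimed to reproduce any particular published p-value.
The shipped twenty-subject paired-score table reproduces both summary
triplets (means 19.83/13.59, SDs 31.19/20.33, CVs 1.57/1.50); note its
printed summary rows are column-swapped relative to the headers, so
consumers should identify columns by recomputed summaries.

## Synthetic cohorts

The generators emulate the study conditions end to end:

- **qPCR controls**: housekeeper Cts ~ Normal (defaults: HPRT1 24.0,
  G6PD 25.0 cycles, SD 0.5 — typical whole-blood values); target
  ΔCt ~ Normal(gene mean, σ) with gene means 3–8 cycles and σ chosen so the
  fold-change CV hits the per-gene target. The CV → σ map is the exact
  lognormal inversion σ_ln = √ln(1 + CV²) (log2 scale: divided by ln 2).
  Default CVs are the ten-donor reference values (0.23, 1.26, 0.48, 0.13,
  0.96, 0.08).
- **Patients** add per-gene log2 elevations (default Normal(3, 1)) to the
  control model; the sidecar records the elevations and the implied true
  score, median(2^elevation).
- **Counts**: NegativeBinomial(mean = FPKM·length·libsize/10⁹·2^elevation,
  var = μ + 0.05μ²), library sizes uniform in 2–4·10⁷ reads, FPKM baselines
  from the twenty-donor RNA-seq reference summaries, plausible transcript
  lengths (length cancels out of every fold-change quantity), plus 200
  filler genes so size factors are well conditioned. Dispersion 0
  degenerates to Poisson.
- **Paired platforms**: lognormal latent scores (log2-normal(1.5, 2),
  spanning ≈ 0.3–100) observed by each platform through independent
  lognormal noise.

Every generator is a pure function of (spec, seed).

What the generators do *not* model: assay-level run effects (subject
heterogeneity is assumed to be the only variance source, matching the
assay's design assumption), amplification-efficiency differences between
genes, transcriptome-wide expression (only panel + filler genes), batch
effects between repositories, and correlated ISG co-regulation (per-gene
noise is independent). Passing tests therefore demonstrate the statistical
machinery on data satisfying the model's assumptions, not robustness to
those real-world violations.

## Statistical facts the test suite respects

Three consequences of the heavy-tailed lognormal noise model are easy to
misstate and are tested in their estimable forms:

- The *sample* CV of a CV ≥ 1 lognormal is noisy even at n = 1000 (its
  sampling SD exceeds 5% of the target), so generator calibration is
  asserted on the average empirical CV over replicate cohorts (each gene
  within ~1% of target over 12 replicates), not on a single cohort.
- At n = 10 the sample CV is biased downward, so a gene with population
  CV 1.26 fails the λ criterion in a minority (~30%) of simulated cohorts —
  but it is by far the panel's dominant failure mode, while a CV 0.08 gene
  essentially never fails; the end-to-end test asserts exactly that
  asymmetry.
- Recovering patient elevation ranks is attenuation-limited: with iid
  Normal(3, 1) elevations the per-gene biological noise (up to 1.4 log2)
  caps the qPCR-route Spearman near 0.6 regardless of cohort size. A graded
  design (elevation levels spanning 0–6 log2) separates the signal and is
  recovered at ρ ≈ 0.99; the RNA-seq route at iid elevations reaches
  ρ ≈ 0.92.

## Tolerances for published-value comparisons

Reference per-gene means and SDs are printed at two decimals while the
published λ values were computed from unrounded data. Comparisons therefore
use exact interval propagation of the half-ulp input rounding:
|λ_computed − λ_published| ≤ λ·(0.005/mean + 0.005/SD) + 0.005. For almost
every table cell this is *tighter* than a blanket 2%; for the one
small-magnitude cell (RNA-seq IFI27 at n = 15, mean 0.35, SD 0.23) it is
the only bound any reimplementation could meet, since input rounding alone
moves that λ by up to 3.6%.

## Problem sizes used by the default test run

The suite favors exact small-instance oracles (exhaustive 2×2 χ² tables,
all 2⁶ missingness patterns, all 6! gene permutations) plus seeded
simulations sized for stable pass/fail margins: 10⁵-replicate Monte Carlo
for the power function, 12 × n = 1000 cohorts for CV calibration, 500
seeds for concordance detection, 1000 for null calibration. The whole run
takes well under a minute on one core.
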