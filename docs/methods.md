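# Methods

This note documents the models and procedures implemented in `eggprint`,
the parameters that matter, the design choices made where the design was
genuinely open, and the limits of what the synthetic test bed can show.

## Study design and the synthetic generator

The package targets the small-n, large-p regime of a two-group spawn
quality study: 8 females whose spawns produced > 50% viable 4 h embryos
("high"), 8 below 30% ("low"), each profiled on a ~15,000-probe ovary
microarray. The generator (`eggprint.synthetic`) encodes these conditions
as defaults and draws complete studies:

- **Latent quality.** Each female has a latent quality u_i on the percent
  scale (high group truncated-normal around 67.3 ± 8, low around 9.0 ± 6 —
  the group means observed in this kind of study). The recorded
  `pct_4h_viable` is u_i plus 3% measurement noise, clipped to its group's
  range; downstream metrics (24 h, hatch, 5 dph survival) degrade from it
  multiplicatively. Morphometrics carry no group signal (broodstock are
  size-matched).
- **Fingerprint.** On the glog2 scale, fingerprint gene g in sample i is
  μ_g + β_g·z_i + λ·f_{m(g),i} + ε, with z the standardized latent quality.
  |β_g| is drawn just under the cap `max_log2_shift / Δz` so that no
  between-group shift exceeds 0.2 log2-fold units; signs are fixed at
  145 positive (down-regulated in low-quality ovaries) vs 88 negative,
  i.e. 62.2% down in poor spawners. Per-gene shares of the collective
  signal (β_g²/Σβ²) stay below `max_single_gene_share` = 2%.
- **Modules.** The 23 module factors f_m are orthogonalized against z
  before use: module structure lives entirely in the phenotype-independent
  residuals, which is what the reverse-residualization + MMC stages are
  supposed to recover. `within_module_r` (default 0.85) sets the factor's
  share of each gene's non-phenotype variance; after measurement noise the
  effective residual correlation is ≈ 0.8, inside the 0.6–0.9 range that
  relevance-network thresholds at |r| ≥ 0.6 presuppose. Module sizes are
  random with a floor of 5 genes.
- **Raw scale.** Intensities invert the glog model:
  b_i·2^signal·m + N(50, 10²) background, floored at zero, with per-array
  scale factors b_i (lognormal, sd 0.1) and spot-level multiplicative noise
  m (lognormal, sd 0.01). This gives VSN a real affine miscalibration and a
  real additive/multiplicative variance structure to estimate.
- **Genotype.** 48 microsatellite loci × 4 alleles, dosages in {0,1,2}
  drawn from Dirichlet allele frequencies, independent of phenotype — a
  negative control for the "does pedigree explain egg quality" question.
- **Duplicates.** The first 17 fingerprint genes get a twin probe with
  extra spot noise, exercising duplicate collapse (250 probes → 233 genes).

**Noise magnitudes are the package's choice.** Real studies do not publish
their arrays' error model. The defaults (`fingerprint_noise_sd` = 0.075
glog units, `multiplicative_sd` = 0.01, fingerprint baselines in the
bright half of the intensity range) were chosen once so that the planted
structure is recoverable *in principle* at n = 16: each fingerprint gene's
group shift sits around t ≈ 4 (so the P ≤ 0.10 screen keeps it) and the
within-module residual correlation stays near 0.8 (so modularity
clustering has something to find). At materially noisier settings the
modularity-optimal partition of an n = 16 correlation matrix genuinely
differs from the planted one — no optimizer can recover what the sampling
noise has erased — and per-gene effects become statistically invisible to
any screen. Conversely this means the green test suite certifies the
*machinery*, not performance on arbitrary real data; see "Limitations".

## Normalization

`vsn_normalize` fits the affine/glog model in two steps. Per-array affine
parameters (s_i, o_i) are estimated by trimmed least squares against an
iteratively refined consensus profile (default trim 10%, protecting the
fit from differential probes), with the geometric mean of the scales
anchored at 1. The glog shape c is then estimated from the mean–variance
relation of the calibrated intensities: fitting
var_g = a + b·(mean_g − m0)² across probes (robustly, in log space) gives
the additive noise floor a, the squared multiplicative CV b, and the
common background level m0; c = √(a/b) is the intensity where the two
noise regimes cross, and m0 is folded into the offsets. The transform is
strictly monotone, so within-array rank order is preserved. This is an
independent re-implementation of the affine + generalized-log model;
numerical equality with other VSN implementations is not claimed. A fully
constant matrix is passed through as a degenerate identity case; a single
constant array inside a varying matrix is an error (it cannot be
calibrated).

## Probe screening

Binary mode: two-sided Welch t-test of high vs low samples per probe
(unequal variances are the safe assumption at n = 8 per group);
intermediate samples (pct 4 h in [30, 50]) are excluded from binary
screening but retained for continuous-target modeling. Continuous mode:
two-sided t-test on the simple-regression slope. No multiple-testing
correction is applied — the screen is a deliberate dimensionality
reduction at raw P ≤ 0.10 (retaining ~10% of probes under the null by
construction), and downstream selection is by model sensitivity, not by p.
Degenerate probes (zero within-group variance) get a 10⁻⁸ variance floor
and a flag rather than an infinite t. Ties in p are broken by probe id so
ranks are a permutation.

## Neural-network ensembles

`TinyNet` (one hidden layer, tanh, linear output, L2 penalty on weights)
is trained by full-batch L-BFGS with analytic gradients, deterministic
given its seed. Two choices matter and are worth stating plainly:

- **Near-zero initialization + strong shrinkage.** Weights start at
  N(0, 10⁻³); the default L2 penalty is 1.0 for the expression ensembles.
  In the p ≫ n regime (1,469 inputs, 12 training samples) the fitted
  per-feature weights are of order 10⁻³ — smaller than the random
  initialization scale of standard MLP implementations. An optimizer that
  leaves initialization noise in the weights produces perturbation
  sensitivities that are mostly noise; starting near zero and letting the
  penalty prune guarantees that every surviving weight was demanded by the
  data, which is what makes sensitivity a usable importance measure. The
  penalty is a config key; for low-dimensional inputs (genotype dosages,
  the 1-input reverse model) the appropriate default is much milder
  (10⁻² and 10⁻³ respectively), because heavy shrinkage would bias
  predictions toward the training mean.
- **R² definition.** Model and CV R² are squared Pearson correlations
  between observed and predicted phenotype. With 4-sample holdouts the
  1 − SS_res/SS_tot definition is routinely negative; the squared
  correlation stays in [0, 1] but has a null floor of E[r²] = 1/(n−1) = 1/3
  at holdout size 4. Consequently a permuted-phenotype null scores ~0.4
  mean CV R², and **differences against that null, not absolute CV R²,
  are the meaningful robustness measure**. The genotype share uses pooled
  out-of-fold predictive R² (1 − SS_res/SS_tot, floored at 0) instead,
  precisely because "explains nothing" must be reportable as ~0.

Each of the 20 models draws its own 75/25 split without replacement;
feature standardization uses training-split statistics only (a leaky
global-standardization variant exists solely so tests can demonstrate the
difference); the target is affinely mapped to [0, 1] by the training-split
range. Per-model CV R² values are averaged (a pooled option exists).
Sensitivities are finite differences: mean |f(x + σ_j e_j) − f(x)| over
training samples and models, normalized to shares. The subset cascade
(screened set → top 250 → top 100) re-trains fresh ensembles with derived
seeds; subset performance is compared by one-way ANOVA on arcsin-√R² with
Duncan's new multiple range test (protection levels
α_p = 1 − (1−α)^(p−1), studentized-range critical values).

One master seed drives everything through counter-derived sub-seeds
(SHA-256 of "seed:stage" in the pipeline; a SeedSequence per ensemble), so
the full report is byte-reproducible.

## Reverse residualization

To study co-expression *beyond* the quality effect, the mapping is
reversed: one multi-output network (phenotype → all 233 gene expressions)
is fit on standardized outputs and subtracted; residual + fitted =
observed holds exactly by construction. A per-gene single-output mode is
available. A constant phenotype degenerates to per-gene means (centered
residuals), which is handled, not raised. The planted check: genes built
as β·z + noise retain |r(residual, phenotype)| < 0.15 after removal.

## Modulated modularity clustering

The gene × gene residual correlation matrix (Pearson by default, Spearman
optional) is sharpened through w = |r|^s for s on a grid (default 1..30).
For each s, weighted Newman modularity
Q = Σ_modules [S_in/2m − (S_deg/2m)²] is maximized by average-linkage
agglomeration on 1 − w scanning every merge level, followed by greedy
single-gene reassignment to a first-order local optimum; the
partition/sharpness pair with the global maximum Q is returned, ties going
to fewer modules, then lower sharpness. On a 4-gene toy the optimizer
provably hits the exhaustive-enumeration maximum; on planted blocks it
recovers the truth exactly.

A caveat discovered during development and built into the API: because
w = |r|^s is scale-free, sharpening inflates Q even on pure noise (random
n = 400 correlations reach Q ≈ 0.5 at s = 4), so the absolute Q* is *not*
evidence of structure. The partition is therefore flagged
`low_confidence` unless the number of correlation pairs beyond the
3-sigma Fisher-z bound tanh(3/√(n−3)) clearly exceeds (3×) its null
expectation of 0.27% of pairs — a deterministic, sample-size-aware check.

## Relevance networks

Within each module, gene pairs with |Pearson r| of residuals ≥ 0.6 become
edges carrying the signed correlation (direction matters for reading the
biology even though the threshold is on magnitude). Components below 5
genes are retained in the data structure but flagged not-depicted.
Cross-module edges are available behind a flag. Exports: three-column SIF
(relation `pos`/`neg`) and GraphML with r, |r| and module attributes.
Thresholding is monotone by construction: raising the cutoff never adds an
edge.

## Spawn statistics

Quality labels: > 50% viable 4 h embryos → high, < 30% → low, the gap →
intermediate, missing → unassigned (idempotent and total). Group
comparisons use Student's pooled-variance t-tests — proportion metrics are
arcsin-√ transformed first; morphometrics are tested on their natural
scale. (The probe screen deliberately uses Welch instead; each choice is
documented at its stage.)

## Numerical choices and degenerate inputs

- Variance floor 10⁻⁸ on screen standard errors; feature-SD floor 10⁻¹²
  in standardization.
- Expression writers emit `%.17g` floats and readers parse with
  round-trip precision, so write → read is bitwise exact.
- Duplicate collapse averages arithmetically on the glog scale (symmetric,
  standard for within-array replicates); collapsing an already-collapsed
  matrix is a no-op.
- Zero-variance genes: named error in MMC (correlation undefined); zero
  fold-differences and end-of-order placement in the clustergram.
- Equal-Q MMC partitions resolve to fewer modules, then lower sharpness;
  module labels are canonicalized by first appearance, so gene order only
  permutes names.

## Limitations

- The synthetic generator emulates the *statistical* structure of a
  fingerprint study (effect-size caps, share bounds, planted modules,
  additive/multiplicative array noise). It does not emulate probe-sequence
  effects, spatial artifacts, batch structure, dye chemistry, or the
  biological correlation between survival metrics beyond a simple
  multiplicative decay. Green tests certify the machinery and its
  null-calibration, not performance on any particular real dataset.
- At n = 16, absolute CV R² values are optimistic (null floor 1/3 under
  the squared-correlation definition); only contrasts against permuted
  nulls should be interpreted.
- The MMC optimizer is a heuristic (agglomeration + greedy refinement);
  global optimality is guaranteed only where enumeration is feasible and
  is validated by planted-structure recovery otherwise.
- Series-matrix support covers the fenced data table of the GEO dialect,
  not full SOFT metadata.
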