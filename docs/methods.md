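# Methods

This note documents the statistical models behind each stage, the
defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical decisions a maintainer should
know about.

## Data model

A *spot* is one printed replicate of one feature in one block
(mini-array) of one slide, quantified as median foreground `fg` and
median local background `bg` pixel intensities (arbitrary scanner
units, 16-bit range). Medians are the default because they resist
pixel outliers; mean columns can be selected through the parser
dialect. One block serves one serum sample; features are antigens,
control immunoglobulin spots, purification-tag spots, or
printing-buffer spots. Coordinates are 1-based (GenePix convention),
and only one wavelength channel is processed per run. Parsing is total
and order-preserving: every data row becomes a record or the parse
fails naming the column/row at fault — never a silent drop.

## Background correction

The foreground includes the background, so some estimate of the
background must be removed before anything else.

* **local**: `fg − bg`. Unbiased but noisy; negative values are
  *flagged, never silently replaced* — downstream stages decide
  (half-minimum replacement before logs, or a transform that accepts
  negatives).
* **global**: `fg − median(bg over slide)`. Preferable when local
  estimates vary more than the true field.
* **moving minimum**: `fg − min(bg over block)`. For artefacts
  confined to one block which inflate many of its local backgrounds:
  the block minimum is the estimate least affected.
* **half moving minimum**: moving minimum, then any value ≤ 0 is set
  to half the smallest *positive* corrected value in scope. The
  replacement scope defaults to the block (the unit the method
  targets; configurable to the slide). The scope erroring out when it
  contains no positive value is deliberate — replacement would be
  undefined.
* **normexp**: model `X = B + S` with `B ~ Normal(μ, σ²)` and
  `S ~ Exponential(mean θ)`; the corrected intensity is the posterior
  mean, with `μ_s = x − μ − σ²/θ`:

      E[S | X = x] = μ_s + σ·φ(μ_s/σ)/Φ(μ_s/σ),

  computed on the log scale (log-pdf minus log-cdf) so the Mills
  ratio stays accurate deep in the left tail. One parameter set per
  slide: every spot passes through the same smooth, strictly positive,
  strictly increasing map. Estimation is method-of-moments — `μ` and
  `σ` from the median and MAD of the local backgrounds, `θ` from
  `mean(fg) − μ` floored at 1 intensity unit — with an optional
  maximum-likelihood refinement of all three by direct optimization of
  the convolution likelihood. Moments are the default because they
  are fast, deterministic and already accurate at slide sizes
  (≥ 30 spots enforced).
* **log-linear**: per slide, a threshold δ = smallest positive
  `fg − bg`, floored at 1 unit, anchors the interpolation at the
  observed positive range. Differences ≥ δ are kept; smaller ones are
  replaced by `δ·exp(1 − (bg + δ)/fg)`, which meets the linear branch
  continuously at `fg = bg + δ` and decays smoothly toward zero, so
  the corrected value is a continuous, positive, monotone function of
  the foreground. (The exponent is floored at −700 so the output
  stays representable-positive rather than underflowing to 0.)

Diagnostics reported per slide/block: Spearman correlation of `fg` vs
`bg` (low values justify plain local subtraction), block-wise
background medians and IQRs (block artefacts stand out), and
buffer-spot summaries (background reactivity and printing carry-over).

## Replicate quality control

`CV% = 100·s/x̄` with the *sample* standard deviation (n−1); at
n = 2–3 the denominator convention visibly changes the number, hence
it is fixed and documented. CV is undefined (reported as missing,
counted as "out of range") when the mean is non-positive.

Policy, per (sample, feature) set: pass if the full-set CV meets the
cutoff (default 20%); else exempt-and-keep if the mean is below the
low-intensity threshold — near the detection floor tiny absolute
differences produce huge CVs that carry no information, so such CVs
are *ignored*, not used to reject; else search all subsets of size ≥ 2
(default) exhaustively for the minimum-CV subset, keeping it if it
meets the cutoff; else fail (the set is dropped, recorded as a flag,
never an exception). Ties in the subset search break toward the larger
mean, then lexicographically smallest indices — a deterministic rule.
Retained replicates are averaged; a failed set becomes a missing cell.
Tag subtraction removes each antigen's per-sample tag signal
(replicate-averaged, background-corrected), clamped at a floor
(default 0); it is optional because it only applies to designs with
tagged constructs.

## Normalization

All four methods preserve matrix shape and missing-value positions.

* **log2** of background-corrected values, minus an optional residual
  background estimate α̂; values ≤ α̂ become missing with a reported
  count. Simple, but inflates variance near zero and cannot take
  negatives.
* **Cyclic loess** (pairwise): for each distinct pair of arrays, fit
  a LOESS curve to M over A and split the fitted trend evenly between
  the two arrays, sweeping all pairs for `n_cycles` (default 3)
  cycles. The smoother is local-linear with tricube weights, span 0.7,
  3 robustness iterations (common microarray practice; all exposed in
  config). A faster "fast" variant normalizes each array against the
  across-array mean pseudo-array instead of all pairs. Raw or
  pre-logged input is accepted; identical arrays are an exact fixed
  point. The method assumes arrays mostly agree — for designs
  expecting strong between-sample differences, prefer RLM or VSN.
* **RLM**: control spots (e.g. IgG/IgM dilutions) are assumed to bind
  constantly up to technical effects. Their log2 values are fitted to
  `y = intercept + slide + block + protein + ε` by iteratively
  reweighted least squares with Huber weights (tuning constant 1.345,
  MAD residual scale, ≤ 50 iterations, tol 1e-6), sum-to-zero
  constraints on each factor for identifiability. Only the estimated
  slide-plus-block effect is subtracted from the data (the protein
  effect models spotted amount/affinity of the controls and has no
  business being removed from antigens), so within-sample feature
  contrasts are *exactly* preserved. Constant or saturated controls on
  a slide abort with a diagnostic: saturation hides exactly the
  variation the method needs.
* **VSN**: under the two-component model `y ≈ μ·e^η + ε`
  (multiplicative noise η, additive noise ε), the transform
  `h(y) = glog2((y − a_i)/b_i)`, `glog2(u) = log2(u + √(u²+1)) =
  arsinh(u)/ln 2`, renders the variance approximately independent of
  the mean. `glog2` is computed through `arsinh`, which is stable for
  large negative arguments where the direct logarithm cancels.
  Per-array parameters maximize the profile likelihood in which every
  feature has its own transformed mean, all features share one
  residual variance, and the Jacobian of `h` is included; `b_i > 0`
  is enforced by optimizing `log b_i`. Robustness is least-trimmed
  refitting: fit, set aside the `trim_fraction` (default 0.1) of
  features with the largest standardized residual sums, refit, iterate
  to a fixed point (≤ 5 rounds). Optimization is L-BFGS-B from two
  deterministic starts (per-array MAD and MAD/10) — a smooth-objective
  method matters here because the objective has a degenerate `b → 0`
  "log-collapse" region that simplex methods can wander into.
  With background-corrected input the offsets `a_i` are fixed at 0.

  *Identifiability*: a common factor on all `b_i` changes `h` only
  near zero intensity, so with few near-background features the
  overall scale of `b` lies on a nearly flat ridge of the likelihood;
  at 50 features × 6 arrays the data genuinely cannot pin it down.
  The *relative* per-array calibration — the thing between-array
  normalization depends on — is well identified (recovered within a
  few percent in the tests); recovery is therefore assessed on
  geometric-mean-normalized scales. The reported `eta_sd`/`eps_sd`
  are back-calculated from the stabilized residual scale via the
  high- and low-intensity limits of `Var h`.

## MVD diagnostics

Per feature: mean and sd across samples. Reported: the profile ordered
by mean rank with a running-median sd over a centred window (default
10% of features — display smoothing only), the Spearman rho between
means and sds (ties mid-ranked; degenerate ranks reported as missing
with a tie flag), and a trend test on the sd sequence in mean-rank
order. Cox–Stuart pairs each `x_t` with `x_{t+⌈n/2⌉}` and refers the
positive-difference count among untied pairs to an exact two-sided
binomial(½); Mann–Kendall uses `S = Σ_{i<j} sign(x_j − x_i)` with the
tie-corrected variance and a continuity-corrected normal
approximation, two-sided by default (one-sided exposed). The tests are
applied to the *unsmoothed* sd sequence: running-window smoothing
induces serial dependence that destroys both tests' null calibration,
while raw per-feature sds are essentially independent under a
homoscedastic null — the calibration checks (empirical size 3–5.5% at
nominal 5%) rely on this.

## Batch correction

The location/scale model `Y_wsk = α_k + Xβ_k + γ_wk + δ_wk·ε_wsk` is
corrected empirical-Bayes style: (1) feature-wise least squares on
batch indicators plus covariates gives `α̂_k`, `β̂_k` and the pooled
residual scale `σ̂_k` (1/N denominator); (2) standardized residuals
`Z` yield per-batch per-feature locations `γ̂_wk` and scales `δ̂²_wk`;
(3) hyperparameters per batch by method of moments across features —
normal prior for locations, inverse-gamma for scales; (4) the
conjugate posterior pair `(γ*, δ*²)` is iterated to a fixed point
(tol 1e-4, ≤ 200 iterations); (5) the adjustment
`σ̂_k/δ*_wk·(Z − γ*_wk) + α̂_k + Xβ̂_k` rescales with the pooled
feature scale `σ̂_k` — the internally consistent choice, and the one
that makes a single batch an exact no-op (single-batch input is
returned unchanged). The implementation agrees with the Bioconductor
reference implementation of this estimator to ~1e-15 on shared
fixtures (cross-checked in the test suite via Rscript).

Nonparametric mode replaces step (4) with likelihood-weighted averages
of the other features' `(γ̂, δ̂²)` (≥ 2 samples per batch required);
mean-only mode shrinks and removes locations but leaves scales — for
tiny batches whose variances are barely estimable. Covariates in `X`
must not be confounded with batch (singular designs abort). Features
with zero pooled variance cannot be standardized and pass through with
a warning. Batch diagnostics: PCA scores with variance explained,
Euclidean sample distances, per-batch feature summaries.

## Synthetic experiments

The generator emulates a KILchip-like design: 21 blocks per slide
(default), one sample per block, antigens/controls/tags/buffer printed
in triplicate. Intensities follow `fg = bg + μ·e^η + ε` with a normal
background field (mean 300, sd 40), per-feature lognormal true signals
(median ≈ 1500, log-sd 1.2 — spanning the realistic MFI range and
creating the usual mean–variance dependence), per-(feature, sample)
biological variation (log-sd 0.5), multiplicative noise ση = 0.15
(≈ 15% replicate CV, typical of a well-behaved array run) and additive
noise σ = 30 units. Controls bind constantly (20 000 units); tagged
antigens (30% of antigens, round-robin over 3 tags) carry 300 units of
additive anti-tag reactivity; buffer spots carry background only.
Optional slide/block log2 offsets, per-batch location/scale effects,
and background-annulus artefacts (block-confined bg inflation leaving
fg untouched) give every stage a recoverable ground truth. Everything
is determined by one seed, and the ground truth (true μ per feature ×
sample, effects, noise parameters, artefact blocks) is written next to
the data.

What the generator does *not* emulate: spatial gradients within
blocks, pixel-level morphology, scanner saturation, carry-over between
adjacent spots, or missing/flagged spots. Passing tests therefore
demonstrate correctness of the algorithms under the stated noise
model, not robustness to every failure mode of real slides.

## Problem sizes and determinism

Tests and the acceptance script run on deliberately compact designs —
2 slides × 3–4 blocks × 20–60 antigens, 50 × 6 matrices for VSN
recovery, 100 × 40 for batch correction, 2 000 replicates for test
calibration — sizes at which every check completes in seconds to a
couple of minutes while leaving the statistical conclusions
unambiguous. All randomness flows from explicit seeds
(`numpy.random.default_rng`); the pipeline is bitwise reproducible
given config + seed, and matrices are written at full precision
(`%.17g`, re-read with round-trip float parsing — pandas' default fast
parser is *not* correctly rounded).

## Known limitations

* The normexp moment estimator is biased when the background is
  strongly skewed; the ML refinement helps but is not the default.
* RLM normalization operates on the replicate-averaged matrix with one
  (slide, block) label per sample; designs where one sample spans
  blocks with very different behaviour lose within-sample block
  resolution.
* The VSN trimming scheme (least-trimmed refit over features) is one
  defensible robustification of the profile ML; alternatives (Huber
  weights on residuals) would differ in detail.
* Cox–Stuart is conservative at short sequence lengths (exact binomial
  discreteness); Mann–Kendall's normal approximation needs n ≳ 10.
* Batch correction assumes batch effects are additive/multiplicative
  on the normalized scale; feature-specific batch × biology
  interactions are not modelled.
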