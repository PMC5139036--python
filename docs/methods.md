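# Methods

## Model and tests

Expression values of probe *i* under condition *c* ∈ {1, 2} are modelled as
independent samples G_ijc with condition-specific mean μ_ic and variance
σ²_ic, estimated by the usual sample mean and (n_c − 1)-denominator sample
variance.  Six single-hypothesis tests are implemented exactly as their
textbook formulas read:

* **Student t** — pooled variance σ̂²_p weighted by (n_c − 1), statistic
  (1/n₁ + 1/n₂)^(−1/2)(μ̂₁ − μ̂₂)/σ̂_p, reference t(n₁+n₂−2).
* **Welch t** — statistic (μ̂₁ − μ̂₂)/√(σ̂₁²/n₁ + σ̂₂²/n₂), reference a
  central t with the Welch–Satterthwaite ν used as a real number (no
  rounding: the approximation is defined for non-integer df and rounding
  only discards accuracy).
* **STSD** — Student t applied after dividing each group by its own sample
  standard deviation, with *no* centering: centering would delete the mean
  signal the test is meant to retain, while pure rescaling makes a scale
  change invisible.
* **F** — variance ratio σ̂₁²/σ̂₂², reference F(n₁−1, n₂−1).
* **Levene / Brown–Forsythe** — the one-way ANOVA F ratio on absolute
  deviations from the group mean (Levene) or group median (Brown–Forsythe;
  midpoint interpolation on even n), reference F(1, n₁+n₂−2).  This
  reference is asymptotic; its error is visible in large simulations but
  small at n = 40.

Sidedness conventions (the sources leave them implicit): t-type tests are
two-sided via 2·P(T ≥ |t|); the variance-ratio F is two-sided via
2·min(P(F ≤ f), P(F ≥ f)) capped at 1, because variance heterogeneity has
no preferred direction; Levene-type statistics are referred to the upper
tail only, as in ordinary ANOVA.

Under the dual null H₀₃ (equal means *and* equal variances) with
spherically symmetric noise, mean-test statistics are independent of
variance-test statistics.  The joint tests build on that independence:

* **IMVT / FWT / BFWT** — Fisher combinations −2(ln p_mean + ln p_var)
  referred to χ²₄, pairing Welch t with Levene (recommended), F, or
  Brown–Forsythe.
* **SMVT** — reject H₀₃ when p_WT ≤ α₁ or p_LF ≤ α₂; under independence the
  overall size is α₁ + α₂ − α₁α₂, and the equal split α₁ = α₂ = 1 − √(1−α)
  controls the total at α.  The decision rule defines no p-value, so the
  reported p_SMVT = 1 − (1 − min(p_WT, p_LF))² is a Šidák-style convention
  chosen because "p_SMVT ≤ α" reproduces the split rule exactly at the
  equal split.  (An alternative inline reading of the split level,
  1 − √α, fails the size identity and is not used.)
* **LRT** — the two-sample normal likelihood ratio with MLE variances
  (n_c−1)/n_c·σ̂²_c and pooled-mean alternative, −2 ln Λ referred to χ²₂.
  Λ is computed in log space (sums of ½n_c ln terms) so large n cannot
  under- or overflow; the statistic is clipped at 0 against round-off.
  The χ²₂ reference is known to fail at small n (the simulations reproduce
  the inflation); no small-sample correction is attempted.

Degenerate inputs follow explicit conventions: identical constant groups
give statistic 0 / p = 1; zero-variance configurations that make a
statistic undefined raise a `DegenerateSampleError` naming the probe; a
Levene denominator of 0 with positive numerator yields p = 0 with a logged
warning.  Component p-values entering logarithms are floored at 1e-300 —
far below any decision threshold, but keeping the Fisher statistic finite.

## Simulation engine

Group 1 is drawn from the standard family member (N(0,1) or Laplace(0,1));
group 2 as r + (1+s)·X with X standard, so r is the mean shift and 1+s the
spread multiplier in both families (for the Laplace family the second
moment is 2(1+s)², but s plays the identical role, preserving cross-family
comparability of (r, s) grids).  All requested tests are evaluated on the
same replicate draws, so power comparisons are paired; one NumPy generator
per study (spawned per grid point from the study seed) replaces per-
replicate streams — pairing holds by construction and the fully vectorized
kernels evaluate 100,000 replicates in seconds.  Results are tidy tables
(test, family, n₁, n₂, r, s, α, rejections, replicates, proportion, mc_se)
with mc_se = √(p̂(1−p̂)/R), and the 95% binomial concentration band
α ± 1.96√(α(1−α)/R) clipped to [0,1].  Default replicate counts are 10,000
(quick studies) and 100,000 (high-precision null diagnostics), both
selectable.

## Background calibration

Latent factors and covariates inflate every per-probe test; structure
aligned with the condition must be estimated *without* absorbing true
signal.  The pipeline:

1. **Robust probes** — keep probes with p_WT > τ and p_Levene > τ
   (τ = 0.05, unadjusted) on the raw matrix.  The threshold is a
   screening device, not an inference: it only needs to exclude strongly
   condition-associated probes from the background estimate.
2. **Background PCA** — probe-wise mean-centering (no unit-variance
   scaling: normalized intensities share a scale, and scaling would let
   noise-dominated probes outvote structured ones), SVD of the
   samples × probes matrix, scores U·S, variance proportions s²ᵢ/Σs².
3. **Component truncation** — only components that stand above a
   permutation noise floor count as estimable structure.  The criterion is
   iterative parallel analysis: at step k the accepted components are
   deflated, each probe of the residual is permuted independently across
   samples, and component k+1 must exceed the 95th percentile of permuted
   top singular values by a 10% margin (compensating the edge bias of
   comparing a deflated running maximum with a fresh permutation maximum).
   Because a component carried by a few very loud probes is invariant
   under per-probe permutation, the scan continues past isolated failures
   and stops only after two consecutive ones.  Screening *all*
   ~(n_samples − 1) PCs instead is available (`n_components="all"`) but
   not the default: the screen then flags, by selection, the handful of
   noise directions most aligned with the condition contrast, and
   residualizing those systematically deflates every downstream mean test.
4. **Screening** — each structured PC's score vector is split by condition
   and tested with Welch t and Levene; a PC is significant when either
   p < τ_pc (0.05, unadjusted, matching the magnitude of the smallest
   reported real-data screening p-values).
5. **Residualization** — per-probe OLS on intercept + covariates +
   significant PC scores; the condition label is never in the design, so
   condition-driven signal survives.  A rank-deficient design is an error.
6. **Second pass** — robust probes are re-tested on their residuals,
   violators dropped, and the background model re-estimated (`max_iter`
   extends this toward a fixed point; default 2 passes).
7. **Reporting** — per-probe statistics and p-values for all tests on the
   residuals, BH q-values (step-up with cumulative-minimum enforcement)
   and a Bonferroni flag on the IMVT p-values, the genomic inflation
   factor λ = median(χ²₁-quantile of 1−p)/median(χ²₁) before and after
   calibration, and Beta order-statistic QQ bands.

## The synthetic-data generator

`FixtureSpec` emulates the statistical anatomy of a two-condition
microarray study (default 5,000 probes, 40 + 40 samples):

* a **dominant inert factor** (≈94% of total variance) carried by a 2%
  block of loud probes with heavy-tailed loadings, normalized to a fixed
  total strength.  Confining it to a block mirrors intensity-dominated
  arrays and keeps its chance condition alignment from moving genome-wide
  median statistics;
* two **latent confounders** with dense loadings: a mean-shifted factor
  (shift 0.45 between conditions, also heteroscedastic so its PC is
  detectable through the variance channel, whose removal barely costs the
  mean tests) and a purely variance-inflated factor (spread ×5 in
  condition 2).  Factor scores keep their natural sampling variation:
  zeroing their chance per-condition means would put factor variance into
  test denominators with no matching numerator term and deflate every
  loaded probe — a lesson learned the hard way during design;
* **covariates** — age (slightly condition-shifted) and a menopause
  indicator tracking age but balanced across conditions by construction,
  both with dense probe loadings;
* **50 planted MVDE probes** cycling through (r, s) = (1.3, 0), (0, 1.8),
  (0.9, 0.9) in noise-SD units, applied to the idiosyncratic noise of
  condition-2 samples; planted probes do not load on the dominant factor,
  so the planted effect sizes are interpretable.  A truth table
  accompanies every fixture.

What the generator does **not** emulate: probe-specific intensity-variance
relationships, correlated noise within co-expression modules, heavy-tailed
or skewed per-probe noise (except via the Laplace option), and missing
values.  Passing the end-to-end tests therefore shows that the pipeline
recovers planted structure under an idealized factor model — not that it
is robust to every pathology of real arrays.  The post-calibration λ of a
fixture realization also varies noticeably from seed to seed (chance
alignment of the removed, estimated directions with the condition
contrast enters λ quadratically, hence one-sidedly), so occasional
realizations fall outside the typical [0.9, 1.2] window; the standard
fixture (seed 0) sits mid-window.

## Numerical and testing choices

Statistics are computed by vectorized kernels on stacked samples; the
scalar API wraps single rows of the same code path, and the test suite
checks both against naive loop-level transcriptions of the formulas to
1e-10 relative tolerance.  Monte-Carlo checks are derandomized at the
package-default seed 0.  Where an empirical size is compared with the 95%
binomial band at 10,000 replicates, an outside-band cell is re-estimated
at 100,000 replicates against the *same* band before being called a
failure — the tolerance is unchanged, only the estimator's noise is
reduced.  Problem sizes in the test suite (10,000-replicate studies,
100,000-replicate null diagnostics, the 5,000-probe fixture) were chosen
to keep the full run in well under a minute while leaving every
statistical margin intact.

## Known limitations

* The Levene/Brown–Forsythe F reference and the χ²₄ reference built on it
  are asymptotic; at n = 40 the IMVT's true size is within a few percent
  of nominal (slightly above under Laplace noise), and at very small n the
  anti-conservatism grows — as the simulations show for the LRT and STSD.
* The moderated Welch t is not shipped; the registry accepts any function
  `TwoGroupSample -> TestResult` as a plug-in mean test.
* Robust-probe selection assumes a majority of null probes; studies where
  most probes respond to the condition would leave too small (or biased) a
  robust set.
* The calibration design is shared across probes (one OLS design); probe-
  specific confounding is out of scope.
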