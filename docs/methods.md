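# Methods

This document records the statistical model behind each pipeline stage,
the generative model of the synthetic cohort, the numerical choices,
and the limitations. Notation: the exposure X is age at natural
menopause in years (population mean 50, SD 5 in the reference setting);
G_j ∈ {0, 1, 2} is the dosage of the counted allele of SNP j; w_j > 0
is its weight; S = Σ_j w_j G_j is the weighted genetic risk score.

## 1. Instruments and the genetic risk score

An instrument table carries `snp, chrom, pos, effect_allele,
other_allele, beta, eaf` (optionally `se, pval, annotation`). Before
scoring, every variant is oriented so that the counted allele is the
**exposure-decreasing** one: if the published effect-allele beta is
positive, the counted allele becomes the other allele, the weight is
|beta|, and the counted-allele frequency is 1 − eaf. A higher score
therefore always predicts an earlier menopause, and downstream signs do
not depend on how the source GWAS chose its effect alleles.

Missing dosages are mean-imputed at 2 × counted-allele frequency
(`missing="impute"`, the default) or the individual is dropped
(`"complete_case"`).

**Pruning.** For sources that are not already independent, variants
are greedily selected in ascending p-value order (ties broken by id;
|beta|/se substitutes when p is absent). A candidate is kept only if it
is ≥ 10 Mb from every kept variant on the same chromosome, or has
dosage r² < 0.001 with each of them. These are the conventional
"independent signal" defaults for this exposure; both are parameters.

**Strength.** R² is taken from the univariable regression of X on S;
F = R²(n − 2)/(1 − R²). A k-regressor version
F = (R²/k)·((n − k − 1)/(1 − R²)) is also reported. Note the two
coincide only at k = 1; published F statistics computed from per-SNP
joint models will not match the single-score formula.

## 2. Phenome scan

The scan regresses every phenome field on the score, adjusting for age
and ten genetic principal components (`age, pc1..pc10`; sex is never a
covariate because scans are run within sex). Trait types are resolved
automatically unless declared:

* exactly 2 distinct non-missing values → binary;
* numeric with ≥ 20 distinct values → continuous;
* numeric with 3–19 distinct values → ordered categorical;
* non-numeric with ≥ 3 values → unordered categorical;
* a single distinct value → skipped.

Routing:

* **continuous** — the field is inverse-normal rank transformed,
  Φ⁻¹((r − 0.5)/m) with average ranks for ties, then fit by OLS. The
  transform makes p-values invariant to monotone recodings of the raw
  field, which is essential when scanning thousands of heterogeneous
  fields.
* **binary** — logistic regression; fields with fewer than 10 cases or
  10 controls are skipped (estimates there are unstable and would
  pollute the FDR ranking).
* **ordered categorical** — proportional-odds logistic regression
  (statsmodels `OrderedModel`). If the optimizer fails to converge the
  fit is retried once with the score rescaled to unit variance (the
  estimate is rescaled back).
* **unordered categorical** — multinomial logistic regression with a
  likelihood-ratio test against the score-free model (df = number of
  non-reference categories); the reported estimate is the
  largest-magnitude category contrast.

Per-field failures are recorded as skips with a reason, never raised,
so one pathological field cannot abort a phenome-wide run.

## 3. Multiple testing

Two thresholds are computed from the vector of scan p-values:

* **Bonferroni**: α/n.
* **Rank-based FDR**: sort p-values ascending, find the largest rank k
  with p₍ₖ₎ **strictly** < α·k/n, and set the threshold P_t = α·k/n.
  Membership is p ≤ P_t. The strict inequality matches the classical
  step-up construction; on the reference scan dimensions (n = 18,961,
  α = 0.05) ranks 221 / 172 / 102 give thresholds 5.83 × 10⁻⁴ /
  4.54 × 10⁻⁴ / 2.69 × 10⁻⁴ and Bonferroni 2.64 × 10⁻⁶.

QQ data are returned as a data frame of −log₁₀ p against expected
quantiles −log₁₀((i − 0.5)/n), with both thresholds attached as
reference lines; p = 0 is floored at the smallest positive float.

## 4. One-sample MR

A two-stage estimator. Stage one regresses X on S plus covariates and
keeps the fitted values X̂. Stage two regresses the outcome on X̂ plus
the same covariates — OLS for continuous outcomes, logistic for binary.
The reported standard error is the second-stage model SE; first-stage
uncertainty is **not** propagated (each estimate carries a note saying
so). With an F statistic in the hundreds-to-thousands range the
first-stage contribution is negligible; with weak instruments the
interval is anti-conservative and a proper 2SLS/IV variance should be
used instead.

For continuous outcomes the two-stage slope is algebraically the
covariate-adjusted reduced-form coefficient divided by the first-stage
coefficient; the test suite asserts this identity to 8 digits.

## 5. Two-sample MR

**Harmonization** matches exposure and outcome records by SNP id.
Swapped alleles flip the outcome beta and complement its frequency;
strand flips (allele complements) are resolved; palindromic (A/T, C/G)
variants with frequency in (0.42, 0.58) in either source are excluded
as unalignable, outside that band they are aligned by frequency
concordance. Irreconcilable pairs are excluded with reason
`allele_mismatch`. All exclusions are returned, not silently dropped.

**Estimators** (β_Xj, β_Yj per-SNP effects, σ_j outcome SE):

* *Wald ratio* (single SNP): β_Yj/β_Xj with delta-method SE σ_j/|β_Xj|.
* *IVW*: weighted through-origin regression of β_Y on β_X with weights
  1/σ_j², i.e. Σwβ_Xβ_Y / Σwβ_X². Multiplicative random effects scale
  the SE by √max(1, Q/(k − 1)) where Q is Cochran's heterogeneity
  statistic (the default); fixed effects are available.
* *MR-Egger*: the same weighted regression with a free intercept, after
  orienting all SNPs to β_X ≥ 0. The intercept estimates the mean
  directional pleiotropy under the InSIDE assumption; inference uses a
  t distribution with k − 2 df and a residual variance floored at 1
  (never deflated below the fixed-effect model).
* *Weighted median*: per-SNP ratios sorted, weights w_j =
  (|β_Xj|/σ_j)², the 50 % point of the cumulative weight
  c_j = Σw − 0.5w_j found by linear interpolation. Consistent when ≥
  50 % of the weight comes from valid instruments. SE by parametric
  bootstrap (resampling β_X, β_Y from their reported SEs).
* *Mode-based* (simple and weighted): the maximizer of a Gaussian KDE
  over the ratio estimates, bandwidth 0.9·min(sd, mad)·n^(−1/5) times a
  user factor, evaluated on a 512-point grid spanning
  [min − 3h, max + 3h]. SE by the same parametric bootstrap.

All estimators accept `per_decrease` (default True): estimates and
intervals are negated onto the per-year-decrease scale. The Egger
intercept is invariant under this flip (only the slope reverses).

## 6. Synthetic cohort generator

The generator exists to give the pipeline a ground truth
(`TruthRecord`) against which recovery can be asserted. Per
`SimConfig`:

* **Genotypes**: Binomial(2, p_j) under Hardy–Weinberg, p_j uniform on
  `maf_range`. Optional LD blocks (a latent block variable mixed into
  member SNPs), missingness MCAR at `missing_rate`, and a crude
  two-population structure flag.
* **Instruments**: |β_j| ~ U(0.05, 0.35) with random signs, SEs implied
  by z ~ U(6, 25), non-palindromic allele pairs, chromosome/position
  laid out cyclically, a configurable fraction annotated as
  DNA-damage-response.
* **Exposure**: X = μ − b·(S − mean(S)) + c_x·U + ε, with b chosen from
  the *realized* score SD so that the population R² of S on X equals
  `target_r2` (E[R²] = target to O(1/n); realized R² at n = 20,000 is
  0.073 ± 0.01 when targeting 0.073). U is a standard-normal
  confounder; the noise variance is σ²(1 − R²) − c_x². Because the
  score counts decreasing alleles, the true per-SNP exposure effects
  are β_Xj = b·w_j on the oriented dosages.
* **Traits**: linear predictor effect·(X − 50) + c_y·U +
  age_effect·(age − 55) + pleiotropy, where pleiotropy adds oriented
  dosages times per-SNP coefficients α_j (zero, balanced, or
  directional with mean `pleiotropy_mean`). Continuous traits add
  Gaussian noise; binary traits pass the predictor through a logistic
  link whose intercept is solved (Brent) to hit the target prevalence;
  ordered traits threshold a latent variable with logistic noise at
  empirical quantiles; unordered traits use Gumbel-max utilities over a
  fixed contrast pattern.
* **Male control**: `simulate_male_cohort` draws a cohort with no
  exposure pathway but the **same** instrument table and the same
  pleiotropy coefficients (seed substreams are spawned from one
  `SeedSequence`, so the shared components are bit-identical). An
  exposure-mediated trait effect therefore appears only in the female
  scan; a pleiotropic one appears in both.
* **Summary statistics**: per-SNP β̂_X = b·w + noise and β̂_Y =
  θ·w + sign(w)·α + noise with SEs σ = sd/√(2p(1 − p)n). Directional
  pleiotropy is applied on the exposure-increasing orientation so that
  MR-Egger's intercept recovers `pleiotropy_mean` after its β_X ≥ 0
  re-orientation.

What the generator does **not** emulate: realistic LD beyond block
exchangeability, relatedness, fine-grained population stratification,
selection/participation bias, phenotype measurement error structure,
and time-to-event outcomes.

## 7. Numerical choices

* All randomness flows through `numpy.random.SeedSequence(seed).spawn`
  with named substreams, so adding a trait does not perturb genotype
  draws and the male cohort shares exactly the intended components.
* Weighted least squares in the two-sample estimators is solved by
  `numpy.linalg.solve` on the normal equations (k is at most a few
  hundred, conditioning is benign); the test suite checks agreement
  with independent oracles to 1 × 10⁻⁸.
* OrderedModel fits use BFGS with a pandas Categorical endog; a single
  retry rescales the score to unit variance when the first fit fails.
* Bootstrap SEs default to 1,000 replicates with a fixed seed argument.

## 8. Open design decisions and limitations

* Second-stage-only SEs in one-sample MR (see §4) — adequate for
  strong instruments, anti-conservative otherwise.
* The rank-based FDR rule controls FDR under independence/PRDS;
  phenome fields scanned against one shared score are positively
  correlated, so the realized null rejection fraction has wider spread
  than the binomial approximation suggests.
* The single-score F statistic and the k-regressor F disagree whenever
  strength is computed from a joint per-SNP model; the package reports
  both rather than choosing.
* Mode-based estimators are grid-based; estimates are resolved to the
  grid spacing (range/511), which is far below their sampling error at
  realistic k.
* Problem sizes used in tests and in `scripts/acceptance.py`
  (e.g. 1,000 null fields at n = 5,000; 50-replicate recovery studies)
  are package choices balancing statistical resolution against runtime,
  not properties of the methods.
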