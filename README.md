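# mrphewas

A Mendelian randomization phenome-wide association study (MR-pheWAS)
toolkit, built around the reproductive-ageing use case: a weighted
genetic risk score (GRS) for age at natural menopause is screened
against thousands of phenotype fields to find traits causally
downstream of earlier (or later) menopause, and candidate signals are
followed up with formal one-sample and two-sample MR estimators.

The package ships a fully synthetic cohort generator with known ground
truth, so every stage of the pipeline — score construction, automated
phenome scanning, rank-based multiple-testing control, and causal
effect estimation — can be validated end to end without any real data.

## The scientific problem

Observational associations between age at menopause and later-life
disease are confounded (by adiposity, smoking, socioeconomic position,
…) and prone to reverse causation. Mendelian randomization sidesteps
this by using germline genetic variants as instruments: alleles are
fixed at conception, so a score built from variants that shift
menopause timing is (under the usual instrumental-variable assumptions)
independent of confounders of the menopause–outcome relationship.

The hypothesis-free variant of this design, MR-pheWAS, regresses the
GRS on every field in a phenome simultaneously and asks which
associations survive multiple-testing control. Because a single score
aggregates many variants, an association can reflect either a causal
effect of the exposure or horizontal pleiotropy (variants affecting the
outcome through other pathways). The package therefore includes two
built-in triangulation devices:

* **Stratified scores** — instruments can be split by functional
  annotation (here: DNA-damage-response genes vs the rest) and scanned
  separately.
* **A male negative control** — exposure-mediated effects of a
  *female* reproductive trait cannot appear in men, whereas shared
  pleiotropic pathways can; scanning a simulated male cohort with the
  same score separates the two.

## Conventions

* The GRS counts **exposure-decreasing** alleles: published
  effect-allele weights with positive sign are flipped to the other
  allele before scoring, so a higher score always means an earlier
  expected menopause.
* All causal estimates are reported **per year decrease** of the
  exposure by default (`per_decrease=True` everywhere); a planted
  log-odds of +0.04 per year *increase* is reported as −0.04, i.e. an
  odds ratio of ≈ 0.96 per year decrease.
* Multiple-testing control uses the rank-based FDR rule: the largest
  rank *k* with p₍ₖ₎ < α·k/n sets the threshold P_t = α·k/n, alongside
  Bonferroni α/n.

## Worked example

```python
from mrphewas import (SimConfig, simulate_cohort, compute_grs,
                      run_phenome_scan, fdr_rank_threshold, OneSampleMR)

cfg = SimConfig(
    n_individuals=5000, n_snps=60, seed=7,
    trait_spec=[
        dict(field_id="heel_bmd", trait_type="continuous", effect=0.05,
             category="bone"),
        dict(field_id="breast_cancer", trait_type="binary", effect=0.04,
             prevalence=0.3, category="cancer"),
        dict(field_id="tea_intake", trait_type="continuous", effect=0.0,
             category="diet"),
    ])
cohort, instruments, truth = simulate_cohort(cfg)

score = compute_grs(cohort.genotypes, instruments)
scan = run_phenome_scan(score, cohort.phenome, cohort.meta,
                        cohort.covariates)
print(scan.to_frame()[["field_id", "model", "estimate", "pvalue"]])
```

```
        field_id     model  estimate    pvalue
0       heel_bmd    linear -0.050668  0.000121
1  breast_cancer  logistic -0.109029  0.000176
2     tea_intake    linear  0.001394  0.915916
```

The two planted effects surface with the right signs on the
per-year-decrease scale (heel BMD planted at +0.05 per year increase)
and the null trait does not. Thresholding and follow-up:

```python
thr = fdr_rank_threshold(scan.pvalues, field_ids=scan.pvalues.index)
print(thr.summary())

model = OneSampleMR(score, cohort.exposure, cohort.covariates)
print(model.first_stage.strength)
print(model.fit(cohort.phenome["heel_bmd"], "continuous").summary())
```

```
n_tests=3  alpha=0.05
Bonferroni threshold: 0.0167 (2 significant)
FDR threshold:        0.0333 (rank 2, 2 significant)
InstrumentStrength(r_squared=0.0836..., f_statistic=456.0..., n=5000, ...)
two_stage_linear: -0.03909 (95% CI -0.05894, -0.01924; SE 0.0101; p=0.000115; n=5000)
```

Two-sample MR runs on summary statistics alone. Harmonization matches
SNPs by id, resolves swapped and strand-flipped alleles, and excludes
ambiguous palindromic variants:

```python
from mrphewas import TwoSampleMR, simulate_summary_stats
from mrphewas.simulate import sumstats_frames

cfg = SimConfig(n_snps=150, seed=7)
_, inst, _ = simulate_cohort(cfg)
pairs = simulate_summary_stats(inst, true_effect=0.04, seed=7)
exposure_tbl, outcome_tbl = sumstats_frames(pairs, n_exposure=201_323,
                                            n_outcome=100_000)
print(TwoSampleMR.from_summary_tables(exposure_tbl, outcome_tbl)
      .fit(seed=7).summary())
```

```
Two-sample MR on 150 harmonized SNPs
ivw: -0.03617 (95% CI -0.03988, -0.03246; SE 0.00189; p=1.54e-81; n=150)
egger: -0.02993 (95% CI -0.03948, -0.02037; SE 0.00488; p=7.31e-09; n=150)
  intercept 0.001532 (SE 0.0011; p=0.167)
weighted_median: -0.03856 (95% CI -0.04406, -0.03305; SE 0.00281; p=6.68e-43; n=150)
simple_mode: -0.03568 (95% CI -0.04918, -0.02217; SE 0.00689; p=2.26e-07; n=150)
weighted_mode: -0.0425 (95% CI -0.05397, -0.03104; SE 0.00585; p=3.7e-13; n=150)
```

## Command line

Every stage is also a `mrphewas` subcommand operating on TSV/JSON
files, plus a one-shot orchestrator:

```
mrphewas simulate  --config config.yaml --out data/
mrphewas grs       --instruments data/instruments.tsv --genotypes data/genotypes.tsv --out scores.tsv
mrphewas scan      --scores scores.tsv --phenome data/phenome.tsv --meta data/phenome_meta.tsv \
                   --covariates data/covariates.tsv --out scan.tsv
mrphewas thresholds --scan scan.tsv --out thresholds.json
mrphewas mr1       --scores scores.tsv ... --out mr1.tsv
mrphewas mr2       --exposure-stats ... --outcome-stats ... --out mr2.tsv
mrphewas run       --config config.yaml --out run/ --seed 44
```

`mrphewas run` executes the full pipeline (simulate → GRS with full,
pruned and annotation-stratified scores → female and male phenome scans
→ thresholds and QQ data → one-sample MR on the FDR-significant fields
→ two-sample MR) and writes a `manifest.json` with SHA-256 digests of
every output, so reruns can be verified byte-for-byte.

## Package layout

| Module | Contents |
| --- | --- |
| `mrphewas.simulate` | synthetic cohort / male control / summary-statistics generators with `TruthRecord` ground truth |
| `mrphewas.instruments` | instrument table, allele orientation, weighted GRS, distance+r² pruning, annotation strata, R²/F strength |
| `mrphewas.scan` | `PhenomeScan` model: automated trait typing, inverse-normal rank transform, linear/logistic/ordered/multinomial routing |
| `mrphewas.thresholds` | Bonferroni and rank-based FDR thresholds, QQ data |
| `mrphewas.onesample` | `OneSampleMR`: two-stage estimator with covariate adjustment |
| `mrphewas.twosample` | `TwoSampleMR`: harmonization, Wald ratio, IVW, MR-Egger, weighted median, mode-based estimators |
| `mrphewas.report` | pipeline orchestration, manifests, category summaries, sex comparison |

The modelling API follows the statsmodels convention: construct a model
object (`PhenomeScan`, `OneSampleMR`, `TwoSampleMR`), call `.fit()`,
and inspect a results object with `.to_frame()` / `.summary()`.

See `docs/methods.md` for the statistical methods, the generative model
behind the simulator, and the numerical choices.

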