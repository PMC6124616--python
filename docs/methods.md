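# Methods

## Model

The unit of analysis is a genotyped individual who may report their own
birthweight (`BW`), the birthweight of their first offspring (`BW_O`), or
both. The model is a three-variable Gaussian path model with two latent
genotypes: the individual's mother's (`G_G`) and their offspring's (`G_O`).
Transmission paths between genotype variables are fixed at ½ (autosomal
Mendelian inheritance, additivity), every genotype variable has variance Φ,
and the free structural parameters are

| parameter | meaning | default start |
|---|---|---|
| `m` | maternal path: effect of a genotype on the carrier's offspring's phenotype | method of moments |
| `f` | fetal path: effect of a genotype on the carrier's own phenotype | method of moments |
| `Φ` | genotype variance (≈1 for standardized dosages, `2p(1−p)` raw) | pooled Var(SNP) |
| `σ²_ε`, `σ²_εo` | residual phenotype variances | moment residual |
| `ρ` | covariance of the two phenotype residuals (residual mother–offspring similarity) | moment residual |
| `μ_BW`, `μ_BWO`, `μ_SNP` | means, estimated jointly (phenotypes assumed pre-standardized, means not forced to zero) | sample means |

Units: `m` and `f` are phenotype-SD per genotype-SD when dosages are
standardized, matching the scale of a conditional (mother + offspring
genotype) regression. The model assumes multivariate normality of the
observed triple, additivity, no maternal–fetal genotype interaction, and no
paternal pathway; dosages are exogenous, so their own non-normality is
benign.

## Likelihood and missing data

Records are grouped by observation pattern (`both`, `own_only`,
`offspring_only`; dosage is never missing). Each group contributes the
multivariate-normal likelihood of exactly its observed subvector —
full-information maximum likelihood, unbiased under missing-completely-at-
random masking. Two numerically identical objectives are provided: a
per-record sum of log densities (`neg2_loglik_raw`) and the per-group
summary form `n[k ln 2π + ln|Σ| + tr(SΣ⁻¹) + (x̄−μ)ᵀΣ⁻¹(x̄−μ)]`
(`neg2_loglik_cov`, with ML divide-by-n covariances). The constant is kept in
the summary form so the two agree exactly, and tests assert their fits agree
to 1e-4. The summary route is the default: it is ~two orders of magnitude
faster and admits cohorts that can only share summary statistics.

When no group observes both phenotypes (missingness design iv), ρ does not
enter any group's likelihood; it is structurally dropped from the parameter
vector rather than left to drift. Likewise the mean/variance of a phenotype
observed in no group is excluded.

## Optimisation and inference

Variances are optimized on the log scale; ρ is unconstrained with positive
definiteness of the implied covariance checked at every evaluation
(violations return a large penalty, never silent NaN). L-BFGS-B starts from a
method-of-moments point that, for the just-identified full model on complete
data, is already the ML solution. Up to `restarts` (default 10) jittered
attempts emulate a try-hard retry loop: further attempts run only if an
attempt fails to converge or yields an unusable Hessian, and the best
objective is kept. This matters mainly at minor allele frequencies below ~5%.

Standard errors come from the inverse of a central-finite-difference Hessian
of −2lnL at the optimum (step 1e-4 on each parameter's working scale;
parameter covariance = 2 H⁻¹). Wald statistics are `(estimate/SE)²` on 1 df.
Likelihood-ratio tests compare nested fits with the statistic floored at
zero (optimizer noise can leave a reduced model fractionally lower); the
full-versus-null comparison is the 2-df omnibus test of any variant effect.
Wald is the default reported test — the Wald/LRT p-value difference is
negligible (asserted in tests at median < 1e-2) and Wald needs one fit
instead of two.

## What the simulator emulates

`simulate` draws grand-maternal genotypes from Hardy–Weinberg, transmits
alleles to mother and offspring with independent Hardy–Weinberg fathers
(fathers are generated and discarded, never observed), standardizes dosages,
and builds

```
BW   = m·G_G + f·SNP + β_U·U + ε        BW_O = m·SNP + f·G_O + β_U·U + ε_O
```

with `U ~ N(0,1)` shared within family and residual variances chosen for
asymptotic unit phenotype variance. Scenario effect sizes are signed variance
fractions; the working coefficient is `sign·√|v|`. Defaults are the study
conditions: 30 000 families, allele frequency 0.5, `β_U = β_UO = 0.5`
(so the true residual covariance is 0.25), clean complete data.

Degradations: classical measurement error adds Gaussian noise sized from the
empirical variance to hit a target R² of degraded-on-true regression;
offspring-report discretization rounds to the nearest integer on the
unit-variance scale, which concentrates ~99% of mass in six bins — an
emulation of pound-rounded reports, since the exact real-world bin edges are
not reproduced. Four missingness designs mask phenotypes completely at
random in fixed fractions (½ both + ½ own-only; ½ both + ½ offspring-only;
½/¼/¼; ½ own-only + ½ offspring-only with no overlap), assigned by index
blocks after a seeded shuffle for reproducibility.

Not emulated: gestational age, sex effects, informative missingness,
X-linked loci, genotyping error, population structure. Passing tests
therefore demonstrate correctness of the estimator under its own
assumptions, not robustness to those real-data complications.

## Monte-Carlo harness

`run_scenario` derives replicate seeds as `seed + replicate index`, fits the
requested model variants per replicate, and aggregates rejection rates at
α = 0.05, mean estimates, bias with a 95% CI, and mean standard errors.
Non-converged replicates are excluded and counted; a scenario under 90%
convergence is flagged. A rate P at R replicates carries Monte-Carlo
standard error √(P(1−P)/R); all internal comparisons use three of these (or
three empirical SEs for means).

Problem sizes: the package's own checks run the published scenario grid at
desk scale — 500–1000 replicates for single-test powers and type-1 error,
300–400 for the 2-df powers, 150 per cell for the 3×3 bias grid, 10⁷
families for the moment closed-form check, 10⁶ for ρ recovery. The
no-overlap design's tiny maternal bias (~2–3% of the true value) needs ~10⁴
replicates to resolve; the desk-scale check bounds it by 3% of truth plus
Monte-Carlo noise at the replicate count actually run.

## Design choices and limitations

- Paths, not variance fractions, are the free parameters; the fraction→path
  conversion lives in the scenario layer so that fitted coefficients stay on
  the conditional-regression scale.
- Φ is freely estimated rather than fixed to the sample dosage variance; on
  standardized simulated data it lands on 1 to sampling error, and on raw
  dosages it absorbs `2p(1−p)`.
- The summary-statistics bridge assumes the contributing cohort's phenotype
  is standardized and its dosage on the raw 0–2 scale; mixing dosage scales
  across groups is the caller's responsibility.
- Phenotype cleaning reuses the own-report rules for offspring reports
  (0.5 kg repeat-report discordance, 2.5–4.5 kg window) and residualizes own
  birthweight on sex with a simple additive adjustment before z-scoring.
- Low minor allele frequency (<5%) degrades optimisation stability; the
  restart loop mitigates but does not eliminate this.
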