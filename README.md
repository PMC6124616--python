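# dyadsem

Jointly estimate **maternal** and **fetal** genetic effects on a perinatal
phenotype — birthweight is the motivating case — from cohorts where genotypes
are observed in only one generation.

## The problem

A variant associated with birthweight may act through the individual's own
genotype (a *fetal* effect, `f`), through their mother's genotype via the
intrauterine environment (a *maternal* effect, `m`), or both. The standard
design regresses a person's birthweight (or, for mothers, their offspring's
birthweight) on that person's own dosage. Because a mother and her child share
half their alleles, each of those regressions is biased whenever the other
effect exists: the expected slopes are `f + m/2` and `m + f/2`, not `f` and
`m`.

`dyadsem` fits a structural equation model in which the untyped relatives'
genotypes — the individual's mother's (`G_G`) and the individual's
offspring's (`G_O`) — are latent variables tied to the observed dosage
(`SNP`) by Mendelian transmission paths fixed at ½. All genotype variables
share a variance Φ, giving

```
Cov(G_G, SNP) = Cov(SNP, G_O) = Φ/2        Cov(G_G, G_O) = Φ/4
```

and the observed-variable moments

```
Var(BW)        = Φ(m² + f² + mf) + σ²_ε        Cov(BW,  SNP) = Φ(f + m/2)
Var(BW_O)      = Φ(m² + f² + mf) + σ²_εo       Cov(BW_O,SNP) = Φ(m + f/2)
Cov(BW, BW_O)  = Φ((m² + f²)/2 + (5/4)mf) + ρ  Var(SNP)      = Φ
```

where `BW` and `BW_O` are the individual's own and their offspring's
phenotype and ρ is the covariance of the two phenotype residuals (residual
mother–offspring similarity). Maximising the multivariate-normal likelihood
over (m, f, Φ, σ²_ε, σ²_εo, ρ, means) separates the two effects without any
offspring genotypes.

Individuals missing one of the two phenotypes still contribute through the
likelihood of their observed pair (full-information maximum likelihood), and
cohorts that can only share unconditional GWAS summary statistics (allele
frequency, beta, phenotype variance, N) enter as reconstructed covariance
groups — see `summary_stats_to_group`.

## Worked example

```python
from dyadsem import (MaternalFetalSEM, ScenarioConfig, simulate_dataset,
                     fit_model, wald_test, lrt, summaries_from_data, NULL)

# 30 000 dyads; the fetal path explains 0.04% of variance, the maternal 0.02%
config = ScenarioConfig(n_families=30_000, v_fetal=0.0004, v_maternal=0.0002,
                        seed=42)
data = simulate_dataset(config)

sem = MaternalFetalSEM(random_state=0).fit(data)
print(f"fetal effect    f = {sem.f_:+.4f} (SE {sem.se_f_:.4f})")
print(f"maternal effect m = {sem.m_:+.4f} (SE {sem.se_m_:.4f})")
print(f"residual covariance rho = {sem.params_.rho:.3f}")

full = sem.result_
print(f"Wald fetal    P = {wald_test(full, 'fetal').p_value:.4f}")
print(f"Wald maternal P = {wald_test(full, 'maternal').p_value:.4f}")
null = fit_model(summaries_from_data(data), NULL)
omnibus = lrt(full, null)
print(f"2-df omnibus  chi2 = {omnibus.statistic:.1f}, P = {omnibus.p_value:.2e}")
```

prints

```
fetal effect    f = +0.0168 (SE 0.0077)
maternal effect m = +0.0150 (SE 0.0077)
residual covariance rho = 0.243
Wald fetal    P = 0.0295
Wald maternal P = 0.0504
2-df omnibus  chi2 = 27.6, P = 1.01e-06
```

The generating values were f = 0.020 and m = 0.014; both estimates land
within one standard error of truth, and ρ̂ recovers the simulated
shared-confounder covariance 0.5 × 0.5 = 0.25. The single-path Wald tests are
borderline at these small effect sizes while the 2-df omnibus test detects
the variant decisively — exactly the behaviour the Monte-Carlo study
quantifies.

## Command line

```bash
dyadsem simulate --n-families 30000 --v-fetal 0.0004 --seed 1 --out sim.tsv
dyadsem fit --data sim.tsv --out estimates.tsv
dyadsem power-study --config grid.yaml --out power.tsv
dyadsem clean --data reports.tsv --out cleaned.tsv
```

`power-study` runs a full Monte-Carlo grid (effect sizes × allele frequency ×
measurement error × missingness) and writes bias, power and type-1-error
tables; `clean` applies the self-reported-birthweight rules (multiple births
excluded, repeat reports reconciled within 0.5 kg, 2.5–4.5 kg plausibility
window).

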