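# varhet

Variance-heterogeneity screening for potentially interacting SNPs.

## The problem

Genome-wide searches for gene-gene or gene-environment interaction are
crippled by the size of the search space: testing every SNP against
every candidate interactor squares (or worse) the number of tests. But a
SNP that interacts with *some* factor leaves a fingerprint that needs no
knowledge of the factor: within the carrier genotype classes the trait
is a mixture over factor levels, so its **variance** is inflated. A
per-SNP test of variance homogeneity across genotypes (a "vQTL" scan)
can therefore pre-screen for interaction candidates, after which the
search for the interacting partner is restricted to the hits.

`varhet` is for statistical geneticists and epidemiologists who want to
run that screen, calibrate it, and understand its power limits. It
provides:

- the three variance-homogeneity tests in 2-df and 1-df forms —
  Bartlett, Bartlett after rank-based inverse-normal transformation,
  and Levene/Brown-Forsythe (the robust default);
- the generative trait model
  `y = mu + beta_g*g + beta_F*F + beta_gF*g*F + eps` with
  `g ~ Binomial(2, P_B)`, normal factor `F`, and normal/t/chi-square
  standardized residuals, plus a type-I-error and power simulation
  harness;
- closed-form noncentrality (NCP) and power theory: per-genotype
  variances, the expected Bartlett NCP, the direct interaction test's
  `NCP = beta_gF^2 N 2 P_B (1-P_B) sigma_F^2 / sigma_eps^2`, and the
  optimal factor effects maximizing the screen's power;
- a genome-wide scan CLI over VCF or TSV genotypes.

Two facts the theory makes precise: the screen's power depends strongly
and non-monotonically (M-shaped) on the *unobservable* main effect of
the interacting factor, and with a single interacting factor it never
exceeds the power of the direct test — there is even a blind spot
(`beta_F = -beta_gF/2` for a binary factor) where a real interaction
produces exactly equal variances.

## Worked example

How good can the screen ever be? Calibrate the interaction effect so
that the *direct* test (which observes the factor) has 80% power at
alpha = 0.05 for a 5% interacting allele in N = 10,000 people, then hand
the variance screen its best case — the factor main effect maximizing
its NCP:

```
$ varhet power --pb 0.05 --alpha 0.05
beta_gF for 80% direct power: 0.0908953
variance-test power at optimal beta_F: 0.414
```

Even in its best case the screen reaches 41% power where the direct
test has 80% — and away from the optimal factor effect it can be far
lower. Simulating one cohort under a strong interaction and testing it:

```
$ varhet simulate --n 10000 --pb 0.1 --beta-f 1 --beta-gf 0.5 --seed 42 --out cohort.tsv
$ varhet test --in cohort.tsv --method levene --contrast 2df
method   contrast  stat     df  p            n0    n1    n2   var0     var1     var2
levene   2df       125.875  2   1.02368e-54  8120  1777  103  1.96475  3.26975  4.73395
```

The per-genotype variances climb from 1.96 (AA) through 3.27 (AB) to
4.73 (BB) — close to the theoretical values (2, 3.25, 5) from
`varhet.genotype_variances` — and Levene's test rejects homogeneity
overwhelmingly.

The same machinery in Python:

```python
from varhet import ModelParams, simulate_trait, levene_test, table1_power

cohort = simulate_trait(ModelParams(beta_f=1.0, beta_gf=0.5, p_b=0.1), 10_000, seed=42)
res = levene_test(cohort.y, cohort.g)     # TestResult(statistic, df, p_value, ...)
ceiling = table1_power(0.05, alpha=0.05)  # 0.414
```

Other subcommands: `varhet type1 --config exp.yaml` (type-I-error grid
over residual families x allele frequencies x SNP effects),
`varhet validate-ncp` (analytic NCP vs simulation), `varhet power-curves`
(NCP/power tables for plotting), and

```
varhet scan --vcf data.vcf --pheno pheno.tsv --id-col IID --pheno-col crp \
            --log-transform --test levene --min-group-n 30 --out scan.tsv --qq qq.tsv
```

for a genome-wide scan (per-SNP group sizes, variances, MAF, statistic,
p, genome-wide flag at 5e-8, and BH q-values).

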