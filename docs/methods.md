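# Methods

## The screening idea

If a SNP interacts with some factor in determining a quantitative trait,
the trait distribution within a carrier genotype class is a mixture over
the (unobserved) factor levels, so its variance is inflated relative to
non-carriers. A per-SNP test of variance homogeneity across the three
genotype classes therefore screens for *potentially* interacting SNPs
without knowing the interacting variable. `varhet` implements the tests,
the generative model used to calibrate them, the closed-form power theory
relating the screen to the direct interaction test, and a genome-wide
scan front-end.

## Generative model

For individual *i*,

    y_i = mu + beta_g * g_i + beta_F * F_i + beta_gF * g_i * F_i + eps_i

with `g_i ~ Binomial(2, P_B)` (HWE allele counts of the interacting
allele B; genotypes AA/AB/BB coded 0/1/2), `F_i ~ N(mu_F, sigma2_F)`, and
`eps_i` a standardized residual. The three components are independent.
Without loss of generality the defaults are `mu = mu_F = 0`,
`sigma2_F = 1`, `sigma2_eps = 1`.

Residual families: normal, Student t (df 2, 5, 10) and chi-square
(df 1, 5, 15), covering symmetric heavy tails and skew. Each is
standardized to mean 0 and variance 1: chi-square by its theoretical
moments (`(x - df)/sqrt(2 df)`), t with df > 2 by `sqrt(df/(df-2))`. t
with df <= 2 has no finite variance, so no theoretical standardization
exists; we standardize those samples by their empirical mean and SD.
This is a package design choice — it makes every simulated residual
vector have unit sample variance by construction, which is the property
the calibration study actually needs — and it is unit-tested.

A SNP main effect explaining a fraction `r2` of trait variance is mapped
to the coefficient scale by

    beta_g = sqrt( r2 * sigma2_eps / ((1 - r2) * 2 P_B (1 - P_B)) ).

RNG discipline: one integer seed (or `SeedSequence`) spawns three
independent substreams for g, F and eps, so changing one component's
parameters never perturbs the others' draws; the experiment harness
derives per-replicate streams from `(seed, cell_index, replicate_index)`
so any grid cell reproduces in isolation.

## Variance-homogeneity tests

* **Bartlett** (2 df): the classic likelihood-ratio-type statistic with
  unbiased group variances (divisor `n_j - 1`) and the Bartlett
  correction denominator, referred to chi-square(k-1). Most powerful for
  normal traits; its type I error inflates with skewness and heavy
  tails.
* **rank-INT + Bartlett**: the whole trait is replaced by normal
  quantiles at plotting positions `(rank - 0.5)/n` (average ranks for
  ties), then Bartlett is applied. The transform is deliberately global:
  when the SNP has a main effect the common transform distorts the
  per-genotype distributions, and the test over-rejects even though the
  marginal distribution is exactly normal. This artifact is a finding,
  not a bug; the plotting position is a documented choice (Blom's
  `(r - 3/8)/(n + 1/4)` would serve equally and differs negligibly at
  n = 10,000).
* **Levene / Brown-Forsythe** (2 df): one-way ANOVA on
  `Z_i = |y_i - median(y | g_i)|`, referred to F(k-1, N-k). Robust to
  non-normality; the recommended screen and the scan default. At
  N = 10,000 the F and chi-square(k-1) references agree to 3 decimals
  (property-tested).

**1-df contrasts** test one genotype class against the other two pooled.
Each genotype group is first centered at its own location (mean for
Bartlett, median for Levene) so that a mean difference between the two
pooled genotypes cannot masquerade as variance heterogeneity; the
2-group test is then applied. For Bartlett the pooled complement's
variance uses divisor `n_pool - 2`, charging it the two location
parameters estimated inside it; the analytic 1-df NCP uses the same
convention so theory and simulation agree by construction.

Degenerate inputs: groups with fewer than 2 observations are dropped
(reducing k); fewer than 2 usable groups raises `DegenerateGroupError`;
a zero group variance raises `ZeroVarianceError` for Bartlett (the log
is undefined) rather than returning infinity. A zero Levene denominator
with zero numerator returns statistic 0, p = 1.

## Power theory

With a normal residual the within-genotype trait variance is
`(beta_F + beta_gF * g)^2 sigma2_F + sigma2_eps`, i.e.

    var_AA = beta_F^2 s2F + s2e
    var_AB = var_AA + beta_gF^2 s2F + 2 beta_gF beta_F s2F
    var_BB = var_AA + 4 beta_gF^2 s2F + 4 beta_gF beta_F s2F.

Substituting these population variances and continuous HWE-expected
group sizes `N * ((1-P_B)^2, 2 P_B (1-P_B), P_B^2)` into the Bartlett
statistic gives the expected noncentrality parameter (NCP) of the
variance test; power is the noncentral chi-square tail beyond the null
quantile. The correction denominator is included (it is ~1 at
N = 10,000) so the analytic NCP matches the statistic the simulation
computes; `E[chi2_df(ncp)] = df + ncp` is the validation identity used
by `ncp_validation`.

The direct interaction test — the 1-df Wald test of the g*F product in
a regression that observes F — has

    NCP = beta_gF^2 * N * 2 P_B (1 - P_B) * s2F / s2e,

the variance of g*F after projecting out F. It does not depend on
beta_F; the variance test's NCP does, non-monotonically: the curve in
beta_F is M-shaped, with two maxima and an interior minimum (at
beta_F values where carrier and non-carrier variances cancel). The
stationary factor effects for the two 1-df extremes solve

    beta_F^2 + beta_gF beta_F - s2e/s2F = 0              (AA vs AB)
    beta_F^2 + 3 beta_gF beta_F + 2 beta_gF^2 - s2e/s2F = 0  (AB vs BB)

(both with discriminant `beta_gF^2 + 4 s2e/s2F`; we carry the ratio
`s2e/s2F`, which is what maximizing the printed variance-ratio
expressions yields and is dimensionally consistent — at the default
`s2F = 1` it is indistinguishable from a product convention). The 2-df
optimum has no closed form; `optimal_beta_f_2df` finds it by a dense
grid over `[-10, 10]` x the `sigma_eps*sigma_F` scale refined by bounded
scalar minimization (xatol 1e-10).

The benchmark table (`table1_power`) composes: calibrate `beta_gF` so
the direct test has 80% power at the chosen alpha (noncentral chi-square
inversion by Brent bisection) -> maximize the 2-df expected NCP over
`beta_F` -> convert to 2-df noncentral power. N = 10,000 is used; the
construction is asymptotically N-invariant because the direct-power
constraint pins `beta_gF^2 * N` (checked: results move < 0.005 between
N = 10,000 and 100,000).

**Blind spot.** For a binary factor F in {-1, +1} with P(F=+1) = f and a
dominant-coded genotype, `Var(y|carrier) = s2e + 4 (beta_F+beta_gF)^2
f(1-f)` and `Var(y|non-carrier) = s2e + 4 beta_F^2 f(1-f)` are equal
whenever `beta_F = -beta_gF/2`, so the screen has power alpha while the
direct test has essentially full power; with f != 1/2 the interaction
leaks into a marginal mean effect instead. Absence of variance
heterogeneity therefore never excludes interaction.

## Simulation harness

`type1_error_grid` crosses allele frequencies {5, 10, 25, 50}%, SNP
main effects explaining {0, 1, 5}% of variance, and the seven residual
families, with `beta_F = beta_gF = 0` (homogeneity holds everywhere).
Reference replicate scale is 10,000 cohorts of N = 10,000; the default
here is 2,000 replicates (binomial SE ~0.005 at the 5% level), chosen
as the package's single-CPU working scale, with the full scale one
config key away. Replicates where a test cannot be formed are dropped
and counted; a cell aborts if more than 1% fail. Rates below 100
replicates are refused.

## Genome-wide scan

Inputs: VCF (GT field, phased or unphased; multi-allelic sites skipped
with a logged reason) via cyvcf2, or a plain TSV allele-count matrix;
phenotype as a TSV keyed by sample ID, optionally natural-log
transformed (`--log-transform`; natural log, not log10 — stated because
the choice changes per-group location-scale structure, though any
monotone choice leaves ranks intact). Samples are intersected; missing
calls are excluded pairwise per SNP. Default test is Levene 2-df;
genotype classes below `--min-group-n` (default 30; variance estimates
below that are unstable) are dropped, and SNPs left with fewer than two
classes are reported with a skip reason. No QC is applied silently —
every filter is an explicit flag. Output columns follow the fixed
per-SNP schema plus a clearly supplementary Benjamini-Hochberg q-value
column; the genome-wide flag uses 5e-8. `qq_table` emits expected vs
observed -log10 p for calibration plots.

## What the synthetic data does and does not emulate

The generator reproduces the study conditions: a single biallelic SNP in
HWE, one independent interacting factor, iid residuals from the seven
families. It does not emulate LD between SNPs, non-HWE genotypes,
covariates, relatedness or population structure, heteroscedasticity of
mean-variance type, or imputation dosage uncertainty. Calibration
results here therefore certify the tests' behavior under the model, not
under every real-data pathology — in particular, a mean-variance
relationship in a real trait can produce variance heterogeneity at a
purely main-effect SNP, which is why the scan reports group variances
and sizes for inspection rather than a bare p-value.

## Numerical choices

- Bartlett statistics are clamped at 0 against tiny negative float noise.
- `power_from_ncp(0, ...)` returns alpha exactly (the noncentral sf is
  bypassed at ncp = 0).
- `ncp_for_power` brackets by doubling and solves with Brent (xtol
  1e-12); the round trip reproduces the target power to 1e-8.
- Continuous (non-integer) expected group sizes are used in all analytic
  NCPs.
- Scan output is byte-deterministic: no hidden randomness anywhere in
  the scan path.
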