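"""Closed-form power theory for the variance-heterogeneity screen.

Under the generative model with a normal residual, the trait variance
within each genotype class is

    var_AA = beta_f^2 s2_F + s2_e
    var_AB = var_AA + beta_gf^2 s2_F + 2 beta_gf beta_f s2_F
    var_BB = var_AA + 4 beta_gf^2 s2_F + 4 beta_gf beta_f s2_F

(equivalently ``(beta_f + beta_gf * g)^2 s2_F + s2_e`` for g copies of the
interacting allele).  Substituting these population variances, together
with HWE-expected group sizes, into Bartlett's statistic yields the
expected noncentrality parameter (NCP) of the variance test; power is then
the noncentral chi-square upper tail beyond the null quantile.

The *direct* interaction test — the Wald test of the g*F product term in a
regression that observes the factor — has

    NCP = beta_gf^2 * N * 2 P_B (1 - P_B) s2_F / s2_e,

independent of the factor's main effect beta_f.  The variance test's NCP,
by contrast, depends on beta_f non-monotonically (an M-shaped curve with
two maxima), and with a single interacting factor its power never exceeds
the direct test's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import ModelParams

__all__ = [
    "VarianceTriple",
    "NcpResult",
    "OptimalFactorEffect",
    "genotype_variances",
    "hwe_group_sizes",
    "direct_test_ncp",
    "expected_variance_ncp",
    "optimal_beta_f_closed",
    "optimal_beta_f_2df",
    "power_from_ncp",
    "ncp_for_power",
    "beta_gf_for_direct_power",
    "table1_power",
    "binary_factor_conditional_variances",
    "power_curves",
]

CONTRASTS = ("2df", "AA_vs_rest", "AB_vs_rest", "BB_vs_rest")


@dataclass(frozen=True)
class VarianceTriple:
    var_aa: float
    var_ab: float
    var_bb: float

    def as_array(self) -> np.ndarray:
        return np.array([self.var_aa, self.var_ab, self.var_bb])


@dataclass(frozen=True)
class NcpResult:
    """Noncentrality parameter and power of one test at given design."""

    ncp: float
    df: int
    power: float
    alpha: float
    n: int
    params: ModelParams


@dataclass(frozen=True)
class OptimalFactorEffect:
    """Stationary factor effects maximizing variance heterogeneity."""

    contrast: str
    roots: tuple


def genotype_variances(params: ModelParams) -> VarianceTriple:
    """Population trait variance in each genotype class (normal residual)."""
    s2f, s2e = params.sigma2_f, params.residual.sigma2_eps
    bf, bgf = params.beta_f, params.beta_gf
    var_aa = bf**2 * s2f + s2e
    return VarianceTriple(
        var_aa=var_aa,
        var_ab=var_aa + bgf**2 * s2f + 2.0 * bgf * bf * s2f,
        var_bb=var_aa + 4.0 * bgf**2 * s2f + 4.0 * bgf * bf * s2f,
    )


def hwe_group_sizes(n: int, p_b: float) -> np.ndarray:
    """Expected (continuous) genotype-class sizes under HWE."""
    return n * np.array([(1.0 - p_b) ** 2, 2.0 * p_b * (1.0 - p_b), p_b**2])


def power_from_ncp(ncp: float, df1: int, alpha: float) -> float:
    """Upper-tail power of a noncentral chi-square test at level alpha."""
    if ncp < 0:
        raise ValueError(f"ncp must be >= 0, got {ncp}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if ncp == 0.0:
        return alpha
    crit = stats.chi2.isf(alpha, df1)
    return float(stats.ncx2.sf(crit, df1, ncp))


def ncp_for_power(target_power: float, df1: int, alpha: float) -> float:
    """Invert power_from_ncp: NCP at which the test reaches target power."""
    if not alpha <= target_power < 1.0:
        raise ValueError("target power must lie in [alpha, 1)")
    if target_power == alpha:
        return 0.0
    f = lambda ncp: power_from_ncp(ncp, df1, alpha) - target_power
    hi = 8.0
    while f(hi) < 0:
        hi *= 2.0
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-12))


def direct_test_ncp(params: ModelParams, n: int, alpha: float = 0.05) -> NcpResult:
    """NCP and power of the 1-df Wald test of the g*F interaction term.

    With ``var(g*F) = 2 P_B (1 + P_B) s2_F`` and ``cov(F, g*F) = 2 P_B s2_F``
    the part of g*F orthogonal to F has variance ``2 P_B (1 - P_B) s2_F``,
    hence ``NCP = beta_gf^2 N 2 P_B (1 - P_B) s2_F / s2_e``.
    """
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    pb, s2f = params.p_b, params.sigma2_f
    var_gf = 2.0 * pb * (1.0 + pb) * s2f
    cov_f_gf = 2.0 * pb * s2f
    ncp = params.beta_gf**2 * n * (var_gf - cov_f_gf**2 / s2f) / params.residual.sigma2_eps
    return NcpResult(
        ncp=float(ncp), df=1, power=power_from_ncp(ncp, 1, alpha), alpha=alpha, n=n, params=params
    )


def _bartlett_population(variances, sizes, dfs=None) -> float:
    """Bartlett statistic evaluated at population variances and expected n_j.

    Group sizes may be continuous; dfs default to n_j - 1.  The Bartlett
    correction denominator is included (it is ~1 at the sample sizes of
    interest but keeps the analytic NCP aligned with the statistic the
    simulation actually computes).
    """
    v = np.asarray(variances, dtype=float)
    nj = np.asarray(sizes, dtype=float)
    dfs = nj - 1.0 if dfs is None else np.asarray(dfs, dtype=float)
    k = len(v)
    df_tot = dfs.sum()
    pooled = np.sum(dfs * v) / df_tot
    stat = df_tot * math.log(pooled) - np.sum(dfs * np.log(v))
    corr = 1.0 + (np.sum(1.0 / dfs) - 1.0 / df_tot) / (3.0 * (k - 1))
    return max(float(stat / corr), 0.0)


def expected_variance_ncp(
    params: ModelParams, n: int, contrast: str = "2df", alpha: float = 0.05
) -> NcpResult:
    """Expected NCP of the variance-homogeneity test (Bartlett form).

    Population genotype variances and HWE-expected (continuous) group
    sizes are substituted into Bartlett's statistic.  For 1-df contrasts
    the complement's variance is the size-weighted mixture of its two
    population variances — mean-centering per genotype removes the
    between-genotype mean spread, so no mean-shift term enters — and its
    df is (n_pool - 2), matching the empirical test's convention.
    """
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    if contrast not in CONTRASTS:
        raise ValueError(f"contrast must be one of {CONTRASTS}, got {contrast!r}")
    v = genotype_variances(params).as_array()
    nj = hwe_group_sizes(n, params.p_b)
    if contrast == "2df":
        ncp = _bartlett_population(v, nj)
        df = 2
    else:
        t = CONTRASTS.index(contrast) - 1
        others = [j for j in range(3) if j != t]
        n_pool = nj[others].sum()
        v_pool = np.sum(nj[others] * v[others]) / n_pool
        ncp = _bartlett_population(
            [v[t], v_pool], [nj[t], n_pool], dfs=[nj[t] - 1.0, n_pool - 2.0]
        )
        df = 1
    return NcpResult(
        ncp=ncp, df=df, power=power_from_ncp(ncp, df, alpha), alpha=alpha, n=n, params=params
    )


def optimal_beta_f_closed(
    beta_gf: float,
    sigma2_eps: float = 1.0,
    sigma2_f: float = 1.0,
    contrast: str = "AA_vs_AB",
) -> OptimalFactorEffect:
    """Closed-form stationary factor effects for the two 1-df extremes.

    When the BB class is negligible (P_B^2 << 2 P_B (1-P_B)), heterogeneity
    is driven by the relative variance gap (var_AB - var_AA)/var_AA, whose
    stationary points in beta_f solve

        beta_f^2 + beta_gf beta_f - s2_e/s2_F = 0          (AA vs AB)

    and when AA is negligible, (var_BB - var_AB)/var_AB gives

        beta_f^2 + 3 beta_gf beta_f + 2 beta_gf^2 - s2_e/s2_F = 0   (AB vs BB)

    Both quadratics share the discriminant beta_gf^2 + 4 s2_e/s2_F.
    """
    if contrast not in ("AA_vs_AB", "AB_vs_BB"):
        raise ValueError(f"contrast must be 'AA_vs_AB' or 'AB_vs_BB', got {contrast!r}")
    disc = math.sqrt(beta_gf**2 + 4.0 * sigma2_eps / sigma2_f)
    shift = beta_gf if contrast == "AA_vs_AB" else 3.0 * beta_gf
    roots = ((-shift + disc) / 2.0, (-shift - disc) / 2.0)
    return OptimalFactorEffect(contrast=contrast, roots=roots)


def optimal_beta_f_2df(
    params: ModelParams, n: int, grid_points: int = 2001, span: float = 10.0
) -> OptimalFactorEffect:
    """Factor effect maximizing the 2-df expected NCP, found numerically.

    The NCP is M-shaped in beta_f: a dense grid over
    ``[-span*s, span*s]`` (s = sigma_eps * sigma_f scale) locates the
    global maximum, which bounded scalar minimization then refines.
    """
    if params.beta_gf == 0.0:
        raise ValueError("objective is flat when beta_gf = 0; no optimum exists")

    def ncp_at(bf: float) -> float:
        p = ModelParams(
            mu=params.mu,
            beta_g=params.beta_g,
            beta_f=bf,
            beta_gf=params.beta_gf,
            p_b=params.p_b,
            mu_f=params.mu_f,
            sigma2_f=params.sigma2_f,
            residual=params.residual,
        )
        return expected_variance_ncp(p, n, "2df").ncp

    scale = math.sqrt(params.residual.sigma2_eps * params.sigma2_f)
    grid = np.linspace(-span * scale, span * scale, grid_points)
    vals = np.array([ncp_at(b) for b in grid])
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid_points - 1)]
    res = optimize.minimize_scalar(
        lambda b: -ncp_at(b), bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
    )
    return OptimalFactorEffect(contrast="2df_numeric", roots=(float(res.x),))


def beta_gf_for_direct_power(
    p_b: float,
    n: int,
    alpha: float,
    target_power: float,
    sigma2_eps: float = 1.0,
    sigma2_f: float = 1.0,
) -> float:
    """Interaction effect at which the direct test reaches target power."""
    ncp = ncp_for_power(target_power, 1, alpha)
    return math.sqrt(ncp * sigma2_eps / (n * 2.0 * p_b * (1.0 - p_b) * sigma2_f))


def table1_power(
    p_b: float,
    alpha: float,
    n: int = 10_000,
    direct_power: float = 0.8,
    sigma2_eps: float = 1.0,
    sigma2_f: float = 1.0,
) -> float:
    """Power of the 2-df variance test at the optimal factor effect.

    The interaction effect is first calibrated so the direct test has the
    stated power at the same alpha; the variance test is then granted its
    best case — the factor main effect that maximizes its expected NCP.
    This is the ceiling of the screen's power relative to an oracle that
    observes the interacting factor.
    """
    bgf = beta_gf_for_direct_power(p_b, n, alpha, direct_power, sigma2_eps, sigma2_f)
    from .model import ResidualSpec

    params = ModelParams(
        beta_gf=bgf, p_b=p_b, sigma2_f=sigma2_f, residual=ResidualSpec(sigma2_eps=sigma2_eps)
    )
    bf_opt = optimal_beta_f_2df(params, n).roots[0]
    params_opt = ModelParams(
        beta_f=bf_opt,
        beta_gf=bgf,
        p_b=p_b,
        sigma2_f=sigma2_f,
        residual=ResidualSpec(sigma2_eps=sigma2_eps),
    )
    ncp = expected_variance_ncp(params_opt, n, "2df").ncp
    return power_from_ncp(ncp, 2, alpha)


def binary_factor_conditional_variances(
    beta_f: float, beta_gf: float, f_freq: float, sigma2_eps: float = 1.0
) -> tuple[float, float]:
    """Trait variances by carrier status for a binary factor F in {-1, +1}.

    With a dominant-coded genotype (g' = 1 for any B carrier) and P(F=+1)
    = f_freq:

        Var(y | g'=0) = s2_e + 4 beta_f^2 f (1-f)
        Var(y | g'=1) = s2_e + 4 (beta_f + beta_gf)^2 f (1-f)

    The two are equal whenever beta_f = -beta_gf/2 even though the
    interaction is present — the variance screen is then blind while the
    direct test retains full power.
    """
    if not 0.0 < f_freq < 1.0:
        raise ValueError(f"frequency of +1 must be in (0, 1), got {f_freq}")
    fq = 4.0 * f_freq * (1.0 - f_freq)
    return (sigma2_eps + beta_f**2 * fq, sigma2_eps + (beta_f + beta_gf) ** 2 * fq)


def power_curves(
    beta_f_values,
    beta_gf_values,
    p_b_values,
    n: int = 10_000,
    alpha: float = 0.05,
    sigma2_eps: float = 1.0,
    sigma2_f: float = 1.0,
) -> pd.DataFrame:
    """NCP/power table over a (beta_f, beta_gf, P_B) grid, plot-ready.

    One row per grid point per test: the direct interaction test and the
    variance test under each contrast (2df and the three 1-df forms).
    """
    from .model import ResidualSpec

    rows = []
    resid = ResidualSpec(sigma2_eps=sigma2_eps)
    for pb in p_b_values:
        for bgf in beta_gf_values:
            for bf in beta_f_values:
                params = ModelParams(
                    beta_f=bf, beta_gf=bgf, p_b=pb, sigma2_f=sigma2_f, residual=resid
                )
                direct = direct_test_ncp(params, n, alpha)
                rows.append(
                    dict(beta_f=bf, beta_gf=bgf, p_b=pb, test="direct", contrast="1df",
                         ncp=direct.ncp, df=1, power=direct.power)
                )
                for contrast in CONTRASTS:
                    res = expected_variance_ncp(params, n, contrast, alpha)
                    rows.append(
                        dict(beta_f=bf, beta_gf=bgf, p_b=pb, test="variance",
                             contrast=contrast, ncp=res.ncp, df=res.df, power=res.power)
                    )
    return pd.DataFrame(rows)
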