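"""Variance-homogeneity tests across genotype classes.

Three tests are provided, each in a 2-df (AA vs AB vs BB) and 1-df
(one genotype vs the pooled other two) form:

* Bartlett's test — the likelihood-ratio-type statistic

      T^2 = [ (N-k) ln s2_p - sum_j (n_j - 1) ln s2_j ] / C,
      C   = 1 + ( sum_j 1/(n_j-1) - 1/(N-k) ) / (3 (k-1)),

  with pooled variance ``s2_p = sum_j (n_j-1) s2_j / (N-k)``, referred to
  chi-square with k-1 df.  Powerful for normal traits, badly anti-
  conservative under skew or heavy tails.

* Bartlett's test after a rank-based inverse-normal transform (rank-INT)
  of the whole trait.  The marginal distribution becomes exactly normal,
  but when the SNP has a main effect the per-genotype distributions are
  distorted by the common transform, so the type I error is still
  inflated — this artifact is one of the method's documented pitfalls.

* Levene's test in the Brown-Forsythe form — one-way ANOVA on absolute
  deviations from per-genotype medians, ``Z_i = |y_i - med(y | g_i)|``,
  referred to F(k-1, N-k).  Robust to non-normality; the recommended
  screen for real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "TestResult",
    "DegenerateGroupError",
    "ZeroVarianceError",
    "bartlett_test",
    "rank_int",
    "rint_bartlett_test",
    "levene_test",
    "one_df_test",
    "CONTRAST_1DF",
]

CONTRAST_1DF = {0: "AA_vs_rest", 1: "AB_vs_rest", 2: "BB_vs_rest"}


class DegenerateGroupError(ValueError):
    """Fewer than two usable genotype groups (each needs n >= 2)."""


class ZeroVarianceError(ValueError):
    """A genotype group has zero variance; Bartlett's log is undefined."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of one variance-homogeneity test on one SNP."""

    method: str
    contrast: str
    statistic: float
    df1: int
    p_value: float
    df2: int | None = None  # None => chi-square reference
    group_sizes: tuple = ()
    group_variances: tuple = ()


def _split_groups(y, g, min_n: int = 2):
    """Per-genotype observation arrays, dropping groups smaller than min_n."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g)
    if y.shape != g.shape:
        raise ValueError("y and g must have the same length")
    groups = [y[g == lvl] for lvl in np.unique(g)]
    return [grp for grp in groups if grp.size >= min_n]


def _bartlett_from_ss(ss, dfs) -> float:
    """Bartlett statistic from per-group sums of squares and their dfs.

    Accepting explicit dfs lets the 1-df contrast charge the pooled
    complement two estimated means instead of one.
    """
    ss = np.asarray(ss, dtype=float)
    dfs = np.asarray(dfs, dtype=float)
    k = len(ss)
    variances = ss / dfs
    if np.any(variances <= 0):
        raise ZeroVarianceError(
            "a genotype group has zero variance; Bartlett's statistic is undefined"
        )
    df_tot = dfs.sum()
    pooled = ss.sum() / df_tot
    stat = df_tot * np.log(pooled) - np.sum(dfs * np.log(variances))
    corr = 1.0 + (np.sum(1.0 / dfs) - 1.0 / df_tot) / (3.0 * (k - 1))
    return max(stat / corr, 0.0)


def bartlett_test(y, g) -> TestResult:
    """Bartlett's 2-df test of equal trait variance across genotypes."""
    groups = _split_groups(y, g)
    k = len(groups)
    if k < 2:
        raise DegenerateGroupError(f"need >=2 genotype groups with n >= 2, got {k}")
    ss = [np.sum((grp - grp.mean()) ** 2) for grp in groups]
    dfs = [grp.size - 1 for grp in groups]
    stat = _bartlett_from_ss(ss, dfs)
    return TestResult(
        method="bartlett",
        contrast="2df" if k == 3 else f"{k}group",
        statistic=stat,
        df1=k - 1,
        p_value=float(stats.chi2.sf(stat, k - 1)),
        group_sizes=tuple(grp.size for grp in groups),
        group_variances=tuple(s / d for s, d in zip(ss, dfs)),
    )


def rank_int(y) -> np.ndarray:
    """Rank-based inverse-normal transform of a trait vector.

    Values are replaced by standard-normal quantiles at plotting positions
    ``(rank - 0.5) / n``; ties receive average ranks and therefore map to
    equal outputs.  Order is preserved, and the marginal distribution of a
    tie-free sample becomes exactly normal.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("rank-INT needs at least 2 observations")
    if np.all(y == y[0]):
        raise ValueError("rank-INT undefined for a constant vector")
    ranks = stats.rankdata(y, method="average")
    return special.ndtri((ranks - 0.5) / y.size)


def rint_bartlett_test(y, g) -> TestResult:
    """Bartlett's test applied to the rank-INT-transformed trait.

    The transform is applied to the whole trait before grouping — the
    per-genotype distortion this induces when the SNP has a main effect is
    intrinsic to the procedure, not a bug.
    """
    res = bartlett_test(rank_int(y), g)
    return TestResult(
        method="rint_bartlett",
        contrast=res.contrast,
        statistic=res.statistic,
        df1=res.df1,
        p_value=res.p_value,
        df2=res.df2,
        group_sizes=res.group_sizes,
        group_variances=res.group_variances,
    )


def _levene_anova(z_groups) -> tuple[float, int, int]:
    """One-way ANOVA F statistic on the per-group absolute deviations."""
    k = len(z_groups)
    sizes = np.array([z.size for z in z_groups], dtype=float)
    n_tot = sizes.sum()
    means = np.array([z.mean() for z in z_groups])
    grand = np.sum(sizes * means) / n_tot
    num = np.sum(sizes * (means - grand) ** 2)
    den = np.sum([np.sum((z - m) ** 2) for z, m in zip(z_groups, means)])
    if den == 0.0:
        if num == 0.0:
            return 0.0, k - 1, int(n_tot - k)
        raise ZeroVarianceError("Levene denominator is zero with nonzero numerator")
    stat = (n_tot - k) / (k - 1) * num / den
    return float(stat), k - 1, int(n_tot - k)


def levene_test(y, g) -> TestResult:
    """Levene's (Brown-Forsythe) 2-df test: ANOVA on |y - group median|."""
    groups = _split_groups(y, g)
    k = len(groups)
    if k < 2:
        raise DegenerateGroupError(f"need >=2 genotype groups with n >= 2, got {k}")
    z_groups = [np.abs(grp - np.median(grp)) for grp in groups]
    stat, df1, df2 = _levene_anova(z_groups)
    return TestResult(
        method="levene",
        contrast="2df" if k == 3 else f"{k}group",
        statistic=stat,
        df1=df1,
        df2=df2,
        p_value=float(stats.f.sf(stat, df1, df2)) if stat > 0 else 1.0,
        group_sizes=tuple(grp.size for grp in groups),
        group_variances=tuple(grp.var(ddof=1) for grp in groups),
    )


def one_df_test(y, g, target: int, method: str = "levene") -> TestResult:
    """1-df variance test of one genotype class against the other two pooled.

    Each genotype group is first centered at its own location (mean for
    Bartlett, median for Levene) so that mean differences between the two
    pooled genotypes cannot masquerade as variance heterogeneity; the
    two-group version of the chosen test is then applied.  For Bartlett the
    pooled complement's variance uses divisor (n_pool - 2), charging it the
    two location parameters estimated inside it.
    """
    if target not in (0, 1, 2):
        raise ValueError(f"target genotype must be 0, 1 or 2, got {target}")
    if method not in ("bartlett", "levene"):
        raise ValueError(f"method must be 'bartlett' or 'levene', got {method}")
    y = np.asarray(y, dtype=float)
    g = np.asarray(g)
    center = np.mean if method == "bartlett" else np.median
    tgt, rest = [], []
    for lvl in np.unique(g):
        grp = y[g == lvl]
        if grp.size < 2:
            continue
        centered = grp - center(grp)
        (tgt if lvl == target else rest).append(centered)
    if not tgt or not rest:
        raise DegenerateGroupError(
            f"target genotype {target} and its complement both need >= 2 observations"
        )
    z_t = np.concatenate(tgt)
    z_r = np.concatenate(rest)
    contrast = CONTRAST_1DF[target]
    n_t, n_r = z_t.size, z_r.size
    if method == "bartlett":
        dfs = [n_t - 1, n_r - len(rest)]
        if min(dfs) < 1:
            raise DegenerateGroupError("not enough observations after centering")
        # groups are already mean-centered, so SS is around zero
        ss = [np.sum(z_t**2), np.sum(z_r**2)]
        stat = _bartlett_from_ss(ss, dfs)
        return TestResult(
            method="bartlett",
            contrast=contrast,
            statistic=stat,
            df1=1,
            p_value=float(stats.chi2.sf(stat, 1)),
            group_sizes=(n_t, n_r),
            group_variances=tuple(s / d for s, d in zip(ss, dfs)),
        )
    stat, df1, df2 = _levene_anova([np.abs(z_t), np.abs(z_r)])
    return TestResult(
        method="levene",
        contrast=contrast,
        statistic=stat,
        df1=df1,
        df2=df2,
        p_value=float(stats.f.sf(stat, df1, df2)) if stat > 0 else 1.0,
        group_sizes=(n_t, n_r),
        group_variances=(z_t.var(ddof=1), z_r.var(ddof=1)),
    )
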