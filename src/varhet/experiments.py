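"""Monte-Carlo harness: type I error grids, empirical power, NCP checks.

The canonical type-I-error design crosses interacting-allele frequencies
{5%, 10%, 25%, 50%} with SNP main effects explaining {0%, 1%, 5%} of trait
variance and seven residual families (normal, t with df 2/5/10, chi-square
with df 1/5/15), with the factor and interaction effects set to zero —
variance homogeneity holds in every cell, so any excess rejection is test
miscalibration.  Cohorts of 10,000 individuals are the reference scale;
the default replicate count here is 2,000 (binomial SE ~ 0.005 at the 5%
level), with the full-scale 10,000 available through the config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .hettests import (
    DegenerateGroupError,
    bartlett_test,
    levene_test,
    one_df_test,
    rank_int,
    rint_bartlett_test,
)
from .model import ModelParams, ResidualSpec, beta_g_from_r2, simulate_trait

__all__ = [
    "ExperimentConfig",
    "PAPER_RESIDUAL_GRID",
    "run_single_test",
    "type1_error_grid",
    "empirical_power",
    "ncp_validation",
    "direct_interaction_test",
]

logger = logging.getLogger(__name__)

PAPER_RESIDUAL_GRID = (
    ResidualSpec("normal"),
    ResidualSpec("t", 2),
    ResidualSpec("t", 5),
    ResidualSpec("t", 10),
    ResidualSpec("chisq", 1),
    ResidualSpec("chisq", 5),
    ResidualSpec("chisq", 15),
)

_TESTS_2DF = {
    "bartlett": bartlett_test,
    "rint_bartlett": rint_bartlett_test,
    "levene": levene_test,
}


def run_single_test(y, g, test: str, contrast: str = "2df"):
    """Dispatch one (test, contrast) pair to the underlying procedure."""
    if contrast == "2df":
        try:
            fn = _TESTS_2DF[test]
        except KeyError:
            raise ValueError(f"unknown test {test!r}") from None
        return fn(y, g)
    target = {"AA_vs_rest": 0, "AB_vs_rest": 1, "BB_vs_rest": 2}.get(contrast)
    if target is None:
        raise ValueError(f"unknown contrast {contrast!r}")
    if test == "rint_bartlett":
        return one_df_test(rank_int(y), g, target, method="bartlett")
    return one_df_test(y, g, target, method=test)


@dataclass(frozen=True)
class ExperimentConfig:
    """Grid definition for a type-I-error study."""

    allele_freqs: tuple = (0.05, 0.10, 0.25, 0.50)
    r2_values: tuple = (0.0, 0.01, 0.05)
    residual_specs: tuple = PAPER_RESIDUAL_GRID
    n: int = 10_000
    reps: int = 2_000
    alpha_levels: tuple = (0.05, 0.01)
    tests: tuple = (("bartlett", "2df"), ("rint_bartlett", "2df"), ("levene", "2df"))
    seed: int = 0
    max_degenerate_frac: float = 0.01

    def __post_init__(self):
        if self.reps < 100:
            raise ValueError("need at least 100 replicates for a reported rate")
        if not (self.allele_freqs and self.r2_values and self.residual_specs):
            raise ValueError("all grids must be non-empty")


def _cell_pvalues(params: ModelParams, n: int, reps: int, tests, seed, cell_idx: int,
                  max_degenerate_frac: float = 0.01) -> dict:
    """P-values of every (test, contrast) over replicate cohorts of a cell.

    Replicate r of cell c draws from the substream (seed, c, r), so any
    cell is reproducible in isolation.  Replicates where a test cannot be
    formed (a genotype class too small) are dropped and counted; the cell
    aborts if more than ``max_degenerate_frac`` of them fail.
    """
    pvals = {tc: [] for tc in tests}
    degenerate = 0
    for r in range(reps):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(cell_idx, r))
        cohort = simulate_trait(params, n, ss)
        try:
            rep_p = {tc: run_single_test(cohort.y, cohort.g, *tc).p_value for tc in tests}
        except DegenerateGroupError:
            degenerate += 1
            continue
        for tc, p in rep_p.items():
            pvals[tc].append(p)
    if degenerate > max_degenerate_frac * reps:
        raise RuntimeError(
            f"{degenerate}/{reps} degenerate replicates in cell {cell_idx}; "
            "grid point not reportable"
        )
    if degenerate:
        logger.warning("cell %d: dropped %d degenerate replicates", cell_idx, degenerate)
    return {tc: np.array(p) for tc, p in pvals.items()}


def type1_error_grid(config: ExperimentConfig) -> pd.DataFrame:
    """Empirical type I error over the full factorial design.

    Returns one row per (test, contrast, residual family, P_B, r2, alpha)
    with the rejection rate, its binomial Monte-Carlo SE and the replicate
    count.  Deterministic given the config seed.
    """
    rows = []
    cell_idx = 0
    for spec in config.residual_specs:
        for pb in config.allele_freqs:
            for r2 in config.r2_values:
                beta_g = beta_g_from_r2(r2, pb, spec.sigma2_eps) if r2 > 0 else 0.0
                params = ModelParams(beta_g=beta_g, p_b=pb, residual=spec)
                pvals = _cell_pvalues(
                    params, config.n, config.reps, config.tests, config.seed, cell_idx,
                    config.max_degenerate_frac,
                )
                for (test, contrast), p in pvals.items():
                    for alpha in config.alpha_levels:
                        rate = float(np.mean(p < alpha))
                        rows.append(
                            dict(test=test, contrast=contrast, residual=spec.label,
                                 p_b=pb, r2=r2, alpha=alpha, empirical_rate=rate,
                                 mc_se=float(np.sqrt(rate * (1 - rate) / p.size)),
                                 reps=p.size)
                        )
                cell_idx += 1
    return pd.DataFrame(rows)


def empirical_power(
    params: ModelParams,
    n: int,
    reps: int,
    alpha: float,
    test: str = "bartlett",
    contrast: str = "2df",
    seed: int = 0,
) -> dict:
    """Rejection rate of one test under a fixed alternative."""
    if reps < 100:
        raise ValueError("need at least 100 replicates for a reported rate")
    pvals = _cell_pvalues(params, n, reps, [(test, contrast)], seed, 0)[(test, contrast)]
    rate = float(np.mean(pvals < alpha))
    return dict(test=test, contrast=contrast, alpha=alpha, empirical_rate=rate,
                mc_se=float(np.sqrt(rate * (1 - rate) / pvals.size)), reps=int(pvals.size))


def ncp_validation(params: ModelParams, n: int, reps: int, seed: int = 0,
                   contrast: str = "2df") -> dict:
    """Compare the analytic NCP with the mean simulated Bartlett statistic.

    A noncentral chi-square with df degrees of freedom and noncentrality
    ncp has mean df + ncp, so the mean statistic minus df estimates the
    NCP directly.
    """
    from .power import expected_variance_ncp

    analytic = expected_variance_ncp(params, n, contrast).ncp
    stats_ = []
    for r in range(reps):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(0, r))
        cohort = simulate_trait(params, n, ss)
        res = run_single_test(cohort.y, cohort.g, "bartlett", contrast)
        stats_.append(res.statistic)
    stats_ = np.array(stats_)
    df = 2 if contrast == "2df" else 1
    return dict(
        analytic_ncp=float(analytic),
        mean_stat_minus_df=float(stats_.mean() - df),
        mc_se=float(stats_.std(ddof=1) / np.sqrt(reps)),
        reps=reps,
        contrast=contrast,
    )


def direct_interaction_test(y, g, f) -> dict:
    """Wald test of the interaction term in y ~ 1 + g + F + g*F (OLS).

    This is the oracle benchmark that observes the interacting factor; the
    variance screen is compared against it.  Returns the coefficient, its
    standard error and the two-sided p-value.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    X = np.column_stack([np.ones(n), np.asarray(g, dtype=float),
                         np.asarray(f, dtype=float),
                         np.asarray(g, dtype=float) * np.asarray(f, dtype=float)])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient (monomorphic SNP or constant F?)")
    resid = y - X @ coef
    dof = n - X.shape[1]
    sigma2 = resid @ resid / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[3, 3])
    tstat = coef[3] / se
    return dict(beta_gf_hat=float(coef[3]), se=float(se), t=float(tstat),
                p_value=float(2.0 * stats.t.sf(abs(tstat), dof)), dof=dof)
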