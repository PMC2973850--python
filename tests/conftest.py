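import numpy as np
import pytest

from varhet import ModelParams, ResidualSpec, simulate_trait


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def null_cohort():
    """A null-model cohort: no SNP, factor or interaction effect."""
    params = ModelParams(p_b=0.25, residual=ResidualSpec("normal"))
    return simulate_trait(params, 10_000, seed=7)


def bartlett_brute(groups):
    """Direct transcription of the Bartlett statistic for an oracle check.

    T^2 = [(N-k) ln s2_p - sum (n_j-1) ln s2_j] / C with
    s2_p = sum (n_j-1) s2_j / (N-k),
    C = 1 + (sum 1/(n_j-1) - 1/(N-k)) / (3(k-1)).
    """
    import math

    k = len(groups)
    n = [len(g) for g in groups]
    N = sum(n)
    s2 = [np.var(g, ddof=1) for g in groups]
    s2p = sum((nj - 1) * s for nj, s in zip(n, s2)) / (N - k)
    num = (N - k) * math.log(s2p) - sum((nj - 1) * math.log(s) for nj, s in zip(n, s2))
    corr = 1 + (sum(1 / (nj - 1) for nj in n) - 1 / (N - k)) / (3 * (k - 1))
    return num / corr


def levene_brute(groups):
    """Direct transcription of the Brown-Forsythe statistic (median centers)."""
    k = len(groups)
    n = [len(g) for g in groups]
    N = sum(n)
    z = [np.abs(np.asarray(g) - np.median(g)) for g in groups]
    zbar = [zz.mean() for zz in z]
    grand = sum(nj * m for nj, m in zip(n, zbar)) / N
    num = (N - k) * sum(nj * (m - grand) ** 2 for nj, m in zip(n, zbar))
    den = (k - 1) * sum(((zz - m) ** 2).sum() for zz, m in zip(z, zbar))
    return num / den
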