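"""Generative trait model for variance-heterogeneity screening.

The trait of individual *i* is generated as

    y_i = mu + beta_g * g_i + beta_f * F_i + beta_gf * g_i * F_i + eps_i

where ``g_i ~ Binomial(2, p_b)`` counts copies of the interacting allele B
(genotypes AA/AB/BB coded 0/1/2), ``F_i ~ N(mu_f, sigma2_f)`` is a
(possibly unobserved) interacting factor, and ``eps_i`` is a standardized
residual drawn from one of several families (normal, Student t, chi-square)
so that the robustness of variance tests to non-normal traits can be
studied.  The three components are mutually independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ResidualSpec",
    "ModelParams",
    "SimulatedCohort",
    "simulate_genotypes",
    "simulate_residuals",
    "simulate_factor",
    "simulate_binary_factor",
    "simulate_trait",
    "beta_g_from_r2",
]

# Residual grids used throughout the simulation study.
T_DF_GRID = (2, 5, 10)
CHISQ_DF_GRID = (1, 5, 15)


def _as_rng(seed) -> np.random.Generator:
    """Coerce an int seed, SeedSequence or Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ResidualSpec:
    """Residual-error distribution: family, degrees of freedom, variance.

    Draws are standardized to zero mean and unit variance, then scaled by
    ``sqrt(sigma2_eps)``.  Standardization uses theoretical moments where
    they exist (t with df > 2, all chi-square); for t with df <= 2 the
    theoretical variance is infinite, so the sample is standardized by its
    empirical mean and standard deviation instead.
    """

    family: str = "normal"
    df: float | None = None
    sigma2_eps: float = 1.0

    def __post_init__(self):
        if self.family not in ("normal", "t", "chisq"):
            raise ValueError(f"unknown residual family {self.family!r}")
        if self.family != "normal":
            if self.df is None or self.df <= 0:
                raise ValueError(f"{self.family} residuals need df > 0, got {self.df}")
        if self.sigma2_eps <= 0:
            raise ValueError("sigma2_eps must be > 0")

    @classmethod
    def parse(cls, text: str, sigma2_eps: float = 1.0) -> "ResidualSpec":
        """Parse a compact 'family[:df]' string, e.g. 'normal', 'chisq:5'."""
        family, _, df = text.partition(":")
        return cls(family=family, df=float(df) if df else None, sigma2_eps=sigma2_eps)

    @property
    def label(self) -> str:
        return self.family if self.family == "normal" else f"{self.family}:{self.df:g}"


@dataclass(frozen=True)
class ModelParams:
    """Full parameter vector of the generative trait model."""

    mu: float = 0.0
    beta_g: float = 0.0
    beta_f: float = 0.0
    beta_gf: float = 0.0
    p_b: float = 0.5
    mu_f: float = 0.0
    sigma2_f: float = 1.0
    residual: ResidualSpec = field(default_factory=ResidualSpec)

    def __post_init__(self):
        if not 0.0 <= self.p_b <= 1.0:
            raise ValueError(f"allele frequency p_b must be in [0, 1], got {self.p_b}")
        if self.sigma2_f <= 0:
            raise ValueError("sigma2_f must be > 0")


@dataclass(frozen=True)
class SimulatedCohort:
    """One simulated cohort: genotypes, factor, residuals and trait."""

    g: np.ndarray
    f: np.ndarray
    eps: np.ndarray
    y: np.ndarray
    params: ModelParams
    seed: object = None

    def __len__(self) -> int:
        return self.y.size


def simulate_genotypes(n: int, p_b: float, seed=None) -> np.ndarray:
    """Draw ``n`` allele counts, iid Binomial(2, p_b), i.e. HWE genotypes."""
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    if not 0.0 <= p_b <= 1.0:
        raise ValueError(f"allele frequency must be in [0, 1], got {p_b}")
    rng = _as_rng(seed)
    return rng.binomial(2, p_b, size=n).astype(np.int8)


def simulate_residuals(n: int, spec: ResidualSpec = ResidualSpec(), seed=None) -> np.ndarray:
    """Draw ``n`` standardized residuals from the requested family.

    Chi-square draws are centered by df and scaled by sqrt(2*df); t draws
    with df > 2 are scaled by sqrt(df / (df - 2)); t draws with df <= 2
    (infinite variance) are standardized empirically within the sample.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    rng = _as_rng(seed)
    if spec.family == "normal":
        x = rng.standard_normal(n)
    elif spec.family == "t":
        x = rng.standard_t(spec.df, size=n)
        if spec.df > 2:
            x /= np.sqrt(spec.df / (spec.df - 2.0))
        else:
            x = (x - x.mean()) / x.std(ddof=1)
    else:  # chisq
        x = (rng.chisquare(spec.df, size=n) - spec.df) / np.sqrt(2.0 * spec.df)
    return x * np.sqrt(spec.sigma2_eps)


def simulate_factor(n: int, mu_f: float = 0.0, sigma2_f: float = 1.0, seed=None) -> np.ndarray:
    """Draw ``n`` iid N(mu_f, sigma2_f) values of the interacting factor."""
    if sigma2_f <= 0:
        raise ValueError(f"factor variance must be > 0, got {sigma2_f}")
    rng = _as_rng(seed)
    return mu_f + np.sqrt(sigma2_f) * rng.standard_normal(n)


def simulate_binary_factor(n: int, f_freq: float, seed=None) -> np.ndarray:
    """Draw ``n`` iid values from {-1, +1} with P(+1) = f_freq.

    A two-point factor is the simplest exposure under which interaction can
    leave all genotype variances equal (see the analytic counterexample in
    :mod:`varhet.power`).
    """
    if not 0.0 < f_freq < 1.0:
        raise ValueError(f"frequency of +1 must be in (0, 1), got {f_freq}")
    rng = _as_rng(seed)
    return np.where(rng.random(n) < f_freq, 1.0, -1.0)


def simulate_trait(params: ModelParams, n: int, seed=None) -> SimulatedCohort:
    """Simulate a cohort of ``n`` individuals under the generative model.

    An integer seed (or SeedSequence) is split into three independent
    substreams for genotypes, factor and residuals, so changing the
    parameters of one component never perturbs the draws of the others.
    A Generator may also be passed; the three components then consume it
    sequentially.
    """
    if isinstance(seed, np.random.Generator):
        rng_g = rng_f = rng_e = seed
    else:
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        rng_g, rng_f, rng_e = (np.random.default_rng(c) for c in ss.spawn(3))
    g = simulate_genotypes(n, params.p_b, rng_g)
    f = simulate_factor(n, params.mu_f, params.sigma2_f, rng_f)
    eps = simulate_residuals(n, params.residual, rng_e)
    y = params.mu + params.beta_g * g + params.beta_f * f + params.beta_gf * g * f + eps
    return SimulatedCohort(g=g, f=f, eps=eps, y=y, params=params, seed=seed)


def beta_g_from_r2(r2: float, p_b: float, sigma2_eps: float = 1.0) -> float:
    """SNP main effect that explains a fraction ``r2`` of trait variance.

    Under HWE the additive genotype contributes variance
    ``beta_g**2 * 2 * p_b * (1 - p_b)``; solving
    ``r2 = var_g / (var_g + sigma2_eps)`` for ``beta_g`` gives

        beta_g = sqrt( r2 * sigma2_eps / ((1 - r2) * 2 * p_b * (1 - p_b)) )
    """
    if not 0.0 <= r2 < 1.0:
        raise ValueError(f"r2 must be in [0, 1), got {r2}")
    if not 0.0 < p_b < 1.0:
        raise ValueError(f"need polymorphic SNP (0 < p_b < 1), got {p_b}")
    return float(np.sqrt(r2 * sigma2_eps / ((1.0 - r2) * 2.0 * p_b * (1.0 - p_b))))
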