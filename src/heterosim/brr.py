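"""Bayesian ridge regression with additive and dominance effect classes.

Fits y_i = mu + sum_j X_ij a_j + sum_j Z_ij d_j + e_i by single-site Gibbs
sampling, where X is the allele-count coding (0/1/2 for aa/aA/AA) and Z the
heterozygosity indicator.  Both effect classes have Gaussian priors with a
shared class variance; the two class variances and the residual variance
carry scaled-inverse-chi-square hyperpriors (df 5) whose scales follow the
usual Bayesian-ridge rule of allocating an assumed model R2 (default 0.5,
split equally over the classes) over the column variances of each design.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import gibbs_brr
from .config import ChainConfig
from .errors import AlignmentError, ConfigurationError, DataError, DiagnosticError

__all__ = ["TrainingData", "MarkerEstimates", "make_training_data",
           "fit_brr_gibbs", "predict", "geweke_z"]


@dataclass
class TrainingData:
    """Design matrices and phenotypes for one training cohort."""
    X: np.ndarray            # (n, p) int8 allele counts 0/1/2
    Z: np.ndarray            # (n, p) int8 heterozygosity indicator
    y: np.ndarray            # (n,) float
    breed: str = ""
    generation: int = -1

    def __post_init__(self):
        if self.X.shape != self.Z.shape or self.X.shape[0] != self.y.shape[0]:
            raise AlignmentError("X, Z and y dimensions inconsistent")
        if not np.all((self.X == 1) == (self.Z == 1)):
            raise DataError("Z must be 1 exactly where X is 1 (heterozygotes)")
        if not np.all(np.isfinite(self.y)):
            raise DataError("non-finite phenotypes in training data")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def make_training_data(panel, snp_indices: np.ndarray, y: np.ndarray,
                       breed: str = "", generation: int = -1) -> TrainingData:
    X = panel.dosages(snp_indices)
    Z = (X == 1).astype(np.int8)
    return TrainingData(X=X, Z=Z, y=np.asarray(y, float),
                        breed=breed, generation=generation)


@dataclass
class MarkerEstimates:
    """Posterior means and chain summaries from one Gibbs fit."""
    mu: float
    a_hat: np.ndarray
    d_hat: np.ndarray
    chain: ChainConfig
    seed: int
    var_chains: dict = field(default_factory=dict)   # mu, s2a, s2d, s2e chains
    geweke: dict = field(default_factory=dict)

    @property
    def n_snps(self) -> int:
        return self.a_hat.shape[0]

    def frame(self):
        import pandas as pd
        return pd.DataFrame({"snp": np.arange(self.n_snps),
                             "a_hat": self.a_hat, "d_hat": self.d_hat})


def fit_brr_gibbs(data: TrainingData, chain: ChainConfig,
                  seed: int, fixed_variances: tuple | None = None) -> MarkerEstimates:
    """Run the Gibbs sampler and return posterior-mean marker effects.

    ``fixed_variances`` = (s2a, s2d, s2e) makes the hyperpriors degenerate
    (variance components held constant), in which case the posterior mean
    coincides with the closed-form ridge solution in expectation.
    A constant phenotype vector is legal: all effects shrink to zero.
    """
    chain.validate()
    if data.n < 2 or data.p < 1:
        raise ConfigurationError("need at least 2 records and 1 marker")
    # columns are centered for the Gibbs sweep (decorrelates the intercept
    # from the effects, which mixes far better); the reported intercept is
    # mapped back to the raw 0/1/2 coding
    mx = data.X.mean(axis=0, dtype=np.float64)
    mz = data.Z.mean(axis=0, dtype=np.float64)
    Xt = np.ascontiguousarray(data.X.T - mx[:, None], dtype=np.float32)
    Zt = np.ascontiguousarray(data.Z.T - mz[:, None], dtype=np.float32)
    y = np.asarray(data.y, dtype=np.float64)
    vy = float(np.var(y))
    if vy <= 0:
        vy = 1e-6  # degenerate constant y: arbitrary scale, effects shrink to 0
    df = chain.df
    r2_class = chain.r2 / 2.0
    msx = float(np.sum(np.var(Xt, axis=1)))
    msz = float(np.sum(np.var(Zt, axis=1)))
    # prior scale so that E[s2] * MS approximates the allotted variance
    # share; an all-constant design (e.g. no heterozygotes anywhere) keeps
    # the plain per-effect scale so its estimates shrink to the prior mean
    S_a = vy * r2_class * (df + 2.0) / df / (msx if msx > 0 else 1.0)
    S_d = vy * r2_class * (df + 2.0) / df / (msz if msz > 0 else 1.0)
    S_e = vy * (1.0 - chain.r2) * (df + 2.0) / df
    if fixed_variances is None:
        fix = False
        s2a0 = S_a * df / (df - 2.0)
        s2d0 = S_d * df / (df - 2.0)
        s2e0 = S_e * df / (df - 2.0)
    else:
        fix = True
        s2a0, s2d0, s2e0 = map(float, fixed_variances)
    a_hat, d_hat, mu_hat, mu_c, s2a_c, s2d_c, s2e_c = gibbs_brr(
        Xt, Zt, y, chain.n_iter, chain.burn_in,
        df, S_a, df, S_d, df, S_e, fix, s2a0, s2d0, s2e0, int(seed))
    # posterior mean of the raw-coding intercept (linearity of expectation)
    mu_hat = mu_hat - mx @ a_hat - mz @ d_hat
    var_chains = {"mu": mu_c, "s2a": s2a_c, "s2d": s2d_c, "s2e": s2e_c}
    geweke = {k: geweke_z(v[chain.burn_in:]) for k, v in var_chains.items()}
    return MarkerEstimates(mu=float(mu_hat), a_hat=a_hat, d_hat=d_hat,
                           chain=chain, seed=int(seed),
                           var_chains=var_chains, geweke=geweke)


def predict(X: np.ndarray, Z: np.ndarray, estimates: MarkerEstimates) -> np.ndarray:
    """Fitted values mu + X a_hat + Z d_hat."""
    if X.shape[1] != estimates.n_snps or Z.shape[1] != estimates.n_snps:
        raise AlignmentError("genotype SNP set does not match the estimates")
    return (estimates.mu + X.astype(float) @ estimates.a_hat
            + Z.astype(float) @ estimates.d_hat)


def _spectral_density_zero(x: np.ndarray) -> float:
    """Spectral density at frequency zero via a Bartlett-windowed
    autocovariance sum (Newey-West)."""
    n = x.shape[0]
    xc = x - x.mean()
    gamma0 = float(xc @ xc) / n
    if gamma0 < 1e-30:
        return 0.0
    lag = min(n - 1, max(1, int(round(n ** (1.0 / 3.0)))))
    s = gamma0
    for k in range(1, lag + 1):
        cov = float(xc[:-k] @ xc[k:]) / n
        s += 2.0 * (1.0 - k / (lag + 1.0)) * cov
    return max(s, 0.0)


def geweke_z(chain: np.ndarray, first_fraction: float = 0.1,
             last_fraction: float = 0.5) -> float:
    """Geweke convergence diagnostic.

    Compares the means of the first and last segments of a chain, with the
    variance of each segment mean estimated from the spectral density at
    frequency zero.  A chain with (numerically) zero variance returns 0.
    """
    chain = np.asarray(chain, float)
    if chain.shape[0] < 100:
        raise DiagnosticError(f"chain of length {chain.shape[0]} too short (< 100)")
    if not (0 < first_fraction < 1 and 0 < last_fraction < 1
            and first_fraction + last_fraction <= 1):
        raise DiagnosticError("segment fractions must be in (0, 1) and not overlap")
    n = chain.shape[0]
    x1 = chain[:int(n * first_fraction)]
    x2 = chain[n - int(n * last_fraction):]
    s1 = _spectral_density_zero(x1)
    s2 = _spectral_density_zero(x2)
    denom = s1 / x1.shape[0] + s2 / x2.shape[0]
    if denom < 1e-30:
        return 0.0
    return float((x1.mean() - x2.mean()) / np.sqrt(denom))
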