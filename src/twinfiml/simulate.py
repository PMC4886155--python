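"""Twin-data simulator with MCAR/MAR/MNAR covariate missingness.

The defaults reproduce the study design the package is built around:
280 MZ + 720 DZ pairs (the usual MZ:DZ ratio in European twin registers),
ACE components (0.5, 0.3, 0.2), phenotypic mean zero, zero-mean covariates
with an exchangeable within-pair covariance (variance 1, correlation .1)
and between-pair covariance (variance 1, correlation .5), and equal
regression weights solved so that the covariates explain 39% of total
phenotypic variance (total variance 1.64 with five covariates).

Missingness is imposed on covariate entries with *exact proportion
control*: the number of deleted entries is fixed at
``round(proportion * 2 * n_pairs * K)`` (round-half-to-even) and entries
are selected by weighted sampling without replacement.  MCAR uses uniform
weights; MAR weights each entry by a logistic function of the twin's
phenotype, ``1 / (1 + exp(2 + 1.7 * y))``, so lower-scoring twins are more
likely to lose covariate values; MNAR applies the same logistic to the
covariate's own value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import TwinDataset
from .params import ACEParams, CovariateStructure, RegressionWeights, Zygosity
from .model import _covariate_cov_raw, ace_covariance

__all__ = [
    "MissingnessSpec",
    "SimulationConfig",
    "solve_equal_beta",
    "population_phenotypic_variance",
    "draw_covariates",
    "draw_phenotypes",
    "simulate_dataset",
    "impose_missingness",
]

MECHANISMS = ("MCAR", "MAR", "MNAR")


@dataclass(frozen=True)
class MissingnessSpec:
    """How covariate entries go missing.

    ``proportion`` is the fraction of *all* covariate entries
    (2 * n_pairs * K of them) to delete.  The logistic intercept/slope
    defaults (2, 1.7) give a deletion weight of about 0.12 at a phenotype
    (or covariate value) of zero, rising towards 1 as the value decreases.
    """

    mechanism: str
    proportion: float
    logit_intercept: float = 2.0
    logit_slope: float = 1.7

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}, got {self.mechanism!r}")
        if not 0.0 <= self.proportion < 1.0:
            raise ValueError("proportion must lie in [0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    """Generating configuration for one synthetic twin dataset."""

    n_mz: int = 280
    n_dz: int = 720
    ace: ACEParams = field(default_factory=lambda: ACEParams(0.5, 0.3, 0.2, mu_y=0.0))
    cov: CovariateStructure = field(default_factory=lambda: CovariateStructure.exchangeable(5))
    weights: RegressionWeights | None = None
    variance_explained: float = 0.39
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_mz < 0 or self.n_dz < 0 or self.n_mz + self.n_dz < 1:
            raise ValueError("need n_mz, n_dz >= 0 with at least one pair in total")
        if self.weights is None and not 0.0 < self.variance_explained < 1.0:
            raise ValueError("variance_explained must lie in (0, 1)")

    def resolved_weights(self) -> RegressionWeights:
        """Explicit weights if given, else equal weights solved from the target fraction."""
        if self.weights is not None:
            return self.weights
        return solve_equal_beta(self.variance_explained, self.ace, self.cov)


def solve_equal_beta(
    target_fraction: float, ace: ACEParams, cov: CovariateStructure
) -> RegressionWeights:
    """Equal regression weights explaining a target fraction of total variance.

    With equal weights ``b * 1`` the covariate contribution to a twin's
    phenotypic variance is ``b^2 * 1' (Sigma_w + Sigma_b) 1``; setting the
    explained fraction ``f`` of the *total* variance gives

        b = sqrt( f / (1 - f) * sigma2_P / (1' (Sw + Sb) 1) )

    and a total phenotypic variance of ``sigma2_P / (1 - f)``.
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must lie in (0, 1)")
    ones = np.ones(cov.K)
    denom = float(ones @ cov.Sigma_twin @ ones)
    if denom <= 0:
        raise ValueError("degenerate covariate structure: 1'(Sw+Sb)1 must be positive")
    b = np.sqrt(target_fraction / (1.0 - target_fraction) * ace.sigma2_P / denom)
    return RegressionWeights(np.full(cov.K, b))


def population_phenotypic_variance(
    ace: ACEParams, cov: CovariateStructure, weights: RegressionWeights
) -> float:
    """Total variance of one twin's phenotype: ACE total + beta'(Sw+Sb)beta."""
    return float(ace.sigma2_P + weights.beta @ cov.Sigma_twin @ weights.beta)


def draw_covariates(
    n_pairs: int, cov: CovariateStructure, rng: np.random.Generator
) -> np.ndarray:
    """i.i.d. 2K-dimensional MVN covariate draws, returned as (n, 2, K)."""
    full = _covariate_cov_raw(cov.Sigma_w, cov.Sigma_b)
    chol = np.linalg.cholesky(full)
    z = rng.standard_normal((n_pairs, 2 * cov.K))
    flat = z @ chol.T + np.concatenate([cov.mu_x, cov.mu_x])
    return flat.reshape(n_pairs, 2, cov.K)


def draw_phenotypes(
    X: np.ndarray,
    ace: ACEParams,
    weights: RegressionWeights,
    zygosity: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Phenotypes conditional on complete covariates, (n, 2).

    Residuals around ``mu_y + X @ beta`` are bivariate normal with the
    zygosity-specific ACE covariance.
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("draw_phenotypes requires complete covariate data")
    n = X.shape[0]
    mean = ace.mu_y + np.einsum("nsk,k->ns", X, weights.beta)
    resid = np.empty((n, 2))
    zcode = np.asarray([1 if z is Zygosity.MZ else 0 for z in zygosity])
    z = rng.standard_normal((n, 2))
    for code, zyg in ((1, Zygosity.MZ), (0, Zygosity.DZ)):
        sel = zcode == code
        if sel.any():
            chol = np.linalg.cholesky(ace_covariance(ace, zyg))
            resid[sel] = z[sel] @ chol.T
    return mean + resid


def simulate_dataset(
    config: SimulationConfig, rng: np.random.Generator | int | None = None
) -> TwinDataset:
    """Draw one complete dataset (covariates then conditional phenotypes)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    n = config.n_mz + config.n_dz
    zyg = np.asarray(
        [Zygosity.MZ] * config.n_mz + [Zygosity.DZ] * config.n_dz, dtype=object
    )
    weights = config.resolved_weights()
    X = draw_covariates(n, config.cov, rng)
    y = draw_phenotypes(X, config.ace, weights, zyg, rng)
    fam = [f"fam{i:05d}" for i in range(n)]
    return TwinDataset(fam, zyg, y, X)


def _deletion_weights(data: TwinDataset, spec: MissingnessSpec) -> np.ndarray:
    """Per-entry deletion weight, shape (n, 2, K)."""
    n, K = len(data), data.K
    if spec.mechanism == "MCAR":
        return np.ones((n, 2, K))
    if spec.mechanism == "MAR":
        if np.isnan(data.y).any():
            raise ValueError("MAR mechanism requires observed phenotypes")
        w = 1.0 / (1.0 + np.exp(spec.logit_intercept + spec.logit_slope * data.y))
        return np.repeat(w[:, :, None], K, axis=2)
    # MNAR: logistic of the entry's own value
    return 1.0 / (1.0 + np.exp(spec.logit_intercept + spec.logit_slope * data.X))


def impose_missingness(
    data: TwinDataset,
    spec: MissingnessSpec,
    rng: np.random.Generator | int | None = None,
) -> TwinDataset:
    """Mask an exact count of covariate entries by weighted sampling.

    Exactly ``round(proportion * 2 * n_pairs * K)`` entries (round-half-to-
    even) are deleted.  Selection is weighted sampling *without*
    replacement — equivalent to sequentially drawing entries with
    probability proportional to their remaining weights — implemented via
    the exponential-race construction (smallest ``Exp(1) / weight`` keys).
    """
    if np.isnan(data.X).any():
        raise ValueError("impose_missingness requires complete covariate data")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n, K = len(data), data.K
    total = 2 * n * K
    count = round(spec.proportion * total)  # round-half-to-even
    if count > total:
        raise ValueError("requested missing count exceeds the number of covariate entries")
    out = data.copy()
    if count == 0:
        return out
    w = _deletion_weights(data, spec).reshape(-1)
    keys = rng.exponential(size=total) / w
    chosen = np.argpartition(keys, count - 1)[:count]
    flatX = out.X.reshape(-1)
    flatX[chosen] = np.nan
    return out
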