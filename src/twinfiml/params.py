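"""Parameter containers for the joint twin phenotype–covariate model.

The univariate ACE twin model decomposes residual phenotypic variance into
additive-genetic (A), common-environmental (C) and unique-environmental (E)
parts.  Covariates enter through a linear regression on the phenotypic mean
and, in the full-information formulation, through their own between/within
twin-pair covariance decomposition (``Sigma_b`` / ``Sigma_w``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Zygosity",
    "ACEParams",
    "CovariateStructure",
    "RegressionWeights",
    "JointModel",
]

# Smallest-eigenvalue / largest-eigenvalue ratio below which a covariance
# matrix is treated as numerically singular.
_EIG_RATIO_TOL = 1e-10


class Zygosity(Enum):
    """Twin-pair zygosity; fixes the additive-genetic correlation ``rho``."""

    MZ = "MZ"
    DZ = "DZ"

    @property
    def rho(self) -> float:
        """Correlation between the twins' additive polygenic factors."""
        return 1.0 if self is Zygosity.MZ else 0.5

    @classmethod
    def from_token(cls, token: str) -> "Zygosity":
        """Parse an ``MZ``/``DZ`` token, case-insensitively."""
        try:
            return cls(str(token).strip().upper())
        except ValueError:
            raise ValueError(
                f"unknown zygosity token {token!r}; expected 'MZ' or 'DZ'"
            ) from None


@dataclass(frozen=True)
class ACEParams:
    """ACE variance components and the phenotypic regression intercept.

    Parameters
    ----------
    sigma2_A, sigma2_C
        Additive-genetic and common-environmental variances (>= 0).
    sigma2_E
        Unique-environmental variance (> 0; the model is degenerate at 0).
    mu_y
        Phenotypic intercept: the conditional mean of a twin's phenotype is
        ``mu_y + x @ beta``.
    """

    sigma2_A: float
    sigma2_C: float
    sigma2_E: float
    mu_y: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma2_A < 0 or self.sigma2_C < 0:
            raise ValueError("sigma2_A and sigma2_C must be non-negative")
        if self.sigma2_E <= 0:
            raise ValueError("sigma2_E must be strictly positive")
        if not np.isfinite([self.sigma2_A, self.sigma2_C, self.sigma2_E, self.mu_y]).all():
            raise ValueError("ACE parameters must be finite")

    @property
    def sigma2_P(self) -> float:
        """Total residual phenotypic variance A + C + E."""
        return self.sigma2_A + self.sigma2_C + self.sigma2_E


def _check_symmetric(name: str, m: np.ndarray, k: int) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (k, k):
        raise ValueError(f"{name} must be {k}x{k}, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    return 0.5 * (m + m.T)


def _is_pd(m: np.ndarray) -> bool:
    ev = np.linalg.eigvalsh(m)
    return ev[0] > _EIG_RATIO_TOL * max(ev[-1], 1.0)


@dataclass(frozen=True)
class CovariateStructure:
    """Between/within twin-pair decomposition of the covariate covariance.

    A twin's own covariate covariance is ``Sigma_w + Sigma_b``; the
    cross-twin covariate covariance is ``Sigma_b``.  ``Sigma_w`` must be
    positive definite, ``Sigma_b`` positive semi-definite, and the implied
    2K x 2K covariate covariance positive definite.
    """

    K: int
    mu_x: np.ndarray
    Sigma_w: np.ndarray
    Sigma_b: np.ndarray

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be a positive integer")
        mu = np.asarray(self.mu_x, dtype=float).reshape(-1)
        if mu.shape != (self.K,):
            raise ValueError(f"mu_x must have length {self.K}")
        sw = _check_symmetric("Sigma_w", self.Sigma_w, self.K)
        sb = _check_symmetric("Sigma_b", self.Sigma_b, self.K)
        if not _is_pd(sw):
            raise ValueError("Sigma_w must be positive definite")
        if np.linalg.eigvalsh(sb)[0] < -1e-10:
            raise ValueError("Sigma_b must be positive semi-definite")
        twin = sw + sb
        full = np.block([[twin, sb], [sb, twin]])
        if not _is_pd(full):
            raise ValueError("implied 2Kx2K covariate covariance is not positive definite")
        object.__setattr__(self, "mu_x", mu)
        object.__setattr__(self, "Sigma_w", sw)
        object.__setattr__(self, "Sigma_b", sb)

    @classmethod
    def exchangeable(
        cls,
        K: int,
        *,
        w_var: float = 1.0,
        w_corr: float = 0.1,
        b_var: float = 1.0,
        b_corr: float = 0.5,
        mu_x: np.ndarray | None = None,
    ) -> "CovariateStructure":
        """Exchangeable (equal diagonal / equal off-diagonal) structure.

        The defaults are the simulation-design values: within-pair variance 1
        with correlation .1, between-pair variance 1 with correlation .5,
        covariate means zero.
        """
        eye = np.eye(K)
        ones = np.ones((K, K))
        sw = w_var * ((1 - w_corr) * eye + w_corr * ones)
        sb = b_var * ((1 - b_corr) * eye + b_corr * ones)
        mu = np.zeros(K) if mu_x is None else np.asarray(mu_x, dtype=float)
        return cls(K=K, mu_x=mu, Sigma_w=sw, Sigma_b=sb)

    @property
    def Sigma_twin(self) -> np.ndarray:
        """A single twin's covariate covariance, ``Sigma_w + Sigma_b``."""
        return self.Sigma_w + self.Sigma_b


@dataclass(frozen=True)
class RegressionWeights:
    """Regression coefficients of the covariates on the phenotype."""

    beta: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.beta, dtype=float).reshape(-1)
        if b.size < 1 or not np.isfinite(b).all():
            raise ValueError("beta must be a non-empty finite vector")
        object.__setattr__(self, "beta", b)

    @property
    def K(self) -> int:
        return self.beta.size


@dataclass(frozen=True)
class JointModel:
    """Joint multivariate-normal model over (y1, y2, x1-block, x2-block).

    ``cov_dz`` optionally gives DZ pairs their own covariate covariance
    decomposition (same covariate means); by default MZ and DZ pairs share
    one structure.
    """

    ace: ACEParams
    cov: CovariateStructure
    weights: RegressionWeights
    cov_dz: CovariateStructure | None = None

    def __post_init__(self) -> None:
        if self.weights.K != self.cov.K:
            raise ValueError(
                f"dimension mismatch: beta has length {self.weights.K}, "
                f"covariate structure has K={self.cov.K}"
            )
        if self.cov_dz is not None:
            if self.cov_dz.K != self.cov.K:
                raise ValueError("cov_dz must have the same number of covariates")
            if not np.array_equal(self.cov_dz.mu_x, self.cov.mu_x):
                raise ValueError("cov_dz must share the covariate means mu_x")

    def structure_for(self, zyg: "Zygosity") -> CovariateStructure:
        if zyg is Zygosity.DZ and self.cov_dz is not None:
            return self.cov_dz
        return self.cov

    @property
    def K(self) -> int:
        return self.cov.K

    @property
    def dim(self) -> int:
        """Dimension of the joint vector, 2 + 2K."""
        return 2 + 2 * self.cov.K
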