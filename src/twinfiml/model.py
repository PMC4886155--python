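"""Model core: ACE, covariate and joint covariance builders and likelihoods.

Two likelihoods are provided.

``loglik_usual``
    The conventional twin-model likelihood: phenotypes conditional on
    complete covariates, bivariate normal per intact pair and univariate
    normal per singleton.  It requires twin-wise-deleted data (every
    retained individual has an observed phenotype and complete covariates).

``loglik_full_information``
    The joint likelihood over phenotypes *and* covariates: each pair
    contributes the multivariate-normal log-density of exactly its observed
    coordinates, obtained by marginalizing the (2+2K)-dimensional joint
    normal.  No record is deleted; any observed value contributes.

The package-wide coordinate convention for the joint vector is
``(y1, y2, x1_1..x1_K, x2_1..x2_K)``.
"""

from __future__ import annotations

import numpy as np

from .data import TwinDataset
from .params import (
    ACEParams,
    CovariateStructure,
    JointModel,
    RegressionWeights,
    Zygosity,
)

__all__ = [
    "ace_covariance",
    "covariate_covariance",
    "joint_covariance",
    "joint_mean",
    "observed_submodel",
    "loglik_full_information",
    "loglik_usual",
    "twinwise_delete",
    "heritability",
]

_LOG2PI = np.log(2.0 * np.pi)
_EIG_RATIO_TOL = 1e-10


# ---------------------------------------------------------------------------
# raw-array assemblers (dtype-agnostic; shared with the fast fitting path)
# ---------------------------------------------------------------------------

def _ace_cov_raw(s2a, s2c, s2e, rho, dtype=float):
    total = s2a + s2c + s2e
    off = rho * s2a + s2c
    return np.array([[total, off], [off, total]], dtype=dtype)


def _covariate_cov_raw(sw, sb):
    twin = sw + sb
    return np.block([[twin, sb], [sb, twin]])


def _joint_cov_raw(s2a, s2c, s2e, rho, beta, sw, sb):
    """Assemble the (2+2K) x (2+2K) joint covariance from raw arrays."""
    twin = sw + sb
    ace = s2a + s2c + s2e
    ac = rho * s2a + s2c
    bt_twin = beta @ twin          # row vector beta^T (Sigma_w + Sigma_b)
    bt_b = beta @ sb               # row vector beta^T Sigma_b
    var_y = ace + beta @ bt_twin
    cov_y = ac + beta @ bt_b
    K = beta.shape[0]
    dtype = np.result_type(beta, sw, sb, np.asarray(s2a))
    out = np.zeros((2 + 2 * K, 2 + 2 * K), dtype=dtype)
    out[0, 0] = out[1, 1] = var_y
    out[0, 1] = out[1, 0] = cov_y
    out[0, 2 : 2 + K] = bt_twin
    out[0, 2 + K :] = bt_b
    out[1, 2 : 2 + K] = bt_b
    out[1, 2 + K :] = bt_twin
    out[2:, 0] = out[0, 2:]
    out[2:, 1] = out[1, 2:]
    out[2:, 2:] = _covariate_cov_raw(sw, sb)
    return out


def _joint_mean_raw(mu_y, beta, mu_x):
    K = mu_x.shape[0]
    dtype = np.result_type(beta, mu_x, np.asarray(mu_y))
    mean_y = mu_y + beta @ mu_x
    out = np.empty(2 + 2 * K, dtype=dtype)
    out[0] = out[1] = mean_y
    out[2 : 2 + K] = mu_x
    out[2 + K :] = mu_x
    return out


# ---------------------------------------------------------------------------
# public builders
# ---------------------------------------------------------------------------

def ace_covariance(ace: ACEParams, zyg: Zygosity) -> np.ndarray:
    """2x2 phenotypic residual covariance of a twin pair.

    Diagonal is A + C + E; off-diagonal is ``rho * A + C`` where rho is 1
    for MZ and 0.5 for DZ pairs.
    """
    if not isinstance(zyg, Zygosity):
        raise TypeError(f"zyg must be a Zygosity, got {zyg!r}")
    return _ace_cov_raw(ace.sigma2_A, ace.sigma2_C, ace.sigma2_E, zyg.rho)


def covariate_covariance(cov: CovariateStructure) -> np.ndarray:
    """2K x 2K covariate covariance: ``[[Sw+Sb, Sb], [Sb, Sw+Sb]]``."""
    return _covariate_cov_raw(cov.Sigma_w, cov.Sigma_b)


def joint_covariance(model: JointModel, zyg: Zygosity) -> np.ndarray:
    """Joint covariance of (y1, y2, x1-block, x2-block).

    The phenotypic block is the ACE covariance inflated by the covariate
    quadratic forms; the phenotype-covariate blocks are ``(Sw+Sb) beta``
    (own twin) and ``Sb beta`` (co-twin); the covariate block equals
    :func:`covariate_covariance`.
    """
    if not isinstance(zyg, Zygosity):
        raise TypeError(f"zyg must be a Zygosity, got {zyg!r}")
    structure = model.structure_for(zyg)
    sigma = _joint_cov_raw(
        model.ace.sigma2_A,
        model.ace.sigma2_C,
        model.ace.sigma2_E,
        zyg.rho,
        model.weights.beta,
        structure.Sigma_w,
        structure.Sigma_b,
    )
    ev = np.linalg.eigvalsh(sigma)
    if ev[0] <= _EIG_RATIO_TOL * max(ev[-1], 1.0):
        raise np.linalg.LinAlgError(
            "joint covariance is not positive definite for the requested parameters"
        )
    return sigma


def joint_mean(model: JointModel) -> np.ndarray:
    """Joint mean vector ``(mu_y + beta @ mu_x, same, mu_x, mu_x)``.

    Conditioning the joint normal on the covariates recovers the
    conditional phenotype mean ``mu_y + x @ beta``.
    """
    return _joint_mean_raw(model.ace.mu_y, model.weights.beta, model.cov.mu_x)


def observed_submodel(
    mean: np.ndarray, cov: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Restrict a multivariate-normal to its observed coordinates.

    Marginalizing a multivariate normal is coordinate selection: the
    sub-mean and sub-covariance indexed by ``mask``.
    """
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != mean.shape:
        raise ValueError("mask and mean must have the same shape")
    if not mask.any():
        raise ValueError("at least one coordinate must be observed")
    idx = np.flatnonzero(mask)
    return mean[idx], cov[np.ix_(idx, idx)]


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------

def _mvn_logpdf(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    """Log-density via Cholesky solve; raises LinAlgError if cov is not PD."""
    ev = np.linalg.eigvalsh(cov)
    if ev[0] <= _EIG_RATIO_TOL * max(ev[-1], 1.0):
        raise np.linalg.LinAlgError("covariance numerically singular")
    chol = np.linalg.cholesky(cov)
    z = np.linalg.solve(chol, x - mean)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return float(-0.5 * (x.size * _LOG2PI + logdet + z @ z))


def loglik_full_information(data: TwinDataset, model: JointModel) -> float:
    """Sum over pairs of the observed-coordinate joint MVN log-density.

    Reference (record-by-record) implementation; the optimizer uses an
    algebraically identical sufficient-statistic path
    (:mod:`twinfiml._likelihood`) that is tested against this one.
    """
    if data.K != model.K:
        raise ValueError(f"data has K={data.K} covariates, model has K={model.K}")
    mu = joint_mean(model)
    sigma = {z: joint_covariance(model, z) for z in (Zygosity.MZ, Zygosity.DZ)}
    vals = data.stacked_values()
    obs = ~np.isnan(vals)
    total = 0.0
    for i in range(len(data)):
        m, s = observed_submodel(mu, sigma[data.zygosity[i]], obs[i])
        total += _mvn_logpdf(vals[i, obs[i]], m, s)
    return total


def twinwise_delete(data: TwinDataset) -> TwinDataset:
    """Apply twin-wise deletion, the conventional missing-covariate strategy.

    An individual twin with at least one missing covariate (or a missing
    phenotype) is removed entirely — phenotype and covariates; the co-twin
    is retained as a singleton if itself complete.  Pairs with both twins
    incomplete are dropped.  Removed individuals are encoded as all-NaN
    sides of the retained pairs.
    """
    keep_indiv = data.y_observed & data.X_observed.all(axis=2)  # (n, 2)
    out = data.copy()
    for side in (0, 1):
        drop = ~keep_indiv[:, side]
        out.y[drop, side] = np.nan
        out.X[drop, side, :] = np.nan
    keep_pair = keep_indiv.any(axis=1)
    if not keep_pair.any():
        raise ValueError("twin-wise deletion removed every individual")
    return out.subset(keep_pair)


def loglik_usual(
    data: TwinDataset, ace: ACEParams, weights: RegressionWeights
) -> float:
    """Conditional (phenotype-given-covariates) log-likelihood.

    Precondition: ``data`` is twin-wise deleted.  Intact pairs contribute a
    bivariate normal with ACE covariance; singletons a univariate normal
    with variance A + C + E.  An empty dataset contributes 0 by convention
    (an empty sum), but ``TwinDataset`` cannot be empty, so this arises only
    for ``data=None``.
    """
    if data is None or len(data) == 0:
        return 0.0
    if weights.K != data.K:
        raise ValueError("beta length does not match the number of covariates")
    present = data.y_observed & data.X_observed.all(axis=2)
    # precondition: every individual is either fully complete or fully absent
    absent = ~data.y_observed & ~data.X_observed.any(axis=2)
    if not (present | absent).all():
        raise ValueError(
            "loglik_usual requires twin-wise deleted data "
            "(retained individuals must have observed phenotype and complete covariates)"
        )
    resid = data.y - ace.mu_y - np.einsum("nsk,k->ns", np.nan_to_num(data.X), weights.beta)
    total_var = ace.sigma2_P
    zcode = data.zygosity_codes()
    ll = 0.0
    pair_mask = present.all(axis=1)
    for code, rho in ((1, 1.0), (0, 0.5)):
        sel = pair_mask & (zcode == code)
        if sel.any():
            off = rho * ace.sigma2_A + ace.sigma2_C
            det = total_var**2 - off**2
            if det <= 0:
                raise np.linalg.LinAlgError("ACE covariance not positive definite")
            e1, e2 = resid[sel, 0], resid[sel, 1]
            quad = (total_var * (e1**2 + e2**2) - 2.0 * off * e1 * e2) / det
            ll += -0.5 * (sel.sum() * (2 * _LOG2PI + np.log(det)) + quad.sum())
    single_mask = present & ~pair_mask[:, None]
    if single_mask.any():
        e = resid[single_mask]
        ll += -0.5 * (e.size * (_LOG2PI + np.log(total_var)) + (e**2).sum() / total_var)
    return float(ll)


def heritability(ace: ACEParams) -> float:
    """Narrow-sense heritability ``sigma2_A / (A + C + E)``."""
    total = ace.sigma2_P
    if total <= 0:
        raise ValueError("total phenotypic variance must be positive")
    return ace.sigma2_A / total
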