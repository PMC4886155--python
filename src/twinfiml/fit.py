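"""Maximum-likelihood estimation for both missing-covariate strategies.

``fit_full_information`` maximizes the joint phenotype+covariate likelihood
over all ACE components, regression weights, covariate means and the
between/within covariate covariance matrices, using every observed value.
``fit_usual`` first applies twin-wise deletion and then maximizes the
conventional conditional likelihood over the ACE components, intercept and
regression weights.

Positivity of variance components is enforced by optimizing them on the log
scale; the covariate covariance matrices are parameterized through
lower-triangular Cholesky factors with log-scale diagonals (or, optionally,
through an exchangeable variance/correlation pair).  Standard errors are
square roots of the diagonal of the inverse observed information, computed
by central finite differences in the natural parameterization; the
heritability standard error follows by the delta method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from ._likelihood import PatternStats, chain_gradient, loglik_patterns
from .data import TwinDataset
from .model import (
    _joint_cov_raw,
    _joint_mean_raw,
    heritability,
    twinwise_delete,
)
from .params import ACEParams, CovariateStructure, RegressionWeights

__all__ = [
    "FitResult",
    "fit_full_information",
    "fit_usual",
    "observed_information",
    "standard_errors",
    "delta_method_h2_se",
]

_LOG2PI = np.log(2.0 * np.pi)
_BOUNDARY_TOL = 1e-6
# gtol is the binding criterion; ftol is kept below the stated relative
# log-likelihood change (1e-8) so the gradient test decides convergence
_OPTIONS = dict(maxiter=2000, ftol=1e-11, gtol=1e-5, maxls=60)


# ---------------------------------------------------------------------------
# result container
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Estimates, uncertainties and diagnostics of one model fit."""

    approach: str
    ace: ACEParams
    weights: RegressionWeights
    h2: float
    loglik: float
    converged: bool
    n_pairs_used: int
    n_singletons_used: int
    mu_x: np.ndarray | None = None
    Sigma_w: np.ndarray | None = None
    Sigma_b: np.ndarray | None = None
    se: dict | None = None
    h2_se: float = np.nan
    n_iter: int = 0
    boundary: tuple = ()
    message: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0 + 1e-12:
            raise ValueError(f"h2 out of [0, 1]: {self.h2}")
        if self.se is not None:
            bad = [k for k, v in self.se.items() if np.isfinite(v) and v < 0]
            if bad:
                raise ValueError(f"negative standard errors for {bad}")

    def to_row(self) -> dict:
        """Flat record for the study harness."""
        row = {
            "approach": self.approach,
            "sigma2_A": self.ace.sigma2_A,
            "sigma2_C": self.ace.sigma2_C,
            "sigma2_E": self.ace.sigma2_E,
            "mu_y": self.ace.mu_y,
            "h2": self.h2,
            "h2_se": self.h2_se,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_pairs_used": self.n_pairs_used,
            "n_singletons_used": self.n_singletons_used,
        }
        for j, b in enumerate(self.weights.beta, start=1):
            row[f"beta_{j}"] = b
        for name in ("sigma2_A", "sigma2_C", "sigma2_E"):
            row[f"se_{name}"] = self.se.get(name, np.nan) if self.se else np.nan
        return row

    def to_text(self) -> str:
        """Stable key-value serialization."""
        lines = [f"approach: {self.approach}"]
        for k, v in self.to_row().items():
            if k != "approach":
                lines.append(f"{k}: {v}")
        if self.boundary:
            lines.append(f"boundary: {','.join(self.boundary)}")
        lines.append(f"message: {self.message}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# parameter maps
# ---------------------------------------------------------------------------

def _tril_indices(K: int):
    iu = np.tril_indices(K)
    return iu, iu[0] == iu[1]


def _chol_from_vec(vec, K: int):
    iu, diag = _tril_indices(K)
    L = np.zeros((K, K), dtype=vec.dtype)
    v = vec.copy()
    v[diag] = np.exp(v[diag])
    L[iu] = v
    return L


def _vec_from_chol(L: np.ndarray, K: int) -> np.ndarray:
    iu, diag = _tril_indices(K)
    v = L[iu].copy()
    v[diag] = np.log(v[diag])
    return v


def _sym_from_vech(vec, K: int):
    iu, _ = _tril_indices(K)
    S = np.zeros((K, K), dtype=vec.dtype)
    S[iu] = vec
    S = S + S.T - np.diag(np.diagonal(S))
    return S


def _expit(z):
    return 1.0 / (1.0 + np.exp(-z))


def _exchangeable_mat(var, corr, K: int):
    eye = np.eye(K)
    return var * ((1.0 - corr) * eye + corr * np.ones((K, K)))


class _FullParamMap:
    """Unconstrained theta <-> model moments for the joint model."""

    def __init__(self, K: int, structure: str = "free") -> None:
        if structure not in ("free", "exchangeable"):
            raise ValueError("covariate structure must be 'free' or 'exchangeable'")
        self.K = K
        self.structure = structure
        self.T = K * (K + 1) // 2 if structure == "free" else 2
        self.size = 4 + 2 * K + 2 * self.T
        # natural vector: [s2A, s2C, s2E, mu_y, beta, mu_x, vech(Sw), vech(Sb)]
        # or [..., v_w, r_w, v_b, r_b] for the exchangeable structure
        self.natural_size = self.size

    # -- unconstrained ------------------------------------------------------
    def build(self, theta):
        K, T = self.K, self.T
        s2 = np.exp(theta[:3])
        mu_y = theta[3]
        beta = theta[4 : 4 + K]
        mu_x = theta[4 + K : 4 + 2 * K]
        if self.structure == "free":
            lw = _chol_from_vec(theta[4 + 2 * K : 4 + 2 * K + T], K)
            lb = _chol_from_vec(theta[4 + 2 * K + T :], K)
            sw, sb = lw @ lw.T, lb @ lb.T
        else:
            lo = -1.0 / (K - 1) if K > 1 else -1.0
            vw, vb = np.exp(theta[4 + 2 * K]), np.exp(theta[4 + 2 * K + 2])
            rw = lo + (1.0 - lo) * _expit(theta[4 + 2 * K + 1])
            rb = lo + (1.0 - lo) * _expit(theta[4 + 2 * K + 3])
            sw = _exchangeable_mat(vw, rw, K)
            sb = _exchangeable_mat(vb, rb, K)
        mu = _joint_mean_raw(mu_y, beta, mu_x)
        sig = {
            1: _joint_cov_raw(s2[0], s2[1], s2[2], 1.0, beta, sw, sb),
            0: _joint_cov_raw(s2[0], s2[1], s2[2], 0.5, beta, sw, sb),
        }
        return mu, sig

    def pack(self, s2, mu_y, beta, mu_x, sw, sb) -> np.ndarray:
        K = self.K
        theta = np.empty(self.size)
        theta[:3] = np.log(np.maximum(s2, 1e-8))
        theta[3] = mu_y
        theta[4 : 4 + K] = beta
        theta[4 + K : 4 + 2 * K] = mu_x
        if self.structure == "free":
            theta[4 + 2 * K : 4 + 2 * K + self.T] = _vec_from_chol(np.linalg.cholesky(sw), K)
            theta[4 + 2 * K + self.T :] = _vec_from_chol(np.linalg.cholesky(sb), K)
        else:
            lo = -1.0 / (K - 1) if K > 1 else -1.0
            for off, m in ((0, sw), (2, sb)):
                var = float(np.diagonal(m).mean())
                corr = float(m[0, 1] / var) if K > 1 else 0.0
                corr = np.clip(corr, lo + 1e-4, 1.0 - 1e-4)
                theta[4 + 2 * K + off] = np.log(max(var, 1e-8))
                theta[4 + 2 * K + off + 1] = np.log((corr - lo) / (1.0 - corr))
        return theta

    def unpack(self, theta):
        mu, _ = self.build(theta)
        K, T = self.K, self.T
        s2 = np.exp(theta[:3])
        beta = theta[4 : 4 + K].copy()
        mu_x = theta[4 + K : 4 + 2 * K].copy()
        if self.structure == "free":
            lw = _chol_from_vec(theta[4 + 2 * K : 4 + 2 * K + T], K)
            lb = _chol_from_vec(theta[4 + 2 * K + T :], K)
            sw, sb = lw @ lw.T, lb @ lb.T
        else:
            lo = -1.0 / (K - 1) if K > 1 else -1.0
            vw, vb = np.exp(theta[4 + 2 * K]), np.exp(theta[4 + 2 * K + 2])
            rw = lo + (1.0 - lo) * _expit(theta[4 + 2 * K + 1])
            rb = lo + (1.0 - lo) * _expit(theta[4 + 2 * K + 3])
            sw = _exchangeable_mat(vw, rw, K)
            sb = _exchangeable_mat(vb, rb, K)
        return s2, float(theta[3]), beta, mu_x, sw, sb

    # -- natural ------------------------------------------------------------
    def natural_names(self) -> list[str]:
        K = self.K
        names = ["sigma2_A", "sigma2_C", "sigma2_E", "mu_y"]
        names += [f"beta_{j}" for j in range(1, K + 1)]
        names += [f"mu_x_{j}" for j in range(1, K + 1)]
        if self.structure == "free":
            iu, _ = _tril_indices(K)
            names += [f"Sigma_w[{i},{j}]" for i, j in zip(*iu)]
            names += [f"Sigma_b[{i},{j}]" for i, j in zip(*iu)]
        else:
            names += ["var_w", "corr_w", "var_b", "corr_b"]
        return names

    def natural_from_estimates(self, s2, mu_y, beta, mu_x, sw, sb) -> np.ndarray:
        K = self.K
        phi = np.empty(self.natural_size)
        phi[:3] = s2
        phi[3] = mu_y
        phi[4 : 4 + K] = beta
        phi[4 + K : 4 + 2 * K] = mu_x
        if self.structure == "free":
            iu, _ = _tril_indices(K)
            phi[4 + 2 * K : 4 + 2 * K + self.T] = sw[iu]
            phi[4 + 2 * K + self.T :] = sb[iu]
        else:
            phi[4 + 2 * K] = np.diagonal(sw).mean()
            phi[4 + 2 * K + 1] = sw[0, 1] / phi[4 + 2 * K] if K > 1 else 0.0
            phi[4 + 2 * K + 2] = np.diagonal(sb).mean()
            phi[4 + 2 * K + 3] = sb[0, 1] / phi[4 + 2 * K + 2] if K > 1 else 0.0
        return phi

    def build_natural(self, phi):
        K = self.K
        s2 = phi[:3]
        mu_y = phi[3]
        beta = phi[4 : 4 + K]
        mu_x = phi[4 + K : 4 + 2 * K]
        if self.structure == "free":
            sw = _sym_from_vech(phi[4 + 2 * K : 4 + 2 * K + self.T], K)
            sb = _sym_from_vech(phi[4 + 2 * K + self.T :], K)
        else:
            sw = _exchangeable_mat(phi[4 + 2 * K], phi[4 + 2 * K + 1], K)
            sb = _exchangeable_mat(phi[4 + 2 * K + 2], phi[4 + 2 * K + 3], K)
        mu = _joint_mean_raw(mu_y, beta, mu_x)
        sig = {
            1: _joint_cov_raw(s2[0], s2[1], s2[2], 1.0, beta, sw, sb),
            0: _joint_cov_raw(s2[0], s2[1], s2[2], 0.5, beta, sw, sb),
        }
        return mu, sig


# ---------------------------------------------------------------------------
# starting values
# ---------------------------------------------------------------------------

def _make_pd(m: np.ndarray, floor: float = 1e-2) -> np.ndarray:
    w, v = np.linalg.eigh(0.5 * (m + m.T))
    w = np.maximum(w, floor)
    return (v * w) @ v.T


def _moment_starts(data: TwinDataset):
    K = data.K
    ind_y = data.y.reshape(-1)
    ind_x = data.X.reshape(-1, K)
    with np.errstate(invalid="ignore"):
        var_y = np.nanvar(ind_y, ddof=1)
    if not np.isfinite(var_y) or var_y <= 0:
        var_y = 1.0
    s2 = np.array([0.4, 0.2, 0.4]) * var_y
    mu_x = np.nanmean(ind_x, axis=0)
    mu_x[~np.isfinite(mu_x)] = 0.0
    complete = ~np.isnan(ind_y) & ~np.isnan(ind_x).any(axis=1)
    if complete.sum() >= K + 2:
        design = np.column_stack([np.ones(int(complete.sum())), ind_x[complete]])
        coef, *_ = np.linalg.lstsq(design, ind_y[complete], rcond=None)
        mu_y, beta = float(coef[0]), coef[1:]
    else:
        m = np.nanmean(ind_y)
        mu_y, beta = (float(m) if np.isfinite(m) else 0.0), np.zeros(K)
    pair_complete = ~np.isnan(data.X).any(axis=(1, 2))
    if pair_complete.sum() >= K + 2:
        x1 = data.X[pair_complete, 0]
        x2 = data.X[pair_complete, 1]
        m = int(pair_complete.sum())
        c1, c2 = x1 - x1.mean(axis=0), x2 - x2.mean(axis=0)
        c12 = c1.T @ c2 / (m - 1)
        sb = 0.5 * (c12 + c12.T)
        twin = 0.5 * (c1.T @ c1 + c2.T @ c2) / (m - 1)
        sw = twin - sb
    else:
        v = np.nanvar(ind_x, axis=0)
        v[~np.isfinite(v) | (v <= 0)] = 1.0
        sw = np.diag(0.5 * v)
        sb = np.diag(0.5 * v)
    return s2, mu_y, beta, mu_x, _make_pd(sw), _make_pd(sb)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_full_information(
    data: TwinDataset,
    *,
    compute_se: bool = True,
    covariate_structure: str = "free",
    start: np.ndarray | None = None,
) -> FitResult:
    """Fit the joint phenotype+covariate model by full-information ML.

    Every record contributes the log-density of exactly its observed
    coordinates; nothing is deleted.  ``covariate_structure='exchangeable'``
    constrains Sigma_w and Sigma_b to equal-variance/equal-correlation form.
    """
    if data is None or len(data) == 0:
        raise ValueError("fit_full_information requires at least one record")
    pmap = _FullParamMap(data.K, covariate_structure)
    stats = PatternStats(data)

    def objective(theta):
        mu, sig = pmap.build(theta)
        out = loglik_patterns(mu, sig, stats, want_grad=True)
        ll, grads = out
        if not np.isfinite(ll) or grads is None:
            return 1e12, np.zeros_like(theta)
        grad = chain_gradient(theta, pmap.build, *grads)
        return -ll, -grad

    theta0 = pmap.pack(*_moment_starts(data)) if start is None else np.asarray(start, float)
    res = minimize(objective, theta0, jac=True, method="L-BFGS-B", options=_OPTIONS)
    s2, mu_y, beta, mu_x, sw, sb = pmap.unpack(res.x)
    ace = ACEParams(s2[0], s2[1], s2[2], mu_y=mu_y)
    weights = RegressionWeights(beta)
    boundary = tuple(
        name
        for name, val in zip(("sigma2_A", "sigma2_C", "sigma2_E"), s2)
        if val < _BOUNDARY_TOL
    )
    se_dict, h2_se = None, np.nan
    if compute_se:
        se_dict, h2_se = _full_information_se(pmap, stats, s2, mu_y, beta, mu_x, sw, sb)
    return FitResult(
        approach="full_information",
        ace=ace,
        weights=weights,
        mu_x=mu_x,
        Sigma_w=sw,
        Sigma_b=sb,
        h2=float(np.clip(heritability(ace), 0.0, 1.0)),
        h2_se=h2_se,
        se=se_dict,
        loglik=float(-res.fun),
        converged=bool(res.success),
        n_iter=int(res.nit),
        n_pairs_used=len(data),
        n_singletons_used=0,
        boundary=boundary,
        message=str(res.message),
    )


def _full_information_se(pmap, stats, s2, mu_y, beta, mu_x, sw, sb):
    """Observed-information SEs in the natural parameterization.

    The Hessian is obtained by central finite differences of the analytic
    score; each score evaluation is exact to machine precision, so a small
    relative step is safe.
    """
    phi = pmap.natural_from_estimates(s2, mu_y, beta, mu_x, sw, sb)

    def score(p):
        mu, sig = pmap.build_natural(p)
        ll, grads = loglik_patterns(mu, sig, stats, want_grad=True)
        if grads is None:
            raise np.linalg.LinAlgError("information evaluated at an invalid point")
        return chain_gradient(p, pmap.build_natural, *grads)

    n = phi.size
    H = np.empty((n, n))
    h = 1e-5 * np.maximum(np.abs(phi), 1e-2)
    try:
        for i in range(n):
            e = np.zeros(n)
            e[i] = h[i]
            H[i] = (score(phi + e) - score(phi - e)) / (2.0 * h[i])
        info = -0.5 * (H + H.T)
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        names = pmap.natural_names()
        return {k: np.nan for k in names}, np.nan
    diag = np.diagonal(cov)
    names = pmap.natural_names()
    se = {k: (np.sqrt(d) if d > 0 else np.nan) for k, d in zip(names, diag)}
    h2_se = delta_method_h2_se(s2, cov[:3, :3])
    return se, h2_se


def fit_usual(data: TwinDataset, *, compute_se: bool = True) -> FitResult:
    """Twin-wise deletion followed by conditional ML.

    Individuals with any missing covariate (or missing phenotype) are
    dropped; complete co-twins are retained as singletons.  The likelihood
    is then the product of bivariate-normal pair terms and univariate
    singleton terms.
    """
    if data is None or len(data) == 0:
        raise ValueError("fit_usual requires at least one record")
    deleted = twinwise_delete(data)  # raises if everything is removed
    K = data.K
    present = deleted.y_observed  # post-deletion: observed == fully complete
    pair_mask = present.all(axis=1)
    n_pairs_used = int(pair_mask.sum())
    n_singles = int(present.sum() - 2 * n_pairs_used)
    zcode = deleted.zygosity_codes()

    yp = deleted.y[pair_mask]
    xp = deleted.X[pair_mask]
    zp = zcode[pair_mask]
    single = present.reshape(-1) & ~np.repeat(pair_mask, 2)
    ys = deleted.y.reshape(-1)[single]
    xs = deleted.X.reshape(-1, K)[single]

    def loglik_natural(phi):
        s2a, s2c, s2e = phi[0], phi[1], phi[2]
        if s2e <= 0 or s2a < 0 or s2c < 0:
            return -np.inf
        mu_y = phi[3]
        beta = phi[4:]
        total = s2a + s2c + s2e
        ll = 0.0
        for code, rho in ((1, 1.0), (0, 0.5)):
            sel = zp == code
            if sel.any():
                off = rho * s2a + s2c
                det = total**2 - off**2
                if det <= 0:
                    return -np.inf
                e = yp[sel] - mu_y - xp[sel] @ beta
                quad = (total * (e**2).sum() - 2.0 * off * (e[:, 0] * e[:, 1]).sum()) / det
                ll += -0.5 * (sel.sum() * (2 * _LOG2PI + np.log(det)) + quad)
        if ys.size:
            e = ys - mu_y - xs @ beta
            ll += -0.5 * (ys.size * (_LOG2PI + np.log(total)) + (e**2).sum() / total)
        return float(ll)

    def objective(theta):
        phi = np.concatenate([np.exp(theta[:3]), theta[3:]])
        return -loglik_natural(phi)

    s2_0, mu_y0, beta0, *_ = _moment_starts(deleted)
    theta0 = np.concatenate([np.log(np.maximum(s2_0, 1e-8)), [mu_y0], beta0])
    res = minimize(objective, theta0, method="L-BFGS-B", options=_OPTIONS)
    s2 = np.exp(res.x[:3])
    ace = ACEParams(s2[0], s2[1], s2[2], mu_y=float(res.x[3]))
    weights = RegressionWeights(res.x[4:])
    boundary = tuple(
        name
        for name, val in zip(("sigma2_A", "sigma2_C", "sigma2_E"), s2)
        if val < _BOUNDARY_TOL
    )
    names = ["sigma2_A", "sigma2_C", "sigma2_E", "mu_y"] + [
        f"beta_{j}" for j in range(1, K + 1)
    ]
    se_dict, h2_se = None, np.nan
    if compute_se:
        phi_hat = np.concatenate([s2, res.x[3:]])
        se_arr, cov, ok = standard_errors(loglik_natural, phi_hat, return_cov=True)
        se_dict = dict(zip(names, se_arr))
        h2_se = delta_method_h2_se(s2, cov[:3, :3]) if ok else np.nan
    return FitResult(
        approach="usual",
        ace=ace,
        weights=weights,
        h2=float(np.clip(heritability(ace), 0.0, 1.0)),
        h2_se=h2_se,
        se=se_dict,
        loglik=float(-res.fun),
        converged=bool(res.success),
        n_iter=int(res.nit),
        n_pairs_used=n_pairs_used,
        n_singletons_used=n_singles,
        boundary=boundary,
        message=str(res.message),
    )


# ---------------------------------------------------------------------------
# observed information / standard errors
# ---------------------------------------------------------------------------

def observed_information(loglik_fn, x: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Negative Hessian of the log-likelihood by central finite differences."""
    x = np.asarray(x, dtype=float)
    p = x.size
    h = step * np.maximum(np.abs(x), 1e-2)
    H = np.empty((p, p))
    f0 = loglik_fn(x)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        H[i, i] = (loglik_fn(x + ei) - 2.0 * f0 + loglik_fn(x - ei)) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                loglik_fn(x + ei + ej)
                - loglik_fn(x + ei - ej)
                - loglik_fn(x - ei + ej)
                + loglik_fn(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return -H


def standard_errors(loglik_fn, x: np.ndarray, step: float = 1e-5, return_cov: bool = False):
    """Observed-information standard errors at a maximizer.

    Returns an array of SEs (NaN where the information is not invertible or
    the corresponding variance is negative).  With ``return_cov=True`` also
    returns the full parameter covariance and an invertibility flag.
    """
    info = observed_information(loglik_fn, x, step=step)
    try:
        cov = np.linalg.inv(info)
        ok = True
    except np.linalg.LinAlgError:
        cov = np.full_like(info, np.nan)
        ok = False
    diag = np.diagonal(cov)
    se = np.where(diag > 0, np.sqrt(np.abs(diag)), np.nan)
    if return_cov:
        return se, cov, ok
    return se


def delta_method_h2_se(s2: np.ndarray, cov3: np.ndarray) -> float:
    """Delta-method SE of h2 = A / (A + C + E) from the ACE covariance block."""
    a, c, e = s2
    total = a + c + e
    grad = np.array([c + e, -a, -a]) / total**2
    var = float(grad @ cov3 @ grad)
    return float(np.sqrt(var)) if var > 0 and np.isfinite(var) else np.nan
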