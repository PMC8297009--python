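"""Maximum-likelihood confirmatory factor analysis with robust corrections.

Fits any :class:`~pfactorlab.models.ModelSpec` to a sample covariance (in
this package usually a Pearson correlation matrix) by minimizing the
normal-theory discrepancy

    F_ML(theta) = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - p

over free loadings, free factor correlations and residual variances, with
factors identified by unit variance. When raw data are available the
mean-scaled (Satorra-Bentler) chi-square and sandwich standard errors are
computed from the empirical fourth-moment matrix, the standard robustness
correction for skewed data.

Residual variances and factor correlations are unconstrained during
optimization: Heywood cases (negative unique variances) and non-positive-
definite latent covariance matrices are diagnosed after the fit rather
than prevented, mirroring how inadmissible solutions surface in practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .models import ModelSpec, ParameterSet, model_df

__all__ = [
    "SampleMoments",
    "AdmissibilityReport",
    "FitResult",
    "fit_ml",
    "check_admissibility",
    "duplication_matrix",
    "fourth_moment_matrix",
    "satorra_bentler_scaling",
]

_EIG_TOL = -1e-8  # eigenvalue threshold for "non-positive-definite" flags
_CONVERGED_GRAD_TOL = 1e-4  # gradient inf-norm below which a fit counts as converged


def duplication_matrix(p: int) -> np.ndarray:
    """D such that vec(M) = D vech(M) for symmetric p x p M (lower-triangle vech)."""
    rows_i, rows_j = np.tril_indices(p)
    D = np.zeros((p * p, len(rows_i)))
    for col, (i, j) in enumerate(zip(rows_i, rows_j)):
        D[i * p + j, col] = 1.0
        D[j * p + i, col] = 1.0
    return D


def _vech(mat: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(mat.shape[0])
    return mat[i, j]


def fourth_moment_matrix(data: np.ndarray) -> np.ndarray:
    """Asymptotic covariance (Gamma) of sqrt(n) vech(S), estimated from raw data.

    Gamma_{ab} = E[d_a d_b] - E[d_a] E[d_b] with d = vech of the centered
    cross-product for each row; biased (1/n) divisor.
    """
    x = np.asarray(data, dtype=float)
    xc = x - x.mean(axis=0)
    i, j = np.tril_indices(x.shape[1])
    y = xc[:, i] * xc[:, j]
    ybar = y.mean(axis=0)
    return (y.T @ y) / len(y) - np.outer(ybar, ybar)


@dataclass
class SampleMoments:
    """Sample covariance matrix, sample size and optional fourth moments.

    ``means``/``sds`` record the scaling applied when the matrix was
    computed from standardized data, so factor-scoring weights can be
    applied to new observations on the original scale.
    """

    covariance: np.ndarray
    n: int
    fourth_moment: np.ndarray | None = None
    means: np.ndarray | None = None
    sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.covariance = np.asarray(self.covariance, dtype=float)
        p = self.covariance.shape[0]
        if self.covariance.shape != (p, p):
            raise ValueError("covariance must be square")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")

    @classmethod
    def from_data(cls, data, standardize: bool = True) -> "SampleMoments":
        """Moments from a raw data matrix (rows = subjects).

        With ``standardize=True`` (default) the Pearson correlation matrix
        is analyzed and the fourth-moment matrix is computed on the
        standardized scale.
        """
        x = np.asarray(data, dtype=float)
        means = x.mean(axis=0)
        sds = x.std(axis=0, ddof=0)
        if np.any(sds == 0):
            raise ValueError("zero-variance column in data")
        if standardize:
            x = (x - means) / sds
        cov = np.cov(x, rowvar=False, ddof=0)
        return cls(
            covariance=cov,
            n=len(x),
            fourth_moment=fourth_moment_matrix(x),
            means=means,
            sds=sds,
        )

    @classmethod
    def from_covariance(cls, covariance, n: int) -> "SampleMoments":
        return cls(covariance=np.asarray(covariance, dtype=float), n=int(n))


@dataclass
class AdmissibilityReport:
    """Solution-quality flags; ``overall_admissible`` is their conjunction."""

    converged: bool
    all_loadings_significant: bool
    no_negative_loadings: bool
    no_negative_variances: bool
    no_npd_issues: bool
    alpha: float = 0.05

    @property
    def overall_admissible(self) -> bool:
        return (
            self.converged
            and self.all_loadings_significant
            and self.no_negative_loadings
            and self.no_negative_variances
            and self.no_npd_issues
        )

    def to_dict(self) -> dict:
        return {
            "converged": self.converged,
            "all_loadings_significant": self.all_loadings_significant,
            "no_negative_loadings": self.no_negative_loadings,
            "no_negative_variances": self.no_negative_variances,
            "no_npd_issues": self.no_npd_issues,
            "overall_admissible": self.overall_admissible,
            "alpha": self.alpha,
        }


@dataclass
class FitResult:
    """Estimates and diagnostics from one ML fit."""

    spec: ModelSpec
    params: ParameterSet
    theta: np.ndarray
    f_min: float
    chi2_naive: float
    df: int
    n: int
    converged: bool
    gradient_norm: float
    standard_errors_naive: np.ndarray | None = None
    standard_errors_robust: np.ndarray | None = None
    chi2_scaled: float | None = None
    scaling_factor: float | None = None
    se_warning: str | None = None
    moments: SampleMoments | None = None
    admissibility: AdmissibilityReport | None = None

    @property
    def chi2(self) -> float:
        """Scaled statistic when available, else the naive one."""
        return self.chi2_naive if self.chi2_scaled is None else self.chi2_scaled

    @property
    def implied(self) -> np.ndarray:
        lam, phi = self.params.loadings, self.params.factor_correlations
        return lam @ phi @ lam.T + np.diag(self.params.residual_variances)

    @property
    def standard_errors(self) -> np.ndarray | None:
        if self.standard_errors_robust is not None:
            return self.standard_errors_robust
        return self.standard_errors_naive

    @property
    def z_values(self) -> np.ndarray | None:
        se = self.standard_errors
        if se is None:
            return None
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.theta / se

    def free_loading_indices(self) -> np.ndarray:
        return np.arange(self.spec.n_free_loadings)

    def to_dict(self) -> dict:
        out = {
            "model_id": self.spec.model_id,
            "n": self.n,
            "df": self.df,
            "f_min": self.f_min,
            "chi2_naive": self.chi2_naive,
            "chi2_scaled": self.chi2_scaled,
            "scaling_factor": self.scaling_factor,
            "converged": self.converged,
            "loadings": self.params.loadings.tolist(),
            "factor_correlations": self.params.factor_correlations.tolist(),
            "residual_variances": self.params.residual_variances.tolist(),
            "standard_errors": None
            if self.standard_errors is None
            else self.standard_errors.tolist(),
        }
        if self.admissibility is not None:
            out["admissibility"] = self.admissibility.to_dict()
        return out


class _Parameterization:
    """Maps the flat parameter vector to (Lambda, Phi, Theta) and back."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.load_idx = np.argwhere(spec.loading_pattern)  # (n_load, 2)
        self.corr_pairs = spec.correlation_pairs()
        self.p = len(spec.indicators)
        self.k = spec.n_factors
        self.n_load = len(self.load_idx)
        self.n_corr = len(self.corr_pairs)
        self.n_free = self.n_load + self.n_corr + self.p

    def start_values(self) -> np.ndarray:
        theta = np.empty(self.n_free)
        theta[: self.n_load] = 0.5
        theta[self.n_load : self.n_load + self.n_corr] = 0.0
        theta[self.n_load + self.n_corr :] = 0.5
        return theta

    def unpack(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        lam = np.zeros((self.p, self.k))
        lam[self.load_idx[:, 0], self.load_idx[:, 1]] = theta[: self.n_load]
        phi = np.eye(self.k)
        for m, (a, b) in enumerate(self.corr_pairs):
            phi[a, b] = phi[b, a] = theta[self.n_load + m]
        resid = theta[self.n_load + self.n_corr :]
        return lam, phi, resid

    def sigma(self, theta: np.ndarray) -> np.ndarray:
        lam, phi, resid = self.unpack(theta)
        return lam @ phi @ lam.T + np.diag(resid)

    def jacobian_vech(self, theta: np.ndarray) -> np.ndarray:
        """d vech(Sigma) / d theta, one column per free parameter."""
        lam, phi, _ = self.unpack(theta)
        lam_phi = lam @ phi
        p = self.p
        cols = []
        for i, f in self.load_idx:
            d = np.zeros((p, p))
            d[i, :] += lam_phi[:, f]
            d[:, i] += lam_phi[:, f]
            cols.append(_vech(d))
        for a, b in self.corr_pairs:
            d = np.outer(lam[:, a], lam[:, b])
            d = d + d.T
            cols.append(_vech(d))
        for i in range(p):
            d = np.zeros((p, p))
            d[i, i] = 1.0
            cols.append(_vech(d))
        return np.column_stack(cols)


_PENALTY_EIG = 1e-8
_PENALTY_SCALE = 1e4


def _grad_from_multiplier(a, theta, par: _Parameterization):
    """Gradient of tr(A Sigma(theta)) for symmetric A, one entry per free parameter."""
    lam, phi, _ = par.unpack(theta)
    grad = np.empty_like(theta)
    alp = a @ lam @ phi
    grad[: par.n_load] = 2.0 * alp[par.load_idx[:, 0], par.load_idx[:, 1]]
    lal = lam.T @ a @ lam
    for m, (i, j) in enumerate(par.corr_pairs):
        grad[par.n_load + m] = 2.0 * lal[i, j]
    grad[par.n_load + par.n_corr :] = np.diag(a)
    return grad


def _fml_and_grad(theta, par: _Parameterization, s, logdet_s):
    sigma = par.sigma(theta)
    eigvals, eigvecs = np.linalg.eigh(sigma)
    if eigvals[0] <= _PENALTY_EIG:
        # smooth surrogate outside the PD region: penalize eigenvalue
        # shortfall so line searches are pushed back toward feasibility
        bad = eigvals < _PENALTY_EIG
        shortfall = _PENALTY_EIG - eigvals[bad]
        f = _PENALTY_SCALE * (1.0 + np.sum(shortfall))
        a = -_PENALTY_SCALE * (eigvecs[:, bad] @ eigvecs[:, bad].T)
        return f, _grad_from_multiplier(a, theta, par)
    logdet = np.sum(np.log(eigvals))
    sigma_inv = (eigvecs / eigvals) @ eigvecs.T
    f = logdet + np.trace(s @ sigma_inv) - logdet_s - par.p
    # dF = tr[(Sigma^-1 - Sigma^-1 S Sigma^-1) dSigma]
    a = sigma_inv - sigma_inv @ s @ sigma_inv
    return f, _grad_from_multiplier(a, theta, par)


def _fisher_polish(theta, par: _Parameterization, s, logdet_s, gtol, max_iter=200):
    """Fisher-scoring refinement with a Levenberg-Marquardt ridge.

    Newton steps on the expected information 2 Delta' W Delta; the ridge
    adapts so the iteration degrades gracefully to gradient descent on the
    flat directions of collapsing (quasi-Heywood) solutions."""
    dup = duplication_matrix(par.p)
    f, g = _fml_and_grad(theta, par, s, logdet_s)
    lam_ridge = 1e-6
    eye = np.eye(par.n_free)
    for _ in range(max_iter):
        if np.max(np.abs(g)) < gtol:
            break
        sigma = par.sigma(theta)
        if np.linalg.eigvalsh(sigma)[0] <= _PENALTY_EIG:
            break  # outside the PD region: leave it to the caller
        sigma_inv = np.linalg.inv(sigma)
        weight = _normal_theory_weight(sigma_inv, dup)
        delta = par.jacobian_vech(theta)
        h = 2.0 * delta.T @ weight @ delta
        scale = max(np.trace(h) / h.shape[0], 1e-8)
        improved = False
        for _ in range(15):
            try:
                step = np.linalg.solve(h + lam_ridge * scale * eye, g)
            except np.linalg.LinAlgError:
                lam_ridge *= 10.0
                continue
            f_new, g_new = _fml_and_grad(theta - step, par, s, logdet_s)
            if f_new < f:
                theta = theta - step
                f, g = f_new, g_new
                lam_ridge = max(lam_ridge / 3.0, 1e-9)
                improved = True
                break
            lam_ridge *= 10.0
        if not improved:
            break
    return theta, f, g


def _canonical_sign(lam: np.ndarray, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resolve factor sign indeterminacy: each factor's loading sum positive."""
    lam, phi = lam.copy(), phi.copy()
    for f in range(lam.shape[1]):
        if lam[:, f].sum() < 0:
            lam[:, f] *= -1.0
            phi[f, :] *= -1.0
            phi[:, f] *= -1.0
    return lam, phi


def _normal_theory_weight(sigma_inv: np.ndarray, dup: np.ndarray) -> np.ndarray:
    return 0.5 * dup.T @ np.kron(sigma_inv, sigma_inv) @ dup


def satorra_bentler_scaling(
    delta: np.ndarray,
    weight: np.ndarray,
    gamma: np.ndarray,
    df: int,
) -> float:
    """Mean-scaling factor c = tr(U Gamma) / df for the scaled chi-square.

    U = W - W Delta (Delta' W Delta)^-1 Delta' W, with W the normal-theory
    weight matrix evaluated at the fitted Sigma and Gamma the empirical
    fourth-moment matrix.
    """
    h = delta.T @ weight @ delta
    wd = weight @ delta
    u = weight - wd @ np.linalg.solve(h, wd.T)
    return float(np.trace(u @ gamma) / df)


def fit_ml(
    moments: SampleMoments,
    spec: ModelSpec,
    max_iter: int = 500,
    gtol: float = 1e-7,
    start: np.ndarray | None = None,
    compute_se: bool = True,
) -> FitResult:
    """Fit a model to sample moments by maximum likelihood.

    Non-convergence is reported through the ``converged`` flag, never as an
    exception; a non-positive-definite sample matrix is an exception (the
    discrepancy function is undefined).
    """
    s = moments.covariance
    try:
        chol_s = np.linalg.cholesky(s)
    except np.linalg.LinAlgError as exc:
        raise ValueError("sample covariance matrix is not positive definite") from exc
    logdet_s = 2.0 * np.sum(np.log(np.diag(chol_s)))

    par = _Parameterization(spec)
    theta0 = par.start_values() if start is None else np.asarray(start, dtype=float)
    # quasi-Newton first (fast on the penalized-smooth surface), then
    # Fisher scoring to drive the gradient to tolerance, with a
    # trust-region rescue for the rare cases both leave unconverged
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(
            _fml_and_grad,
            theta0,
            args=(par, s, logdet_s),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "maxfun": 20 * max_iter, "gtol": gtol, "ftol": 1e-15},
        )
        theta, f_min, grad = res.x, res.fun, res.jac
        if np.max(np.abs(grad)) > gtol:
            theta, f_min, grad = _fisher_polish(theta, par, s, logdet_s, gtol)
        # a solution running down an unbounded Heywood ridge (residual
        # variances far below zero on the standardized metric) never meets
        # the gradient criterion: flag it instead of polishing further
        _, _, resid_now = par.unpack(theta)
        diverging = resid_now.min() < -1.0
        if np.max(np.abs(grad)) > _CONVERGED_GRAD_TOL and not diverging:
            res2 = optimize.minimize(
                _fml_and_grad,
                theta,
                args=(par, s, logdet_s),
                jac=True,
                method="trust-constr",
                options={"maxiter": max_iter, "gtol": gtol, "xtol": 1e-14},
            )
            if res2.fun <= f_min:
                theta = res2.x
                theta2, f2, g2 = _fisher_polish(theta, par, s, logdet_s, gtol, max_iter=30)
                theta, f_min, grad = theta2, f2, g2

    f_min, grad = _fml_and_grad(theta, par, s, logdet_s)
    grad_norm = float(np.max(np.abs(grad))) if np.all(np.isfinite(grad)) else np.inf
    converged = (
        bool(np.isfinite(f_min))
        and f_min < _PENALTY_SCALE / 2
        and grad_norm < _CONVERGED_GRAD_TOL
    )

    lam, phi, resid = par.unpack(theta)
    lam, phi = _canonical_sign(lam, phi)
    # write the sign-fixed values back into the canonical theta layout
    theta = np.concatenate([
        lam[par.load_idx[:, 0], par.load_idx[:, 1]],
        [phi[a, b] for a, b in par.corr_pairs],
        resid,
    ])
    params = ParameterSet(
        loadings=lam,
        factor_correlations=phi,
        residual_variances=resid,
        factor_labels=spec.factor_labels,
        indicators=spec.indicators,
    )

    df = model_df(spec)
    fit = FitResult(
        spec=spec,
        params=params,
        theta=theta,
        f_min=max(float(f_min), 0.0) if np.isfinite(f_min) else float("inf"),
        chi2_naive=float(moments.n * max(f_min, 0.0)) if np.isfinite(f_min) else float("inf"),
        df=df,
        n=moments.n,
        converged=converged,
        gradient_norm=grad_norm,
        moments=moments,
    )

    if compute_se and converged:
        _add_corrections(fit, par)
    fit.admissibility = check_admissibility(fit)
    return fit


def _add_corrections(fit: FitResult, par: _Parameterization) -> None:
    """Normal-theory SEs always; scaled chi-square and sandwich SEs when
    the sample moments carry a fourth-moment matrix."""
    sigma = fit.implied
    try:
        sigma_inv = np.linalg.inv(sigma)
    except np.linalg.LinAlgError:
        fit.se_warning = "implied covariance singular; no standard errors"
        return
    dup = duplication_matrix(par.p)
    weight = _normal_theory_weight(sigma_inv, dup)
    delta = par.jacobian_vech(fit.theta)
    h = delta.T @ weight @ delta
    rank = np.linalg.matrix_rank(h, tol=1e-10 * np.abs(h).max())
    if rank < h.shape[0]:
        fit.se_warning = "rank-deficient information matrix; naive values retained"
        h_inv = np.linalg.pinv(h)
    else:
        h_inv = np.linalg.inv(h)
    with np.errstate(invalid="ignore"):
        fit.standard_errors_naive = np.sqrt(np.clip(np.diag(h_inv), 0.0, None) / fit.n)

    gamma = fit.moments.fourth_moment if fit.moments is not None else None
    if gamma is None:
        return
    if fit.se_warning is not None:
        return
    try:
        c = satorra_bentler_scaling(delta, weight, gamma, fit.df)
    except np.linalg.LinAlgError:
        fit.se_warning = "scaling factor not computable; naive values retained"
        return
    if c <= 0 or not np.isfinite(c):
        fit.se_warning = "non-positive scaling factor; naive values retained"
        return
    fit.scaling_factor = c
    fit.chi2_scaled = fit.chi2_naive / c
    sandwich = h_inv @ (delta.T @ weight @ gamma @ weight @ delta) @ h_inv
    with np.errstate(invalid="ignore"):
        fit.standard_errors_robust = np.sqrt(np.clip(np.diag(sandwich), 0.0, None) / fit.n)


def check_admissibility(fit: FitResult, alpha: float = 0.05) -> AdmissibilityReport:
    """Apply the admissibility screen: convergence, all free loadings
    significant at two-sided ``alpha``, no negative standardized loadings
    (after the canonical sign convention), no negative residual variances,
    and positive-definite implied and latent covariance matrices."""
    n_load = fit.spec.n_free_loadings
    crit = stats.norm.ppf(1.0 - alpha / 2.0)

    z = fit.z_values
    if z is None or not np.all(np.isfinite(z[:n_load])):
        significant = False
    else:
        significant = bool(np.all(np.abs(z[:n_load]) >= crit))

    diag = np.diag(fit.implied)
    with np.errstate(invalid="ignore"):
        std_load = fit.params.loadings / np.sqrt(np.clip(diag, 1e-12, None))[:, None]
    free = fit.spec.loading_pattern
    no_neg_load = bool(np.all(std_load[free] > -1e-8))

    no_neg_var = bool(np.all(fit.params.residual_variances > _EIG_TOL))

    implied_ok = np.linalg.eigvalsh(fit.implied).min() > _EIG_TOL
    latent_ok = np.linalg.eigvalsh(fit.params.factor_correlations).min() > _EIG_TOL
    return AdmissibilityReport(
        converged=fit.converged,
        all_loadings_significant=significant,
        no_negative_loadings=no_neg_load,
        no_negative_variances=no_neg_var,
        no_npd_issues=bool(implied_ok and latent_ok),
        alpha=alpha,
    )
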