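"""Discrepancy-function fitting of a ModelSpec to sample moments.

Default estimator is unweighted least squares (ULS) over the nonredundant
moment vector; DWLS (user-supplied diagonal weights) and a normal-theory ML
discrepancy are also available.  Standard errors use a sandwich formula
with a normal-theory moment covariance — an approximation to raw-data
weighted least squares, adequate for significance *patterns* but not exact
replication of published SEs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .model_spec import ModelSpec, ThetaVector, theta_unpack
from .moments import (
    ImpliedMoments,
    SampleMoments,
    criterion_residuals,
    implied_covariance,
    implied_jacobian,
    vech,
    vech_indices,
)

__all__ = [
    "FitResult",
    "StandardizedSolution",
    "ConvergenceError",
    "NotIdentifiedError",
    "HeywoodWarning",
    "fit",
    "standardize",
    "rsquared",
    "standard_errors",
    "default_start",
]


class ConvergenceError(RuntimeError):
    pass


class NotIdentifiedError(RuntimeError):
    """Jacobian at the solution is rank deficient; see the identification module."""


class HeywoodWarning(UserWarning):
    pass


@dataclass
class FitResult:
    model: ModelSpec
    moments: SampleMoments
    theta: ThetaVector
    discrepancy: float
    df: int
    statistic: float
    converged: bool
    grad_norm: float
    implied: ImpliedMoments
    estimator: str
    se: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)
    n_restarts_used: int = 0

    def estimates(self) -> pd.Series:
        return pd.Series(self.theta.values, index=self.theta.labels, name="estimate")


@dataclass
class StandardizedSolution:
    loadings: pd.DataFrame            # indicator x factor standardized loadings
    factor_corr: pd.DataFrame         # factors (and criterion latents) correlation matrix
    regressions: pd.DataFrame | None  # criterion x factor standardized coefficients
    r2: pd.Series | None              # per criterion (regression mode)
    reliability: pd.Series            # per indicator, 1 - standardized residual variance
    residual_corr: pd.DataFrame | None = None  # criterion residual correlations


# ---------------------------------------------------------------------------


def default_start(model: ModelSpec, moments: SampleMoments) -> ThetaVector:
    """Start values: loadings 1, factor variances half the mean indicator
    variance, covariances 0, error variances half the indicator variance."""
    theta = model.default_theta()
    s = moments.subset(model.var_names)
    diag = dict(zip(s.order, np.diag(s.matrix)))
    ind_var = np.mean([diag[v.name] for v in model.variables if v.role == "indicator"])
    vals = theta.values
    for j, cells in enumerate(model.slot_cells):
        c = cells[0]
        if c.matrix == "loading":
            vals[j] = 1.0
        elif c.matrix == "factor_cov":
            if c.row == c.col:
                fac = model.factor(c.row)
                vals[j] = 1.0 if fac.kind == "criterion-latent" else 0.5 * ind_var
            else:
                vals[j] = 0.0
        elif c.matrix == "error_cov":
            vals[j] = 0.5 * diag.get(c.row, 1.0) if c.row == c.col else 0.0
        elif c.matrix in ("regression", "criterion_residual_cov"):
            vals[j] = 0.0
    return theta


def _residual_fn(model, sdata, widx, sqw):
    def resid(values):
        mats = theta_unpack(model, values)
        from .moments import _sigma_from_matrices

        sigma = _sigma_from_matrices(model, mats)
        return sqw * (vech(sigma, widx) - sdata)

    return resid


def _jitter(values, slot_kinds, rng):
    out = values.copy()
    for j, kind in enumerate(slot_kinds):
        if kind == "variance":
            out[j] = abs(out[j]) * rng.uniform(0.5, 1.5) + 1e-3
        else:
            out[j] = out[j] * rng.uniform(0.8, 1.2) + rng.normal(0, 0.1)
    return out


def _slot_kinds(model: ModelSpec) -> list[str]:
    kinds = []
    for cells in model.slot_cells:
        c = cells[0]
        if c.matrix in ("factor_cov", "error_cov") and c.row == c.col:
            kinds.append("variance")
        else:
            kinds.append("other")
    return kinds


def fit(
    model: ModelSpec,
    moments: SampleMoments,
    estimator: str = "ULS",
    weights: np.ndarray | None = None,
    start: ThetaVector | None = None,
    restarts: int = 5,
    seed: int = 0,
    gtol: float = 1e-8,
) -> FitResult:
    """Minimize the discrepancy between sample and implied moments.

    ULS: F = sum_m (s_m - sigma_m)^2; DWLS uses the supplied per-moment
    weights; ML uses log|Sigma| + tr(S Sigma^-1) - log|S| - p.  A seeded
    jittered-restart schedule guards against bad starts; non-convergence
    after the schedule raises :class:`ConvergenceError`.
    """
    estimator = estimator.upper()
    if estimator not in ("ULS", "DWLS", "ML"):
        raise ValueError(f"unknown estimator {estimator!r}")
    s = moments.subset(model.var_names)
    widx = vech_indices(model)
    sdata = vech(s.matrix, widx)
    if estimator == "DWLS":
        if weights is None:
            raise ValueError("DWLS requires a weight vector")
        w = np.asarray(weights, float)
        if w.shape != sdata.shape:
            raise ValueError("weights not conformable with the moment vector")
    else:
        w = np.ones_like(sdata)
    sqw = np.sqrt(w)

    theta0 = (start or default_start(model, moments)).copy()
    if len(theta0) != model.n_free:
        raise ValueError("start vector not conformable with the model")
    kinds = _slot_kinds(model)
    rng = np.random.default_rng(seed)

    resid = _residual_fn(model, sdata, widx, sqw)

    def jac(values):
        return sqw[:, None] * implied_jacobian(model, values)

    best = None
    x0 = theta0.values.copy()
    attempts = 0
    for attempt in range(restarts + 1):
        attempts = attempt
        if estimator in ("ULS", "DWLS"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sol = optimize.least_squares(
                    resid, x0, jac=jac, method="trf",
                    xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
                )
            xhat = sol.x
            F = float(np.sum(resid(xhat) ** 2))
            grad = 2 * jac(xhat).T @ resid(xhat)
        else:
            Smat = s.matrix
            sign, logdet_s = np.linalg.slogdet(Smat)
            p = Smat.shape[0]

            def fml(values):
                sigma = implied_covariance(model, values).matrix
                try:
                    chol = np.linalg.cholesky(sigma)
                except np.linalg.LinAlgError:
                    return 1e10
                logdet = 2 * np.sum(np.log(np.diag(chol)))
                tr = float(np.trace(np.linalg.solve(sigma, Smat)))
                return logdet + tr - logdet_s - p

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sol = optimize.minimize(fml, x0, method="L-BFGS-B",
                                        options={"maxiter": 5000, "ftol": 1e-14,
                                                 "gtol": 1e-10})
            xhat = sol.x
            F = float(fml(xhat))
            grad = optimize.approx_fprime(xhat, fml, 1e-7)
        gnorm = float(np.max(np.abs(grad)))
        gtol_eff = max(gtol, 1e-4) if estimator == "ML" else max(gtol, 1e-6 * max(1.0, F))
        ok = np.all(np.isfinite(xhat)) and gnorm <= gtol_eff
        if best is None or F < best[1]:
            best = (xhat, F, gnorm, ok)
        if ok and F <= best[1] + 1e-12:
            break
        x0 = _jitter(theta0.values, kinds, rng)

    xhat, F, gnorm, ok = best
    if not ok:
        raise ConvergenceError(
            f"optimizer failed to converge after {restarts} restarts "
            f"(gradient inf-norm {gnorm:.3g})"
        )

    theta_hat = ThetaVector(xhat, list(model.slot_labels))
    implied = implied_covariance(model, theta_hat)
    warns = _heywood_checks(model, theta_hat)
    for msg in warns:
        warnings.warn(msg, HeywoodWarning)

    df = model.n_moments - model.n_free
    return FitResult(
        model=model, moments=s, theta=theta_hat, discrepancy=F, df=df,
        statistic=(s.n - 1) * F, converged=True, grad_norm=gnorm,
        implied=implied, estimator=estimator, warnings=warns,
        n_restarts_used=attempts,
    )


def _heywood_checks(model: ModelSpec, theta: ThetaVector) -> list[str]:
    warns = []
    for j, cells in enumerate(model.slot_cells):
        c = cells[0]
        if c.matrix in ("factor_cov", "error_cov") and c.row == c.col:
            if theta.values[j] < -1e-10:
                warns.append(f"Heywood case: negative variance estimate at "
                             f"{model.slot_labels[j]} = {theta.values[j]:.4g}")
    if model.mode == "regression":
        psi = criterion_residuals(model, theta)
        for i, name in enumerate(model.criterion_names):
            if psi[i, i] < -1e-10:
                warns.append(f"Heywood case: negative residual variance for criterion "
                             f"{name} = {psi[i, i]:.4g}")
    return warns


# ---------------------------------------------------------------------------
# standardization


def standardize(fitres: FitResult) -> StandardizedSolution:
    """Standardized loadings, factor correlations, regressions, R^2 and
    reliabilities at the fitted solution."""
    if not fitres.converged:
        raise ValueError("standardize requires a converged fit")
    model = fitres.model
    mats = theta_unpack(model, fitres.theta)
    lam, phi = mats["lambda"], mats["phi"]
    sigma = fitres.implied.matrix
    sd_var = np.sqrt(np.diag(sigma))
    sd_fac = np.sqrt(np.diag(phi))
    if np.any(np.diag(phi) <= 0) or np.any(np.diag(sigma) <= 0):
        raise ValueError("zero or negative variance in a standardization denominator")

    ind = [i for i, v in enumerate(model.variables) if v.role == "indicator"]
    ind_names = [model.var_names[i] for i in ind]
    load_std = lam[ind, :] * sd_fac[None, :] / sd_var[ind, None]
    loadings = pd.DataFrame(load_std, index=ind_names, columns=model.factor_names)

    denom = np.outer(sd_fac, sd_fac)
    factor_corr = pd.DataFrame(phi / denom, index=model.factor_names,
                               columns=model.factor_names)

    tht = mats["theta"]
    rel = pd.Series(
        [1.0 - tht[i, i] / sigma[i, i] for i in ind], index=ind_names, name="reliability"
    )

    regressions = r2 = residual_corr = None
    if model.mode == "regression":
        beta = mats["beta"]
        crit = model.criterion_names
        vnames = model.var_names
        sd_crit = np.array([sd_var[vnames.index(c)] for c in crit])
        b_std = (beta * sd_fac[:, None] / sd_crit[None, :]).T
        regressions = pd.DataFrame(b_std, index=crit, columns=model.factor_names)
        r2 = rsquared(fitres)
        psi = criterion_residuals(model, fitres.theta)
        d = np.sqrt(np.abs(np.diag(psi)))
        with np.errstate(divide="ignore", invalid="ignore"):
            residual_corr = pd.DataFrame(psi / np.outer(d, d), index=crit, columns=crit)

    return StandardizedSolution(loadings, factor_corr, regressions, r2, rel, residual_corr)


def rsquared(fitres: FitResult) -> pd.Series:
    """Per-criterion R^2 = 1 - residual variance / implied total variance."""
    model = fitres.model
    if model.mode != "regression":
        raise ValueError("R^2 is defined in regression-extension mode only")
    psi = criterion_residuals(model, fitres.theta)
    sigma = fitres.implied.matrix
    vnames = model.var_names
    out = {}
    for i, c in enumerate(model.criterion_names):
        total = sigma[vnames.index(c), vnames.index(c)]
        out[c] = 1.0 - psi[i, i] / total
    return pd.Series(out, name="r2")


# ---------------------------------------------------------------------------
# standard errors


def _normal_theory_gamma(sigma: np.ndarray, idx) -> np.ndarray:
    """Cov of sample moments under normality: Gamma_{(ij),(kl)} =
    sigma_ik sigma_jl + sigma_il sigma_jk (scaled by 1/(n-1) downstream)."""
    m = len(idx)
    G = np.empty((m, m))
    for a, (i, j) in enumerate(idx):
        for b, (k, l) in enumerate(idx):
            G[a, b] = sigma[i, k] * sigma[j, l] + sigma[i, l] * sigma[j, k]
    return G


def standard_errors(
    fitres: FitResult,
    moments: SampleMoments | None = None,
    rank_tol_factor: float = 1e3,
) -> np.ndarray:
    """Sandwich (GLS / delta-method) standard errors.

    V = (J'WJ)^-1 J'W Gamma W J (J'WJ)^-1 / (n-1) with Gamma the
    normal-theory covariance of the moment vector at the fitted solution.
    Raises :class:`NotIdentifiedError` when the Jacobian is rank deficient.
    """
    model = fitres.model
    moments = moments or fitres.moments
    idx = vech_indices(model)
    J = implied_jacobian(model, fitres.theta)
    sv = np.linalg.svd(J, compute_uv=False)
    tol = max(J.shape) * np.finfo(float).eps * sv[0] * rank_tol_factor
    rank = int(np.sum(sv > tol))
    if rank < model.n_free:
        raise NotIdentifiedError(
            f"model is not locally identified at the solution (rank {rank} < "
            f"{model.n_free} free parameters); run the identification module "
            "for the null-space directions"
        )
    if fitres.estimator == "DWLS":
        raise NotImplementedError("SEs implemented for ULS/ML fits")
    W = np.eye(len(idx))
    gamma = _normal_theory_gamma(fitres.implied.matrix, idx)
    A = J.T @ W @ J
    Ainv = np.linalg.inv(A)
    B = J.T @ W @ gamma @ W @ J
    V = Ainv @ B @ Ainv / (moments.n - 1)
    se = np.sqrt(np.diag(V))
    fitres.se = se
    return se


def significance(fitres: FitResult, z: float = 1.96) -> pd.DataFrame:
    """Estimate / SE table with a two-sided significance flag at |z| >= 1.96."""
    if fitres.se is None:
        standard_errors(fitres)
    est = fitres.theta.values
    zval = np.divide(est, fitres.se, out=np.zeros_like(est), where=fitres.se > 0)
    return pd.DataFrame(
        {"estimate": est, "se": fitres.se, "z": zval, "significant": np.abs(zval) >= z},
        index=fitres.theta.labels,
    )
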