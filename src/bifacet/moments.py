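"""Sample and model-implied moment matrices.

Moments are half-vectorized (lower triangle, row-major); the diagonal
entries of unit-variance latent-response criteria are fixed by convention
and excluded from the nonredundant moment vector, which is also the
degrees-of-freedom convention used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_spec import ModelSpec, ThetaVector, theta_unpack

__all__ = [
    "SampleMoments",
    "ImpliedMoments",
    "MomentError",
    "assemble_moments",
    "vech_indices",
    "vech",
    "implied_covariance",
    "implied_jacobian",
]


class MomentError(ValueError):
    pass


@dataclass
class SampleMoments:
    order: list[str]
    matrix: np.ndarray
    n: int
    scales: dict[str, str] = field(default_factory=dict)  # name -> continuous|latent-response
    source: str = "assembled"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        p = len(self.order)
        if self.matrix.shape != (p, p):
            raise MomentError(f"matrix shape {self.matrix.shape} != ({p},{p})")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise MomentError("moment matrix is not symmetric")
        if np.any(np.diag(self.matrix) <= 0):
            raise MomentError("non-positive diagonal entry")
        for name in self.order:
            self.scales.setdefault(name, "continuous")

    def subset(self, names: list[str]) -> "SampleMoments":
        idx = [self.order.index(n) for n in names]
        return SampleMoments(list(names), self.matrix[np.ix_(idx, idx)], self.n,
                             {n: self.scales[n] for n in names}, self.source)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.order, columns=self.order)


@dataclass
class ImpliedMoments:
    order: list[str]
    matrix: np.ndarray
    theta: np.ndarray
    model: ModelSpec

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.order, columns=self.order)


# ---------------------------------------------------------------------------
# assembly from a printed correlation/variance summary


def assemble_moments(
    names: list[str],
    lower: np.ndarray | list[list[float]],
    n: int,
    scales: dict[str, str],
) -> SampleMoments:
    """Build a full moment matrix from a lower-triangle summary.

    ``lower`` carries correlations off-diagonal; the diagonal holds variances
    for continuous variables and 1 for latent-response variables.  Pairs of
    continuous variables are rescaled to covariances (r * SD_i * SD_j); mixed
    pairs to r * SD of the continuous member; latent-response pairs stay on
    the correlation metric.
    """
    p = len(names)
    L = np.asarray(lower, dtype=float)
    if L.shape != (p, p):
        raise MomentError(f"lower-triangle input must be {p}x{p}")
    if np.any(np.abs(np.triu(L, 1)[np.triu_indices(p, 1)]) > 1e-12):
        raise MomentError("upper triangle of the input must be empty (zeros)")
    diag = np.diag(L).copy()
    for i, name in enumerate(names):
        sc = scales.get(name, "continuous")
        if sc == "continuous":
            if not np.isfinite(diag[i]) or diag[i] <= 0:
                raise MomentError(f"missing/invalid variance for continuous variable {name}")
        elif sc == "latent-response":
            if not np.isclose(diag[i], 1.0):
                raise MomentError(f"latent-response variable {name} must have unit diagonal")
        else:
            raise MomentError(f"unknown scale {sc!r} for {name}")
    sd = np.sqrt(diag)
    M = np.diag(diag)
    for i in range(p):
        for j in range(i):
            r = L[i, j]
            if abs(r) > 1:
                raise MomentError(f"|r| > 1 for pair ({names[i]},{names[j]})")
            ci = scales.get(names[i], "continuous") == "continuous"
            cj = scales.get(names[j], "continuous") == "continuous"
            if ci and cj:
                v = r * sd[i] * sd[j]
            elif ci:
                v = r * sd[i]
            elif cj:
                v = r * sd[j]
            else:
                v = r
            M[i, j] = M[j, i] = v
    return SampleMoments(list(names), M, int(n), dict(scales), source="assembled")


# ---------------------------------------------------------------------------
# half-vectorization


def vech_indices(model: ModelSpec) -> list[tuple[int, int]]:
    """Lower-triangle (row-major) index pairs of the nonredundant moments,
    excluding fixed latent-response criterion diagonals."""
    fixed_diag = {i for i, v in enumerate(model.variables) if v.scale == "latent-response"}
    out = []
    for i in range(len(model.variables)):
        for j in range(i + 1):
            if i == j and i in fixed_diag:
                continue
            out.append((i, j))
    return out


def vech(matrix: np.ndarray, idx: list[tuple[int, int]]) -> np.ndarray:
    rows = [i for i, _ in idx]
    cols = [j for _, j in idx]
    return matrix[rows, cols]


# ---------------------------------------------------------------------------
# implied moments


def _sigma_from_matrices(model: ModelSpec, mats: dict[str, np.ndarray]) -> np.ndarray:
    lam, phi, tht = mats["lambda"], mats["phi"], mats["theta"]
    if model.mode != "regression":
        sigma = lam @ phi @ lam.T + tht
    else:
        crit = model.criterion_names
        vnames = model.var_names
        ind_rows = [i for i, v in enumerate(model.variables) if v.role == "indicator"]
        crit_rows = [vnames.index(c) for c in crit]
        beta, psi_off = mats["beta"], mats["psi_offdiag"]
        p = len(vnames)
        sigma = np.zeros((p, p))
        lam_i = lam[ind_rows, :]
        s_ii = lam_i @ phi @ lam_i.T + tht[np.ix_(ind_rows, ind_rows)]
        s_ic = lam_i @ phi @ beta
        explained = beta.T @ phi @ beta
        # criterion residual variances derived: total latent-response variance = 1
        psi = psi_off.copy()
        np.fill_diagonal(psi, 1.0 - np.diag(explained))
        s_cc = explained + psi
        sigma[np.ix_(ind_rows, ind_rows)] = s_ii
        sigma[np.ix_(ind_rows, crit_rows)] = s_ic
        sigma[np.ix_(crit_rows, ind_rows)] = s_ic.T
        sigma[np.ix_(crit_rows, crit_rows)] = s_cc
    return 0.5 * (sigma + sigma.T)


def implied_covariance(model: ModelSpec, theta: ThetaVector | np.ndarray) -> ImpliedMoments:
    """Model-implied moment matrix Sigma(theta)."""
    mats = theta_unpack(model, theta)
    sigma = _sigma_from_matrices(model, mats)
    values = theta.values if isinstance(theta, ThetaVector) else np.asarray(theta, float)
    return ImpliedMoments(model.var_names, sigma, values.copy(), model)


def criterion_residuals(model: ModelSpec, theta: ThetaVector | np.ndarray) -> np.ndarray:
    """Residual covariance matrix of the criteria (regression mode)."""
    if model.mode != "regression":
        raise MomentError("criterion residuals are defined in regression mode only")
    mats = theta_unpack(model, theta)
    explained = mats["beta"].T @ mats["phi"] @ mats["beta"]
    psi = mats["psi_offdiag"].copy()
    np.fill_diagonal(psi, 1.0 - np.diag(explained))
    return psi


def _sigma_vech(model: ModelSpec, values: np.ndarray, idx) -> np.ndarray:
    mats = theta_unpack(model, values)
    return vech(_sigma_from_matrices(model, mats), idx)


def implied_jacobian(
    model: ModelSpec,
    theta: ThetaVector | np.ndarray,
    h: float = 1e-6,
    analytic: bool | None = None,
) -> np.ndarray:
    """d vech(Sigma) / d theta, one column per free slot.

    Default: central finite differences with relative step ``h``.  In
    covariance mode ``analytic=True`` uses exact derivatives (the implied
    structure is bilinear); both routes agree to ~1e-6.
    """
    values = theta.values if isinstance(theta, ThetaVector) else np.asarray(theta, float)
    idx = vech_indices(model)
    if analytic is None:
        analytic = False
    if analytic:
        if model.mode == "regression":
            raise MomentError("analytic Jacobian implemented for covariance mode only")
        return _analytic_jacobian(model, values, idx)

    m = len(idx)
    J = np.empty((m, model.n_free))
    for j in range(model.n_free):
        step = h * max(1.0, abs(values[j]))
        up, dn = values.copy(), values.copy()
        up[j] += step
        dn[j] -= step
        J[:, j] = (_sigma_vech(model, up, idx) - _sigma_vech(model, dn, idx)) / (2 * step)
    if not np.all(np.isfinite(J)):
        raise MomentError("non-finite entries in the implied-moment Jacobian")
    return J


def _analytic_jacobian(model: ModelSpec, values: np.ndarray, idx) -> np.ndarray:
    mats = theta_unpack(model, values)
    lam, phi = mats["lambda"], mats["phi"]
    vidx = {n: i for i, n in enumerate(model.var_names)}
    fidx = {n: i for i, n in enumerate(model.factor_names)}
    p, q = lam.shape
    J = np.zeros((len(idx), model.n_free))
    phil = phi @ lam.T  # q x p
    for jslot, cells in enumerate(model.slot_cells):
        dS = np.zeros((p, p))
        for cell in cells:
            if cell.matrix == "loading":
                i, f = vidx[cell.row], fidx[cell.col]
                # d(lam phi lam^T) for lam[i,f]: e_i (phi lam^T)_f,: + sym
                contrib = np.zeros((p, p))
                contrib[i, :] += phil[f, :]
                contrib[:, i] += phil[f, :]
                dS += contrib
            elif cell.matrix == "factor_cov":
                a, b = fidx[cell.row], fidx[cell.col]
                E = np.zeros((q, q))
                E[a, b] = 1.0
                if a != b:
                    E[b, a] = 1.0
                dS += lam @ E @ lam.T
            elif cell.matrix == "error_cov":
                i, j = vidx[cell.row], vidx[cell.col]
                dS[i, j] += 1.0
                if i != j:
                    dS[j, i] += 1.0
            else:
                raise MomentError("analytic Jacobian implemented for covariance mode only")
        J[:, jslot] = vech(dS, idx)
    return J
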