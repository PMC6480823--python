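"""Local identification via the rank of the implied-moment Jacobian.

A model is locally identified at a generic parameter point when the
Jacobian of the nonredundant implied moments has full column rank.  The
checker evaluates the Jacobian at several random admissible points and
reports the maximal rank, the deficiency, and an orthonormal basis of the
null space labeled by parameter.

For the equal-loadings extended bifactor family the null space is known in
closed form: shifting the general-factor/criterion covariance by delta and
every specific-factor/criterion covariance by -delta leaves the implied
moments unchanged.  :func:`nonidentification_family` constructs that shift
exactly, in both covariance and regression parameterizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_spec import ModelSpec, ModelSpecError, ThetaVector
from .moments import implied_covariance, implied_jacobian

__all__ = [
    "IdentificationReport",
    "local_identification_rank",
    "nonidentification_family",
    "admissible_point",
]


@dataclass
class IdentificationReport:
    n_free: int
    rank: int
    deficiency: int
    null_directions: np.ndarray          # n_free x deficiency, orthonormal columns
    parameter_labels: list[str]
    n_points: int
    tolerance: float
    singular_values: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def identified(self) -> bool:
        return self.deficiency == 0

    def labeled_directions(self, threshold: float = 1e-8) -> list[dict[str, float]]:
        out = []
        for k in range(self.deficiency):
            v = self.null_directions[:, k]
            out.append({lab: float(x) for lab, x in zip(self.parameter_labels, v)
                        if abs(x) > threshold})
        return out

    def to_dict(self) -> dict:
        return {
            "n_free": self.n_free,
            "rank": self.rank,
            "deficiency": self.deficiency,
            "identified": self.identified,
            "n_points": self.n_points,
            "tolerance": self.tolerance,
            "singular_values": self.singular_values.tolist(),
            "null_directions": self.labeled_directions(),
        }


def admissible_point(model: ModelSpec, rng: np.random.Generator) -> ThetaVector:
    """Draw a random admissible parameter point: variances U(0.5, 2),
    off-diagonal covariances shrunk toward zero, free loadings U(0.5, 1.5),
    regressions small."""
    theta = model.default_theta()
    vals = theta.values
    var_of: dict[tuple[str, str], float] = {}
    # first pass: variances
    for j, cells in enumerate(model.slot_cells):
        c = cells[0]
        if c.matrix in ("factor_cov", "error_cov") and c.row == c.col:
            vals[j] = rng.uniform(0.5, 2.0)
            var_of[(c.matrix, c.row)] = vals[j]
    fixed_var = {("factor_cov", c.row): c.value for c in model.cells
                 if c.status == "fixed" and c.matrix == "factor_cov" and c.row == c.col}
    var_of.update(fixed_var)
    for j, cells in enumerate(model.slot_cells):
        c = cells[0]
        if c.matrix == "loading":
            vals[j] = rng.uniform(0.5, 1.5)
        elif c.matrix == "factor_cov" and c.row != c.col:
            vi = var_of.get(("factor_cov", c.row), 1.0)
            vj = var_of.get(("factor_cov", c.col), 1.0)
            vals[j] = rng.uniform(-0.3, 0.3) * np.sqrt(vi * vj)
        elif c.matrix == "error_cov" and c.row != c.col:
            vals[j] = rng.uniform(-0.2, 0.2)
        elif c.matrix == "regression":
            vals[j] = rng.uniform(-0.3, 0.3)
        elif c.matrix == "criterion_residual_cov":
            vals[j] = rng.uniform(-0.2, 0.2)
    return theta


def local_identification_rank(
    model: ModelSpec,
    n_points: int = 25,
    seed: int = 7,
    points: list[ThetaVector] | None = None,
    rank_tol_factor: float = 1e3,
) -> IdentificationReport:
    """Numerical local-identification check.

    Rank is the maximum over evaluation points of the SVD rank of the
    implied-moment Jacobian; singular values below
    ``max(dim) * eps * sigma_max * rank_tol_factor`` count as zero.  Null
    directions come from the point attaining the maximal rank.
    """
    rng = np.random.default_rng(seed)
    if points is None:
        points = [admissible_point(model, rng) for _ in range(n_points)]
    if not points:
        raise ValueError("no admissible evaluation point found")

    best = None
    for theta in points:
        J = implied_jacobian(model, theta)
        U, sv, Vt = np.linalg.svd(J)
        tol = max(J.shape) * np.finfo(float).eps * (sv[0] if sv.size else 1.0) * rank_tol_factor
        rank = int(np.sum(sv > tol))
        if best is None or rank > best[0]:
            best = (rank, sv, Vt, tol)
    rank, sv, Vt, tol = best
    deficiency = model.n_free - rank
    null = Vt[rank:, :].T if deficiency > 0 else np.zeros((model.n_free, 0))
    return IdentificationReport(
        n_free=model.n_free, rank=rank, deficiency=deficiency,
        null_directions=null, parameter_labels=list(model.slot_labels),
        n_points=len(points), tolerance=tol, singular_values=sv,
    )


# ---------------------------------------------------------------------------
# the explicit nonidentification family for equal-loadings extended bifactors


def _equal_loading_structure(model: ModelSpec) -> tuple[str, list[str]]:
    """Return (general factor, specific factors); require every indicator
    loading fixed to one common value."""
    general = [f.name for f in model.factors if f.kind == "general"]
    specific = [f.name for f in model.factors if f.kind == "specific"]
    if len(general) != 1 or not specific:
        raise ModelSpecError("model is not a bifactor structure (need one general "
                             "factor and >= 1 specific factors)")
    fixed_vals = set()
    for c in model.cells:
        if c.matrix == "loading" and c.col in [general[0], *specific]:
            if c.status != "fixed":
                raise ModelSpecError("nonidentification family requires all-fixed "
                                     "(equal) loadings")
            fixed_vals.add(c.value)
    if len(fixed_vals) != 1:
        raise ModelSpecError("nonidentification family requires equal loadings")
    return general[0], specific


def nonidentification_family(
    model: ModelSpec,
    theta: ThetaVector,
    delta: float,
    criteria: list[str] | None = None,
) -> ThetaVector:
    """Shift theta along the analytic null direction.

    Covariance mode: Cov(G,C) += delta, Cov(S_k,C) -= delta for every
    specific factor and every requested criterion; the implied moments are
    unchanged exactly.  Regression mode: beta_G += delta/Var(G),
    beta_k -= delta/Var(S_k); the derived residual variances recompensate
    automatically and the free residual covariances are recompensated here
    so that Sigma is preserved exactly.
    """
    g, specifics = _equal_loading_structure(model)
    criteria = criteria or model.criterion_names
    if not criteria:
        raise ModelSpecError("model has no criterion variables")

    out = theta.copy()
    if model.mode != "regression":
        for c in criteria:
            for fac, sign in [(g, +1.0)] + [(s, -1.0) for s in specifics]:
                j = model.slot_of("factor_cov", c, fac)
                out.values[j] += sign * delta
        return out

    sigma_before = implied_covariance(model, theta).matrix
    var_g = _current_value(model, theta, "factor_cov", g, g)
    for c in criteria:
        jg = model.slot_of("regression", c, g)
        out.values[jg] += delta / var_g
        for s in specifics:
            var_s = _current_value(model, theta, "factor_cov", s, s)
            js = model.slot_of("regression", c, s)
            out.values[js] -= delta / var_s
    # recompensate free residual covariances so the criterion block matches
    from .moments import criterion_residuals

    sigma_after = implied_covariance(model, out).matrix
    vnames = model.var_names
    for cell in model.cells:
        if cell.matrix != "criterion_residual_cov" or cell.status == "fixed":
            continue
        j = model.slot_of("criterion_residual_cov", cell.row, cell.col)
        i1, i2 = vnames.index(cell.row), vnames.index(cell.col)
        out.values[j] += sigma_before[i1, i2] - sigma_after[i1, i2]
    psi = criterion_residuals(model, out)
    if np.any(np.diag(psi) < 0):
        raise ModelSpecError("delta exhausts the residual-variance headroom "
                             "(negative compensated residual variance)")
    return out


def _current_value(model: ModelSpec, theta: ThetaVector, matrix, row, col) -> float:
    cell = model.cell(matrix, row, col)
    if cell.status == "fixed":
        return float(cell.value)
    return float(theta.values[model.slot_of(matrix, row, col)])
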