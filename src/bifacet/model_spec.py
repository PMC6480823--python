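"""Model parameterization: variables, factors, and free/fixed/equality cells.

A model is described declaratively (factors, loadings, covariance cells,
regressions) and compiled into a :class:`ModelSpec` that owns a lossless
bijection between the free cells and a flat parameter vector
(:class:`ThetaVector`).  Two modes are supported:

* ``covariance`` — criterion variables are represented by unit-variance
  latent-response factors that may covary freely with the measurement
  factors and with each other.
* ``regression`` — criterion variables are regressed on the measurement
  factors; their residual variances are derived so that the total implied
  criterion variance is exactly 1 (no free total variance).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VariableDef",
    "FactorDef",
    "ParameterCell",
    "ModelSpec",
    "ThetaVector",
    "ModelSpecError",
    "build_model",
    "theta_pack",
    "theta_unpack",
]

MATRICES = ("loading", "factor_cov", "error_cov", "regression", "criterion_residual_cov")


class ModelSpecError(ValueError):
    """Raised when a model description violates an invariant."""


@dataclass(frozen=True)
class VariableDef:
    name: str
    role: str  # "indicator" | "criterion"
    facet: str | None = None
    scale: str = "continuous"  # "continuous" | "latent-response"

    def __post_init__(self):
        if self.role not in ("indicator", "criterion"):
            raise ModelSpecError(f"unknown role {self.role!r} for variable {self.name}")
        if self.scale not in ("continuous", "latent-response"):
            raise ModelSpecError(f"unknown scale {self.scale!r} for variable {self.name}")
        if self.role == "indicator" and self.facet is None:
            raise ModelSpecError(f"indicator {self.name} lacks a facet label")


@dataclass(frozen=True)
class FactorDef:
    name: str
    kind: str  # "general" | "facet" | "specific" | "reference" | "criterion-latent"
    scaling: str = "one-loading-fixed"  # or "variance-fixed"

    def __post_init__(self):
        if self.kind not in ("general", "facet", "specific", "reference", "criterion-latent"):
            raise ModelSpecError(f"unknown factor kind {self.kind!r}")
        if self.scaling not in ("one-loading-fixed", "variance-fixed"):
            raise ModelSpecError(f"factor {self.name}: unknown scaling {self.scaling!r}")


@dataclass(frozen=True)
class ParameterCell:
    """One cell of one model matrix.

    ``status`` is ``"free"``, ``"fixed"`` or ``"equal"``; fixed cells carry
    ``value``, equality cells carry a shared ``label``.  Symmetric matrices
    are stored lower-triangle only (row comes at or after col in the model
    ordering).
    """

    matrix: str
    row: str
    col: str
    status: str
    value: float | None = None
    label: str | None = None
    start: float = 0.0

    def __post_init__(self):
        if self.matrix not in MATRICES:
            raise ModelSpecError(f"unknown matrix {self.matrix!r}")
        if self.status not in ("free", "fixed", "equal"):
            raise ModelSpecError(f"unknown status {self.status!r}")
        if self.status == "fixed":
            if self.value is None or not np.isfinite(self.value):
                raise ModelSpecError(f"fixed cell {self.key} lacks a finite value")
        if self.status == "equal" and not self.label:
            raise ModelSpecError(f"equality cell {self.key} lacks a label")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.matrix, self.row, self.col)


@dataclass
class ThetaVector:
    values: np.ndarray
    labels: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels),):
            raise ModelSpecError(
                f"theta length {self.values.shape} does not match {len(self.labels)} labels"
            )

    def __len__(self) -> int:
        return len(self.labels)

    def copy(self) -> "ThetaVector":
        return ThetaVector(self.values.copy(), list(self.labels))

    def with_updates(self, updates: dict[str, float]) -> "ThetaVector":
        out = self.copy()
        index = {lab: i for i, lab in enumerate(out.labels)}
        for lab, val in updates.items():
            if lab not in index:
                raise ModelSpecError(f"unknown parameter label {lab!r}")
            out.values[index[lab]] = val
        return out

    def get(self, label: str) -> float:
        return float(self.values[self.labels.index(label)])


@dataclass
class ModelSpec:
    """A validated, compiled model.

    ``slot_labels`` lists the free parameters after equality reduction;
    ``slot_cells`` maps each slot to the cells it fills.
    """

    variables: list[VariableDef]
    factors: list[FactorDef]
    cells: list[ParameterCell]
    mode: str  # "covariance" | "regression" | "measurement-only"
    slot_labels: list[str] = field(default_factory=list)
    slot_cells: list[list[ParameterCell]] = field(default_factory=list)

    # ---- derived views -------------------------------------------------
    @property
    def var_names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def indicator_names(self) -> list[str]:
        return [v.name for v in self.variables if v.role == "indicator"]

    @property
    def criterion_names(self) -> list[str]:
        return [v.name for v in self.variables if v.role == "criterion"]

    @property
    def n_free(self) -> int:
        return len(self.slot_labels)

    @property
    def n_moments(self) -> int:
        """Nonredundant sample moments: lower triangle incl. diagonal, minus
        the unit-variance latent-response criterion diagonals (fixed, not data)."""
        p = len(self.variables)
        n_fixed_diag = sum(1 for v in self.variables if v.scale == "latent-response")
        return p * (p + 1) // 2 - n_fixed_diag

    def factor(self, name: str) -> FactorDef:
        for f in self.factors:
            if f.name == name:
                return f
        raise ModelSpecError(f"unknown factor {name!r}")

    def variable(self, name: str) -> VariableDef:
        for v in self.variables:
            if v.name == name:
                return v
        raise ModelSpecError(f"unknown variable {name!r}")

    def cell(self, matrix: str, row: str, col: str) -> ParameterCell:
        for c in self.cells:
            if c.key == (matrix, row, col) or (
                c.matrix == matrix and {c.row, c.col} == {row, col}
            ):
                return c
        raise ModelSpecError(f"no cell {matrix}[{row},{col}]")

    def slot_of(self, matrix: str, row: str, col: str) -> int:
        cell = self.cell(matrix, row, col)
        for j, cells in enumerate(self.slot_cells):
            if any(c.key == cell.key for c in cells):
                return j
        raise ModelSpecError(f"cell {matrix}[{row},{col}] is not free")

    def default_theta(self) -> ThetaVector:
        vals = np.array([cells[0].start for cells in self.slot_cells], dtype=float)
        return ThetaVector(vals, list(self.slot_labels))


# ---------------------------------------------------------------------------
# compilation


def _auto_label(cell: ParameterCell) -> str:
    short = {
        "loading": "lam",
        "factor_cov": "phi",
        "error_cov": "theta",
        "regression": "beta",
        "criterion_residual_cov": "psi",
    }[cell.matrix]
    return f"{short}[{cell.row},{cell.col}]"


def _compile_slots(cells: list[ParameterCell]) -> tuple[list[str], list[list[ParameterCell]]]:
    labels: list[str] = []
    slot_cells: list[list[ParameterCell]] = []
    by_label: dict[str, int] = {}
    fixed_labels = {c.label for c in cells if c.status == "fixed" and c.label}
    for c in cells:
        if c.status == "fixed":
            continue
        if c.status == "equal":
            if c.label in fixed_labels:
                raise ModelSpecError(f"equality label {c.label!r} also used on a fixed cell")
            if c.label in by_label:
                slot_cells[by_label[c.label]].append(c)
                continue
            lab = c.label
        else:
            lab = _auto_label(c)
            if lab in by_label:
                raise ModelSpecError(f"duplicate cell {c.key}")
        by_label[lab] = len(labels)
        labels.append(lab)
        slot_cells.append([c])
    return labels, slot_cells


def build_model(config: dict) -> ModelSpec:
    """Compile a declarative model description into a validated ModelSpec.

    ``config`` keys: ``mode``, ``variables``, ``factors``, ``loadings``,
    ``factor_covs``, ``error_covs`` (optional), ``regressions`` and
    ``residual_covs`` (regression mode).  Cells not mentioned receive
    defaults: free error variances for continuous indicators, zero error
    covariances, zero factor covariances, free factor variances (fixed 1
    under variance-fixed scaling).
    """
    mode = config.get("mode", "covariance")
    if mode not in ("covariance", "regression", "measurement-only"):
        raise ModelSpecError(f"unknown mode {mode!r}")

    variables = [v if isinstance(v, VariableDef) else VariableDef(**v) for v in config["variables"]]
    names = [v.name for v in variables]
    if len(set(names)) != len(names):
        raise ModelSpecError("variable names are not unique")

    factors = [f if isinstance(f, FactorDef) else FactorDef(**f) for f in config.get("factors", [])]
    if len(factors) < 1:
        raise ModelSpecError("at least one factor is required")
    if sum(v.role == "indicator" for v in variables) < 2:
        raise ModelSpecError("at least two indicators are required")

    criteria = [v for v in variables if v.role == "criterion"]
    if mode == "covariance":
        # criterion variables become unit-variance latent-response factors
        for c in criteria:
            factors.append(FactorDef(c.name, "criterion-latent", "variance-fixed"))

    fnames = [f.name for f in factors]
    if len(set(fnames)) != len(fnames):
        raise ModelSpecError("factor names are not unique")

    def _chk_var(n):
        if n not in names:
            raise ModelSpecError(f"unknown variable {n!r} in a cell")

    def _chk_fac(n):
        if n not in fnames:
            raise ModelSpecError(f"unknown factor {n!r} in a cell")

    def _mkcell(matrix, row, col, spec) -> ParameterCell:
        if isinstance(spec, ParameterCell):
            return spec
        d = dict(spec)
        status = d.pop("status", "free")
        return ParameterCell(matrix, row, col, status, d.get("value"), d.get("label"),
                             d.get("start", 0.0))

    cells: list[ParameterCell] = []
    seen: set[tuple] = set()

    def _add(cell: ParameterCell):
        k = (cell.matrix, frozenset((cell.row, cell.col))) if cell.matrix in (
            "factor_cov", "error_cov", "criterion_residual_cov") else cell.key
        if k in seen:
            raise ModelSpecError(f"duplicate cell {cell.key}")
        seen.add(k)
        cells.append(cell)

    # loadings --------------------------------------------------------------
    for entry in config.get("loadings", []):
        d = dict(entry)
        var, fac = d.pop("var"), d.pop("factor")
        _chk_var(var)
        _chk_fac(fac)
        if "start" not in d:
            d["start"] = 1.0
        _add(_mkcell("loading", var, fac, d))
    if mode == "covariance":
        for c in criteria:
            _add(ParameterCell("loading", c.name, c.name, "fixed", 1.0))

    loaded = {c.row for c in cells if c.matrix == "loading"}
    for v in variables:
        if v.role == "indicator" and v.name not in loaded:
            raise ModelSpecError(f"indicator {v.name} loads on no factor")
        if mode == "covariance" and v.name not in loaded:
            raise ModelSpecError(f"criterion {v.name} unreachable")

    # factor covariances ----------------------------------------------------
    phi_given = {}
    for entry in config.get("factor_covs", []):
        d = dict(entry)
        r, c = d.pop("row"), d.pop("col")
        _chk_fac(r)
        _chk_fac(c)
        phi_given[frozenset((r, c))] = d
    for f in factors:
        key = frozenset((f.name,))
        spec = phi_given.pop(key, None)
        if f.scaling == "variance-fixed":
            if spec is not None and spec.get("status", "free") != "fixed":
                raise ModelSpecError(f"factor {f.name}: variance must stay fixed under "
                                     "variance-fixed scaling")
            spec = spec or {"status": "fixed", "value": 1.0}
        elif spec is None:
            spec = {"status": "free", "start": 1.0}
        _add(_mkcell("factor_cov", f.name, f.name, spec))
    for fa, fb in itertools.combinations(fnames, 2):
        spec = phi_given.pop(frozenset((fa, fb)), {"status": "fixed", "value": 0.0})
        _add(_mkcell("factor_cov", fb, fa, spec))  # lower triangle in factor order
    if phi_given:
        raise ModelSpecError(f"dangling factor_cov entries: {sorted(map(tuple, phi_given))}")

    # error (co)variances ---------------------------------------------------
    theta_given = {}
    for entry in config.get("error_covs", []):
        d = dict(entry)
        r, c = d.pop("row"), d.pop("col")
        _chk_var(r)
        _chk_var(c)
        theta_given[frozenset((r, c))] = d
    for v in variables:
        spec = theta_given.pop(frozenset((v.name,)), None)
        if v.role == "criterion":
            if mode == "covariance":
                # variance lives in the criterion-latent factor (fixed 1)
                spec = spec or {"status": "fixed", "value": 0.0}
            else:
                continue  # derived residual variance, not a cell
        elif spec is None:
            spec = {"status": "free", "start": 1.0}
        _add(_mkcell("error_cov", v.name, v.name, spec))
    for key, spec in theta_given.items():
        r, c = sorted(key, key=names.index)
        _add(_mkcell("error_cov", c, r, spec))

    # regressions and criterion residual covariances ------------------------
    if mode == "regression":
        if not criteria:
            raise ModelSpecError("regression mode requires at least one criterion")
        for entry in config.get("regressions", []):
            d = dict(entry)
            fac, crit = d.pop("factor"), d.pop("criterion")
            _chk_fac(fac)
            _chk_var(crit)
            role = next(v for v in variables if v.name == crit).role
            if role != "criterion":
                raise ModelSpecError(f"regression target {crit} is not a criterion ({role})")
            _add(_mkcell("regression", crit, fac, d))
        for entry in config.get("residual_covs", []):
            d = dict(entry)
            r, c = d.pop("row"), d.pop("col")
            _chk_var(r)
            _chk_var(c)
            if r == c:
                raise ModelSpecError("criterion residual variances are derived, not cells")
            _add(_mkcell("criterion_residual_cov", r, c, d))
    elif config.get("regressions") or config.get("residual_covs"):
        raise ModelSpecError(f"regression cells are not allowed in {mode} mode")

    labels, slot_cells = _compile_slots(cells)
    model = ModelSpec(variables, factors, cells, mode, labels, slot_cells)

    # scaling sanity: one-loading-fixed factors need at least one fixed loading
    for f in factors:
        if f.scaling == "one-loading-fixed":
            has_fixed = any(
                c.matrix == "loading" and c.col == f.name and c.status == "fixed"
                for c in cells
            )
            if not has_fixed:
                raise ModelSpecError(f"factor {f.name}: one-loading-fixed scaling but no "
                                     "fixed loading")
    return model


# ---------------------------------------------------------------------------
# pack / unpack


def theta_pack(model: ModelSpec, cell_values: dict[tuple, float] | None = None) -> ThetaVector:
    """Flatten the model's free cells into a ThetaVector.

    Without ``cell_values`` the start values are used.  Equality-labeled
    cells share one slot; their supplied values must agree.
    """
    vals = np.empty(model.n_free)
    for j, cells in enumerate(model.slot_cells):
        if cell_values is None:
            vals[j] = cells[0].start
        else:
            got = {cell_values[c.key] for c in cells if c.key in cell_values}
            if not got:
                raise ModelSpecError(f"no value supplied for slot {model.slot_labels[j]}")
            if len(got) > 1:
                raise ModelSpecError(f"conflicting values for slot {model.slot_labels[j]}")
            vals[j] = got.pop()
    return ThetaVector(vals, list(model.slot_labels))


def theta_unpack(model: ModelSpec, theta: ThetaVector | np.ndarray) -> dict[str, np.ndarray]:
    """Fill the model matrices from a flat vector.

    Returns dense matrices keyed ``"lambda"`` (obs x factors), ``"phi"``
    (factors x factors, symmetric), ``"theta"`` (obs x obs, symmetric) and,
    in regression mode, ``"beta"`` (factors x criteria) and ``"psi_offdiag"``
    (criteria x criteria with zero diagonal; diagonal residual variances are
    derived at the moment-computation stage).
    """
    values = theta.values if isinstance(theta, ThetaVector) else np.asarray(theta, float)
    if values.shape != (model.n_free,):
        raise ModelSpecError(
            f"theta length {values.shape[0] if values.ndim else 0} != {model.n_free} free slots"
        )
    vidx = {n: i for i, n in enumerate(model.var_names)}
    fidx = {n: i for i, n in enumerate(model.factor_names)}
    cidx = {n: i for i, n in enumerate(model.criterion_names)}
    p, q, r = len(vidx), len(fidx), len(cidx)

    lam = np.zeros((p, q))
    phi = np.zeros((q, q))
    tht = np.zeros((p, p))
    beta = np.zeros((q, r))
    psi = np.zeros((r, r))

    def _place(cell: ParameterCell, val: float):
        if cell.matrix == "loading":
            lam[vidx[cell.row], fidx[cell.col]] = val
        elif cell.matrix == "factor_cov":
            i, j = fidx[cell.row], fidx[cell.col]
            phi[i, j] = phi[j, i] = val
        elif cell.matrix == "error_cov":
            i, j = vidx[cell.row], vidx[cell.col]
            tht[i, j] = tht[j, i] = val
        elif cell.matrix == "regression":
            beta[fidx[cell.col], cidx[cell.row]] = val
        else:  # criterion_residual_cov
            i, j = cidx[cell.row], cidx[cell.col]
            psi[i, j] = psi[j, i] = val

    for cell in model.cells:
        if cell.status == "fixed":
            _place(cell, cell.value)
    for j, cells in enumerate(model.slot_cells):
        for cell in cells:
            _place(cell, values[j])

    out = {"lambda": lam, "phi": phi, "theta": tht}
    if model.mode == "regression":
        out["beta"] = beta
        out["psi_offdiag"] = psi
    return out
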