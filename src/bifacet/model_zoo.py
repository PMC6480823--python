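"""Ready-made model builders for the bundled six-indicator / two-grade layout.

Catalog keys follow the figure layout of the accompanying study design:

====================  ======================================================
key                   structure
====================  ======================================================
fig1a_equal           bifactor, equal loadings (all fixed 1), no criteria
fig1b_equal           + 2 criteria correlating with all factors (NOT identified)
fig1b_equal_fix_s     fig1b_equal with all specific-criterion covariances 0
fig1b_equal_fix_g     fig1b_equal with the g-criterion covariances 0
fig1b_free_g          free g loadings (first fixed 1), specific loadings 1
fig1b_free_g_fix_s    fig1b_free_g with specific-criterion covariances 0
fig1b_free_g_fix_g    fig1b_free_g with g-criterion covariances 0
fig1c                 latent regression on G and the specifics (free g loadings)
fig2a                 correlated first-order factors, no criteria
fig2b                 + 2 criteria correlating with the facet factors
fig2c                 latent multiple regression of the criteria on the facets
fig3a                 bifactor(S-1), no criteria (needs reference_facet)
fig3b                 + correlating criteria
fig3c                 latent regression variant
====================  ======================================================

``fig3*`` keys accept a ``_ref<FACET>`` suffix (e.g. ``fig3b_refAN``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import FitResult, rsquared, standardize
from .model_spec import ModelSpec, ModelSpecError, build_model

__all__ = [
    "CATALOG_KEYS",
    "CompositeDefinition",
    "make_model",
    "composite_from_regression",
    "s1_part_correlations",
    "FACETS",
    "CRITERIA",
]

FACETS: dict[str, list[str]] = {
    "NS": ["NS1", "NS2"],
    "AN": ["AN1", "AN2"],
    "UN": ["UN1", "UN2"],
}
CRITERIA = ["Math", "Eng"]

CATALOG_KEYS = (
    "fig1a_equal", "fig1b_equal", "fig1b_equal_fix_s", "fig1b_equal_fix_g",
    "fig1b_free_g", "fig1b_free_g_fix_s", "fig1b_free_g_fix_g", "fig1c",
    "fig2a", "fig2b", "fig2c", "fig2d", "fig3a", "fig3b", "fig3c",
)


@dataclass
class CompositeDefinition:
    """Exact linear combination of facet factors predicting one criterion."""

    criterion: str
    weights: dict[str, float]            # facet factor -> regression weight
    correlation: float                   # composite-criterion correlation = sqrt(R^2)
    degenerate: bool = False


def _variables(with_criteria: bool) -> list[dict]:
    out = []
    for facet, inds in FACETS.items():
        for name in inds:
            out.append({"name": name, "role": "indicator", "facet": facet,
                        "scale": "continuous"})
    if with_criteria:
        for c in CRITERIA:
            out.append({"name": c, "role": "criterion", "scale": "latent-response"})
    return out


def _crit_cov_cells(factors: list[str], fixed_zero: set[str] | None = None) -> list[dict]:
    fixed_zero = fixed_zero or set()
    cells = []
    for c in CRITERIA:
        for f in factors:
            status = ({"status": "fixed", "value": 0.0} if f in fixed_zero
                      else {"status": "free"})
            cells.append({"row": c, "col": f, **status})
    cells.append({"row": CRITERIA[1], "col": CRITERIA[0], "status": "free"})
    return cells


def _bifactor_config(equal: bool, criteria: bool, fix_s: bool = False,
                     fix_g: bool = False, regression: bool = False) -> dict:
    factors = [{"name": "G", "kind": "general", "scaling": "one-loading-fixed"}]
    for facet in FACETS:
        factors.append({"name": f"{facet}-S", "kind": "specific",
                        "scaling": "one-loading-fixed"})
    loadings = []
    first = True
    for facet, inds in FACETS.items():
        for name in inds:
            if equal or first:
                loadings.append({"var": name, "factor": "G", "status": "fixed",
                                 "value": 1.0})
            else:
                loadings.append({"var": name, "factor": "G", "status": "free",
                                 "start": 1.0})
            first = False
            loadings.append({"var": name, "factor": f"{facet}-S", "status": "fixed",
                             "value": 1.0})
    config: dict = {
        "mode": "regression" if regression else "covariance",
        "variables": _variables(criteria),
        "factors": factors,
        "loadings": loadings,
        "factor_covs": [],
    }
    fac_names = ["G"] + [f"{f}-S" for f in FACETS]
    if criteria and not regression:
        fixed = set()
        if fix_s:
            fixed |= {f"{f}-S" for f in FACETS}
        if fix_g:
            fixed.add("G")
        config["factor_covs"] = _crit_cov_cells(fac_names, fixed)
    if regression:
        regs = []
        for c in CRITERIA:
            for f in fac_names:
                if fix_s and f != "G":
                    regs.append({"factor": f, "criterion": c, "status": "fixed",
                                 "value": 0.0})
                elif fix_g and f == "G":
                    regs.append({"factor": f, "criterion": c, "status": "fixed",
                                 "value": 0.0})
                else:
                    regs.append({"factor": f, "criterion": c, "status": "free"})
        config["regressions"] = regs
        config["residual_covs"] = [{"row": CRITERIA[0], "col": CRITERIA[1],
                                    "status": "free"}]
    return config


def _first_order_config(criteria: bool, regression: bool = False) -> dict:
    factors = [{"name": f, "kind": "facet", "scaling": "one-loading-fixed"}
               for f in FACETS]
    loadings = [{"var": name, "factor": facet, "status": "fixed", "value": 1.0}
                for facet, inds in FACETS.items() for name in inds]
    fac_names = list(FACETS)
    factor_covs = [{"row": b, "col": a, "status": "free"}
                   for i, a in enumerate(fac_names) for b in fac_names[i + 1:]]
    config: dict = {
        "mode": "regression" if regression else "covariance",
        "variables": _variables(criteria),
        "factors": factors,
        "loadings": loadings,
        "factor_covs": factor_covs,
    }
    if criteria and not regression:
        config["factor_covs"] = factor_covs + _crit_cov_cells(fac_names)
    if regression:
        config["regressions"] = [{"factor": f, "criterion": c, "status": "free"}
                                 for c in CRITERIA for f in fac_names]
        config["residual_covs"] = [{"row": CRITERIA[0], "col": CRITERIA[1],
                                    "status": "free"}]
    return config


def _s1_config(reference: str, criteria: bool, regression: bool = False) -> dict:
    if reference not in FACETS:
        raise ModelSpecError(f"unknown reference facet {reference!r}")
    others = [f for f in FACETS if f != reference]
    factors = [{"name": reference, "kind": "reference", "scaling": "one-loading-fixed"}]
    factors += [{"name": f"{f}-S", "kind": "specific", "scaling": "one-loading-fixed"}
                for f in others]
    loadings = []
    for name in FACETS[reference]:
        loadings.append({"var": name, "factor": reference, "status": "fixed",
                         "value": 1.0})
    for facet in others:
        for name in FACETS[facet]:
            # non-reference indicators load on the reference factor with a free
            # loading, equal within facet, and on their specific factor with 1
            loadings.append({"var": name, "factor": reference, "status": "equal",
                             "label": f"lam_{facet}_on_{reference}", "start": 0.5})
            loadings.append({"var": name, "factor": f"{facet}-S", "status": "fixed",
                             "value": 1.0})
    fac_names = [reference] + [f"{f}-S" for f in others]
    # specific factors correlate with each other but not with the reference
    factor_covs = [{"row": f"{others[1]}-S", "col": f"{others[0]}-S", "status": "free"}]
    config: dict = {
        "mode": "regression" if regression else "covariance",
        "variables": _variables(criteria),
        "factors": factors,
        "loadings": loadings,
        "factor_covs": factor_covs,
    }
    if criteria and not regression:
        config["factor_covs"] = factor_covs + _crit_cov_cells(fac_names)
    if regression:
        config["regressions"] = [{"factor": f, "criterion": c, "status": "free"}
                                 for c in CRITERIA for f in fac_names]
        config["residual_covs"] = [{"row": CRITERIA[0], "col": CRITERIA[1],
                                    "status": "free"}]
    return config


def make_model(name: str, reference_facet: str | None = None) -> ModelSpec:
    """Build a catalog model; ``fig3*`` keys require a reference facet
    (either the argument or a ``_ref<FACET>`` suffix)."""
    key = name
    if "_ref" in key:
        key, _, suffix = key.partition("_ref")
        if reference_facet is not None and reference_facet != suffix:
            raise ModelSpecError(f"conflicting reference facets {suffix!r} vs "
                                 f"{reference_facet!r}")
        reference_facet = suffix
    builders = {
        "fig1a_equal": lambda: _bifactor_config(equal=True, criteria=False),
        "fig1b_equal": lambda: _bifactor_config(equal=True, criteria=True),
        "fig1b_equal_fix_s": lambda: _bifactor_config(True, True, fix_s=True),
        "fig1b_equal_fix_g": lambda: _bifactor_config(True, True, fix_g=True),
        "fig1b_free_g": lambda: _bifactor_config(False, True),
        "fig1b_free_g_fix_s": lambda: _bifactor_config(False, True, fix_s=True),
        "fig1b_free_g_fix_g": lambda: _bifactor_config(False, True, fix_g=True),
        "fig1c": lambda: _bifactor_config(False, True, regression=True),
        "fig1c_equal": lambda: _bifactor_config(True, True, regression=True),
        "fig2a": lambda: _first_order_config(criteria=False),
        "fig2b": lambda: _first_order_config(criteria=True),
        "fig2c": lambda: _first_order_config(criteria=True, regression=True),
        "fig2d": lambda: _first_order_config(criteria=True, regression=True),
    }
    if key in builders:
        return build_model(builders[key]())
    if key in ("fig3a", "fig3b", "fig3c"):
        if reference_facet is None:
            raise ModelSpecError(f"{key} requires a reference facet")
        return build_model(_s1_config(
            reference_facet,
            criteria=key != "fig3a",
            regression=key == "fig3c",
        ))
    raise ModelSpecError(f"unknown catalog key {name!r}")


# ---------------------------------------------------------------------------


def composite_from_regression(fitres: FitResult, criterion: str) -> CompositeDefinition:
    """Composite-factor reformulation of a latent multiple regression.

    The composite's weights are the regression coefficients; its correlation
    with the criterion is sqrt(b_s' Corr(F) b_s), asserted equal to sqrt(R^2).
    """
    model = fitres.model
    if model.mode != "regression":
        raise ValueError("composite definition requires a regression-extension fit")
    if criterion not in model.criterion_names:
        raise ValueError(f"unknown criterion {criterion!r}")
    sol = standardize(fitres)
    b_s = sol.regressions.loc[criterion].to_numpy()
    corr = sol.factor_corr.to_numpy()
    comp_corr = float(np.sqrt(max(0.0, b_s @ corr @ b_s)))
    r2 = float(rsquared(fitres)[criterion])
    if not np.isclose(comp_corr, np.sqrt(max(0.0, r2)), atol=1e-8):
        raise AssertionError("composite-criterion correlation does not equal sqrt(R^2)")
    from .model_spec import theta_unpack

    beta = theta_unpack(model, fitres.theta)["beta"]
    cidx = model.criterion_names.index(criterion)
    weights = {f: float(beta[i, cidx]) for i, f in enumerate(model.factor_names)}
    degenerate = all(abs(wv) < 1e-12 for wv in weights.values())
    return CompositeDefinition(criterion, weights, comp_corr if not degenerate else 0.0,
                               degenerate)


def s1_part_correlations(fitres: FitResult) -> pd.DataFrame:
    """Factor-criterion correlations of a bifactor(S-1) covariance fit.

    Reference-factor rows are zero-order correlations; specific-factor rows
    are part (semi-partial) correlations of the facet residualized on the
    reference factor.
    """
    model = fitres.model
    kinds = {f.name: f.kind for f in model.factors}
    if "reference" not in kinds.values():
        raise ValueError("not a bifactor(S-1) model (no reference factor)")
    if model.mode == "regression":
        raise ValueError("part correlations are read off the covariance-extension fit")
    sol = standardize(fitres)
    crit = model.criterion_names
    rows = []
    for fname, kind in kinds.items():
        if kind == "criterion-latent":
            continue
        label = "zero-order" if kind == "reference" else "part"
        for c in crit:
            rows.append({"factor": fname, "criterion": c, "kind": label,
                         "correlation": float(sol.factor_corr.loc[fname, c])})
    return pd.DataFrame(rows)
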