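"""Mixed correlation estimation: Pearson, polychoric, polyserial.

Polychoric and polyserial correlations use two-step estimation — thresholds
from the marginal cumulative proportions via the inverse normal CDF, then a
one-dimensional maximum-likelihood search for the latent correlation on
(-1+eps, 1-eps).  Bivariate-normal rectangle probabilities come from the
scipy multivariate-normal CDF quadrature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .moments import SampleMoments

__all__ = ["CorrEstimate", "polychoric", "polyserial", "mixed_matrix"]

log = logging.getLogger(__name__)

_EPS = 1e-6
_CLAMP = 1.0 - 1e-6


@dataclass
class CorrEstimate:
    value: float
    type: str  # "pearson" | "polychoric" | "polyserial"
    thresholds: dict[str, np.ndarray] = field(default_factory=dict)
    converged: bool = True
    clamped: bool = False

    def __post_init__(self):
        if abs(self.value) > 1:
            raise ValueError(f"|correlation| > 1: {self.value}")
        for key, t in self.thresholds.items():
            t = np.asarray(t, float)
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"thresholds for {key} are not strictly increasing")


# ---------------------------------------------------------------------------
# helpers


def _collapse_empty_margins(table: np.ndarray, axis: int) -> np.ndarray:
    """Merge empty margin categories into the adjacent category toward the
    median category; always logged."""
    table = np.asarray(table, float)
    while True:
        margin = table.sum(axis=1 - axis)
        empty = np.flatnonzero(margin == 0)
        if empty.size == 0 or table.shape[axis] <= 2:
            return table
        k = empty[0]
        ncat = table.shape[axis]
        # merge toward the median category
        target = k + 1 if k < (ncat - 1) / 2 else k - 1
        target = min(max(target, 0), ncat - 1)
        if target == k:
            target = k - 1 if k > 0 else k + 1
        log.warning("collapsing empty category %d into %d on axis %d", k, target, axis)
        idx = [i for i in range(ncat) if i != k]
        merged = np.take(table, idx, axis=axis)
        # nothing to add since the category is empty; just drop it
        table = merged


def _thresholds_from_margin(margin: np.ndarray) -> np.ndarray:
    cum = np.cumsum(margin) / margin.sum()
    return stats.norm.ppf(cum[:-1])


def _bvn_cdf(a: float, b: float, rho: float) -> float:
    if a == -np.inf or b == -np.inf:
        return 0.0
    if a == np.inf and b == np.inf:
        return 1.0
    if a == np.inf:
        return float(stats.norm.cdf(b))
    if b == np.inf:
        return float(stats.norm.cdf(a))
    return float(stats.multivariate_normal.cdf(
        [a, b], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]],
        allow_singular=True))


def _rectangle_probs(tx: np.ndarray, ty: np.ndarray, rho: float) -> np.ndarray:
    ax = np.concatenate(([-np.inf], tx, [np.inf]))
    ay = np.concatenate(([-np.inf], ty, [np.inf]))
    K, L = len(ax) - 1, len(ay) - 1
    cdf = np.empty((K + 1, L + 1))
    for i in range(K + 1):
        for j in range(L + 1):
            cdf[i, j] = _bvn_cdf(ax[i], ay[j], rho)
    P = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
    return np.clip(P, 1e-12, None)


# ---------------------------------------------------------------------------
# estimators


def polychoric(table: np.ndarray | pd.DataFrame) -> CorrEstimate:
    """Two-step polychoric correlation from a K x L contingency table."""
    T = np.asarray(table, float)
    if T.ndim != 2 or min(T.shape) < 2:
        raise ValueError("contingency table must be at least 2 x 2")
    if T.sum() <= 0:
        raise ValueError("contingency table has no observations")
    T = _collapse_empty_margins(T, axis=0)
    T = _collapse_empty_margins(T, axis=1)
    tx = _thresholds_from_margin(T.sum(axis=1))
    ty = _thresholds_from_margin(T.sum(axis=0))

    def negll(rho):
        P = _rectangle_probs(tx, ty, rho)
        return -float(np.sum(T * np.log(P)))

    res = optimize.minimize_scalar(negll, bounds=(-_CLAMP, _CLAMP), method="bounded",
                                   options={"xatol": 1e-8})
    rho = float(res.x)
    clamped = abs(rho) >= _CLAMP - 1e-9
    if clamped:
        rho = np.sign(rho) * _CLAMP
        log.warning("polychoric estimate clamped at %+.6f (near-perfect association)", rho)
    return CorrEstimate(rho, "polychoric", {"x": tx, "y": ty},
                        converged=bool(res.success), clamped=clamped)


def polyserial(x: np.ndarray, y: np.ndarray) -> CorrEstimate:
    """Two-step polyserial correlation of a continuous x with ordinal codes y."""
    x = np.asarray(x, float)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    sd = np.std(x, ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("x is constant")
    cats, codes = np.unique(y, return_inverse=True)
    if cats.size < 2:
        raise ValueError("y has a single observed category")
    counts = np.bincount(codes, minlength=cats.size).astype(float)
    tau = _thresholds_from_margin(counts)
    z = (x - np.mean(x)) / sd
    upper = np.concatenate((tau, [np.inf]))[codes]
    lower = np.concatenate(([-np.inf], tau))[codes]

    def negll(rho):
        s = np.sqrt(1.0 - rho * rho)
        pu = stats.norm.cdf((upper - rho * z) / s)
        pl = stats.norm.cdf((lower - rho * z) / s)
        return -float(np.sum(np.log(np.clip(pu - pl, 1e-300, None))))

    res = optimize.minimize_scalar(negll, bounds=(-_CLAMP, _CLAMP), method="bounded",
                                   options={"xatol": 1e-8})
    rho = float(res.x)
    clamped = abs(rho) >= _CLAMP - 1e-9
    if clamped:
        rho = np.sign(rho) * _CLAMP
        log.warning("polyserial estimate clamped at %+.6f", rho)
    return CorrEstimate(rho, "polyserial", {"y": tau},
                        converged=bool(res.success), clamped=clamped)


def mixed_matrix(data: pd.DataFrame, scales: dict[str, str]) -> SampleMoments:
    """Pairwise mixed moment matrix on the hybrid metric.

    Continuous pairs: Pearson covariances (variances on the diagonal).
    Continuous/ordinal pairs: polyserial correlation times the continuous
    SD.  Ordinal pairs: polychoric correlation; ordinal diagonal = 1.
    """
    names = list(data.columns)
    for name in names:
        if name not in scales:
            raise ValueError(f"no scale declared for column {name!r}")
        if scales[name] not in ("continuous", "ordinal"):
            raise ValueError(f"unknown scale {scales[name]!r} for column {name!r}")
    p = len(names)
    M = np.zeros((p, p))
    sds = {}
    for i, name in enumerate(names):
        if scales[name] == "continuous":
            M[i, i] = np.var(data[name].to_numpy(float), ddof=1)
            sds[name] = np.sqrt(M[i, i])
        else:
            M[i, i] = 1.0
    for i in range(p):
        for j in range(i):
            a, b = names[i], names[j]
            try:
                ca = scales[a] == "continuous"
                cb = scales[b] == "continuous"
                if ca and cb:
                    va = data[a].to_numpy(float)
                    vb = data[b].to_numpy(float)
                    M[i, j] = np.cov(va, vb, ddof=1)[0, 1]
                elif ca or cb:
                    xcol, ycol = (a, b) if ca else (b, a)
                    est = polyserial(data[xcol].to_numpy(float), data[ycol].to_numpy())
                    M[i, j] = est.value * sds[xcol]
                else:
                    tab = pd.crosstab(data[a], data[b]).to_numpy(float)
                    M[i, j] = polychoric(tab).value
            except Exception as exc:
                raise RuntimeError(f"mixed-matrix estimation failed for pair "
                                   f"({a},{b}): {exc}") from exc
            M[j, i] = M[i, j]
    sc = {n: ("continuous" if scales[n] == "continuous" else "latent-response")
          for n in names}
    return SampleMoments(names, M, len(data), sc, source="raw")
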