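"""Bundled example data and the moments CSV dialect.

The CSV dialect stores the lower triangle (correlations off-diagonal,
variances / unit diagonals on the diagonal) with a header row of variable
names; a JSON sidecar declares the sample size and each variable's scale.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .moments import MomentError, SampleMoments, assemble_moments

__all__ = ["ability_grades", "grade_proportions", "read_moments_csv", "write_moments_csv"]

_DATA = resources.files("bifacet") / "data"
_ABILITY_SHA256 = "ce102892151da5b8dbe42b2fffb9bb1608a72b7a84b36fca3ad41d6cfe41b899"


def _load_lower(text: str) -> tuple[list[str], np.ndarray]:
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    header = lines[0].split(",")[1:]
    p = len(header)
    L = np.zeros((p, p))
    for i, ln in enumerate(lines[1:]):
        parts = ln.split(",")
        vals = [float(x) if x.strip() else np.nan for x in parts[1 : i + 2]]
        L[i, : len(vals)] = vals
    return header, L


def ability_grades(verify_checksum: bool = True) -> SampleMoments:
    """The bundled 8-variable ability/grades moment summary (n = 219)."""
    csv_text = (_DATA / "ability_grades.csv").read_text()
    if verify_checksum:
        digest = hashlib.sha256(csv_text.encode()).hexdigest()
        if digest != _ABILITY_SHA256:
            raise MomentError("bundled ability_grades.csv failed its checksum")
    meta = json.loads((_DATA / "ability_grades.json").read_text())
    names, L = _load_lower(csv_text)
    return assemble_moments(names, L, meta["n"], meta["scales"])


def grade_proportions() -> dict[str, list[float]]:
    """Printed category proportions of the two grade variables."""
    meta = json.loads((_DATA / "ability_grades.json").read_text())
    return meta["grade_proportions"]


def read_moments_csv(csv_path: str | Path, meta_path: str | Path | None = None) -> SampleMoments:
    csv_path = Path(csv_path)
    if meta_path is None:
        meta_path = csv_path.with_suffix(".json")
    meta = json.loads(Path(meta_path).read_text())
    names, L = _load_lower(csv_path.read_text())
    return assemble_moments(names, L, meta["n"], meta["scales"])


def write_moments_csv(moments: SampleMoments, csv_path: str | Path,
                      meta_path: str | Path | None = None) -> None:
    """Write the full (already rescaled) moment matrix plus sidecar.

    Note: output is on the covariance metric, with a ``full_matrix`` marker
    so it round-trips through :func:`read_full_moments_csv`.
    """
    csv_path = Path(csv_path)
    if meta_path is None:
        meta_path = csv_path.with_suffix(".json")
    df = pd.DataFrame(moments.matrix, index=moments.order, columns=moments.order)
    df.index.name = "variable"
    df.to_csv(csv_path, float_format="%.10g")
    Path(meta_path).write_text(json.dumps(
        {"n": moments.n, "scales": moments.scales, "full_matrix": True}, indent=2))


def read_full_moments_csv(csv_path: str | Path,
                          meta_path: str | Path | None = None) -> SampleMoments:
    csv_path = Path(csv_path)
    if meta_path is None:
        meta_path = csv_path.with_suffix(".json")
    meta = json.loads(Path(meta_path).read_text())
    df = pd.read_csv(csv_path, index_col=0)
    return SampleMoments(list(df.columns), df.to_numpy(float), meta["n"], meta["scales"])
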