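"""Collinearity screening of environmental covariates by variance inflation
factors (VIF).

VIF_j = 1 / (1 - R²_j), where R²_j comes from regressing variable j (OLS with
intercept) on all the others. Variables are removed one at a time — always the
one with the largest VIF — until every remaining variable has VIF strictly
below the threshold (default 10.0), the conventional cutoff below which
collinearity is considered unproblematic for model building.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["VifReport", "compute_vif", "select_variables", "sample_cells"]

# 1 - R^2 below this is treated as numerically perfect collinearity -> VIF = +inf
_PERFECT_COLLINEARITY_TOL = 1e-10


@dataclass
class VifReport:
    """Record of the iterative VIF filter: per-iteration values, removal
    order, and the retained set."""

    threshold: float
    iterations: list[dict[str, float]] = field(default_factory=list)
    removed: list[str] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    n_observations: int = 0
    subsampled: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, vifs in enumerate(self.iterations):
            for name, v in vifs.items():
                rows.append({"iteration": i, "variable": name, "vif": v,
                             "removed": name == (self.removed[i] if i < len(self.removed) else None)})
        return pd.DataFrame(rows)


def _as_matrix(x, names: list[str] | None) -> tuple[np.ndarray, list[str]]:
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), list(x.columns)
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("sample matrix must be 2-D (observations x variables)")
    if names is None:
        names = [f"v{j}" for j in range(x.shape[1])]
    return x, list(names)


def compute_vif(x, names: list[str] | None = None) -> pd.Series:
    """Per-variable VIF of an observations × variables matrix.

    Perfect collinearity yields +inf rather than an error. Requires at least
    variables + 2 observations and nonzero variance in every column.
    """
    mat, names = _as_matrix(x, names)
    n, p = mat.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} observations for {p} variables, got {n}")
    sds = mat.std(axis=0)
    if np.any(sds == 0):
        bad = [names[j] for j in np.flatnonzero(sds == 0)]
        raise ValueError(f"zero-variance variables: {bad}")
    if p == 1:
        return pd.Series([1.0], index=names)
    out = np.empty(p)
    for j in range(p):
        others = np.delete(mat, j, axis=1)
        r2 = sm.OLS(mat[:, j], sm.add_constant(others)).fit().rsquared
        resid = 1.0 - r2
        out[j] = np.inf if resid < _PERFECT_COLLINEARITY_TOL else 1.0 / resid
    return pd.Series(out, index=names)


def select_variables(x, names: list[str] | None = None, threshold: float = 10.0,
                     subsampled: bool = False) -> VifReport:
    """Iteratively drop the variable with the largest VIF until all are below
    the threshold (strict: a VIF exactly at the threshold is removed).

    Ties go to the variable appearing first in input order. At least one
    variable is always retained.
    """
    mat, names = _as_matrix(x, names)
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 variables to select among")
    report = VifReport(threshold=threshold, n_observations=mat.shape[0],
                       subsampled=subsampled)
    keep = list(range(mat.shape[1]))
    while True:
        vifs = compute_vif(mat[:, keep], [names[j] for j in keep])
        report.iterations.append(dict(vifs))
        if len(keep) == 1 or np.nanmax(vifs.to_numpy()) < threshold:
            break
        worst = int(np.argmax(vifs.to_numpy()))  # first max -> first in input order
        report.removed.append(vifs.index[worst])
        keep.pop(worst)
    report.retained = [names[j] for j in keep]
    return report


def sample_cells(stack, max_cells: int = 100_000, seed: int = 0,
                 variables: list[str] | None = None) -> tuple[pd.DataFrame, bool]:
    """Cells × variables sample for the VIF regressions.

    Uses every cell of the calibration-region raster, or a seeded uniform
    subsample when the grid exceeds ``max_cells``; the flag in the return
    value records which.
    """
    mat = stack.as_matrix(variables)
    names = stack.variable_names if variables is None else list(variables)
    subsampled = mat.shape[0] > max_cells
    if subsampled:
        rng = np.random.default_rng(seed)
        idx = rng.choice(mat.shape[0], size=max_cells, replace=False)
        mat = mat[idx]
    return pd.DataFrame(mat, columns=names), subsampled
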