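"""Population-based multivariable regression of conductance influence.

A population of model cells with log-normally varied conductances is
simulated under a stated condition; regressing standardized phenotypes
(APD90, CaT amplitude, IKr block threshold, ...) onto standardized log2
multipliers yields, per phenotype, a coefficient for each of the 16
parameters whose magnitude and sign quantify that parameter's influence.
Parameters are then ranked by coefficient magnitude into top-k / bottom-k
groups, used to ask whether the calibration pipeline constrains the
parameters that matter.

Ordinary least squares is the default (the design matrix of independent
log-normal draws is well-conditioned); partial least squares is available
as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arrhythmia import ikr_block_threshold
from .constants import CONDUCTANCE_NAMES
from .evaluation import extract_features
from .model_core import ConductanceSet, ModelError, SolverSettings, simulate
from .protocols import Condition, extract_window

__all__ = [
    "RegressionResult", "population_outputs", "build_design", "regress",
    "rank_groups", "sensitivity_constraint_report",
]

log = logging.getLogger(__name__)


@dataclass
class RegressionResult:
    """Standardized coefficients (16 x outputs), R^2 per output."""

    coefficients: pd.DataFrame  # index: parameter names, columns: outputs
    r_squared: dict[str, float]
    n_cells: int

    @property
    def outputs(self) -> list[str]:
        return list(self.coefficients.columns)


def population_outputs(cells: list[ConductanceSet], cond: Condition,
                       solver: SolverSettings | None = None,
                       duration_s: float | None = None,
                       include_threshold: bool = False,
                       threshold_resolution_pct: float = 1.0,
                       threshold_duration_s: float | None = None):
    """Simulate each cell under ``cond`` and extract phenotypes.

    Returns ``(outputs_df, excluded)`` where ``outputs_df`` has one row per
    retained cell (columns ``apd90_ms``, ``cat_amplitude_mM``,
    ``beat_rate_hz`` and optionally ``ikr_threshold_pct``) and ``excluded``
    lists ``(cell_index, reason)`` for quiescent/arrhythmic/failed cells.
    """
    solver = solver or SolverSettings()
    rows, index, excluded = [], [], []
    for i, cell in enumerate(cells):
        try:
            traj = simulate(cell, cond, duration_s=duration_s, solver=solver)
        except ModelError as exc:
            excluded.append((i, f"simulation failed: {exc}"))
            continue
        feats = extract_features(extract_window(traj, cond))
        if feats.quiescent or not np.isfinite(feats.apd90_ms):
            excluded.append((i, "quiescent or unmeasurable window"))
            continue
        row = {"apd90_ms": feats.apd90_ms,
               "cat_amplitude_mM": feats.cat_amplitude,
               "beat_rate_hz": feats.beat_rate_hz}
        if include_threshold:
            try:
                thr = ikr_block_threshold(
                    cell, cond, resolution_pct=threshold_resolution_pct,
                    solver=solver, duration_s=threshold_duration_s)
                row["ikr_threshold_pct"] = thr.threshold_pct
            except ValueError as exc:
                excluded.append((i, f"threshold undefined: {exc}"))
                continue
        rows.append(row)
        index.append(i)
    for i, reason in excluded:
        log.info("population_outputs: cell %d excluded (%s)", i, reason)
    return pd.DataFrame(rows, index=index), excluded


def _standardize(mat: np.ndarray, what: str) -> np.ndarray:
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=0)
    zero = np.where(sd == 0)[0]
    if zero.size:
        names = ([CONDUCTANCE_NAMES[z] for z in zero]
                 if what == "parameter" else list(zero))
        raise ValueError(f"zero-variance {what} column(s): {names}")
    return (mat - mu) / sd


def build_design(cells: list[ConductanceSet], outputs: pd.DataFrame):
    """Column-standardized design: X = log2 multipliers of the retained
    cells, Y = phenotype values; rows aligned via ``outputs.index``."""
    sel = [cells[i] for i in outputs.index]
    x_raw = np.log2(np.stack([c.to_vector() for c in sel]))
    x = _standardize(x_raw, "parameter")
    y = _standardize(outputs.to_numpy(dtype=float), "output")
    return x, y


def regress(x: np.ndarray, y: np.ndarray,
            output_names: list[str] | None = None,
            method: str = "ols", n_pls_components: int = 8) -> RegressionResult:
    """Least-squares (or PLS) coefficients per output, with R^2.

    Requires at least 3 rows per column; raises on rank deficiency.
    Coefficients retain their sign; row permutation leaves them unchanged.
    """
    y = y[:, None] if y.ndim == 1 else y
    n, k = x.shape
    if n < 3 * k:
        raise ValueError(f"need >= {3 * k} cells for {k} parameters, got {n}")
    if np.linalg.matrix_rank(x) < k:
        raise ValueError("design matrix is rank deficient")
    if output_names is None:
        output_names = [f"y{j}" for j in range(y.shape[1])]
    if method == "ols":
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    elif method == "pls":
        from sklearn.cross_decomposition import PLSRegression

        pls = PLSRegression(n_components=min(n_pls_components, k),
                            scale=False)
        pls.fit(x, y)
        beta = pls.coef_.T if pls.coef_.shape[0] == y.shape[1] else pls.coef_
    else:
        raise ValueError("method must be 'ols' or 'pls'")
    resid = y - x @ beta
    ss_res = np.sum(resid ** 2, axis=0)
    ss_tot = np.sum((y - y.mean(axis=0)) ** 2, axis=0)
    r2 = 1.0 - ss_res / ss_tot
    coef = pd.DataFrame(beta, index=list(CONDUCTANCE_NAMES),
                        columns=output_names)
    return RegressionResult(coefficients=coef,
                            r_squared=dict(zip(output_names, r2.tolist())),
                            n_cells=n)


def rank_groups(result: RegressionResult, k: int = 4) -> dict[str, dict]:
    """Top-k and bottom-k parameters per output, ranked by |coefficient|;
    ties break deterministically by the canonical parameter order."""
    if k > len(CONDUCTANCE_NAMES):
        raise ValueError(f"k={k} exceeds the number of parameters")
    out = {}
    for col in result.outputs:
        mag = result.coefficients[col].abs().to_numpy()
        order = np.lexsort((np.arange(len(mag)), -mag))
        names = [CONDUCTANCE_NAMES[i] for i in order]
        out[col] = {"top": names[:k], "bottom": names[-k:][::-1]}
    return out


def sensitivity_constraint_report(metrics: pd.DataFrame,
                                  result: RegressionResult,
                                  k: int = 4) -> dict[str, dict]:
    """Group calibration error/spread values by sensitivity rank.

    ``metrics`` has one row per (cell, parameter) with columns
    ``parameter``, plus value columns (e.g. ``error``, ``spread``).  For
    each regression output, returns the value arrays of the top-k and
    bottom-k parameter groups (k parameters x number of cells values per
    group) for reporting/plotting.
    """
    if not set(metrics["parameter"]) <= set(CONDUCTANCE_NAMES):
        raise ValueError("metrics parameter names do not match the model")
    groups = rank_groups(result, k=k)
    value_cols = [c for c in metrics.columns if c != "parameter"
                  and np.issubdtype(metrics[c].dtype, np.number)]
    report: dict[str, dict] = {}
    for output, grp in groups.items():
        entry: dict = {"top_parameters": grp["top"],
                       "bottom_parameters": grp["bottom"]}
        for which in ("top", "bottom"):
            sub = metrics[metrics["parameter"].isin(grp[which])]
            for col in value_cols:
                entry[f"{which}_{col}"] = sub[col].to_numpy()
        report[output] = entry
    return report
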