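"""Microbial activity statistics: log-linear relation to root exudation.

Substrate-induced respiration (SIR, μg CO₂-C g⁻¹ dry soil h⁻¹) and the
denitrifying enzyme assay (DEA, μg N₂O-N g⁻¹ dry soil h⁻¹) respond
multiplicatively to the carbon supplied by root exudation, so the model
fitted here is

    log(activity) = intercept + slope · exudation + ε

with the Pearson correlation computed between log-activity and
exudation. The natural log is used; the base only rescales slope and
intercept, never r.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError

ACTIVITY_COLUMNS = ("sir", "dea", "exudation")


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r between log-activity and exudation, with the fitted line."""

    r: float
    p: float
    slope: float
    intercept: float
    n: int


def log_linear_correlation(
    activity: Sequence[float], exudation: Sequence[float]
) -> CorrelationResult:
    """Correlate log-transformed activity with exudation rate.

    Requires ≥ 3 paired observations and strictly positive activities
    (zeros cannot be log-transformed and are rejected, naming the
    offending positions). The p-value is the two-sided t-based test of
    r = 0.
    """
    a = np.asarray(activity, dtype=float)
    x = np.asarray(exudation, dtype=float)
    if a.shape != x.shape or a.ndim != 1:
        raise ValueError("activity and exudation must be equal-length vectors")
    if len(a) < 3:
        raise ValueError("need at least 3 observations")
    bad = np.flatnonzero(a <= 0)
    if bad.size:
        raise ValueError(f"non-positive activity at positions {bad.tolist()}; cannot log-transform")
    log_a = np.log(a)
    if np.ptp(x) == 0 or np.ptp(log_a) == 0:
        raise DegenerateInputError("zero variance in activity or exudation")
    fit = stats.linregress(x, log_a)
    return CorrelationResult(
        r=float(fit.rvalue),
        p=float(fit.pvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=len(a),
    )


def pooled_log_linear_correlation(
    activities: dict[str, Sequence[float]], exudation: Sequence[float]
) -> CorrelationResult:
    """Correlation with several activities stacked into one vector.

    The exudation vector is repeated once per activity. Offered because
    a single correlation may be reported jointly for SIR and DEA; the
    per-activity form is :func:`log_linear_correlation`.
    """
    stacked = np.concatenate([np.asarray(v, dtype=float) for v in activities.values()])
    x = np.concatenate([np.asarray(exudation, dtype=float)] * len(activities))
    return log_linear_correlation(stacked, x)


def group_summary(
    table: pd.DataFrame, by: str = "species"
) -> pd.DataFrame:
    """Mean and standard error of each activity per group.

    ``table`` is the per-sample activity table (columns: species,
    strategy, sir, dea, exudation); ``by`` is the grouping column. SE is
    sd/√n; single-sample groups get SE = NaN with ``se_defined = False``.
    """
    if by not in table.columns:
        raise ValueError(f"grouping column {by!r} not in table")
    rows = []
    for name, block in table.groupby(by, sort=True):
        row: dict = {by: name, "n": len(block)}
        for col in ACTIVITY_COLUMNS:
            if col not in block.columns:
                continue
            vals = block[col].to_numpy(dtype=float)
            row[f"{col}_mean"] = float(vals.mean())
            if len(vals) > 1:
                row[f"{col}_se"] = float(vals.std(ddof=1) / np.sqrt(len(vals)))
            else:
                row[f"{col}_se"] = float("nan")
        row["se_defined"] = len(block) > 1
        rows.append(row)
    return pd.DataFrame(rows).set_index(by)
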