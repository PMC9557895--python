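"""Outcome and exposure preparation.

The outcome of all interaction models is rank-based inverse-normalized BMI:
values are ranked (ties share the average rank) and mapped through the normal
quantile function at Blom fractions, (r - 3/8) / (n + 1/4).  The transform
limits heteroscedasticity- and skew-driven biases in scale-dependent
interaction tests; it is computed once on the full analysis sample, not per
stratum.

Severity scores (cases only) are dichotomized at their median with a >=
rule, mirroring the below/above-median presentation of severity effects.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import DegenerateInputError, EmptyGroupError, InsufficientDataError

__all__ = ["inverse_normal_transform", "severity_split", "prepare_cohort"]


def inverse_normal_transform(values, offset: float = 3.0 / 8.0):
    """Rank-based inverse normal transform with a configurable rank offset.

    transformed = Phi^-1((r - c) / (n + 1 - 2c)) with c = 3/8 (Blom) by
    default.  Ties share the average rank; missing values stay missing and
    do not consume ranks.  Raises if fewer than 3 finite values or if all
    finite values are identical.
    """
    is_series = isinstance(values, pd.Series)
    arr = np.asarray(values, dtype=float)
    mask = np.isfinite(arr)
    n = int(mask.sum())
    if n < 3:
        raise InsufficientDataError(f"need >= 3 finite values, got {n}")
    finite = arr[mask]
    if finite.max() == finite.min():
        raise DegenerateInputError("all values identical; transform undefined")
    r = rankdata(finite, method="average")
    out = np.full(arr.shape, np.nan)
    out[mask] = norm.ppf((r - offset) / (n + 1.0 - 2.0 * offset))
    if is_series:
        return pd.Series(out, index=values.index, name="bmi_int")
    return out


def severity_split(severity: pd.Series) -> tuple[pd.Series, float]:
    """Dichotomize case severity at the median (score >= median -> 1).

    Returns the indicator (missing where severity is missing, i.e. controls)
    and the threshold used.  If every score is equal the split is degenerate
    (everyone is "above median" under the >= rule); a warning is emitted.
    """
    scores = severity.dropna()
    if scores.empty:
        raise EmptyGroupError("no cases with severity scores")
    threshold = float(np.median(scores.to_numpy(float)))
    if scores.nunique() == 1:
        warnings.warn(
            f"all severity scores equal ({threshold:g}); degenerate median split",
            stacklevel=2,
        )
    out = pd.Series(pd.array([pd.NA] * len(severity), dtype="Int64"),
                    index=severity.index, name="severity_high")
    out[scores.index] = (scores.to_numpy(float) >= threshold).astype(np.int64)
    return out, threshold


def prepare_cohort(phenotypes: pd.DataFrame, offset: float = 3.0 / 8.0) -> pd.DataFrame:
    """Augment a phenotype table with bmi_int and the severity median split."""
    out = phenotypes.copy()
    out["bmi_int"] = inverse_normal_transform(out["bmi_raw"], offset=offset)
    if "severity" in out.columns and out["severity"].notna().any():
        out["severity_high"], _ = severity_split(out["severity"])
    return out
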