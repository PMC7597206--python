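"""Sparsity-AUC aggregation, asymmetry scores and hypothesis tests.

Each topological property is measured over a range of sparsity
thresholds, summarised by the area under the property-vs-threshold
curve (trapezoidal rule on the fractional threshold axis), averaged over
a subject's trials within one emotion category, and then compared
between hemispheres:

* paired t-tests of left vs right per-subject AUC values (positive t =
  left > right);
* one-sample t-tests of the asymmetry score
  AS(X) = 100 (X_R - X_L) / (X_R + X_L) against zero (positive =
  rightward dominance);
* per homologous electrode pair, the same two tests on nodal
  efficiency, with Benjamini-Hochberg FDR control across the 14 pairs
  within each band x category family.
"""

from __future__ import annotations

import logging
import warnings
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# AUC over the sparsity range
# ---------------------------------------------------------------------------

def auc(thresholds: np.ndarray, values: np.ndarray) -> float:
    """Trapezoidal area under a metric curve over the threshold axis.

    Thresholds are fractions (e.g. 0.05 ... 0.40) and must be strictly
    increasing; at least two points are required.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    values = np.asarray(values, dtype=float)
    if thresholds.ndim != 1 or thresholds.size < 2:
        raise ValidationError("AUC needs at least two threshold points")
    if values.shape[0] != thresholds.size:
        raise ValidationError("thresholds and values lengths differ")
    if np.any(np.diff(thresholds) <= 0):
        raise ValidationError("thresholds must be strictly increasing")
    return float(np.trapezoid(values, thresholds, axis=0)) if values.ndim == 1 \
        else np.trapezoid(values, thresholds, axis=0)


def subject_average(records: pd.DataFrame,
                    value_col: str = "auc",
                    keys: tuple[str, ...] = ("subject", "category", "band",
                                             "hemisphere", "metric"),
                    ) -> pd.DataFrame:
    """Arithmetic mean of per-trial AUC values within each group."""
    keys = [k for k in keys if k in records.columns]
    return (records.groupby(list(keys), as_index=False, sort=True)[value_col]
            .mean())


# ---------------------------------------------------------------------------
# Asymmetry score
# ---------------------------------------------------------------------------

def asymmetry_score(x_left, x_right):
    """AS(X) = 100 (X_R - X_L) / (X_R + X_L).

    Positive = rightward asymmetry, negative = leftward; bounded by
    [-100, 100] for non-negative inputs.  Undefined (NaN, with a
    warning) when both values are zero.
    """
    xl = np.asarray(x_left, dtype=float)
    xr = np.asarray(x_right, dtype=float)
    total = xl + xr
    bad = total == 0
    if np.any(bad):
        warnings.warn("asymmetry score undefined where X(L) + X(R) = 0",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(bad, np.nan, 100.0 * (xr - xl) / np.where(bad, 1.0, total))
    if np.isscalar(x_left) and np.isscalar(x_right):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Hypothesis tests
# ---------------------------------------------------------------------------

def paired_hemisphere_test(left: np.ndarray, right: np.ndarray
                           ) -> tuple[float, float]:
    """Two-tailed paired t-test on left-minus-right differences.

    Positive t means left > right.  Zero-variance differences yield a
    (NaN, NaN) sentinel with a warning.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape or left.ndim != 1:
        raise ValidationError("paired test needs two equal-length vectors")
    if left.size < 3:
        raise ValidationError("paired test needs at least 3 subjects")
    diff = left - right
    if np.ptp(diff) == 0 and diff[0] == 0:
        # identical hemispheres: t = 0 by convention, p = 1
        return 0.0, 1.0
    if np.std(diff, ddof=1) == 0:
        warnings.warn("zero-variance differences: paired t undefined",
                      stacklevel=2)
        return float("nan"), float("nan")
    res = sps.ttest_rel(left, right)
    return float(res.statistic), float(res.pvalue)


def one_sample_as_test(values: np.ndarray) -> tuple[float, float]:
    """Two-tailed one-sample t-test of asymmetry scores against zero."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 3:
        raise ValidationError("one-sample test needs at least 3 values")
    if np.std(values, ddof=1) == 0:
        warnings.warn("zero-variance sample: one-sample t undefined",
                      stacklevel=2)
        return float("nan"), float("nan")
    res = sps.ttest_1samp(values, 0.0)
    return float(res.statistic), float(res.pvalue)


def normality_check(values: np.ndarray, alpha: float = 0.05
                    ) -> tuple[float, float, bool]:
    """Shapiro-Wilk omnibus normality test.

    Returns (statistic, p, passed) where ``passed`` means the sample is
    consistent with normality at the given alpha.  Failures are logged;
    downstream analysis proceeds with the flag attached.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 3:
        raise ValidationError("normality check needs at least 3 values")
    if np.ptp(values) == 0:
        warnings.warn("constant sample: normality test undefined", stacklevel=2)
        return float("nan"), float("nan"), False
    stat, p = sps.shapiro(values)
    passed = bool(p > alpha)
    if not passed:
        logger.info("normality check failed (W=%.3f, p=%.4f)", stat, p)
    return float(stat), float(p), passed


def fdr_correct(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR correction at level q.

    Returns (reject flags, adjusted p-values).  NaN entries (from
    degenerate tests) are excluded from the family and never rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("expected a 1-D collection of p-values")
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    reject = np.zeros(p.shape, dtype=bool)
    adjusted = np.full(p.shape, np.nan)
    if finite.any():
        rej, adj, _, _ = multipletests(p[finite], alpha=q, method="fdr_bh")
        reject[finite] = rej
        adjusted[finite] = adj
    return reject, adjusted


__all__ = [
    "auc", "subject_average", "asymmetry_score", "paired_hemisphere_test",
    "one_sample_as_test", "normality_check", "fdr_correct",
]
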