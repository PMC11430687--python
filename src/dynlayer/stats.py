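"""Two-group statistics for reconfiguration metrics.

Independent-samples t-tests (equal-variance by default, Welch optional) are
run per unit at each aggregation level, with Benjamini–Hochberg FDR
correction applied within each (metric × level) family.  Spearman rank
correlations relate metrics to clinical scores.  The t-statistic sign
follows the declared group order: a negative t means the first group's mean
is lower.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["ttest_by_level", "fdr_correct", "spearman"]

RESULT_COLUMNS = ["metric", "level", "unit", "t", "p_raw", "p_fdr",
                  "mean_g1", "mean_g2", "sd_g1", "sd_g2", "n_g1", "n_g2",
                  "flag"]


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _ttest(x: np.ndarray, y: np.ndarray, equal_var: bool) -> tuple[float, float, str]:
    if np.std(x) == 0 and np.std(y) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0, "zero_variance"
        return np.inf * np.sign(np.mean(x) - np.mean(y)), 0.0, "zero_variance"
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p), ""


def ttest_by_level(values: pd.DataFrame, group_order: tuple[str, str],
                   equal_var: bool = True) -> pd.DataFrame:
    """Between-group t-tests for every (metric, level, unit) in a tidy table.

    Parameters
    ----------
    values:
        Tidy per-subject table with columns ``subject``, ``group``,
        ``metric``, ``level``, ``unit``, ``value``.
    group_order:
        ``(g1, g2)``; t is computed as g1 vs g2 so ``sign(t) =
        sign(mean_g1 − mean_g2)``.
    equal_var:
        Pooled-variance t by default; ``False`` gives Welch's t.

    Returns
    -------
    One row per unit with raw and BH-adjusted p (family = metric × level),
    group means/SDs/sizes, and a ``flag`` column marking degenerate
    (zero-variance) comparisons.
    """
    required = {"subject", "group", "metric", "level", "unit", "value"}
    missing = required - set(values.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")
    g1, g2 = group_order
    rows = []
    for (metric, level, unit), sub in values.groupby(
            ["metric", "level", "unit"], sort=True):
        x = sub.loc[sub["group"] == g1, "value"].to_numpy(float)
        y = sub.loc[sub["group"] == g2, "value"].to_numpy(float)
        if len(x) < 2 or len(y) < 2:
            raise ValueError(
                f"need >= 2 subjects per group for {metric}/{level}/{unit}")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError(f"non-finite values in {metric}/{level}/{unit}")
        t, p, flag = _ttest(x, y, equal_var)
        rows.append({"metric": metric, "level": level, "unit": unit,
                     "t": t, "p_raw": p,
                     "mean_g1": x.mean(), "mean_g2": y.mean(),
                     "sd_g1": x.std(ddof=1), "sd_g2": y.std(ddof=1),
                     "n_g1": len(x), "n_g2": len(y), "flag": flag})
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    for _, idx in out.groupby(["metric", "level"]).groups.items():
        out.loc[idx, "p_fdr"] = fdr_correct(out.loc[idx, "p_raw"].to_numpy())
    return out[RESULT_COLUMNS]


def spearman(metric_values, scores) -> tuple[float, float]:
    """Spearman rank correlation with average-rank tie handling.

    Returns ``(r, p)`` two-sided; a constant input vector makes the
    correlation undefined and yields ``(nan, nan)``.
    """
    x = np.asarray(metric_values, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = sps.spearmanr(x, y)
    return float(r), float(p)
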