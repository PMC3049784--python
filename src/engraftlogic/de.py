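"""Median normalization and per-probe G0-vs-G1 differential expression.

Each sample column is normalized by its own median, matching the
single-experiment normalization applied to the deposited arrays.  DE is
then called per tissue with a two-fold-change / p<0.01 rule: fold change
is the ratio of mean normalized G0 intensity to mean normalized G1
intensity on the linear scale, and the p-value comes from a two-sample
unequal-variance (Welch) t-test on log2 normalized intensities — a
transparent stand-in for the proprietary per-probe error model used on
the original arrays.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from engraftlogic.matrix import ExpressionMatrix


def normalize_median(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Divide every sample column by its median; post-median is exactly 1."""
    matrix.validate()
    values = matrix.values / matrix.values.median(axis=0)
    return ExpressionMatrix(
        values=values, samples=matrix.samples, feature_meta=matrix.feature_meta
    )


def welch_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Welch t-test p-values for two replicate blocks.

    Degenerate convention: rows where both groups have zero variance get
    p = 0 if the means differ and p = 1 if they are identical.
    """
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    if degenerate.any():
        equal = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
    return p


def test_de(
    matrix: ExpressionMatrix,
    tissue: str,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.01,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Call G0-vs-G1 differential expression for one tissue.

    Returns a DataFrame with one row per feature (no silent drops):
    feature_id (index), tissue, fold_change (mean G0 / mean G1, linear
    normalized scale), direction (up_G0 iff fold_change > 1), p_value and
    is_de (|fold change| >= ``fc_threshold`` in either direction, at-least
    semantics, AND p < ``p_threshold``).  ``bh_correct`` optionally applies
    Benjamini-Hochberg to the p-values before thresholding (off by
    default: the original analysis thresholds raw p-values).
    """
    g0_cols = matrix.group_columns(tissue, "G0")
    g1_cols = matrix.group_columns(tissue, "G1")
    if len(g0_cols) < 2 or len(g1_cols) < 2:
        raise ValueError(
            f"tissue {tissue!r} needs >=2 replicates per phase "
            f"(found G0={len(g0_cols)}, G1={len(g1_cols)})"
        )
    g0 = matrix.values[g0_cols].to_numpy()
    g1 = matrix.values[g1_cols].to_numpy()
    fold = g0.mean(axis=1) / g1.mean(axis=1)
    p = welch_pvalues(np.log2(g0), np.log2(g1))
    p_eff = p
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        p_eff = multipletests(p, method="fdr_bh")[1]
    is_de = (np.maximum(fold, 1.0 / fold) >= fc_threshold) & (p_eff < p_threshold)
    return pd.DataFrame(
        {
            "tissue": tissue,
            "fold_change": fold,
            "direction": np.where(fold > 1.0, "up_G0", "up_G1"),
            "p_value": p,
            "is_de": is_de,
        },
        index=matrix.values.index.copy(),
    )


def de_set(calls: pd.DataFrame) -> set[str]:
    """Feature ids called DE in a per-tissue call table."""
    return set(calls.index[calls["is_de"]])
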