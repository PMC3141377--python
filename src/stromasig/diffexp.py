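"""Per-gene univariate differential expression, cancer vs normal.

The test is a two-sample t on log2 intensities, Welch (unequal variance)
by default because the design is unbalanced (20 tumors vs 6 normals); a
pooled-variance option is provided.  Fold changes follow the signed
convention used in microarray signature tables: the ratio r = 2^(tumor
mean - normal mean) is reported as r when r >= 1 and as -1/r otherwise,
so -25 means 25-fold lower in tumor.  P-values are floored at 1e-16 so
that downstream log transforms stay finite.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .io_formats import ExpressionMatrix, GeneSet

P_FLOOR = 1e-16

DE_COLUMNS = ["p_value", "fold_change", "direction"]


def fold_change(tumor_mean_log2: float, normal_mean_log2: float) -> float:
    """Signed expression ratio from the two class means (log2 scale)."""
    if not (np.isfinite(tumor_mean_log2) and np.isfinite(normal_mean_log2)):
        raise AnalysisError("fold_change needs finite means")
    r = 2.0 ** (tumor_mean_log2 - normal_mean_log2)
    return float(r if r >= 1.0 else -1.0 / r)


def _signed_fc(delta_log2: np.ndarray) -> np.ndarray:
    r = 2.0 ** delta_log2
    return np.where(r >= 1.0, r, -1.0 / r)


def univariate_de(matrix: ExpressionMatrix, test: str = "welch") -> pd.DataFrame:
    """Two-sided per-gene t-test between the cancer and normal classes.

    Returns a DataFrame indexed by gene id with columns ``p_value``
    (floored at 1e-16), ``fold_change`` (signed) and ``direction``
    (``up``/``down``).  Genes that are constant across all samples get
    p = 1 and fold change 1.
    """
    if test not in ("welch", "pooled"):
        raise AnalysisError(f"unknown test {test!r}; use 'welch' or 'pooled'")
    cancer = matrix.samples_in_class("cancer")
    normal = matrix.samples_in_class("normal")
    if len(cancer) < 2 or len(normal) < 2:
        raise AnalysisError(
            f"need >=2 samples per class, got {len(cancer)} cancer / "
            f"{len(normal)} normal")
    a = matrix.values[cancer].to_numpy()
    b = matrix.values[normal].to_numpy()
    import warnings as _warnings
    with np.errstate(divide="ignore", invalid="ignore"), \
            _warnings.catch_warnings():
        # degenerate (constant) genes are repaired explicitly below
        _warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=(test == "pooled"))
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    equal_means = np.isclose(mean_a, mean_b, rtol=0.0, atol=0.0)
    # zero variance in both classes: p=1 if means coincide, else maximally
    # significant (floored)
    degenerate = (a.var(axis=1) == 0.0) & (b.var(axis=1) == 0.0)
    p = np.where(degenerate, np.where(equal_means, 1.0, 0.0), p)
    p = np.where(np.isnan(p), 1.0, p)
    p = np.clip(p, P_FLOOR, 1.0)
    fc = _signed_fc(mean_a - mean_b)
    direction = np.where(mean_a >= mean_b, "up", "down")
    return pd.DataFrame(
        {"p_value": p, "fold_change": fc, "direction": direction},
        index=matrix.values.index)


def signature(de: pd.DataFrame, alpha: float):
    """Split genes with p < alpha into up- and down-regulated gene sets."""
    if not 0.0 < alpha < 1.0:
        raise AnalysisError("alpha must lie in (0, 1)")
    hits = de[de["p_value"] < alpha]
    up = frozenset(hits.index[hits["direction"] == "up"])
    down = frozenset(hits.index[hits["direction"] == "down"])
    return GeneSet("up", up), GeneSet("down", down)
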