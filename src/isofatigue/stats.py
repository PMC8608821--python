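"""Statistical comparisons used in the endurance-test analysis.

Covers the study-level inference: coefficient-of-variation screening of
repeated maximal contractions, paired comparisons of early versus late
power output, repeated-measures ANOVA across the three muscle groups with
Bonferroni-corrected pairwise post-hocs, Pearson correlations, and the
F-tests for equality of slope and intercept between two fitted regression
lines (used to compare linear and non-linear actual-versus-estimated
maps).  All p-values are two-tailed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM

__all__ = [
    "LineComparison",
    "cv_percent",
    "paired_t",
    "rm_anova",
    "compare_regression_lines",
    "pearson",
]


@dataclass
class LineComparison:
    """Slope/intercept equality tests between two regression lines.

    The slope test compares a common-slope (two intercepts) model to
    fully separate lines; when slopes do not differ, the intercept test
    compares a single line to the common-slope model.  Residual sums of
    squares and degrees of freedom of the nested fits are retained.
    """

    F_slope: float
    p_slope: float
    F_intercept: float
    p_intercept: float
    sse_separate: float
    df_separate: int
    sse_common_slope: float
    df_common_slope: int
    sse_single: float
    df_single: int


def cv_percent(values: np.ndarray) -> float:
    """Coefficient of variation, percent: 100 × sample SD / mean.

    Used to screen repeated maximal contractions (the protocol requires
    CV < 10 % across the three attempts).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    mean = float(np.mean(x))
    if mean == 0.0:
        raise ZeroDivisionError("CV undefined for zero mean")
    return 100.0 * float(np.std(x, ddof=1)) / mean


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-tailed paired-samples t-test; returns (t, p).

    Identical samples give t = 0, p = 1; zero-variance non-zero
    differences are degenerate and reported as t = ±inf, p = 0.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need two equal-length samples of n >= 2")
    d = x - y
    if np.std(d, ddof=1) == 0:
        if np.allclose(d, 0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = sps.ttest_rel(x, y)
    return float(t), float(p)


def rm_anova(
    groups: np.ndarray | pd.DataFrame, alpha: float = 0.05, repeated: bool = True
) -> dict:
    """One-way ANOVA across conditions with pairwise post-hocs.

    ``groups`` is an (n_subjects × n_conditions) array or DataFrame of
    complete blocks — every subject measured under every condition (the
    three muscle groups of the protocol).  By default a repeated-measures
    ANOVA is fitted (subjects are their own controls); ``repeated=False``
    falls back to a one-way independent ANOVA.  Post-hoc pairwise paired
    t-tests are Bonferroni-corrected over the number of pairs, with
    significance flags at ``alpha`` and ``alpha/5`` intended as the
    0.05 / 0.01 marks of a results figure.

    Returns ``{"F", "p", "posthoc"}`` where ``posthoc`` is a DataFrame
    with one row per condition pair.
    """
    if isinstance(groups, pd.DataFrame):
        data = groups.to_numpy(dtype=float)
        names = [str(c) for c in groups.columns]
    else:
        data = np.asarray(groups, dtype=float)
        names = [f"cond{j + 1}" for j in range(data.shape[1])]
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("need an (n_subjects, n_conditions >= 2) block design")
    if not np.all(np.isfinite(data)):
        raise ValueError("incomplete blocks: all subjects need all conditions")
    n, k = data.shape

    if repeated:
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "condition": np.tile(names, n),
                "value": data.ravel(),
            }
        )
        table = AnovaRM(long, "value", "subject", within=["condition"]).fit().anova_table
        F = float(table["F Value"].iloc[0])
        p = float(table["Pr > F"].iloc[0])
    else:
        F, p = sps.f_oneway(*[data[:, j] for j in range(k)])
        F, p = float(F), float(p)

    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    m = len(pairs)
    rows = []
    for i, j in pairs:
        t, praw = paired_t(data[:, i], data[:, j])
        padj = min(1.0, praw * m)
        rows.append(
            {
                "pair": f"{names[i]} vs {names[j]}",
                "t": t,
                "p_raw": praw,
                "p_bonferroni": padj,
                "sig_05": padj < alpha,
                "sig_01": padj < alpha / 5.0,
            }
        )
    return {"F": F, "p": p, "posthoc": pd.DataFrame(rows)}


def _line_sse(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def compare_regression_lines(
    x1: np.ndarray, y1: np.ndarray, x2: np.ndarray, y2: np.ndarray
) -> LineComparison:
    """F-tests for equality of slope and of intercept between two simple
    regression lines fitted on independent datasets.

    Nested extra-sum-of-squares tests: slope — separate lines (4
    parameters) versus common slope with separate intercepts (3); then,
    conditional on a common slope, intercept — common slope versus a
    single line (2).  Symmetric in the two datasets.
    """
    a1 = np.asarray(x1, dtype=float); b1 = np.asarray(y1, dtype=float)
    a2 = np.asarray(x2, dtype=float); b2 = np.asarray(y2, dtype=float)
    if a1.size != b1.size or a2.size != b2.size:
        raise ValueError("x/y lengths must match within each dataset")
    if min(a1.size, a2.size) < 3:
        raise ValueError("need at least three points per line")
    if np.std(a1) == 0 or np.std(a2) == 0:
        raise ValueError("degenerate predictor (zero variance)")
    n1, n2 = a1.size, a2.size

    sse_sep = _line_sse(np.column_stack([np.ones(n1), a1]), b1) + _line_sse(
        np.column_stack([np.ones(n2), a2]), b2
    )
    df_sep = n1 + n2 - 4

    g1 = np.concatenate([np.ones(n1), np.zeros(n2)])
    g2 = 1.0 - g1
    x = np.concatenate([a1, a2])
    y = np.concatenate([b1, b2])
    sse_cs = _line_sse(np.column_stack([g1, g2, x]), y)
    df_cs = n1 + n2 - 3

    sse_one = _line_sse(np.column_stack([np.ones(n1 + n2), x]), y)
    df_one = n1 + n2 - 2

    F_slope = max(0.0, (sse_cs - sse_sep)) / (sse_sep / df_sep) if sse_sep > 0 else 0.0
    p_slope = float(sps.f.sf(F_slope, 1, df_sep)) if sse_sep > 0 else 1.0
    F_int = max(0.0, (sse_one - sse_cs)) / (sse_cs / df_cs) if sse_cs > 0 else 0.0
    p_int = float(sps.f.sf(F_int, 1, df_cs)) if sse_cs > 0 else 1.0

    return LineComparison(
        F_slope=float(F_slope),
        p_slope=p_slope,
        F_intercept=float(F_int),
        p_intercept=p_int,
        sse_separate=sse_sep,
        df_separate=df_sep,
        sse_common_slope=sse_cs,
        df_common_slope=df_cs,
        sse_single=sse_one,
        df_single=df_one,
    )


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-tailed p-value."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need at least three paired points")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = sps.pearsonr(a, b)
    return float(r), float(p)
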