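"""Robustness-study statistics.

Bland–Altman agreement between two measurement conditions, a Spearman
correlogram with hierarchical-clustering ordering, and the one-way
single-score agreement intraclass correlation coefficient, ICC(1,1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "BlandAltmanResult",
    "ICCResult",
    "SpearmanResult",
    "bland_altman",
    "bland_altman_table",
    "spearman_matrix",
    "icc_oneway",
]


@dataclass
class BlandAltmanResult:
    """Bias and 95% limits of agreement for paired measurements.

    Differences are ``B - A`` (the condition order is recorded);
    the SD uses the n-1 denominator and the limits are
    ``bias +/- 1.96 SD``.
    """

    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    n: int
    label_a: str = "A"
    label_b: str = "B"
    relative: bool = False


@dataclass
class ICCResult:
    """One-way random-effects, single-score, agreement ICC."""

    icc: float
    ms_between: float
    ms_within: float
    n_subjects: int
    n_raters: int
    degenerate: bool = False


@dataclass
class SpearmanResult:
    """Pairwise Spearman correlations with a clustered ordering."""

    r: pd.DataFrame  # signed correlations
    abs_r: pd.DataFrame  # |r|, rows/cols in clustered order
    order: list  # feature names in clustered order
    dropped: list  # constant features excluded from clustering


def bland_altman(
    a, b, label_a: str = "A", label_b: str = "B", relative: bool = False
) -> BlandAltmanResult:
    """Bland–Altman agreement between two paired measurement series.

    With ``relative=True`` the differences are percentages of the
    pair means, ``100 (B - A) / ((A + B) / 2)``, which removes the
    value-dependent spread seen for intensity-scale features.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired measurements must have equal length")
    if a.ndim != 1 or a.size < 2:
        raise ValueError("need at least 2 paired measurements")
    diffs = b - a
    if relative:
        means = (a + b) / 2.0
        if np.any(means == 0):
            raise ValueError("relative differences undefined when a pair mean is 0")
        diffs = 100.0 * diffs / means
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        bias, sd, bias - 1.96 * sd, bias + 1.96 * sd, a.size, label_a, label_b, relative
    )


def bland_altman_table(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    label_a: str = "A",
    label_b: str = "B",
) -> pd.DataFrame:
    """Per-feature Bland–Altman statistics for two same-subject tables.

    Both absolute and percentage differences are reported, plus the
    bias normalized by the feature's mean magnitude so features on
    different scales can be compared.
    """
    common = [c for c in table_a.columns if c in table_b.columns]
    if not common:
        raise ValueError("no common feature columns")
    if len(table_a) != len(table_b):
        raise ValueError("tables must describe the same subjects")
    rows = []
    for col in common:
        a = table_a[col].to_numpy(dtype=float)
        b = table_b[col].to_numpy(dtype=float)
        res = bland_altman(a, b, label_a, label_b)
        mean_abs = float(np.mean(np.abs((a + b) / 2.0)))
        rows.append(
            {
                "feature": col,
                "n": res.n,
                "bias": res.bias,
                "sd_diff": res.sd_diff,
                "loa_lower": res.loa_lower,
                "loa_upper": res.loa_upper,
                "mean_abs_value": mean_abs,
                "rel_bias": res.bias / mean_abs if mean_abs > 0 else np.nan,
                "rel_loa_width": (res.loa_upper - res.loa_lower) / mean_abs
                if mean_abs > 0
                else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def spearman_matrix(table: pd.DataFrame) -> SpearmanResult:
    """Spearman rank correlations between all feature pairs.

    Ranks use average ranks for ties. The correlogram reports |r|,
    with rows ordered by complete-linkage hierarchical clustering on
    the distance ``1 - |r|``. Constant features have undefined
    correlations: they are reported as missing and excluded from the
    clustering order.
    """
    if table.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if table.shape[1] < 2:
        raise ValueError("need at least 2 features")
    r = table.corr(method="spearman")
    constant = [c for c in table.columns if table[c].nunique() <= 1]
    keep = [c for c in table.columns if c not in constant]
    if len(keep) >= 2:
        sub = r.loc[keep, keep].abs()
        dist = squareform((1.0 - sub).to_numpy(), checks=False)
        link = hierarchy.linkage(dist, method="complete")
        order = [keep[i] for i in hierarchy.leaves_list(link)]
    else:
        order = keep
    order = order + constant
    return SpearmanResult(r, r.abs().loc[order, order], order, constant)


def icc_oneway(ratings) -> ICCResult:
    """ICC(1,1): one-way random effects, absolute agreement, single score.

    ``ratings`` is an n_subjects x n_raters table with no missing
    entries. The estimate is ``(MSB - MSW) / (MSB + (k - 1) MSW)``
    from the one-way ANOVA decomposition. When the decomposition is
    fully degenerate (no variance anywhere) the ICC is reported as 0
    with the ``degenerate`` flag set.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2D subjects x raters table")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings table must be complete")
    grand = x.mean()
    subj_means = x.mean(axis=1)
    ssb = k * float(((subj_means - grand) ** 2).sum())
    ssw = float(((x - subj_means[:, None]) ** 2).sum())
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    denom = msb + (k - 1) * msw
    if denom == 0:
        return ICCResult(0.0, msb, msw, n, k, degenerate=True)
    return ICCResult((msb - msw) / denom, msb, msw, n, k)
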