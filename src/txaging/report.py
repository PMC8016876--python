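"""Presentation statistics: volcano tables, z-score heat-map input, and
small-sample group comparisons.

The heat-map input standardizes each feature row to mean 0 / SD 1
(sample SD, n-1) and orders rows by complete-linkage hierarchical
clustering on the distance ``1 - Pearson r`` between rows, so features
with similar age profiles sit together regardless of absolute level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import complete, leaves_list
from scipy.spatial.distance import squareform

__all__ = [
    "volcano_table",
    "HeatmapInput",
    "zscore_cluster",
    "kruskal_wallis",
    "relative_expression",
]


def volcano_table(
    fits: pd.DataFrame, alpha: float = 0.01, log10_cap: float = 300.0
) -> pd.DataFrame:
    """Classify fits into up / down / ns and compute -log10 p for plotting.

    ``p = 0`` is capped at ``log10_cap`` on the -log10 scale.
    """
    df = fits[["beta_age", "p_wald"]].copy()
    with np.errstate(divide="ignore"):
        df["neg_log10_p"] = np.minimum(-np.log10(df["p_wald"]), log10_cap)
    cls = pd.Series("ns", index=df.index, dtype=object)
    sig = df["p_wald"] < alpha
    cls[sig & (df["beta_age"] > 0)] = "up"
    cls[sig & (df["beta_age"] < 0)] = "down"
    df["class"] = cls
    return df


@dataclass
class HeatmapInput:
    """Row-standardized matrix with a clustering-derived row order."""

    zscores: pd.DataFrame
    row_order: list  # clustered rows first, constant (flagged) rows last
    constant_rows: list


def zscore_cluster(matrix: pd.DataFrame) -> HeatmapInput:
    """Row-wise z-scores plus complete-linkage order on 1 - Pearson r.

    Constant rows (SD 0) cannot be standardized or correlated; they are
    flagged and placed after the clustered rows.  Leaf order follows the
    standard recursive left-subtree-first traversal; ties in the distance
    matrix resolve by input row index (scipy's stable behaviour).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    vals = matrix.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=1)
    constant = sd == 0
    z = np.full_like(vals, np.nan)
    mean = vals.mean(axis=1)
    z[~constant] = (vals[~constant] - mean[~constant, None]) / sd[~constant, None]
    zdf = pd.DataFrame(z, index=matrix.index, columns=matrix.columns)

    variable_idx = np.flatnonzero(~constant)
    if len(variable_idx) >= 2:
        corr = np.corrcoef(vals[variable_idx])
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # enforce symmetry
        linkage = complete(squareform(dist, checks=False))
        order = [matrix.index[variable_idx[i]] for i in leaves_list(linkage)]
    else:
        order = [matrix.index[i] for i in variable_idx]
    const_rows = [matrix.index[i] for i in np.flatnonzero(constant)]
    return HeatmapInput(zscores=zdf, row_order=order + const_rows, constant_rows=const_rows)


def kruskal_wallis(values_young, values_old) -> tuple[float, float]:
    """Two-sided Kruskal-Wallis comparison of two groups.

    Rank-based H with ties correction; p from the chi-square distribution
    with 1 degree of freedom (two groups).  Identical pooled values give
    H = 0, p = 1.
    """
    a = np.asarray(values_young, dtype=float)
    b = np.asarray(values_old, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if np.ptp(np.concatenate([a, b])) == 0:
        return 0.0, 1.0
    res = stats.kruskal(a, b)
    return float(res.statistic), float(res.pvalue)


def relative_expression(target_values, reference_values) -> np.ndarray:
    """Elementwise target/reference ratio (e.g. normalization to GAPDH).

    Zero reference entries yield NaN (flagged missing) rather than an
    error, since a failed reference reaction should not void the rest.
    """
    t = np.asarray(target_values, dtype=float)
    r = np.asarray(reference_values, dtype=float)
    if t.shape != r.shape:
        raise ValueError("target and reference must have the same shape")
    if (r < 0).any():
        raise ValueError("reference values must be non-negative")
    out = np.full_like(t, np.nan)
    ok = r > 0
    out[ok] = t[ok] / r[ok]
    return out


def plot_volcano(table: pd.DataFrame, path, title: str = "") -> None:
    """Render a volcano plot (beta vs -log10 p) to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"up": "tab:red", "down": "tab:blue", "ns": "0.6"}
    fig, ax = plt.subplots(figsize=(5, 4))
    for cls, grp in table.groupby("class"):
        ax.scatter(grp["beta_age"], grp["neg_log10_p"], s=6, c=colors.get(cls, "k"),
                   label=cls, alpha=0.7)
    ax.set_xlabel("age coefficient")
    ax.set_ylabel("-log10 p")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
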