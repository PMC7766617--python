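"""Multivariate overview and group-difference testing.

Thin wrappers over numpy/scipy/statsmodels: log10 + Pareto scaling with
seeded low-value imputation, SVD-based PCA, Kruskal-Wallis with
Benjamini-Hochberg correction, and heat-map row/column ordering with
class-median behavior labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .feature_io import ValidationError

__all__ = [
    "preprocess",
    "pca_overview",
    "kw_bh",
    "heatmap_order",
    "PcaResult",
    "DEFAULT_ALPHA",
]

DEFAULT_ALPHA = 0.05
LOG_EPSILON = 1.0


def preprocess(matrix: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """log10(x + 1) then Pareto scaling (mean-center, divide by sqrt(sd)).

    Missing cells are imputed from a seeded uniform draw in
    (0, min_positive / 10) before the log transform.  Constant columns map
    to zero columns.
    """
    if (matrix.fillna(0) < 0).any().any():
        raise ValidationError("matrix must be nonnegative")
    x = matrix.astype(float).copy()
    if x.isna().all().any():
        raise ValidationError("all-missing column")
    mask = x.isna()
    if mask.any().any():
        positive = x.values[~np.isnan(x.values) & (x.values > 0)]
        ceiling = positive.min() / 10 if positive.size else 1e-6
        rng = np.random.default_rng(seed)
        x = x.mask(mask, pd.DataFrame(rng.uniform(0, ceiling, size=x.shape),
                                      index=x.index, columns=x.columns))
    logged = np.log10(x + LOG_EPSILON)
    centered = logged - logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=1)
    scale = np.sqrt(sd)
    scale[scale == 0] = 1.0  # constant column -> zero column
    return centered / scale


@dataclass(frozen=True)
class PcaResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray


def pca_overview(scaled: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    """SVD-based PCA of a samples x compounds matrix."""
    if scaled.shape[0] < 3:
        raise ValidationError("PCA needs >= 3 samples")
    x = scaled.values - scaled.values.mean(axis=0)
    if not np.any(x):
        raise ValidationError("rank-0 matrix")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s ** 2 / (x.shape[0] - 1)
    evr = var / np.sum(var)
    k = n_components or min(x.shape)
    comps = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame((u * s)[:, :k], index=scaled.index, columns=comps),
        loadings=pd.DataFrame(vt[:k].T, index=scaled.columns, columns=comps),
        explained_variance_ratio=evr[:k],
    )


def kw_bh(
    matrix: pd.DataFrame,
    classes: pd.Series | list[str],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Kruskal-Wallis per feature column, Benjamini-Hochberg adjusted.

    Returns a DataFrame indexed by feature with columns p, p_adj, significant.
    """
    labels = pd.Series(classes, index=matrix.index)
    groups = labels.unique()
    if len(groups) < 2:
        raise ValidationError("need >= 2 classes")
    if (labels.value_counts() < 2).any():
        raise ValidationError("every class needs >= 2 members")
    pvals = []
    for col in matrix.columns:
        samples = [matrix.loc[labels == g, col].values for g in groups]
        if np.ptp(np.concatenate(samples)) == 0:
            pvals.append(1.0)  # kruskal rejects all-identical input
        else:
            pvals.append(float(sps.kruskal(*samples).pvalue))
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {"p": pvals, "p_adj": p_adj, "significant": reject},
        index=matrix.columns,
    )


def bh_adjust(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (convenience wrapper)."""
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    return list(p_adj)


def _behavior_label(medians: dict[str, float]) -> str:
    """e.g. medians {F: 3, L: 2, B: 1} -> 'F > L > B'; ties use '='."""
    ordered = sorted(medians.items(), key=lambda kv: (-kv[1], kv[0]))
    parts = [ordered[0][0]]
    for (_, prev), (cls, val) in zip(ordered, ordered[1:]):
        parts.append("=" if val == prev else ">")
        parts.append(cls)
    return " ".join(parts)


def heatmap_order(
    matrix: pd.DataFrame,
    classes: pd.Series | list[str],
) -> tuple[list[str], list, dict[str, str]]:
    """Column order (samples grouped by class), row order, and per-row
    behavior labels from the ordering of class median abundances.
    """
    if matrix.empty:
        raise ValidationError("empty significant matrix")
    labels = pd.Series(classes, index=matrix.index)
    col_order = sorted(matrix.index, key=lambda s: (labels[s], s))
    row_labels: dict[str, str] = {}
    for feature in matrix.columns:
        medians = {g: float(matrix.loc[labels == g, feature].median())
                   for g in labels.unique()}
        row_labels[feature] = _behavior_label(medians)
    row_order = sorted(matrix.columns, key=lambda f: (row_labels[f], str(f)))
    return row_order, col_order, row_labels
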