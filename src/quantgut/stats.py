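"""Statistical layer: compositional/absolute PCA, group comparisons, correlations.

* CLR transform of relative abundances (pseudocount = global minimum
  non-zero value, added to zero cells only) for compositional PCA.
* log10 + per-feature standardization (mean 0, SD 1, sample SD) of absolute
  abundances for absolute-profile PCA.
* Kruskal-Wallis omnibus followed by pairwise Wilcoxon-Mann-Whitney tests
  (exact when both groups have n <= 8) with Benjamini-Hochberg FDR
  adjustment across the pairwise family.
* Pearson correlation of paired log10 loads (lumenal vs mucosal).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# transforms


def clr_transform(relative: pd.DataFrame) -> pd.DataFrame:
    """Centered log-ratio transform with the minimum-nonzero pseudocount.

    The pseudocount (the smallest non-zero value anywhere in the table) is
    added to zero cells only; rows are then re-closed before taking
    ln(x) - mean(ln(x)) per row.
    """
    x = relative.to_numpy(dtype=float).copy()
    if np.any(np.nansum(x, axis=1) == 0):
        raise ValueError("CLR transform is undefined for all-zero rows")
    nz = x[x > 0]
    pseudo = nz.min()
    x[x == 0] = pseudo
    x = x / x.sum(axis=1, keepdims=True)
    logx = np.log(x)
    out = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(out, index=relative.index, columns=relative.columns)


def log10_standardize(
    absolute: pd.DataFrame, floor: Optional[float] = None
) -> pd.DataFrame:
    """Per-feature z-scores of log10 abundances (sample SD, ddof=1).

    Zeros (below-LLOD cells) are replaced by `floor` before the log; when no
    floor is given, the smallest non-zero value in the table is used.
    Zero-variance features are dropped with a warning.
    """
    x = absolute.to_numpy(dtype=float).copy()
    if floor is None:
        pos = x[x > 0]
        if pos.size == 0:
            raise ValueError("table has no positive values")
        floor = float(pos.min())
    x[x <= 0] = floor
    logx = np.log10(x)
    sd = logx.std(axis=0, ddof=1)
    keep = sd > 0
    if not np.all(keep):
        dropped = list(absolute.columns[~keep])
        warnings.warn(f"dropping zero-variance feature(s): {dropped[:5]}")
    z = (logx[:, keep] - logx[:, keep].mean(axis=0)) / sd[keep]
    return pd.DataFrame(z, index=absolute.index, columns=absolute.columns[keep])


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaModel:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    preprocessing: str = ""


def run_pca(matrix: pd.DataFrame, n_components: int = 2, preprocessing: str = "") -> PcaModel:
    """PCA with a deterministic sign convention: in each component the
    largest-magnitude loading is made positive."""
    n, p = matrix.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    if n_components > min(n - 1, p):
        raise ValueError("n_components exceeds min(samples - 1, features)")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(matrix.to_numpy(dtype=float))
    load = pca.components_.T  # features x components
    for j in range(load.shape[1]):
        i = np.argmax(np.abs(load[:, j]))
        if load[i, j] < 0:
            load[:, j] *= -1
            scores[:, j] *= -1
    cols = [f"PC{j + 1}" for j in range(n_components)]
    return PcaModel(
        pd.DataFrame(scores, index=matrix.index, columns=cols),
        pd.DataFrame(load, index=matrix.columns, columns=cols),
        pca.explained_variance_ratio_,
        preprocessing,
    )


# ---------------------------------------------------------------------------
# group comparisons


@dataclass
class GroupComparisonResult:
    feature: str
    kw_statistic: float
    kw_p: float
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: group_a, group_b, statistic, p, q


def _mwu_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    method = "exact" if (len(a) <= 8 and len(b) <= 8) else "asymptotic"
    try:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    except ValueError:  # exact method refuses ties
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    values: pd.Series,
    groups: pd.Series,
    pairs: Optional[Sequence[tuple[str, str]]] = None,
    feature: str = "",
) -> GroupComparisonResult:
    """Kruskal-Wallis omnibus + pairwise MWU with BH adjustment.

    `values` and `groups` are aligned per-sample series. The BH family is
    the set of requested pairwise comparisons for this feature.
    """
    groups = groups.reindex(values.index)
    labels = [g for g in pd.unique(groups) if not pd.isna(g)]
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {g: values[groups == g].to_numpy(dtype=float) for g in labels}
    for g, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    pooled = np.concatenate(list(arrays.values()))
    if np.all(pooled == pooled[0]):
        kw_stat, kw_p = 0.0, 1.0
    else:
        kw_stat, kw_p = sps.kruskal(*arrays.values())
    if pairs is None:
        pairs = list(itertools.combinations(labels, 2))
    rows = []
    for ga, gb in pairs:
        a, b = arrays[ga], arrays[gb]
        if np.all(np.concatenate([a, b]) == a[0] if a.size else False):
            stat, p = float(a.size * b.size / 2), 1.0
        else:
            stat, p = _mwu_p(a, b)
        rows.append({"group_a": ga, "group_b": gb, "statistic": stat, "p": p})
    pw = pd.DataFrame(rows)
    if len(pw):
        pw["q"] = multipletests(pw["p"].to_numpy(), method="fdr_bh")[1]
    return GroupComparisonResult(feature, float(kw_stat), float(kw_p), pw)


def compare_feature_table(
    table: pd.DataFrame,
    groups: pd.Series,
    pairs: Optional[Sequence[tuple[str, str]]] = None,
) -> list[GroupComparisonResult]:
    return [
        compare_groups(table[c], groups, pairs, feature=str(c)) for c in table.columns
    ]


# ---------------------------------------------------------------------------
# load correlation


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    scale: str = "log10"


def correlate_loads(
    lumenal: pd.Series, mucosal: pd.Series, scale: str = "log10"
) -> CorrelationResult:
    """Pearson correlation of paired (log10) lumenal vs mucosal loads."""
    paired = pd.concat([lumenal, mucosal], axis=1, join="inner").dropna()
    if len(paired) < 3:
        raise ValueError("need at least 3 paired samples")
    x, y = paired.iloc[:, 0].to_numpy(float), paired.iloc[:, 1].to_numpy(float)
    if scale == "log10":
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("loads must be positive for log10 correlation")
        x, y = np.log10(x), np.log10(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the load series")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), len(paired), scale)
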