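"""Downstream statistics on analyte x sample matrices.

The study design emulated here is three genotype groups (e.g. wild type,
hetero- and homozygous transgenics). The layer provides per-analyte fold
changes and two-sample t tests feeding a volcano selection
(|fold change| > 1.5 and P < 0.05), one-way ANOVA with Sidak-adjusted
pairwise comparisons against a reference group, PCA of samples, and
z-scored matrices with average-linkage hierarchical clustering for heat
maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .simulate import StudyMatrix

__all__ = [
    "fold_change",
    "t_test",
    "volcano_select",
    "sidak_adjust",
    "anova_sidak",
    "PcaResult",
    "pca",
    "heatmap_matrix",
]

FC_THRESHOLD = 1.5
P_THRESHOLD = 0.05


def fold_change(matrix: StudyMatrix, group_a: str, group_b: str) -> pd.Series:
    """Per-analyte ratio of arithmetic group means (b over a).

    A zero denominator yields +inf (flagged downstream), matching the
    convention that a fold change is undefined rather than clipped.
    """
    a = matrix.values[matrix.group_columns(group_a)].mean(axis=1)
    b = matrix.values[matrix.group_columns(group_b)].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = b / a
    return fc.rename("fold_change")


def t_test(
    matrix: StudyMatrix, group_a: str, group_b: str, flavor: str = "welch"
) -> pd.Series:
    """Two-sided two-sample t test per analyte.

    ``flavor='welch'`` (default) does not assume equal variances;
    ``'student'`` pools them. Zero variance in both groups with equal means
    is reported as p = 1.
    """
    if flavor not in ("welch", "student"):
        raise ValueError(f"flavor must be 'welch' or 'student', got {flavor!r}")
    a = matrix.values[matrix.group_columns(group_a)].to_numpy(float)
    b = matrix.values[matrix.group_columns(group_b)].to_numpy(float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need n >= 2 per group")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(a, b, axis=1, equal_var=(flavor == "student"))
    p = np.asarray(res.pvalue, float)
    degenerate = np.isnan(p) & np.isclose(a.mean(axis=1), b.mean(axis=1))
    p[degenerate] = 1.0
    return pd.Series(p, index=matrix.values.index, name="p_value")


def volcano_select(
    matrix: StudyMatrix,
    group_a: str,
    group_b: str,
    fc_threshold: float = FC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    flavor: str = "welch",
) -> pd.DataFrame:
    """Volcano table: differential iff |FC| beyond threshold AND p below it.

    The fold-change gate is symmetric on the log scale (FC > 1.5 or
    FC < 1/1.5, both strict); direction is recorded as up/down in b
    relative to a.
    """
    fc = fold_change(matrix, group_a, group_b)
    p = t_test(matrix, group_a, group_b, flavor=flavor)
    with np.errstate(divide="ignore"):
        log2fc = np.log2(fc)
    up = (fc > fc_threshold) & (p < p_threshold)
    down = (fc < 1.0 / fc_threshold) & (p < p_threshold)
    return pd.DataFrame({
        "fold_change": fc,
        "log2_fc": log2fc,
        "p_value": p,
        "selected": up | down,
        "direction": np.where(up, "up", np.where(down, "down", "")),
    })


def sidak_adjust(p: np.ndarray | float, m: int) -> np.ndarray | float:
    """Sidak correction for m comparisons: p_adj = 1 - (1 - p)^m.

    Monotone in p and bounded in [0, 1].
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1.0 - (1.0 - np.asarray(p, float)) ** m if np.ndim(p) else 1.0 - (1.0 - p) ** m


def anova_sidak(matrix: StudyMatrix, reference_group: str) -> pd.DataFrame:
    """One-way ANOVA per analyte plus Sidak-adjusted pairwise t tests.

    Each non-reference group is compared with ``reference_group`` by a
    Student t test, and the pairwise p-values are Sidak-adjusted for the
    number of comparisons made per analyte (mirroring '... versus reference'
    figure annotations).
    """
    groups = list(dict.fromkeys(matrix.sample_groups))
    if len(groups) < 2:
        raise ValueError("need >= 2 groups for ANOVA")
    if reference_group not in groups:
        raise KeyError(f"unknown reference group {reference_group!r}")
    arrays = {g: matrix.values[matrix.group_columns(g)].to_numpy(float) for g in groups}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_res = sps.f_oneway(*arrays.values(), axis=1)
    out = pd.DataFrame(
        {"F": f_res.statistic, "p_anova": f_res.pvalue}, index=matrix.values.index
    )
    others = [g for g in groups if g != reference_group]
    m = len(others)
    for g in others:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = sps.ttest_ind(
                arrays[g], arrays[reference_group], axis=1, equal_var=True
            ).pvalue
        out[f"p_{g}_vs_{reference_group}"] = p
        out[f"p_adj_{g}_vs_{reference_group}"] = sidak_adjust(p, m)
    return out


@dataclass
class PcaResult:
    scores: pd.DataFrame              # samples x components
    loadings: pd.DataFrame            # analytes x components
    explained_variance_ratio: np.ndarray


def pca(matrix: StudyMatrix, scale: bool = False, n_components: int | None = None) -> PcaResult:
    """PCA of samples via SVD of the centered (optionally unit-scaled) matrix.

    Analytes are variables, samples are observations. Constant analytes are
    dropped with a warning when ``scale`` is on. Sign convention: within
    each component the largest-magnitude loading is positive, which makes
    the decomposition deterministic.
    """
    X = matrix.values.T  # samples x analytes
    if X.isna().any().any():
        raise ValueError("missing values; impute before PCA")
    sd = X.std(axis=0, ddof=1)
    if scale and (sd == 0).any():
        dropped = sd.index[sd == 0].tolist()
        warnings.warn(f"dropping {len(dropped)} constant analyte(s) for scaling")
        X = X.loc[:, sd > 0]
        sd = sd[sd > 0]
    C = X - X.mean(axis=0)
    if scale:
        C = C / sd
    U, S, Vt = np.linalg.svd(C.to_numpy(float), full_matrices=False)
    k = n_components or min(C.shape)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(S.size):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    var = S**2 / (C.shape[0] - 1)
    ratio = var / (C.to_numpy(float) ** 2).sum() * (C.shape[0] - 1)
    comp = [f"PC{j + 1}" for j in range(S.size)]
    return PcaResult(
        scores=pd.DataFrame(U * S, index=X.index, columns=comp),
        loadings=pd.DataFrame(Vt.T, index=C.columns, columns=comp),
        explained_variance_ratio=ratio,
    )


def heatmap_matrix(
    matrix: StudyMatrix, analytes: list[str] | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Z-scored analyte x sample matrix plus a hierarchical row order.

    Each analyte's values are standardized across samples (zero-variance
    rows become all-zero with a warning); rows are ordered by
    average-linkage hierarchical clustering on Euclidean distance, with
    scipy's deterministic leaf ordering (ties broken by input order).
    """
    sub = matrix.values if analytes is None else matrix.values.loc[analytes]
    if sub.empty:
        raise ValueError("empty analyte subset")
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    if (sd == 0).any():
        warnings.warn(f"{int((sd == 0).sum())} zero-variance analyte(s); z-scores set to 0")
    z = sub.sub(mean, axis=0).div(sd.replace(0.0, np.inf), axis=0)
    if len(z) < 2:
        return z, z.index.tolist()
    link = hierarchy.linkage(pdist(z.to_numpy(float)), method="average")
    order = hierarchy.leaves_list(link)
    return z.iloc[order], z.index[order].tolist()
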