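"""Univariate screening, feature-set intersections and PCA overview.

Screening follows the usual omics recipe: per-feature two-sided Welch
t-tests between two phenotype groups, Benjamini-Hochberg adjustment across
the features of that one comparison, significance at adjusted p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .peak_matrix import PeakMatrix
from .preprocess import autoscale

ALPHA_DEFAULT = 0.05


@dataclass
class TestResult:
    feature_id: str
    t_stat: float
    dof: float
    p: float
    p_adj: float
    significant: bool


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Two-sided Welch t-test (unequal variances, Welch-Satterthwaite dof).

    Degenerate case: two constant, equal groups carry no evidence and
    return (0, dof, 1) instead of NaN.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t needs >= 2 observations per group")
    if x.std() == 0 and y.std() == 0:
        if x[0] == y[0]:
            return 0.0, float(x.size + y.size - 2), 1.0
        return math_inf_t(x, y)
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def math_inf_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Two constant but different groups: infinite evidence of a difference."""
    sign = 1.0 if x[0] > y[0] else -1.0
    return sign * float("inf"), float(x.size + y.size - 2), 0.0


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order kept."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_features(
    pm: PeakMatrix,
    group_a: str,
    group_b: str,
    alpha: float = ALPHA_DEFAULT,
) -> tuple[set[str], pd.DataFrame]:
    """Welch t per feature between two phenotype groups, BH across features.

    Returns the significant feature set and the full result table.  Group
    membership is taken from the ``phenotype_label`` of study samples.
    """
    study = pm.samples.loc[pm.study_mask]
    mask_a = (study["phenotype_label"] == group_a).to_numpy()
    mask_b = (study["phenotype_label"] == group_b).to_numpy()
    for name, m in ((group_a, mask_a), (group_b, mask_b)):
        if not m.any():
            raise ValueError(f"group {name!r} has no study samples")
    X = pm.intensities[pm.study_mask]
    rows = []
    for j, fid in enumerate(pm.features["feature_id"]):
        t, dof, p = welch_t(X[mask_a, j], X[mask_b, j])
        rows.append((fid, t, dof, p))
    table = pd.DataFrame(rows, columns=["feature_id", "t_stat", "dof", "p"])
    table["p_adj"] = bh_fdr(table["p"].to_numpy())
    table["significant"] = table["p_adj"] < alpha
    return set(table.loc[table["significant"], "feature_id"]), table


def intersect_counts(sets: dict[str, set]) -> pd.DataFrame:
    """Exclusive intersection sizes (UpSet semantics).

    Every element is counted in exactly one cell: the cell of the full
    combination of sets containing it.  Rows are indexed by the
    '&'-joined sorted member names.
    """
    if len(sets) < 2:
        raise ValueError("intersect_counts needs >= 2 sets")
    names = sorted(sets)
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(*(sets[n] for n in names if n not in combo), set())
            exclusive = inside - outside
            rows.append({"cell": "&".join(combo), "degree": r, "count": len(exclusive)})
    return pd.DataFrame(rows)


def pca(X_scaled: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal components of an autoscaled matrix via SVD.

    Returns (scores, loadings, explained variance %) for the first k
    components; k beyond the matrix rank is truncated.
    """
    X = np.asarray(X_scaled, float)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    k_eff = min(k, rank)
    total_ss = float(np.sum(s**2))
    scores = U[:, :k_eff] * s[:k_eff]
    loadings = Vt[:k_eff].T
    explained = 100.0 * s[:k_eff] ** 2 / total_ss if total_ss > 0 else np.zeros(k_eff)
    return scores, loadings, explained


def pca_overview(pm: PeakMatrix, k: int = 4) -> dict:
    """Autoscale the study-sample submatrix and run PCA, as a first look at
    class structure and batch stability."""
    X = pm.intensities[pm.study_mask]
    scaled, _, _, kept = autoscale(X)
    scores, loadings, explained = pca(scaled, k)
    return {
        "scores": pd.DataFrame(
            scores,
            index=pm.samples.loc[pm.study_mask, "sample_id"].to_numpy(),
            columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
        ),
        "loadings": pd.DataFrame(
            loadings,
            index=pm.features.loc[kept, "feature_id"].to_numpy(),
            columns=[f"PC{i + 1}" for i in range(loadings.shape[1])],
        ),
        "explained_pct": explained,
    }
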