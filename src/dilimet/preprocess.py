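"""Within-batch QC-SVRC drift correction, quality filters and scaling.

The drift corrector fits, per feature and batch, a support-vector
regression (RBF kernel) of pooled-QC intensity on injection order.  The
regularization constant C is fixed at the median QC intensity; the
insensitivity half-width epsilon and the kernel width gamma are chosen on
a grid by leave-one-out cross-validation with RMSECV as the target.
Corrected intensities are the raw values multiplied by C over the fitted
trend, which normalizes every injection to the QC reference level while
keeping intensities positive.

Downstream quality filters follow the usual QC-guideline conventions:
features with robust QC-to-sample dispersion ratio (D-ratio*) above 20 %
after correction are removed, features whose blank signal times 10 exceeds
the study median are treated as contaminants, and features whose
within-group medians never exceed 15000 AU are discarded as too weak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import _libsvm

from .peak_matrix import PeakMatrix

_libsvm.set_verbosity_wrap(0)

#: defaults quoted by the QC-SVRC procedure
EPS_RANGE_DEFAULT = (0.025, 0.08)     # fraction of median QC intensity
GAMMA_RANGE_DEFAULT = (1.0, 1.0e4)
N_EPS_DEFAULT = 8
N_GAMMA_DEFAULT = 13
D_RATIO_MAX_DEFAULT = 20.0            # percent
BLANK_FACTOR_DEFAULT = 10.0
INTENSITY_THRESHOLD_DEFAULT = 15000.0  # AU
TREND_FLOOR_FRACTION = 0.01           # of C, safeguards near-zero trends


@dataclass
class DriftFit:
    """Fitted QC trend for one (feature, batch).

    ``trend`` holds the predicted QC-level intensity at every injection
    order of the batch (aligned with ``orders``).
    """

    feature_id: str
    batch_id: str
    C: float
    epsilon: float
    gamma: float
    rmsecv: float
    orders: np.ndarray
    trend: np.ndarray


@dataclass
class QCMetrics:
    feature_id: str
    rsd_qc: float          # percent
    d_ratio_star: float    # percent


def _order_scale(orders: np.ndarray, all_orders: np.ndarray) -> np.ndarray:
    """Rescale injection order to [0, 1] over the batch range so that the
    kernel width search range is comparable across batch sizes."""
    lo, hi = float(np.min(all_orders)), float(np.max(all_orders))
    if hi == lo:
        return np.zeros_like(orders, dtype=float)
    return (np.asarray(orders, float) - lo) / (hi - lo)


def _svr_fit_predict(
    x_train: np.ndarray, y_train: np.ndarray, x_eval: np.ndarray,
    C: float, eps: float, gamma: float,
) -> np.ndarray:
    """Fit an RBF epsilon-SVR and evaluate it at ``x_eval``.

    Uses the libsvm backend directly (epsilon-SVR, svm_type 3) to avoid
    estimator-construction overhead in the grid search; the decision
    function is the standard kernel expansion over the support vectors.
    """
    out = _libsvm.fit(
        np.ascontiguousarray(x_train[:, None], np.float64),
        np.ascontiguousarray(y_train, np.float64),
        svm_type=3, kernel="rbf", C=C, epsilon=eps, gamma=gamma, tol=1e-4,
    )
    sv, dual_coef, intercept = out[1], out[3], out[4]
    K = np.exp(-gamma * (np.asarray(x_eval, float)[:, None] - sv[:, 0][None, :]) ** 2)
    return K @ dual_coef[0] + intercept[0]


def _loo_rmse(x: np.ndarray, y: np.ndarray, C: float, eps: float, gamma: float) -> float:
    """Leave-one-out RMSE of an RBF-kernel SVR on (x, y)."""
    n = len(y)
    errs = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        m = idx != i
        errs[i] = _svr_fit_predict(x[m], y[m], x[i : i + 1], C, eps, gamma)[0] - y[i]
    return float(np.sqrt(np.mean(errs**2)))


def svrc_grid(C: float,
              eps_range: tuple[float, float] = EPS_RANGE_DEFAULT,
              gamma_range: tuple[float, float] = GAMMA_RANGE_DEFAULT,
              n_eps: int = N_EPS_DEFAULT,
              n_gamma: int = N_GAMMA_DEFAULT) -> tuple[np.ndarray, np.ndarray]:
    """Search grid: epsilon linear over the given fraction of C, gamma
    log-spaced over its range."""
    eps_grid = np.linspace(eps_range[0] * C, eps_range[1] * C, n_eps)
    gamma_grid = np.geomspace(gamma_range[0], gamma_range[1], n_gamma)
    return eps_grid, gamma_grid


def fit_qc_svrc(
    qc_intensities: np.ndarray,
    qc_orders: np.ndarray,
    all_orders: np.ndarray,
    eps_range: tuple[float, float] = EPS_RANGE_DEFAULT,
    gamma_range: tuple[float, float] = GAMMA_RANGE_DEFAULT,
    n_eps: int = N_EPS_DEFAULT,
    n_gamma: int = N_GAMMA_DEFAULT,
    feature_id: str = "",
    batch_id: str = "",
) -> DriftFit:
    """Fit the QC trend for one feature in one batch.

    Ties in RMSECV are broken toward the smallest gamma, then the smallest
    epsilon, preferring the smoother trend.  With fewer than 4 QC points
    the trend is unsupported and an error is raised; with all-equal QC
    intensities the trend is the constant C and no search is run.
    """
    qc_y = np.asarray(qc_intensities, float)
    qc_x = np.asarray(qc_orders, float)
    all_orders = np.asarray(all_orders, float)
    if qc_y.size < 4:
        raise ValueError(
            f"QC-SVRC needs >= 4 QC points, got {qc_y.size} "
            f"(feature {feature_id!r}, batch {batch_id!r})"
        )
    if np.any(qc_y <= 0):
        raise ValueError("QC intensities must be positive")
    C = float(np.median(qc_y))
    if np.all(qc_y == qc_y[0]):
        return DriftFit(feature_id, batch_id, C, 0.0, 0.0, 0.0,
                        all_orders.copy(), np.full(all_orders.shape, C))

    xs = _order_scale(qc_x, all_orders)
    eps_grid, gamma_grid = svrc_grid(C, eps_range, gamma_range, n_eps, n_gamma)
    best = (math.inf, None, None)
    for gamma in gamma_grid:          # ascending: ties keep smallest gamma
        for eps in eps_grid:          # ascending: then smallest epsilon
            rmse = _loo_rmse(xs, qc_y, C, eps, gamma)
            if best[1] is None or rmse < best[0] * (1.0 - 1e-12):
                best = (rmse, eps, gamma)
    rmsecv, eps, gamma = best
    trend = _svr_fit_predict(xs, qc_y, _order_scale(all_orders, all_orders), C, eps, gamma)
    return DriftFit(feature_id, batch_id, C, float(eps), float(gamma),
                    float(rmsecv), all_orders.copy(), trend)


def fit_drift_models(pm: PeakMatrix, **grid_kwargs) -> list[DriftFit]:
    """Fit one QC trend per (feature, batch) across the whole matrix."""
    fits: list[DriftFit] = []
    for batch, grp in pm.samples.groupby("batch_id", sort=True):
        rows = grp.index.to_numpy()
        qc_rows = rows[(pm.samples.loc[rows, "role"] == "qc").to_numpy()]
        all_orders = pm.samples.loc[rows, "injection_order"].to_numpy(float)
        qc_orders = pm.samples.loc[qc_rows, "injection_order"].to_numpy(float)
        for j, fid in enumerate(pm.features["feature_id"]):
            fits.append(
                fit_qc_svrc(pm.intensities[qc_rows, j], qc_orders, all_orders,
                            feature_id=fid, batch_id=str(batch), **grid_kwargs)
            )
    return fits


def apply_drift_correction(
    pm: PeakMatrix,
    fits: list[DriftFit],
    floor_fraction: float = TREND_FLOOR_FRACTION,
) -> PeakMatrix:
    """Multiply every intensity by C over the fitted trend, per batch.

    Trend values at or below ``floor_fraction * C`` are floored there and a
    warning is recorded in the provenance log.
    """
    out = pm.copy()
    by_key = {(f.feature_id, f.batch_id): f for f in fits}
    col_of = {fid: j for j, fid in enumerate(pm.features["feature_id"])}
    n_floored = 0
    for batch, grp in out.samples.groupby("batch_id", sort=True):
        rows = grp.index.to_numpy()
        orders = out.samples.loc[rows, "injection_order"].to_numpy(float)
        for fid, j in col_of.items():
            fit = by_key.get((fid, str(batch)))
            if fit is None:
                raise ValueError(f"no drift fit for feature {fid!r} in batch {batch!r}")
            pos = {o: k for k, o in enumerate(fit.orders)}
            trend = np.array([fit.trend[pos[o]] for o in orders])
            floor = floor_fraction * fit.C
            low = trend <= floor
            if low.any():
                n_floored += int(low.sum())
                trend = np.where(low, floor, trend)
            out.intensities[rows, j] *= fit.C / trend
    out.log(
        "apply_drift_correction: QC-SVRC multiplicative correction applied"
        + (f" ({n_floored} trend values floored)" if n_floored else "")
    )
    return out


def correct_drift(pm: PeakMatrix, **grid_kwargs) -> tuple[PeakMatrix, list[DriftFit]]:
    """Convenience: fit and apply QC-SVRC in one call."""
    fits = fit_drift_models(pm, **grid_kwargs)
    return apply_drift_correction(pm, fits), fits


# ---------------------------------------------------------------------- #
# dispersion metrics and filters
# ---------------------------------------------------------------------- #
def robust_sd(values: np.ndarray) -> float:
    """1.4826 x median absolute deviation (consistent for a Gaussian)."""
    v = np.asarray(values, float)
    return float(1.4826 * np.median(np.abs(v - np.median(v))))


def d_ratio_star(qc_values: np.ndarray, study_values: np.ndarray) -> float:
    """Robust QC-to-sample dispersion ratio, in percent.

    Returns +inf when the study samples have zero robust dispersion (the
    feature carries no biological variation and is removed upstream).
    """
    qc_values = np.asarray(qc_values, float)
    study_values = np.asarray(study_values, float)
    if qc_values.size < 2 or study_values.size < 2:
        raise ValueError("d_ratio_star needs >= 2 values per vector")
    s_qc = robust_sd(qc_values)
    s_study = robust_sd(study_values)
    if s_study == 0:
        return math.inf if s_qc > 0 else 0.0
    return 100.0 * s_qc / s_study


def qc_metrics(pm: PeakMatrix) -> pd.DataFrame:
    """Per-feature QC RSD (%) and D-ratio* (%) over the whole matrix.

    QC pools are batch-specific (each pool averages the samples of its own
    batch), so QC values are centered per batch (to the pooled grand level)
    before dispersion is measured; otherwise pool-composition differences
    would masquerade as technical variance.
    """
    qc_mask = pm.qc_mask
    study = pm.intensities[pm.study_mask]
    qc = pm.intensities[qc_mask].copy()
    batches = pm.samples.loc[qc_mask, "batch_id"].to_numpy()
    grand = qc.mean(axis=0)
    for b in np.unique(batches):
        sel = batches == b
        qc[sel] += grand - qc[sel].mean(axis=0)
    rows = []
    for j, fid in enumerate(pm.features["feature_id"]):
        mean = grand[j]
        rsd = 100.0 * qc[:, j].std(ddof=1) / mean if mean > 0 else math.inf
        rows.append(QCMetrics(fid, float(rsd), d_ratio_star(qc[:, j], study[:, j])))
    return pd.DataFrame([r.__dict__ for r in rows])


def d_ratio_filter(
    pm: PeakMatrix, max_d_ratio: float = D_RATIO_MAX_DEFAULT
) -> tuple[PeakMatrix, list[str]]:
    """Remove features whose D-ratio* exceeds the threshold (strict >)."""
    metrics = qc_metrics(pm)
    bad = (metrics["d_ratio_star"] > max_d_ratio).to_numpy()
    removed = list(metrics.loc[bad, "feature_id"])
    out = pm.subset(feature_mask=~bad)
    out.log(f"d_ratio_filter: removed {len(removed)} features with D-ratio* > {max_d_ratio}%")
    return out, removed


def between_batch_scale(pm: PeakMatrix, bridge_ids: set[str] | None = None) -> PeakMatrix:
    """Scale each batch so bridge-sample medians agree across batches.

    Per feature and batch b, the scaling factor is the median bridge
    intensity in b divided by the median bridge intensity pooled across
    batches; all intensities in b are divided by it.  Afterwards bridge
    duplicates are dropped from every batch but the last (by batch_id sort
    order), mirroring the exclusion of replicated samples from batch 1.
    Features with a zero pooled bridge median are flagged and excluded.
    """
    out = pm.copy()
    if bridge_ids is None:
        bridge_ids = set(out.samples.loc[out.samples["role"] == "bridge", "sample_id"])
    bridge_mask = out.samples["sample_id"].isin(bridge_ids).to_numpy()
    batches = sorted(out.samples["batch_id"].unique())
    if len(batches) < 2:
        out.log("between_batch_scale: single batch, no scaling applied")
        return out
    n_bridge_per_batch = {
        b: int((bridge_mask & (out.samples["batch_id"] == b).to_numpy()).sum()) for b in batches
    }
    if min(n_bridge_per_batch.values()) < 3:
        raise ValueError(
            f"between_batch_scale needs >= 3 bridge samples per batch, got {n_bridge_per_batch}"
        )

    pooled = np.median(out.intensities[bridge_mask], axis=0)
    dead = pooled == 0
    for b in batches:
        in_batch = (out.samples["batch_id"] == b).to_numpy()
        med_b = np.median(out.intensities[bridge_mask & in_batch], axis=0)
        factor = np.where(dead, 1.0, med_b / np.where(pooled == 0, 1.0, pooled))
        factor = np.where(factor == 0, 1.0, factor)
        out.intensities[in_batch] /= factor[None, :]

    keep_batch = batches[-1]
    drop = bridge_mask & (out.samples["batch_id"] != keep_batch).to_numpy()
    out = out.subset(sample_mask=~drop, feature_mask=~dead)
    out.log(
        f"between_batch_scale: scaled {len(batches)} batches on {int(bridge_mask.sum())} "
        f"bridge injections; dropped {int(drop.sum())} duplicates"
        + (f"; excluded {int(dead.sum())} zero-median features" if dead.any() else "")
    )
    return out


def blank_filter(
    pm: PeakMatrix, blank_factor: float = BLANK_FACTOR_DEFAULT
) -> tuple[PeakMatrix, list[str]]:
    """Remove features whose max blank signal x factor exceeds the study median."""
    if not pm.blank_mask.any():
        out = pm.copy()
        out.log("blank_filter: no blank injections present, filter skipped")
        return out, []
    blank_max = pm.intensities[pm.blank_mask].max(axis=0)
    study_median = np.median(pm.intensities[pm.study_mask], axis=0)
    bad = blank_factor * blank_max > study_median
    removed = list(pm.features.loc[bad, "feature_id"])
    out = pm.subset(feature_mask=~bad)
    out.log(
        f"blank_filter: removed {len(removed)} features with "
        f"{blank_factor:g} x max(blank) > median(study)"
    )
    return out, removed


def group_intensity_filter(
    pm: PeakMatrix,
    groups: pd.Series | dict[str, str] | None = None,
    threshold: float = INTENSITY_THRESHOLD_DEFAULT,
) -> PeakMatrix:
    """Keep features whose median intensity in at least one phenotype group
    strictly exceeds the threshold (default 15000 AU).

    ``groups`` maps study sample_id to group label; by default the
    ``phenotype_label`` column of the sample metadata is used.  Empty
    groups are ignored with a provenance note.
    """
    study = pm.samples.loc[pm.study_mask]
    if groups is None:
        labels = study["phenotype_label"]
    elif isinstance(groups, dict):
        labels = study["sample_id"].map(groups)
    else:
        labels = study["sample_id"].map(dict(zip(groups.index, groups.values)))
    if labels.isna().any():
        missing = study.loc[labels.isna(), "sample_id"].tolist()
        raise ValueError(f"study samples without a group label: {missing[:5]}")

    X = pm.intensities[pm.study_mask]
    best = np.full(pm.n_features, -math.inf)
    for g in labels.unique():
        sel = (labels == g).to_numpy()
        if not sel.any():
            continue
        best = np.maximum(best, np.median(X[sel], axis=0))
    keep = best > threshold
    out = pm.subset(feature_mask=keep)
    out.log(
        f"group_intensity_filter: kept {int(keep.sum())}/{pm.n_features} features "
        f"with a group median > {threshold:g} AU"
    )
    return out


def autoscale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise autoscaling to mean 0 and unit sample standard deviation.

    Returns ``(scaled, centers, scales, kept)`` where ``kept`` is the
    boolean mask of retained (non-constant) columns; constant columns are
    dropped from the scaled matrix.
    """
    X = np.asarray(X, float)
    if X.shape[0] < 2:
        raise ValueError("autoscale needs >= 2 samples")
    centers = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    kept = scales > 0
    scaled = (X[:, kept] - centers[kept]) / scales[kept]
    return scaled, centers, scales, kept
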