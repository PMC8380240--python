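"""PLS-DA engine and the one-vs-rest phenotype model.

Partial least squares discriminant analysis relates the autoscaled feature
matrix X to a class-coded response y (1 for members of the class, 0 for
the rest) through a small number of latent variables (LVs) extracted by
NIPALS.  Out-of-sample error is estimated by subjectwise double
cross-validation (2CV): an outer loop holds out whole patients for
testing while an inner loop, run only on the remaining patients, selects
the LV count by cross-validated classification accuracy.  Discrimination
is summarised by the AUROC (Mann-Whitney formulation) and its
significance by patient-level permutation testing.

The user-facing entry point is :class:`OneVsRestPLSDA`, a statsmodels-style
model object built from a filtered peak matrix; its :meth:`~OneVsRestPLSDA.fit`
returns a :class:`OneVsRestResults` carrying the per-class 2CV predictions,
AUROCs, permutation p-values, VIP scores and the combined two-LV PLS2
overview model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .peak_matrix import PeakMatrix
from .preprocess import autoscale

DEFAULT_CLASSES = ("cholestatic", "hepatocellular", "recovered")
NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 500


class ConvergenceError(RuntimeError):
    """NIPALS failed to converge for a latent variable."""


# ---------------------------------------------------------------------- #
# core PLS
# ---------------------------------------------------------------------- #
@dataclass
class PLSModel:
    """Fitted NIPALS PLS model (PLS1 for one response column, PLS2 otherwise).

    Weights ``W`` and loadings ``P`` live in the autoscaled X space;
    ``x_center``/``x_scale``/``y_center`` hold the training scaling so the
    model can be applied to new raw data.
    """

    n_lv: int
    W: np.ndarray            # features x LV, unit-norm columns
    P: np.ndarray            # features x LV
    Q: np.ndarray            # LV x y-columns
    T: np.ndarray            # samples x LV (training scores)
    x_center: np.ndarray
    x_scale: np.ndarray
    kept: np.ndarray         # mask of non-constant training features
    y_center: np.ndarray
    y_coding: tuple[float, float] = (0.0, 1.0)
    class_names: tuple[str, ...] = ()

    @property
    def decision_threshold(self) -> float:
        return 0.5 * (self.y_coding[0] + self.y_coding[1])

    def coef(self, n_lv: int | None = None) -> np.ndarray:
        """Regression vector(s) B = W (P'W)^-1 Q' using the first n_lv LVs."""
        a = self.n_lv if n_lv is None else n_lv
        if not 1 <= a <= self.n_lv:
            raise ValueError(f"n_lv must lie in [1, {self.n_lv}]")
        W, P, Q = self.W[:, :a], self.P[:, :a], self.Q[:a]
        return W @ np.linalg.solve(P.T @ W, Q)


def fit_pls(
    X: np.ndarray,
    Y: np.ndarray,
    n_lv: int,
    scale: bool = True,
    class_names: tuple[str, ...] = (),
) -> PLSModel:
    """Fit a PLS model by NIPALS with per-component deflation of X.

    ``X`` and ``Y`` are raw; autoscaling of X (and centering of Y) is done
    here and stored on the model.  ``n_lv`` is capped at
    ``min(n_samples - 1, n_features)``; rank exhaustion truncates further.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if scale:
        Xs, centers, scales, kept = autoscale(X)
    else:
        Xs, centers, scales = X.copy(), np.zeros(p), np.ones(p)
        kept = np.ones(p, bool)
    y_center = Y.mean(axis=0)
    F = Y - y_center
    E = Xs
    a_max = min(n_lv, n - 1, int(kept.sum()))

    W_cols, P_cols, Q_rows, T_cols = [], [], [], []
    for _ in range(a_max):
        u = F[:, int(np.argmax(F.var(axis=0)))]
        if np.allclose(u, 0):
            break
        t_old = np.zeros(n)
        for _it in range(NIPALS_MAX_ITER):
            w = E.T @ u
            nw = np.linalg.norm(w)
            if nw < 1e-13:
                break
            w /= nw
            t = E @ w
            tt = t @ t
            if tt < 1e-13:
                break
            q = F.T @ t / tt
            qq = q @ q
            if qq < 1e-13:
                break
            u = F @ q / qq
            if np.linalg.norm(t - t_old) <= NIPALS_TOL * max(np.linalg.norm(t), 1.0):
                break
            t_old = t
        else:
            raise ConvergenceError(
                f"NIPALS did not converge within {NIPALS_MAX_ITER} iterations"
            )
        if nw < 1e-13 or tt < 1e-13 or qq < 1e-13:
            break
        pload = E.T @ t / tt
        E = E - np.outer(t, pload)
        F = F - np.outer(t, q)
        W_cols.append(w)
        P_cols.append(pload)
        Q_rows.append(q)
        T_cols.append(t)
    if not W_cols:
        raise ValueError("no latent variable could be extracted (degenerate input)")
    return PLSModel(
        n_lv=len(W_cols),
        W=np.column_stack(W_cols),
        P=np.column_stack(P_cols),
        Q=np.vstack(Q_rows),
        T=np.column_stack(T_cols),
        x_center=centers,
        x_scale=scales,
        kept=kept,
        y_center=y_center,
        class_names=class_names,
    )


def predict(model: PLSModel, X_new: np.ndarray, n_lv: int | None = None) -> np.ndarray:
    """Continuous (unthresholded) predicted y for new raw samples."""
    X_new = np.asarray(X_new, float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.x_center.size:
        raise ValueError(
            f"feature count mismatch: model expects {model.x_center.size}, "
            f"got {X_new.shape[1]}"
        )
    kept = model.kept
    Xs = (X_new[:, kept] - model.x_center[kept]) / model.x_scale[kept]
    out = Xs @ model.coef(n_lv) + model.y_center
    return out[:, 0] if out.shape[1] == 1 else out


def vip(model: PLSModel) -> np.ndarray:
    """Variable importance in projection over the model's features.

    vip_f = sqrt(p * sum_a SSY_a (w_fa / ||w_a||)^2 / sum_a SSY_a), with
    SSY_a the y-variance explained by LV a; mean(vip^2) = 1 identically.
    Features dropped as constant during autoscaling receive VIP 0.
    """
    ssy = np.einsum("ij,ij->i", model.Q, model.Q) * np.einsum(
        "ia,ia->a", model.T, model.T
    ).ravel()
    p_eff = model.W.shape[0]
    w2 = model.W**2  # columns already unit-norm
    scores = np.sqrt(p_eff * (w2 @ ssy) / ssy.sum())
    full = np.zeros(model.kept.size)
    full[model.kept] = scores
    return full


def auroc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Probability that a random positive outscores a random negative,
    ties counted one half (Mann-Whitney formulation)."""
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, float)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auroc needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# ---------------------------------------------------------------------- #
# subjectwise cross-validation
# ---------------------------------------------------------------------- #
@dataclass
class CVScheme:
    """Subjectwise fold assignment: all samples of a patient share a fold."""

    fold_of_sample: np.ndarray
    fold_of_patient: dict[str, int]
    k: int
    seed: int


def subjectwise_folds(
    patient_ids: np.ndarray,
    labels: np.ndarray,
    k: int,
    seed: int,
    max_redraws: int = 100,
) -> CVScheme:
    """Randomize patients (not samples) to k folds, stratified on the
    patient-level majority label; re-draw (up to ``max_redraws``) until
    every training split contains every class."""
    patient_ids = np.asarray(patient_ids)
    labels = np.asarray(labels)
    patients = pd.Series(labels).groupby(pd.Series(patient_ids)).agg(
        lambda s: s.value_counts().idxmax()
    )
    if k > len(patients):
        raise ValueError(f"k={k} exceeds the {len(patients)} distinct patients")
    classes = np.unique(labels)
    rng = np.random.default_rng(seed)
    for _ in range(max_redraws):
        fold_of_patient: dict[str, int] = {}
        start = int(rng.integers(k))
        i = start
        for lab in sorted(pd.unique(patients.values)):
            members = list(patients.index[patients.values == lab])
            rng.shuffle(members)
            for pid in members:
                fold_of_patient[pid] = i % k
                i += 1
        fold_of_sample = np.array([fold_of_patient[pid] for pid in patient_ids])
        ok = all(
            set(classes) <= set(labels[fold_of_sample != f]) for f in range(k)
        ) and all((fold_of_sample == f).any() for f in range(k))
        if ok:
            return CVScheme(fold_of_sample, fold_of_patient, k, seed)
    raise RuntimeError(
        f"could not build {k} subjectwise folds with all classes in every "
        f"training split after {max_redraws} draws"
    )


def select_n_lv(
    X: np.ndarray,
    y: np.ndarray,
    patient_ids: np.ndarray,
    k_inner: int = 5,
    seed: int = 0,
    max_lv: int = 10,
) -> int:
    """LV count maximizing subjectwise CV classification accuracy.

    Predictions are thresholded at the midpoint of the y coding (0.5 for
    0/1).  Ties break toward the fewest LVs.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    scheme = subjectwise_folds(patient_ids, y, k_inner, seed)
    a_cap = max_lv
    hits = np.zeros(max_lv)
    counted = np.zeros(max_lv)
    for f in range(scheme.k):
        test = scheme.fold_of_sample == f
        train = ~test
        model = fit_pls(X[train], y[train], max_lv)
        a_fold = model.n_lv
        a_cap = min(a_cap, a_fold)
        for a in range(1, a_fold + 1):
            y_hat = predict(model, X[test], n_lv=a)
            hits[a - 1] += int(((y_hat >= model.decision_threshold) == (y[test] >= 0.5)).sum())
            counted[a - 1] += test.sum()
    acc = np.where(counted[:a_cap] > 0, hits[:a_cap] / counted[:a_cap], -1.0)
    return int(np.argmax(acc)) + 1  # argmax takes the first (fewest-LV) maximum


def double_cv(
    X: np.ndarray,
    y: np.ndarray,
    patient_ids: np.ndarray,
    k_outer: int = 7,
    k_inner: int = 5,
    seed: int = 0,
    max_lv: int = 10,
) -> tuple[np.ndarray, dict]:
    """Subjectwise double cross-validation.

    The outer loop holds out whole-patient test folds; the inner loop,
    run only on the remaining patients, selects the LV count; a model with
    that count, fitted on all non-test data (autoscaling refit inside the
    split), predicts the test fold.  Every sample receives exactly one
    out-of-sample prediction.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    patient_ids = np.asarray(patient_ids)
    outer = subjectwise_folds(patient_ids, y, k_outer, seed)
    y_hat = np.full(y.size, np.nan)
    chosen: list[int] = []
    for f in range(k_outer):
        test = outer.fold_of_sample == f
        train = ~test
        # leakage guard: the tested patients must be absent from training
        assert not set(patient_ids[test]) & set(patient_ids[train])
        a = select_n_lv(X[train], y[train], patient_ids[train],
                        k_inner=k_inner, seed=seed + 1000 + f, max_lv=max_lv)
        model = fit_pls(X[train], y[train], a)
        y_hat[test] = predict(model, X[test])
        chosen.append(model.n_lv)
    assert not np.isnan(y_hat).any(), "2CV coverage incomplete"
    return y_hat, {"n_lv_per_fold": chosen, "outer_scheme": outer}


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    patient_ids: np.ndarray,
    n_perm: int = 100,
    seed: int = 0,
    k_outer: int = 7,
    k_inner: int = 5,
    max_lv: int = 10,
    observed_auroc: float | None = None,
) -> tuple[float, float, np.ndarray]:
    """Permutation p-value of the 2CV AUROC.

    Class labels are permuted at the patient level (preserving the
    repeated-measures structure) and the full 2CV pipeline is re-run per
    permutation; p = (1 + #{perm AUROC >= observed}) / (n_perm + 1).
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    patient_ids = np.asarray(patient_ids)
    if observed_auroc is None:
        y_hat, _ = double_cv(X, y, patient_ids, k_outer, k_inner, seed, max_lv)
        observed_auroc = auroc(y >= 0.5, y_hat)
    patients = pd.Series(y).groupby(pd.Series(patient_ids)).agg("mean") >= 0.5
    pids = np.array(patients.index)
    plabels = patients.to_numpy()
    rng = np.random.default_rng(seed)
    perm_aurocs = np.empty(n_perm)
    for b in range(n_perm):
        perm = dict(zip(pids, rng.permutation(plabels)))
        y_perm = np.array([1.0 if perm[pid] else 0.0 for pid in patient_ids])
        y_hat, _ = double_cv(X, y_perm, patient_ids, k_outer, k_inner,
                             seed=seed + 7919 * (b + 1), max_lv=max_lv)
        perm_aurocs[b] = auroc(y_perm >= 0.5, y_hat)
    p = (1.0 + float((perm_aurocs >= observed_auroc - 1e-12).sum())) / (n_perm + 1.0)
    return p, observed_auroc, perm_aurocs


# ---------------------------------------------------------------------- #
# one-vs-rest phenotype model (Model / Results pair)
# ---------------------------------------------------------------------- #
class OneVsRestPLSDA:
    """One-vs-rest PLS-DA suite over the three modelling phenotypes.

    The model is built from a filtered peak matrix (or raw arrays): the
    three classes in ``classes`` are the training phenotypes; samples with
    any other label (the mixed cohort) are held aside and only ever
    predicted, never trained on.

    Examples
    --------
    >>> model = OneVsRestPLSDA.from_peak_matrix(pm)      # doctest: +SKIP
    >>> res = model.fit(seed=1, n_perm=100)              # doctest: +SKIP
    >>> print(res.summary())                             # doctest: +SKIP
    """

    def __init__(
        self,
        X: np.ndarray,
        labels: np.ndarray,
        patient_ids: np.ndarray,
        sample_ids: np.ndarray | None = None,
        feature_ids: np.ndarray | None = None,
        classes: tuple[str, ...] = DEFAULT_CLASSES,
    ) -> None:
        self.X = np.asarray(X, float)
        self.labels = np.asarray(labels)
        self.patient_ids = np.asarray(patient_ids)
        n = self.X.shape[0]
        self.sample_ids = (
            np.array([f"S{i:03d}" for i in range(n)]) if sample_ids is None else np.asarray(sample_ids)
        )
        self.feature_ids = (
            np.array([f"F{j:04d}" for j in range(self.X.shape[1])])
            if feature_ids is None
            else np.asarray(feature_ids)
        )
        self.classes = tuple(classes)
        present = set(self.labels)
        missing = [c for c in self.classes if c not in present]
        if missing:
            raise ValueError(f"training classes absent from the data: {missing}")
        self.train_mask = np.isin(self.labels, self.classes)

    @classmethod
    def from_peak_matrix(
        cls, pm: PeakMatrix, classes: tuple[str, ...] = DEFAULT_CLASSES
    ) -> "OneVsRestPLSDA":
        study = pm.study_mask
        return cls(
            pm.intensities[study],
            pm.samples.loc[study, "phenotype_label"].to_numpy(),
            pm.samples.loc[study, "patient_id"].to_numpy(),
            sample_ids=pm.samples.loc[study, "sample_id"].to_numpy(),
            feature_ids=pm.features["feature_id"].to_numpy(),
            classes=classes,
        )

    def fit(
        self,
        k_outer: int = 7,
        k_inner: int = 5,
        n_perm: int = 100,
        seed: int = 0,
        max_lv: int = 10,
        vip_threshold: float = 1.0,
    ) -> "OneVsRestResults":
        """Run the full suite: per-class 2CV, AUROC, permutation test, VIP
        selection, held-aside (mixed) prediction and the combined PLS2 model.

        Set ``n_perm=0`` to skip permutation testing.
        """
        from .stats import intersect_counts  # deferred: avoids cycle at import

        tm = self.train_mask
        X_tr = self.X[tm]
        pids_tr = self.patient_ids[tm]
        held = ~tm

        per_class: dict[str, dict] = {}
        vip_table = pd.DataFrame(index=self.feature_ids)
        pred = pd.DataFrame(
            index=self.sample_ids,
            data={
                "patient_id": self.patient_ids,
                "label": self.labels,
                "prediction_source": np.where(tm, "2cv", "model"),
            },
        )
        for ci, cls_name in enumerate(self.classes):
            y = (self.labels[tm] == cls_name).astype(float)
            sub_seed = seed + 101 * (ci + 1)
            y_hat_cv, info = double_cv(
                X_tr, y, pids_tr, k_outer, k_inner, sub_seed, max_lv
            )
            a_full = select_n_lv(X_tr, y, pids_tr, k_inner, sub_seed + 13, max_lv)
            full_model = fit_pls(X_tr, y, a_full, class_names=(cls_name, "rest"))
            col = np.full(self.X.shape[0], np.nan)
            col[tm] = y_hat_cv
            if held.any():
                col[held] = predict(full_model, self.X[held])
            pred[f"y_{cls_name}"] = col
            cls_auroc = auroc(y >= 0.5, y_hat_cv)
            if n_perm:
                p_val, _, perm_dist = permutation_test(
                    X_tr, y, pids_tr, n_perm, sub_seed + 29,
                    k_outer, k_inner, max_lv, observed_auroc=cls_auroc,
                )
            else:
                p_val, perm_dist = float("nan"), np.empty(0)
            vip_table[cls_name] = vip(full_model)
            per_class[cls_name] = {
                "auroc": cls_auroc,
                "permutation_p": p_val,
                "perm_aurocs": perm_dist,
                "n_lv": full_model.n_lv,
                "n_lv_per_fold": info["n_lv_per_fold"],
                "model": full_model,
            }

        vip_sets = {
            c: set(vip_table.index[vip_table[c] > vip_threshold]) for c in self.classes
        }
        vip_cells = intersect_counts(vip_sets)
        union = sorted(set.union(*vip_sets.values()))
        col_of = {fid: j for j, fid in enumerate(self.feature_ids)}
        union_idx = np.array([col_of[f] for f in union], int)
        Y2 = np.column_stack(
            [(self.labels[tm] == c).astype(float) for c in self.classes]
        )
        pls2 = (
            fit_pls(X_tr[:, union_idx], Y2, 2, class_names=self.classes)
            if union_idx.size >= 2
            else None
        )
        return OneVsRestResults(
            model=self,
            predictions=pred,
            per_class=per_class,
            vip_scores=vip_table,
            vip_sets=vip_sets,
            vip_intersections=vip_cells,
            pls2_model=pls2,
            pls2_features=union,
            settings={
                "k_outer": k_outer, "k_inner": k_inner, "n_perm": n_perm,
                "seed": seed, "max_lv": max_lv, "vip_threshold": vip_threshold,
            },
        )


@dataclass
class OneVsRestResults:
    """Results of the one-vs-rest suite.

    ``predictions`` has one row per sample with the three continuous
    predicted y values (2CV out-of-sample for training-class samples,
    plain model predictions for held-aside samples) stored unconstrained;
    mapping onto the phenotype simplex lives in the ternary module.
    """

    model: OneVsRestPLSDA
    predictions: pd.DataFrame
    per_class: dict[str, dict]
    vip_scores: pd.DataFrame
    vip_sets: dict[str, set]
    vip_intersections: pd.DataFrame
    pls2_model: PLSModel | None
    pls2_features: list[str]
    settings: dict = field(default_factory=dict)

    @property
    def aurocs(self) -> dict[str, float]:
        return {c: d["auroc"] for c, d in self.per_class.items()}

    @property
    def permutation_p(self) -> dict[str, float]:
        return {c: d["permutation_p"] for c, d in self.per_class.items()}

    def predict_new(self, X_new: np.ndarray, feature_ids: np.ndarray) -> pd.DataFrame:
        """Predict the three class responses for new raw samples.

        Columns of ``X_new`` are matched to the model's features by
        ``feature_ids``; every model feature must be present.
        """
        col = {f: j for j, f in enumerate(np.asarray(feature_ids))}
        missing = [f for f in self.model.feature_ids if f not in col]
        if missing:
            raise ValueError(f"new data lacks model features, e.g. {missing[:5]}")
        Xa = np.asarray(X_new, float)[:, [col[f] for f in self.model.feature_ids]]
        return pd.DataFrame(
            {f"y_{c}": predict(d["model"], Xa) for c, d in self.per_class.items()}
        )

    def to_ternary(self) -> pd.DataFrame:
        """Constrained simplex coordinates and recovery distances per sample."""
        from .ternary import ternary_table

        return ternary_table(self.predictions)

    def plot_ternary(self, path: str | None = None, trajectories: bool = False):
        from .ternary import plot_simplex

        coords = self.to_ternary()
        meta = self.predictions[["patient_id", "label"]]
        return plot_simplex(coords.join(meta), path=path, trajectories=trajectories)

    def summary(self) -> str:
        lines = [
            "One-vs-rest PLS-DA phenotype model (subjectwise 2CV)",
            "=" * 64,
            f"{'class':<16}{'AUROC':>8}{'perm p':>10}{'LVs':>6}{'VIP>1':>8}",
            "-" * 64,
        ]
        thr = self.settings.get("vip_threshold", 1.0)
        for c in self.model.classes:
            d = self.per_class[c]
            lines.append(
                f"{c + ' vs rest':<16}{d['auroc']:>8.3f}"
                f"{d['permutation_p']:>10.4g}{d['n_lv']:>6d}"
                f"{len(self.vip_sets[c]):>8d}"
            )
        lines.append("-" * 64)
        n_tr = int(self.model.train_mask.sum())
        n_held = int((~self.model.train_mask).sum())
        lines.append(
            f"training samples: {n_tr}  held-aside (mixed): {n_held}  "
            f"features: {self.model.X.shape[1]}"
        )
        lines.append(
            f"combined PLS2 model: {len(self.pls2_features)} features "
            f"(union of VIP > {thr:g}), "
            + (f"{self.pls2_model.n_lv} LVs" if self.pls2_model else "not fitted")
        )
        s = self.settings
        lines.append(
            f"2CV: k_outer={s.get('k_outer')} k_inner={s.get('k_inner')} "
            f"n_perm={s.get('n_perm')} seed={s.get('seed')}"
        )
        return "\n".join(lines)


def one_vs_rest_suite(
    pm: PeakMatrix,
    classes: tuple[str, ...] = DEFAULT_CLASSES,
    **fit_kwargs,
) -> OneVsRestResults:
    """Functional wrapper: build the model from a peak matrix and fit it."""
    return OneVsRestPLSDA.from_peak_matrix(pm, classes=classes).fit(**fit_kwargs)
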