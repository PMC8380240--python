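"""NIPALS PLS, VIP, AUROC, subjectwise CV, 2CV and the one-vs-rest suite."""

import numpy as np
import pandas as pd
import pytest

from dilimet.plsda import (
    OneVsRestPLSDA,
    auroc,
    double_cv,
    fit_pls,
    permutation_test,
    predict,
    select_n_lv,
    subjectwise_folds,
    vip,
)


# ------------------------------------------------------------------ #
# NIPALS core
# ------------------------------------------------------------------ #
def test_exact_linear_single_feature():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(20)
    X = np.column_stack([x, rng.standard_normal(20)])
    y = 3.0 * x + 1.0
    model = fit_pls(X, y, 2)
    fitted = predict(model, X)
    assert np.corrcoef(fitted, y)[0, 1] ** 2 == pytest.approx(1.0, abs=1e-10)


def test_full_rank_pls_equals_ols():
    """With as many LVs as the X rank, PLS predictions reproduce ordinary
    least squares on the same autoscaled data."""
    rng = np.random.default_rng(1)
    X = rng.standard_normal((15, 4))
    y = rng.standard_normal(15)
    model = fit_pls(X, y, 4)
    assert model.n_lv == 4
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    beta, *_ = np.linalg.lstsq(Xs, y - y.mean(), rcond=None)
    np.testing.assert_allclose(predict(model, X), Xs @ beta + y.mean(), atol=1e-8)


def test_scores_orthogonality_and_row_equivariance():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((30, 10))
    y = rng.standard_normal(30)
    model = fit_pls(X, y, 5)
    gram = model.T.T @ model.T
    np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-8)
    # permuting sample order permutes scores rows identically
    perm = rng.permutation(30)
    model_p = fit_pls(X[perm], y[perm], 5)
    np.testing.assert_allclose(model_p.T, model.T[perm], atol=1e-8)


def test_predict_matches_regression_vector_and_centering():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((25, 6))
    y = rng.standard_normal(25)
    model = fit_pls(X, y, 3)
    Xs = (X - model.x_center) / model.x_scale
    np.testing.assert_allclose(
        predict(model, X), Xs @ model.coef()[:, 0] + model.y_center[0], atol=1e-10
    )
    # a row at the training center predicts the y center
    np.testing.assert_allclose(
        predict(model, model.x_center[None, :]), model.y_center, atol=1e-10
    )


def test_predict_feature_mismatch_raises():
    model = fit_pls(np.random.default_rng(0).standard_normal((10, 4)),
                    np.arange(10.0), 2)
    with pytest.raises(ValueError, match="feature count"):
        predict(model, np.ones((2, 3)))


def test_pls_matches_sklearn_cross_check():
    """Independent cross-check of the NIPALS path against the established
    PLS regression implementation."""
    from sklearn.cross_decomposition import PLSRegression

    rng = np.random.default_rng(4)
    X = rng.standard_normal((40, 12))
    y = X[:, 0] - 2 * X[:, 3] + 0.1 * rng.standard_normal(40)
    ours = predict(fit_pls(X, y, 3), X)
    theirs = PLSRegression(n_components=3, scale=True).fit(X, y).predict(X).ravel()
    np.testing.assert_allclose(ours, theirs, atol=1e-6)


# ------------------------------------------------------------------ #
# VIP
# ------------------------------------------------------------------ #
def test_vip_single_feature_is_one():
    rng = np.random.default_rng(5)
    x = rng.standard_normal(15)
    model = fit_pls(x[:, None], 2 * x + rng.standard_normal(15) * 0.1, 1)
    np.testing.assert_allclose(vip(model), [1.0], atol=1e-12)


def test_vip_mean_square_is_one():
    rng = np.random.default_rng(6)
    for n_lv in (1, 3, 6):
        X = rng.standard_normal((30, 20))
        y = rng.standard_normal(30)
        model = fit_pls(X, y, n_lv)
        v = vip(model)
        assert np.mean(v**2) == pytest.approx(1.0, rel=1e-10)


def test_vip_recovers_planted_discriminants():
    """10 planted discriminant features among 200: at least 8 of the top-10
    VIP features are planted."""
    rng = np.random.default_rng(7)
    n = 80
    y = np.repeat([0.0, 1.0], n // 2)
    X = rng.standard_normal((n, 200))
    planted = rng.choice(200, 10, replace=False)
    X[:, planted] += 1.5 * y[:, None]
    model = fit_pls(X, y, 2)
    top10 = np.argsort(vip(model))[::-1][:10]
    assert len(set(top10) & set(planted)) >= 8


# ------------------------------------------------------------------ #
# AUROC
# ------------------------------------------------------------------ #
def test_auroc_separated_and_ties():
    assert auroc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
    assert auroc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5


def test_auroc_pair_counting_oracle():
    labels = np.array([1, 1, 0, 0])
    scores = np.array([0.9, 0.4, 0.6, 0.1])
    wins = 0.0
    for sp in scores[labels == 1]:
        for sn in scores[labels == 0]:
            wins += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    assert auroc(labels, scores) == pytest.approx(wins / 4) == pytest.approx(0.75)


def test_auroc_monotone_invariance_and_errors():
    rng = np.random.default_rng(8)
    labels = rng.integers(0, 2, 50)
    labels[0], labels[1] = 0, 1
    scores = rng.standard_normal(50)
    a = auroc(labels, scores)
    assert auroc(labels, np.exp(scores)) == pytest.approx(a)
    assert auroc(labels, 3 * scores - 7) == pytest.approx(a)
    with pytest.raises(ValueError):
        auroc(np.ones(5), np.arange(5))


# ------------------------------------------------------------------ #
# subjectwise CV
# ------------------------------------------------------------------ #
def test_subjectwise_folds_keep_patients_together():
    pids = np.repeat([f"P{i}" for i in range(12)], 3)
    labels = np.repeat(["a"] * 6 + ["b"] * 6, 3)
    scheme = subjectwise_folds(pids, labels, 4, seed=0)
    df = pd.DataFrame({"pid": pids, "fold": scheme.fold_of_sample})
    assert (df.groupby("pid")["fold"].nunique() == 1).all()
    # every training split contains both classes
    for f in range(4):
        rest = labels[scheme.fold_of_sample != f]
        assert set(rest) == {"a", "b"}


def test_subjectwise_folds_deterministic_and_single_sample_patients():
    pids = np.array([f"P{i}" for i in range(20)])
    labels = np.array(["a", "b"] * 10)
    s1 = subjectwise_folds(pids, labels, 5, seed=3)
    s2 = subjectwise_folds(pids, labels, 5, seed=3)
    np.testing.assert_array_equal(s1.fold_of_sample, s2.fold_of_sample)
    # 1 sample per patient reduces to stratified sample-wise CV
    for f in range(5):
        fold_labels = labels[s1.fold_of_sample == f]
        assert 0 < fold_labels.size <= 4


def test_subjectwise_folds_k_exceeding_patients():
    with pytest.raises(ValueError):
        subjectwise_folds(np.array(["P1", "P2"]), np.array(["a", "b"]), 3, 0)


# ------------------------------------------------------------------ #
# LV selection and 2CV
# ------------------------------------------------------------------ #
def test_select_n_lv_max_one():
    rng = np.random.default_rng(9)
    X = rng.standard_normal((40, 5))
    y = (X[:, 0] > 0).astype(float)
    pids = np.array([f"P{i}" for i in range(40)])
    assert select_n_lv(X, y, pids, max_lv=1) == 1


def test_select_n_lv_needs_second_direction():
    """y depends on a signal masked by a measured nuisance direction: one
    latent variable is dominated by the nuisance and a second is needed."""
    rng = np.random.default_rng(10)
    n = 150
    s = rng.standard_normal(n)
    nuis = rng.standard_normal(n)
    X = np.column_stack([s + 2 * nuis, nuis, 0.05 * rng.standard_normal((n, 3))])
    y = (s > 0).astype(float)
    pids = np.array([f"P{i}" for i in range(n)])
    chosen = select_n_lv(X, y, pids, k_inner=5, seed=1, max_lv=5)
    assert chosen >= 2


def test_select_n_lv_pure_noise_stays_near_chance():
    rng = np.random.default_rng(11)
    X = rng.standard_normal((60, 20))
    y = rng.integers(0, 2, 60).astype(float)
    pids = np.array([f"P{i}" for i in range(60)])
    chosen = select_n_lv(X, y, pids, k_inner=5, seed=2, max_lv=8)
    # evaluate the chosen complexity honestly on fresh folds
    scheme = subjectwise_folds(pids, y, 5, seed=99)
    hits = 0
    for f in range(5):
        test = scheme.fold_of_sample == f
        model = fit_pls(X[~test], y[~test], chosen)
        hits += (((predict(model, X[test]) >= 0.5)) == (y[test] >= 0.5)).sum()
    assert 0.3 <= hits / 60 <= 0.7


def test_double_cv_coverage_and_no_leakage():
    rng = np.random.default_rng(12)
    n_pat = 21
    pids = np.repeat([f"P{i}" for i in range(n_pat)], 2)
    y = np.repeat((np.arange(n_pat) % 2).astype(float), 2)
    X = rng.standard_normal((2 * n_pat, 15)) + 2 * y[:, None]
    y_hat, info = double_cv(X, y, pids, k_outer=5, k_inner=3, seed=0, max_lv=4)
    assert np.isfinite(y_hat).all()
    scheme = info["outer_scheme"]
    for f in range(5):
        test_p = set(pids[scheme.fold_of_sample == f])
        train_p = set(pids[scheme.fold_of_sample != f])
        assert not test_p & train_p
    assert auroc(y >= 0.5, y_hat) >= 0.9  # separable data


def test_permutation_p_floor_on_separable_data():
    rng = np.random.default_rng(13)
    n_pat = 24
    pids = np.repeat([f"P{i}" for i in range(n_pat)], 2)
    y = np.repeat((np.arange(n_pat) % 2).astype(float), 2)
    X = rng.standard_normal((2 * n_pat, 10)) + 3 * y[:, None]
    p, obs, dist = permutation_test(
        X, y, pids, n_perm=20, seed=1, k_outer=4, k_inner=3, max_lv=3
    )
    assert obs >= 0.95
    assert p == pytest.approx(1.0 / 21.0)
    assert p >= 1.0 / 21.0 - 1e-12  # add-one bound: p can never be smaller


# ------------------------------------------------------------------ #
# one-vs-rest suite
# ------------------------------------------------------------------ #
def test_one_vs_rest_missing_class_raises():
    rng = np.random.default_rng(14)
    X = rng.standard_normal((20, 5))
    labels = np.array(["cholestatic"] * 10 + ["recovered"] * 10)
    pids = np.array([f"P{i}" for i in range(20)])
    with pytest.raises(ValueError, match="hepatocellular"):
        OneVsRestPLSDA(X, labels, pids)


def test_one_vs_rest_structure(ovr_fit):
    study, res = ovr_fit
    pred = res.predictions
    # every sample carries all three continuous predictions
    for c in ("cholestatic", "hepatocellular", "recovered"):
        assert f"y_{c}" in pred.columns
        assert np.isfinite(pred[f"y_{c}"]).all()
    # training-class samples predicted out-of-sample, mixed by the models
    assert (pred.loc[pred["label"] == "mixed", "prediction_source"] == "model").all()
    assert (pred.loc[pred["label"] != "mixed", "prediction_source"] == "2cv").all()
    # VIP identity holds per fitted model
    for c, d in res.per_class.items():
        v = res.vip_scores[c].to_numpy()
        assert np.mean(v[v >= 0] ** 2) == pytest.approx(1.0, rel=1e-6)
    assert len(res.pls2_features) == len(set.union(*res.vip_sets.values()))
    assert res.pls2_model.n_lv == 2


def test_mixed_samples_blend_between_disease_corners(ovr_fit):
    """Mixed patients are convex blends of the two injury phenotypes.  At
    their first (full-strength) timepoint, before recovery dilutes the
    planted effects, both injury predictions exceed the recovered
    prediction on average."""
    study, res = ovr_fit
    pred = res.predictions.join(
        study.samples.set_index("sample_id")[["timepoint_index"]]
    )
    mixed = pred[(pred["label"] == "mixed") & (pred["timepoint_index"] == 0)]
    assert len(mixed) > 0
    assert mixed["y_cholestatic"].mean() > mixed["y_recovered"].mean()
    assert mixed["y_hepatocellular"].mean() > mixed["y_recovered"].mean()


def test_summary_reports_key_numbers(ovr_fit):
    _, res = ovr_fit
    text = res.summary()
    assert "AUROC" in text and "perm p" in text
    for c in ("cholestatic", "hepatocellular", "recovered"):
        assert c in text
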