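"""QC-SVRC drift correction, dispersion metrics, filters and scaling."""

import math

import numpy as np
import pytest

from dilimet.preprocess import (
    apply_drift_correction,
    autoscale,
    between_batch_scale,
    blank_filter,
    d_ratio_star,
    fit_qc_svrc,
    group_intensity_filter,
    robust_sd,
    svrc_grid,
)

from conftest import make_pm


# ------------------------------------------------------------------ #
# QC-SVRC
# ------------------------------------------------------------------ #
def test_constant_qc_gives_identity_correction():
    orders = np.arange(1.0, 41.0)
    qc_orders = orders[::8]
    fit = fit_qc_svrc(np.full(qc_orders.size, 5000.0), qc_orders, orders)
    np.testing.assert_allclose(fit.trend, 5000.0)
    assert fit.C == 5000.0
    pm = make_pm(np.full((5, 1), 123.0), roles=["qc", "study", "study", "study", "qc"])
    fit2 = fit_qc_svrc(
        np.full(4, 123.0),
        np.array([1, 2, 3, 4.0]),
        pm.samples["injection_order"].to_numpy(float),
        feature_id="F0",
        batch_id="B1",
    )
    corrected = apply_drift_correction(pm, [fit2])
    np.testing.assert_allclose(corrected.intensities, pm.intensities)


def test_too_few_qcs_rejected():
    with pytest.raises(ValueError, match=">= 4 QC"):
        fit_qc_svrc(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]), np.arange(1.0, 10))


def test_linear_drift_reduces_qc_spread():
    """QCs on a 0.2 %-per-injection ramp: correction shrinks their RSD."""
    orders = np.arange(1.0, 81.0)
    qc_orders = orders[::8]
    rng = np.random.default_rng(0)
    qc = 10000.0 * (1 + 0.002 * qc_orders) * (1 + 0.01 * rng.standard_normal(qc_orders.size))
    fit = fit_qc_svrc(qc, qc_orders, orders)
    pos = {o: i for i, o in enumerate(fit.orders)}
    corrected = qc * fit.C / np.array([fit.trend[pos[o]] for o in qc_orders])
    assert corrected.std() / corrected.mean() < qc.std() / qc.mean()


def test_grid_choice_matches_brute_force_oracle():
    """The returned (epsilon, gamma) attains the grid-wide minimum RMSECV,
    re-verified by an exhaustive leave-one-out scan through the public
    sklearn SVR estimator."""
    from sklearn.svm import SVR

    rng = np.random.default_rng(42)
    orders = np.arange(1.0, 41.0)
    qc_orders = orders[::5]
    qc = 5e4 * (1 + 0.3 * np.sin(qc_orders / 10)) * (1 + 0.05 * rng.standard_normal(qc_orders.size))
    fit = fit_qc_svrc(qc, qc_orders, orders, n_eps=4, n_gamma=5)

    xs = (qc_orders - orders.min()) / (orders.max() - orders.min())
    eps_grid, gamma_grid = svrc_grid(fit.C, n_eps=4, n_gamma=5)
    best = (math.inf, None, None)
    for gamma in gamma_grid:
        for eps in eps_grid:
            errs = []
            for i in range(qc.size):
                m = np.arange(qc.size) != i
                svr = SVR(kernel="rbf", C=fit.C, epsilon=eps, gamma=gamma, tol=1e-4)
                svr.fit(xs[m, None], qc[m])
                errs.append(svr.predict(xs[i : i + 1, None])[0] - qc[i])
            rmse = float(np.sqrt(np.mean(np.square(errs))))
            if best[1] is None or rmse < best[0] * (1 - 1e-12):
                best = (rmse, eps, gamma)
    assert fit.rmsecv == pytest.approx(best[0], rel=1e-6)
    assert fit.epsilon == pytest.approx(best[1], rel=1e-9)
    assert fit.gamma == pytest.approx(best[2], rel=1e-9)


def test_trend_doubling_halves_intensity():
    pm = make_pm([[100.0], [100.0], [100.0], [100.0], [100.0]])
    fit = fit_qc_svrc(
        np.full(4, 50.0),
        np.array([1.0, 2, 4, 5]),
        pm.samples["injection_order"].to_numpy(float),
        feature_id="F0",
        batch_id="B1",
    )
    fit.trend = np.array([50.0, 50, 100, 50, 50])  # trend = 2C at order 3
    corrected = apply_drift_correction(pm, [fit])
    np.testing.assert_allclose(corrected.intensities[:, 0], [100, 100, 50, 100, 100])


def test_trend_floor_guard_logs_warning():
    pm = make_pm([[100.0], [100.0], [100.0], [100.0]])
    fit = fit_qc_svrc(
        np.full(4, 50.0),
        np.arange(1.0, 5),
        pm.samples["injection_order"].to_numpy(float),
        feature_id="F0",
        batch_id="B1",
    )
    fit.trend = np.array([50.0, -5.0, 50, 50])  # non-physical trend value
    corrected = apply_drift_correction(pm, [fit])
    # floored at 1 % of C = 0.5 -> correction factor C/0.5 = 100
    assert corrected.intensities[1, 0] == pytest.approx(100.0 * 50 / 0.5)
    assert any("floored" in line for line in corrected.provenance_log)


# ------------------------------------------------------------------ #
# dispersion metrics
# ------------------------------------------------------------------ #
def test_d_ratio_hand_computed_oracle():
    """qc {9,10,11,10}: MAD 0.5; study {5,10,15,20,10,12}: MAD 2.5;
    ratio 0.5/2.5 = 20 %."""
    qc = np.array([9.0, 10, 11, 10])
    study = np.array([5.0, 10, 15, 20, 10, 12])
    assert d_ratio_star(qc, study) == pytest.approx(100 * 0.5 / 2.5)


def test_d_ratio_degenerate_cases():
    assert d_ratio_star(np.array([7.0, 7, 7, 7]), np.array([1.0, 2, 3])) == 0.0
    same = np.array([5.0, 6, 7, 8])
    assert d_ratio_star(same, same) == pytest.approx(100.0)
    assert d_ratio_star(np.array([1.0, 2]), np.array([3.0, 3, 3])) == math.inf


def test_robust_sd_matches_gaussian_sd_asymptotically():
    rng = np.random.default_rng(1)
    x = rng.normal(10, 2, 100_000)
    assert robust_sd(x) == pytest.approx(2.0, rel=0.02)


# ------------------------------------------------------------------ #
# between-batch scaling
# ------------------------------------------------------------------ #
def _two_batch_pm(offset=2.0):
    """Bridge triplets in both batches, batch-2 intensities offset-fold."""
    base = np.array([[10.0], [20.0], [30.0], [40.0]])
    b1 = np.vstack([base, [[15.0]]])
    b2 = offset * np.vstack([base[:3], [[25.0]], [[35.0]]])
    X = np.vstack([b1, b2])
    roles = ["bridge", "bridge", "bridge", "study", "study"] * 2
    batches = ["B1"] * 5 + ["B2"] * 5
    pm = make_pm(X, roles=roles, batches=batches)
    ids = ["S0", "S1", "S2", "S3", "S4", "S0", "S1", "S2", "S5", "S6"]
    pm.samples["sample_id"] = ids
    return pm


def test_between_batch_scaling_equalizes_bridge_medians():
    pm = _two_batch_pm(offset=2.0)
    out = between_batch_scale(pm)
    # all bridge duplicates from batch 1 dropped, batch 2 copies kept
    bridge = out.samples["role"] == "bridge"
    assert set(out.samples.loc[bridge, "batch_id"]) == {"B2"}
    # the two batch scaling factors bring each batch to the pooled median
    b1_bridge_median = np.median([10, 20, 30])
    pooled = np.median([10, 20, 30, 20, 40, 60])
    kept = out.intensities[bridge.to_numpy(), 0]
    np.testing.assert_allclose(np.median(kept), pooled)
    # study samples in batch 1 rescaled by the same factor as their batch
    s3 = out.intensities[(out.samples["sample_id"] == "S3").to_numpy(), 0]
    np.testing.assert_allclose(s3, 40.0 / (b1_bridge_median / pooled))


def test_identical_batches_scale_by_one():
    pm = _two_batch_pm(offset=1.0)
    out = between_batch_scale(pm)
    study_before = pm.intensities[(pm.samples["role"] == "study").to_numpy(), 0]
    study_after = out.intensities[(out.samples["role"] == "study").to_numpy(), 0]
    np.testing.assert_allclose(np.sort(study_after), np.sort(study_before))


def test_random_offsets_zero_bridge_median_difference():
    """Random per-feature batch offsets: after scaling, bridge medians are
    exactly equal across batches (checked before duplicate removal)."""
    rng = np.random.default_rng(3)
    n_bridge, p = 5, 7
    true = rng.uniform(100, 1000, (n_bridge, p))
    factors = rng.uniform(0.5, 2.0, p)
    X = np.vstack([true, true * factors[None, :]])
    pm = make_pm(
        X,
        roles=["bridge"] * (2 * n_bridge),
        batches=["B1"] * n_bridge + ["B2"] * n_bridge,
    )
    pm.samples["sample_id"] = [f"S{i}" for i in range(n_bridge)] * 2
    out = between_batch_scale(pm)
    # surviving (batch 2) bridge medians land exactly on the pooled median
    b2 = out.intensities[(out.samples["batch_id"] == "B2").to_numpy()]
    med_b2 = np.median(b2, axis=0)
    pooled = np.median(np.vstack([true, true * factors[None, :]]), axis=0)
    np.testing.assert_allclose(med_b2, pooled, rtol=1e-12)


def test_between_batch_needs_three_bridges():
    pm = _two_batch_pm()
    drop = ~pm.samples["sample_id"].isin(["S0"]) | (pm.samples["batch_id"] == "B1")
    sub = pm.subset(sample_mask=drop.to_numpy())
    with pytest.raises(ValueError, match="bridge"):
        between_batch_scale(sub)


# ------------------------------------------------------------------ #
# blank / intensity filters, autoscaling
# ------------------------------------------------------------------ #
def test_blank_filter_rule_boundaries():
    X = np.array(
        [
            [2000.0, 2000.0],  # study median 2000 for both features
            [2000.0, 2000.0],
            [2000.0, 2000.0],
            [100.0, 300.0],    # blank: 10x100=1000 <= 2000 keep; 10x300=3000 > 2000 drop
        ]
    )
    pm = make_pm(X, roles=["study"] * 3 + ["blank"])
    out, removed = blank_filter(pm)
    assert removed == ["F1"]
    assert out.n_features == 1


def test_blank_filter_without_blanks_is_noop():
    pm = make_pm(np.ones((3, 2)))
    out, removed = blank_filter(pm)
    assert removed == []
    assert any("skipped" in line for line in out.provenance_log)


def test_group_intensity_filter_strict_boundary():
    X = np.array([[14999.0, 15001.0]] * 4)
    pm = make_pm(X, labels=["cholestatic", "cholestatic", "recovered", "recovered"])
    out = group_intensity_filter(pm)
    assert list(out.features["feature_id"]) == ["F1"]


def test_group_intensity_filter_matches_brute_force(tiny_study):
    pm, _ = tiny_study
    study = pm.subset(sample_mask=pm.study_mask)
    out = group_intensity_filter(study, threshold=15000)
    labels = study.samples["phenotype_label"]
    keep_expected = []
    for j, fid in enumerate(study.features["feature_id"]):
        med = max(
            np.median(study.intensities[(labels == g).to_numpy(), j])
            for g in labels.unique()
        )
        if med > 15000:
            keep_expected.append(fid)
    assert list(out.features["feature_id"]) == keep_expected


def test_filters_are_idempotent(tiny_study):
    pm, _ = tiny_study
    once = group_intensity_filter(pm)
    twice = group_intensity_filter(once)
    assert twice.n_features == once.n_features
    b_once, _ = blank_filter(pm)
    b_twice, _ = blank_filter(b_once)
    assert b_twice.n_features == b_once.n_features


def test_autoscale_basics_and_round_trip():
    scaled, centers, scales, kept = autoscale(np.array([[1.0], [2.0], [3.0]]))
    np.testing.assert_allclose(scaled[:, 0], [-1, 0, 1])
    X = np.array([[1.0, 5.0], [2.0, 5.0], [4.0, 5.0]])
    scaled, centers, scales, kept = autoscale(X)
    assert list(kept) == [True, False]  # constant column dropped
    # held-out data scaled then inverted recovers the originals
    held = np.array([[10.0], [-3.0]])
    forward = (held - centers[kept]) / scales[kept]
    back = forward * scales[kept] + centers[kept]
    np.testing.assert_allclose(back, held)
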