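"""Shared fixtures: synthetic studies at the default study conditions.

The heavy fixtures (drift-corrected and fully preprocessed default study,
fitted one-vs-rest suite) are session-scoped so the preprocessing chain
runs once for the whole suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dilimet.peak_matrix import PeakMatrix
from dilimet.plsda import OneVsRestPLSDA
from dilimet.preprocess import (
    between_batch_scale,
    blank_filter,
    correct_drift,
    d_ratio_filter,
    group_intensity_filter,
    qc_metrics,
)
from dilimet.synthetic import DriftSpec, StudyDesign, generate_study, small_design

#: seed of the shared default study (arbitrary fixed constant)
STUDY_SEED = 1


def make_pm(
    intensities,
    roles=None,
    batches=None,
    patient_ids=None,
    labels=None,
    timepoints=None,
    feature_ids=None,
) -> PeakMatrix:
    """Hand-build a small PeakMatrix for targeted unit tests."""
    X = np.asarray(intensities, float)
    n, p = X.shape
    roles = roles or ["study"] * n
    batches = batches or ["B1"] * n
    order_within: dict[str, int] = {}
    orders = []
    for b in batches:
        order_within[b] = order_within.get(b, 0) + 1
        orders.append(order_within[b])
    samples = pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "patient_id": patient_ids or [f"P{i}" for i in range(n)],
            "injection_order": orders,
            "batch_id": batches,
            "role": roles,
            "timepoint_index": timepoints or [0] * n,
            "phenotype_label": labels or ["unknown"] * n,
        }
    )
    features = pd.DataFrame(
        {
            "feature_id": feature_ids or [f"F{j}" for j in range(p)],
            "mz": np.linspace(100, 200, p),
            "rt": np.linspace(10, 20, p),
            "esi_mode": ["positive"] * p,
            "annotation": [""] * p,
            "metabolite_class": [""] * p,
            "metabolite_subclass": [""] * p,
            "excluded_flag": ["none"] * p,
        }
    )
    return PeakMatrix(samples, features, X)


@pytest.fixture(scope="session")
def default_study():
    """Default synthetic study: drift amplitude 0.3, noise CV 0.1."""
    pm, clinical = generate_study(
        StudyDesign(seed=STUDY_SEED), drift=DriftSpec(amplitude=0.3), noise_cv=0.1
    )
    return pm, clinical


@pytest.fixture(scope="session")
def corrected_default_study(default_study):
    """QC-SVRC-corrected default study with before/after QC metrics."""
    pm, _ = default_study
    metrics_before = qc_metrics(pm)
    corrected, fits = correct_drift(pm)
    metrics_after = qc_metrics(corrected)
    return {
        "raw": pm,
        "corrected": corrected,
        "fits": fits,
        "before": metrics_before,
        "after": metrics_after,
    }


@pytest.fixture(scope="session")
def processed_default_study(corrected_default_study):
    """Fully preprocessed default study (all filters and scaling applied)."""
    corrected = corrected_default_study["corrected"]
    filtered, dr_removed = d_ratio_filter(corrected)
    scaled = between_batch_scale(filtered)
    blanked, blank_removed = blank_filter(scaled)
    final = group_intensity_filter(blanked)
    return {
        "final": final,
        "d_ratio_removed": dr_removed,
        "blank_removed": blank_removed,
        "after_scale": scaled,
    }


@pytest.fixture(scope="session")
def ovr_fit(processed_default_study):
    """One-vs-rest PLS-DA suite fitted on the preprocessed default study,
    with 50 patient-level permutations per class."""
    pm = processed_default_study["final"]
    study = pm.subset(sample_mask=pm.study_mask)
    model = OneVsRestPLSDA.from_peak_matrix(study)
    return study, model.fit(n_perm=50, seed=11)


@pytest.fixture()
def tiny_study():
    """A small fast study for structural tests (function-scoped copy)."""
    pm, clinical = generate_study(small_design(seed=3), noise_cv=0.1)
    return pm, clinical
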