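"""Synthetic LC-MS DILI study generator.

Emulates the acquisition structure the downstream analysis assumes: two
injection batches with pooled-QC replicates every 8 (batch 1) and every 10
(batch 2) samples, blanks at the end of each batch, bridge samples
re-injected in batch 2 for between-batch scaling, smooth multiplicative
within-batch signal drift, multiplicative lognormal measurement noise,
phenotype-dependent metabolite effects (bile-acid-like features elevated
in cholestatic injury, phospholipid-like features depressed in active
injury, amino-acid-like features elevated in hepatocellular injury),
per-patient longitudinal recovery trajectories, and a clinical-chemistry
table whose ALT/ALP values reproduce each sample's planted label under the
rule-based classifier.

The generator deliberately does not share the drift corrector's functional
form: drift trends are random smooth curves (a slow sinusoid plus a
low-order polynomial of injection order), while the corrector is a kernel
support-vector regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .clinical import ClinicalRecord, classify_phenotype
from .peak_matrix import FEATURE_COLUMNS, PeakMatrix


@dataclass
class EffectTemplate:
    """Multiplicative phenotype effect (log2 scale) for one feature class.

    The recovered baseline is by definition 0 on the log scale; the two
    stored effects are fold-changes of the fully expressed cholestatic and
    hepatocellular phenotypes relative to that baseline.
    """

    feature_class: str
    log2_effect_cholestatic: float
    log2_effect_hepatocellular: float


@dataclass
class DriftSpec:
    """Within-batch signal-drift model.

    family : {"linear", "exponential-decay", "smooth-random"}
    amplitude : maximum relative deviation of the drift multiplier from 1
    per_feature_variation : relative spread of per-feature amplitudes
    """

    family: str = "smooth-random"
    amplitude: float = 0.3
    per_feature_variation: float = 0.3

    def __post_init__(self) -> None:
        if self.family not in ("linear", "exponential-decay", "smooth-random"):
            raise ValueError(f"unknown drift family {self.family!r}")
        if not 0 <= self.amplitude < 1:
            raise ValueError("drift amplitude must lie in [0, 1)")


@dataclass
class StudyDesign:
    """Size and acquisition layout of a synthetic study.

    Defaults reproduce the structure of the study the pipeline was designed
    around: ~60 patients over three modelling phenotypes plus a mixed
    cohort, 2-5 serum samples per patient collected during clinical
    follow-up (with gradual recovery between visits), 300 LC-MS features,
    QC injections every 8 samples in batch 1 and every 10 in batch 2, 15
    bridge samples replicated across batches, and 2 / 6 blanks at the
    batch ends.
    """

    n_patients_per_phenotype: dict[str, int] = field(
        default_factory=lambda: {
            "cholestatic": 18,
            "hepatocellular": 18,
            "recovered": 18,
            "mixed": 6,
        }
    )
    timepoints_per_patient: tuple[int, int] = (2, 5)
    n_features: int = 300
    frac_bileacid_like: float = 0.15
    frac_phospholipid_like: float = 0.15
    frac_aminoacid_like: float = 0.10
    batch1_qc_interval: int = 8
    batch2_qc_interval: int = 10
    n_bridge: int = 15
    n_blanks_per_batch: tuple[int, int] = (2, 6)
    n_contaminants: int = 5
    n_unstable: int = 5
    recovery_rate: float = 0.25
    biological_cv_range: tuple[float, float] = (0.7, 1.1)
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.frac_bileacid_like, self.frac_phospholipid_like, self.frac_aminoacid_like)
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("feature-class fractions must lie in [0,1] and sum to <= 1")
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")
        if sum(self.n_patients_per_phenotype.values()) <= 0:
            raise ValueError("at least one patient is required")
        if any(n < 0 for n in self.n_patients_per_phenotype.values()):
            raise ValueError("patient counts must be non-negative")
        lo, hi = self.timepoints_per_patient
        if lo < 1 or hi < lo:
            raise ValueError("timepoints_per_patient must be a valid range with min >= 1")
        if not 0 <= self.recovery_rate <= 1:
            raise ValueError("recovery_rate must lie in [0, 1]")
        lo, hi = self.biological_cv_range
        if not 0 <= lo <= hi < 5:
            raise ValueError("biological_cv_range must satisfy 0 <= lo <= hi < 5")


def default_effects() -> list[EffectTemplate]:
    """Planted fold-changes for the three discriminant feature classes.

    Magnitudes are free parameters of the simulation (the real study does
    not quantify effect sizes); they are chosen to give clearly separable
    but noisy phenotypes at the default noise level.
    """
    return [
        EffectTemplate("bile_acid_like", 2.0, 0.3),
        EffectTemplate("phospholipid_like", -0.8, -2.0),
        EffectTemplate("amino_acid_like", 0.2, 1.8),
    ]


# metabolite class/subclass labels attached to planted feature classes
_CLASS_ANNOTATION = {
    "bile_acid_like": ("Steroids and steroid derivatives", "Bile acids, alcohols and derivatives"),
    "phospholipid_like": ("Glycerophospholipids", "Glycerophosphocholines"),
    "amino_acid_like": ("Carboxylic acids and derivatives", "Amino acids, peptides, and analogues"),
    "other": ("", ""),
}

# lognormal location anchors (medians) for phenotype-conditional chemistry,
# taken from the group means of the cohort the design emulates
_CLINICAL_ANCHORS = {
    # label: (alt, alp, ast, ggt, bilirubin, albumin)
    "cholestatic": (103.0, 341.0, 74.0, 472.0, 4.0, 3.9),
    "hepatocellular": (744.0, 128.0, 482.0, 249.0, 4.0, 3.9),
    "mixed": (133.0, 138.0, 82.0, 189.0, 1.5, 4.1),
    "recovered": (28.0, 87.0, 29.0, 61.0, 0.7, 4.3),
}
_CLINICAL_SIGMA = 0.45  # log-scale spread of ALT/ALP draws


def generate_trajectory(
    patient_phenotype: str,
    n_timepoints: int,
    recovery_rate: float,
    seed: int | None = None,
) -> np.ndarray:
    """Per-timepoint effect weights decaying geometrically toward recovery.

    Weight 1 is the fully expressed phenotype, weight 0 the recovered
    baseline; weight at timepoint t is ``(1 - recovery_rate) ** t``.  The
    decay is deterministic; ``seed`` is accepted for interface symmetry
    with the stochastic generators.
    """
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    if patient_phenotype == "recovered":
        return np.zeros(n_timepoints)
    t = np.arange(n_timepoints, dtype=float)
    return (1.0 - recovery_rate) ** t


def _drift_curves(drift: DriftSpec, n_features: int, n_orders: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Per-feature multiplicative drift over injection order, shape (features, orders)."""
    t = np.linspace(0.0, 1.0, n_orders)
    amp = drift.amplitude * (1.0 + drift.per_feature_variation * rng.uniform(-1, 1, n_features))
    amp = np.clip(amp, 0.0, 0.95)
    if drift.family == "linear":
        sign = rng.choice([-1.0, 1.0], n_features)
        dev = np.outer(sign, 2.0 * t - 1.0)
    elif drift.family == "exponential-decay":
        dev = -(1.0 - np.exp(-3.0 * t))[None, :] * np.ones((n_features, 1))
    else:
        # smooth-random: one slow sinusoid (conditioning/recovery cycle of
        # the source) plus a random cubic, rescaled to the peak amplitude
        freq = rng.uniform(0.6, 1.2, n_features)
        phase = rng.uniform(0, 2 * np.pi, n_features)
        w_sin = rng.uniform(0.7, 1.0, n_features)
        coef = rng.normal(scale=0.3, size=(n_features, 3))
        poly = coef @ np.vstack([t, t**2, t**3])
        dev = w_sin[:, None] * np.sin(2 * np.pi * freq[:, None] * t[None, :] + phase[:, None]) + poly
        peak = np.abs(dev).max(axis=1)
        peak[peak == 0] = 1.0
        dev = dev / peak[:, None]
    g = 1.0 + amp[:, None] * dev
    return np.clip(g, 0.05, None)


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and the given CV."""
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, shape)


def _draw_chemistry(label: str, rng: np.random.Generator) -> dict[str, float]:
    """Draw one clinical record consistent with ``label`` under the R-score rules.

    Lognormal draws anchored at the group medians; rejection sampling until
    the rule-based classifier reproduces the label (cap 1000 draws, then a
    deterministic prototype at the anchor values).
    """
    alt0, alp0, ast0, ggt0, bili0, alb0 = _CLINICAL_ANCHORS[label]
    for _ in range(1000):
        alt = alt0 * rng.lognormal(0.0, _CLINICAL_SIGMA)
        alp = alp0 * rng.lognormal(0.0, _CLINICAL_SIGMA)
        if classify_phenotype(ClinicalRecord(alt=alt, alp=alp)) == label:
            break
    else:
        alt, alp = alt0, alp0
    return {
        "alt": alt,
        "alp": alp,
        "ast": ast0 * rng.lognormal(0.0, 0.5),
        "ggt": ggt0 * rng.lognormal(0.0, 0.6),
        "bilirubin": bili0 * rng.lognormal(0.0, 0.7),
        "albumin": float(np.clip(rng.normal(alb0, 0.4), 2.0, 5.5)),
    }


def generate_study(
    design: StudyDesign,
    effects: list[EffectTemplate] | None = None,
    drift: DriftSpec | None = None,
    noise_cv: float = 0.1,
) -> tuple[PeakMatrix, pd.DataFrame]:
    """Generate one complete synthetic study.

    Returns the peak matrix (study, bridge, QC and blank injections across
    two batches) and the per-study-sample clinical table.  The intensity of
    feature f in sample s is

        baseline_f x 2^(weight_s * effect_f(label_s)) x drift_f(order_s) x noise,

    QCs are the batch-wise pooled mean of the study samples' true signal
    under the same drift and noise, blanks carry ~0.1-1 % of baseline
    (carry-over level) except for planted contaminant features, and bridge
    samples share one true intensity across both batches before drift is
    applied.
    """
    if effects is None:
        effects = default_effects()
    if drift is None:
        drift = DriftSpec()
    if not 0 <= noise_cv < 1:
        raise ValueError("noise_cv must lie in [0, 1)")
    rng = np.random.default_rng(design.seed)

    # ---------------- feature panel ----------------
    p = design.n_features
    n_ba = int(round(design.frac_bileacid_like * p))
    n_pl = int(round(design.frac_phospholipid_like * p))
    n_aa = int(round(design.frac_aminoacid_like * p))
    classes = np.array(
        ["bile_acid_like"] * n_ba
        + ["phospholipid_like"] * n_pl
        + ["amino_acid_like"] * n_aa
        + ["other"] * (p - n_ba - n_pl - n_aa)
    )
    rng.shuffle(classes)
    eff_by_class = {e.feature_class: e for e in effects}
    log2_chol = np.array(
        [getattr(eff_by_class.get(c), "log2_effect_cholestatic", 0.0) for c in classes]
    )
    log2_hep = np.array(
        [getattr(eff_by_class.get(c), "log2_effect_hepatocellular", 0.0) for c in classes]
    )
    baseline = 10.0 ** rng.uniform(4.0, 6.0, p)  # log-uniform over [1e4, 1e6] AU
    other_idx = np.flatnonzero(classes == "other")
    n_cont = min(design.n_contaminants, other_idx.size)
    contaminant = np.zeros(p, bool)
    contaminant[rng.choice(other_idx, n_cont, replace=False)] = True
    # features chemically unstable in the pooled QC: extra QC-only variance,
    # planted so the D-ratio* filter has true positives to remove
    free_idx = np.flatnonzero((classes == "other") & ~contaminant)
    n_unst = min(design.n_unstable, free_idx.size)
    unstable = np.zeros(p, bool)
    unstable[rng.choice(free_idx, n_unst, replace=False)] = True
    qc_instability_cv = 2.0

    features = pd.DataFrame(
        {
            "feature_id": [f"F{i:04d}" for i in range(p)],
            "mz": np.round(rng.uniform(70, 1200, p), 4),
            "rt": np.round(rng.uniform(10, 600, p), 2),
            "esi_mode": rng.choice(["positive", "negative"], p),
            "annotation": ["" for _ in range(p)],
            "metabolite_class": [_CLASS_ANNOTATION[c][0] for c in classes],
            "metabolite_subclass": [_CLASS_ANNOTATION[c][1] for c in classes],
            "excluded_flag": ["none"] * p,
            "effect_class": classes,
            "contaminant": contaminant,
            "qc_unstable": unstable,
        }
    )[FEATURE_COLUMNS + ["effect_class", "contaminant", "qc_unstable"]]

    # ---------------- patients and samples ----------------
    # per-feature inter-individual dispersion: untargeted serum panels show
    # heterogeneous, large between-subject spreads.  Folded-Gaussian
    # multipliers give that dispersion without displacing the pooled-QC
    # level (arithmetic mean) far above the study median.
    cv_lo, cv_hi = design.biological_cv_range
    bio_sd = rng.uniform(cv_lo, cv_hi, p)

    lo, hi = design.timepoints_per_patient
    sample_rows: list[dict] = []
    clinical_rows: list[dict] = []
    true_log2: list[np.ndarray] = []  # per-sample true log2 deviation from baseline
    bio_mult: list[np.ndarray] = []   # per-sample biological multiplier (patient-level)
    pid_counter = 0
    for phenotype, n_pat in design.n_patients_per_phenotype.items():
        for _ in range(n_pat):
            pid_counter += 1
            patient_id = f"P{pid_counter:03d}"
            n_t = int(rng.integers(lo, hi + 1))
            weights = generate_trajectory(phenotype, n_t, design.recovery_rate)
            blend = rng.uniform(0.3, 0.7) if phenotype == "mixed" else None
            # inter-individual variation: one multiplier per patient and
            # feature, shared by all of the patient's timepoints
            bio = np.abs(1.0 + bio_sd * rng.standard_normal(p))
            for t_idx, w in enumerate(weights):
                if phenotype == "mixed":
                    eff = w * (blend * log2_chol + (1.0 - blend) * log2_hep)
                elif phenotype == "cholestatic":
                    eff = w * log2_chol
                elif phenotype == "hepatocellular":
                    eff = w * log2_hep
                else:
                    eff = np.zeros(p)
                label = phenotype if (phenotype == "recovered" or w > 0.5) else "recovered"
                sid = f"S{len(sample_rows):03d}"
                sample_rows.append(
                    {
                        "sample_id": sid,
                        "patient_id": patient_id,
                        "role": "study",
                        "timepoint_index": t_idx,
                        "phenotype_label": label,
                        "effect_weight": w,
                    }
                )
                true_log2.append(eff)
                bio_mult.append(bio)
                clinical_rows.append(
                    {"sample_id": sid, "patient_id": patient_id, "timepoint": t_idx,
                     **_draw_chemistry(label, rng), "label": label}
                )
    n_study = len(sample_rows)
    true_signal = baseline[None, :] * 2.0 ** np.vstack(true_log2) * np.vstack(bio_mult)

    # ---------------- batch layout ----------------
    assign = rng.permutation(n_study)
    half = n_study // 2
    batch_of = np.empty(n_study, int)
    batch_of[assign[:half]] = 0
    batch_of[assign[half:]] = 1
    b1_members = np.flatnonzero(batch_of == 0)
    n_bridge = min(design.n_bridge, b1_members.size)
    bridge_idx = set(rng.choice(b1_members, n_bridge, replace=False))

    qc_true = [true_signal[batch_of == b].mean(axis=0) for b in (0, 1)]

    # per batch: interleave study samples with QCs, blanks at the end
    intervals = (design.batch1_qc_interval, design.batch2_qc_interval)
    rows: list[dict] = []
    values: list[np.ndarray] = []  # drift-free values per injection
    for b in (0, 1):
        batch_id = f"B{b + 1}"
        interval = intervals[b]
        members = [i for i in np.flatnonzero(batch_of == b)]
        if b == 1:
            members = members + sorted(bridge_idx)  # bridge re-injections
        rng.shuffle(members)
        order = 0
        injections: list[tuple[dict, np.ndarray]] = []

        def _qc_row() -> tuple[dict, np.ndarray]:
            val = qc_true[b].copy()
            if n_unst:
                val[unstable] *= _lognormal_noise(rng, qc_instability_cv, n_unst)
            return (
                {"sample_id": f"QC{b + 1}_{sum(r['role'] == 'qc' for r, _ in injections):02d}",
                 "patient_id": "", "role": "qc", "timepoint_index": -1,
                 "phenotype_label": "unknown", "effect_weight": np.nan},
                val,
            )

        injections.append(_qc_row())
        for k, idx in enumerate(members):
            meta = dict(sample_rows[idx])
            meta["role"] = "bridge" if idx in bridge_idx else "study"
            injections.append((meta, true_signal[idx]))
            if (k + 1) % interval == 0:
                injections.append(_qc_row())
        if injections[-1][0]["role"] != "qc":
            injections.append(_qc_row())
        for j in range(design.n_blanks_per_batch[b]):
            blank = baseline * rng.uniform(0.001, 0.01, p)
            blank[contaminant] = baseline[contaminant] * rng.uniform(0.8, 1.2, n_cont)
            injections.append(
                ({"sample_id": f"BL{b + 1}_{j:02d}", "patient_id": "", "role": "blank",
                  "timepoint_index": -1, "phenotype_label": "unknown",
                  "effect_weight": np.nan}, blank)
            )

        g = _drift_curves(drift, p, len(injections), rng)  # (features, orders)
        for o, (meta, val) in enumerate(injections):
            meta = dict(meta)
            meta["injection_order"] = o + 1
            meta["batch_id"] = batch_id
            rows.append(meta)
            drifted = val * g[:, o]
            values.append(drifted * _lognormal_noise(rng, noise_cv, p))
        del injections

    samples = pd.DataFrame(rows)[
        ["sample_id", "patient_id", "injection_order", "batch_id", "role",
         "timepoint_index", "phenotype_label", "effect_weight"]
    ]
    pm = PeakMatrix(samples, features, np.vstack(values))
    pm.log(
        f"generate_study: seed={design.seed} n_study={n_study} n_features={p} "
        f"drift={drift.family}/{drift.amplitude} noise_cv={noise_cv}"
    )
    clinical = pd.DataFrame(clinical_rows)
    return pm, clinical


def generate_two_mode_study(
    design: StudyDesign, **kwargs
) -> tuple[PeakMatrix, PeakMatrix, pd.DataFrame]:
    """Generate one study and split its feature panel by ESI mode.

    Convenience for exercising mode-combination: both returned matrices
    share the same injections and clinical table.
    """
    pm, clinical = generate_study(design, **kwargs)
    pos = pm.subset(feature_mask=(pm.features["esi_mode"] == "positive").to_numpy())
    neg = pm.subset(feature_mask=(pm.features["esi_mode"] == "negative").to_numpy())
    return pos, neg, clinical


def small_design(seed: int = 0, **overrides) -> StudyDesign:
    """A reduced design for fast tests: ~24 patients, 60 features."""
    base = StudyDesign(
        n_patients_per_phenotype={
            "cholestatic": 7, "hepatocellular": 7, "recovered": 7, "mixed": 3
        },
        n_features=60,
        n_bridge=8,
        seed=seed,
    )
    return replace(base, **overrides) if overrides else base
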