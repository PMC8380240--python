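"""Peak-table data model and delimited-text I/O.

A :class:`PeakMatrix` is the single currency flowing through the pipeline:
a samples x features intensity matrix (arbitrary units) together with one
metadata table per axis and an append-only provenance log.  Files are
tab-separated UTF-8 text, samples as rows, features as columns.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_ROLES = frozenset({"study", "qc", "blank", "bridge"})
PHENOTYPES = frozenset({"cholestatic", "hepatocellular", "mixed", "recovered", "unknown"})

#: sample-metadata columns that must always be present
SAMPLE_COLUMNS = [
    "sample_id",
    "patient_id",
    "injection_order",
    "batch_id",
    "role",
    "timepoint_index",
    "phenotype_label",
]

#: feature-metadata columns that must always be present
FEATURE_COLUMNS = [
    "feature_id",
    "mz",
    "rt",
    "esi_mode",
    "annotation",
    "metabolite_class",
    "metabolite_subclass",
    "excluded_flag",
]


class PeakMatrixError(ValueError):
    """Raised on structural violations of the peak-table contract."""


@dataclass
class PeakMatrix:
    """Samples x features intensity matrix with aligned metadata.

    Parameters
    ----------
    samples : pandas.DataFrame
        One row per injected sample; must carry :data:`SAMPLE_COLUMNS`.
        Rows align positionally with the rows of ``intensities``.
    features : pandas.DataFrame
        One row per LC-MS feature; must carry :data:`FEATURE_COLUMNS` and
        unique ``feature_id`` values.
    intensities : numpy.ndarray
        Float array of shape ``(n_samples, n_features)``; NaN marks a
        missing (unintegrated) peak.
    provenance_log : list of str
        Append-only record of the transformations applied so far.
    """

    samples: pd.DataFrame
    features: pd.DataFrame
    intensities: np.ndarray
    provenance_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.features = self.features.reset_index(drop=True)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.validate()

    # ------------------------------------------------------------------ #
    # structure
    # ------------------------------------------------------------------ #
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_samples, self.n_features)

    def validate(self) -> None:
        if self.intensities.ndim != 2:
            raise PeakMatrixError("intensity matrix must be 2-D")
        n_s, n_f = self.intensities.shape
        if n_s != len(self.samples):
            raise PeakMatrixError(
                f"sample axis mismatch: matrix has {n_s} rows but sample "
                f"metadata lists {len(self.samples)} samples"
            )
        if n_f != len(self.features):
            raise PeakMatrixError(
                f"feature axis mismatch: matrix has {n_f} columns but feature "
                f"metadata lists {len(self.features)} features"
            )
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise PeakMatrixError(f"sample metadata lacks columns: {missing}")
        missing = [c for c in FEATURE_COLUMNS if c not in self.features.columns]
        if missing:
            raise PeakMatrixError(f"feature metadata lacks columns: {missing}")
        if self.features["feature_id"].duplicated().any():
            dup = self.features["feature_id"][self.features["feature_id"].duplicated()]
            raise PeakMatrixError(f"duplicate feature_id: {sorted(set(dup))}")
        bad_roles = set(self.samples["role"]) - SAMPLE_ROLES
        if bad_roles:
            raise PeakMatrixError(f"unknown sample roles: {sorted(bad_roles)}")
        # injection order unique within a batch; sample_id unique within a batch
        for batch, grp in self.samples.groupby("batch_id"):
            if grp["injection_order"].duplicated().any():
                raise PeakMatrixError(f"duplicate injection_order in batch {batch!r}")
            if grp["sample_id"].duplicated().any():
                dup = grp["sample_id"][grp["sample_id"].duplicated()]
                raise PeakMatrixError(
                    f"duplicate sample_id within batch {batch!r}: {sorted(set(dup))}"
                )
        finite = self.intensities[np.isfinite(self.intensities)]
        if finite.size and (finite < 0).any():
            raise PeakMatrixError("negative intensities are not permitted")

    # ------------------------------------------------------------------ #
    # convenience masks and accessors
    # ------------------------------------------------------------------ #
    @property
    def study_mask(self) -> np.ndarray:
        """Boolean mask of biological study samples (bridge replicates count)."""
        return self.samples["role"].isin(["study", "bridge"]).to_numpy()

    @property
    def qc_mask(self) -> np.ndarray:
        return (self.samples["role"] == "qc").to_numpy()

    @property
    def blank_mask(self) -> np.ndarray:
        return (self.samples["role"] == "blank").to_numpy()

    def log(self, message: str) -> None:
        """Append one entry to the provenance log."""
        self.provenance_log.append(message)

    def copy(self) -> "PeakMatrix":
        return PeakMatrix(
            self.samples.copy(),
            self.features.copy(),
            self.intensities.copy(),
            list(self.provenance_log),
        )

    def subset(
        self,
        sample_mask: np.ndarray | None = None,
        feature_mask: np.ndarray | None = None,
        note: str | None = None,
    ) -> "PeakMatrix":
        """Return a new PeakMatrix restricted to the given rows/columns."""
        smask = np.ones(self.n_samples, bool) if sample_mask is None else np.asarray(sample_mask)
        fmask = np.ones(self.n_features, bool) if feature_mask is None else np.asarray(feature_mask)
        out = PeakMatrix(
            self.samples.loc[smask].copy(),
            self.features.loc[fmask].copy(),
            self.intensities[np.ix_(smask, fmask)],
            list(self.provenance_log),
        )
        if note:
            out.log(note)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Intensities as a DataFrame indexed by (batch_id, sample_id)."""
        idx = pd.MultiIndex.from_frame(self.samples[["batch_id", "sample_id"]])
        return pd.DataFrame(self.intensities, index=idx, columns=self.features["feature_id"].to_numpy())


# ---------------------------------------------------------------------- #
# I/O
# ---------------------------------------------------------------------- #
_MATRIX_FILE = "intensities.tsv"
_SAMPLE_FILE = "samples.tsv"
_FEATURE_FILE = "features.tsv"
_LOG_FILE = "provenance.txt"


def write_peak_table(pm: PeakMatrix, out_dir: str) -> dict[str, str]:
    """Write matrix, both metadata tables and the provenance log as TSV/text.

    Returns a dict of the four file paths keyed by
    ``{"intensities", "samples", "features", "provenance"}``.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "intensities": os.path.join(out_dir, _MATRIX_FILE),
        "samples": os.path.join(out_dir, _SAMPLE_FILE),
        "features": os.path.join(out_dir, _FEATURE_FILE),
        "provenance": os.path.join(out_dir, _LOG_FILE),
    }
    mat = pd.DataFrame(pm.intensities, columns=pm.features["feature_id"].to_numpy())
    mat.insert(0, "sample_id", pm.samples["sample_id"].to_numpy())
    mat.insert(1, "batch_id", pm.samples["batch_id"].to_numpy())
    mat.to_csv(paths["intensities"], sep="\t", index=False, float_format="%.10g")
    pm.samples.to_csv(paths["samples"], sep="\t", index=False)
    pm.features.to_csv(paths["features"], sep="\t", index=False)
    with open(paths["provenance"], "w", encoding="utf-8") as fh:
        for line in pm.provenance_log:
            fh.write(line + "\n")
    return paths


def read_peak_table(
    path: str,
    sample_meta_path: str | None = None,
    feature_meta_path: str | None = None,
) -> PeakMatrix:
    """Read a peak table written by :func:`write_peak_table`.

    ``path`` may be the run directory or the intensity-matrix file itself;
    the metadata paths default to the sibling files of the standard layout.
    Empty intensity cells become NaN (missing) and are reported in the log.
    """
    if os.path.isdir(path):
        base = path
        path = os.path.join(base, _MATRIX_FILE)
    else:
        base = os.path.dirname(path)
    sample_meta_path = sample_meta_path or os.path.join(base, _SAMPLE_FILE)
    feature_meta_path = feature_meta_path or os.path.join(base, _FEATURE_FILE)
    for p in (path, sample_meta_path, feature_meta_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)

    mat = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "batch_id": str})
    samples = pd.read_csv(
        sample_meta_path, sep="\t", dtype={"sample_id": str, "patient_id": str, "batch_id": str}
    )
    features = pd.read_csv(feature_meta_path, sep="\t", dtype={"feature_id": str})
    samples["patient_id"] = samples["patient_id"].fillna("")
    for col in ("annotation", "metabolite_class", "metabolite_subclass"):
        if col in features.columns:
            features[col] = features[col].fillna("")

    values = mat.drop(columns=["sample_id", "batch_id"], errors="ignore")
    if len(values) != len(samples):
        raise PeakMatrixError(
            f"sample axis mismatch: matrix has {len(values)} rows but sample "
            f"metadata lists {len(samples)} samples"
        )
    if values.shape[1] != len(features):
        raise PeakMatrixError(
            f"feature axis mismatch: matrix has {values.shape[1]} columns but "
            f"feature metadata lists {len(features)} features"
        )
    if list(values.columns) != list(features["feature_id"]):
        raise PeakMatrixError("feature_id order differs between matrix and metadata")
    if "sample_id" in mat.columns and not (
        mat["sample_id"].to_numpy() == samples["sample_id"].to_numpy()
    ).all():
        raise PeakMatrixError("sample_id order differs between matrix and metadata")

    log_path = os.path.join(base, _LOG_FILE)
    log: list[str] = []
    if os.path.exists(log_path):
        with open(log_path, encoding="utf-8") as fh:
            log = [line.rstrip("\n") for line in fh]
    intensities = values.to_numpy(dtype=float)
    n_missing = int(np.isnan(intensities).sum())
    pm = PeakMatrix(samples, features, intensities, log)
    if n_missing:
        pm.log(f"read: {n_missing} empty intensity cells read as missing")
    return pm


def combine_modes(pm_pos: PeakMatrix, pm_neg: PeakMatrix) -> PeakMatrix:
    """Feature-wise concatenation of the two ionization modes.

    Both inputs must contain the same set of study sample_ids (sample_ids
    must be unique per input, i.e. modes are combined after bridge
    duplicates have been resolved).  Sample order of ``pm_pos`` is kept and
    feature_ids are prefixed with their ESI mode.
    """
    for name, pm in (("positive", pm_pos), ("negative", pm_neg)):
        if pm.samples["sample_id"].duplicated().any():
            raise PeakMatrixError(
                f"{name}-mode matrix has duplicate sample_ids; resolve bridge "
                "replicates before combining modes"
            )
    ids_pos = set(pm_pos.samples.loc[pm_pos.study_mask, "sample_id"])
    ids_neg = set(pm_neg.samples.loc[pm_neg.study_mask, "sample_id"])
    if ids_pos != ids_neg:
        only_pos = sorted(ids_pos - ids_neg)
        only_neg = sorted(ids_neg - ids_pos)
        raise PeakMatrixError(
            "study sample sets differ between modes: "
            f"only in positive {only_pos}, only in negative {only_neg}"
        )

    keep = pm_pos.samples["sample_id"].isin(set(pm_neg.samples["sample_id"])).to_numpy()
    samples = pm_pos.samples.loc[keep].reset_index(drop=True)
    order = pm_neg.samples.set_index("sample_id").index
    neg_row = {sid: i for i, sid in enumerate(order)}
    neg_idx = [neg_row[sid] for sid in samples["sample_id"]]

    def _prefixed(pm: PeakMatrix, tag: str) -> pd.DataFrame:
        feats = pm.features.copy()
        feats["feature_id"] = [f"{tag}_{fid}" for fid in feats["feature_id"]]
        return feats

    features = pd.concat(
        [_prefixed(pm_pos, "pos"), _prefixed(pm_neg, "neg")], ignore_index=True
    )
    intensities = np.hstack(
        [pm_pos.intensities[keep, :], pm_neg.intensities[neg_idx, :]]
    )
    out = PeakMatrix(samples, features, intensities, list(pm_pos.provenance_log))
    out.log(
        f"combine_modes: {pm_pos.n_features} positive + {pm_neg.n_features} "
        f"negative features over {out.n_samples} shared samples"
    )
    return out


def split_modes(pm: PeakMatrix) -> tuple[PeakMatrix, PeakMatrix]:
    """Inverse of :func:`combine_modes`: split by feature_id mode prefix."""
    out = []
    for tag in ("pos", "neg"):
        mask = pm.features["feature_id"].str.startswith(tag + "_").to_numpy()
        sub = pm.subset(feature_mask=mask)
        sub.features["feature_id"] = [
            fid[len(tag) + 1 :] for fid in sub.features["feature_id"]
        ]
        out.append(sub)
    return out[0], out[1]
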