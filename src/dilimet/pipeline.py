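"""End-to-end orchestration, configuration and the command-line interface.

``run_all`` chains the full analysis: per-mode QC-SVRC drift correction,
D-ratio* filtering, between-batch bridge scaling, blank filtering, mode
combination, group-intensity filtering, clinical R-scores, PCA overview,
univariate screening, the one-vs-rest PLS-DA suite and the ternary
phenotype mapping.  Every intermediate table is written as TSV, together
with a machine-readable run manifest and a human-readable log.

A single run seed fans out to per-stage child seeds through a
counter-based scheme so any stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import sys
import zlib
from dataclasses import dataclass, field

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical import ALP_UNL_DEFAULT, ALT_UNL_DEFAULT, annotate_clinical_table
from .peak_matrix import PeakMatrix, combine_modes, read_peak_table, write_peak_table
from .plsda import OneVsRestPLSDA
from .preprocess import (
    BLANK_FACTOR_DEFAULT,
    D_RATIO_MAX_DEFAULT,
    EPS_RANGE_DEFAULT,
    GAMMA_RANGE_DEFAULT,
    INTENSITY_THRESHOLD_DEFAULT,
    N_EPS_DEFAULT,
    N_GAMMA_DEFAULT,
    between_batch_scale,
    blank_filter,
    correct_drift,
    d_ratio_filter,
    group_intensity_filter,
    qc_metrics,
)
from .stats import differential_features, intersect_counts, pca_overview
from .synthetic import DriftSpec, StudyDesign, generate_study
from .ternary import build_trajectories, plot_simplex, ternary_table

logger = logging.getLogger("dilimet")


@dataclass
class PipelineConfig:
    """All pipeline thresholds and grids in one place."""

    eps_range: tuple[float, float] = EPS_RANGE_DEFAULT
    gamma_range: tuple[float, float] = GAMMA_RANGE_DEFAULT
    n_eps: int = N_EPS_DEFAULT
    n_gamma: int = N_GAMMA_DEFAULT
    d_ratio_max: float = D_RATIO_MAX_DEFAULT
    blank_factor: float = BLANK_FACTOR_DEFAULT
    intensity_threshold: float = INTENSITY_THRESHOLD_DEFAULT
    alpha: float = 0.05
    vip_threshold: float = 1.0
    k_outer: int = 7
    k_inner: int = 5
    n_perm: int = 100
    max_lv: int = 10
    alt_unl: float = ALT_UNL_DEFAULT
    alp_unl: float = ALP_UNL_DEFAULT
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("d_ratio_max", "blank_factor", "intensity_threshold",
                     "alpha", "vip_threshold", "alt_unl", "alp_unl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("eps_range", "gamma_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["eps_range"] = list(d["eps_range"])
        d["gamma_range"] = list(d["gamma_range"])
        return d


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31) from the run seed."""
    ss = np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _setup_logging(out_dir: str) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(os.path.join(out_dir, "log.txt"), mode="w"),
    ):
        handler.setFormatter(fmt)
        logger.addHandler(handler)


def _preprocess_one_mode(pm: PeakMatrix, config: PipelineConfig, tag: str) -> PeakMatrix:
    logger.info("[%s] QC-SVRC drift correction (%d features)", tag, pm.n_features)
    corrected, _ = correct_drift(
        pm, eps_range=config.eps_range, gamma_range=config.gamma_range,
        n_eps=config.n_eps, n_gamma=config.n_gamma,
    )
    corrected, removed = d_ratio_filter(corrected, config.d_ratio_max)
    logger.info("[%s] D-ratio* filter removed %d features", tag, len(removed))
    if corrected.samples["batch_id"].nunique() > 1:
        corrected = between_batch_scale(corrected)
        logger.info("[%s] between-batch bridge scaling applied", tag)
    corrected, removed = blank_filter(corrected, config.blank_factor)
    logger.info("[%s] blank filter removed %d features", tag, len(removed))
    return corrected


def run_all(
    config: PipelineConfig,
    peak_matrices: list[PeakMatrix],
    clinical: pd.DataFrame,
    out_dir: str,
) -> dict:
    """Execute the full pipeline and write all outputs to ``out_dir``.

    ``peak_matrices`` holds one matrix per ionization mode (one or two
    entries).  Returns a dict with the in-memory results keyed by stage.
    """
    os.makedirs(out_dir, exist_ok=True)
    _setup_logging(out_dir)
    results: dict = {}
    stage = "start"
    try:
        # ---- clinical labels -------------------------------------------------
        stage = "clinical"
        clin = annotate_clinical_table(clinical, config.alt_unl, config.alp_unl)
        clin.to_csv(os.path.join(out_dir, "clinical_annotated.tsv"), sep="\t", index=False)
        label_of = dict(zip(clin["sample_id"], clin["phenotype"]))
        results["clinical"] = clin
        logger.info("clinical: %d records annotated with R-score and phenotype", len(clin))

        # ---- per-mode preprocessing -----------------------------------------
        stage = "preprocess"
        qc_before = [qc_metrics(pm) for pm in peak_matrices]
        processed = [
            _preprocess_one_mode(pm, config, f"mode{i + 1}")
            for i, pm in enumerate(peak_matrices)
        ]
        stage = "combine_modes"
        pm = processed[0] if len(processed) == 1 else combine_modes(*processed)
        # rule-based labels override generator labels where clinical data exist
        relabel = pm.samples["sample_id"].map(label_of)
        has = relabel.notna() & pm.samples["role"].isin(["study", "bridge"])
        pm.samples.loc[has, "phenotype_label"] = relabel[has]
        stage = "group_intensity_filter"
        pm = group_intensity_filter(pm, threshold=config.intensity_threshold)
        write_peak_table(pm, os.path.join(out_dir, "peak_table_processed"))
        qc_after = qc_metrics(pm)
        pd.concat(qc_before, keys=range(len(qc_before))).to_csv(
            os.path.join(out_dir, "qc_metrics_before.tsv"), sep="\t", index=False
        )
        qc_after.to_csv(os.path.join(out_dir, "qc_metrics_after.tsv"), sep="\t", index=False)
        results["peak_matrix"] = pm
        logger.info("preprocessing done: %d samples x %d features retained", *pm.shape)

        # ---- PCA overview ----------------------------------------------------
        stage = "pca"
        study_pm = pm.subset(sample_mask=pm.study_mask, note="study samples only")
        overview = pca_overview(study_pm, k=4)
        overview["scores"].to_csv(os.path.join(out_dir, "pca_scores.tsv"), sep="\t")
        overview["loadings"].to_csv(os.path.join(out_dir, "pca_loadings.tsv"), sep="\t")
        results["pca"] = overview
        logger.info(
            "PCA: first %d components explain %.2f%% of variance",
            len(overview["explained_pct"]), float(np.sum(overview["explained_pct"])),
        )

        # ---- univariate screening -------------------------------------------
        stage = "screening"
        comparisons = [
            ("hepatocellular", "cholestatic"),
            ("hepatocellular", "recovered"),
            ("cholestatic", "recovered"),
        ]
        sig_sets = {}
        for a, b in comparisons:
            sig, table = differential_features(study_pm, a, b, alpha=config.alpha)
            name = f"{a}_vs_{b}"
            sig_sets[name] = sig
            table.to_csv(os.path.join(out_dir, f"screen_{name}.tsv"), sep="\t", index=False)
            logger.info("screening %s: %d significant features", name, len(sig))
        cells = intersect_counts(sig_sets)
        cells.to_csv(os.path.join(out_dir, "screen_intersections.tsv"), sep="\t", index=False)
        results["screening"] = {"sets": sig_sets, "intersections": cells}

        # ---- one-vs-rest PLS-DA ---------------------------------------------
        stage = "plsda"
        model = OneVsRestPLSDA.from_peak_matrix(study_pm)
        fit = model.fit(
            k_outer=config.k_outer, k_inner=config.k_inner,
            n_perm=config.n_perm, seed=stage_seed(config.seed, "plsda"),
            max_lv=config.max_lv, vip_threshold=config.vip_threshold,
        )
        fit.predictions.to_csv(os.path.join(out_dir, "predictions.tsv"), sep="\t")
        fit.vip_scores.to_csv(os.path.join(out_dir, "vip_scores.tsv"), sep="\t")
        fit.vip_intersections.to_csv(
            os.path.join(out_dir, "vip_intersections.tsv"), sep="\t", index=False
        )
        with open(os.path.join(out_dir, "model_summary.json"), "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "aurocs": fit.aurocs,
                    "permutation_p": fit.permutation_p,
                    "n_lv": {c: d["n_lv"] for c, d in fit.per_class.items()},
                    "n_vip_features": {c: len(s) for c, s in fit.vip_sets.items()},
                    "pls2_n_features": len(fit.pls2_features),
                },
                fh, indent=2,
            )
        with open(os.path.join(out_dir, "model_summary.txt"), "w", encoding="utf-8") as fh:
            fh.write(fit.summary() + "\n")
        results["plsda"] = fit
        logger.info("PLS-DA: AUROCs %s", {k: round(v, 3) for k, v in fit.aurocs.items()})

        # ---- ternary mapping -------------------------------------------------
        stage = "ternary"
        coords = fit.to_ternary()
        full = coords.join(fit.predictions[["patient_id", "label"]])
        full.to_csv(os.path.join(out_dir, "ternary.tsv"), sep="\t")
        meta = study_pm.samples[["sample_id", "patient_id", "timepoint_index"]]
        trajectories = build_trajectories(fit.predictions, meta)
        plot_simplex(full, path=os.path.join(out_dir, "ternary.svg"), trajectories=True)
        results["ternary"] = {"coordinates": full, "trajectories": trajectories}
        logger.info("ternary: %d samples mapped, %d patient trajectories",
                    len(full), len(trajectories))

        # ---- manifest --------------------------------------------------------
        stage = "manifest"
        manifest = {
            "package": "dilimet",
            "version": __version__,
            "config": config.to_dict(),
            "inputs": {
                "n_modes": len(peak_matrices),
                "shapes": [list(p.shape) for p in peak_matrices],
                "n_clinical_records": len(clinical),
            },
        }
        with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2)
        results["manifest"] = manifest
    except Exception:
        logger.exception("pipeline aborted at stage %r", stage)
        raise RuntimeError(f"pipeline aborted at stage {stage!r}") from sys.exc_info()[1]
    return results


def simulate(
    out_dir: str,
    design: StudyDesign | None = None,
    drift: DriftSpec | None = None,
    noise_cv: float = 0.1,
    seed: int = 0,
) -> dict[str, str]:
    """Generate a synthetic study and write it ready-to-run to disk."""
    if design is None:
        design = StudyDesign(seed=stage_seed(seed, "simulate"))
    pm, clinical = generate_study(design, drift=drift, noise_cv=noise_cv)
    paths = write_peak_table(pm, out_dir)
    clin_path = os.path.join(out_dir, "clinical.tsv")
    clinical.to_csv(clin_path, sep="\t", index=False)
    paths["clinical"] = clin_path
    return paths


def load_study(study_dir: str) -> tuple[PeakMatrix, pd.DataFrame]:
    """Read a study directory written by :func:`simulate`."""
    pm = read_peak_table(study_dir)
    clinical = pd.read_csv(
        os.path.join(study_dir, "clinical.tsv"), sep="\t",
        dtype={"sample_id": str, "patient_id": str},
    )
    return pm, clinical


# ---------------------------------------------------------------------- #
# command-line interface (thin wrappers over the library)
# ---------------------------------------------------------------------- #
@click.group()
def cli() -> None:
    """DILI serum-metabolomics phenotyping pipeline."""


@cli.command("simulate")
@click.option("--out", "out_dir", required=True, type=click.Path())
@click.option("--seed", default=0, show_default=True, type=int)
@click.option("--n-features", default=300, show_default=True, type=int)
@click.option("--noise-cv", default=0.1, show_default=True, type=float)
@click.option("--drift-amplitude", default=0.3, show_default=True, type=float)
def cli_simulate(out_dir, seed, n_features, noise_cv, drift_amplitude) -> None:
    """Write a synthetic study (peak table + clinical table)."""
    design = StudyDesign(n_features=n_features, seed=stage_seed(seed, "simulate"))
    drift = DriftSpec(amplitude=drift_amplitude)
    simulate(out_dir, design=design, drift=drift, noise_cv=noise_cv, seed=seed)
    click.echo(f"synthetic study written to {out_dir}")


@cli.command("rscore")
@click.option("--clinical", "clin_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_path", required=True, type=click.Path())
@click.option("--alt-unl", default=ALT_UNL_DEFAULT, show_default=True, type=float)
@click.option("--alp-unl", default=ALP_UNL_DEFAULT, show_default=True, type=float)
def cli_rscore(clin_path, out_path, alt_unl, alp_unl) -> None:
    """Append r_score and phenotype columns to a clinical table."""
    table = pd.read_csv(clin_path, sep="\t")
    annotate_clinical_table(table, alt_unl, alp_unl).to_csv(out_path, sep="\t", index=False)
    click.echo(f"annotated clinical table written to {out_path}")


@cli.command("run-all")
@click.option("--study", "study_dir", required=True, type=click.Path(exists=True))
@click.option("--out", "out_dir", required=True, type=click.Path())
@click.option("--config", "config_path", default=None, type=click.Path(exists=True))
@click.option("--seed", default=None, type=int, help="overrides the config seed")
@click.option("--n-perm", default=None, type=int, help="overrides the config n_perm")
def cli_run_all(study_dir, out_dir, config_path, seed, n_perm) -> None:
    """Run the full pipeline on a study directory."""
    config = PipelineConfig.from_file(config_path) if config_path else PipelineConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    if n_perm is not None:
        config = dataclasses.replace(config, n_perm=n_perm)
    pm, clinical = load_study(study_dir)
    run_all(config, [pm], clinical, out_dir)
    click.echo(f"pipeline outputs written to {out_dir}")


@cli.command("preprocess")
@click.option("--study", "study_dir", required=True, type=click.Path(exists=True))
@click.option("--out", "out_dir", required=True, type=click.Path())
@click.option("--config", "config_path", default=None, type=click.Path(exists=True))
def cli_preprocess(study_dir, out_dir, config_path) -> None:
    """Drift-correct, filter and scale a peak table; write the result."""
    config = PipelineConfig.from_file(config_path) if config_path else PipelineConfig()
    pm = read_peak_table(study_dir)
    os.makedirs(out_dir, exist_ok=True)
    _setup_logging(out_dir)
    out = _preprocess_one_mode(pm, config, "mode1")
    out = group_intensity_filter(out, threshold=config.intensity_threshold)
    write_peak_table(out, os.path.join(out_dir, "peak_table_processed"))
    qc_metrics(out).to_csv(os.path.join(out_dir, "qc_metrics_after.tsv"), sep="\t", index=False)
    click.echo(f"processed peak table written to {out_dir}")


@cli.command("screen")
@click.option("--study", "study_dir", required=True, type=click.Path(exists=True),
              help="directory holding a processed peak table")
@click.option("--out", "out_dir", required=True, type=click.Path())
@click.option("--alpha", default=0.05, show_default=True, type=float)
def cli_screen(study_dir, out_dir, alpha) -> None:
    """Univariate Welch-t / BH-FDR screening between phenotype groups."""
    pm = read_peak_table(study_dir)
    os.makedirs(out_dir, exist_ok=True)
    study_pm = pm.subset(sample_mask=pm.study_mask)
    for a, b in [("hepatocellular", "cholestatic"), ("hepatocellular", "recovered"),
                 ("cholestatic", "recovered")]:
        sig, table = differential_features(study_pm, a, b, alpha=alpha)
        table.to_csv(os.path.join(out_dir, f"screen_{a}_vs_{b}.tsv"), sep="\t", index=False)
        click.echo(f"{a} vs {b}: {len(sig)} significant features")


@cli.command("plsda")
@click.option("--study", "study_dir", required=True, type=click.Path(exists=True))
@click.option("--out", "out_dir", required=True, type=click.Path())
@click.option("--seed", default=0, show_default=True, type=int)
@click.option("--n-perm", default=100, show_default=True, type=int)
def cli_plsda(study_dir, out_dir, seed, n_perm) -> None:
    """Fit the one-vs-rest PLS-DA suite on a processed peak table."""
    pm = read_peak_table(study_dir)
    os.makedirs(out_dir, exist_ok=True)
    fit = OneVsRestPLSDA.from_peak_matrix(pm).fit(n_perm=n_perm, seed=seed)
    fit.predictions.to_csv(os.path.join(out_dir, "predictions.tsv"), sep="\t")
    fit.vip_scores.to_csv(os.path.join(out_dir, "vip_scores.tsv"), sep="\t")
    click.echo(fit.summary())


@cli.command("ternary")
@click.option("--predictions", "pred_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_dir", required=True, type=click.Path())
def cli_ternary(pred_path, out_dir) -> None:
    """Map a prediction table onto the phenotype simplex and plot it."""
    pred = pd.read_csv(pred_path, sep="\t", index_col=0)
    os.makedirs(out_dir, exist_ok=True)
    coords = ternary_table(pred)
    if "label" in pred.columns:
        coords = coords.join(pred[["label"]])
    coords.to_csv(os.path.join(out_dir, "ternary.tsv"), sep="\t")
    plot_simplex(coords, path=os.path.join(out_dir, "ternary.svg"))
    click.echo(f"ternary coordinates written to {out_dir}")
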