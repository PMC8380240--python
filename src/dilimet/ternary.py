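"""Phenotype simplex: constrained predictions, ternary coordinates,
Cartesian embedding, recovery distances and longitudinal trajectories.

The three one-vs-rest predicted y values of a sample are clipped to
[0, 1] and normalized by their sum, giving the (cholestatic,
hepatocellular, recovered) shares of the sample on the 2-simplex.  The
simplex is embedded as an equilateral triangle of side 1 with the
cholestatic vertex bottom-left, hepatocellular bottom-right and recovered
on top; the Euclidean distance to the recovered vertex is an intuitive,
dimensionless ([0, 1]) measure of how far a sample is from the recovered
metabolome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: triangle vertices (side length 1): cholestatic, hepatocellular, recovered
VERTICES = {
    "cholestatic": (0.0, 0.0),
    "hepatocellular": (1.0, 0.0),
    "recovered": (0.5, math.sqrt(3.0) / 2.0),
}

_PLOT_COLORS = {
    "cholestatic": "green",
    "hepatocellular": "orange",
    "mixed": "grey",
    "recovered": "tab:blue",
    "unknown": "black",
    "unclassifiable": "black",
}


@dataclass
class TernaryCoordinate:
    """Normalized (cholestatic, hepatocellular, recovered) shares."""

    c: float
    h: float
    r: float
    indeterminate: bool = False

    def __post_init__(self) -> None:
        total = self.c + self.h + self.r
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"shares must sum to 1, got {total}")
        for v in (self.c, self.h, self.r):
            if not -1e-12 <= v <= 1 + 1e-12:
                raise ValueError("shares must lie in [0, 1]")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.c, self.h, self.r)


@dataclass
class Trajectory:
    """Time-ordered simplex coordinates of one patient."""

    patient_id: str
    timepoints: list[int]
    coordinates: list[TernaryCoordinate]
    labels: list[str]
    recovery_distances: list[float]


def constrain(y_hat: float) -> float:
    """Clip an unbounded PLS predicted y to [0, 1]."""
    return float(min(1.0, max(0.0, y_hat)))


def to_ternary(y_c: float, y_h: float, y_r: float) -> TernaryCoordinate:
    """Clip the three predictions to [0, 1] and normalize by their sum.

    The all-zero case has no defined direction on the simplex; it maps to
    the centroid with an explicit indeterminate flag so downstream plots
    never silently drop samples.
    """
    c, h, r = constrain(y_c), constrain(y_h), constrain(y_r)
    total = c + h + r
    if total == 0.0:
        return TernaryCoordinate(1 / 3, 1 / 3, 1 / 3, indeterminate=True)
    return TernaryCoordinate(c / total, h / total, r / total)


def embed(coord: TernaryCoordinate) -> tuple[float, float]:
    """Barycentric embedding into the unit-side equilateral triangle."""
    vc, vh, vr = (VERTICES[k] for k in ("cholestatic", "hepatocellular", "recovered"))
    x = coord.c * vc[0] + coord.h * vh[0] + coord.r * vr[0]
    y = coord.c * vc[1] + coord.h * vh[1] + coord.r * vr[1]
    return (x, y)


def recovery_distance(coord: TernaryCoordinate) -> float:
    """Euclidean distance from the sample to the recovered vertex."""
    x, y = embed(coord)
    vx, vy = VERTICES["recovered"]
    return math.hypot(x - vx, y - vy)


def ternary_table(predictions: pd.DataFrame) -> pd.DataFrame:
    """Per-sample simplex coordinates from a one-vs-rest prediction table.

    ``predictions`` must carry columns ``y_cholestatic``,
    ``y_hepatocellular`` and ``y_recovered`` (unconstrained).  Returns a
    DataFrame (same index) with shares c/h/r, Cartesian x/y, the recovery
    distance and the indeterminate flag.
    """
    rows = []
    for _, row in predictions.iterrows():
        coord = to_ternary(row["y_cholestatic"], row["y_hepatocellular"], row["y_recovered"])
        x, y = embed(coord)
        rows.append(
            {
                "c": coord.c, "h": coord.h, "r": coord.r,
                "x": x, "y": y,
                "recovery_distance": recovery_distance(coord),
                "indeterminate": coord.indeterminate,
            }
        )
    return pd.DataFrame(rows, index=predictions.index)


def build_trajectories(
    predictions: pd.DataFrame, sample_meta: pd.DataFrame
) -> list[Trajectory]:
    """Per-patient time-ordered trajectories with recovery distances.

    ``sample_meta`` must carry ``sample_id``, ``patient_id`` and
    ``timepoint_index`` for the predicted samples; duplicate
    (patient, timepoint) pairs are an error.
    """
    coords = ternary_table(predictions)
    meta = sample_meta.set_index("sample_id").loc[coords.index]
    if meta.duplicated(subset=None).any() and meta.index.duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    labels = (
        predictions["label"]
        if "label" in predictions.columns
        else meta.get("phenotype_label", pd.Series("unknown", index=meta.index))
    )
    out: list[Trajectory] = []
    for pid, grp in meta.groupby("patient_id", sort=True):
        if not pid:
            continue
        if grp["timepoint_index"].duplicated().any():
            raise ValueError(f"duplicate (patient, timepoint) for patient {pid!r}")
        order = grp.sort_values("timepoint_index")
        tps, cs, ls, ds = [], [], [], []
        for sid, row in order.iterrows():
            coord = TernaryCoordinate(
                coords.at[sid, "c"], coords.at[sid, "h"], coords.at[sid, "r"],
                bool(coords.at[sid, "indeterminate"]),
            )
            tps.append(int(row["timepoint_index"]))
            cs.append(coord)
            ls.append(str(labels.loc[sid]))
            ds.append(coords.at[sid, "recovery_distance"])
        out.append(Trajectory(str(pid), tps, cs, ls, ds))
    return out


def plot_simplex(
    table: pd.DataFrame,
    path: str | None = None,
    trajectories: bool = False,
    ax=None,
):
    """Plot samples (and optional per-patient trajectories) on the simplex.

    ``table`` is a ternary table joined with ``label`` (for colors) and,
    if trajectories are requested, ``patient_id``.  Returns the axes.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5.5))
    tri = np.array(
        [VERTICES["cholestatic"], VERTICES["hepatocellular"], VERTICES["recovered"],
         VERTICES["cholestatic"]]
    )
    ax.plot(tri[:, 0], tri[:, 1], color="black", lw=1)
    for name, (vx, vy) in VERTICES.items():
        dy = 0.04 if name == "recovered" else -0.06
        ax.text(vx, vy + dy, name, ha="center", fontsize=9)
    labels = table.get("label", pd.Series("unknown", index=table.index))
    for lab in labels.unique():
        sel = labels == lab
        ax.scatter(
            table.loc[sel, "x"], table.loc[sel, "y"],
            s=18, alpha=0.8, label=str(lab),
            color=_PLOT_COLORS.get(str(lab), "black"),
        )
    if trajectories and "patient_id" in table.columns:
        for _, grp in table.groupby("patient_id"):
            if len(grp) > 1:
                ax.plot(grp["x"], grp["y"], lw=0.8, color="0.4", alpha=0.6)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.legend(loc="upper left", fontsize=8, frameon=False)
    if path:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax
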