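"""R-score and rule-based DILI phenotype classification.

The R-score compares the fold-elevation of alanine aminotransferase (ALT,
a hepatocellular enzyme) with the fold-elevation of alkaline phosphatase
(ALP, a ductal enzyme), each relative to its upper normal limit (UNL):

    R = ([ALT]/[ALT]_UNL) / ([ALP]/[ALP]_UNL)

High R means transaminase elevation dominates (hepatocellular injury);
low R means ductal enzymes dominate (cholestatic injury).  The rule set
used here is the standard clinical one: cholestatic if ALP >= 147 U/L and
R < 2, hepatocellular if ALT >= 56 U/L and R >= 5, mixed if 2 < R < 5,
recovered if ALT < 56 U/L and ALP < 147 U/L.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: default upper normal limits (U/L), consistent with the rule thresholds
ALT_UNL_DEFAULT = 56.0
ALP_UNL_DEFAULT = 147.0

LABELS = ("cholestatic", "hepatocellular", "mixed", "recovered", "unclassifiable")


@dataclass
class ClinicalRecord:
    """Per-sample liver chemistry.  Enzyme activities in U/L, bilirubin in
    mg/dL, albumin in g/dL; optional analytes may be None."""

    alt: float
    alp: float
    ast: float | None = None
    ggt: float | None = None
    total_bilirubin: float | None = None
    albumin: float | None = None
    alt_unl: float = ALT_UNL_DEFAULT
    alp_unl: float = ALP_UNL_DEFAULT

    def __post_init__(self) -> None:
        if self.alt < 0 or self.alp < 0:
            raise ValueError("enzyme activities must be non-negative")
        if self.alt_unl <= 0 or self.alp_unl <= 0:
            raise ValueError("upper normal limits must be positive")


def r_score(rec: ClinicalRecord) -> float:
    """R-score ([ALT]/[ALT]_UNL) / ([ALP]/[ALP]_UNL), unrounded.

    Raises ``ZeroDivisionError`` for ALP = 0, which signals an invalid
    laboratory record rather than a computable phenotype.
    """
    if rec.alp == 0:
        raise ZeroDivisionError("ALP = 0: invalid laboratory record")
    return (rec.alt / rec.alt_unl) / (rec.alp / rec.alp_unl)


def classify_phenotype(rec: ClinicalRecord) -> str:
    """Apply the rule-based phenotype classification.

    Rules are applied in the order recovered -> cholestatic ->
    hepatocellular -> mixed.  The printed inequalities leave two gaps which
    are resolved explicitly rather than silently: R exactly 2 with elevated
    enzymes maps to mixed, and any elevated-enzyme record matching no rule
    is labelled ``unclassifiable``.
    """
    if rec.alt < rec.alt_unl and rec.alp < rec.alp_unl:
        return "recovered"
    r = r_score(rec)
    if rec.alp >= rec.alp_unl and r < 2:
        return "cholestatic"
    if rec.alt >= rec.alt_unl and r >= 5:
        return "hepatocellular"
    if 2 <= r < 5:
        return "mixed"
    return "unclassifiable"


def annotate_clinical_table(table: pd.DataFrame,
                            alt_unl: float = ALT_UNL_DEFAULT,
                            alp_unl: float = ALP_UNL_DEFAULT) -> pd.DataFrame:
    """Append ``r_score`` and ``phenotype`` columns to a clinical table.

    The table must carry ``alt`` and ``alp`` columns (U/L).  Rows with
    ALP = 0 receive NaN / ``unclassifiable``.
    """
    out = table.copy()
    scores, labels = [], []
    for alt, alp in zip(out["alt"], out["alp"]):
        rec = ClinicalRecord(alt=float(alt), alp=float(alp),
                             alt_unl=alt_unl, alp_unl=alp_unl)
        try:
            scores.append(r_score(rec))
            labels.append(classify_phenotype(rec))
        except ZeroDivisionError:
            scores.append(float("nan"))
            labels.append("unclassifiable")
    out["r_score"] = scores
    out["phenotype"] = labels
    return out
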