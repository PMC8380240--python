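"""dilimet: serum LC-MS metabolomics phenotyping of drug-induced liver injury.

Pipeline stages: peak-table QC-SVRC drift correction and quality
filtering, univariate screening, one-vs-rest PLS-DA with subjectwise
double cross-validation, and ternary-plot integration of the constrained
class predictions for classifying and monitoring cholestatic,
hepatocellular, mixed and recovered DILI patients.
"""

__version__ = "0.1.0"

from .clinical import ClinicalRecord, classify_phenotype, r_score
from .peak_matrix import PeakMatrix, combine_modes, read_peak_table, write_peak_table
from .plsda import OneVsRestPLSDA, OneVsRestResults
from .synthetic import DriftSpec, EffectTemplate, StudyDesign, generate_study

__all__ = [
    "ClinicalRecord",
    "classify_phenotype",
    "r_score",
    "PeakMatrix",
    "read_peak_table",
    "write_peak_table",
    "combine_modes",
    "OneVsRestPLSDA",
    "OneVsRestResults",
    "StudyDesign",
    "DriftSpec",
    "EffectTemplate",
    "generate_study",
]
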