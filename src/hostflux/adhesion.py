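"""Forestomach-adhesion classification relative to a reference strain.

Adherent cell densities (log10 CFU/g) are expressed as a percentage of the
positive-control reference and classified as effective (≥ 6.9 log10, i.e.
≥ 20% of the reference), ineffective (≤ 6.6 log10, ≤ 10%), or intermediate
in the unassigned gap between the two printed thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from hostflux.errors import InputError

__all__ = [
    "AdhesionRecord",
    "relative_adherence",
    "classify_adhesion",
    "classify_table",
    "EFFECTIVE_LOG10",
    "INEFFECTIVE_LOG10",
    "REFERENCE_LOG10",
]

EFFECTIVE_LOG10 = 6.9    # ≥ this: effective adhesion (≥ 20% of reference)
INEFFECTIVE_LOG10 = 6.6  # ≤ this: ineffective adhesion (≤ 10% of reference)
REFERENCE_LOG10 = 7.6    # implied reference density (both thresholds agree)


@dataclass
class AdhesionRecord:
    strain: str
    log10_cfu_per_g: float
    reference_log10: float
    relative_percent: float
    adhesion_class: str


def relative_adherence(strain_log10: float, reference_log10: float = REFERENCE_LOG10) -> float:
    """Adherence as a percentage of the reference: 100 × 10^(strain − ref)."""
    if not (math.isfinite(strain_log10) and math.isfinite(reference_log10)):
        raise InputError("adherence values must be finite")
    return 100.0 * 10.0 ** (strain_log10 - reference_log10)


def classify_adhesion(strain_log10: float) -> str:
    """Three-class call; boundary equality goes to the adjacent definitive
    class (≥ 6.9 effective, ≤ 6.6 ineffective)."""
    if strain_log10 >= EFFECTIVE_LOG10:
        return "effective"
    if strain_log10 <= INEFFECTIVE_LOG10:
        return "ineffective"
    return "intermediate"


def classify_table(table: pd.DataFrame, value_column: str = "log10_cfu_per_g",
                   strain_column: str = "strain",
                   reference_log10: float = REFERENCE_LOG10) -> pd.DataFrame:
    """Classify a per-strain adhesion table.

    Adds relative percent, class, and a bubble-size column (area
    proportional to log-transformed relative counts, for plotting).
    """
    if value_column not in table.columns or strain_column not in table.columns:
        raise InputError("adhesion table missing required columns")
    out = table.copy()
    out["reference_log10"] = reference_log10
    out["relative_percent"] = [relative_adherence(v, reference_log10)
                               for v in out[value_column]]
    out["adhesion_class"] = [classify_adhesion(v) for v in out[value_column]]
    out["bubble_area"] = np.log10(np.maximum(out["relative_percent"], 1e-6) + 1.0)
    return out
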