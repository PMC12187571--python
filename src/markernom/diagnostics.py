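"""Immunoreactive-score (IRS) diagnostics.

The IRS multiplies staining intensity (0-3) by the banded proportion of
positive cells (0-4), giving scores in {0..12}. The diagnostic curve
tabulates sensitivity and specificity over every integer cutoff under the
rule "positive iff IRS >= c", and the workflow rule calls a sample
compatible with the target entity iff IRS exceeds the positivity cutoff
(default IRS > 1).
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .containers import IRSRecord, irs_frame, proportion_category

__all__ = [
    "compute_irs",
    "diagnostic_curve",
    "classify_sample",
    "DiagnosticCurve",
]


def compute_irs(intensity: int, percent_positive: float,
                bands: tuple[float, float, float, float] = (0, 10, 50, 80),
                ) -> tuple[int, int]:
    """Return (proportion_category, irs) for one stained section.

    Banding: category 0 for 0% positive cells, 1 for (0,10)%, 2 for
    [10,50]%, 3 for (50,80]%, 4 for (80,100]%. irs = intensity x category.
    """
    if intensity not in (0, 1, 2, 3):
        raise ValueError("intensity must be an integer in {0,1,2,3}")
    cat = proportion_category(percent_positive, bands)
    return cat, intensity * cat


@dataclass
class DiagnosticCurve:
    """Cutoff-indexed sensitivity/specificity with the named operating points."""

    table: pd.DataFrame                  # cutoff, sensitivity, specificity, TP/FP/TN/FN
    specificity_at_positive_rule: float  # rule IRS > 1, i.e. cutoff c = 2
    sensitivity_at_positive_rule: float
    max_cutoff_full_sensitivity: int     # largest c with sensitivity == 100%


def diagnostic_curve(records: list[IRSRecord] | pd.DataFrame,
                     target_entity: str) -> DiagnosticCurve:
    """Sensitivity/specificity at every integer IRS cutoff.

    For each cutoff c in 0..12, a sample is called positive iff irs >= c;
    sensitivity = 100*TP/(TP+FN) over target-entity samples and specificity
    = 100*TN/(TN+FP) over the mimics. Also reports the positivity-rule
    operating point (IRS > 1, i.e. c = 2) and the largest cutoff that still
    reaches 100% sensitivity.
    """
    df = irs_frame(records) if isinstance(records, list) else records
    if "irs" not in df.columns or df["irs"].isna().any():
        raise ValueError("every record needs an irs value")
    is_target = df["entity"] == target_entity
    n_target = int(is_target.sum())
    n_mimic = int((~is_target).sum())
    if n_target == 0 or n_mimic == 0:
        raise ValueError("need >= 1 target and >= 1 non-target record")
    irs = df["irs"].to_numpy()
    rows = []
    for c in range(13):
        positive = irs >= c
        tp = int((positive & is_target).sum())
        fn = n_target - tp
        fp = int((positive & ~is_target).sum())
        tn = n_mimic - fp
        rows.append({
            "cutoff": c,
            "sensitivity": 100.0 * tp / n_target,
            "specificity": 100.0 * tn / n_mimic,
            "TP": tp, "FP": fp, "TN": tn, "FN": fn,
        })
    table = pd.DataFrame(rows)
    full_sens = table.loc[table["sensitivity"] == 100.0, "cutoff"]
    at_rule = table.set_index("cutoff").loc[2]
    return DiagnosticCurve(
        table=table,
        specificity_at_positive_rule=float(at_rule["specificity"]),
        sensitivity_at_positive_rule=float(at_rule["sensitivity"]),
        max_cutoff_full_sensitivity=int(full_sens.max()),
    )


def classify_sample(irs: int, cutoff: int = 1) -> str:
    """Diagnostic workflow decision for a single stained sample.

    Returns ``'compatible_with_target'`` iff irs > cutoff, else
    ``'reconsider_molecular_testing'`` (the boundary is exclusive: an IRS
    equal to the cutoff triggers reconsideration).
    """
    if irs not in range(13):
        raise ValueError("irs must be an integer in {0..12}")
    return ("compatible_with_target" if irs > cutoff
            else "reconsider_molecular_testing")
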