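"""Multidrug-resistance reversal folds from IC50 summaries.

RF = IC50 of the cytotoxic drug alone / IC50 in the presence of the
modulator.  IC50 estimation itself (dose-response curve fitting) is out of
scope; this module consumes fitted IC50 values.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError


@dataclass
class ReversalRecord:
    label: str
    ic50_alone: float  # µM
    ic50_combo: float  # µM
    rf: float


def reversal_fold(ic50_alone: float, ic50_combo: float) -> float:
    """Fold potentiation of the cytotoxic drug by the modulator."""
    if ic50_alone <= 0 or ic50_combo <= 0:
        raise ValidationError("IC50 values must be positive")
    return ic50_alone / ic50_combo


def reversal_table(records) -> pd.DataFrame:
    """RF for each (label, ic50_alone_uM, ic50_combo_uM) row.

    ``records`` is a DataFrame with those columns or an iterable of
    (label, alone, combo) tuples; RF is rounded to 2 decimals for display.
    """
    if isinstance(records, pd.DataFrame):
        rows = records[["label", "ic50_alone_uM", "ic50_combo_uM"]].itertuples(index=False)
    else:
        rows = records
    out = [
        ReversalRecord(str(label), float(alone), float(combo), reversal_fold(float(alone), float(combo)))
        for label, alone, combo in rows
    ]
    df = pd.DataFrame(
        {
            "label": [r.label for r in out],
            "ic50_alone_uM": [r.ic50_alone for r in out],
            "ic50_combo_uM": [r.ic50_combo for r in out],
            "rf": [round(r.rf, 2) for r in out],
        }
    )
    return df
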