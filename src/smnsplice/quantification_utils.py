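"""ΔΔCt relative qPCR quantification and gel-band isoform fractions.

fold = 2^(−ΔΔCt) with ΔCt = Ct(target) − Ct(reference) per condition and
ΔΔCt = ΔCt(treated) − ΔCt(control); replicates are averaged on the Ct scale
and the control condition's fold is 1 by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CT_COLUMNS = ["sample", "condition", "gene", "ct"]


def validate_ct_table(table: pd.DataFrame, reference_gene: str) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns {missing}")
    if not np.isfinite(table["ct"]).all():
        raise ValueError("non-finite Ct values")
    for cond, grp in table.groupby("condition"):
        if reference_gene not in set(grp["gene"]):
            raise ValueError(
                f"reference gene {reference_gene!r} absent in condition {cond!r}"
            )
    return table


def delta_delta_ct(
    table: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    control_condition: str,
) -> pd.DataFrame:
    """Per-condition fold change of ``target_gene`` relative to control.

    Ct replicates are arithmetic-averaged per (condition, gene) before the
    ΔΔCt subtraction, so the result is invariant to any constant machine
    offset added to every Ct.
    """
    validate_ct_table(table, reference_gene)
    mean_ct = table.groupby(["condition", "gene"])["ct"].mean()
    conditions = table["condition"].unique()
    if control_condition not in conditions:
        raise ValueError(f"control condition {control_condition!r} absent")
    delta = {
        cond: mean_ct[(cond, target_gene)] - mean_ct[(cond, reference_gene)]
        for cond in conditions
    }
    rows = [
        {
            "condition": cond,
            "gene": target_gene,
            "delta_ct": delta[cond],
            "delta_delta_ct": delta[cond] - delta[control_condition],
            "fold_change": 2.0 ** -(delta[cond] - delta[control_condition]),
        }
        for cond in conditions
    ]
    return pd.DataFrame(rows)


def isoform_fraction(alt_band: float, canonical_band: float) -> float:
    """Densitometry fraction alt / (alt + canonical) of an RT-PCR gel."""
    if alt_band < 0 or canonical_band < 0:
        raise ValueError("band intensities must be non-negative")
    total = alt_band + canonical_band
    if total == 0:
        raise ValueError("both band intensities are zero")
    return alt_band / total
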