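"""Relative quantification of qRT-PCR cycle thresholds (2^-ddCt).

Fold change of a target gene between a treated and a control sample,
normalized to a reference gene (beta-actin role):

    ddCt = (Ct_target,treat - Ct_ref,treat) - (Ct_target,ctrl - Ct_ref,ctrl)
    fold = 2 ** (-ddCt)

Replicates are averaged on the Ct scale (technical then biological) before
the delta-deltas are formed.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd


def fold_change(ct_target_treat: float, ct_ref_treat: float,
                ct_target_ctrl: float, ct_ref_ctrl: float) -> float:
    """2^-ddCt relative expression of treated vs control."""
    ddct = (ct_target_treat - ct_ref_treat) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)


def ddct_table(records: pd.DataFrame, control_condition: str) -> pd.DataFrame:
    """Per-gene, per-condition fold changes from a tidy Ct table.

    ``records`` needs columns gene, condition, replicate, ct_target,
    ct_reference. Replicate Ct values are averaged per (gene, condition)
    before the 2^-ddCt computation against ``control_condition``.
    """
    required = {"gene", "condition", "ct_target", "ct_reference"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    means = (records.groupby(["gene", "condition"])
             [["ct_target", "ct_reference"]].mean())
    rows = []
    for (gene, cond), row in means.iterrows():
        if cond == control_condition:
            continue
        try:
            ctrl = means.loc[(gene, control_condition)]
        except KeyError:
            raise ValueError(f"no control measurements for gene {gene!r}")
        rows.append({
            "gene": gene, "condition": cond,
            "fold_change": fold_change(row["ct_target"], row["ct_reference"],
                                       ctrl["ct_target"],
                                       ctrl["ct_reference"])})
    return pd.DataFrame(rows, columns=["gene", "condition", "fold_change"])
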