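"""qPCR quantification: ΔCT / ΔΔCT relative expression and fold enrichment.

Relative expression uses the ΔCT method: for each (condition, target) the
mean Ct is normalised against the average of the housekeeping targets'
mean Cts (e.g. GAPDH and 18S rRNA) and relative expression is 2^(−ΔCT).
Re-normalising ΔCT to a control condition (ΔΔCT) yields a fold change vs
control and a knockdown efficiency (1 − fold).

Fold enrichment (CUT&RUN-qPCR style) compares an antibody condition's Ct
with its matched IgG control per locus, fold = 2^(Ct_IgG − Ct_antibody),
then expresses every condition's fold relative to a designated control
condition (which therefore maps to 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["delta_ct_expression", "fold_enrichment", "validate_ct_table"]

_CT_COLUMNS = {"condition", "target_id", "replicate", "ct"}


def validate_ct_table(table: pd.DataFrame) -> None:
    missing = _CT_COLUMNS - set(table.columns)
    if missing:
        raise ValueError(f"Ct table is missing columns: {sorted(missing)}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")


def delta_ct_expression(table: pd.DataFrame, housekeeping=("GAPDH", "RN18S"),
                        control_condition: str | None = None):
    """ΔCT relative expression per (condition, target), optionally ΔΔCT.

    Parameters
    ----------
    table : frame with columns condition, target_id, replicate, ct.
    housekeeping : target ids averaged into the normaliser; every condition
        must contain all of them, otherwise the condition is skipped and an
        error record emitted.
    control_condition : if given, ΔΔCT columns (fold vs control and
        knockdown efficiency) are added; the control condition itself maps
        to fold 1.

    Returns
    -------
    (DataFrame, list of dict)
        Rows condition, target_id, delta_ct, rel_expr (+ ddct,
        fold_vs_control, knockdown_efficiency when a control is set), and a
        list of skip records for conditions missing housekeeping targets.
    """
    validate_ct_table(table)
    hk = list(housekeeping)
    means = table.groupby(["condition", "target_id"])["ct"].mean()
    rows, errors = [], []
    for cond in sorted(table["condition"].unique()):
        cond_means = means.loc[cond]
        absent = [t for t in hk if t not in cond_means.index]
        if absent:
            errors.append({"condition": cond, "error": f"missing housekeeping targets {absent}"})
            continue
        hk_mean = float(np.mean([cond_means[t] for t in hk]))
        for target in sorted(cond_means.index):
            if target in hk:
                continue
            dct = float(cond_means[target]) - hk_mean
            rows.append({"condition": cond, "target_id": target,
                         "delta_ct": dct, "rel_expr": 2.0 ** (-dct)})
    out = pd.DataFrame(rows, columns=["condition", "target_id", "delta_ct", "rel_expr"])
    if control_condition is not None and not out.empty:
        ctrl = out[out["condition"] == control_condition].set_index("target_id")["delta_ct"]
        out["ddct"] = out["delta_ct"] - out["target_id"].map(ctrl)
        out["fold_vs_control"] = 2.0 ** (-out["ddct"])
        out["knockdown_efficiency"] = 1.0 - out["fold_vs_control"]
    return out, errors


def fold_enrichment(table: pd.DataFrame, igg_map: dict, control_condition: str):
    """Fold enrichment per (condition, locus) relative to a control sample.

    Parameters
    ----------
    table : frame with columns condition, target_id (locus), replicate, ct.
    igg_map : condition -> its IgG control condition (IgG conditions map to
        themselves and thus get raw fold 1).
    control_condition : the sample whose fold defines the unit (maps to 1).

    Returns
    -------
    (DataFrame, list of dict)
        Rows condition, target_id, fold_raw, fold_rel; loci missing their
        IgG rows are skipped with an error record.
    """
    validate_ct_table(table)
    if control_condition not in igg_map:
        raise ValueError(f"control condition {control_condition!r} not in igg_map")
    means = table.groupby(["condition", "target_id"])["ct"].mean()
    rows, errors = [], []
    for cond in sorted(igg_map):
        igg = igg_map[cond]
        if cond not in means.index.get_level_values(0):
            errors.append({"condition": cond, "error": "condition absent from table"})
            continue
        for locus in sorted(means.loc[cond].index):
            if (igg, locus) not in means.index:
                errors.append({"condition": cond, "target_id": locus,
                               "error": f"missing IgG rows ({igg})"})
                continue
            fold = 2.0 ** (float(means[(igg, locus)]) - float(means[(cond, locus)]))
            rows.append({"condition": cond, "target_id": locus, "fold_raw": fold})
    out = pd.DataFrame(rows, columns=["condition", "target_id", "fold_raw"])
    if not out.empty:
        ctrl = out[out["condition"] == control_condition].set_index("target_id")["fold_raw"]
        out["fold_rel"] = out["fold_raw"] / out["target_id"].map(ctrl)
    return out, errors
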