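"""Relative qPCR quantification by the 2^-ddCt method.

Each animal's target lncRNA Ct is normalized against a reference
(housekeeping) gene measured on the same animal (dCt), then against the mean
dCt of the control group (ddCt); relative expression is 2^(-ddCt), so the
control-group mean is ~1 by construction.  Technical replicates are averaged
on the Ct scale before dCt.  Amplification efficiency is fixed at 2 (the
2^-ddCt assumption).  Group comparison uses the classical unpaired two-sample
t-test with pooled variance (Welch's correction available by flag).
"""

from __future__ import annotations

import math
import os
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps


class QPCRError(ValueError):
    pass


REQUIRED_COLUMNS = ("animal_id", "group", "gene", "ct")


def read_ct_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a long-format Ct CSV: animal_id, group, gene, ct (one row per
    technical replicate)."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise QPCRError(f"{path}: missing column(s) {missing}")
    df["ct"] = pd.to_numeric(df["ct"], errors="raise")
    bad = ~((df["ct"] > 0) & (df["ct"] < 45))
    if bad.any():
        raise QPCRError(f"{path}: Ct values outside (0, 45) at rows {list(df.index[bad][:5])}")
    return df


def delta_delta_ct(
    records: pd.DataFrame,
    target: str,
    reference: str = "GAPDH",
    control_group: str = "control",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-animal relative expression of *target* by 2^-ddCt.

    Returns
    -------
    per_animal : DataFrame
        animal_id, group, delta_ct, delta_delta_ct, rel_expr.
    summary : DataFrame
        per group: n, mean and SD of relative expression, and the group
        fold change versus the control group.
    """
    for col in REQUIRED_COLUMNS:
        if col not in records.columns:
            raise QPCRError(f"records missing column {col!r}")
    mean_ct = (
        records.groupby(["animal_id", "group", "gene"])["ct"].mean().reset_index()
    )
    tgt = mean_ct[mean_ct["gene"] == target].set_index("animal_id")
    ref = mean_ct[mean_ct["gene"] == reference].set_index("animal_id")
    if tgt.empty:
        raise QPCRError(f"no Ct records for target {target!r}")
    no_ref = tgt.index.difference(ref.index)
    if len(no_ref):
        warnings.warn(
            f"excluding animal(s) without reference gene {reference!r}: {list(no_ref)}",
            stacklevel=2,
        )
        tgt = tgt.drop(index=no_ref)
    per_animal = pd.DataFrame(
        {
            "group": tgt["group"],
            "delta_ct": tgt["ct"] - ref.loc[tgt.index, "ct"],
        }
    )
    control = per_animal[per_animal["group"] == control_group]
    if control.empty:
        raise QPCRError(f"no animals in control group {control_group!r}")
    base = control["delta_ct"].mean()
    per_animal["delta_delta_ct"] = per_animal["delta_ct"] - base
    per_animal["rel_expr"] = 2.0 ** (-per_animal["delta_delta_ct"])
    per_animal = per_animal.reset_index().rename(columns={"index": "animal_id"})
    summary = (
        per_animal.groupby("group")["rel_expr"].agg(n="size", mean="mean", sd="std").reset_index()
    )
    ctrl_mean = float(summary.loc[summary["group"] == control_group, "mean"].iloc[0])
    summary["fold_vs_control"] = summary["mean"] / ctrl_mean
    return per_animal, summary


def unpaired_t(group_a, group_b, welch: bool = False) -> tuple[float, float]:
    """Classical two-sample t-test (pooled variance unless ``welch``)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise QPCRError("each group needs n >= 2")
    if not welch and np.ptp(a) == 0 and np.ptp(b) == 0 and a.var(ddof=1) + b.var(ddof=1) == 0:
        raise QPCRError("zero pooled variance")
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    if math.isnan(float(t)):
        raise QPCRError("zero pooled variance")
    return float(t), float(p)


def validate_targets(
    records: pd.DataFrame,
    targets: list[str] | None = None,
    reference: str = "GAPDH",
    control_group: str = "control",
    welch: bool = False,
) -> pd.DataFrame:
    """ddCt + unpaired t for every target gene; one summary row per target.

    Columns: gene, per-group mean ± SD of relative expression, fold change
    (HF vs control), t, p.
    """
    genes = targets if targets is not None else [
        g for g in records["gene"].unique() if g != reference
    ]
    rows = []
    for gene in genes:
        per_animal, summary = delta_delta_ct(records, gene, reference, control_group)
        groups = {g: d["rel_expr"].to_numpy() for g, d in per_animal.groupby("group")}
        other = [g for g in groups if g != control_group]
        if len(other) != 1:
            raise QPCRError(f"{gene}: expected exactly one non-control group, got {other}")
        case = other[0]
        t, p = unpaired_t(groups[case], groups[control_group], welch=welch)
        s = summary.set_index("group")
        rows.append(
            {
                "gene": gene,
                f"mean_{case}": s.loc[case, "mean"],
                f"sd_{case}": s.loc[case, "sd"],
                f"mean_{control_group}": s.loc[control_group, "mean"],
                f"sd_{control_group}": s.loc[control_group, "sd"],
                "fold_change": s.loc[case, "fold_vs_control"],
                "t": t,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def write_qpcr_tsv(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t", index=False)
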