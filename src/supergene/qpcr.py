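"""Relative copy-number quantification from qPCR Ct panels (2^-dCt).

Input is a long-format panel: one row per (sample, gene, technical
replicate) with columns ``sample_id, group, gene_id, role, replicate, ct``
where ``role`` is ``target`` or ``housekeeping``.

Replicate QC excludes individual replicates that read more than a threshold
(default 0.5 cycles) above their replicate-group mean — the pipetting-artifact
guard; a (sample, gene) measurement with fewer than two surviving replicates
is dropped.  Quantities are 2^-dCt with dCt taken against the arithmetic mean
of the housekeeping-gene mean Cts, which equals geometric-mean normalization
on the linear scale, and are then scaled to the calibrator group's mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("sample_id", "group", "gene_id", "role", "replicate", "ct")


def _check_panel(panel: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel is missing columns {missing}")
    if (panel["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    if not (panel["role"] == "housekeeping").any():
        raise ValueError("panel must contain at least one housekeeping gene")


@dataclass
class QCResult:
    """Filtered panel plus an audit log of everything excluded."""

    panel: pd.DataFrame
    excluded_replicates: pd.DataFrame
    dropped_measurements: pd.DataFrame


def replicate_qc(panel: pd.DataFrame, threshold: float = 0.5) -> QCResult:
    """Drop replicates reading > ``threshold`` cycles above their group mean.

    The mean is the plain mean of all replicates of the (sample, gene) group
    (a single pass; the mean is not recomputed after exclusions).  Groups
    left with fewer than two replicates are dropped entirely and logged.
    """
    _check_panel(panel)
    panel = panel.copy()
    group_mean = panel.groupby(["sample_id", "gene_id"])["ct"].transform("mean")
    excess = panel["ct"] - group_mean
    excluded = panel[excess > threshold].copy()
    excluded["excess"] = excess[excess > threshold]
    kept = panel[excess <= threshold]
    counts = kept.groupby(["sample_id", "gene_id"])["ct"].transform("size")
    dropped = kept[counts < 2].copy()
    kept = kept[counts >= 2].reset_index(drop=True)
    return QCResult(
        panel=kept,
        excluded_replicates=excluded.reset_index(drop=True),
        dropped_measurements=dropped.reset_index(drop=True),
    )


def relative_copy_number(panel: pd.DataFrame, calibrator_group: str) -> pd.DataFrame:
    """Per-sample, per-target normalized quantities (2^-dCt over calibrator mean).

    For each sample, dCt(target) = mean replicate Ct of the target minus the
    arithmetic mean of the housekeeping genes' mean Cts; the linear quantity
    2^-dCt is then divided by the calibrator group's mean quantity for that
    target.  Samples lacking any housekeeping measurement are an error.
    """
    _check_panel(panel)
    if calibrator_group not in set(panel["group"]):
        raise ValueError(f"calibrator group {calibrator_group!r} not in panel")
    mean_ct = (
        panel.groupby(["sample_id", "group", "gene_id", "role"], as_index=False)["ct"]
        .mean()
    )
    hkg = (
        mean_ct[mean_ct["role"] == "housekeeping"]
        .groupby("sample_id")["ct"]
        .mean()
        .rename("hkg_ct")
    )
    targets = mean_ct[mean_ct["role"] == "target"].copy()
    samples_without_hkg = set(targets["sample_id"]) - set(hkg.index)
    if samples_without_hkg:
        raise ValueError(f"samples without housekeeping measurements: {sorted(samples_without_hkg)}")
    targets = targets.merge(hkg, on="sample_id")
    targets["delta_ct"] = targets["ct"] - targets["hkg_ct"]
    targets["quantity"] = 2.0 ** (-targets["delta_ct"])
    cal = (
        targets[targets["group"] == calibrator_group]
        .groupby("gene_id")["quantity"]
        .mean()
        .rename("calibrator_quantity")
    )
    targets = targets.merge(cal, on="gene_id")
    targets["relative_quantity"] = targets["quantity"] / targets["calibrator_quantity"]
    return (
        targets[["sample_id", "group", "gene_id", "delta_ct", "quantity", "relative_quantity"]]
        .sort_values(["gene_id", "group", "sample_id"])
        .reset_index(drop=True)
    )


def group_mean_quantities(relative: pd.DataFrame) -> pd.DataFrame:
    """Group x gene mean relative quantity with standard errors."""
    g = relative.groupby(["group", "gene_id"])["relative_quantity"]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": "mean_quantity", "sem": "se", "count": "n"})
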