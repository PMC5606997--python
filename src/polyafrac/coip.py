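"""Co-IP mass-spectrometry enrichment scoring from LFQ tables.

Each protein identified in a bait co-immunoprecipitation gets two
coordinates: *abundance*, the mean bait LFQ intensity divided by the
protein's molecular weight (a rough molar amount), and *specificity*, the
ratio of mean bait LFQ to the background level in the negative-control
purification.  Proteins never detected in the control have their background
set to a floor (1 in raw LFQ units by convention), so bait-only interactors
land at the top of the specificity axis instead of dividing by zero.
Genuine interactors score high on both axes of the log-log dot plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CoipPoint", "score_coip", "export_dotplot"]


@dataclass(frozen=True)
class CoipPoint:
    protein_id: str
    mw: float  # kDa
    lfq_bait: float
    lfq_control: float
    abundance: float
    specificity: float
    is_contaminant: bool = False


def score_coip(
    table: pd.DataFrame,
    runs: pd.DataFrame,
    background_floor: float = 1.0,
    contaminants=(),
) -> pd.DataFrame:
    """Score every bait-detected protein for abundance and specificity.

    Parameters
    ----------
    table
        One row per protein with columns ``protein_id``, ``mw_kda`` and one
        LFQ intensity column per run (zero = undetected).
    runs
        Run sheet indexed by run id with an ``arm`` column in
        {"bait", "control"}; its index selects the LFQ columns.
    background_floor
        Background level substituted when a protein is undetected in the
        control arm.
    contaminants
        Iterable of protein ids flagged as common contaminants; they stay in
        the returned table but are excluded from plot export.

    Replicate runs are reduced by the arithmetic mean within each arm.
    Proteins undetected in every bait run are dropped.
    """
    if "arm" not in runs.columns:
        raise ValueError("run sheet must have an 'arm' column")
    bad = sorted(set(runs["arm"]) - {"bait", "control"})
    if bad:
        raise ValueError(f"unknown run arms: {bad}")
    bait_cols = list(runs.index[runs["arm"] == "bait"])
    ctrl_cols = list(runs.index[runs["arm"] == "control"])
    if not bait_cols or not ctrl_cols:
        raise ValueError("need at least one bait and one control run")
    missing = [c for c in bait_cols + ctrl_cols if c not in table.columns]
    if missing:
        raise ValueError(f"LFQ table lacks run columns: {missing}")

    mw = pd.to_numeric(table["mw_kda"], errors="coerce")
    bad_mw = table.loc[~(mw > 0) | mw.isna(), "protein_id"]
    if len(bad_mw):
        raise ValueError(f"missing or non-positive molecular weight for: {list(bad_mw)}")

    lfq = table[bait_cols + ctrl_cols].to_numpy(float)
    if np.any(lfq < 0):
        i, j = np.argwhere(lfq < 0)[0]
        raise ValueError(
            f"negative LFQ intensity for protein "
            f"{table['protein_id'].iloc[i]!r} in run {(bait_cols + ctrl_cols)[j]!r}"
        )

    mean_bait = table[bait_cols].mean(axis=1).to_numpy(float)
    mean_ctrl = table[ctrl_cols].mean(axis=1).to_numpy(float)

    contaminants = set(contaminants)
    out = pd.DataFrame(
        {
            "protein_id": table["protein_id"].to_numpy(),
            "mw_kda": mw.to_numpy(float),
            "lfq_bait": mean_bait,
            "lfq_control": mean_ctrl,
        }
    )
    out["abundance"] = out["lfq_bait"] / out["mw_kda"]
    background = np.where(mean_ctrl > 0, mean_ctrl, background_floor)
    out["specificity"] = out["lfq_bait"] / background
    out["is_contaminant"] = out["protein_id"].isin(contaminants)
    out = out[out["lfq_bait"] > 0].reset_index(drop=True)
    return out


def export_dotplot(points: pd.DataFrame, bait_id: str | None = None) -> pd.DataFrame:
    """Log-log plot coordinates, contaminants excluded.

    Returns columns protein_id, log10_abundance, log10_specificity and
    is_bait (the bait protein itself, when named, is flagged so it can be
    highlighted).
    """
    keep = points[~points["is_contaminant"]]
    out = pd.DataFrame(
        {
            "protein_id": keep["protein_id"].to_numpy(),
            "log10_abundance": np.log10(keep["abundance"].to_numpy(float)),
            "log10_specificity": np.log10(keep["specificity"].to_numpy(float)),
        }
    )
    out["is_bait"] = out["protein_id"] == bait_id if bait_id is not None else False
    return out


def plot_coip(points: pd.DataFrame, bait_id: str | None = None, ax=None):
    """Dot plot of abundance vs specificity on log axes."""
    import matplotlib.pyplot as plt

    coords = export_dotplot(points, bait_id)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(
        coords["log10_abundance"], coords["log10_specificity"], s=12, alpha=0.7
    )
    if bait_id is not None:
        b = coords[coords["is_bait"]]
        ax.scatter(b["log10_abundance"], b["log10_specificity"], s=40, color="red")
    ax.set_xlabel("log10 abundance (LFQ / MW)")
    ax.set_ylabel("log10 specificity (bait / background)")
    return ax
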