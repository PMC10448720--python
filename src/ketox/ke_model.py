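"""Key-event (KE) curve composition, scoring, ranking and ROC evaluation.

A KE groups assays that probe one biological target or mechanism.  For each
chemical the member assays' normalized responses are composed into a single
KE curve on the shared grid; its area under the curve in log10-concentration
(normalized by the eleven-decade width) is the raw KE score, which is then
scaled within the KE so the most active chemical scores exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from ketox.curves import ConcentrationGrid, ResponseSurface

#: supported composition rules for multi-assay KEs
AGGREGATION_MODES = ("mean", "sum-rescaled")


@dataclass(frozen=True)
class KECurve:
    chem_id: str
    ke_id: str
    values: np.ndarray  # on the shared grid, each in [0, 1]


@dataclass(frozen=True)
class KEScore:
    chem_id: str
    ke_id: str
    raw_auc: float
    scaled: float


def compose_ke_curves(
    ke_id: str,
    member_assays: Sequence[str],
    surfaces: Mapping[str, ResponseSurface],
    chem_ids: Sequence[str],
    mode: str = "mean",
) -> pd.DataFrame:
    """Compose all chemicals' KE curves for one KE.

    Returns a chem_id-indexed frame of curve values on the grid.  The
    default ``mean`` rule averages member-assay normalized responses
    (zeros substituted for untested chemicals), which keeps every curve
    value in [0, 1].  ``sum-rescaled`` sums instead, then rescales the whole
    KE by its global maximum.
    """
    if not member_assays:
        raise ValueError(f"KE {ke_id!r} has no member assays")
    if mode not in AGGREGATION_MODES:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    ref = surfaces[member_assays[0]].grid
    for a in member_assays[1:]:
        if not np.array_equal(surfaces[a].grid.log10_points, ref.log10_points):
            raise ValueError("member assay surfaces must share one grid")
    stack = np.stack(
        [np.stack([surfaces[a].row(c) for a in member_assays]) for c in chem_ids]
    )  # (n_chem, n_assay, n_grid)
    if mode == "mean":
        values = stack.mean(axis=1)
    else:
        values = stack.sum(axis=1)
        peak = values.max()
        if peak > 0:
            values = values / peak
    grid = surfaces[member_assays[0]].grid
    cols = [f"{lg:.3f}" for lg in grid.log10_points]
    return pd.DataFrame(values, index=pd.Index(list(chem_ids), name="chem_id"), columns=cols)


def compose_ke_curve(
    ke_id: str,
    member_assays: Sequence[str],
    surfaces: Mapping[str, ResponseSurface],
    chem_id: str,
    mode: str = "mean",
) -> KECurve:
    """Single-chemical convenience wrapper around :func:`compose_ke_curves`.

    Note ``sum-rescaled`` is a KE-wide rule; for a single chemical it
    rescales by that chemical's own maximum.
    """
    frame = compose_ke_curves(ke_id, member_assays, surfaces, [chem_id], mode=mode)
    return KECurve(chem_id=chem_id, ke_id=ke_id, values=frame.iloc[0].to_numpy())


def ke_score(curve_values: np.ndarray, grid: ConcentrationGrid) -> float:
    """Raw KE score: trapezoidal AUC in log10 concentration over the grid width.

    A constant-1 curve scores exactly 1; a flat curve scores 0.
    """
    values = np.asarray(curve_values, dtype=float)
    if values.shape != grid.log10_points.shape:
        raise ValueError("curve length must match the grid")
    return float(np.trapezoid(values, x=grid.log10_points) / grid.width)


def scale_scores(raw: pd.Series) -> pd.Series:
    """Scale raw scores within one KE by the maximum; an all-zero KE stays zero."""
    peak = raw.max() if len(raw) else 0.0
    if not peak or peak <= 0:
        return raw * 0.0
    return raw / peak


def rank_chemicals(scaled: pd.Series) -> list[str]:
    """Chemicals ordered by descending score, ties broken by chem_id ascending."""
    return sorted(scaled.index, key=lambda c: (-scaled[c], c))


def ke_roc_auc(scaled: pd.Series, hepatotoxic: pd.Series) -> float:
    """ROC AUC of a KE's scaled scores against hepatotoxicity labels.

    Equals the Mann-Whitney concordance probability with half credit for
    ties.  Chemicals lacking a label are ignored; a single-class label set
    is an error.
    """
    common = scaled.index.intersection(hepatotoxic.dropna().index)
    y = hepatotoxic.loc[common].astype(int)
    if y.nunique() < 2:
        raise ValueError("ROC AUC undefined: need both a positive and a negative label")
    return float(roc_auc_score(y.to_numpy(), scaled.loc[common].to_numpy()))


def score_table(
    ke_members: Mapping[str, Sequence[str]],
    surfaces: Mapping[str, ResponseSurface],
    chem_ids: Sequence[str],
    grid: ConcentrationGrid,
    mode: str = "mean",
) -> pd.DataFrame:
    """Long table of per-chemical KE scores: ``chem_id,ke_id,raw_auc,scaled_score``."""
    frames = []
    for ke_id, members in ke_members.items():
        curves = compose_ke_curves(ke_id, list(members), surfaces, chem_ids, mode=mode)
        raw = curves.apply(lambda row: ke_score(row.to_numpy(), grid), axis=1)
        scaled = scale_scores(raw)
        frames.append(
            pd.DataFrame(
                {
                    "chem_id": raw.index,
                    "ke_id": ke_id,
                    "raw_auc": raw.to_numpy(),
                    "scaled_score": scaled.to_numpy(),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chem_id", "ke_id", "raw_auc", "scaled_score"])
    return pd.concat(frames, ignore_index=True)


def scores_wide(score_frame: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long score table to chem_id x ke_id scaled scores."""
    if score_frame.empty:
        return pd.DataFrame()
    return score_frame.pivot(index="chem_id", columns="ke_id", values="scaled_score").sort_index()


def roc_summary(score_frame: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Per-KE ROC table: ``ke_id,n_pos,n_neg,roc_auc`` (NaN when undefined)."""
    rows = []
    hepatotoxic = labels["hepatotoxic"]
    for ke_id, group in score_frame.groupby("ke_id", sort=True):
        scaled = group.set_index("chem_id")["scaled_score"]
        common = scaled.index.intersection(hepatotoxic.dropna().index)
        y = hepatotoxic.loc[common].astype(int)
        n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
        try:
            auc = ke_roc_auc(scaled, hepatotoxic)
        except ValueError:
            auc = float("nan")
        rows.append({"ke_id": ke_id, "n_pos": n_pos, "n_neg": n_neg, "roc_auc": auc})
    return pd.DataFrame(rows, columns=["ke_id", "n_pos", "n_neg", "roc_auc"])


def plot_ke_curves(curves: pd.DataFrame, grid: ConcentrationGrid, path, title: str = "") -> None:
    """Export KE curves as a log-x line plot (one line per chemical)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for chem_id, row in curves.iterrows():
        ax.plot(grid.points, row.to_numpy(), lw=1, label=str(chem_id))
    ax.set_xscale("log")
    ax.set_xlabel("concentration (uM)")
    ax.set_ylabel("composite normalized response")
    ax.set_ylim(-0.02, 1.02)
    if title:
        ax.set_title(title)
    if len(curves) <= 10:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
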