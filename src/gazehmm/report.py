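"""Figures for a pipeline run: representative ROI maps, scatters, group bars."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Ellipse

from .errors import AnalysisError
from .hmm import HiddenMarkovModel
from .vhem import ClusteringResult

logger = logging.getLogger(__name__)

_ROI_COLORS = ["tab:red", "tab:green", "tab:blue", "tab:orange",
               "tab:purple", "tab:brown"]


def plot_representative(model: HiddenMarkovModel, title: str, path: Path) -> None:
    """ROI ellipses (2 SD) with the prior vector and transition matrix."""
    fig, (ax, ax_t) = plt.subplots(
        1, 2, figsize=(9, 4), gridspec_kw={"width_ratios": [2, 1]}
    )
    for k in range(model.K):
        vals, vecs = np.linalg.eigh(model.covariances[k])
        angle = float(np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1])))
        w, h = 2 * 2 * np.sqrt(vals[-1]), 2 * 2 * np.sqrt(vals[0])
        color = _ROI_COLORS[k % len(_ROI_COLORS)]
        ax.add_patch(Ellipse(model.means[k], w, h, angle=angle,
                             alpha=0.3, color=color))
        ax.annotate(f"{k + 1}\nπ={model.prior[k]:.2f}", model.means[k],
                    ha="center", va="center", fontsize=8)
    ax.set_xlim(-18, 18)
    ax.set_ylim(12, -12)  # y grows downward in screen coordinates
    ax.set_xlabel("x (deg)")
    ax.set_ylabel("y (deg)")
    ax.set_title(title)
    ax_t.axis("off")
    cell = [[f"{v:.2f}" for v in row] for row in model.transition]
    tbl = ax_t.table(cellText=cell,
                     rowLabels=[f"from {k + 1}" for k in range(model.K)],
                     colLabels=[f"to {k + 1}" for k in range(model.K)],
                     loc="center")
    tbl.scale(1.0, 1.3)
    ax_t.set_title("transition matrix", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _scatter(x, y, xlabel, ylabel, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, s=25)
    if len(x) >= 2:
        coef = np.polyfit(x, y, 1)
        xs = np.linspace(min(x), max(x), 20)
        ax.plot(xs, np.polyval(coef, xs), "k--", lw=1)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _group_bar(df, group_col, value_col, ylabel, path: Path) -> bool:
    groups = ["centralized", "distributed"]
    means, sems = [], []
    for g in groups:
        vals = df.loc[df[group_col] == g, value_col].to_numpy()
        if len(vals) == 0:
            logger.warning("group %s empty; bar plot suppressed", g)
            return False
        means.append(vals.mean())
        sems.append(vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0)
    fig, ax = plt.subplots(figsize=(3.2, 4))
    ax.bar(groups, means, yerr=sems, capsize=4, color=["tab:blue", "tab:red"])
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return True


def render_report(bundle, clusterings: Dict[str, ClusteringResult],
                  outdir: str | Path) -> List[Path]:
    """Representative plots, dc-vs-measure scatters, and group bar plots."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    df = bundle.participants
    if df.empty:
        raise AnalysisError("no participant results to plot")
    for wtype, cl in clusterings.items():
        for label in ("centralized", "distributed"):
            p = outdir / f"representative_{wtype}_{label}.png"
            plot_representative(cl.representative(label),
                                f"{label} pattern ({wtype})", p)
            written.append(p)
    if "dc_pre_target" in df:
        p = outdir / "scatter_dc_dprime.png"
        _scatter(df["dc_pre_target"], df["dprime"], "D-C scale (pre-target)",
                 "d'", p)
        written.append(p)
        p = outdir / "bars_dprime.png"
        if _group_bar(df, "group_pre_target", "dprime", "d'", p):
            written.append(p)
    if "dc_pre_probe" in df:
        p = outdir / "scatter_dc_proportion_fa.png"
        _scatter(df["dc_pre_probe"], df["proportion_fa"],
                 "D-C scale (pre-probe)", "proportion rated FA", p)
        written.append(p)
        p = outdir / "bars_proportion_fa.png"
        if _group_bar(df, "group_pre_probe", "proportion_fa",
                      "proportion rated FA", p):
            written.append(p)
    return written
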