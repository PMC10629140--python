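"""Figure and table emission for a finished evaluation.

Figures are artifacts for humans; nothing downstream asserts on pixels.
Three figure families mirror the standard presentation of this analysis:
stacked bars of similarity-level percentages per ROI/category/model,
two-set overlap (Venn-style) diagrams per ROI and level, and MAE vs mean
CCC scatter plots per category.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .concordance import LEVELS
from .errors import SctRadiomicsError

_LEVEL_COLORS = {
    "excellent": "#2ca02c",
    "good": "#ffcc00",
    "moderate": "#d62728",
    "poor": "#222222",
}


def level_distribution_figure(level_summary: pd.DataFrame, out_path) -> Path:
    """Stacked-bar level percentages, one panel per ROI."""
    if level_summary.empty:
        raise SctRadiomicsError("level summary is empty; nothing to plot")
    rois = sorted(set(level_summary["roi"]))
    fig, axes = plt.subplots(
        1, len(rois), figsize=(3.2 * len(rois), 4.0), squeeze=False, sharey=True
    )
    for ax, roi in zip(axes[0], rois):
        sub = level_summary[level_summary["roi"] == roi]
        labels = [f"{c}\n{m}" for c, m in zip(sub["category"], sub["model"])]
        bottom = [0.0] * len(sub)
        for lv in LEVELS:
            vals = sub[f"pct_{lv}"].to_numpy()
            ax.bar(labels, vals, bottom=bottom, color=_LEVEL_COLORS[lv], label=lv)
            bottom = [b + v for b, v in zip(bottom, vals)]
        ax.set_title(roi)
        ax.tick_params(axis="x", labelsize=7, rotation=90)
    axes[0][0].set_ylabel("% of features")
    axes[0][-1].legend(loc="upper right", fontsize=7)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def overlap_figure(overlap: pd.DataFrame, out_path) -> Path:
    """Two-circle overlap diagrams (counts annotated), one panel per ROI/level."""
    if overlap.empty:
        raise SctRadiomicsError("overlap table is empty; nothing to plot")
    rows = overlap.reset_index(drop=True)
    n = len(rows)
    ncol = min(4, n)
    nrow = (n + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.0 * ncol, 3.0 * nrow), squeeze=False)
    for idx, row in rows.iterrows():
        ax = axes[idx // ncol][idx % ncol]
        for cx, color in ((-0.45, "tab:red"), (0.45, "tab:green")):
            ax.add_patch(plt.Circle((cx, 0), 0.8, alpha=0.4, color=color))
        ax.text(-0.8, 0, str(row["a_only"]), ha="center")
        ax.text(0.8, 0, str(row["b_only"]), ha="center")
        ax.text(0, 0, str(row["intersection"]), ha="center")
        ax.set_title(f"{row['roi']} / {row['level']}", fontsize=8)
        ax.set_xlim(-1.6, 1.6)
        ax.set_ylim(-1.2, 1.2)
        ax.axis("off")
    for k in range(n, nrow * ncol):
        axes[k // ncol][k % ncol].axis("off")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def mae_ccc_figure(mae_ccc: pd.DataFrame, out_path) -> Path:
    """MAE vs mean CCC scatter, one panel per category, points = ROIs."""
    if mae_ccc.empty:
        raise SctRadiomicsError("MAE/CCC correlation table is empty")
    categories = sorted(set(mae_ccc["category"]))
    fig, axes = plt.subplots(
        1, len(categories), figsize=(4.0 * len(categories), 3.6), squeeze=False
    )
    for ax, cat in zip(axes[0], categories):
        sub = mae_ccc[mae_ccc["category"] == cat]
        for _, row in sub.iterrows():
            pts = row["points"]
            if isinstance(pts, str):  # round-tripped through CSV
                import ast

                pts = ast.literal_eval(pts)
            xs = [p[1] for p in pts]
            ys = [p[2] for p in pts]
            ax.scatter(xs, ys, label=f"{row['model']} (r={row['pearson']:.2f})")
        ax.set_xlabel("MAE (HU)")
        ax.set_ylabel("mean CCC")
        ax.set_title(cat)
        ax.legend(fontsize=7)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def iqm_table_text(iqm_summary: pd.DataFrame) -> str:
    """Human-readable mean +/- SD IQM table (rows ROIs, columns model x metric)."""
    pivot = iqm_summary.pivot_table(
        index="roi", columns=["model", "metric"], values=["mean", "sd"]
    )
    lines = []
    models = sorted(set(iqm_summary["model"]))
    metrics = ("mae", "rmse", "ssim", "psnr")
    header = ["roi"] + [f"{m}:{k}" for m in models for k in metrics]
    lines.append("\t".join(header))
    for roi in sorted(set(iqm_summary["roi"])):
        cells = [roi]
        for m in models:
            for k in metrics:
                mean = pivot.loc[roi, ("mean", m, k)]
                sd = pivot.loc[roi, ("sd", m, k)]
                cells.append(f"{mean:.2f} ± {sd:.2f}")
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def render_report(out_dir) -> list[Path]:
    """Render all figures/tables from the CSVs in an evaluate output directory."""
    out_dir = Path(out_dir)
    needed = ["level_summary.csv", "overlap.csv", "mae_ccc.csv", "iqm_summary.csv"]
    for fname in needed:
        if not (out_dir / fname).exists():
            raise SctRadiomicsError(f"missing input file: {out_dir / fname}")
    level_summary = pd.read_csv(out_dir / "level_summary.csv")
    overlap = pd.read_csv(out_dir / "overlap.csv")
    mae_ccc = pd.read_csv(out_dir / "mae_ccc.csv")
    iqm_summary = pd.read_csv(out_dir / "iqm_summary.csv")
    artifacts = [
        level_distribution_figure(level_summary, out_dir / "fig_level_distribution.png"),
        overlap_figure(overlap, out_dir / "fig_overlap.png"),
        mae_ccc_figure(mae_ccc, out_dir / "fig_mae_ccc.png"),
    ]
    table = out_dir / "iqm_table.txt"
    table.write_text(iqm_table_text(iqm_summary))
    artifacts.append(table)
    return artifacts
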