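"""Report figures: VI bar charts with effect directions and RDA biplots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .brt import BRTResult
from .rda import RDAResult

_DIR_MARK = {"positive": "⊕", "negative": "⊖", "mixed": "±"}


def vi_barplot(result: BRTResult, title: str = "", path: str | Path | None = None):
    """Horizontal bar chart of relative influence, annotated with the
    direction of each driver's effect (⊕ positive, ⊖ negative, ± mixed)."""
    vi = result.vi.sort_values()
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(vi) + 1.2))
    ax.barh(vi.index, vi.values, color="steelblue")
    for i, (name, value) in enumerate(vi.items()):
        ax.text(
            value + 0.5,
            i,
            _DIR_MARK.get(result.direction.get(name, "mixed"), "?"),
            va="center",
        )
    ax.set_xlabel("relative influence (VI, % of 100)")
    note = f"CV R² = {result.cv_r2:.2f}"
    if result.sac_share is not None:
        note += f"; spatial autocorrelation {result.sac_share:.1f}%"
    ax.set_title(title or note, fontsize=10)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def rda_biplot(
    result: RDAResult,
    path: str | Path | None = None,
    min_arrow: float = 0.1,
):
    """Correlation biplot of the first two constrained axes: species scores
    as points, driver arrows from the biplot scores (arrows shorter than
    ``min_arrow`` are dropped for readability)."""
    if result.species_scores.shape[1] < 2:
        raise ValueError("need at least two constrained axes for a biplot")
    fig, ax = plt.subplots(figsize=(6, 6))
    sp = result.species_scores
    ax.scatter(sp.iloc[:, 0], sp.iloc[:, 1], color="grey", s=12)
    for name, row in sp.iterrows():
        ax.annotate(str(name), (row.iloc[0], row.iloc[1]), fontsize=7, alpha=0.8)
    scale = float(sp.iloc[:, :2].abs().to_numpy().max()) or 1.0
    for name, row in result.biplot_scores.iterrows():
        x, y = row.iloc[0], row.iloc[1]
        if (x**2 + y**2) ** 0.5 < min_arrow:
            continue
        ax.annotate(
            "",
            xy=(x * scale, y * scale),
            xytext=(0, 0),
            arrowprops=dict(arrowstyle="->", color="firebrick"),
        )
        ax.annotate(str(name), (x * scale, y * scale), color="firebrick", fontsize=8)
    p1, p2 = 100 * result.proportion[0], 100 * result.proportion[1]
    ax.set_xlabel(f"RDA1 ({p1:.2f}% of variance)")
    ax.set_ylabel(f"RDA2 ({p2:.2f}% of variance)")
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
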