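"""Optional figure output: correlation heatmap and ROC curves."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .stats import RocReport


def correlation_heatmap(correlations: pd.DataFrame, path: str | Path) -> Path:
    """Heatmap of Spearman r (imaging readouts x histology scores).

    Stars follow the conventional thresholds: * p<0.05, ** p<0.01,
    *** p<0.005.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = correlations.pivot(index="metric", columns="score", values="r")
    pgrid = correlations.pivot(index="metric", columns="score", values="p")
    fig, ax = plt.subplots(figsize=(1.2 * len(grid.columns) + 2, 0.6 * len(grid) + 2))
    im = ax.imshow(grid.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(grid.columns)), grid.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(grid.index)), grid.index)
    for i in range(len(grid.index)):
        for j in range(len(grid.columns)):
            r = grid.iat[i, j]
            p = pgrid.iat[i, j]
            if np.isfinite(r):
                stars = "***" if p < 0.005 else "**" if p < 0.01 else "*" if p < 0.05 else ""
                ax.text(j, i, f"{r:+.2f}{stars}", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="Spearman r")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def roc_plot(reports: list[RocReport], path: str | Path) -> Path:
    """Overlayed ROC curves with the chosen operating points marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for rep in reports:
        ax.plot(rep.fpr, rep.tpr, label=f"{rep.contrast} (AUC {rep.auc:.2f})")
        ax.plot(
            1 - rep.specificity_pct / 100, rep.sensitivity_pct / 100, "o", ms=6
        )
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
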