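"""Heatmap rendering of sweep tables (density maps and q maps)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_sweep_heatmap"]


def plot_sweep_heatmap(
    table: pd.DataFrame,
    value: str = "mean_final_density",
    path: str | Path = "sweep.png",
    annotate: str | None = "n_coexistent",
) -> Path:
    """Render one grayscale heatmap panel per diffusion level D: metabolic
    neighbourhood h on the x axis, replication neighbourhood r on the y axis,
    cells shaded by ``value`` and annotated with ``annotate`` (for example
    coexistent-replicate counts or q)."""
    d_levels = sorted(table["D"].unique())
    r_levels = list(dict.fromkeys(table["r"]))
    h_levels = list(dict.fromkeys(table["h"]))
    fig, axes = plt.subplots(
        1, len(d_levels), figsize=(3.2 * len(d_levels), 3.2), squeeze=False
    )
    for ax, D in zip(axes[0], d_levels):
        sub = table[table["D"] == D]
        mat = np.full((len(r_levels), len(h_levels)), np.nan)
        ann = np.empty((len(r_levels), len(h_levels)), dtype=object)
        for _, row in sub.iterrows():
            i = r_levels.index(row["r"])
            j = h_levels.index(row["h"])
            mat[i, j] = row[value]
            ann[i, j] = "" if annotate is None else f"{row[annotate]:g}"
        ax.imshow(mat, cmap="gray", vmin=0, origin="lower")
        if annotate is not None:
            for i in range(len(r_levels)):
                for j in range(len(h_levels)):
                    if ann[i, j]:
                        ax.text(j, i, ann[i, j], ha="center", va="center",
                                color="tab:red", fontsize=9)
        ax.set_xticks(range(len(h_levels)), h_levels)
        ax.set_yticks(range(len(r_levels)), r_levels)
        ax.set_xlabel("h")
        ax.set_ylabel("r")
        ax.set_title(f"D = {D:g}")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
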