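"""Diagnostic plots (not publication figures).

Scatter of per-gene density against a covariate, and the correlation
time-course (rho against generation cutoff). The covariate axis of the
scatter is square-root transformed purely for visual dispersion — rank
correlations are unaffected by monotone transforms.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .density import DensityTable
from .stats import _covariate_values

__all__ = ["plot_density_vs_covariate", "plot_rho_time_course"]


def plot_density_vs_covariate(
    density: DensityTable, covariate, path: str | Path
) -> None:
    cov_id, values = _covariate_values(covariate)
    genes = [g for g in density.frame.index if g in values]
    x = np.array([values[g] for g in genes], dtype=float)
    y = density.frame.loc[genes, "density"].to_numpy()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(np.sqrt(x), y, s=4, alpha=0.3, edgecolors="none")
    ax.set_xlabel(f"sqrt({cov_id})")
    ax.set_ylabel("mutations per nt")
    ax.set_title(
        f"{density.subset.populations_label}, {density.subset.scheme}, "
        f"cutoff {density.subset.cutoff}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_rho_time_course(report: pd.DataFrame, path: str | Path) -> None:
    """rho against generation cutoff, one line per covariate x scheme panel
    (zeros included, all population selectors shown faceted by selector)."""
    sub = report[report["zeros"] == "include"]
    selectors = sorted(sub["populations"].unique())
    fig, axes = plt.subplots(
        1, max(len(selectors), 1), figsize=(5 * max(len(selectors), 1), 4),
        squeeze=False,
    )
    for ax, selector in zip(axes[0], selectors):
        panel = sub[sub["populations"] == selector]
        for (cov, scheme), grp in panel.groupby(["covariate_id", "scheme"]):
            grp = grp.sort_values("cutoff")
            ax.plot(grp["cutoff"], grp["rho"], marker="o", ms=3,
                    label=f"{cov} / {scheme}")
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_xlabel("generation cutoff")
        ax.set_ylabel("Spearman rho")
        ax.set_title(selector)
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
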