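"""Optional figure helpers (matplotlib, Agg-safe).

These mirror the standard presentation of the analyses: a red-to-green
standardised usage heat map (green = over-represented within a residue
column), pI distribution line plots with mean ± SD ribbons, and a CA
axis-1/axis-2 scatter coloured by group.
"""
from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .multivariate import CAResult  # noqa: E402
from .physchem import GroupDistribution  # noqa: E402


def usage_heatmap(z_matrix: pd.DataFrame, path: str | Path) -> None:
    """Standardised usage heat map, red (low) to green (high) per column."""
    fig, ax = plt.subplots(figsize=(10, 0.3 * len(z_matrix) + 2))
    im = ax.imshow(z_matrix.to_numpy(), cmap="RdYlGn", aspect="auto")
    ax.set_xticks(range(len(z_matrix.columns)), z_matrix.columns)
    ax.set_yticks(range(len(z_matrix)), z_matrix.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="column z-score")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def pi_profile_plot(groups: Sequence[GroupDistribution], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    for g in groups:
        centres = [0.5 * (lo + hi) for lo, hi in zip(g.bin_edges, g.bin_edges[1:])]
        mean = list(g.mean_percentages)
        sd = list(g.sd_percentages)
        ax.plot(centres, mean, marker="o", ms=3, label=g.label)
        ax.fill_between(centres, [m - s for m, s in zip(mean, sd)],
                        [m + s for m, s in zip(mean, sd)], alpha=0.2)
    ax.set_xlabel("isoelectric point")
    ax.set_ylabel("% of proteins")
    ax.legend()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def ca_scatter(result: CAResult, path: str | Path,
               groups: Mapping[str, str] | None = None) -> None:
    """Scatter of CA axes 1-2, optionally coloured by organism group."""
    scores = result.row_scores
    fig, ax = plt.subplots(figsize=(6, 5))
    if groups:
        for g in sorted(set(groups.values())):
            members = [o for o in scores.index if groups.get(o) == g]
            sub = scores.loc[members]
            ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], s=18, label=g)
        ax.legend()
    else:
        ax.scatter(scores.iloc[:, 0], scores.iloc[:, 1], s=18)
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    ax.set_xlabel(f"axis 1 ({result.inertia_percent[0]:.1f}% inertia)")
    if result.n_axes > 1:
        ax.set_ylabel(f"axis 2 ({result.inertia_percent[1]:.1f}% inertia)")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
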