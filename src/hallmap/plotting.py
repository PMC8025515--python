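"""Optional matplotlib renderings of the comparison outputs.

These are conveniences over the TSV outputs, not publication-exact
reproductions of any particular figure style.
"""

from __future__ import annotations

from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from matplotlib.figure import Figure

from .setcomp import IntersectionProfile


def upset_matrix_plot(profile: IntersectionProfile, ax=None) -> "Figure":
    """Bar-plus-membership-matrix rendering of exclusive intersection counts."""
    import matplotlib.pyplot as plt

    names = sorted(profile.set_totals)
    combos = sorted(profile.exclusive, key=lambda c: -len(profile.exclusive[c]))
    counts = [len(profile.exclusive[c]) for c in combos]
    if ax is None:
        fig, (ax, ax_m) = plt.subplots(
            2, 1, sharex=True, figsize=(max(4, len(combos) * 0.5), 5),
            gridspec_kw={"height_ratios": [2, 1]},
        )
    else:
        fig = ax.figure
        ax_m = None
    xs = np.arange(len(combos))
    ax.bar(xs, counts, color="0.25")
    ax.set_ylabel("exclusive genes")
    if ax_m is not None:
        for j, combo in enumerate(combos):
            for i, name in enumerate(names):
                ax_m.plot(j, i, "o", color="0.15" if name in combo else "0.85", ms=6)
        ax_m.set_yticks(range(len(names)), names)
        ax_m.set_xticks([])
        ax_m.set_ylim(-0.5, len(names) - 0.5)
    fig.tight_layout()
    return fig


def similarity_heatmap(matrix: pd.DataFrame, title: str = "", ax=None) -> "Figure":
    """Heatmap of a symmetric similarity matrix (Jaccard or BMA scores)."""
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(max(3, 0.5 * len(matrix.columns) + 2), 4))
    else:
        fig = ax.figure
    im = ax.imshow(matrix.to_numpy(dtype=float), cmap="coolwarm", vmin=0, vmax=1)
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90)
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    return fig


def jaccard_heatmap(long_table: pd.DataFrame, ax=None) -> "Figure":
    """Combination x scheme-pair heatmap from the long-format Jaccard table."""
    import matplotlib.pyplot as plt

    table = long_table.assign(
        pair=long_table["scheme_a"] + " vs " + long_table["scheme_b"]
    ).pivot(index="combination", columns="pair", values="jaccard")
    if ax is None:
        fig, ax = plt.subplots(figsize=(max(4, 0.8 * table.shape[1] + 2),
                                        max(3, 0.3 * table.shape[0] + 1)))
    else:
        fig = ax.figure
    im = ax.imshow(table.to_numpy(dtype=float), cmap="coolwarm", vmin=0, vmax=1,
                   aspect="auto")
    ax.set_xticks(range(table.shape[1]), table.columns, rotation=45, ha="right")
    ax.set_yticks(range(table.shape[0]), table.index, fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    return fig
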