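"""Minimal gridded plots (no cartography)."""

from __future__ import annotations

import numpy as np

CATEGORY_COLORS = {
    "NS": "#d9d9d9",
    "NEO": "#d7191c",
    "PALEO": "#2c7bb6",
    "MIXED": "#c2a5cf",
    "SUPER": "#7b3294",
}


def plot_categories(canape_table, ax=None, cell_size: float = 1.0):
    """Plot per-cell CANAPE categories as colored grid squares.

    ``canape_table`` is the DataFrame from :func:`phylospat.canape.canape_classify`
    (indexed by "i_j" cell ids). Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    from .grid_io import parse_cell_id

    if ax is None:
        _, ax = plt.subplots()
    for cid, row in canape_table.iterrows():
        i, j = parse_cell_id(cid)
        ax.add_patch(
            Rectangle(
                (i * cell_size, j * cell_size),
                cell_size,
                cell_size,
                facecolor=CATEGORY_COLORS.get(row["category"], "#000000"),
                edgecolor="none",
            )
        )
    cells = np.array([parse_cell_id(c) for c in canape_table.index])
    ax.set_xlim(cells[:, 0].min() * cell_size, (cells[:, 0].max() + 1) * cell_size)
    ax.set_ylim(cells[:, 1].min() * cell_size, (cells[:, 1].max() + 1) * cell_size)
    ax.set_aspect("equal")
    return ax
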