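"""One plot helper: the ln-femur-length distribution by character state."""

from __future__ import annotations

import numpy as np

from .dataset import TraitTable


def group_quantile_plot(table: TraitTable, path=None):
    """Quantile (box) plot of ln femur length grouped by projection state
    (absent = 0 on top, present = 1 below), the standard summary figure for
    a binary-group size comparison.  Saves to ``path`` if given; returns the
    matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    y = table.ln_femur()
    z = table.projections
    groups = [y[z == 0], y[z == 1]]
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.boxplot(
        groups[::-1],
        vert=False,
        tick_labels=["present (1)", "absent (0)"],
        whis=(0, 100),
    )
    for gi, g in enumerate(groups[::-1], start=1):
        ax.plot(g, np.full_like(g, gi), "o", ms=4, alpha=0.5)
    ax.set_xlabel("femur length (ln cm)")
    ax.set_ylabel("metaplastic projections")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
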