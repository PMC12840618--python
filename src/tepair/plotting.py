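"""Basic figures: window profiles and the specificity heatmap.

Matplotlib is imported lazily so the core pipeline has no plotting
dependency; pass ``path`` to save, otherwise the Axes is returned.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .pairing import SpecificityMatrix


def plot_profile(
    profile: pd.DataFrame,
    path: str | Path | None = None,
    title: str = "Homotypic pairing profile",
):
    """Counts vs window offset; hotspot arm thick, coldfield arm thin."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    x = profile["window_offset_bp"] / 1_000
    hot_cols = [c for c in profile.columns if c.startswith("hot")]
    cold_cols = [c for c in profile.columns if c.startswith("cold")]
    for col in hot_cols:
        ax.plot(x, profile[col], lw=2.5, label=col)
    for col in cold_cols:
        ax.plot(x, profile[col], lw=1.0, label=col)
    ax.axvline(0, color="grey", lw=0.5, ls=":")
    ax.set_xlabel("window offset from contact point (kb)")
    ax.set_ylabel("homotypic pairing count")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return ax


def plot_matrix(
    matrix: SpecificityMatrix,
    path: str | Path | None = None,
    title: str = "Pairwise hot/cold specificity",
):
    """Family x family hot/cold ratio heatmap, diverging around 1."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = matrix.values.to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4.5))
    span = np.nanmax(np.abs(np.log2(values[np.isfinite(values) & (values > 0)])))
    im = ax.imshow(
        np.log2(values), cmap="RdBu_r", vmin=-span, vmax=span
    )
    ax.set_xticks(range(len(matrix.families)), matrix.families, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.families)), matrix.families, fontsize=7)
    fig.colorbar(im, ax=ax, label="log2 hot/cold ratio")
    ax.set_title(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return ax
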