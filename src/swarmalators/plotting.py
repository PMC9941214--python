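"""Static scatter export: positions coloured by phase."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .model import SwarmState

__all__ = ["save_scatter"]


def save_scatter(state: SwarmState, path: str | Path, title: str | None = None) -> None:
    """Save a scatter plot of a state, colouring each agent by its phase."""
    fig, ax = plt.subplots(figsize=(5, 5))
    phase01 = (state.phase % (2 * np.pi)) / (2 * np.pi)
    sc = ax.scatter(state.pos[:, 0], state.pos[:, 1], c=phase01, cmap="hsv", vmin=0, vmax=1, s=12)
    fig.colorbar(sc, ax=ax, label=r"phase / $2\pi$")
    ax.set_aspect("equal")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
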