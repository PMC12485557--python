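"""Histogram plotting for run outcome distributions."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .bn_io import state_to_string
from .emulator import OutcomeDistribution

__all__ = ["plot_distribution"]


def plot_distribution(
    dist: OutcomeDistribution,
    path: str,
    counts: np.ndarray | None = None,
    title: str = "",
    highlight: set[int] | None = None,
) -> None:
    """Bar plot of an outcome distribution (or shot counts) over all 2**n
    basis states; ``highlight`` marks chosen states in a different colour.
    Zero-probability outcomes are drawn at zero height, keeping the full
    state axis visible."""
    n = dist.n
    x = np.arange(1 << n)
    y = counts if counts is not None else dist.probs
    colors = [
        "tab:red" if highlight and s in highlight else "tab:blue" for s in x
    ]
    fig, ax = plt.subplots(figsize=(max(6, (1 << n) * 0.35), 4))
    ax.bar(x, y, color=colors)
    ax.set_xticks(x)
    ax.set_xticklabels([state_to_string(s, n) for s in x], rotation=90, fontsize=7)
    ax.set_xlabel("measured state")
    ax.set_ylabel("counts" if counts is not None else "probability")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
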