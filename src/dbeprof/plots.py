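"""Plotting helpers (positional profiles and substitution heatmaps).

Imported lazily so headless runs without plotting never touch matplotlib.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_profile(profile, path, center: int | None = None, halfwidth: int | None = None):
    """Per-position substitution-rate track, optionally marking the window."""
    fig, ax = plt.subplots(figsize=(9, 3))
    x = np.arange(len(profile))
    ax.plot(x, profile.substitution_rate, lw=0.8, color="tab:blue")
    if center is not None and halfwidth is not None:
        ax.axvspan(center - halfwidth, center + halfwidth, color="tab:orange", alpha=0.15)
        ax.axvline(center, color="tab:orange", lw=0.8, ls="--")
    ax.set_xlabel("reference position (bp)")
    ax.set_ylabel("substitution rate")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_combined(combined, path):
    """PAM-anchored multi-guide overlay with the across-guide mean."""
    fig, ax = plt.subplots(figsize=(9, 3))
    for name, vec in combined.per_guide.items():
        ax.plot(combined.rel_positions, vec, lw=0.6, alpha=0.5, label=name)
    ax.plot(combined.rel_positions, combined.mean_rate, lw=1.5, color="black", label="mean")
    ax.set_xlabel("position relative to PAM 3' end (bp)")
    ax.set_ylabel("substitution rate")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_spectrum_heatmap(spec, path):
    """Per-position ref->alt substitution-rate heatmap over the window."""
    df = spec.per_position
    mat = df[["A", "C", "G", "T"]].to_numpy().T
    fig, ax = plt.subplots(figsize=(9, 2.4))
    im = ax.imshow(mat, aspect="auto", cmap="viridis",
                   extent=(df["position"].min(), df["position"].max(), 3.5, -0.5))
    ax.set_yticks(range(4), list("ACGT"))
    ax.set_xlabel("reference position (bp)")
    ax.set_ylabel("substituted base")
    fig.colorbar(im, ax=ax, label="rate")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
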