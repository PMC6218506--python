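"""Convenience rendering of time series and lattice snapshots (matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .observables import SnapshotGrid


def plot_timeseries(series: pd.DataFrame, path) -> None:
    """c(t) and s(t) on a log-sweep axis."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(series["sweep"], series["c"], label="cooperation c")
    ax.plot(series["sweep"], series["s"], label="safe fraction s")
    if len(series) > 1 and series["sweep"].iloc[-1] > 0:
        ax.set_xscale("symlog")
    ax.set_xlabel("Monte Carlo sweep")
    ax.set_ylabel("fraction")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_snapshot(grid: SnapshotGrid, path) -> None:
    """Safe (dark) / dangerous (light) site map at one sweep."""
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(grid.labels, cmap="viridis", vmin=0, vmax=1, interpolation="nearest")
    ax.set_title(f"sweep {grid.sweep}")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
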