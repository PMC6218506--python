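"""Observables: cooperation/safe fractions, stationary statistics, snapshots, jump location.

The two order parameters are the cooperation fraction ``c`` (share of
cooperators) and the safe fraction ``s`` (share of agents whose perception
lies strictly below the cognition threshold); ``d = 1 - s`` is the dangerous
fraction.  Stationary values are trailing-window averages of the recorded
time series, then averaged over replicates.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lattice import LatticeWorld

__all__ = [
    "EnvironmentLabel",
    "SnapshotGrid",
    "cooperation_fraction",
    "safe_fraction",
    "dangerous_fraction",
    "stationary_mean",
    "stationary_stats",
    "perception_snapshot",
    "save_snapshot_csv",
    "locate_jump",
]


class EnvironmentLabel(enum.IntEnum):
    """Per-site environment classification; integer codes are the CSV encoding."""

    SAFE = 0
    DANGEROUS = 1


@dataclass(frozen=True)
class SnapshotGrid:
    """Per-site labels of one lattice at one sweep."""

    side: int
    labels: np.ndarray  # L x L int array over EnvironmentLabel codes
    sweep: int

    def counts(self) -> dict[EnvironmentLabel, int]:
        return {lab: int((self.labels == lab).sum()) for lab in EnvironmentLabel}


def cooperation_fraction(world: LatticeWorld) -> float:
    """Share of cooperators, (#cooperators) / L**2."""
    return float(world.strategy.mean())


def safe_fraction(world: LatticeWorld, theta_th: float) -> float:
    """Share of agents perceiving the environment as safe (theta < theta_th)."""
    return float((world.perception < theta_th).mean())


def dangerous_fraction(world: LatticeWorld, theta_th: float) -> float:
    """Share of agents perceiving the environment as dangerous; equals 1 - s."""
    return 1.0 - safe_fraction(world, theta_th)


def stationary_mean(series: pd.DataFrame, window: int) -> tuple[float, float]:
    """Arithmetic mean of the last ``window`` records of ``c`` and ``s``."""
    if window < 1:
        raise ValueError(f"window must be >= 1; got {window}")
    if window > len(series):
        raise ValueError(f"window {window} exceeds recorded span {len(series)}")
    tail = series.iloc[-window:]
    return float(tail["c"].mean()), float(tail["s"].mean())


def stationary_stats(series: pd.DataFrame, window_sweeps: int, record_every: int) -> tuple[float, float]:
    """Stationary (c, s) averaged over the trailing ``window_sweeps`` sweeps.

    Converts the sweep window to a record count given the recording cadence
    (at least one record is always used).
    """
    n_records = max(1, window_sweeps // record_every)
    return stationary_mean(series, min(n_records, len(series)))


def perception_snapshot(world: LatticeWorld, theta_th: float, sweep: int = 0) -> SnapshotGrid:
    """Label every site SAFE/DANGEROUS by the strict threshold predicate."""
    labels = np.where(
        world.perception < theta_th, int(EnvironmentLabel.SAFE), int(EnvironmentLabel.DANGEROUS)
    ).astype(np.int8)
    return SnapshotGrid(side=world.side, labels=labels, sweep=sweep)


def save_snapshot_csv(grid: SnapshotGrid, path) -> None:
    """Headerless integer CSV grid, {0 = safe, 1 = dangerous}."""
    np.savetxt(path, grid.labels, fmt="%d", delimiter=",")


def locate_jump(curve) -> float:
    """Threshold value at which an ordered (theta_th, s) curve rises fastest.

    ``curve`` is a sequence of (theta_th, value) pairs sorted by theta_th on
    a uniform grid (an (k, 2) array, list of pairs, or DataFrame whose first
    two columns are abscissa and ordinate).  Returns the right edge of the
    largest forward difference — the first grid point at which the elevated
    value is attained; ties break toward the smaller theta_th.
    """
    arr = np.asarray(curve, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("curve must be a sequence of (theta_th, value) pairs")
    if arr.shape[0] < 2:
        raise ValueError("locate_jump needs at least two points")
    x = arr[:, 0]
    if np.any(np.diff(x) <= 0):
        raise ValueError("curve must be sorted by strictly increasing theta_th")
    diffs = np.diff(arr[:, 1])
    i = int(np.argmax(diffs))  # argmax takes the first maximum: smaller-theta tie-break
    return float(x[i + 1])
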