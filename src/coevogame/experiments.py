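"""Parameter-sweep drivers: threshold sweeps, dynamics runs, snapshot schedules.

These reproduce the phase-behaviour experiments — stationary cooperation and
safe fractions versus the cognition threshold for several temptation values —
at a configurable scale.  Scaled-down defaults (L = 50, 2,000 sweeps,
stationary window 500, 5 replicates) keep a full sweep within minutes on one
CPU; the full-scale setup (L = 100, 61,000 sweeps, 10 replicates) is
available through ``paper_scale_params``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dynamics import SimulationResult, run_simulation, write_timeseries_csv
from .lattice import Neighborhood, SimulationParams
from .observables import SnapshotGrid, perception_snapshot, save_snapshot_csv, stationary_stats

__all__ = [
    "SCALED_DEFAULTS",
    "PAPER_DEFAULTS",
    "ExperimentSpec",
    "SweepResult",
    "make_theta_grid",
    "scaled_params",
    "paper_scale_params",
    "cell_seed",
    "run_replicates",
    "run_threshold_sweep",
    "run_dynamics_experiment",
    "run_snapshot_experiment",
    "write_manifest",
]

# Reduced problem size for tests/desk runs: the observables stabilise well
# before 2,000 sweeps at L = 50 (the full-scale dynamics flatten within a few
# hundred sweeps already).
SCALED_DEFAULTS = dict(L=50, sweeps=2_000, stationary_window=500, replicates=5)
PAPER_DEFAULTS = dict(L=100, sweeps=61_000, stationary_window=1_000, replicates=10)


def scaled_params(b0: float, theta_th: float, **overrides) -> SimulationParams:
    """Reduced-scale parameters (L = 50, 2,000 sweeps, 5 replicates)."""
    kw = dict(SCALED_DEFAULTS)
    kw.update(overrides)
    return SimulationParams(b0=b0, theta_th=theta_th, **kw)


def paper_scale_params(b0: float, theta_th: float, **overrides) -> SimulationParams:
    """Full-scale parameters (L = 100, 61,000 sweeps, 10 replicates)."""
    kw = dict(PAPER_DEFAULTS)
    kw.update(overrides)
    return SimulationParams(b0=b0, theta_th=theta_th, **kw)


def make_theta_grid(start: float = 0.0, stop: float = 1.0, step: float = 0.01) -> np.ndarray:
    """Uniform threshold grid, endpoint included, free of float drift."""
    if step <= 0:
        raise ValueError(f"grid step must be > 0; got {step}")
    n = int(round((stop - start) / step))
    grid = np.round(start + step * np.arange(n + 1), 10)
    return grid[grid <= stop + 1e-9]


@dataclass(frozen=True)
class ExperimentSpec:
    """A threshold sweep: temptation values x threshold grid x replicates."""

    b0_values: tuple[float, ...]
    theta_grid: tuple[float, ...]
    base: SimulationParams
    outdir: Path | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "b0_values", tuple(float(b) for b in self.b0_values))
        object.__setattr__(self, "theta_grid", tuple(float(t) for t in self.theta_grid))
        if self.outdir is not None:
            object.__setattr__(self, "outdir", Path(self.outdir))
        for b in self.b0_values:
            if b < 1.0:
                raise ValueError(f"b0 values must be >= 1; got {b}")


@dataclass
class SweepResult:
    """Stationary observables per sweep cell.

    ``replicates`` holds one row per (b0, theta_th, replicate);
    ``means`` averages the replicates per (b0, theta_th).  Both carry
    ``c`` (cooperation), ``s`` (safe) and ``d = 1 - s`` columns.
    """

    replicates: pd.DataFrame
    means: pd.DataFrame


def cell_seed(base_seed: int, b_index: int, theta_index: int, replicate: int) -> list[int]:
    """Deterministic, order-independent seed material for one sweep cell."""
    return [int(base_seed), int(b_index), int(theta_index), int(replicate)]


def _stationary(result: SimulationResult) -> tuple[float, float]:
    p = result.params
    return stationary_stats(result.series, p.stationary_window, p.record_every)


def run_replicates(params: SimulationParams, engine: str = "numba") -> pd.DataFrame:
    """Independent replicate runs; replicate ``r`` uses seed ``params.seed + r``.

    Returns one row per replicate with stationary ``c``, ``s`` and ``d``.
    """
    rows = []
    for r in range(params.replicates):
        result = run_simulation(params, seed=params.seed + r, engine=engine)
        c, s = _stationary(result)
        rows.append((r, c, s, 1.0 - s))
    return pd.DataFrame(rows, columns=["replicate", "c", "s", "d"])


def run_threshold_sweep(spec: ExperimentSpec) -> SweepResult:
    """Run every (b0, theta_th, replicate) cell and collect stationary stats.

    Cell seeds derive from (base seed, b0 index, theta index, replicate), so
    cells may be computed in any order with identical results.  If the spec
    has an output directory, per-replicate and mean tables are written as
    ``sweep_replicates.csv`` / ``sweep_means.csv`` (header
    ``b0,theta_th,replicate,c,s,d``) after checking the directory is
    writable before any simulation starts.
    """
    outdir = spec.outdir
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        if not os.access(outdir, os.W_OK):
            raise PermissionError(f"output directory {outdir} is not writable")
    rows = []
    for bi, b0 in enumerate(spec.b0_values):
        for ti, theta in enumerate(spec.theta_grid):
            params = spec.base.with_(b0=b0, theta_th=theta)
            for r in range(params.replicates):
                seed = cell_seed(spec.base.seed, bi, ti, r)
                result = run_simulation(params, seed=seed)
                c, s = _stationary(result)
                rows.append((b0, theta, r, c, s, 1.0 - s))
    reps = pd.DataFrame(rows, columns=["b0", "theta_th", "replicate", "c", "s", "d"])
    means = (
        reps.groupby(["b0", "theta_th"], sort=True)[["c", "s", "d"]]
        .mean()
        .reset_index()
    )
    if outdir is not None:
        reps.to_csv(outdir / "sweep_replicates.csv", index=False)
        means.to_csv(outdir / "sweep_means.csv", index=False)
    return SweepResult(replicates=reps, means=means)


def run_dynamics_experiment(
    params: SimulationParams, thresholds: Sequence[float], outdir: Path | None = None
) -> dict[float, pd.DataFrame]:
    """One time series per threshold, all else equal.

    Each series is recorded every ``params.record_every`` sweeps and, if an
    output directory is given, written as ``dynamics_theta<value>.csv``.
    """
    out: dict[float, pd.DataFrame] = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
    for theta in thresholds:
        result = run_simulation(params.with_(theta_th=float(theta)))
        out[float(theta)] = result.series
        if outdir is not None:
            write_timeseries_csv(result.series, outdir / f"dynamics_theta{theta:g}.csv")
    return out


def run_snapshot_experiment(
    params: SimulationParams, capture_sweeps: Sequence[int], outdir: Path | None = None
) -> list[SnapshotGrid]:
    """Safe/dangerous snapshots of the SAME run at the requested sweeps."""
    captures = list(capture_sweeps)
    if captures != sorted(captures):
        raise ValueError("capture sweeps must be sorted ascending")
    for k in captures:
        if k > params.sweeps:
            raise ValueError(f"capture sweep {k} exceeds total sweeps {params.sweeps}")
    result = run_simulation(params, capture_sweeps=captures)
    grids = [
        perception_snapshot(result.captures[k], params.theta_th, sweep=k) for k in captures
    ]
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for grid in grids:
            save_snapshot_csv(grid, outdir / f"snapshot_sweep{grid.sweep}.csv")
    return grids


def write_manifest(path, params: SimulationParams, extra: dict | None = None) -> None:
    """Record fully resolved parameters (and seeds) of a run as plain text."""
    lines = [f"{k} = {v}" for k, v in sorted(vars(params).items())]
    if extra:
        lines += [f"{k} = {v}" for k, v in sorted(extra.items())]
    Path(path).write_text("\n".join(str(l) for l in lines) + "\n")
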