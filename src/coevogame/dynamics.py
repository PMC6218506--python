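"""Coevolutionary update rules and the asynchronous Monte Carlo scheduler.

Two coupled rules drive the dynamics.  When a randomly chosen neighbour *y*
of the focal agent *x* is strictly more successful (U_y > U_x):

* **Perception.**  If *x* and *y* classify the environment the same way,
  *x* reinforces its perception by moving it a step ``delta`` away from the
  cognition threshold (toward 0 on the safe side, toward 1 on the dangerous
  side).  If they classify it oppositely, *x* copies theta_y with the Fermi
  probability ``1 / (1 + exp((dx - dy) / tt))`` where ``dx = |theta_x -
  theta_th|``, ``dy = |theta_y - theta_th|`` and the noise is ``tt =
  max(theta_th, 1 - theta_th)`` — the largest possible distance between a
  perception and the threshold.  The result is clamped to [0, 1].

* **Strategy.**  *x* copies *y*'s strategy with the linear probability
  ``(U_y - U_x) / (degree * b0)``, whose denominator is the maximum
  attainable utility.

Both decisions are evaluated on the same pre-update snapshot ("at the same
time"); the perception write lands before the strategy write.  One Monte
Carlo sweep performs ``L**2`` elementary updates, so each agent is updated
once on average per sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from . import _kernel
from .game import total_utility
from .lattice import (
    EventRecord,
    LatticeWorld,
    SimulationParams,
    build_lattice,
    perceives_safe,
)

__all__ = [
    "FermiTerms",
    "SimulationResult",
    "fermi_copy_probability",
    "update_perception",
    "strategy_copy_probability",
    "elementary_update",
    "run_simulation",
    "write_timeseries_csv",
]


@dataclass(frozen=True)
class FermiTerms:
    """Intermediate quantities of the perception-copy probability.

    Exposed individually so each term can be checked: ``0 <= delta_x,
    delta_y <= tt``, ``0.5 <= tt <= 1`` and ``p`` strictly inside (0, 1).
    """

    delta_x: float
    delta_y: float
    tt: float
    p: float


def fermi_copy_probability(theta_x: float, theta_y: float, theta_th: float) -> FermiTerms:
    """Fermi probability that *x* copies *y*'s perception.

    Only defined when the two agents classify the environment differently
    (opposite sides of the threshold); same-side pairs take the
    reinforcement branch instead and calling this for them is a contract
    violation.
    """
    if perceives_safe(theta_x, theta_th) == perceives_safe(theta_y, theta_th):
        raise ValueError(
            "fermi_copy_probability requires opposite perceptions; "
            f"theta_x={theta_x}, theta_y={theta_y} are on the same side of {theta_th}"
        )
    tt = max(theta_th, 1.0 - theta_th)
    dx = abs(theta_x - theta_th)
    dy = abs(theta_y - theta_th)
    p = 1.0 / (1.0 + math.exp((dx - dy) / tt))
    return FermiTerms(delta_x=dx, delta_y=dy, tt=tt, p=p)


def _new_perception(
    theta_x: float, theta_y: float, theta_th: float, delta: float, u: float
) -> float:
    """Post-update perception of the focal agent (clamped to [0, 1]).

    ``u`` is the uniform variate deciding the Fermi copy; it is ignored on
    the reinforcement branch but always consumed by callers so the RNG
    stream does not depend on which branch fires.
    """
    safe_x = perceives_safe(theta_x, theta_th)
    safe_y = perceives_safe(theta_y, theta_th)
    if safe_x and safe_y:
        nt = theta_x - delta
    elif not safe_x and not safe_y:
        nt = theta_x + delta
    else:
        tt = max(theta_th, 1.0 - theta_th)
        p = 1.0 / (1.0 + math.exp((abs(theta_x - theta_th) - abs(theta_y - theta_th)) / tt))
        nt = theta_y if u < p else theta_x
    return min(1.0, max(0.0, nt))


def update_perception(
    world: LatticeWorld,
    x: tuple[int, int],
    y: tuple[int, int],
    params: SimulationParams,
    rng: np.random.Generator,
) -> float:
    """Apply the perception rule to focal site ``x`` against neighbour ``y``.

    The caller must already have established U_y > U_x.  Returns the new
    theta_x (also written into the world).
    """
    u = float(rng.random())
    nt = _new_perception(
        float(world.perception[x]), float(world.perception[y]), params.theta_th, params.delta, u
    )
    world.perception[x] = nt
    return nt


def strategy_copy_probability(u_x: float, u_y: float, b0: float, degree: int) -> float:
    """Probability that *x* copies the strategy of a more successful *y*.

    Linear in the utility gap, normalised by the maximum attainable utility
    ``degree * b0`` so the result is guaranteed to lie in (0, 1].
    """
    if not u_y > u_x:
        raise ValueError(f"strategy copy requires U_y > U_x; got U_x={u_x}, U_y={u_y}")
    return (u_y - u_x) / (degree * b0)


def _apply_update(
    world: LatticeWorld,
    params: SimulationParams,
    flat_x: int,
    neighbor_choice: int,
    u_perc: float,
    u_strat: float,
) -> EventRecord:
    """One elementary update with the random choices supplied explicitly.

    Reference (pure-Python) semantics; the numba kernel in
    :mod:`coevogame._kernel` replays exactly this logic.
    """
    L = world.side
    table = world.neighbor_table()
    flat_y = int(table[flat_x, neighbor_choice])
    x = divmod(flat_x, L)
    y = divmod(flat_y, L)
    u_x = total_utility(world, x, params)
    u_y = total_utility(world, y, params)
    perception_changed = False
    strategy_changed = False
    if u_y > u_x:
        old_theta = float(world.perception[x])
        nt = _new_perception(
            old_theta, float(world.perception[y]), params.theta_th, params.delta, u_perc
        )
        world.perception[x] = nt
        perception_changed = nt != old_theta
        p = strategy_copy_probability(u_x, u_y, params.b0, params.degree)
        if u_strat < p:
            old_s = world.strategy[x]
            world.strategy[x] = world.strategy[y]
            strategy_changed = world.strategy[x] != old_s
    return EventRecord(
        x=x, y=y, u_x=u_x, u_y=u_y,
        perception_changed=perception_changed, strategy_changed=strategy_changed,
    )


def elementary_update(
    world: LatticeWorld, params: SimulationParams, rng: np.random.Generator
) -> EventRecord:
    """One asynchronous elementary update with random focal agent and neighbour.

    Exactly four variates are consumed per call, in a fixed order — focal
    index, neighbour choice, perception uniform, strategy uniform — whether
    or not the utility gate fires.
    """
    flat_x = int(rng.integers(world.n_agents))
    choice = int(rng.integers(world.degree))
    u_perc = float(rng.random())
    u_strat = float(rng.random())
    return _apply_update(world, params, flat_x, choice, u_perc, u_strat)


def _apply_block_python(
    world: LatticeWorld,
    params: SimulationParams,
    focal: np.ndarray,
    nchoice: np.ndarray,
    u_perc: np.ndarray,
    u_strat: np.ndarray,
) -> None:
    for i in range(focal.shape[0]):
        _apply_update(world, params, int(focal[i]), int(nchoice[i]), float(u_perc[i]), float(u_strat[i]))


@dataclass
class SimulationResult:
    """A finished run: observable time series, final world, optional snapshots."""

    params: SimulationParams
    seed: int
    series: pd.DataFrame  # columns: sweep, c, s
    world: LatticeWorld
    captures: dict[int, LatticeWorld] = field(default_factory=dict)


def run_simulation(
    params: SimulationParams,
    seed: int | Iterable[int] | None = None,
    capture_sweeps: Iterable[int] | None = None,
    engine: Literal["numba", "python"] = "numba",
) -> SimulationResult:
    """Run ``params.sweeps`` Monte Carlo sweeps from a fresh initial world.

    Observables (cooperation fraction ``c``, safe fraction ``s``) are
    recorded at sweep 0 and every ``params.record_every`` sweeps thereafter.
    ``capture_sweeps`` requests full world snapshots at the given sweep
    indices.  ``seed`` overrides ``params.seed`` (replicate drivers pass
    derived seeds).  The run is fully reproducible: identical parameters and
    seed give bit-identical output on both engines, which consume the same
    random stream.
    """
    used_seed = params.seed if seed is None else seed
    rng = np.random.default_rng(used_seed)
    world = build_lattice(params, rng)
    n = params.n_agents
    deg = params.degree
    theta_th = params.theta_th

    wanted_captures = sorted(set(int(k) for k in capture_sweeps)) if capture_sweeps else []
    for k in wanted_captures:
        if k < 0 or k > params.sweeps:
            raise ValueError(f"capture sweep {k} outside [0, {params.sweeps}]")

    strat_flat = world.strategy.ravel()
    theta_flat = world.perception.ravel()
    nbr = world.neighbor_table()

    records: list[tuple[int, float, float]] = [
        (0, float(strat_flat.mean()), float((theta_flat < theta_th).mean()))
    ]
    captures: dict[int, LatticeWorld] = {}
    if wanted_captures and wanted_captures[0] == 0:
        captures[0] = world.copy()

    record_points = set(range(params.record_every, params.sweeps + 1, params.record_every))
    events = sorted(record_points | set(k for k in wanted_captures if k > 0) | (
        {params.sweeps} if params.sweeps > 0 else set()
    ))

    prev = 0
    for ev in events:
        block = ev - prev
        if block > 0:
            m = block * n
            focal = rng.integers(0, n, size=m)
            nchoice = rng.integers(0, deg, size=m)
            u_perc = rng.random(m)
            u_strat = rng.random(m)
            if engine == "numba":
                _kernel.run_block(
                    strat_flat, theta_flat, nbr, focal, nchoice, u_perc, u_strat,
                    params.b0, params.b1, theta_th, params.delta,
                )
            elif engine == "python":
                _apply_block_python(world, params, focal, nchoice, u_perc, u_strat)
            else:
                raise ValueError(f"unknown engine {engine!r}")
        prev = ev
        if ev in record_points:
            records.append((ev, float(strat_flat.mean()), float((theta_flat < theta_th).mean())))
        if ev in captures or ev in wanted_captures:
            captures.setdefault(ev, world.copy())

    series = pd.DataFrame(records, columns=["sweep", "c", "s"])
    return SimulationResult(
        params=params, seed=used_seed, series=series, world=world, captures=captures
    )


def write_timeseries_csv(series: pd.DataFrame, path) -> None:
    """Write a time series as CSV with header ``sweep,c,s``."""
    series.to_csv(path, index=False)
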