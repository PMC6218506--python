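"""Lattice world: agents, parameters, initial populations and toroidal neighbourhoods.

Agents live on an ``L x L`` square lattice with periodic boundary conditions.
Each agent carries a binary strategy (cooperate/defect) and a continuous
environmental-perception value ``theta`` in ``[0, 1]``.  An agent whose
perception lies strictly below the population-wide cognition threshold
``theta_th`` considers the environment *safe*; otherwise it considers the
environment *dangerous*.
"""

from __future__ import annotations

import enum
import functools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Strategy",
    "Neighborhood",
    "SimulationParams",
    "AgentState",
    "LatticeWorld",
    "EventRecord",
    "build_lattice",
    "neighbor_sites",
    "neighbor_table",
    "perceives_safe",
    "save_strategy_grid",
    "save_perception_grid",
    "load_strategy_grid",
    "load_perception_grid",
]


class Strategy(enum.IntEnum):
    """Binary game strategy; integer codes are the on-disk representation."""

    DEFECT = 0
    COOPERATE = 1


class Neighborhood(str, enum.Enum):
    """Lattice interaction topology."""

    MOORE8 = "moore8"
    VONNEUMANN4 = "vonneumann4"

    @property
    def degree(self) -> int:
        return 8 if self is Neighborhood.MOORE8 else 4

    @property
    def offsets(self) -> tuple[tuple[int, int], ...]:
        if self is Neighborhood.MOORE8:
            return ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))
        return ((-1, 0), (0, -1), (0, 1), (1, 0))


@dataclass(frozen=True)
class SimulationParams:
    """All model constants for one simulation.

    Parameters
    ----------
    b0
        Temptation of the weak prisoner's dilemma played by agents who
        perceive the environment as safe.  Must satisfy ``b0 >= 1``;
        ``b0 = 1`` is the degenerate boundary at which the two games
        coincide up to the temptation gap and is admitted only for
        comparison sweeps.
    theta_th
        Population-wide cognition threshold in ``[0, 1]``.  An agent with
        perception ``theta < theta_th`` considers the environment safe.
    L
        Lattice side length; the population holds ``L**2`` agents.
    neighborhood
        ``moore8`` (8 neighbours) or ``vonneumann4`` (4 neighbours).
    b1
        Temptation of the harmony game played by agents who perceive the
        environment as dangerous; ``0 < b1 < 1``.
    delta
        Perception learning rate in ``[0, 1]`` used by the reinforcement
        branch of the perception update.
    sweeps
        Number of Monte Carlo sweeps; one sweep performs ``L**2``
        asynchronous elementary updates.
    record_every
        Sweeps between recorded observables.
    stationary_window
        Number of trailing sweeps averaged for stationary statistics.
    seed
        Base RNG seed; replicate ``r`` of a replicated run uses ``seed + r``.
    replicates
        Number of independent runs averaged by replicate drivers.
    """

    b0: float
    theta_th: float
    L: int = 100
    neighborhood: Neighborhood = Neighborhood.MOORE8
    b1: float = 0.9
    delta: float = 0.001
    sweeps: int = 61_000
    record_every: int = 1
    stationary_window: int = 1_000
    seed: int = 0
    replicates: int = 10

    def __post_init__(self) -> None:
        object.__setattr__(self, "neighborhood", Neighborhood(self.neighborhood))
        if not self.b0 >= 1.0:
            raise ValueError(f"b0 must be >= 1 (weak PD temptation); got {self.b0}")
        if not 0.0 < self.b1 < 1.0:
            raise ValueError(f"b1 must lie in (0, 1) (harmony-game temptation); got {self.b1}")
        if not 0.0 <= self.theta_th <= 1.0:
            raise ValueError(f"theta_th must lie in [0, 1]; got {self.theta_th}")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"delta must lie in [0, 1]; got {self.delta}")
        if self.L < 2:
            raise ValueError(f"L must be >= 2; got {self.L}")
        if self.sweeps < 0:
            raise ValueError(f"sweeps must be >= 0; got {self.sweeps}")
        if self.record_every < 1:
            raise ValueError(f"record_every must be >= 1; got {self.record_every}")
        if self.stationary_window < 1:
            raise ValueError(f"stationary_window must be >= 1; got {self.stationary_window}")
        if self.sweeps >= 1 and self.stationary_window > self.sweeps:
            raise ValueError(
                f"stationary_window ({self.stationary_window}) exceeds sweeps ({self.sweeps})"
            )
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1; got {self.replicates}")

    @property
    def n_agents(self) -> int:
        return self.L * self.L

    @property
    def degree(self) -> int:
        return self.neighborhood.degree

    def with_(self, **kwargs) -> "SimulationParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class AgentState:
    """One agent's strategy and perception value."""

    strategy: Strategy
    perception: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.perception <= 1.0:
            raise ValueError(f"perception must lie in [0, 1]; got {self.perception}")


@dataclass(frozen=True)
class EventRecord:
    """What happened during one elementary update.

    Perception or strategy changes imply the update gate ``U_y > U_x`` fired.
    """

    x: tuple[int, int]
    y: tuple[int, int]
    u_x: float
    u_y: float
    perception_changed: bool
    strategy_changed: bool


@dataclass
class LatticeWorld:
    """``L x L`` toroidal grid of agent states.

    ``strategy`` is an int8 array over {0 = defect, 1 = cooperate};
    ``perception`` is a float64 array over ``[0, 1]``.  Both are addressed
    ``[row, col]`` with 0-based row-major coordinates.
    """

    side: int
    neighborhood: Neighborhood
    strategy: np.ndarray = field(repr=False)
    perception: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.neighborhood = Neighborhood(self.neighborhood)
        shape = (self.side, self.side)
        if self.strategy.shape != shape or self.perception.shape != shape:
            raise ValueError("strategy and perception grids must both be L x L")

    @property
    def n_agents(self) -> int:
        return self.side * self.side

    @property
    def degree(self) -> int:
        return self.neighborhood.degree

    def agent(self, site: tuple[int, int]) -> AgentState:
        r, c = site
        return AgentState(Strategy(int(self.strategy[r, c])), float(self.perception[r, c]))

    def neighbor_table(self) -> np.ndarray:
        """Flat-index neighbour table of shape ``(L*L, degree)``."""
        return neighbor_table(self.side, self.neighborhood)

    def copy(self) -> "LatticeWorld":
        return LatticeWorld(
            self.side, self.neighborhood, self.strategy.copy(), self.perception.copy()
        )


def perceives_safe(theta: float, theta_th: float) -> bool:
    """True iff an agent with perception ``theta`` considers the environment safe.

    The comparison is strict: at ``theta == theta_th`` the environment is
    considered dangerous, so ``theta_th = 0`` classifies every agent as
    dangerous and ``theta_th = 1`` classifies (almost) every agent as safe.
    """
    return theta < theta_th


def neighbor_sites(
    site: tuple[int, int], L: int, neighborhood: Neighborhood | str
) -> list[tuple[int, int]]:
    """Ordered neighbour sites of ``site`` on the ``L x L`` torus.

    Offsets are applied in a fixed row-major order and wrapped modulo ``L``.
    The focal site is never included.  For ``L = 2`` with the Moore
    neighbourhood, wraparound makes some sites appear more than once; the
    degree is constant regardless.
    """
    neighborhood = Neighborhood(neighborhood)
    r, c = site
    if not (0 <= r < L and 0 <= c < L):
        raise ValueError(f"site {site} out of bounds for L={L}")
    return [((r + dr) % L, (c + dc) % L) for dr, dc in neighborhood.offsets]


@functools.lru_cache(maxsize=32)
def neighbor_table(L: int, neighborhood: Neighborhood) -> np.ndarray:
    """Precomputed flat-index neighbour table, shape ``(L*L, degree)``.

    Row ``i`` lists the flat indices (``row * L + col``) of site ``i``'s
    neighbours in the same fixed offset order as :func:`neighbor_sites`.
    """
    neighborhood = Neighborhood(neighborhood)
    table = np.empty((L * L, neighborhood.degree), dtype=np.int64)
    for r in range(L):
        for c in range(L):
            for j, (nr, nc) in enumerate(neighbor_sites((r, c), L, neighborhood)):
                table[r * L + c, j] = nr * L + nc
    table.setflags(write=False)
    return table


def build_lattice(params: SimulationParams, rng: np.random.Generator) -> LatticeWorld:
    """Construct the initial population.

    Strategies are equally divided: exactly ``L**2 / 2`` cooperators and as
    many defectors, placed by a random permutation (an exact split removes
    initial-composition variance).  Perceptions are drawn independently from
    Uniform[0, 1].  The RNG is consumed in a fixed order (strategies first,
    then perceptions) so a given seed reproduces the world bit for bit.
    """
    n = params.n_agents
    if n % 2 != 0:
        raise ValueError(
            f"L**2 = {n} is odd: an exact half/half cooperator/defector split is "
            "impossible; use an even number of agents"
        )
    strategies = np.zeros(n, dtype=np.int8)
    strategies[: n // 2] = 1
    strategies = rng.permutation(strategies)
    perceptions = rng.random(n)
    return LatticeWorld(
        params.L,
        params.neighborhood,
        strategies.reshape(params.L, params.L),
        perceptions.reshape(params.L, params.L),
    )


def save_strategy_grid(world: LatticeWorld, path) -> None:
    """Headerless integer CSV grid, {1 = cooperate, 0 = defect}."""
    np.savetxt(path, world.strategy, fmt="%d", delimiter=",")


def save_perception_grid(world: LatticeWorld, path) -> None:
    """Headerless real-valued CSV grid of perception values."""
    np.savetxt(path, world.perception, fmt="%.17g", delimiter=",")


def load_strategy_grid(path) -> np.ndarray:
    return np.loadtxt(path, dtype=np.int8, delimiter=",", ndmin=2)


def load_perception_grid(path) -> np.ndarray:
    return np.loadtxt(path, dtype=np.float64, delimiter=",", ndmin=2)
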