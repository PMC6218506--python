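"""Payoff matrices for the two environments and multigame utility computation.

Agents who perceive the environment as safe play Nowak's weak prisoner's
dilemma (T = b0 > 1, R = 1, S = P = 0); agents who perceive it as dangerous
play a harmony game (T = b1 < 1, R = 1, S = P = 0).  Each agent always scores
its interactions with its OWN matrix, selected by its own perception — this
is what makes the population a multigame.
"""

from __future__ import annotations

from typing import NamedTuple

from .lattice import LatticeWorld, SimulationParams, Strategy, perceives_safe

__all__ = ["PayoffMatrix", "payoff_matrix_for", "pairwise_payoff", "total_utility"]


class PayoffMatrix(NamedTuple):
    """The (T, R, S, P) quadruple of a symmetric 2x2 game."""

    T: float
    R: float = 1.0
    S: float = 0.0
    P: float = 0.0


def payoff_matrix_for(safe: bool, b0: float, b1: float) -> PayoffMatrix:
    """Matrix an agent uses given its perception of the environment.

    ``safe`` selects the weak PD (T = b0 > 1, strictly); ``dangerous``
    selects the harmony game (T = b1, 0 < b1 < 1).  R = 1 and S = P = 0 in
    both environments.
    """
    if not b0 > 1.0:
        raise ValueError(f"weak PD requires temptation b0 > 1; got {b0}")
    if not 0.0 < b1 < 1.0:
        raise ValueError(f"harmony game requires 0 < b1 < 1; got {b1}")
    return PayoffMatrix(T=b0 if safe else b1)


def pairwise_payoff(matrix: PayoffMatrix, mine: Strategy, theirs: Strategy) -> float:
    """Payoff the focal agent earns from one interaction under ``matrix``."""
    if mine == Strategy.COOPERATE:
        return matrix.R if theirs == Strategy.COOPERATE else matrix.S
    return matrix.T if theirs == Strategy.COOPERATE else matrix.P


def total_utility(
    world: LatticeWorld, site: tuple[int, int], params: SimulationParams
) -> float:
    """Total utility of ``site``: sum of pairwise payoffs against all neighbours.

    The matrix is chosen once from the focal agent's own perception (it is
    built directly from the parameters so the degenerate boundary b0 = 1 used
    by comparison sweeps remains runnable).  Utilities are recomputed from
    the current state on demand — never cached — so asynchronous updates
    always see fresh values.
    """
    L = world.side
    r, c = site
    if not (0 <= r < L and 0 <= c < L):
        raise ValueError(f"site {site} out of bounds for L={L}")
    theta = float(world.perception[r, c])
    matrix = PayoffMatrix(T=params.b0 if perceives_safe(theta, params.theta_th) else params.b1)
    mine = Strategy(int(world.strategy[r, c]))
    flat = world.strategy.ravel()
    table = world.neighbor_table()
    return sum(
        pairwise_payoff(matrix, mine, Strategy(int(flat[j]))) for j in table[r * L + c]
    )
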