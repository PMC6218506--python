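"""Numba-compiled inner loop of the asynchronous Monte Carlo scheduler.

The kernel consumes pre-generated random variates (4 per elementary update:
focal index, neighbour choice, perception uniform, strategy uniform) so its
trajectory is bit-identical to the pure-Python engine in
:mod:`coevogame.dynamics` when fed the same arrays.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _utility(strat, theta, nbr, i, b0, b1, theta_th):
    # focal agent's own matrix: T = b0 if it perceives safety (theta < theta_th), else b1
    t = b0 if theta[i] < theta_th else b1
    s = strat[i]
    u = 0.0
    for k in range(nbr.shape[1]):
        sj = strat[nbr[i, k]]
        if s == 1:
            if sj == 1:
                u += 1.0
        else:
            if sj == 1:
                u += t
    return u


@njit(cache=True)
def run_block(strat, theta, nbr, focal, nchoice, u_perc, u_strat, b0, b1, theta_th, delta):
    """Apply a block of elementary updates in place.

    ``focal[i]`` is the flat index of the focal agent of update ``i``;
    ``nchoice[i]`` indexes its neighbour list; ``u_perc``/``u_strat`` are the
    uniforms for the perception-copy and strategy-copy decisions.  Both
    update rules are gated on the strict utility inequality U_y > U_x and
    evaluate their probabilities on the pre-update snapshot; the perception
    write happens before the strategy write.
    """
    tt = theta_th if theta_th >= 0.5 else 1.0 - theta_th
    denom = nbr.shape[1] * b0
    for i in range(focal.shape[0]):
        x = focal[i]
        y = nbr[x, nchoice[i]]
        ux = _utility(strat, theta, nbr, x, b0, b1, theta_th)
        uy = _utility(strat, theta, nbr, y, b0, b1, theta_th)
        if uy > ux:
            tx = theta[x]
            ty = theta[y]
            safe_x = tx < theta_th
            safe_y = ty < theta_th
            if safe_x and safe_y:
                nt = tx - delta  # reinforce: move away from the threshold, toward 0
            elif (not safe_x) and (not safe_y):
                nt = tx + delta  # reinforce: move away from the threshold, toward 1
            else:
                dx = abs(tx - theta_th)
                dy = abs(ty - theta_th)
                p = 1.0 / (1.0 + math.exp((dx - dy) / tt))
                nt = ty if u_perc[i] < p else tx
            if nt >= 1.0:
                nt = 1.0
            elif nt <= 0.0:
                nt = 0.0
            theta[x] = nt
            if u_strat[i] < (uy - ux) / denom:
                strat[x] = strat[y]
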