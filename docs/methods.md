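# Methods

## Model

The population lives on an L×L square lattice with periodic boundaries.
Each site holds one agent with a binary strategy s ∈ {cooperate, defect}
and a perception value θ ∈ [0, 1]. A single population-wide cognition
threshold θ_th classifies agents: θ < θ_th (strictly) means the agent
perceives the environment as *safe*, otherwise as *dangerous*. The strict
inequality makes the edge cases unambiguous: at θ_th = 0 nobody is safe, at
θ_th = 1 almost everybody is.

Perception selects the game. Safe agents score their interactions with the
weak prisoner's dilemma (T = b₀ > 1, R = 1, S = P = 0); dangerous agents
with a harmony game (T = b₁ < 1, R = 1, S = P = 0). In a mixed pair each
agent uses its own matrix — that is the multigame assumption: the same
encounter is a different game to differently-minded players. An agent's
total utility is the sum of its pairwise payoffs against all k neighbours
(k = 8 Moore, k = 4 von Neumann), recomputed from the current state on
demand and never cached, so asynchronous updates always compare fresh
values.

### Update rules

One sweep = L² elementary updates. Each update draws a uniform random focal
agent x and a uniform random neighbour y, and fires only on the strict
utility gate U_y > U_x; ties change nothing. When the gate fires, both
decisions are evaluated on the same pre-update snapshot, the perception
write landing before the strategy write:

1. *Perception.* Same-side pairs reinforce: θ_x moves δ away from the
   threshold (toward 0 on the safe side, toward 1 on the dangerous side),
   clamped to [0, 1]. Opposite-side pairs use the Fermi rule: x copies θ_y
   with probability 1/(1 + exp((Δx − Δy)/tt)), Δi = |θ_i − θ_th|,
   tt = max(θ_th, 1 − θ_th). tt is the largest possible distance between a
   perception and the threshold, so the exponent is confined to [−1, 1] and
   the probability to [1/(1+e), e/(1+e)] ≈ [0.27, 0.73]; an agent whose view
   lies further from the threshold than its partner's is the harder one to
   persuade.

2. *Strategy.* x copies s_y with probability (U_y − U_x)/(k·b₀). The
   denominator is the maximum attainable utility (only the safe-side
   temptation b₀ > 1 can exceed R·k), which guarantees a probability in
   (0, 1] for every reachable state, for either neighbourhood degree.

### Initial conditions

Strategies are *exactly* half cooperators and half defectors, assigned by a
random permutation. The exact split (rather than per-agent coin flips)
removes initial-composition variance between replicates; it requires L² to
be even, which the builder enforces with a clear error. Perceptions are
i.i.d. Uniform[0, 1], so the initial safe fraction has expectation θ_th.

## Parameters

| name | meaning | default | why |
|---|---|---|---|
| b₀ | safe-side PD temptation (dimensionless payoff) | required, ≥ 1 | the swept control parameter; b₀ = 1 admitted only as the degenerate boundary for comparison sweeps |
| b₁ | dangerous-side HG temptation | 0.9 | keeps the two matrices close so only the temptation gap differs |
| θ_th | cognition threshold | required, ∈ [0, 1] | the second control parameter |
| δ | perception learning rate | 0.001 | small relative to the [0, 1] range: reinforcement acts on a much slower timescale than copying |
| L | lattice side | 100 (full) / 50 (reduced) | 10⁴ agents at full scale |
| sweeps | Monte Carlo sweeps | 61,000 / 2,000 | observables stabilise within a few hundred sweeps at reduced scale |
| stationary_window | trailing sweeps averaged | 1,000 / 500 | separates the measurement tail from the transient |
| replicates | independent runs | 10 / 5 | replicate r uses seed + r |

The reduced scale (L = 50, 2,000 sweeps, 500-sweep window, 5 replicates) is
the package's own choice for desk-scale experiments and is what the test
suite and `scripts/acceptance.py` use; `--paper-scale` switches the CLI to
the full setup.

## Randomness and reproducibility

Each elementary update consumes exactly four variates — focal index,
neighbour choice, perception uniform, strategy uniform — whether or not the
gate fires. The numba kernel and the pure-Python reference engine therefore
consume identical streams and produce bit-identical trajectories (this is
asserted in the tests). Runs are deterministic in (parameters, seed); sweep
cells derive order-independent seeds from (base seed, b₀ index, θ index,
replicate) via numpy's `SeedSequence`.

## Observables

c = cooperator fraction; s = fraction with θ < θ_th; d = 1 − s. Stationary
values are means over the trailing window, then averaged across replicates.
`locate_jump` reports the right edge of the largest forward difference of an
(θ_th, s) curve on a uniform grid, ties breaking toward the smaller
threshold — the first grid point at which the elevated value is attained.
Snapshots label each site SAFE/DANGEROUS and serialise as headerless
integer CSV grids.

## Numerical and design choices

* Equality θ = θ_th is routed to the dangerous side everywhere (predicate,
  reinforcement branch membership, observables), so no rule ever disagrees
  about which side an agent is on.
* Clamping is applied after every perception write: θ ≥ 1 ↦ 1, θ ≤ 0 ↦ 0.
* The strict gate makes configurations with globally tied utilities (e.g.
  an all-cooperator world) absorbing: no update can fire. At b₀ = 1 the
  near-ubiquitous payoff ties freeze most perception dynamics, which is why
  the safe fraction then tracks the threshold roughly linearly instead of
  jumping.
* b₀ = 1 is accepted by the parameter container (degenerate weak-PD
  boundary used in comparison sweeps) but rejected by the standalone payoff
  matrix constructor, whose contract is the strict game-theoretic
  definition.
* A "step" on all time axes is one sweep (L² elementary updates), the only
  reading under which macroscopic change within 100 steps is possible.

## What the simulator emulates, and what it does not

The generator *is* the study system — there is no external data. It
emulates a homogeneous crowd with a shared, fixed cognition threshold and
identical update rules. It does not model heterogeneous or random
thresholds, threshold intervals/bounded confidence, altruists or undecided
agents, join/withdraw dynamics, non-lattice topologies, or any physical
evacuation geometry. Passing tests therefore demonstrate properties of this
idealised lattice model, not of real evacuating crowds.

## Known limitations

* **Transition locations.** Under the strict utility gate the all-safe
  fixation (s = 1) at b₀ = 1.2 emerges only at θ_th ≈ 0.9 at this model's
  stationary state (confirmed at full scale, L = 100 with 61,000 sweeps),
  while published accounts of closely related dynamics place the transition
  near θ_th ≈ 0.63–0.71. Extensive experiments with the unstated tie
  behaviour (allowing U_y = U_x to fire the perception rule, or ungating it
  entirely) move the transition to ≈ 0.5 but destroy the suppressed-s regime
  at b₀ = 1.1 and the near-linear b₀ = 1 curve, so the strict gate is kept.
  The mid-range transition point appears to depend on an implementation
  detail not recoverable from the printed update rules; quantitative
  transition locations from this simulator should be treated as
  model-variant-specific.
* Harmony-game coarsening toward full cooperation is slow: at reduced scale
  (L = 50) the cooperation fraction at θ_th = 0.05, b₀ = 1.2 reaches ≈ 0.985
  by sweep 2,000 and ≈ 0.993 by sweep 8,000; full fixation needs run lengths
  closer to the full-scale 61,000 sweeps.
* Stationary statistics are plain trailing-window means; no equilibration
  diagnostics are applied, so the window must be chosen with the dynamics'
  relaxation time in mind.
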