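# Methods

## Model

A population of `N` agents occupies the nodes of an undirected simple
graph. Agent `I` speaks a language `L_I`, a pair of row-stochastic matrices
over `n` objects and `m` signals: the active matrix `P` (object → signal
production probabilities) and the passive matrix `Q` (signal → object
inference probabilities). Both derive from a nonnegative association matrix
`A` by row- and column-normalization. Communication is never simulated
explicitly; the probability of successful object transfer is used directly
as a payoff,

    F(L1, L2) = ½ Σ_ij ( p_ij⁽¹⁾ q_ji⁽²⁾ + p_ij⁽²⁾ q_ji⁽¹⁾ ),

and an agent's fitness is the *mean* payoff with its graph neighbors
(normalizing by degree removes a purely combinatorial advantage of hubs;
isolated agents have fitness 0). Because fitness depends on how common
compatible languages are in the neighborhood, the model carries a
frequency-dependent "bandwagon" bias toward locally popular languages.

Dynamics are event-based. At each step, with probability `λ` a rewire event
occurs, otherwise a reproduction event:

- **Reproduction (birth–death).** A parent is drawn fitness-proportionally
  from the whole population (uniformly when all fitnesses are zero;
  isolated candidates are redrawn up to 32 times, then the event is a
  logged no-op). A child samples `k` signals per object from the parent
  (counts row-normalized into `S_p`) and from each of `K` informants drawn
  with replacement from the parent's neighbors proportionally to fitness
  (counts pooled object-wise over informants, then row-normalized into
  `S_n`). Its association matrix is `A = (1 − δ)·S_p + δ·S_n`; `δ` is the
  neighbor influence (0 = vertical, 1 = oblique transmission). The child
  replaces a uniformly chosen neighbor of the parent: the node keeps its
  position and links, only its language changes.
- **Rewiring.** A uniform agent `I` disconnects from a neighbor chosen by
  the disconnect rule — uniform, fitness-proportional, or fitness-inverse —
  and reconnects to a non-neighbor chosen by the reconnect rule — uniform,
  or fitness-proportional with probability `1 − reconnect_noise` and
  uniform otherwise. Isolated or fully-connected agents make the event a
  logged no-op; edges are never duplicated, so the edge count is conserved.

Finite `k` makes learning an imperfect, sampling-based reproduction of the
observed languages; languages therefore drift toward binary (0/1) matrices,
and a state in which every relevant informant pool is unanimous on a
degenerate language is absorbing.

## Synthetic initial conditions

All inputs are generated. Initial languages draw their association entries
i.i.d. uniformly from the integers 1–9 (random init), or the population is
seeded with two equal-self-payoff permutation languages in exact proportions
(competition init, largest-remainder rounding, random node assignment).
Graphs come from seven families, all targeting mean degree 4: toroidal von
Neumann lattices, degree-4 rings, Watts–Strogatz small worlds, Erdős–Rényi
`G(N, 4/(N−1))`, Barabási–Albert (2 edges/node), complete, and uniform
random 4-regular graphs. Disconnected ER/BA realizations are kept — agents
on small components simply evolve locally — and path/consensus statistics
are computed on the largest component with a logged warning.

What this generator does *not* emulate: community structure, weighted or
temporal ties, heterogeneous agent capacities, or linguistic noise and
learning biases. Passing tests therefore speak to the dynamics of this
idealized model, not to empirical language data.

## Parameters and defaults

| parameter | meaning | default |
|---|---|---|
| `n`, `m` | objects, signals | 5, 5 (payoff ceiling `F_max = 5`) |
| `K` | informants sampled per learning event | 4 |
| `k` | responses recorded per object per informant | 1 |
| `δ` | neighbor influence (oblique weight) | 1.0 |
| `λ` | per-step rewire probability | 0.0 (static network) |
| `h` | convergence threshold on relative distance | 0.05 |
| `reconnect_noise` | uniform fallback for payoff-seeking reconnection | 0.10 |
| degree target | mean degree of all graph families | 4 |
| `record_every` | trajectory recording interval | `N` events |

## Numerical conventions

- **Zero signal column.** If a signal is never associated with any object,
  its row of `Q` is the uniform distribution `1/n` (a hearer must infer
  something); this keeps `Q` row-stochastic where plain column
  normalization is undefined.
- **Zero-weight selections.** Wherever a fitness-proportional draw meets an
  all-zero weight vector (parent choice, informants, rewiring), the draw
  falls back to uniform.
- **Fitness-inverse disconnection** uses weights `1 − F/F_max` (with
  `F_max = min(n, m)`), which are guaranteed nonnegative.
- **Empty informant pool** with `δ > 0` (only reachable by calling the
  learning routine directly, since parents are never isolated in the
  engine) falls back to parent-only samples.
- **Ties.** The modal object→signal map breaks argmax ties toward the
  smallest signal index; after convergence ties have probability zero.
- **Similarity** between languages is `1 − H/(n·m)` with `H` the Hamming
  distance between the one-hot matrices induced by the modal maps;
  continuous languages are binarized by argmax.
- **Equality** of languages means max elementwise `|ΔP|` and `|ΔQ|` within
  a tolerance (1e-9 for censuses; converged languages are exactly 0/1).
- **Plateau estimator.** `F_conv` is the mean of the final 5 % of recorded
  `F_N` values — an operational estimate that is exact for absorbed runs
  and robust to fluctuation when payoffs only wander around a stable mean.
  `t_conv` is reported on the reproduction-event clock by default, so that
  adaptive runs with different `λ` remain comparable.
- **Probability invariants** are enforced to 1e-9 (double-precision
  headroom over the exact rational arithmetic of count normalization).

## Engine and reproducibility

Languages are stored as stacked arrays (`P`, `Q`, `A` of shape
`(N, n, m)`) with a boolean adjacency matrix and a cached fitness vector;
the cache is refreshed from scratch for every node whose neighborhood
payoffs an event can change, so it never drifts from its definition. The
main loop is a numba-jitted kernel. Every stochastic choice draws from a
single `numpy.random.Generator` in a fixed, documented order (see the
`dynamics` module docstring), and the plain-Python single-event operations
consume the identical stream with identical arithmetic — the test suite
asserts bit-for-bit equality between a kernel run and an event-by-event
reference run. Batch runs use seeds `base_seed + i`.

With `λ = 0` a run may stop early once the state is provably absorbing:
for `δ < 1`, component-wise consensus on degenerate languages; for
`δ = 1`, every neighborhood internally unanimous and degenerate — a
condition that also captures checkerboard *gridlocks* on even-sided
toroidal lattices, where the two lattice parity classes carry different
languages and every informant pool is nevertheless unanimous. Gridlocks
are detected by splitting lattice nodes on `(row + col)` parity and
requiring one class to be ≥ 99 % homogeneous in a language the other class
does not share (the margin tolerates transient newborns). A structural
note: on a *perfect* two-language checkerboard, an added edge between
opposite parity classes leaves every neighborhood unanimous and the state
absorbing; only a same-parity edge (or an imperfect pattern) re-ignites the
dynamics.

## Problem sizes

The package's default experiments run at desk scale: `N ≈ 64–100`,
`t_max ≈ 5×10⁴–4×10⁵`, 8–16 seeds per condition — sizes chosen so that
every preset completes in minutes on a single CPU while the qualitative
contrasts of interest (topology ordering of `t_conv`, small-world speed-up,
the `δ = 0` vs `δ = 1` gap, gridlock formation, competition monotonicity,
core–periphery isolation) are stable across seeds. Paper-scale studies of
this family of models use `N = 400–500` and `t_max` up to `4×10⁶` with ~30
repetitions; those remain available through preset scale factors and
explicit configs.

## Known limitations

- With `δ = 0` and `k = 1`, languages binarize in a single generation and
  no new variation ever enters; the fixed language then usually inherits a
  signal collision from the initial binarization lottery (self-payoff 4
  rather than 5 at these system sizes). A small positive `δ` keeps
  variation alive and yields better final languages — consistent with the
  observation that strictly vertical transmission is fast but not optimal.
- Quasi-stationary quantities under adaptive rewiring (e.g. the isolated
  fraction under fitness-proportional reconnection, ≈ 10 % of agents at
  `N = 100`) depend on system size; larger populations accumulate larger
  isolated fringes.
- Alternative update rules (death–birth, imitation, pairwise comparison),
  selection-strength variation, explicit transmission noise, and learning
  biases are out of scope.
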