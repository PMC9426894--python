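"""Simulation engine: birth-death reproduction, adaptive rewiring, main loop.

Dynamics
--------
At every time step one event occurs: with probability ``lam`` a *rewire*
event, otherwise a *reproduction* event (birth-death updating):

1. a parent is drawn from the whole population with probability proportional
   to its cached total payoff (uniformly if all payoffs are zero; isolated
   candidates are redrawn a bounded number of times);
2. a child language is learned from the parent and ``K`` payoff-proportional
   informants among the parent's neighbors (see
   :func:`elgame.language.learn_language`);
3. the child replaces a uniformly chosen neighbor of the parent: that node
   keeps its position and links, only its language is overwritten.

A rewire event picks a uniform agent ``I``, disconnects a neighbor ``J_old``
chosen by the disconnect rule (uniform / fitness-proportional /
fitness-inverse, the latter weighted ``1 - F/F_max`` to stay nonnegative),
and reconnects to a non-neighbor ``J_new`` chosen by the reconnect rule
(uniform, or fitness-proportional with a ``reconnect_noise`` chance of a
uniform fallback).

Performance and replayability
-----------------------------
``run_simulation`` executes a numba-jitted kernel over stacked arrays
(languages ``P``/``Q``/``A`` of shape (N, n, m), boolean adjacency, payoff
cache ``F``).  The public single-event operations ``reproduction_step`` and
``rewire_event`` are plain-Python references that consume the *same*
``numpy.random.Generator`` stream in the *same* documented draw order and use
the same jitted payoff arithmetic, so a run advanced event-by-event in Python
is bit-identical to the kernel (asserted in the test suite).

Draw order per event: (0) one uniform for the rewire coin iff ``lam > 0``;
reproduction: one uniform per parent attempt (max 32), ``K`` informant
uniforms if ``delta > 0``, ``n*k`` parent-sample uniforms if ``delta < 1``,
``K*n*k`` informant-sample uniforms if ``delta > 0``, one replacement
uniform; rewire: one uniform for ``I``, then (unless a no-op) one for
``J_old``, one noise coin iff the reconnect rule is fitness-proportional, and
one for ``J_new``.

When ``lam == 0`` runs may stop early once the state is provably absorbing:
every node's informant pool shares a single degenerate (0/1 rows) language
— full consensus for ``delta < 1``, and for ``delta = 1`` also checkered
"gridlock" patterns where each neighborhood is internally homogeneous.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from numba import njit

from .language import Language, language_from_association, make_permutation_language, make_random_language
from .networks import NetworkSpec, build_network, graph_to_adjacency, adjacency_to_graph

__all__ = [
    "SimulationConfig",
    "PopulationState",
    "Trajectory",
    "init_population",
    "reproduction_step",
    "rewire_event",
    "step",
    "run_simulation",
    "run_batch",
    "save_state",
    "load_state",
    "state_from_languages",
]

logger = logging.getLogger(__name__)

MAX_PARENT_RETRIES = 32
DISCONNECT_RULES = ("uniform", "fitness_proportional", "fitness_inverse")
RECONNECT_RULES = ("uniform", "fitness_proportional")
#: equality tolerance used by the absorbing-state check
ABSORB_TOL = 1e-12


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """All model, network, learning and rewiring parameters of one run."""

    network: NetworkSpec
    t_max: int
    n: int = 5
    m: int = 5
    K: int = 4
    k: int = 1
    delta: float = 1.0          # neighbor influence
    lam: float = 0.0            # rewire probability per step
    h: float = 0.05             # convergence threshold
    disconnect_rule: str = "uniform"
    reconnect_rule: str = "uniform"
    reconnect_noise: float = 0.10
    seed: int = 0
    init: str = "random"        # "random" | "competition"
    competition_proportions: list[float] | None = None
    competition_perms: list[list[int]] | None = None
    record_every: int | None = None   # default: every N events
    early_stop: bool = True
    snapshot_every: int | None = None

    def __post_init__(self):
        if isinstance(self.network, dict):
            self.network = NetworkSpec(**self.network)
        for name in ("delta", "lam", "h", "reconnect_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if self.n < 1 or self.m < 1 or self.K < 1 or self.k < 1:
            raise ValueError("n, m, K, k must be positive")
        if self.disconnect_rule not in DISCONNECT_RULES:
            raise ValueError(f"disconnect_rule must be one of {DISCONNECT_RULES}")
        if self.reconnect_rule not in RECONNECT_RULES:
            raise ValueError(f"reconnect_rule must be one of {RECONNECT_RULES}")
        if self.init not in ("random", "competition"):
            raise ValueError("init must be 'random' or 'competition'")
        if self.init == "competition":
            props = self.competition_proportions
            if props is None or abs(sum(props) - 1.0) > 1e-9:
                raise ValueError("competition proportions must sum to 1")
            if self.competition_perms is not None and \
                    len(self.competition_perms) != len(props):
                raise ValueError("one permutation per proportion required")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# population state
# ---------------------------------------------------------------------------


@dataclass
class PopulationState:
    """Graph + per-node languages + payoff cache, stored as stacked arrays."""

    adj: np.ndarray            # (N, N) bool
    deg: np.ndarray            # (N,) int64
    P: np.ndarray              # (N, n, m)
    Q: np.ndarray              # (N, m, n)
    A: np.ndarray              # (N, n, m)
    F: np.ndarray              # (N,) payoff cache
    rng: np.random.Generator
    t: int = 0
    repro_events: int = 0
    rewire_events: int = 0
    repro_noops: int = 0
    rewire_noops: int = 0

    @property
    def N(self) -> int:
        return self.adj.shape[0]

    @property
    def n(self) -> int:
        return self.P.shape[1]

    @property
    def m(self) -> int:
        return self.P.shape[2]

    @property
    def graph(self) -> nx.Graph:
        return adjacency_to_graph(self.adj)

    def language(self, node: int) -> Language:
        return Language(self.P[node], self.Q[node], self.A[node])

    @property
    def languages(self) -> list[Language]:
        return [self.language(i) for i in range(self.N)]

    def neighbors(self, node: int) -> np.ndarray:
        return np.flatnonzero(self.adj[node])

    def audit_payoffs(self) -> float:
        """Max deviation of the cache from a from-scratch recomputation."""
        fresh = np.array([_node_payoff(self.adj, self.deg, self.P, self.Q, i)
                          for i in range(self.N)])
        return float(np.max(np.abs(fresh - self.F))) if self.N else 0.0


@dataclass
class Trajectory:
    """Recorded time series of one run."""

    t: np.ndarray                   # step index at each record
    reproduction_events: np.ndarray
    rewire_events: np.ndarray
    F_N: np.ndarray                 # population mean payoff
    isolated_fraction: np.ndarray
    record_every: int
    absorbed: bool = False
    snapshots: list = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t,
            "reproduction_events": self.reproduction_events,
            "rewire_events": self.rewire_events,
            "F_N": self.F_N,
            "isolated_fraction": self.isolated_fraction,
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# jitted numerics shared by kernel and reference steps
# ---------------------------------------------------------------------------


@njit(cache=True)
def _pair(P, Q, a, b):
    n, m = P.shape[1], P.shape[2]
    f = 0.0
    for i in range(n):
        for j in range(m):
            f += P[a, i, j] * Q[b, j, i] + P[b, i, j] * Q[a, j, i]
    return 0.5 * f


@njit(cache=True)
def _node_payoff(adj, deg, P, Q, x):
    if deg[x] == 0:
        return 0.0
    N = adj.shape[0]
    acc = 0.0
    for j in range(N):
        if adj[x, j]:
            acc += _pair(P, Q, x, j)
    return acc / deg[x]


@njit(cache=True)
def _update_payoffs_around(adj, deg, P, Q, F, b):
    N = adj.shape[0]
    F[b] = _node_payoff(adj, deg, P, Q, b)
    for j in range(N):
        if adj[b, j]:
            F[j] = _node_payoff(adj, deg, P, Q, j)


@njit(cache=True)
def _write_child(A, P, Q, b, Ac):
    n, m = Ac.shape
    for i in range(n):
        rs = 0.0
        for j in range(m):
            A[b, i, j] = Ac[i, j]
            rs += Ac[i, j]
        for j in range(m):
            P[b, i, j] = Ac[i, j] / rs
    for j in range(m):
        cs = 0.0
        for i in range(n):
            cs += Ac[i, j]
        if cs > 0.0:
            for i in range(n):
                Q[b, j, i] = Ac[i, j] / cs
        else:
            for i in range(n):
                Q[b, j, i] = 1.0 / n


@njit(cache=True)
def _sample_into(rng, P, a, k, S):
    n, m = P.shape[1], P.shape[2]
    for i in range(n):
        for _ in range(k):
            u = rng.random()
            acc = 0.0
            jj = m - 1
            for j in range(m):
                acc += P[a, i, j]
                if u < acc:
                    jj = j
                    break
            S[i, jj] += 1.0


@njit(cache=True)
def _repro_kernel(rng, adj, deg, P, Q, A, F, K, k, delta, Sp, Sn, Ac, inf):
    N = adj.shape[0]
    n, m = P.shape[1], P.shape[2]
    tot = 0.0
    for i in range(N):
        tot += F[i]
    parent = -1
    for _ in range(MAX_PARENT_RETRIES):
        u = rng.random()
        target = u * tot if tot > 0.0 else u * N
        acc = 0.0
        pick = N - 1
        for i in range(N):
            acc += F[i] if tot > 0.0 else 1.0
            if target < acc:
                pick = i
                break
        if deg[pick] > 0:
            parent = pick
            break
    if parent < 0:
        return -1
    dp = deg[parent]
    if delta > 0.0:
        wsum = 0.0
        for j in range(N):
            if adj[parent, j]:
                wsum += F[j]
        for s in range(K):
            u = rng.random()
            target = u * wsum if wsum > 0.0 else u * dp
            acc = 0.0
            a = -1
            for j in range(N):
                if adj[parent, j]:
                    acc += F[j] if wsum > 0.0 else 1.0
                    a = j
                    if target < acc:
                        break
            inf[s] = a
    for i in range(n):
        for j in range(m):
            Sp[i, j] = 0.0
            Sn[i, j] = 0.0
    if delta < 1.0:
        _sample_into(rng, P, parent, k, Sp)
    if delta > 0.0:
        for s in range(K):
            _sample_into(rng, P, inf[s], k, Sn)
    kk = float(k)
    Kk = float(K * k)
    for i in range(n):
        for j in range(m):
            if delta == 0.0:
                Ac[i, j] = Sp[i, j] / kk
            elif delta == 1.0:
                Ac[i, j] = Sn[i, j] / Kk
            else:
                Ac[i, j] = (1.0 - delta) * (Sp[i, j] / kk) \
                    + delta * (Sn[i, j] / Kk)
    u = rng.random()
    r = int(u * dp)
    if r >= dp:
        r = dp - 1
    b = -1
    c = 0
    for j in range(N):
        if adj[parent, j]:
            if c == r:
                b = j
                break
            c += 1
    _write_child(A, P, Q, b, Ac)
    _update_payoffs_around(adj, deg, P, Q, F, b)
    return b


@njit(cache=True)
def _disconnect_weight(rule, f, fmax):
    if rule == 0:
        return 1.0
    if rule == 1:
        return f
    w = 1.0 - f / fmax
    return w if w > 0.0 else 0.0


@njit(cache=True)
def _rewire_kernel(rng, adj, deg, P, Q, F, drule, rrule, noise, fmax):
    N = adj.shape[0]
    u = rng.random()
    I = int(u * N)
    if I >= N:
        I = N - 1
    dI = deg[I]
    if dI == 0:
        return False
    ncand = N - 1 - dI
    if ncand <= 0:
        return False
    # disconnect
    wsum = 0.0
    for j in range(N):
        if adj[I, j]:
            wsum += _disconnect_weight(drule, F[j], fmax)
    u = rng.random()
    target = u * wsum if wsum > 0.0 else u * dI
    acc = 0.0
    jold = -1
    for j in range(N):
        if adj[I, j]:
            acc += _disconnect_weight(drule, F[j], fmax) if wsum > 0.0 else 1.0
            jold = j
            if target < acc:
                break
    # reconnect
    uniform_mode = True
    if rrule == 1:
        uniform_mode = rng.random() < noise
    wsum2 = 0.0
    if rrule == 1 and not uniform_mode:
        for j in range(N):
            if j != I and not adj[I, j]:
                wsum2 += F[j]
    u = rng.random()
    target = u * wsum2 if wsum2 > 0.0 else u * ncand
    acc = 0.0
    jnew = -1
    for j in range(N):
        if j != I and not adj[I, j]:
            acc += F[j] if wsum2 > 0.0 else 1.0
            jnew = j
            if target < acc:
                break
    adj[I, jold] = False
    adj[jold, I] = False
    adj[I, jnew] = True
    adj[jnew, I] = True
    deg[jold] -= 1
    deg[jnew] += 1
    F[I] = _node_payoff(adj, deg, P, Q, I)
    F[jold] = _node_payoff(adj, deg, P, Q, jold)
    F[jnew] = _node_payoff(adj, deg, P, Q, jnew)
    return True


@njit(cache=True)
def _row_degenerate(P, x, tol):
    n, m = P.shape[1], P.shape[2]
    for i in range(n):
        best = 0.0
        for j in range(m):
            if P[x, i, j] > best:
                best = P[x, i, j]
        if best < 1.0 - tol:
            return False
    return True


@njit(cache=True)
def _same_language(P, Q, a, b, tol):
    n, m = P.shape[1], P.shape[2]
    for i in range(n):
        for j in range(m):
            d = P[a, i, j] - P[b, i, j]
            if d > tol or d < -tol:
                return False
            d = Q[a, j, i] - Q[b, j, i]
            if d > tol or d < -tol:
                return False
    return True


@njit(cache=True)
def _absorbing(adj, deg, P, Q, delta, tol):
    N = adj.shape[0]
    for p in range(N):
        if deg[p] == 0:
            continue
        ref = -1
        for j in range(N):
            if adj[p, j]:
                if not _row_degenerate(P, j, tol):
                    return False
                if ref < 0:
                    ref = j
                elif not _same_language(P, Q, j, ref, tol):
                    return False
        if delta < 1.0:
            if not _row_degenerate(P, p, tol):
                return False
            if not _same_language(P, Q, p, ref, tol):
                return False
    return True


@njit(cache=True)
def _mean_payoff(F):
    acc = 0.0
    for i in range(F.shape[0]):
        acc += F[i]
    return acc / F.shape[0]


@njit(cache=True)
def _isolated_frac(deg):
    c = 0
    for i in range(deg.shape[0]):
        if deg[i] == 0:
            c += 1
    return c / deg.shape[0]


@njit(cache=True)
def _run_chunk(rng, adj, deg, P, Q, A, F, K, k, delta, lam,
               drule, rrule, noise, fmax,
               t, repro, rewires, rnoop, wnoop,
               nsteps, record_every, check_every, early_stop, eq_tol,
               rec_t, rec_repro, rec_rewire, rec_F, rec_iso, rc):
    n, m = P.shape[1], P.shape[2]
    Sp = np.zeros((n, m))
    Sn = np.zeros((n, m))
    Ac = np.zeros((n, m))
    inf = np.zeros(K, dtype=np.int64)
    absorbed = False
    for _ in range(nsteps):
        do_rewire = False
        if lam > 0.0:
            if rng.random() < lam:
                do_rewire = True
        if do_rewire:
            if _rewire_kernel(rng, adj, deg, P, Q, F, drule, rrule, noise, fmax):
                rewires += 1
            else:
                wnoop += 1
        else:
            if _repro_kernel(rng, adj, deg, P, Q, A, F, K, k, delta,
                             Sp, Sn, Ac, inf) >= 0:
                repro += 1
            else:
                rnoop += 1
        t += 1
        if t % record_every == 0:
            rec_t[rc] = t
            rec_repro[rc] = repro
            rec_rewire[rc] = rewires
            rec_F[rc] = _mean_payoff(F)
            rec_iso[rc] = _isolated_frac(deg)
            rc += 1
        if early_stop and lam == 0.0 and t % check_every == 0:
            if _absorbing(adj, deg, P, Q, delta, eq_tol):
                absorbed = True
                break
    return t, repro, rewires, rnoop, wnoop, rc, absorbed


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def _competition_assignment(config: SimulationConfig,
                            rng: np.random.Generator) -> list[tuple[Language, int]]:
    """Languages with exact member counts via largest-remainder rounding."""
    props = config.competition_proportions
    perms = config.competition_perms
    if perms is None:
        if len(props) != 2 or config.n != config.m:
            raise ValueError("default competition languages need two "
                             "proportions and n == m")
        ident = list(range(config.n))
        swap = ident.copy()
        swap[0], swap[1] = swap[1], swap[0]
        perms = [ident, swap]
    langs = [make_permutation_language(p) for p in perms]
    N = config.network.N
    raw = np.array(props, float) * N
    counts = np.floor(raw).astype(int)
    rem = N - counts.sum()
    order = np.argsort(-(raw - counts))
    for g in order[:rem]:
        counts[g] += 1
    return list(zip(langs, counts.tolist()))


def state_from_languages(G: nx.Graph, languages: Sequence[Language],
                         seed: int = 0) -> PopulationState:
    """Assemble a :class:`PopulationState` from an explicit graph and
    per-node languages (useful for hand-built scenarios and offline
    re-analysis of saved bundles)."""
    adj = graph_to_adjacency(G)
    N = adj.shape[0]
    if len(languages) != N:
        raise ValueError(f"need {N} languages, got {len(languages)}")
    n, m = languages[0].n, languages[0].m
    P = np.zeros((N, n, m))
    Q = np.zeros((N, m, n))
    A = np.zeros((N, n, m))
    for i, L in enumerate(languages):
        P[i], Q[i] = L.P, L.Q
        A[i] = L.A if L.A is not None else L.P
    deg = adj.sum(axis=1).astype(np.int64)
    F = np.empty(N)
    for i in range(N):
        F[i] = _node_payoff(adj, deg, P, Q, i)
    return PopulationState(adj=adj, deg=deg, P=P, Q=Q, A=A, F=F,
                           rng=np.random.default_rng(seed))


def init_population(config: SimulationConfig) -> PopulationState:
    """Build the graph, assign initial languages, and fill the payoff cache.

    Draw order from the run's generator: graph construction first, then
    (random init) one language per node ascending, or (competition init) one
    permutation of node ids for group assignment.
    """
    rng = np.random.default_rng(config.seed)
    G = build_network(config.network, rng)
    adj = graph_to_adjacency(G)
    N = adj.shape[0]
    n, m = config.n, config.m
    P = np.zeros((N, n, m))
    Q = np.zeros((N, m, n))
    A = np.zeros((N, n, m))
    if config.init == "random":
        for i in range(N):
            L = make_random_language(n, m, rng)
            P[i], Q[i], A[i] = L.P, L.Q, L.A
    else:
        groups = _competition_assignment(config, rng)
        perm = rng.permutation(N)
        pos = 0
        for L, count in groups:
            for i in perm[pos:pos + count]:
                P[i], Q[i], A[i] = L.P, L.Q, L.A
            pos += count
    deg = adj.sum(axis=1).astype(np.int64)
    F = np.empty(N)
    for i in range(N):
        F[i] = _node_payoff(adj, deg, P, Q, i)
    return PopulationState(adj=adj, deg=deg, P=P, Q=Q, A=A, F=F, rng=rng)


# ---------------------------------------------------------------------------
# reference single-event operations
# ---------------------------------------------------------------------------


def _pick_index(cum: np.ndarray, target: float) -> int:
    idx = int(np.searchsorted(cum, target, side="right"))
    return min(idx, len(cum) - 1)


def reproduction_step(state: PopulationState, config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> PopulationState:
    """One birth-death reproduction event (in place; returns ``state``)."""
    rng = state.rng if rng is None else rng
    F, adj = state.F, state.adj
    N = state.N
    cum = np.cumsum(F)
    tot = float(cum[-1])
    if tot <= 0.0:
        cum = np.cumsum(np.ones(N))
    parent = -1
    for _ in range(MAX_PARENT_RETRIES):
        u = rng.random()
        pick = _pick_index(cum, u * (tot if tot > 0.0 else N))
        if state.deg[pick] > 0:
            parent = pick
            break
    state.t += 1
    if parent < 0:
        state.repro_noops += 1
        logger.warning("reproduction no-op at t=%d: no connected parent found",
                       state.t)
        return state
    nb = np.flatnonzero(adj[parent])
    from .language import learn_language  # local import avoids cycle at load
    pool = [(state.language(j), float(F[j])) for j in nb]
    child = learn_language(state.language(parent), pool, config.delta,
                           config.K, config.k, rng)
    u = rng.random()
    r = min(int(u * len(nb)), len(nb) - 1)
    b = int(nb[r])
    state.A[b] = child.A
    state.P[b] = child.P
    state.Q[b] = child.Q
    _update_payoffs_around(adj, state.deg, state.P, state.Q, F, b)
    state.repro_events += 1
    return state


def _disconnect_weights(rule: str, F: np.ndarray, fmax: float) -> np.ndarray:
    if rule == "uniform":
        return np.ones_like(F)
    if rule == "fitness_proportional":
        return F.copy()
    return np.maximum(1.0 - F / fmax, 0.0)


def rewire_event(state: PopulationState, config: SimulationConfig,
                 rng: np.random.Generator | None = None) -> PopulationState:
    """One adaptive rewiring event (in place; returns ``state``)."""
    rng = state.rng if rng is None else rng
    adj, F = state.adj, state.F
    N = state.N
    fmax = float(min(state.n, state.m))
    u = rng.random()
    I = min(int(u * N), N - 1)
    state.t += 1
    if state.deg[I] == 0:
        state.rewire_noops += 1
        logger.warning("rewire no-op at t=%d: node %d isolated", state.t, I)
        return state
    cand = np.flatnonzero(~adj[I])
    cand = cand[cand != I]
    if cand.size == 0:
        state.rewire_noops += 1
        logger.warning("rewire no-op at t=%d: node %d fully connected",
                       state.t, I)
        return state
    nb = np.flatnonzero(adj[I])
    w = _disconnect_weights(config.disconnect_rule, F[nb], fmax)
    cum = np.cumsum(w)
    wsum = float(cum[-1])
    u = rng.random()
    if wsum > 0.0:
        jold = int(nb[_pick_index(cum, u * wsum)])
    else:
        jold = int(nb[_pick_index(np.cumsum(np.ones(len(nb))), u * len(nb))])
    uniform_mode = True
    if config.reconnect_rule == "fitness_proportional":
        uniform_mode = rng.random() < config.reconnect_noise
    u = rng.random()
    if config.reconnect_rule == "fitness_proportional" and not uniform_mode:
        cum2 = np.cumsum(F[cand])
        wsum2 = float(cum2[-1])
        if wsum2 > 0.0:
            jnew = int(cand[_pick_index(cum2, u * wsum2)])
        else:
            jnew = int(cand[_pick_index(np.cumsum(np.ones(len(cand))),
                                        u * len(cand))])
    else:
        jnew = int(cand[_pick_index(np.cumsum(np.ones(len(cand))),
                                    u * len(cand))])
    adj[I, jold] = adj[jold, I] = False
    adj[I, jnew] = adj[jnew, I] = True
    state.deg[jold] -= 1
    state.deg[jnew] += 1
    for x in (I, jold, jnew):
        F[x] = _node_payoff(adj, state.deg, state.P, state.Q, x)
    state.rewire_events += 1
    return state


def step(state: PopulationState, config: SimulationConfig,
         rng: np.random.Generator | None = None) -> PopulationState:
    """One simulation event: rewire with probability ``lam``, else reproduce."""
    rng = state.rng if rng is None else rng
    if config.lam > 0.0 and rng.random() < config.lam:
        return rewire_event(state, config, rng)
    return reproduction_step(state, config, rng)


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------


def run_simulation(config: SimulationConfig,
                   state: PopulationState | None = None
                   ) -> tuple[PopulationState, Trajectory]:
    """Run (or continue) a simulation for ``config.t_max`` events.

    Fully reproducible from ``config.seed``.  Records the population mean
    payoff and isolated-node fraction every ``record_every`` events (default:
    every ``N``).  With ``lam == 0`` and ``early_stop`` the run halts at
    provably absorbing states; the trajectory is then constant afterwards by
    construction.
    """
    if state is None:
        state = init_population(config)
    N = state.N
    record_every = config.record_every or N
    check_every = max(record_every, 1)
    drule = DISCONNECT_RULES.index(config.disconnect_rule)
    rrule = RECONNECT_RULES.index(config.reconnect_rule)
    fmax = float(min(config.n, config.m))
    t_end = state.t + config.t_max

    cap = config.t_max // record_every + 3
    rec_t = np.zeros(cap, dtype=np.int64)
    rec_repro = np.zeros(cap, dtype=np.int64)
    rec_rewire = np.zeros(cap, dtype=np.int64)
    rec_F = np.zeros(cap)
    rec_iso = np.zeros(cap)
    rec_t[0] = state.t
    rec_repro[0] = state.repro_events
    rec_rewire[0] = state.rewire_events
    rec_F[0] = _mean_payoff(state.F)
    rec_iso[0] = _isolated_frac(state.deg)
    rc = 1

    snapshots: list = []
    absorbed = False
    while state.t < t_end:
        chunk = t_end - state.t
        if config.snapshot_every:
            chunk = min(chunk, config.snapshot_every)
        (state.t, state.repro_events, state.rewire_events,
         state.repro_noops, state.rewire_noops, rc, absorbed) = _run_chunk(
            state.rng, state.adj, state.deg, state.P, state.Q, state.A,
            state.F, config.K, config.k, config.delta, config.lam,
            drule, rrule, config.reconnect_noise, fmax,
            state.t, state.repro_events, state.rewire_events,
            state.repro_noops, state.rewire_noops,
            chunk, record_every, check_every, config.early_stop, ABSORB_TOL,
            rec_t, rec_repro, rec_rewire, rec_F, rec_iso, rc)
        if config.snapshot_every:
            from .observables import language_census
            snapshots.append((state.t, language_census(state)))
        if absorbed:
            logger.info("absorbing state reached at t=%d", state.t)
            break
    if rec_t[rc - 1] != state.t:
        rec_t[rc] = state.t
        rec_repro[rc] = state.repro_events
        rec_rewire[rc] = state.rewire_events
        rec_F[rc] = _mean_payoff(state.F)
        rec_iso[rc] = _isolated_frac(state.deg)
        rc += 1
    traj = Trajectory(
        t=rec_t[:rc].copy(),
        reproduction_events=rec_repro[:rc].copy(),
        rewire_events=rec_rewire[:rc].copy(),
        F_N=rec_F[:rc].copy(),
        isolated_fraction=rec_iso[:rc].copy(),
        record_every=record_every,
        absorbed=absorbed,
        snapshots=snapshots,
    )
    return state, traj


def run_batch(config: SimulationConfig, n_runs: int, base_seed: int
              ) -> tuple[list[Trajectory], pd.DataFrame]:
    """Independent runs with seeds ``base_seed + i``; returns all
    trajectories and a mean +/- standard-error aggregation of ``F_N`` on the
    common recording grid (runs that stop early are held constant at their
    final value, which is exact for absorbing states)."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    trajs: list[Trajectory] = []
    for i in range(n_runs):
        cfg = SimulationConfig.from_dict(config.to_dict())
        cfg.seed = int((base_seed + i) % (2 ** 31 - 1))
        _, traj = run_simulation(cfg)
        trajs.append(traj)
    record_every = trajs[0].record_every
    grid = np.arange(0, config.t_max + 1, record_every)
    vals = np.empty((n_runs, grid.size))
    for r, traj in enumerate(trajs):
        vals[r] = np.interp(grid, traj.t, traj.F_N)
        vals[r, grid > traj.t[-1]] = traj.F_N[-1]
    mean = vals.mean(axis=0)
    se = vals.std(axis=0, ddof=1) / np.sqrt(n_runs) if n_runs > 1 \
        else np.zeros_like(mean)
    summary = pd.DataFrame({"t": grid, "F_N_mean": mean, "F_N_se": se})
    return trajs, summary


# ---------------------------------------------------------------------------
# state bundles
# ---------------------------------------------------------------------------


def save_state(state: PopulationState, path,
               config: SimulationConfig | None = None) -> None:
    """JSON bundle: config echo, edge list, per-node A matrices, payoffs."""
    iu, ju = np.nonzero(np.triu(state.adj, 1))
    bundle = {
        "config": config.to_dict() if config else None,
        "t": state.t,
        "repro_events": state.repro_events,
        "rewire_events": state.rewire_events,
        "N": state.N,
        "edges": [[int(a), int(b)] for a, b in zip(iu, ju)],
        "A": state.A.tolist(),
        "payoffs": state.F.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(bundle, fh)


def load_state(path) -> PopulationState:
    with open(path) as fh:
        bundle = json.load(fh)
    N = bundle["N"]
    A = np.asarray(bundle["A"], float)
    n, m = A.shape[1], A.shape[2]
    adj = np.zeros((N, N), dtype=np.bool_)
    for a, b in bundle["edges"]:
        adj[a, b] = adj[b, a] = True
    P = np.zeros((N, n, m))
    Q = np.zeros((N, m, n))
    for i in range(N):
        L = language_from_association(A[i])
        P[i], Q[i] = L.P, L.Q
    deg = adj.sum(axis=1).astype(np.int64)
    F = np.empty(N)
    for i in range(N):
        F[i] = _node_payoff(adj, deg, P, Q, i)
    st = PopulationState(adj=adj, deg=deg, P=P, Q=Q, A=A, F=F,
                         rng=np.random.default_rng(0),
                         t=bundle["t"], repro_events=bundle["repro_events"],
                         rewire_events=bundle["rewire_events"])
    return st
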