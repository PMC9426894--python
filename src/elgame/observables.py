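"""Convergence statistics, gridlock detection, and population summaries.

Convergence of a run is judged from the recorded mean-payoff series
``F_N(t)``: the plateau payoff ``F_conv`` is estimated as the mean of the
final 5% of records, and the convergence time ``t_conv`` is the earliest
recorded time after which the relative distance

    |F_N - F_conv| / |F_0 - F_conv|

stays within a threshold ``h`` (0.05 by default) until the end of the run.

On even-sided toroidal lattices with purely oblique learning the dynamics
can freeze into a *gridlock*: a checkered pattern where one parity class of
the lattice speaks a single language while the interleaved class does not
share it.  :func:`detect_gridlock` classifies a lattice state by splitting
nodes on ``(row + col) % 2``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .dynamics import PopulationState, Trajectory, _node_payoff
from .language import Language, languages_equal, similarity, PROB_TOL

__all__ = [
    "ConvergenceReport",
    "LanguageCensus",
    "GridlockReport",
    "population_mean_payoff",
    "convergence_stats",
    "detect_gridlock",
    "isolated_fraction",
    "degree_distribution",
    "language_census",
    "dominance",
    "degree_stratified_payoff",
]


@dataclass
class ConvergenceReport:
    F_0: float
    F_conv: float
    t_conv: int
    h: float
    converged: bool

    def to_dict(self) -> dict:
        return {"F_0": self.F_0, "F_conv": self.F_conv,
                "t_conv": int(self.t_conv), "h": self.h,
                "converged": bool(self.converged)}


@dataclass
class LanguageCensus:
    groups: list[tuple[Language, int]]
    similarity_to_refs: list[float] = field(default_factory=list)

    @property
    def sizes(self) -> list[int]:
        return [c for _, c in self.groups]


@dataclass
class GridlockReport:
    detected: bool
    parity: int | None           # parity class of the homogeneous language
    shares: tuple[float, float]  # dominant-language share per parity class


def population_mean_payoff(state: PopulationState) -> float:
    """Mean total payoff, recomputed from scratch (isolated nodes count 0)."""
    if state.N == 0:
        raise ValueError("empty population")
    return float(np.mean([_node_payoff(state.adj, state.deg, state.P,
                                       state.Q, i) for i in range(state.N)]))


def convergence_stats(trajectory: Trajectory, h: float = 0.05,
                      time: str = "reproduction_events") -> ConvergenceReport:
    """Convergence report from a recorded trajectory.

    ``time`` selects the clock: raw steps (``"t"``) or reproduction-event
    count (default), the latter being the natural clock when rewire events
    interleave.  ``t_conv`` is the earliest recorded time after which the
    relative distance to the plateau stays within ``h``; if the trajectory
    starts at its plateau (zero denominator) it is 0.
    """
    F = np.asarray(trajectory.F_N, float)
    if F.size == 0:
        raise ValueError("empty trajectory")
    ts = np.asarray(getattr(trajectory, time))
    tail = max(1, int(np.ceil(0.05 * F.size)))
    F_conv = float(F[-tail:].mean())
    F_0 = float(F[0])
    denom = abs(F_0 - F_conv)
    if denom == 0.0:
        return ConvergenceReport(F_0, F_conv, 0, h, True)
    rel = np.abs(F - F_conv) / denom
    inside = rel <= h
    # earliest index from which every later record stays inside the band
    ok_from = F.size
    for i in range(F.size - 1, -1, -1):
        if inside[i]:
            ok_from = i
        else:
            break
    if ok_from == F.size:
        return ConvergenceReport(F_0, F_conv, int(ts[-1]), h, False)
    return ConvergenceReport(F_0, F_conv, int(ts[ok_from]), h, True)


def isolated_fraction(state: PopulationState) -> float:
    """Fraction of completely isolated (degree-0) agents."""
    return float(np.mean(state.deg == 0))


def degree_distribution(G: nx.Graph | PopulationState) -> dict[int, int]:
    """Exact histogram degree -> node count."""
    if isinstance(G, PopulationState):
        degs = G.deg.tolist()
    else:
        degs = [d for _, d in G.degree()]
    return dict(sorted(Counter(degs).items()))


def language_census(state: PopulationState, tol: float = PROB_TOL,
                    references: list[Language] | None = None
                    ) -> LanguageCensus:
    """Group agents by language equality (greedy first-match grouping).

    With ``references``, also reports the population-weighted mean similarity
    to each reference language.
    """
    reps: list[Language] = []
    counts: list[int] = []
    members: list[int] = []
    for i in range(state.N):
        L = state.language(i)
        for g, rep in enumerate(reps):
            if languages_equal(L, rep, tol):
                counts[g] += 1
                break
        else:
            reps.append(L.copy())
            counts.append(1)
            members.append(i)
    sims = []
    if references:
        N = state.N
        for ref in references:
            s = sum(c * similarity(rep, ref) for rep, c in zip(reps, counts))
            sims.append(s / N)
    order = np.argsort(counts)[::-1]
    groups = [(reps[g], counts[g]) for g in order]
    return LanguageCensus(groups=groups, similarity_to_refs=sims)


def dominance(state: PopulationState, reference: Language,
              tol: float = PROB_TOL) -> bool:
    """True iff every agent speaks ``reference`` within ``tol``."""
    return all(languages_equal(state.language(i), reference, tol)
               for i in range(state.N))


def detect_gridlock(state: PopulationState, side: int,
                    tol: float = PROB_TOL,
                    homogeneity: float = 0.99) -> GridlockReport:
    """Checkerboard-pattern detector for toroidal lattice populations.

    Splits nodes by ``(row + col)`` parity; a gridlock is flagged when one
    parity class is (>= ``homogeneity``) homogeneous in a single language
    that the other class does not share.  The homogeneity margin tolerates
    transient newborns during ongoing dynamics.
    """
    if side * side != state.N:
        raise ValueError(f"state is not a {side}x{side} lattice population")
    nodes = np.arange(state.N)
    parity = (nodes // side + nodes % side) % 2
    cls = [nodes[parity == 0], nodes[parity == 1]]

    def _modal_language_share(idx: np.ndarray) -> tuple[Language, float]:
        reps: list[Language] = []
        counts: list[int] = []
        for i in idx:
            L = state.language(int(i))
            for g, rep in enumerate(reps):
                if languages_equal(L, rep, tol):
                    counts[g] += 1
                    break
            else:
                reps.append(L)
                counts.append(1)
        g = int(np.argmax(counts))
        return reps[g], counts[g] / len(idx)

    best = [_modal_language_share(c) for c in cls]
    shares = (best[0][1], best[1][1])
    for p in (0, 1):
        lang, share = best[p]
        if share < homogeneity:
            continue
        other = cls[1 - p]
        other_share = np.mean([languages_equal(state.language(int(i)), lang, tol)
                               for i in other])
        if other_share < homogeneity:
            return GridlockReport(True, p, shares)
    return GridlockReport(False, None, shares)


def degree_stratified_payoff(state: PopulationState,
                             fraction: float = 0.10) -> tuple[float, float]:
    """Mean payoff of the top and bottom ``fraction`` of nodes by degree
    (ties broken by node id)."""
    if not 0.0 < fraction <= 0.5:
        raise ValueError("fraction must lie in (0, 0.5]")
    count = int(np.ceil(fraction * state.N))
    order = np.lexsort((np.arange(state.N), state.deg))
    bottom = order[:count]
    top = order[::-1][:count]
    return float(state.F[top].mean()), float(state.F[bottom].mean())
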