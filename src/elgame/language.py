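"""Probabilistic object-signal languages and their communication payoffs.

An agent's language maps ``n`` objects to ``m`` signals through two
row-stochastic matrices: the *active* matrix ``P`` (``p_ij`` = probability of
producing signal ``j`` for object ``i``) and the *passive* matrix ``Q``
(``q_ji`` = probability of inferring object ``i`` from signal ``j``).  Both
derive from a nonnegative *association* matrix ``A``:

    p_ij = a_ij / sum_l a_il        (row normalization)
    q_ji = a_ij / sum_l a_lj        (column normalization)

A signal that is never associated with any object leaves the corresponding
row of ``Q`` undefined; by convention the hearer then guesses uniformly,
``q_ji = 1/n``, which keeps ``Q`` row-stochastic.

The symmetric payoff of communication between two languages is

    F(L1, L2) = 1/2 * sum_ij ( p_ij^(1) q_ji^(2) + p_ij^(2) q_ji^(1) ),

i.e. the expected number of objects transferred successfully per exchange,
bounded by min(n, m) and maximized by matched permutation languages.

New languages are learned by sampling: a child records ``k`` signal
observations per object from its parent (sample matrix ``S_p``) and from each
of ``K`` payoff-proportionally chosen informants (pooled into ``S_n``), and
builds ``A = (1 - delta) * S_p + delta * S_n`` where ``delta`` is the
neighbor-influence weight.

RNG contract: every stochastic routine in this module draws from the supplied
``numpy.random.Generator`` in a documented, fixed order (see
:func:`learn_language`), so that simulations are replayable and the jitted
simulation kernel in :mod:`elgame.dynamics` can reproduce them bit for bit.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Language",
    "SampleCounts",
    "make_random_language",
    "make_permutation_language",
    "language_from_association",
    "payoff_pair",
    "total_payoff",
    "sample_responses",
    "learn_language",
    "modal_map",
    "similarity",
    "languages_equal",
]

#: tolerance for row-stochasticity invariants
PROB_TOL = 1e-9


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass
class Language:
    """An object-signal language.

    Parameters
    ----------
    P : (n, m) ndarray
        Active matrix; each row a distribution over signals.
    Q : (m, n) ndarray
        Passive matrix; each row a distribution over objects.
    A : (n, m) ndarray, optional
        Association matrix ``P``/``Q`` derive from.  Absent for hand-built
        languages specified directly through ``P`` and ``Q``.
    """

    P: np.ndarray
    Q: np.ndarray
    A: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.P.shape[0]

    @property
    def m(self) -> int:
        return self.P.shape[1]

    def validate(self, tol: float = PROB_TOL) -> None:
        """Raise ``ValueError`` if the stochasticity invariants are violated."""
        P, Q = np.asarray(self.P, float), np.asarray(self.Q, float)
        if P.ndim != 2 or Q.shape != (P.shape[1], P.shape[0]):
            raise ValueError(f"inconsistent shapes P{P.shape} Q{Q.shape}")
        for name, M in (("P", P), ("Q", Q)):
            if np.any(M < -tol) or np.any(M > 1 + tol):
                raise ValueError(f"{name} has entries outside [0, 1]")
            if np.any(np.abs(M.sum(axis=1) - 1.0) > tol):
                raise ValueError(f"rows of {name} do not sum to 1")
        if self.A is not None:
            ref = language_from_association(self.A)
            if (np.max(np.abs(ref.P - P)) > tol
                    or np.max(np.abs(ref.Q - Q)) > tol):
                raise ValueError("P/Q are not the normalizations of A")

    def copy(self) -> "Language":
        return Language(self.P.copy(), self.Q.copy(),
                        None if self.A is None else self.A.copy())

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {"n": self.n, "m": self.m, "P": self.P.tolist(), "Q": self.Q.tolist()}
        if self.A is not None:
            d["A"] = self.A.tolist()
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "Language":
        if "A" in d:
            lang = language_from_association(np.asarray(d["A"], float))
            return lang
        return cls(np.asarray(d["P"], float), np.asarray(d["Q"], float))

    @classmethod
    def from_json(cls, s: str) -> "Language":
        return cls.from_dict(json.loads(s))

    def to_csv(self, path) -> None:
        """Dump P, Q (and A if present) as labelled CSV blocks."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            for name, M in (("P", self.P), ("Q", self.Q), ("A", self.A)):
                if M is None:
                    continue
                w.writerow([name])
                for row in np.asarray(M):
                    w.writerow([repr(x) for x in row])


@dataclass
class SampleCounts:
    """Observed signal counts per object collected during learning."""

    counts: np.ndarray  # (n, m) nonnegative integers

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def m(self) -> int:
        return self.counts.shape[1]


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def language_from_association(A: np.ndarray) -> Language:
    """Derive a :class:`Language` from an association matrix.

    ``P`` is the row normalization of ``A`` and ``Q`` the column
    normalization; an all-zero column of ``A`` (a signal never produced)
    yields a uniform row of ``Q``.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] < 1 or A.shape[1] < 1:
        raise ValueError("A must be a nonempty 2-D array")
    if np.any(A < 0):
        raise ValueError("A must be nonnegative")
    n, m = A.shape
    row = A.sum(axis=1, keepdims=True)
    if np.any(row == 0):
        raise ValueError("A has an all-zero row: no signal for some object")
    P = A / row
    col = A.sum(axis=0)
    safe = np.where(col > 0, col, 1.0)
    Q = np.where(col[None, :] > 0, A / safe[None, :], 1.0 / n).T
    return Language(P=P, Q=Q, A=A)


def make_random_language(n: int, m: int, rng: np.random.Generator) -> Language:
    """Random initial language: A entries i.i.d. uniform integers in [1, 9]."""
    if n < 1 or m < 1:
        raise ValueError("n and m must be positive")
    A = rng.integers(1, 10, size=(n, m)).astype(float)
    return language_from_association(A)


def make_permutation_language(perm: Sequence[int]) -> Language:
    """Optimal one-to-one language for ``n = m``: object ``i`` -> signal ``perm[i]``."""
    perm = list(perm)
    n = len(perm)
    if sorted(perm) != list(range(n)):
        raise ValueError(f"not a bijection on 0..{n - 1}: {perm}")
    A = np.zeros((n, n))
    A[np.arange(n), perm] = 1.0
    return language_from_association(A)


# ---------------------------------------------------------------------------
# payoffs
# ---------------------------------------------------------------------------


def payoff_pair(L1: Language, L2: Language) -> float:
    """Symmetric communication payoff between two languages."""
    if L1.P.shape != L2.P.shape:
        raise ValueError("languages must share n and m")
    return 0.5 * (np.einsum("ij,ji->", L1.P, L2.Q)
                  + np.einsum("ij,ji->", L2.P, L1.Q))


def total_payoff(node: int, state) -> float:
    """Mean pairwise payoff of ``node`` with its graph neighbors (0 if isolated).

    ``state`` is any object exposing stacked language arrays ``P`` (N, n, m)
    and ``Q`` (N, m, n) plus a boolean adjacency matrix ``adj`` — in practice
    an :class:`elgame.dynamics.PopulationState`.
    """
    N = state.adj.shape[0]
    if not (0 <= node < N):
        raise ValueError(f"unknown node {node}")
    nb = np.flatnonzero(state.adj[node])
    if nb.size == 0:
        return 0.0
    f = 0.5 * (np.einsum("ij,kji->k", state.P[node], state.Q[nb])
               + np.einsum("kij,ji->k", state.P[nb], state.Q[node]))
    return float(f.mean())


# ---------------------------------------------------------------------------
# sampling-based learning
# ---------------------------------------------------------------------------


def sample_responses(L: Language, k: int, rng: np.random.Generator) -> SampleCounts:
    """Record ``k`` signal observations per object from a speaker of ``L``.

    Draw order: for object ``i = 0..n-1`` (ascending), ``k`` uniforms are
    drawn and inverted through the cumulative distribution of row ``i`` of
    ``P``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n, m = L.n, L.m
    counts = np.zeros((n, m), dtype=np.int64)
    for i in range(n):
        cum = np.cumsum(L.P[i])
        idx = np.searchsorted(cum, rng.random(k), side="right")
        np.clip(idx, 0, m - 1, out=idx)
        np.add.at(counts[i], idx, 1)
    return SampleCounts(counts)


def _weighted_indices(weights: np.ndarray, K: int,
                      rng: np.random.Generator) -> np.ndarray:
    """K draws with replacement, probability proportional to ``weights``
    (uniform if all weights are zero).  One uniform is consumed per draw."""
    w = np.asarray(weights, dtype=float)
    cum = np.cumsum(w)          # sequential partial sums
    total = float(cum[-1])
    if total <= 0:
        cum = np.cumsum(np.ones_like(w))
        total = float(len(w))
    u = rng.random(K) * total
    idx = np.searchsorted(cum, u, side="right")
    return np.clip(idx, 0, len(w) - 1)


def learn_language(parent: Language,
                   pool: Sequence[tuple[Language, float]],
                   delta: float, K: int, k: int,
                   rng: np.random.Generator) -> Language:
    """Construct a child language by sampling the parent and ``K`` informants.

    ``pool`` holds candidate informants with selection weights (their total
    payoffs); informants are drawn with replacement proportionally to weight,
    uniformly if all weights are zero.  ``S_p`` is the row-normalized count
    matrix sampled from the parent, ``S_n`` the row normalization of the
    object-wise pooled counts from all ``K`` informants, and the child's
    association matrix is ``A = (1 - delta) * S_p + delta * S_n``.

    With an empty pool the neighbor term is unavailable and the child falls
    back to parent-only samples (``A = S_p``) regardless of ``delta``.

    Draw order (fixed; mirrored by the simulation kernel): (1) ``K``
    informant-selection uniforms if ``delta > 0`` and the pool is non-empty;
    (2) parent samples if ``delta < 1`` or the pool is empty; (3) samples from
    each selected informant, in selection order.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must lie in [0, 1]")
    if K < 1 or k < 1:
        raise ValueError("K and k must be >= 1")
    pool = list(pool)
    use_pool = delta > 0.0 and len(pool) > 0

    informants: np.ndarray | None = None
    if use_pool:
        weights = np.array([w for _, w in pool], dtype=float)
        if np.any(weights < 0):
            raise ValueError("pool weights must be nonnegative")
        informants = _weighted_indices(weights, K, rng)

    S_p = None
    if delta < 1.0 or not use_pool:
        S_p = sample_responses(parent, k, rng).counts / k

    if use_pool:
        pooled = np.zeros((parent.n, parent.m), dtype=np.int64)
        for idx in informants:
            pooled += sample_responses(pool[idx][0], k, rng).counts
        S_n = pooled / (K * k)
        A = S_n if delta == 1.0 else (1.0 - delta) * S_p + delta * S_n
    else:
        A = S_p
    return language_from_association(A)


# ---------------------------------------------------------------------------
# comparison
# ---------------------------------------------------------------------------


def modal_map(L: Language) -> np.ndarray:
    """Most probable signal per object; ties broken by smallest signal index."""
    return np.argmax(L.P, axis=1)


def similarity(L1: Language, L2: Language) -> float:
    """1 - H/(n*m) where H is the Hamming distance between the one-hot
    matrices induced by the modal maps."""
    if L1.P.shape != L2.P.shape:
        raise ValueError("languages must share n and m")
    n, m = L1.n, L1.m
    B1 = np.zeros((n, m), dtype=np.int8)
    B1[np.arange(n), modal_map(L1)] = 1
    B2 = np.zeros((n, m), dtype=np.int8)
    B2[np.arange(n), modal_map(L2)] = 1
    H = int(np.sum(B1 != B2))
    return 1.0 - H / (n * m)


def languages_equal(L1: Language, L2: Language, tol: float = PROB_TOL) -> bool:
    """Elementwise equality of both P and Q matrices within ``tol``."""
    if L1.P.shape != L2.P.shape:
        raise ValueError("languages must share n and m")
    return bool(np.max(np.abs(L1.P - L2.P)) <= tol
                and np.max(np.abs(L1.Q - L2.Q)) <= tol)
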