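"""Preset experiment designs and batch orchestration.

Each preset is a self-contained sweep over simulation configurations at desk
scale (N of order 100, t_max of order 10^5, around 10 seeds per cell), sized
so a preset completes in minutes on one CPU while preserving the qualitative
contrasts of interest (topology ordering, small-world speed-up, neighbor
influence, adaptive rewiring, language competition).  Paper-scale runs
(N = 400-500, t_max up to 4x10^6, 30 repetitions) are reachable through the
``scale`` factor of :func:`run_sweep` or by editing the emitted configs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import SimulationConfig, init_population, run_simulation
from .language import make_permutation_language
from .networks import NetworkSpec
from .observables import convergence_stats, dominance, language_census

__all__ = ["ExperimentPreset", "PRESETS", "run_sweep", "run_competition",
           "competition_languages"]


@dataclass
class ExperimentPreset:
    """A named sweep: one base config plus per-cell overrides."""

    name: str
    base: dict
    cells: list[dict]            # each: {"cell": label, **config overrides}
    n_seeds: int = 10

    def configs(self, scale: float = 1.0, base_seed: int = 0
                ) -> list[tuple[str, int, SimulationConfig]]:
        out = []
        for cell in self.cells:
            cell = dict(cell)
            label = cell.pop("cell")
            for s in range(self.n_seeds):
                d = dict(self.base)
                d.update(cell)
                d["t_max"] = max(1, int(round(d["t_max"] * scale)))
                cell_tag = zlib.crc32(label.encode()) % 10007
                d["seed"] = int((base_seed + 1000 * cell_tag + s)
                                % (2 ** 31 - 1))
                out.append((label, s, SimulationConfig.from_dict(d)))
        return out


def _net(family: str, N: int, **kw) -> dict:
    return {"family": family, "N": N, **kw}


PRESETS: dict[str, ExperimentPreset] = {
    "topologies": ExperimentPreset(
        name="topologies",
        base={"network": _net("random", 100), "t_max": 300_000, "delta": 1.0},
        cells=[
            {"cell": "ring", "network": _net("ring", 100)},
            {"cell": "lattice2d", "network": _net("lattice2d", 81, side=9)},
            {"cell": "random", "network": _net("random", 100)},
            {"cell": "scalefree", "network": _net("scalefree", 100)},
        ],
    ),
    "smallworld": ExperimentPreset(
        name="smallworld",
        base={"network": _net("smallworld", 100, ws_p=0.1),
              "t_max": 300_000, "delta": 1.0},
        cells=[{"cell": f"p={p}",
                "network": _net("smallworld", 100, ws_p=p)}
               for p in (0.01, 0.1, 1.0)],
    ),
    "delta": ExperimentPreset(
        name="delta",
        base={"network": _net("random", 100), "t_max": 300_000},
        cells=[{"cell": f"delta={d}", "delta": d}
               for d in (0.0, 0.25, 0.5, 0.75, 1.0)],
    ),
    "adaptive": ExperimentPreset(
        name="adaptive",
        base={"network": _net("random", 100), "t_max": 150_000,
              "delta": 0.5},
        cells=[{"cell": f"{dr}/{rr}/lam={lam}",
                "disconnect_rule": dr, "reconnect_rule": rr, "lam": lam}
               for dr in ("uniform", "fitness_inverse")
               for rr in ("uniform", "fitness_proportional")
               for lam in (0.1, 0.5, 0.9)],
        n_seeds=8,
    ),
}


def run_sweep(preset: ExperimentPreset | str, scale: float = 1.0,
              base_seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run a preset sweep; returns (long results, per-cell mean +/- SE).

    The long frame holds one row per (cell, seed) with t_conv (reproduction
    events), F_conv, F_0, converged, and the final isolated fraction.
    """
    if isinstance(preset, str):
        try:
            preset = PRESETS[preset]
        except KeyError:
            raise KeyError(f"unknown preset {preset!r}; "
                           f"known: {sorted(PRESETS)}") from None
    rows = []
    for label, s, cfg in preset.configs(scale=scale):
        state, traj = run_simulation(cfg)
        rep = convergence_stats(traj, cfg.h)
        rows.append({"cell": label, "seed": s,
                     "t_conv": rep.t_conv, "F_conv": rep.F_conv,
                     "F_0": rep.F_0, "converged": rep.converged,
                     "isolated_fraction": float(traj.isolated_fraction[-1])})
    long = pd.DataFrame(rows)
    agg = long.groupby("cell")[["t_conv", "F_conv"]].agg(["mean", "sem"])
    agg.columns = ["_".join(c) for c in agg.columns]
    return long, agg.reset_index()


def competition_languages(n: int = 5) -> tuple:
    """Two equal-self-payoff permutation languages one transposition apart."""
    ident = list(range(n))
    swap = ident.copy()
    swap[0], swap[1] = swap[1], swap[0]
    return make_permutation_language(ident), make_permutation_language(swap)


def run_competition(proportions=(0.1, 0.3, 0.5, 0.7, 0.9),
                    n_runs: int = 16, N: int = 100, t_max: int = 150_000,
                    base_seed: int = 0, delta: float = 1.0
                    ) -> pd.DataFrame:
    """Language-competition protocol: two equivalent permutation languages A
    and B seeded in given proportions on a random network; reports the
    frequency of runs ending in A- (and B-) dominance plus the
    population-weighted similarity to A at start and end."""
    A, B = competition_languages()
    rows = []
    for p in proportions:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"proportion must lie in (0, 1], got {p}")
        wins_a = wins_b = 0
        sim0s, sim1s = [], []
        for r in range(n_runs):
            cfg = SimulationConfig(
                network=NetworkSpec("random", N), t_max=t_max, delta=delta,
                init="competition",
                competition_proportions=[p, 1.0 - p],
                competition_perms=[list(range(5)), [1, 0, 2, 3, 4]],
                seed=int((base_seed + 7919 * int(round(1000 * p)) + r)
                         % (2 ** 31 - 1)))
            state = init_population(cfg)
            sim0s.append(language_census(
                state, references=[A]).similarity_to_refs[0])
            state, _ = run_simulation(cfg, state)
            sim1s.append(language_census(
                state, references=[A]).similarity_to_refs[0])
            if dominance(state, A):
                wins_a += 1
            elif dominance(state, B):
                wins_b += 1
        rows.append({"proportion_A": p, "n_runs": n_runs,
                     "dominance_freq_A": wins_a / n_runs,
                     "dominance_freq_B": wins_b / n_runs,
                     "similarity_to_A_start": float(np.mean(sim0s)),
                     "similarity_to_A_end": float(np.mean(sim1s))})
    return pd.DataFrame(rows)
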