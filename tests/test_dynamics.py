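"""Engine contracts: events, caches, determinism, kernel/reference parity."""

import numpy as np
import networkx as nx
import pytest
from scipy import stats

import elgame as eg
from elgame.dynamics import (SimulationConfig, init_population,
                             reproduction_step, rewire_event, step,
                             run_simulation, run_batch, state_from_languages,
                             save_state, load_state, _node_payoff)


def cfg_er(N=50, **kw):
    kw.setdefault("network", {"family": "random", "N": N})
    kw.setdefault("t_max", 1000)
    kw.setdefault("seed", 1)
    return SimulationConfig(**kw)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def test_config_validation():
    with pytest.raises(ValueError):
        cfg_er(delta=1.2)
    with pytest.raises(ValueError):
        cfg_er(lam=-0.1)
    with pytest.raises(ValueError):
        cfg_er(t_max=0)
    with pytest.raises(ValueError):
        cfg_er(disconnect_rule="nope")
    with pytest.raises(ValueError):
        cfg_er(init="competition", competition_proportions=[0.5, 0.4])


def test_config_yaml_roundtrip(tmp_path):
    cfg = cfg_er(delta=0.3, lam=0.2, reconnect_rule="fitness_proportional")
    cfg.to_yaml(tmp_path / "c.yaml")
    cfg2 = SimulationConfig.from_yaml(tmp_path / "c.yaml")
    assert cfg2.to_dict() == cfg.to_dict()


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def test_random_init_distinct_languages_and_exact_cache():
    state = init_population(cfg_er(N=50))
    sigs = {state.A[i].tobytes() for i in range(50)}
    assert len(sigs) == 50  # 25 iid integer entries: collisions essentially impossible
    assert state.audit_payoffs() == 0.0


def test_competition_init_exact_proportions():
    cfg = cfg_er(N=100, init="competition",
                 competition_proportions=[0.5, 0.5])
    state = init_population(cfg)
    from elgame.experiments import competition_languages
    LA, LB = competition_languages()
    count_a = sum(eg.languages_equal(state.language(i), LA)
                  for i in range(100))
    count_b = sum(eg.languages_equal(state.language(i), LB)
                  for i in range(100))
    assert count_a == 50 and count_b == 50


def test_competition_init_rounding():
    cfg = cfg_er(N=10, init="competition",
                 competition_proportions=[0.33, 0.67])
    state = init_population(cfg)
    from elgame.observables import language_census
    sizes = sorted(language_census(state).sizes)
    assert sizes == [3, 7]


# ---------------------------------------------------------------------------
# reproduction
# ---------------------------------------------------------------------------


def test_reproduction_consensus_is_fixed_point():
    L = eg.make_permutation_language(range(5))
    state = state_from_languages(nx.cycle_graph(8), [L] * 8, seed=3)
    cfg = cfg_er(N=8, delta=0.0)
    before = state.P.copy()
    for _ in range(20):
        reproduction_step(state, cfg)
    assert np.array_equal(state.P, before)
    assert state.repro_events == 20


def test_two_node_takeover_with_parental_learning():
    LA = eg.make_permutation_language(range(5))
    LB = eg.make_permutation_language([1, 0, 2, 3, 4])
    G = nx.Graph([(0, 1)])
    state = state_from_languages(G, [LA, LB], seed=9)
    cfg = cfg_er(N=2, delta=0.0)
    reproduction_step(state, cfg)
    # child is an exact copy of the parent and replaces the only neighbor
    assert eg.languages_equal(state.language(0), state.language(1), tol=0.0)
    assert any(eg.languages_equal(state.language(0), L, tol=0.0)
               for L in (LA, LB))


def test_cache_consistency_after_many_events():
    cfg = SimulationConfig(network={"family": "lattice2d", "N": 25, "side": 5},
                           t_max=1000, delta=1.0, seed=4)
    state = init_population(cfg)
    for _ in range(1000):
        step(state, cfg)
    assert state.audit_payoffs() < 1e-9


def test_isolated_nodes_never_parent():
    # star: center 0 is everyone's only neighbor; plus isolated node 4
    G = nx.star_graph(3)
    G.add_node(4)
    L = eg.make_permutation_language(range(5))
    rng = np.random.default_rng(0)
    langs = [L] + [eg.make_random_language(5, 5, rng) for _ in range(4)]
    state = state_from_languages(G, langs, seed=11)
    cfg = cfg_er(N=5, delta=0.0)
    iso_before = state.A[4].copy()
    for _ in range(200):
        reproduction_step(state, cfg)
    assert np.array_equal(state.A[4], iso_before)  # never replaced
    assert state.F[4] == 0.0


# ---------------------------------------------------------------------------
# rewiring
# ---------------------------------------------------------------------------


def test_rewire_conserves_edges_and_caches():
    cfg = cfg_er(N=40, lam=1.0, reconnect_rule="fitness_proportional",
                 disconnect_rule="fitness_inverse", seed=6)
    state = init_population(cfg)
    edges0 = state.deg.sum()
    for _ in range(500):
        rewire_event(state, cfg)
    assert state.deg.sum() == edges0
    assert state.N == 40
    assert state.audit_payoffs() < 1e-9
    assert state.rewire_events + state.rewire_noops == 500


def test_zero_payoff_node_never_reconnected_without_noise():
    # node 5 isolated (payoff 0); consensus cycle nodes all have payoff 5,
    # so every rewiring agent sees positive-weight alternatives
    L = eg.make_permutation_language(range(5))
    G = nx.cycle_graph(5)
    G.add_node(5)
    cfg = cfg_er(N=6, lam=1.0, reconnect_rule="fitness_proportional",
                 reconnect_noise=0.0, seed=8)
    base = state_from_languages(G, [L] * 6, seed=0)
    for trial in range(10_000):
        st = state_from_languages(G, [L] * 6, seed=trial)
        rewire_event(st, cfg)
        assert st.deg[5] == 0
    assert base.F[5] == 0.0


def test_uniform_rewiring_preserves_er_degree_distribution():
    """Pure uniform/uniform rewiring leaves the ER degree histogram
    statistically unchanged (pooled over realizations, chi-square alpha=0.01)."""
    h0 = np.zeros(25, dtype=int)
    h1 = np.zeros(25, dtype=int)
    for s in range(10):
        cfg = SimulationConfig(network={"family": "random", "N": 100},
                               t_max=10_000, lam=1.0, seed=900 + s,
                               early_stop=False)
        st0 = init_population(cfg)
        h0 += np.bincount(st0.deg, minlength=25)[:25]
        st, _ = run_simulation(cfg, st0)
        h1 += np.bincount(st.deg, minlength=25)[:25]

    def merge(h):
        return np.array([h[:3].sum(), h[3], h[4], h[5], h[6:].sum()])

    _, p, _, _ = stats.chi2_contingency(np.vstack([merge(h0), merge(h1)]))
    assert p > 0.01


# ---------------------------------------------------------------------------
# step scheduling
# ---------------------------------------------------------------------------


def test_lambda_zero_is_all_reproductions():
    cfg = cfg_er(N=30, lam=0.0, t_max=500, early_stop=False)
    state, _ = run_simulation(cfg)
    assert state.rewire_events == 0
    assert state.repro_events + state.repro_noops == 500


def test_lambda_one_preserves_language_multiset():
    cfg = cfg_er(N=30, lam=1.0, t_max=2000, early_stop=False, seed=13)
    state0 = init_population(cfg)
    sigs0 = sorted(state0.A[i].tobytes() for i in range(30))
    state, _ = run_simulation(cfg, state0)
    sigs1 = sorted(state.A[i].tobytes() for i in range(30))
    assert sigs0 == sigs1
    assert state.repro_events == 0


def test_event_mix_matches_lambda():
    cfg = cfg_er(N=30, lam=0.5, t_max=10_000, early_stop=False, seed=14)
    state, _ = run_simulation(cfg)
    frac = (state.repro_events + state.repro_noops) / 10_000
    sigma = np.sqrt(0.25 / 10_000)
    assert abs(frac - 0.5) < 4 * sigma


def test_lambda_zero_ignores_rewire_rules():
    t1 = run_simulation(cfg_er(N=30, lam=0.0, seed=21))[1]
    t2 = run_simulation(cfg_er(N=30, lam=0.0, seed=21,
                               disconnect_rule="fitness_inverse",
                               reconnect_rule="fitness_proportional"))[1]
    assert np.array_equal(t1.F_N, t2.F_N)


# ---------------------------------------------------------------------------
# kernel vs reference parity, determinism
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("lam,delta,drule,rrule", [
    (0.0, 1.0, "uniform", "uniform"),
    (0.5, 0.5, "uniform", "fitness_proportional"),
    (0.3, 0.0, "fitness_inverse", "uniform"),
    (0.7, 0.25, "fitness_proportional", "fitness_proportional"),
])
def test_kernel_matches_reference_steps_bitwise(lam, delta, drule, rrule):
    cfg = SimulationConfig(network={"family": "random", "N": 30}, t_max=400,
                           delta=delta, lam=lam, disconnect_rule=drule,
                           reconnect_rule=rrule, seed=11, record_every=50,
                           early_stop=False)
    s1, _ = run_simulation(cfg)
    s2 = init_population(cfg)
    for _ in range(cfg.t_max):
        step(s2, cfg)
    for name in ("P", "Q", "A", "F", "adj", "deg"):
        assert np.array_equal(getattr(s1, name), getattr(s2, name)), name
    assert (s1.repro_events, s1.rewire_events, s1.repro_noops,
            s1.rewire_noops) == (s2.repro_events, s2.rewire_events,
                                 s2.repro_noops, s2.rewire_noops)


def test_runs_are_deterministic_from_seed():
    cfg = cfg_er(N=40, delta=0.7, lam=0.3, t_max=3000, seed=123,
                 early_stop=False)
    _, t1 = run_simulation(cfg)
    _, t2 = run_simulation(cfg)
    assert np.array_equal(t1.F_N, t2.F_N)
    assert np.array_equal(t1.t, t2.t)
    assert np.array_equal(t1.isolated_fraction, t2.isolated_fraction)


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------


def test_consensus_start_stays_at_maximum():
    cfg = SimulationConfig(network={"family": "ring", "N": 20}, t_max=2000,
                           delta=0.0, seed=2, init="competition",
                           competition_proportions=[1.0, 0.0])
    state, traj = run_simulation(cfg)
    assert np.allclose(traj.F_N, 5.0)


def test_payoff_series_bounded():
    cfg = cfg_er(N=50, delta=1.0, t_max=20_000, seed=31)
    _, traj = run_simulation(cfg)
    assert np.all(traj.F_N >= 0.0) and np.all(traj.F_N <= 5.0)


def test_complete_graph_parental_learning_converges_fast_and_high():
    """Pure vertical transmission on a complete graph fixes a shared
    degenerate language quickly; the winning language communicates most
    objects (payoff well above the random-language baseline of ~1), though
    a signal collision inherited from the initial binarization lottery may
    keep it below the optimum of 5."""
    for s in range(5):
        cfg = SimulationConfig(network={"family": "complete", "N": 30},
                               t_max=50_000, delta=0.0, seed=600 + s)
        state, traj = run_simulation(cfg)
        assert traj.absorbed
        assert traj.F_N[-1] >= 2.0
        assert traj.F_N[-1] > traj.F_N[0]


def test_absorbed_run_is_at_fixed_point():
    cfg = cfg_er(N=30, delta=1.0, t_max=100_000, seed=17)
    state, traj = run_simulation(cfg)
    assert traj.absorbed
    # continuing changes nothing
    P = state.P.copy()
    cont = SimulationConfig.from_dict({**cfg.to_dict(), "t_max": 2000})
    state2, _ = run_simulation(cont, state)
    assert np.array_equal(state2.P, P)


def test_run_batch_aggregation():
    cfg = cfg_er(N=30, t_max=5000, delta=1.0)
    trajs, summary = run_batch(cfg, 3, base_seed=50)
    assert len(trajs) == 3
    f0 = np.mean([t.F_N[0] for t in trajs])
    assert summary["F_N_mean"].iloc[0] == pytest.approx(f0)
    t_same, _ = run_batch(cfg, 1, base_seed=50)
    assert np.array_equal(t_same[0].F_N, trajs[0].F_N)


def test_batch_mean_payoff_rises_monotonically_after_smoothing():
    cfg = SimulationConfig(network={"family": "random", "N": 64},
                           t_max=60_000, delta=1.0, seed=0)
    _, summary = run_batch(cfg, 6, base_seed=77)
    F = summary["F_N_mean"].to_numpy()
    w = max(1, len(F) // 10)
    smoothed = np.convolve(F, np.ones(w) / w, mode="valid")
    assert np.all(np.diff(smoothed) >= -1e-9)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def test_state_bundle_roundtrip(tmp_path):
    cfg = cfg_er(N=25, delta=0.5, lam=0.2, t_max=500, seed=33,
                 early_stop=False)
    state, traj = run_simulation(cfg)
    save_state(state, tmp_path / "state.json", config=cfg)
    st2 = load_state(tmp_path / "state.json")
    assert np.array_equal(st2.adj, state.adj)
    np.testing.assert_allclose(st2.A, state.A)
    np.testing.assert_allclose(st2.F, state.F, atol=1e-12)
    assert st2.t == state.t
    traj.to_csv(tmp_path / "traj.csv")
    import pandas as pd
    df = pd.read_csv(tmp_path / "traj.csv")
    assert list(df.columns) == ["t", "reproduction_events", "rewire_events",
                                "F_N", "isolated_fraction"]
    assert len(df) == len(traj.t)
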