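import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ipsonn import (FEATURE_NAMES, Particle, SwarmConfig, fitness, run_ipso,
                    update_position, update_velocity)


def eq9_oracle(l, a, n_f=7):
    """Independent term-by-term evaluation of the pinned fitness formula."""
    d = [l[i] - a[i] for i in range(n_f)]
    sq = (d[0] ** 2 + d[1] ** 2 + d[2] ** 2) / (n_f - 1)
    ab = (abs(d[3]) + abs(d[4]) + abs(d[5]) + abs(d[6])) * math.sqrt(n_f - 1)
    return math.sqrt(sq + ab)


def two_class_table():
    """Feature table where only M separates the two tissue groups."""
    rows = []
    for i in range(10):
        rows.append({"tissue": "WM", "I": 1.0, "S": 2.0, "M": 10.0,
                     "E": 3.0, "H": 1.0, "V": 1.0, "D": 1.0})
        rows.append({"tissue": "GM", "I": 1.0, "S": 2.0, "M": 0.0,
                     "E": 3.0, "H": 1.0, "V": 1.0, "D": 1.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- fitness


def test_fitness_zero_at_identical_vectors(rng):
    v = rng.uniform(0, 10, 7)
    assert fitness(v, v) == 0.0


def test_fitness_symmetric_and_matches_oracle(rng):
    for _ in range(10):
        l, a = rng.uniform(-5, 5, 7), rng.uniform(-5, 5, 7)
        assert fitness(l, a) == pytest.approx(fitness(a, l))
        assert fitness(l, a) == pytest.approx(eq9_oracle(list(l), list(a)))
        assert fitness(l, a) >= 0.0


def test_fitness_rejects_length_mismatch():
    with pytest.raises(ValueError):
        fitness(np.ones(6), np.ones(7))


# ---------------------------------------------------------------- velocity


def _scalar_particle(v, s, pbest, pworst):
    p = Particle(position=np.array([s]), velocity=np.array([v]))
    p.pbest_position = np.array([pbest])
    p.pworst_position = np.array([pworst])
    return p


def test_velocity_hand_arithmetic_scalar_case():
    # w=0.5, V=1, S=0.2, Pbest=0.8, Pworst=0.0, Gbest=1.0, all C=2, r=0.5:
    #   0.5*1 + 2*0.5*(0.8-0.2)*0.8 + 2*0.5*(0.2-0.0)*0.0 + 2*0.5*(1.0-0.2)
    # = 0.5 + 0.48 + 0 + 0.8 = 1.78
    cfg = SwarmConfig(w=0.5, c1b=2.0, c1w=2.0, c2=2.0, v_max=10.0, n_f=1)
    p = _scalar_particle(v=1.0, s=0.2, pbest=0.8, pworst=0.0)
    v = update_velocity(p, np.array([1.0]), cfg, 0.5, 0.5, 0.5)
    assert v[0] == pytest.approx(1.78)


def test_velocity_reduces_to_standard_pso_with_classic_terms(rng):
    cfg = SwarmConfig(w=0.7, c1b=1.5, c1w=0.0, c2=1.3, v_max=100.0,
                      classic_terms=True)
    pos, vel = rng.uniform(0, 1, 7), rng.uniform(-1, 1, 7)
    pbest, g = rng.uniform(0, 1, 7), rng.uniform(0, 1, 7)
    p = Particle(position=pos.copy(), velocity=vel.copy())
    p.pbest_position = pbest.copy()
    r1, r3 = 0.3, 0.9
    v = update_velocity(p, g, cfg, r1, 0.0, r3)
    expected = 0.7 * vel + 1.5 * r1 * (pbest - pos) + 1.3 * r3 * (g - pos)
    assert np.allclose(v, expected)


def test_velocity_all_attractors_at_position_leaves_inertia_only(rng):
    s = rng.uniform(0, 1, 7)
    p = Particle(position=s.copy(), velocity=rng.uniform(-0.3, 0.3, 7))
    p.pbest_position = s.copy()
    p.pworst_position = s.copy()
    cfg = SwarmConfig(w=0.6)
    v = update_velocity(p, s, cfg, 0.4, 0.5, 0.6)
    assert np.allclose(v, 0.6 * p.velocity)


def test_velocity_rejects_r_outside_unit_interval():
    p = Particle(position=np.zeros(7), velocity=np.zeros(7))
    with pytest.raises(ValueError):
        update_velocity(p, np.zeros(7), SwarmConfig(), 1.5, 0.5, 0.5)


def test_position_update_clamps_and_matches_sum(rng):
    p = Particle(position=np.array([0.9, 0.2, 0.5]),
                 velocity=np.array([0.5, -0.5, 0.1]))
    out = update_position(p)
    assert np.allclose(out, [1.0, 0.0, 0.6])
    pos, vel = rng.uniform(0, 1, 7), rng.uniform(-0.2, 0.2, 7)
    q = Particle(position=pos.copy(), velocity=vel.copy())
    assert np.allclose(update_position(q), np.clip(pos + vel, 0, 1))


# ---------------------------------------------------------------- swarm runs


def test_informative_feature_selected_in_95_of_100_runs():
    table = two_class_table()
    hits = 0
    for seed in range(100):
        cfg = SwarmConfig(n_particles=10, max_iter=30, seed=seed)
        res = run_ipso(table, cfg, objective="eq9", target_class="WM")
        hits += "M" in res.selected
    assert hits >= 95


def test_max_iter_one_returns_best_of_initialization():
    obj = lambda p: -float(np.sum((p - 0.5) ** 2))
    cfg = SwarmConfig(n_particles=8, max_iter=1, seed=3)
    res = run_ipso(None, cfg, objective=obj)
    # reproduce the init draws: positions/velocities interleaved per particle
    rg = np.random.default_rng(3)
    best = -np.inf
    best_pos = None
    for _ in range(8):
        pos = rg.uniform(0, 1, 7)
        rg.uniform(-cfg.v_max, cfg.v_max, 7)
        if obj(pos) > best:
            best, best_pos = obj(pos), pos
    assert res.best_fitness == pytest.approx(best)
    assert np.allclose(res.best_position, best_pos)


def test_gbest_trace_is_monotone_nondecreasing():
    obj = lambda p: float(np.sum(p * np.arange(7)))
    res = run_ipso(None, SwarmConfig(n_particles=12, max_iter=50, seed=9),
                   objective=obj)
    assert np.all(np.diff(res.trace) >= 0)


def test_pworst_fitness_never_above_pbest():
    obj = lambda p: float(np.sin(10 * p[0]) + p[3])
    res = run_ipso(None, SwarmConfig(n_particles=6, max_iter=40, seed=2),
                   objective=obj)
    for p in res.particles:
        assert p.pworst_fitness <= p.pbest_fitness


def test_positions_and_velocities_stay_clamped():
    obj = lambda p: float(p[0])
    cfg = SwarmConfig(n_particles=10, max_iter=60, seed=4, v_max=0.3)
    res = run_ipso(None, cfg, objective=obj)
    for p in res.particles:
        assert np.all((p.position >= 0) & (p.position <= 1))
        assert np.all(np.abs(p.velocity) <= 0.3 + 1e-12)


def test_classic_mode_matches_reference_standard_pso_step_for_step():
    """With classic terms and no worst-memory force, the swarm must
    reproduce a textbook global-best PSO trajectory exactly."""
    obj = lambda p: -float(np.sum((p - 0.37) ** 2))
    cfg = SwarmConfig(n_particles=6, max_iter=25, seed=13, c1w=0.0,
                      classic_terms=True)
    res = run_ipso(None, cfg, objective=obj)

    # --- independent reference implementation ---
    rg = np.random.default_rng(13)
    pos, vel = [], []
    for _ in range(cfg.n_particles):
        pos.append(rg.uniform(0, 1, 7))
        vel.append(rg.uniform(-cfg.v_max, cfg.v_max, 7))
    pbest = [p.copy() for p in pos]
    pbest_f = [-np.inf] * cfg.n_particles
    gbest, gbest_f = None, -np.inf
    for it in range(cfg.max_iter):
        for i in range(cfg.n_particles):
            f = obj(pos[i])
            if f > pbest_f[i]:
                pbest_f[i], pbest[i] = f, pos[i].copy()
        k = int(np.argmax(pbest_f))
        if pbest_f[k] > gbest_f:
            gbest_f, gbest = pbest_f[k], pbest[k].copy()
        if it + 1 < cfg.max_iter:
            for i in range(cfg.n_particles):
                r1, r2, r3 = rg.random(3)
                vel[i] = np.clip(
                    cfg.w * vel[i]
                    + cfg.c1b * r1 * (pbest[i] - pos[i])
                    + cfg.c2 * r3 * (gbest - pos[i]),
                    -cfg.v_max, cfg.v_max)
                pos[i] = np.clip(pos[i] + vel[i], 0, 1)

    assert res.best_fitness == pytest.approx(gbest_f)
    assert np.allclose(res.best_position, gbest)
    for p, rp, rv in zip(res.particles, pos, vel):
        assert np.allclose(p.position, rp)
        assert np.allclose(p.velocity, rv)


def test_same_seed_same_result(rng):
    table = two_class_table()
    cfg = SwarmConfig(n_particles=8, max_iter=20, seed=42)
    a = run_ipso(table, cfg, target_class="WM")
    b = run_ipso(table, cfg, target_class="WM")
    assert a.selected == b.selected
    assert np.array_equal(a.best_position, b.best_position)
    assert np.array_equal(a.trace, b.trace)


def test_config_invariants():
    with pytest.raises(ValueError):
        SwarmConfig(w=0.0)
    with pytest.raises(ValueError):
        SwarmConfig(max_iter=0)
    with pytest.raises(ValueError):
        SwarmConfig(c2=-1.0)


@settings(derandomize=True, max_examples=20)
@given(seed=st.integers(0, 10_000))
def test_wrapper_objective_bounded_and_deterministic(seed):
    table = two_class_table()
    cfg = SwarmConfig(n_particles=5, max_iter=5, seed=seed)
    res = run_ipso(table, cfg, objective="wrapper", target_class="WM")
    assert 0.0 <= res.best_fitness <= 1.0
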