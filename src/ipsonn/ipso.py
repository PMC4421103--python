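"""Improved particle swarm optimizer (IPSO) for feature selection.

Standard global-best PSO augmented with a personal-*worst* repulsion
term: besides being pulled toward its personal best and the swarm best,
each particle is pushed away from the worst position it has visited.
The velocity update is

    V <- w*V + C1b*r1*(Pbest - S)∘Pbest + C1w*r2*(S - Pworst)∘Pworst
           + C2*r3*(Gbest - S)

with ∘ an elementwise product (``classic_terms=True`` drops the two ∘
factors, recovering the textbook update).  Positions are continuous
gating weights in [0,1]^7; a feature is selected when the final
swarm-best weight is >= 0.5.

The default objective scores a gating vector by the swarm fitness
measure applied to the gated class-mean feature vector versus the gated
mean of the remaining classes — larger distance, better separation of
the target tissue.  A classifier-wrapper objective (leave-one-out
nearest-centroid accuracy) and arbitrary callables are also accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FeatureVector

N_FEATURES = len(FEATURE_NAMES)

# The fitness groups (I, S, M) as squared differences and (E, H, V, D)
# as absolute differences under one square root:
#   f = sqrt( (dI^2 + dS^2 + dM^2)/(n_f - 1)
#             + (|dE| + |dH| + |dV| + |dD|) * sqrt(n_f - 1) )
# This grouping is pinned; any admissible reading must be symmetric,
# nonnegative and zero at identical vectors.
_SQUARED_GROUP = slice(0, 3)
_ABS_GROUP = slice(3, 7)


def _as_vector(v) -> np.ndarray:
    if isinstance(v, FeatureVector):
        return v.as_array()
    return np.asarray(v, dtype=np.float64)


def fitness(particle_l, particle_a, n_f: int = N_FEATURES) -> float:
    """Pairwise swarm fitness between two feature vectors (see module doc).

    Symmetric, nonnegative, and zero iff the vectors coincide.
    """
    l = _as_vector(particle_l)
    a = _as_vector(particle_a)
    if l.shape != a.shape or l.shape != (n_f,):
        raise ValueError("feature vectors must both have length n_f")
    d = l - a
    sq = float(np.sum(d[_SQUARED_GROUP] ** 2)) / (n_f - 1)
    ab = float(np.sum(np.abs(d[_ABS_GROUP]))) * np.sqrt(n_f - 1)
    return float(np.sqrt(sq + ab))


@dataclass
class SwarmConfig:
    n_particles: int = 20
    max_iter: int = 100
    w: float = 0.72
    c1b: float = 1.49
    c1w: float = 0.5
    c2: float = 1.49
    v_max: float = 0.5
    seed: int = 0
    n_f: int = N_FEATURES
    classic_terms: bool = False  # True -> drop the ∘Pbest / ∘Pworst factors

    def __post_init__(self):
        if not 0 < self.w <= 1:
            raise ValueError("inertia w must be in (0, 1]")
        if min(self.c1b, self.c1w, self.c2) < 0:
            raise ValueError("acceleration coefficients must be nonnegative")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.n_particles < 1:
            raise ValueError("need at least one particle")
        if self.v_max <= 0:
            raise ValueError("v_max must be positive")


@dataclass
class Particle:
    """Position/velocity plus personal best and personal worst memory."""

    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray = None
    pbest_fitness: float = -np.inf
    pworst_position: np.ndarray = None
    pworst_fitness: float = np.inf

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=np.float64)
        self.velocity = np.asarray(self.velocity, dtype=np.float64)
        if self.pbest_position is None:
            self.pbest_position = self.position.copy()
        if self.pworst_position is None:
            self.pworst_position = self.position.copy()

    def record(self, fit: float) -> None:
        """Update personal best/worst memory with the current position."""
        if fit > self.pbest_fitness:
            self.pbest_fitness = fit
            self.pbest_position = self.position.copy()
        if fit < self.pworst_fitness:
            self.pworst_fitness = fit
            self.pworst_position = self.position.copy()


def update_velocity(p: Particle, gbest_position, cfg: SwarmConfig,
                    r1: float, r2: float, r3: float) -> np.ndarray:
    """New clamped velocity from the three-term update (see module doc)."""
    for r in (r1, r2, r3):
        if np.any(np.asarray(r) < 0) or np.any(np.asarray(r) > 1):
            raise ValueError("r1, r2, r3 must lie in [0, 1]")
    g = np.asarray(gbest_position, dtype=np.float64)
    best_fac = 1.0 if cfg.classic_terms else p.pbest_position
    worst_fac = 1.0 if cfg.classic_terms else p.pworst_position
    v = (
        cfg.w * p.velocity
        + cfg.c1b * r1 * (p.pbest_position - p.position) * best_fac
        + cfg.c1w * r2 * (p.position - p.pworst_position) * worst_fac
        + cfg.c2 * r3 * (g - p.position)
    )
    return np.clip(v, -cfg.v_max, cfg.v_max)


def update_position(p: Particle) -> np.ndarray:
    """S <- clamp(S + V, 0, 1), elementwise."""
    return np.clip(p.position + p.velocity, 0.0, 1.0)


# ---------------------------------------------------------------------------
# objectives


def _standardize(table: pd.DataFrame) -> pd.DataFrame:
    X = table[list(FEATURE_NAMES)].astype(float)
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    sd = sd.replace(0.0, 1.0)
    return (X - mu) / sd


def make_separation_objective(feature_table: pd.DataFrame, target_class: str) -> Callable:
    """Swarm-fitness distance between gated class mean and gated rest mean."""
    if "tissue" not in feature_table.columns:
        raise ValueError("feature table needs a 'tissue' column")
    is_target = feature_table["tissue"] == target_class
    if not is_target.any() or is_target.all():
        raise ValueError(f"feature table must contain '{target_class}' and other classes")
    Z = _standardize(feature_table)
    mu_c = Z[is_target.values].mean(axis=0).to_numpy()
    mu_rest = Z[~is_target.values].mean(axis=0).to_numpy()

    def objective(position: np.ndarray) -> float:
        return fitness(position * mu_c, position * mu_rest)

    return objective


def make_wrapper_objective(feature_table: pd.DataFrame, target_class: str) -> Callable:
    """Leave-one-out nearest-centroid accuracy on weighted features."""
    Z = _standardize(feature_table).to_numpy()
    y = (feature_table["tissue"] == target_class).to_numpy()
    n = len(y)
    if n < 3 or not 0 < y.sum() < n:
        raise ValueError("wrapper objective needs both classes and >= 3 rows")

    sums = {c: Z[y == c].sum(axis=0) for c in (True, False)}
    counts = {c: int((y == c).sum()) for c in (True, False)}

    def objective(position: np.ndarray) -> float:
        W = Z * position
        correct = 0
        for i in range(n):
            best, best_d = None, np.inf
            for c in (True, False):
                cnt = counts[c] - (1 if y[i] == c else 0)
                if cnt == 0:
                    continue
                cen = (sums[c] * position - (W[i] if y[i] == c else 0)) / cnt
                d = float(np.sum((W[i] - cen) ** 2))
                if d < best_d:
                    best, best_d = c, d
            correct += best == y[i]
        return correct / n

    return objective


@dataclass
class IPSOResult:
    selected: list
    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray  # gbest fitness per iteration (monotone nondecreasing)
    particles: list = field(default_factory=list, repr=False)


def run_ipso(
    feature_table: Optional[pd.DataFrame],
    cfg: SwarmConfig,
    objective: Union[str, Callable] = "eq9",
    target_class: Optional[str] = None,
) -> IPSOResult:
    """Optimize gating weights and return the selected feature subset.

    ``objective`` is ``"eq9"`` (default separation objective),
    ``"wrapper"`` (nearest-centroid accuracy), or any callable mapping a
    position in [0,1]^n_f to a score to maximize.  Iteration 1 is the
    evaluation of the initial swarm, so ``max_iter=1`` returns the best
    initial particle.  Draw order per movement phase: for each particle
    in index order, ``r1, r2, r3 = rng.random(3)``.
    """
    if callable(objective):
        obj = objective
    elif objective == "eq9":
        if feature_table is None or feature_table.empty:
            raise ValueError("feature table required for the eq9 objective")
        obj = make_separation_objective(feature_table, target_class)
    elif objective == "wrapper":
        obj = make_wrapper_objective(feature_table, target_class)
    else:
        raise ValueError(f"unknown objective {objective!r}")

    rng = np.random.default_rng(cfg.seed)
    particles = [
        Particle(
            position=rng.uniform(0.0, 1.0, cfg.n_f),
            velocity=rng.uniform(-cfg.v_max, cfg.v_max, cfg.n_f),
        )
        for _ in range(cfg.n_particles)
    ]

    gbest_position = None
    gbest_fitness = -np.inf
    trace = np.empty(cfg.max_iter)

    for it in range(cfg.max_iter):
        for p in particles:
            p.record(obj(p.position))
        # ties broken by lowest particle index (argmax keeps the first max)
        fits = np.array([p.pbest_fitness for p in particles])
        k = int(np.argmax(fits))
        if fits[k] > gbest_fitness:
            gbest_fitness = float(fits[k])
            gbest_position = particles[k].pbest_position.copy()
        trace[it] = gbest_fitness

        if it + 1 < cfg.max_iter:
            for p in particles:
                r1, r2, r3 = rng.random(3)
                p.velocity = update_velocity(p, gbest_position, cfg, r1, r2, r3)
                p.position = update_position(p)

    selected = [n for n, wgt in zip(FEATURE_NAMES[: cfg.n_f], gbest_position) if wgt >= 0.5]
    return IPSOResult(
        selected=selected,
        best_position=gbest_position,
        best_fitness=gbest_fitness,
        trace=trace,
        particles=particles,
    )
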