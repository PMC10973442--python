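"""Unsupervised dynamic learning mechanism (UDLM): two-center clustering by
a Gaussian pairwise-learning swarm.

Each particle encodes a candidate pair of cluster centers as one
``2*D``-dimensional position (center1 ++ center2).  Fitness is the *sum
distance*: every data point contributes its Euclidean distance to the
nearer of the two centers, so the global minimum is the optimal 2-center
configuration (the k-medians-flavored k=2 objective with Euclidean
distances).

Per iteration every particle co-evolves with one uniformly random distinct
neighbor.  Writing ``p_i`` for the personal best of the pair member with
the *larger* objective, ``p_j`` for the smaller, and ``g`` for the global
best, candidate positions are drawn coordinate-wise as

    candidate_i ~ Normal(mean=(p_i + p_j)/2, sd=|p_i - p_j|)
    candidate_j ~ Normal(mean=(p_j + g)/2,   sd=|p_j - g|)

(a zero sd yields the mean exactly).  A candidate replaces the owning
particle's personal best only on strict improvement, and the global best is
refreshed after every evaluation, so the gbest history is non-increasing by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyDatasetError, InvalidInputError


@dataclass
class Particle:
    """A candidate pair of centers with personal-best memory.

    The current search position is identified with the personal best: the
    learning rule consumes only personal bests and the global best.
    """

    pbest_position: np.ndarray
    pbest_value: float

    @property
    def position(self) -> np.ndarray:
        return self.pbest_position


@dataclass
class SwarmState:
    particles: list[Particle]
    gbest_position: np.ndarray
    gbest_value: float
    iteration: int
    history: list[float]
    rng_seed: int | None


@dataclass(frozen=True)
class UDLMConfig:
    """Swarm hyperparameters.

    ``init_bounds`` is a per-dimension (low, high) array of shape (2*D, 2);
    ``None`` means the per-feature data range, replicated for both centers.
    Bounds constrain initialization only — the Gaussian learning step has no
    projection.
    """

    pop_size: int = 30
    max_iter: int = 200
    init_bounds: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.pop_size < 1:
            raise InvalidInputError("pop_size must be >= 1")
        if self.max_iter < 1:
            raise InvalidInputError("max_iter must be >= 1")


def _as_points(data: np.ndarray) -> np.ndarray:
    pts = np.asarray(data, dtype=float)
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise InvalidInputError("data must be a non-empty (n, D) array")
    return pts


def split_centers(position: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a 2*D position vector into its two D-dimensional centers."""
    position = np.asarray(position, dtype=float)
    if position.ndim != 1 or position.size % 2:
        raise InvalidInputError("position must be a 1-D vector of even length")
    half = position.size // 2
    return position[:half], position[half:]


def sum_distance(position: np.ndarray, data: np.ndarray) -> float:
    """Clustering objective: sum over points of the distance to the nearer center."""
    pts = _as_points(data)
    c1, c2 = split_centers(position)
    if c1.size != pts.shape[1]:
        raise InvalidInputError(
            f"center dimension {c1.size} does not match data dimension {pts.shape[1]}"
        )
    d1 = np.linalg.norm(pts - c1, axis=1)
    d2 = np.linalg.norm(pts - c2, axis=1)
    return float(np.sum(np.minimum(d1, d2)))


def default_init_bounds(data: np.ndarray) -> np.ndarray:
    """Per-feature [min, max] of the data, replicated for both centers."""
    pts = _as_points(data)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    per_center = np.stack([lo, hi], axis=1)
    return np.vstack([per_center, per_center])


def initialize_swarm(
    data: np.ndarray, config: UDLMConfig, rng: np.random.Generator | None = None
) -> SwarmState:
    """Scatter ``pop_size`` particles uniformly within the init bounds."""
    pts = _as_points(data)
    if pts.shape[0] < 1:
        raise EmptyDatasetError("cannot cluster an empty dataset")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    bounds = (
        np.asarray(config.init_bounds, dtype=float)
        if config.init_bounds is not None
        else default_init_bounds(pts)
    )
    if bounds.shape != (2 * pts.shape[1], 2):
        raise InvalidInputError("init_bounds must have shape (2*D, 2)")
    if np.any(bounds[:, 0] > bounds[:, 1]):
        raise InvalidInputError("init_bounds low must be <= high per dimension")
    particles = []
    for _ in range(config.pop_size):
        pos = rng.uniform(bounds[:, 0], bounds[:, 1])
        particles.append(Particle(pbest_position=pos, pbest_value=sum_distance(pos, pts)))
    best = min(particles, key=lambda p: p.pbest_value)
    return SwarmState(
        particles=particles,
        gbest_position=best.pbest_position.copy(),
        gbest_value=best.pbest_value,
        iteration=0,
        history=[best.pbest_value],
        rng_seed=config.seed,
    )


def pairwise_learning_step(
    p_i: Particle,
    p_j: Particle,
    gbest: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One Gaussian co-evolution step for an ordered pair (worse i, better j).

    The caller orders the pair so that ``p_j.pbest_value <= p_i.pbest_value``.
    """
    xi, xj = p_i.pbest_position, p_j.pbest_position
    g = np.asarray(gbest, dtype=float)
    if not (xi.shape == xj.shape == g.shape):
        raise InvalidInputError("particle and gbest dimensions must agree")
    alpha = (xi + xj) / 2.0
    beta = np.abs(xi - xj)
    chi = (xj + g) / 2.0
    delta = np.abs(xj - g)
    candidate_i = rng.normal(loc=alpha, scale=beta)
    candidate_j = rng.normal(loc=chi, scale=delta)
    return candidate_i, candidate_j


def run_udlm(
    data: np.ndarray, config: UDLMConfig
) -> tuple[tuple[np.ndarray, np.ndarray], SwarmState]:
    """Run the swarm and return the best pair of centers plus the full state.

    Per iteration each particle is paired with one uniformly random distinct
    neighbor; the pair is ordered by personal-best value (on an exact tie
    the particle whose turn it is plays the worse role i).  Both candidates
    are evaluated; each replaces its owner's personal best only on strict
    improvement, and the global best is refreshed after every evaluation.
    With a single particle the pair degenerates to (self, self) and the step
    contracts toward the global best.
    """
    pts = _as_points(data)
    rng = np.random.default_rng(config.seed)
    state = initialize_swarm(pts, config, rng)
    P = state.particles
    for t in range(config.max_iter):
        for k in range(len(P)):
            if len(P) > 1:
                m = int(rng.integers(len(P) - 1))
                if m >= k:
                    m += 1
            else:
                m = k
            # tie -> the first-selected particle k plays role i
            if P[k].pbest_value >= P[m].pbest_value:
                i, j = k, m
            else:
                i, j = m, k
            cand_i, cand_j = pairwise_learning_step(P[i], P[j], state.gbest_position, rng)
            for owner, cand in ((i, cand_i), (j, cand_j)):
                value = sum_distance(cand, pts)
                if value < P[owner].pbest_value:
                    P[owner].pbest_position = cand
                    P[owner].pbest_value = value
                if value < state.gbest_value:
                    state.gbest_position = cand.copy()
                    state.gbest_value = value
        state.iteration = t + 1
        state.history.append(state.gbest_value)
    return split_centers(state.gbest_position), state


def assign_labels(data: np.ndarray, centers: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Index of the nearer center per point; exact ties go to cluster 0."""
    pts = _as_points(data)
    c1, c2 = np.asarray(centers[0], float), np.asarray(centers[1], float)
    if c1.shape != (pts.shape[1],) or c2.shape != (pts.shape[1],):
        raise InvalidInputError("center dimensions must match the data")
    d1 = np.linalg.norm(pts - c1, axis=1)
    d2 = np.linalg.norm(pts - c2, axis=1)
    return (d2 < d1).astype(int)
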