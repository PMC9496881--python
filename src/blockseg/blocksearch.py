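"""Particle-swarm search for the lesion-containing block.

Particles move in the continuous space of block top-left corners under the
classic velocity/position updates

    V <- w*V + c1*R1*(P - X) + c2*R2*(G - X)
    X <- X + V

with inertia ``w``, cognitive pull toward the personal best ``P`` and social
pull toward the global best ``G``; ``R1, R2`` are fresh uniforms per particle
per iteration.  Positions are rounded to integers only for block extraction,
which induces a finite search space and makes exact memoization possible:
every evaluated (row, col) is cached, so revisits are free.

An exhaustive stride-1 search over all positions is provided as the oracle
the swarm is validated against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .anova import anova_fitness

__all__ = [
    "Block",
    "SwarmConfig",
    "SearchResult",
    "sad",
    "evaluate_position",
    "pso_search",
    "exhaustive_search",
    "default_block_size",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Block:
    """A rectangular window [top, top+height) x [left, left+width)."""

    top: int
    left: int
    height: int
    width: int

    def validate(self, image_shape: tuple[int, int]) -> None:
        H, W = image_shape
        if self.height < 2 or self.width < 2:
            raise ValueError(f"block must be at least 2x2, got {self.height}x{self.width}")
        if not (0 <= self.top and self.top + self.height <= H
                and 0 <= self.left and self.left + self.width <= W):
            raise ValueError(
                f"block {self} does not fit inside a {H}x{W} image"
            )

    def view(self, image: np.ndarray) -> np.ndarray:
        return image[self.top:self.top + self.height, self.left:self.left + self.width]


@dataclass(frozen=True)
class SwarmConfig:
    """Swarm hyperparameters and the block geometry being searched.

    ``block_height``/``block_width`` of ``None`` default to a quarter of the
    smaller image dimension, rounded down to an even number.
    """

    np_particles: int = 20
    t_max: int = 50
    omega: float = 0.72
    c1: float = 1.49
    c2: float = 1.49
    v_max: float | None = None
    block_height: int | None = None
    block_width: int | None = None
    fitness_kind: str = "anova"
    random_seed: int = 0

    def validate(self) -> None:
        if self.np_particles < 1:
            raise ValueError("np_particles must be >= 1")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if min(self.omega, self.c1, self.c2) < 0:
            raise ValueError("omega, c1 and c2 must be >= 0")
        if self.fitness_kind not in ("anova", "sad"):
            raise ValueError(f'fitness_kind must be "anova" or "sad", got {self.fitness_kind!r}')

    def resolved(self, image_shape: tuple[int, int]) -> "SwarmConfig":
        """Fill in block size and velocity clamp for a concrete image."""
        self.validate()
        h, w = self.block_height, self.block_width
        if h is None or w is None:
            side = default_block_size(image_shape)
            h = h if h is not None else side
            w = w if w is not None else side
        vmax = self.v_max if self.v_max is not None else float(max(h, w))
        cfg = replace(self, block_height=h, block_width=w, v_max=vmax)
        Block(0, 0, h, w).validate(image_shape)
        return cfg


def default_block_size(image_shape: tuple[int, int]) -> int:
    """A quarter of the smaller image dimension, rounded down to even."""
    side = min(image_shape) // 4
    return max(2, side - side % 2)


@dataclass
class SearchResult:
    """Outcome of a block search."""

    best_block: Block
    best_fitness: float
    fitness_trace: list[float]
    evaluations: int
    cache_hits: int


def sad(block1: np.ndarray, block2: np.ndarray) -> float:
    """Sum of absolute pixel differences (L1 block dissimilarity)."""
    a = np.asarray(block1, dtype=float)
    b = np.asarray(block2, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"blocks differ in shape: {a.shape} vs {b.shape}")
    return float(np.abs(a - b).sum())


class _FitnessCache:
    """Position -> fitness memo with hit/miss bookkeeping."""

    def __init__(self):
        self.table: dict[tuple[int, int], float] = {}
        self.hits = 0

    @property
    def evaluations(self) -> int:
        return len(self.table)


def evaluate_position(position: tuple[int, int], diseased: np.ndarray,
                      reference: np.ndarray, config: SwarmConfig,
                      cache: _FitnessCache, valid_mask: np.ndarray | None = None) -> float:
    """Fitness of the block anchored at an integer (row, col), memoized.

    With a ``valid_mask``, blocks not fully inside the mask's True region
    score 0 (they compare padding, not tissue, and carry no lesion evidence).
    """
    key = (int(position[0]), int(position[1]))
    if key in cache.table:
        cache.hits += 1
        return cache.table[key]
    h, w = config.block_height, config.block_width
    block = Block(key[0], key[1], h, w)
    block.validate(diseased.shape)
    if valid_mask is not None and not block.view(valid_mask).all():
        value = 0.0
    elif config.fitness_kind == "sad":
        value = sad(block.view(diseased), block.view(reference))
    else:
        value = anova_fitness(block.view(diseased), block.view(reference))
    cache.table[key] = value
    return value


def _check_pair(diseased, reference):
    d = np.asarray(diseased, dtype=float)
    r = np.asarray(reference, dtype=float)
    if d.shape != r.shape:
        raise ValueError(f"diseased and reference differ in shape: {d.shape} vs {r.shape}")
    if d.ndim != 2:
        raise ValueError(f"expected 2-d images, got {d.ndim}-d")
    return d, r


def pso_search(diseased: np.ndarray, reference: np.ndarray, config: SwarmConfig,
               valid_mask: np.ndarray | None = None) -> SearchResult:
    """Swarm search for the maximum-fitness block; seeded, reproducible.

    Iteration 1 evaluates the random initial positions; iterations 2..t_max
    apply the velocity/position updates before evaluating, so at most
    ``np_particles * t_max`` unique positions are ever scored.
    """
    d, r = _check_pair(diseased, reference)
    cfg = config.resolved(d.shape)
    h, w = cfg.block_height, cfg.block_width
    hi = np.array([d.shape[0] - h, d.shape[1] - w], dtype=float)
    rng = np.random.default_rng(cfg.random_seed)
    cache = _FitnessCache()

    X = rng.uniform(0.0, 1.0, (cfg.np_particles, 2)) * hi
    V = rng.uniform(-cfg.v_max, cfg.v_max, (cfg.np_particles, 2))

    def score(x) -> float:
        pos = np.clip(np.rint(x), 0, hi).astype(int)
        return evaluate_position((pos[0], pos[1]), d, r, cfg, cache, valid_mask)

    F = np.array([score(x) for x in X])
    P = X.copy()
    Pf = F.copy()
    g = int(Pf.argmax())
    G, Gf = P[g].copy(), float(Pf[g])
    trace = [Gf]

    for t in range(2, cfg.t_max + 1):
        R1 = rng.uniform(size=(cfg.np_particles, 1))
        R2 = rng.uniform(size=(cfg.np_particles, 1))
        V = cfg.omega * V + cfg.c1 * R1 * (P - X) + cfg.c2 * R2 * (G - X)
        V = np.clip(V, -cfg.v_max, cfg.v_max)
        X = np.clip(X + V, 0.0, hi)
        F = np.array([score(x) for x in X])
        improved = F > Pf
        P[improved] = X[improved]
        Pf[improved] = F[improved]
        if Pf.max() > Gf:
            g = int(Pf.argmax())
            G, Gf = P[g].copy(), float(Pf[g])
        trace.append(Gf)
        logger.info("iteration %d: global best %.6g", t, Gf)

    best = np.clip(np.rint(G), 0, hi).astype(int)
    logger.debug("cache: %d unique evaluations, %d hits", cache.evaluations, cache.hits)
    return SearchResult(
        best_block=Block(int(best[0]), int(best[1]), h, w),
        best_fitness=Gf,
        fitness_trace=trace,
        evaluations=cache.evaluations,
        cache_hits=cache.hits,
    )


def exhaustive_search(diseased: np.ndarray, reference: np.ndarray, config: SwarmConfig,
                      valid_mask: np.ndarray | None = None) -> SearchResult:
    """Score every valid top-left position (stride 1) and return the true
    maximum; ties broken by the lexicographically smallest (row, col)."""
    d, r = _check_pair(diseased, reference)
    cfg = config.resolved(d.shape)
    h, w = cfg.block_height, cfg.block_width
    cache = _FitnessCache()
    best_pos, best_fit = (0, 0), -np.inf
    for top in range(d.shape[0] - h + 1):
        for left in range(d.shape[1] - w + 1):
            f = evaluate_position((top, left), d, r, cfg, cache, valid_mask)
            if f > best_fit:
                best_pos, best_fit = (top, left), f
    return SearchResult(
        best_block=Block(best_pos[0], best_pos[1], h, w),
        best_fitness=float(best_fit),
        fitness_trace=[float(best_fit)],
        evaluations=cache.evaluations,
        cache_hits=cache.hits,
    )
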