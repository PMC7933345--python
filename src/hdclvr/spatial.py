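"""Spatially explicit extension of the population model.

Individuals live in a square arena whose side is sized so that the
carrying capacity ``K`` fits at the species' natural density
(``A = sqrt(K pi r^2 / D)`` with home-range radius ``r`` and ``D``
individuals per home range).  Mating is distance-dependent through a
Gaussian radial-basis approach kernel ``P_a = exp(-(eps s)^2)``, offspring
are born at their mother's location, and density regulation acts through
migration rather than extra mortality: individuals whose local density
``d`` (count within one home-range radius, self included) exceeds ``D``
migrate with probability ``1 - D/d``, searching lazily outward for free
space with gamma-distributed step increments; everyone else makes a short
resident move.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .demography import LifeHistoryParams, Population, conceive
from .genetics import DriveParams

__all__ = [
    "SpatialParams",
    "area_side",
    "epsilon_from_range",
    "approach_probability",
    "migration_probability",
    "select_mate",
    "allocate_mates",
    "local_density",
    "move_residents",
    "move_migrants",
    "place_supplement",
    "spatial_step",
    "PLACEMENT_STRATEGIES",
]

PLACEMENT_STRATEGIES = (
    "middle",
    "mean",
    "mode",
    "random",
    "random_10_groups",
    "moving_front",
)


@dataclass(frozen=True)
class SpatialParams:
    """Spatial life-history preset; defaults describe the grey squirrel."""

    home_range_radius: float = 80.0
    max_density: float = 4.0
    mating_range_max: float = 600.0
    mating_range_observations: int = 30
    max_dispersal: float = 10000.0
    max_migration_steps: int = 50

    def __post_init__(self) -> None:
        for name in ("home_range_radius", "max_density", "mating_range_max", "max_dispersal"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.mating_range_observations <= 1:
            raise ValueError("mating_range_observations must be > 1")
        if self.max_migration_steps < 1:
            raise ValueError("max_migration_steps must be >= 1")

    @property
    def epsilon(self) -> float:
        return epsilon_from_range(self.mating_range_max, self.mating_range_observations)

    def arena_side(self, K: int) -> float:
        return area_side(K, self.home_range_radius, self.max_density)


def area_side(K: float, r: float, D: float) -> float:
    """Side of the square arena: ``A = sqrt(K pi r^2) / sqrt(D)``.

    The arena is exactly large enough to hold ``K`` individuals at ``D``
    individuals per circular home range of radius ``r``.
    """
    if K <= 0 or r <= 0 or D <= 0:
        raise ValueError("K, r and D must all be > 0")
    return math.sqrt(K * math.pi * r * r) / math.sqrt(D)


def epsilon_from_range(mating_range_max: float, observations: int) -> float:
    """Calibrate the approach-kernel shape from the observed mating range.

    Solves ``exp(-(eps * s_max)^2) = 1/observations``: the largest of
    ``observations`` observed mating ranges is assigned probability
    ``1/observations``.
    """
    if observations <= 1:
        raise ValueError("observations must be > 1")
    if mating_range_max <= 0:
        raise ValueError("mating_range_max must be > 0")
    return math.sqrt(math.log(observations)) / mating_range_max


def approach_probability(s, epsilon: float):
    """Gaussian radial basis: probability a male at distance ``s`` approaches."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("distance must be >= 0")
    out = np.exp(-((epsilon * s) ** 2))
    return float(out) if out.ndim == 0 else out


def migration_probability(d, D: float):
    """Piecewise: 0 when local density ``d <= D``, else ``1 - D/d``."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("density must be >= 0")
    out = np.where(d > D, 1.0 - D / np.maximum(d, 1e-300), 0.0)
    return float(out) if out.ndim == 0 else out


def select_mate(
    female_xy: np.ndarray,
    male_xy: np.ndarray,
    epsilon: float,
    rng: np.random.Generator,
) -> int | None:
    """Choose a father for one female; ``None`` if no male approaches.

    Each male approaches independently with ``P_a(distance)``; the father
    is uniform among approachers.
    """
    if male_xy.shape[0] == 0:
        return None
    s = np.hypot(male_xy[:, 0] - female_xy[0], male_xy[:, 1] - female_xy[1])
    approach = rng.random(s.size) < approach_probability(s, epsilon)
    idx = np.flatnonzero(approach)
    if idx.size == 0:
        return None
    return int(rng.choice(idx))


def allocate_mates(
    female_xy: np.ndarray,
    male_xy: np.ndarray,
    epsilon: float,
    rng: np.random.Generator,
    chunk: int = 256,
) -> np.ndarray:
    """Vectorised mate allocation for all females at once.

    Returns, per female, the index of the chosen male or -1 when no male
    approached.  A uniform random key per approaching male makes the
    argmax a uniform choice among approachers.
    """
    F = female_xy.shape[0]
    M = male_xy.shape[0]
    out = np.full(F, -1, dtype=np.int64)
    if F == 0 or M == 0:
        return out
    for start in range(0, F, chunk):
        fb = female_xy[start : start + chunk]
        dx = fb[:, 0:1] - male_xy[:, 0][None, :]
        dy = fb[:, 1:2] - male_xy[:, 1][None, :]
        p = np.exp(-((epsilon**2) * (dx * dx + dy * dy)))
        approach = rng.random(p.shape) < p
        keys = rng.random(p.shape)
        keys[~approach] = -1.0
        best = np.argmax(keys, axis=1)
        any_approach = approach.any(axis=1)
        rows = np.flatnonzero(any_approach)
        out[start + rows] = best[rows]
    return out


def local_density(xy: np.ndarray, r: float, tree: cKDTree | None = None) -> np.ndarray:
    """Number of individuals within one home-range radius, self included."""
    if xy.shape[0] == 0:
        return np.zeros(0)
    if tree is None:
        tree = cKDTree(xy)
    return np.asarray(tree.query_ball_point(xy, r, return_length=True), dtype=float)


def move_residents(
    xy: np.ndarray, r: float, arena: float, rng: np.random.Generator
) -> np.ndarray:
    """Single-step resident movement: uniform direction, Gamma(5, r/5)
    distance, resampled (direction and distance) until inside the arena."""
    n = xy.shape[0]
    new = xy.copy()
    pending = np.arange(n)
    while pending.size:
        theta = rng.uniform(0.0, 2.0 * math.pi, pending.size)
        dist = rng.gamma(5.0, r / 5.0, pending.size)
        cx = xy[pending, 0] + dist * np.cos(theta)
        cy = xy[pending, 1] + dist * np.sin(theta)
        ok = (cx >= 0) & (cx <= arena) & (cy >= 0) & (cy <= arena)
        new[pending[ok], 0] = cx[ok]
        new[pending[ok], 1] = cy[ok]
        pending = pending[~ok]
    return new


def move_migrants(
    xy: np.ndarray,
    params: SpatialParams,
    arena: float,
    tree: cKDTree,
    rng: np.random.Generator,
) -> np.ndarray:
    """Lazy outward search for free space, up to ``max_migration_steps``.

    Each step redraws the direction and adds a Gamma(5, 3r/5) increment to
    the cumulative distance from home; the first in-arena candidate whose
    local density (against the pre-movement position snapshot in ``tree``)
    is below ``max_density`` is accepted.  A cumulative distance beyond
    ``max_dispersal`` resets to zero and the search restarts.  After the
    step cap, the last in-arena candidate is kept regardless of density.
    """
    n = xy.shape[0]
    if n == 0:
        return xy.copy()
    r = params.home_range_radius
    final = xy.copy()  # fallback: stay home if no in-arena candidate ever seen
    last = xy.copy()
    have_last = np.zeros(n, dtype=bool)
    cum = np.zeros(n)
    unsettled = np.arange(n)
    for _ in range(params.max_migration_steps):
        if unsettled.size == 0:
            break
        theta = rng.uniform(0.0, 2.0 * math.pi, unsettled.size)
        cum[unsettled] += rng.gamma(5.0, 3.0 * r / 5.0, unsettled.size)
        over = cum[unsettled] > params.max_dispersal
        cum[unsettled[over]] = 0.0  # range exceeded: restart the search
        active = unsettled[~over]
        if active.size:
            cx = xy[active, 0] + cum[active] * np.cos(theta[~over])
            cy = xy[active, 1] + cum[active] * np.sin(theta[~over])
            inside = (cx >= 0) & (cx <= arena) & (cy >= 0) & (cy <= arena)
            cand_idx = active[inside]
            if cand_idx.size:
                cand = np.column_stack([cx[inside], cy[inside]])
                last[cand_idx] = cand
                have_last[cand_idx] = True
                dens = np.asarray(
                    tree.query_ball_point(cand, r, return_length=True), dtype=float
                )
                settled = cand_idx[dens < params.max_density]
                final[settled] = last[settled]
                keep = np.ones(n, dtype=bool)
                keep[settled] = False
                unsettled = unsettled[keep[unsettled]]
    # step cap reached: keep the last in-arena candidate where one exists
    stuck = unsettled[have_last[unsettled]]
    final[stuck] = last[stuck]
    return final


def place_supplement(
    n: int,
    strategy: str,
    pop_xy: np.ndarray,
    arena: float,
    home_range: float,
    event_index: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Locations for ``n`` supplemented animals under a placement strategy.

    ``event_index`` counts supplementation events (1-based) and drives the
    moving front, which climbs the arena in ten steps and then stays at
    the top.  Strategies needing population locations (mean, mode) fall
    back to the arena centre when the population is empty.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if strategy not in PLACEMENT_STRATEGIES:
        raise ValueError(
            f"unknown placement strategy {strategy!r}; choose from {PLACEMENT_STRATEGIES}"
        )
    centre = np.array([arena / 2.0, arena / 2.0])
    if n == 0:
        return np.zeros((0, 2))
    if strategy == "middle":
        return np.tile(centre, (n, 1))
    if strategy == "mean":
        if pop_xy.shape[0] == 0:
            return np.tile(centre, (n, 1))
        return np.tile(pop_xy.mean(axis=0), (n, 1))
    if strategy == "mode":
        if pop_xy.shape[0] == 0:
            return np.tile(centre, (n, 1))
        nbins = max(1, math.ceil(arena / home_range))
        edges = np.linspace(0.0, arena, nbins + 1)
        hist, _, _ = np.histogram2d(pop_xy[:, 0], pop_xy[:, 1], bins=[edges, edges])
        ix, iy = np.unravel_index(np.argmax(hist), hist.shape)
        cell_centre = np.array(
            [(edges[ix] + edges[ix + 1]) / 2.0, (edges[iy] + edges[iy + 1]) / 2.0]
        )
        return np.tile(cell_centre, (n, 1))
    if strategy == "random":
        point = rng.uniform(0.0, arena, 2)
        return np.tile(point, (n, 1))
    if strategy == "random_10_groups":
        points = rng.uniform(0.0, arena, (10, 2))
        group = np.arange(n) % 10  # split as evenly as possible
        return points[group]
    # moving_front
    k = min(max(event_index, 1), 10)
    y = arena * k / 10.0
    x = (np.arange(n) + 0.5) / n * arena  # spread evenly across the width
    return np.column_stack([x, np.full(n, y)])


def spatial_step(
    pop: Population,
    drive: DriveParams,
    life: LifeHistoryParams,
    spatial: SpatialParams,
    arena: float,
    rng: np.random.Generator,
) -> Population:
    """Advance one generation of the spatial model.

    Distance-dependent mate allocation (a female with no approaching male
    does not reproduce), offspring at the mother's location, the global
    density-regulated recruitment cap, then density-dependent migration
    and resident movement for every recruit.
    """
    N = pop.census
    if N == 0:
        return pop
    females = np.flatnonzero(pop.fertile_female_mask())
    males = np.flatnonzero(pop.fertile_male_mask())
    if females.size == 0 or males.size == 0:
        return Population.empty()

    female_xy = np.column_stack([pop.x[females], pop.y[females]])
    male_xy = np.column_stack([pop.x[males], pop.y[males]])
    chosen = allocate_mates(female_xy, male_xy, spatial.epsilon, rng)
    mated = chosen >= 0
    mothers = females[mated]
    fathers = males[chosen[mated]]
    if mothers.size == 0:
        return Population.empty()

    litters = rng.poisson(life.litter_size, mothers.size)
    mother_rep = np.repeat(mothers, litters)
    father_rep = np.repeat(fathers, litters)
    offspring = conceive(pop, mother_rep, father_rep, drive, rng)
    p = life.recruitment_probability(N)
    keep = rng.random(len(offspring)) < p
    new = offspring.subset(np.flatnonzero(keep))
    if new.census == 0:
        return new

    xy = np.column_stack([new.x, new.y])
    tree = cKDTree(xy)
    d = local_density(xy, spatial.home_range_radius, tree=tree)
    migrate = rng.random(new.census) < migration_probability(d, spatial.max_density)
    res_idx = np.flatnonzero(~migrate)
    mig_idx = np.flatnonzero(migrate)
    moved = xy.copy()
    if res_idx.size:
        moved[res_idx] = move_residents(
            xy[res_idx], spatial.home_range_radius, arena, rng
        )
    if mig_idx.size:
        moved[mig_idx] = move_migrants(xy[mig_idx], spatial, arena, tree, rng)
    new.x = moved[:, 0]
    new.y = moved[:, 1]
    return new
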