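"""Randomly mating population life cycle.

Discrete non-overlapping generations: every fertile female is paired with a
uniformly random fertile male (polygynous — males may sire several
litters), litter sizes are Poisson, offspring genotypes are sampled by the
germline machinery in :mod:`hdclvr.genetics`, non-viable conceptions are
removed, and density regulation recruits each surviving offspring with
probability ``min(1, exp(r_max (1 - N/K)) * 2 / litter_size)`` so that the
census equilibrates at the carrying capacity ``K``.

The :class:`Population` container is a structure-of-arrays over
individuals; all per-generation operations are vectorised numpy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genetics import (
    DRIVE,
    Architecture,
    ClvrTargetMode,
    DriveParams,
    ViabilityMode,
    transmit_clvr_batch,
    transmit_homing_batch,
)

__all__ = [
    "LifeHistoryParams",
    "ReleaseSchedule",
    "Population",
    "conceive",
    "step_generation",
    "apply_release",
    "apply_supplementation",
]


@dataclass(frozen=True)
class LifeHistoryParams:
    """Life-history preset; defaults describe the UK grey squirrel.

    ``r_max`` is the maximum per-generation population growth rate on the
    natural-log scale; ``generations_per_year`` follows from the 26-week
    generation time.
    """

    K: int = 3000
    r_max: float = 1.16
    litter_size: float = 2.87
    generations_per_year: int = 2

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("K must be > 0")
        if self.litter_size <= 0:
            raise ValueError("litter_size must be > 0")
        if self.generations_per_year <= 0:
            raise ValueError("generations_per_year must be > 0")

    def recruitment_probability(self, census: int) -> float:
        """Density-dependent survival of a weaned offspring to adulthood."""
        return min(
            1.0,
            math.exp(self.r_max * (1.0 - census / self.K)) * 2.0 / self.litter_size,
        )


@dataclass(frozen=True)
class ReleaseSchedule:
    """Initial release and ongoing supplementation of drive animals.

    Supplementation adds ``floor(supplement_percent/100 * census)`` fresh
    full-daisyfield drive heterozygotes every ``supplement_interval_years``
    (rounded down — so no animals are added once the census falls below
    ``100/supplement_percent`` individuals, avoiding perpetual maintenance
    of a remnant population).
    """

    initial_release: int = 100
    supplement_percent: float = 0.0
    supplement_interval_years: float = 1.0
    placement_strategy: str = "middle"

    def __post_init__(self) -> None:
        if self.initial_release < 0:
            raise ValueError("initial_release must be >= 0")
        if self.supplement_percent < 0:
            raise ValueError("supplement_percent must be >= 0")
        if self.supplement_interval_years <= 0:
            raise ValueError("supplement_interval_years must be > 0")

    def interval_generations(self, generations_per_year: int) -> int:
        g = round(self.supplement_interval_years * generations_per_year)
        if g < 1:
            raise ValueError(
                "supplement_interval_years must coincide with at least one generation"
            )
        return g

    def supplement_count(self, census: int) -> int:
        return int(self.supplement_percent / 100.0 * census)


@dataclass
class Population:
    """Structure-of-arrays container for the living individuals.

    Allele-pair fields have shape (N, 2).  ``x``/``y`` are only meaningful
    in spatial mode but always allocated, so the genetics engine never
    branches on the mode.
    """

    male: np.ndarray
    h_kind: np.ndarray
    h_intact: np.ndarray
    h_func: np.ndarray
    c_intact: np.ndarray
    c_func: np.ndarray
    daisies: np.ndarray
    driving_y: np.ndarray
    sterile: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __len__(self) -> int:
        return self.male.shape[0]

    @property
    def census(self) -> int:
        return len(self)

    @classmethod
    def empty(cls) -> "Population":
        z = np.zeros(0)
        zb = np.zeros(0, dtype=bool)
        z2 = np.zeros((0, 2), dtype=np.int16)
        zb2 = np.zeros((0, 2), dtype=bool)
        return cls(
            male=zb.copy(),
            h_kind=z2.copy(),
            h_intact=z2.copy(),
            h_func=zb2.copy(),
            c_intact=z2.copy(),
            c_func=zb2.copy(),
            daisies=np.zeros(0, dtype=np.int32),
            driving_y=zb.copy(),
            sterile=zb.copy(),
            x=z.copy(),
            y=z.copy(),
        )

    @classmethod
    def wildtype(
        cls,
        n: int,
        params: DriveParams,
        rng: np.random.Generator,
        arena_side: float | None = None,
    ) -> "Population":
        """A wild population: intact loci, no daisies, random 50/50 sex.

        In spatial mode each individual starts at a uniform random location
        in the square arena.
        """
        pop = cls.empty() if n == 0 else cls(
            male=rng.random(n) < 0.5,
            h_kind=np.zeros((n, 2), dtype=np.int16),
            h_intact=np.full((n, 2), params.n_grnas_homing, dtype=np.int16),
            h_func=np.ones((n, 2), dtype=bool),
            c_intact=np.full((n, 2), params.n_grnas_clvr, dtype=np.int16),
            c_func=np.ones((n, 2), dtype=bool),
            daisies=np.zeros(n, dtype=np.int32),
            driving_y=np.zeros(n, dtype=bool),
            sterile=np.zeros(n, dtype=bool),
            x=np.zeros(n),
            y=np.zeros(n),
        )
        if arena_side is not None and n:
            pop.x = rng.uniform(0.0, arena_side, n)
            pop.y = rng.uniform(0.0, arena_side, n)
        return pop

    @classmethod
    def drive_founders(
        cls,
        n: int,
        params: DriveParams,
        rng: np.random.Generator,
        locations: np.ndarray | None = None,
    ) -> "Population":
        """Engineered release animals.

        Drive heterozygotes with one pre-inactivated cleave-and-rescue
        target allele, a full daisyfield, and an even sex split (all-male
        driving-Y carriers for Y-linked architectures).
        """
        if n == 0:
            return cls.empty()
        arch = params.architecture
        if arch.has_driving_y:
            male = np.ones(n, dtype=bool)
            driving_y = np.ones(n, dtype=bool)
            h_kind = np.zeros((n, 2), dtype=np.int16)
            h_intact = np.full((n, 2), params.n_grnas_homing, dtype=np.int16)
            h_func = np.ones((n, 2), dtype=bool)
        else:
            male = np.arange(n) % 2 == 1  # exact 50/50 split
            driving_y = np.zeros(n, dtype=bool)
            h_kind = np.zeros((n, 2), dtype=np.int16)
            h_kind[:, 0] = DRIVE
            h_intact = np.zeros((n, 2), dtype=np.int16)
            h_intact[:, 1] = params.n_grnas_homing
            h_func = np.zeros((n, 2), dtype=bool)
            h_func[:, 1] = True
        c_intact = np.zeros((n, 2), dtype=np.int16)
        c_func = np.zeros((n, 2), dtype=bool)
        c_intact[:, 1] = params.n_grnas_clvr
        c_func[:, 1] = True
        if not arch.has_clvr:
            c_intact[:, 0] = params.n_grnas_clvr
            c_func[:, 0] = True
        daisies = np.full(
            n, params.daisyfield_size if arch.has_daisyfield else 0, dtype=np.int32
        )
        pop = cls(
            male=male,
            h_kind=h_kind,
            h_intact=h_intact,
            h_func=h_func,
            c_intact=c_intact,
            c_func=c_func,
            daisies=daisies,
            driving_y=driving_y,
            sterile=np.zeros(n, dtype=bool),
            x=np.zeros(n),
            y=np.zeros(n),
        )
        if locations is not None:
            pop.x = np.asarray(locations[:, 0], dtype=float).copy()
            pop.y = np.asarray(locations[:, 1], dtype=float).copy()
        return pop

    def subset(self, index: np.ndarray) -> "Population":
        return Population(
            male=self.male[index],
            h_kind=self.h_kind[index],
            h_intact=self.h_intact[index],
            h_func=self.h_func[index],
            c_intact=self.c_intact[index],
            c_func=self.c_func[index],
            daisies=self.daisies[index],
            driving_y=self.driving_y[index],
            sterile=self.sterile[index],
            x=self.x[index],
            y=self.y[index],
        )

    @staticmethod
    def concat(a: "Population", b: "Population") -> "Population":
        return Population(
            male=np.concatenate([a.male, b.male]),
            h_kind=np.concatenate([a.h_kind, b.h_kind]),
            h_intact=np.concatenate([a.h_intact, b.h_intact]),
            h_func=np.concatenate([a.h_func, b.h_func]),
            c_intact=np.concatenate([a.c_intact, b.c_intact]),
            c_func=np.concatenate([a.c_func, b.c_func]),
            daisies=np.concatenate([a.daisies, b.daisies]),
            driving_y=np.concatenate([a.driving_y, b.driving_y]),
            sterile=np.concatenate([a.sterile, b.sterile]),
            x=np.concatenate([a.x, b.x]),
            y=np.concatenate([a.y, b.y]),
        )

    # -- derived masks -----------------------------------------------------

    def fertile_female_mask(self) -> np.ndarray:
        """Haplosufficient fertility: >=1 functional homing-locus allele."""
        return ~self.male & ~self.sterile & self.h_func.any(axis=1)

    def fertile_male_mask(self) -> np.ndarray:
        return self.male & ~self.sterile

    def drive_carrier_mask(self) -> np.ndarray:
        return (self.h_kind == DRIVE).any(axis=1) | self.driving_y

    def class_counts(self, params: DriveParams) -> dict:
        """Census split by genotype class, precedence drive > resistant > wild."""
        drive = self.drive_carrier_mask()
        changed = (self.h_kind != DRIVE) & (
            (self.h_intact < params.n_grnas_homing) | ~self.h_func
        )
        resistant = ~drive & changed.any(axis=1)
        res_functional = ~drive & (changed & self.h_func).any(axis=1)
        res_nonfunctional = resistant & ~res_functional
        wild = ~drive & ~resistant
        return {
            "census": self.census,
            "n_drive": int(drive.sum()),
            "n_res_functional": int(res_functional.sum()),
            "n_res_nonfunctional": int(res_nonfunctional.sum()),
            "n_wildtype": int(wild.sum()),
            "mean_daisies": float(self.daisies.mean()) if len(self) else 0.0,
        }


def _germline_activity(pop: Population, idx: np.ndarray, params: DriveParams) -> np.ndarray:
    arch = params.architecture
    if arch is Architecture.WILDTYPE:
        return np.zeros(idx.size, dtype=bool)
    if arch.has_driving_y:
        carrier = pop.driving_y[idx]
    else:
        carrier = (pop.h_kind[idx] == DRIVE).any(axis=1)
    if arch.has_daisyfield:
        carrier = carrier & (pop.daisies[idx] >= 1)
    return carrier


def conceive(
    pop: Population,
    mother_idx: np.ndarray,
    father_idx: np.ndarray,
    params: DriveParams,
    rng: np.random.Generator,
) -> Population:
    """Sample offspring genotypes for the given matings and filter viability.

    One entry per conceptus.  Offspring are placed at their mother's
    location.  In ``both_sex_fertility`` mode, individuals failing the
    two-copy rule survive but are permanently sterile instead of removed.
    """
    M = mother_idx.size
    if M == 0:
        return Population.empty()
    arch = params.architecture

    act_m = _germline_activity(pop, mother_idx, params)
    act_f = _germline_activity(pop, father_idx, params)

    mh = transmit_homing_batch(
        pop.h_kind[mother_idx], pop.h_intact[mother_idx], pop.h_func[mother_idx],
        act_m, params, rng,
    )
    fh = transmit_homing_batch(
        pop.h_kind[father_idx], pop.h_intact[father_idx], pop.h_func[father_idx],
        act_f, params, rng,
    )
    mc = transmit_clvr_batch(
        pop.c_intact[mother_idx], pop.c_func[mother_idx], act_m, params, rng
    )
    fc = transmit_clvr_batch(
        pop.c_intact[father_idx], pop.c_func[father_idx], act_f, params, rng
    )

    h_kind = np.stack([mh[0], fh[0]], axis=1)
    h_intact = np.stack([mh[1], fh[1]], axis=1)
    h_func = np.stack([mh[2], fh[2]], axis=1)
    c_intact = np.stack([mc[0], fc[0]], axis=1)
    c_func = np.stack([mc[1], fc[1]], axis=1)

    daisies = (
        rng.binomial(pop.daisies[mother_idx], 0.5)
        + rng.binomial(pop.daisies[father_idx], 0.5)
    ).astype(np.int32)

    skewed = params.architecture.has_driving_y & pop.driving_y[father_idx]
    p_male = np.where(skewed, params.driving_y_skew, 0.5)
    male = rng.random(M) < p_male
    driving_y = male & pop.driving_y[father_idx] & arch.has_driving_y

    if arch.has_clvr:
        copies = c_func.sum(axis=1) + (h_kind == DRIVE).sum(axis=1)
        if arch is Architecture.DRIVING_Y_CLVR:
            copies = copies + driving_y
        if params.viability_mode is ViabilityMode.AT_LEAST_TWO_COPIES:
            ok = copies >= 2
        else:
            ok = copies == 2
        if params.clvr_target_mode is ClvrTargetMode.BOTH_SEX_FERTILITY:
            viable = np.ones(M, dtype=bool)
            sterile = ~ok
        else:
            viable = ok
            sterile = np.zeros(M, dtype=bool)
    else:
        viable = np.ones(M, dtype=bool)
        sterile = np.zeros(M, dtype=bool)

    child = Population(
        male=male,
        h_kind=h_kind.astype(np.int16),
        h_intact=h_intact.astype(np.int16),
        h_func=h_func,
        c_intact=c_intact.astype(np.int16),
        c_func=c_func,
        daisies=daisies,
        driving_y=driving_y,
        sterile=sterile,
        x=pop.x[mother_idx].copy(),
        y=pop.y[mother_idx].copy(),
    )
    return child.subset(np.flatnonzero(viable))


def step_generation(
    pop: Population,
    drive: DriveParams,
    life: LifeHistoryParams,
    rng: np.random.Generator,
) -> Population:
    """Advance one non-overlapping generation under random mating.

    Pairing, Poisson litters, viability filtering and density-regulated
    recruitment; parents are replaced by the recruits.  Returns an empty
    population if no fertile pair exists (extinction).
    """
    N = pop.census
    if N == 0:
        return pop
    mothers = np.flatnonzero(pop.fertile_female_mask())
    fertile_males = np.flatnonzero(pop.fertile_male_mask())
    if mothers.size == 0 or fertile_males.size == 0:
        return Population.empty()
    fathers = rng.choice(fertile_males, size=mothers.size, replace=True)
    litters = rng.poisson(life.litter_size, mothers.size)
    mother_rep = np.repeat(mothers, litters)
    father_rep = np.repeat(fathers, litters)
    offspring = conceive(pop, mother_rep, father_rep, drive, rng)
    p = life.recruitment_probability(N)
    keep = rng.random(len(offspring)) < p
    return offspring.subset(np.flatnonzero(keep))


def apply_release(
    pop: Population,
    n: int,
    params: DriveParams,
    rng: np.random.Generator,
    locations: np.ndarray | None = None,
) -> Population:
    """Add ``n`` engineered founders to the population."""
    if n < 0:
        raise ValueError("release size must be >= 0")
    if n == 0:
        return pop
    founders = Population.drive_founders(n, params, rng, locations=locations)
    return Population.concat(pop, founders)


def apply_supplementation(
    pop: Population,
    schedule: ReleaseSchedule,
    params: DriveParams,
    rng: np.random.Generator,
    locations: np.ndarray | None = None,
) -> tuple[Population, int]:
    """Add ``floor(percent/100 * census)`` fresh full-daisyfield animals.

    Returns the augmented population and the number supplemented (zero when
    the floor is zero, including for an extinct population).
    """
    n = schedule.supplement_count(pop.census)
    if n == 0:
        return pop, 0
    if locations is not None:
        locations = locations[:n]
    return apply_release(pop, n, params, rng, locations=locations), n
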