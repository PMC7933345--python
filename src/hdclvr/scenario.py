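"""Scenario configuration and replicate orchestration.

A :class:`ScenarioConfig` bundles drive, life-history, spatial and release
parameters with run settings, round-trips losslessly through YAML, and is
executed by :func:`run_scenario`, which runs seeded independent replicates
and returns a tidy per-generation trajectory table. :func:`run_sweep` runs
a cartesian grid of overrides and summarises each cell.

Seeding: replicate ``k`` of a scenario with master seed ``s`` uses the
stream ``SeedSequence([s, k])``, so each replicate's trajectory depends
only on ``(s, k)`` and not on execution order.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import sys
from dataclasses import dataclass
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .demography import (
    LifeHistoryParams,
    Population,
    ReleaseSchedule,
    apply_release,
    step_generation,
)
from .genetics import Architecture, DriveParams
from .spatial import SpatialParams, place_supplement, spatial_step

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "run_scenario",
    "run_replicate",
    "run_sweep",
    "load_config",
    "save_config",
    "TRAJECTORY_COLUMNS",
]

logger = logging.getLogger("hdclvr")

TRAJECTORY_COLUMNS = [
    "replicate",
    "generation",
    "year",
    "census",
    "n_drive",
    "n_res_functional",
    "n_res_nonfunctional",
    "n_wildtype",
    "mean_daisies",
    "n_supplemented",
]

SNAPSHOT_COLUMNS = ["replicate", "generation", "individual", "x", "y", "genotype_class"]


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete declarative description of one simulation experiment."""

    drive: DriveParams = DriveParams()
    life: LifeHistoryParams = LifeHistoryParams()
    schedule: ReleaseSchedule = ReleaseSchedule()
    spatial: SpatialParams | None = None
    n_generations: int = 100
    n_replicates: int = 20
    master_seed: int = 1

    def __post_init__(self) -> None:
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def is_spatial(self) -> bool:
        return self.spatial is not None

    def to_dict(self) -> dict:
        out: dict[str, Any] = {
            "drive": _section_dict(self.drive),
            "life": _section_dict(self.life),
            "schedule": _section_dict(self.schedule),
            "run": {
                "n_generations": self.n_generations,
                "n_replicates": self.n_replicates,
                "master_seed": self.master_seed,
            },
        }
        if self.spatial is not None:
            out["spatial"] = _section_dict(self.spatial)
        return out

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ScenarioConfig":
        known = {"drive", "life", "schedule", "spatial", "run"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        drive = _build_section(DriveParams, data.get("drive", {}), "drive")
        life = _build_section(LifeHistoryParams, data.get("life", {}), "life")
        schedule = _build_section(ReleaseSchedule, data.get("schedule", {}), "schedule")
        spatial = (
            _build_section(SpatialParams, data["spatial"], "spatial")
            if "spatial" in data and data["spatial"] is not None
            else None
        )
        run = dict(data.get("run", {}))
        unknown_run = set(run) - {"n_generations", "n_replicates", "master_seed"}
        if unknown_run:
            raise ValueError(f"unknown key(s) in section 'run': {sorted(unknown_run)}")
        return cls(drive=drive, life=life, schedule=schedule, spatial=spatial, **run)


def _section_dict(obj) -> dict:
    out = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        out[f.name] = v.value if hasattr(v, "value") else v
    return out


def _build_section(cls, data: Mapping[str, Any], name: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key(s) in section {name!r}: {sorted(unknown)}")
    return cls(**data)


def load_config(path) -> ScenarioConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return ScenarioConfig.from_dict(data)


def save_config(config: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


@dataclass
class ScenarioResult:
    """Per-generation trajectories plus optional spatial snapshots."""

    trajectory: pd.DataFrame
    snapshots: pd.DataFrame | None = None


def _replicate_rng(master_seed: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([master_seed, replicate]))


def _genotype_class(pop: Population, drive: DriveParams) -> np.ndarray:
    drive_mask = pop.drive_carrier_mask()
    changed = (pop.h_kind != 1) & (
        (pop.h_intact < drive.n_grnas_homing) | ~pop.h_func
    )
    resistant = ~drive_mask & changed.any(axis=1)
    out = np.where(drive_mask, "drive", np.where(resistant, "resistant", "wildtype"))
    return out


def run_replicate(
    config: ScenarioConfig,
    replicate: int,
    snapshot_every: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Run one seeded replicate; returns its trajectory (and snapshots)."""
    rng = _replicate_rng(config.master_seed, replicate)
    drive, life, sched = config.drive, config.life, config.schedule
    spatial = config.spatial
    arena = spatial.arena_side(life.K) if spatial is not None else None

    pop = Population.wildtype(life.K, drive, rng, arena_side=arena)
    if sched.initial_release and drive.architecture is not Architecture.WILDTYPE:
        locations = None
        if spatial is not None:
            locations = place_supplement(
                sched.initial_release,
                sched.placement_strategy,
                np.column_stack([pop.x, pop.y]),
                arena,
                spatial.home_range_radius,
                0,
                rng,
            )
        pop = apply_release(pop, sched.initial_release, drive, rng, locations=locations)

    interval = sched.interval_generations(life.generations_per_year)
    rows = []
    snap_rows = []

    def record(generation: int, n_supplemented: int) -> None:
        counts = pop.class_counts(drive)
        rows.append(
            {
                "replicate": replicate,
                "generation": generation,
                "year": generation / life.generations_per_year,
                **counts,
                "n_supplemented": n_supplemented,
            }
        )
        if (
            snapshot_every
            and spatial is not None
            and generation % snapshot_every == 0
            and pop.census
        ):
            cls = _genotype_class(pop, drive)
            snap_rows.extend(
                {
                    "replicate": replicate,
                    "generation": generation,
                    "individual": i,
                    "x": float(pop.x[i]),
                    "y": float(pop.y[i]),
                    "genotype_class": cls[i],
                }
                for i in range(pop.census)
            )

    record(0, 0)
    event = 0
    extinct_logged = False
    for g in range(1, config.n_generations + 1):
        if pop.census:
            if spatial is not None:
                pop = spatial_step(pop, drive, life, spatial, arena, rng)
            else:
                pop = step_generation(pop, drive, life, rng)
        if pop.census == 0 and not extinct_logged:
            logger.info("replicate %d extinct at generation %d", replicate, g)
            extinct_logged = True
        n_sup = 0
        if sched.supplement_percent > 0 and g % interval == 0:
            n_sup = sched.supplement_count(pop.census)
            if n_sup > 0:
                event += 1
                locations = None
                if spatial is not None:
                    locations = place_supplement(
                        n_sup,
                        sched.placement_strategy,
                        np.column_stack([pop.x, pop.y]),
                        arena,
                        spatial.home_range_radius,
                        event,
                        rng,
                    )
                pop = apply_release(pop, n_sup, drive, rng, locations=locations)
        record(g, n_sup)

    traj = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    snaps = pd.DataFrame(snap_rows, columns=SNAPSHOT_COLUMNS) if snapshot_every else None
    return traj, snaps


def run_scenario(
    config: ScenarioConfig,
    snapshot_every: int | None = None,
    progress: bool = False,
) -> ScenarioResult:
    """Run all replicates of a scenario.

    Returns tidy per-generation trajectories with one row per
    (replicate, generation); snapshots (spatial mode, every ``k``-th
    generation) are collected only when requested.
    """
    trajs = []
    snaps = []
    for rep in range(config.n_replicates):
        t, s = run_replicate(config, rep, snapshot_every=snapshot_every)
        trajs.append(t)
        if s is not None:
            snaps.append(s)
        if progress:
            print(f"replicate {rep + 1}/{config.n_replicates} done", file=sys.stderr)
    trajectory = pd.concat(trajs, ignore_index=True)
    snapshots = pd.concat(snaps, ignore_index=True) if snaps else None
    return ScenarioResult(trajectory=trajectory, snapshots=snapshots)


def _apply_override(config: ScenarioConfig, key: str, value) -> ScenarioConfig:
    section, _, fieldname = key.partition(".")
    if not fieldname:
        if section not in ("n_generations", "n_replicates", "master_seed"):
            raise ValueError(f"unknown override key {key!r}")
        return dataclasses.replace(config, **{section: value})
    target = getattr(config, section, None)
    if section not in ("drive", "life", "schedule", "spatial") or target is None:
        raise ValueError(f"unknown override section {section!r}")
    if fieldname not in {f.name for f in dataclasses.fields(target)}:
        raise ValueError(f"unknown key {fieldname!r} in section {section!r}")
    return dataclasses.replace(config, **{section: dataclasses.replace(target, **{fieldname: value})})


def run_sweep(
    config: ScenarioConfig,
    grid: Mapping[str, Iterable],
    progress: bool = False,
) -> pd.DataFrame:
    """Run a cartesian parameter sweep and summarise each cell.

    ``grid`` maps dotted override keys (e.g. ``schedule.supplement_percent``
    or ``drive.daisyfield_size``) to value lists.  Returns one row per cell
    with extinction probability, median time to extinction (years) and the
    equilibrium census of surviving replicates.
    """
    from .reporting import summarize

    keys = list(grid)
    rows = []
    for values in itertools.product(*(list(grid[k]) for k in keys)):
        cell = config
        for k, v in zip(keys, values):
            cell = _apply_override(cell, k, v)
        result = run_scenario(cell, progress=progress)
        summary = summarize(result.trajectory, cell.life.generations_per_year)
        rows.append({**dict(zip(keys, values)), **summary})
    return pd.DataFrame(rows)
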