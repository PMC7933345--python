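"""Bundled grey-squirrel parameter preset and scenario builders.

The grey squirrel (*Sciurus carolinensis*) is an invasive pest in the UK;
its life-history values (carrying capacity 3000, maximum growth rate 1.16
per generation on the log scale, mean litter 2.87, 26-week generation
time) and spatial parameters (80 m home range, 4 animals per home range,
600 m maximum observed mating range out of 30 observations, 10 km maximum
dispersal) parameterise the default simulations.
"""

from __future__ import annotations

from .demography import LifeHistoryParams, ReleaseSchedule
from .genetics import Architecture, DriveParams
from .scenario import ScenarioConfig
from .spatial import SpatialParams

__all__ = [
    "grey_squirrel_life",
    "grey_squirrel_spatial",
    "grey_squirrel_scenario",
]


def grey_squirrel_life() -> LifeHistoryParams:
    """Grey-squirrel life-history defaults."""
    return LifeHistoryParams(K=3000, r_max=1.16, litter_size=2.87, generations_per_year=2)


def grey_squirrel_spatial() -> SpatialParams:
    """Grey-squirrel spatial defaults."""
    return SpatialParams(
        home_range_radius=80.0,
        max_density=4.0,
        mating_range_max=600.0,
        mating_range_observations=30,
        max_dispersal=10000.0,
        max_migration_steps=50,
    )


def grey_squirrel_scenario(
    architecture: str | Architecture = Architecture.HDCLVR,
    *,
    P_n: float = 0.02,
    n_grnas_homing: int = 1,
    n_grnas_clvr: int = 4,
    daisyfield_size: int = 30,
    initial_release: int = 100,
    supplement_percent: float = 0.0,
    supplement_interval_years: float = 1.0,
    placement_strategy: str = "middle",
    spatial: bool = False,
    K: int = 3000,
    n_generations: int = 100,
    n_replicates: int = 20,
    master_seed: int = 1,
) -> ScenarioConfig:
    """A ready-to-run grey-squirrel scenario for a given drive architecture.

    The headline drive settings (1 homing gRNA, 4 cleave-and-rescue gRNAs,
    NHEJ rate 0.02, single release of 100 animals into K=3000) are the
    defaults; everything is overridable.
    """
    arch = Architecture(architecture)
    drive = DriveParams(
        architecture=arch,
        n_grnas_homing=n_grnas_homing if arch.has_homing else max(n_grnas_homing, 0),
        n_grnas_clvr=n_grnas_clvr,
        P_n=P_n,
        daisyfield_size=daisyfield_size if arch.has_daisyfield else 0,
    )
    life = LifeHistoryParams(K=K, r_max=1.16, litter_size=2.87, generations_per_year=2)
    schedule = ReleaseSchedule(
        initial_release=initial_release,
        supplement_percent=supplement_percent,
        supplement_interval_years=supplement_interval_years,
        placement_strategy=placement_strategy,
    )
    return ScenarioConfig(
        drive=drive,
        life=life,
        schedule=schedule,
        spatial=grey_squirrel_spatial() if spatial else None,
        n_generations=n_generations,
        n_replicates=n_replicates,
        master_seed=master_seed,
    )
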