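"""Small deterministic populations and configurations for tests and demos.

Three kinds:

* ``tiny_population`` — ten intact adult dogs (5 F, 5 M), long lifespans;
* ``null_dynamics`` — a configuration with every hazard, migration flow and
  pregnancy risk zeroed and lifespans beyond the horizon, under which the
  trajectory must be exactly constant;
* ``capacity_edge`` — a population sitting exactly at community capacity
  with one pregnant female due to whelp within a day, exercising the
  per-newborn capacity check.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .params import ParameterSet, load_parameters
from .population import (
    ADULT,
    FEMALE,
    MALE,
    NOT_IN_HEAT,
    PREGNANT,
    Population,
    REPRODUCTIVE,
)

FIXTURE_KINDS = ("tiny_population", "null_dynamics", "capacity_edge")

NULL_DYNAMICS_CONFIG: dict[str, float] = {
    "annual_pregnancy_risk.confined": 0.0,
    "annual_pregnancy_risk.unconfined": 0.0,
    "nonage_mortality_annual.puppy.confined": 0.0,
    "nonage_mortality_annual.puppy.unconfined": 0.0,
    "nonage_mortality_annual.young.confined": 0.0,
    "nonage_mortality_annual.young.unconfined": 0.0,
    "nonage_mortality_annual.adult.confined": 0.0,
    "nonage_mortality_annual.adult.unconfined": 0.0,
    "sterilized_nonage_mortality_annual.confined": 0.0,
    "sterilized_nonage_mortality_annual.unconfined": 0.0,
    "annual_immigration_prob": 0.0,
    "annual_emigration_prob": 0.0,
    # lifespans beyond any horizon so age-related death never fires
    "lifespan_dist.male.min": 100.0,
    "lifespan_dist.male.max": 100.0,
    "lifespan_dist.female.min": 100.0,
    "lifespan_dist.female.max": 100.0,
}


def null_dynamics_params(**overrides) -> ParameterSet:
    config = dict(NULL_DYNAMICS_CONFIG)
    config.update(overrides)
    return load_parameters(config)


def _adults(pop: Population, k_female: int, k_male: int,
            rng: np.random.Generator, params: ParameterSet,
            female_state: int = NOT_IN_HEAT) -> None:
    for k, sex, state in ((k_female, FEMALE, female_state),
                          (k_male, MALE, REPRODUCTIVE)):
        if k == 0:
            continue
        age = 2.0 + rng.random(k) * 3.0
        pop.add_dogs(
            sex=np.full(k, sex, dtype=np.int8),
            confined=rng.random(k) < params.proportion_confined,
            birth=-age,
            maturity=np.full(k, 8.0 / 12.0),
            lifespan=np.full(k, 90.0),
            life_class=np.full(k, ADULT, dtype=np.int8),
            state=np.full(k, state, dtype=np.int8),
            state_end=(np.full(k, params.interestrus_years)
                       if state == NOT_IN_HEAT else None),
        )


def tiny_population(seed: int = 0,
                    params: ParameterSet | None = None) -> Population:
    """Ten intact adults (5 F between heats, 5 M reproductive)."""
    params = params or null_dynamics_params()
    rng = np.random.default_rng(seed)
    pop = Population(capacity_hint=64)
    _adults(pop, 5, 5, rng, params)
    pop.initial_size = pop.size
    return pop


def capacity_edge_population(
    seed: int = 0,
    params: ParameterSet | None = None,
) -> tuple[Population, ParameterSet]:
    """A population exactly at community capacity with one whelping imminent.

    One female is pregnant and due in one day; with the population already at
    capacity, all four of her newborns must be removed on arrival.
    """
    params = params or null_dynamics_params(community_capacity=40)
    rng = np.random.default_rng(seed)
    pop = Population(capacity_hint=2 * params.community_capacity)
    n = params.community_capacity
    # one pregnant dam due tomorrow, the rest split between the sexes
    whelp_due = 1.0 / 365.25
    pop.add_dogs(
        sex=np.array([FEMALE], dtype=np.int8),
        confined=np.array([True]),
        birth=np.array([-3.0]),
        maturity=np.array([8.0 / 12.0]),
        lifespan=np.array([90.0]),
        life_class=np.array([ADULT], dtype=np.int8),
        state=np.array([PREGNANT], dtype=np.int8),
        state_end=np.array([whelp_due]),
        conception=np.array([whelp_due - params.gestation_years]),
    )
    rest = n - 1
    _adults(pop, rest // 2, rest - rest // 2, rng, params)
    pop.initial_size = pop.size
    return pop, params


def generate_fixtures(kind: str, seed: int, outdir: str | Path) -> list[Path]:
    """Write a fixture to CSV/YAML files; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if kind == "tiny_population":
        pop = tiny_population(seed)
        path = outdir / "tiny_population.csv"
        pop.to_dataframe().to_csv(path, index=False)
        written.append(path)
    elif kind == "null_dynamics":
        import yaml
        path = outdir / "null_dynamics.yaml"
        path.write_text(yaml.safe_dump(NULL_DYNAMICS_CONFIG))
        written.append(path)
    elif kind == "capacity_edge":
        pop, params = capacity_edge_population(seed)
        path = outdir / "capacity_edge.csv"
        pop.to_dataframe().to_csv(path, index=False)
        written.append(path)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; "
                         f"expected one of {FIXTURE_KINDS}")
    return written
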