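"""Surgical-sterilization strategies as monthly, quota-constrained events.

Four strategies, each run at three surgical-capacity levels (21 / 42 / 84
surgeries per month; level n multiplies every level-1 cell by 2**(n-1)):

A. mixed age, mixed sex — the government program's observed monthly mix of
   6 adult males, 13 adult females, 1 young male, 1 young female;
B. young dogs only, mixed sex — the 21 surgeries reallocated to young dogs
   at the program's overall 7 male : 14 female ratio;
C. females only, mixed age — 21 female surgeries split 20 adult : 1 young,
   the program's 13:1 adult:young ratio among females scaled up by largest
   remainder;
D. young females only — the whole quota on sexually immature females.

Eligibility at each monthly event: adult females only between heats (never
in heat or pregnant), adult males in the reproductive state, young dogs of
either sex if intact; puppies are never operated on.  Unused quota in a cell
is forfeited, never reallocated or carried over.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ParameterSet
from .population import (
    ADULT,
    FEMALE,
    IMMATURE,
    MALE,
    NEUTERED,
    NOT_IN_HEAT,
    Population,
    REPRODUCTIVE,
    SPAYED,
    YOUNG,
)

STRATEGY_ALIASES = {
    "A": "mixed_age_mixed_sex",
    "B": "young_mixed_sex",
    "C": "female_mixed_age",
    "D": "female_young",
    "none": "none",
}
STRATEGY_NAMES = tuple(STRATEGY_ALIASES.values())

# quota cells in fixed processing order: (sex, age-class)
CELLS = (
    ("male", "adult"),
    ("female", "adult"),
    ("male", "young"),
    ("female", "young"),
)

_LEVEL1_QUOTAS = {
    "mixed_age_mixed_sex": {
        ("male", "adult"): 6, ("female", "adult"): 13,
        ("male", "young"): 1, ("female", "young"): 1,
    },
    "young_mixed_sex": {
        ("male", "adult"): 0, ("female", "adult"): 0,
        ("male", "young"): 7, ("female", "young"): 14,
    },
    "female_mixed_age": {
        ("male", "adult"): 0, ("female", "adult"): 20,
        ("male", "young"): 0, ("female", "young"): 1,
    },
    "female_young": {
        ("male", "adult"): 0, ("female", "adult"): 0,
        ("male", "young"): 0, ("female", "young"): 21,
    },
}


@dataclass(frozen=True)
class InterventionSpec:
    """Monthly surgical quota broken down by sex and age class."""

    strategy: str
    capacity_level: int
    monthly_quota: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def total_monthly(self) -> int:
        return sum(self.monthly_quota.values())

    def validate(self) -> None:
        if self.strategy not in STRATEGY_NAMES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if any(q < 0 for q in self.monthly_quota.values()):
            raise ValueError("quota values must be nonnegative")


def build_intervention(strategy: str, capacity_level: int) -> InterventionSpec:
    """Quota table for a named strategy at a surgical-capacity level.

    ``strategy`` accepts the letters A-D or the descriptive names; level n
    scales every level-1 cell by ``2**(n-1)`` (21, 42, 84 total surgeries).
    """
    name = STRATEGY_ALIASES.get(strategy, strategy)
    if name == "none":
        return InterventionSpec("none", capacity_level, {c: 0 for c in CELLS})
    if name not in _LEVEL1_QUOTAS:
        raise ValueError(f"unknown strategy {strategy!r}")
    if capacity_level not in (1, 2, 3):
        raise ValueError(f"capacity_level must be 1, 2 or 3, got {capacity_level}")
    mult = 2 ** (capacity_level - 1)
    quota = {cell: q * mult for cell, q in _LEVEL1_QUOTAS[name].items()}
    return InterventionSpec(name, capacity_level, quota)


def _eligible_mask(pop: Population, sex: str, age_class: str) -> np.ndarray:
    n = pop.n_rows
    sex_code = FEMALE if sex == "female" else MALE
    m = pop.alive[:n] & (pop.sex[:n] == sex_code)
    if age_class == "adult":
        if sex == "female":
            m &= pop.state[:n] == NOT_IN_HEAT
        else:
            m &= pop.state[:n] == REPRODUCTIVE
    else:  # young: intact, not yet mature
        m &= (pop.life_class[:n] == YOUNG) & (pop.state[:n] == IMMATURE)
    return m


def sterilization_event(
    pop: Population,
    spec: InterventionSpec,
    t: float,
    rng: np.random.Generator,
    params: ParameterSet,
) -> int:
    """Perform one monthly round of surgeries; returns the number done.

    For each quota cell, up to the quota of eligible dogs are drawn uniformly
    without replacement and moved to the absorbing spayed/neutered state:
    their non-age mortality switches to the sterilized rate and their
    scheduled lifespan is rescaled by ``sterilized_lifespan_scale``
    (quantile-preserving: the whole lifespan distribution scales, so the
    rescale is multiplication).  Shortfalls go unused.
    """
    done = 0
    for sex, age_class in CELLS:
        quota = spec.monthly_quota.get((sex, age_class), 0)
        if quota <= 0:
            continue
        mask = _eligible_mask(pop, sex, age_class)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        k = min(quota, idx.size)
        chosen = idx if k == idx.size else rng.choice(idx, size=k, replace=False)
        pop.state[chosen] = SPAYED if sex == "female" else NEUTERED
        pop.state_end[chosen] = np.inf
        pop.conception[chosen] = np.nan
        pop.lifespan[chosen] = pop.lifespan[chosen] * params.sterilized_lifespan_scale
        pop.tallies[f"sterilized_{sex}_{age_class}"] += k
        done += k
    return done
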