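"""Continuous-time simulation of the dog population over the 20-year horizon.

The engine advances a vectorized tick loop over the union of the weekly
hazard grid and every exact event time (quarterly migration, monthly surgery,
yearly recording, the horizon).  Scheduled per-dog events — weaning, sexual
maturity, heat end, whelping, age-related death — carry exact due times and
fire when the clock first crosses them, so sub-week durations (18-day heat,
65-day gestation) are honored exactly; stochastic hazards (non-age mortality,
per-heat conception, migration) are Bernoulli draws whose per-interval
probabilities come from constant-hazard compounding of the annual risks,
which makes the loop independent of how the grid partitions time.

Within a tick, event kinds execute in a fixed order — deaths, emigration,
aging, reproduction, immigration, surgery — and within a kind dogs are
processed in id order, so a replay with the same seed is bit-identical.
Events scheduled for dogs that died or emigrated are discarded lazily: the
alive mask simply excludes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interventions import InterventionSpec, sterilization_event
from .params import ParameterSet, annual_prob_to_interval_prob
from .population import (
    ADULT,
    FEMALE,
    IMMATURE,
    IN_HEAT,
    LIFE_CLASS_NAMES,
    MALE,
    NOT_IN_HEAT,
    PREGNANT,
    PUPPY,
    Population,
    REPRODUCTIVE,
    SPAYED,
    NEUTERED,
    STATE_NAMES,
    TALLY_KEYS,
    YOUNG,
    _redraw_above,
    draw_lifespan,
)

_N_STATES = 7
_TIME_DECIMALS = 9


@dataclass
class Trajectory:
    """Recorded snapshots of one simulation run.

    ``counts[t, sex, life_class, state]`` strata sum to ``total[t]``;
    ``tallies[t]`` are the cumulative event counters at each snapshot.
    """

    times: np.ndarray
    total: np.ndarray
    counts: np.ndarray          # (T, 2, 3, 7)
    tallies: np.ndarray         # (T, len(TALLY_KEYS))
    initial_size: int

    @property
    def final_size(self) -> int:
        return int(self.total[-1])

    def tally(self, snapshot: int, key: str) -> int:
        return int(self.tallies[snapshot, TALLY_KEYS.index(key)])

    def conservation_residual(self) -> np.ndarray:
        """size - (initial + births - removals + immigrants - deaths - emigrants)
        at every snapshot; all-zero when the bookkeeping is consistent."""
        g = {k: self.tallies[:, TALLY_KEYS.index(k)] for k in TALLY_KEYS}
        expected = (self.initial_size + g["births"] - g["newborn_removals"]
                    + g["immigrants"] - g["deaths_age"] - g["deaths_nonage"]
                    - g["emigrants"])
        return self.total - expected

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-snapshot-per-stratum table."""
        rows = []
        for t_i, t in enumerate(self.times):
            for sex_code, sex in ((FEMALE, "female"), (MALE, "male")):
                for lc, lc_name in LIFE_CLASS_NAMES.items():
                    for st, st_name in STATE_NAMES.items():
                        c = int(self.counts[t_i, sex_code, lc, st])
                        if c:
                            rows.append((float(t), sex, lc_name, st_name, c))
        df = pd.DataFrame(rows, columns=["time", "sex", "life_class", "state", "count"])
        return df


def _tick_times(params: ParameterSet, with_surgery: bool,
                record_every: float) -> tuple[np.ndarray, set, set, set]:
    h = params.horizon
    eps = 10.0 ** (-_TIME_DECIMALS)
    step = params.hazard_step * 7.0 / 365.25
    grids = [np.arange(step, h + eps, step)]
    migration = np.round(
        np.arange(params.migration_period, h + eps, params.migration_period),
        _TIME_DECIMALS)
    grids.append(migration)
    surgery = np.array([])
    if with_surgery:
        surgery = np.round(
            np.arange(params.surgery_period, h + eps, params.surgery_period),
            _TIME_DECIMALS)
        grids.append(surgery)
    record = np.round(np.arange(record_every, h + eps, record_every),
                      _TIME_DECIMALS)
    grids.append(record)
    grids.append(np.array([h]))
    ticks = np.unique(np.round(np.concatenate(grids), _TIME_DECIMALS))
    ticks = ticks[(ticks > 0) & (ticks <= h + eps)]
    record_set = set(record.tolist()) | {np.round(h, _TIME_DECIMALS)}
    return ticks, set(migration.tolist()), set(surgery.tolist()), record_set


# ---------------------------------------------------------------------------
# vectorized life-cycle operations (each processes every due dog at a tick)


def mortality_process(pop: Population, params: ParameterSet, t1: float,
                      dt: float, rng: np.random.Generator,
                      p_cache: dict) -> int:
    """Age-related deaths (scheduled lifespan crossed) then non-age-related
    Bernoulli deaths at the per-interval hazard for each dog's class."""
    n = pop.n_rows
    alive = pop.alive[:n]
    # (a) deterministic death at the scheduled lifespan
    due = alive & (pop.birth[:n] + pop.lifespan[:n] <= t1)
    k_age = int(np.count_nonzero(due))
    if k_age:
        pop.alive[:n][due] = False
        pop.tallies["deaths_age"] += k_age
        alive = pop.alive[:n]
    # (b) non-age-related hazard
    key = round(dt, _TIME_DECIMALS)
    if key not in p_cache:
        p8 = np.empty(8)
        for lc_code, lc in enumerate(("puppy", "young", "adult")):
            for conf_code, conf in enumerate(("unconfined", "confined")):
                p8[lc_code * 2 + conf_code] = annual_prob_to_interval_prob(
                    params.nonage_mortality_annual[lc][conf], dt)
        for conf_code, conf in enumerate(("unconfined", "confined")):
            p8[6 + conf_code] = annual_prob_to_interval_prob(
                params.sterilized_nonage_mortality_annual[conf], dt)
        p_cache[key] = p8
    p8 = p_cache[key]
    idx = np.flatnonzero(alive)
    if idx.size == 0:
        return k_age
    code = pop.life_class[idx] * 2 + pop.confined[idx]
    sterilized = (pop.state[idx] == SPAYED) | (pop.state[idx] == NEUTERED)
    code = np.where(sterilized, 6 + pop.confined[idx], code)
    dead = rng.random(idx.size) < p8[code]
    k_nonage = int(np.count_nonzero(dead))
    if k_nonage:
        pop.alive[idx[dead]] = False
        pop.tallies["deaths_nonage"] += k_nonage
    return k_age + k_nonage


def age_transition(pop: Population, params: ParameterSet, t1: float) -> None:
    """Puppy→young at weaning age, young→adult at maturity; on adulthood
    intact females enter their first heat, intact males become reproductive."""
    n = pop.n_rows
    alive = pop.alive[:n]
    birth = pop.birth[:n]
    lc = pop.life_class[:n]
    weaned = alive & (lc == PUPPY) & (birth + params.weaning_years <= t1)
    if weaned.any():
        pop.life_class[:n][weaned] = YOUNG
    mature = alive & (pop.life_class[:n] == YOUNG) & \
        (birth + pop.maturity[:n] <= t1)
    if mature.any():
        pop.life_class[:n][mature] = ADULT
        intact = mature & (pop.state[:n] == IMMATURE)
        fem = intact & (pop.sex[:n] == FEMALE)
        if fem.any():
            pop.state[:n][fem] = IN_HEAT
            # first heat begins the instant maturity is reached
            pop.state_end[:n][fem] = birth[fem] + pop.maturity[:n][fem] \
                + params.heat_years
        male = intact & (pop.sex[:n] == MALE)
        if male.any():
            pop.state[:n][male] = REPRODUCTIVE


def whelp(pop: Population, params: ParameterSet, t1: float,
          rng: np.random.Generator) -> int:
    """Deliver every litter due by ``t1``; returns number of puppies added.

    Each dam bears ``litter_sex_split`` puppies (confinement inherited, fresh
    maturity and lifespan draws).  Newborns are admitted one at a time in dam
    id order while the population is below community capacity; the rest are
    removed immediately and tallied.  Dams restart the interestrus clock from
    the moment of whelping.
    """
    n = pop.n_rows
    due = pop.alive[:n] & (pop.state[:n] == PREGNANT) & (pop.state_end[:n] <= t1)
    dams = np.flatnonzero(due)
    if dams.size == 0:
        return 0
    # several litters can fall due in one tick: deliver in whelp-time order
    # (ties by id) so the capacity check matches a strict event ordering
    dams = dams[np.lexsort((dams, pop.state_end[dams]))]
    lm, lf = params.litter_sex_split
    litter = params.litter_size
    total = dams.size * litter
    space = max(0, params.community_capacity - pop.size)
    n_add = min(total, space)
    pop.tallies["births"] += total
    pop.tallies["newborn_removals"] += total - n_add
    whelp_times = pop.state_end[dams].copy()
    if n_add:
        # newborns in dam-major order, males then females within a litter
        sex_pattern = np.array([MALE] * lm + [FEMALE] * lf, dtype=np.int8)
        sexes = np.tile(sex_pattern, dams.size)[:n_add]
        birth = np.repeat(whelp_times, litter)[:n_add]
        conf = np.repeat(pop.confined[dams], litter)[:n_add]
        maturity = np.full(n_add, params.adult_age_male_years)
        fem = sexes == FEMALE
        if fem.any():
            lo, hi = params.female_maturity_years
            maturity[fem] = lo + rng.random(int(fem.sum())) * (hi - lo)
        lifespan = np.empty(n_add)
        if fem.any():
            lifespan[fem] = draw_lifespan("female", False, params, rng,
                                          size=int(fem.sum()))
        if (~fem).any():
            lifespan[~fem] = draw_lifespan("male", False, params, rng,
                                           size=int((~fem).sum()))
        pop.add_dogs(
            sex=sexes, confined=conf, birth=birth, maturity=maturity,
            lifespan=lifespan,
            life_class=np.full(n_add, PUPPY, dtype=np.int8),
            state=np.full(n_add, IMMATURE, dtype=np.int8),
        )
    pop.state[dams] = NOT_IN_HEAT
    pop.state_end[dams] = whelp_times + params.interestrus_years
    pop.conception[dams] = np.nan
    return n_add


def female_cycle_step(pop: Population, params: ParameterSet, t1: float,
                      rng: np.random.Generator,
                      p_heat: tuple[float, float]) -> None:
    """Advance every female whose heat or interestrus interval ended by ``t1``.

    A heat that ends resolves conception once, at the per-heat probability for
    the dog's confinement — but only if at least one reproductive (intact,
    mature) male exists anywhere in the population.  Conceiving females enter
    gestation; the rest wait one interestrus interval for the next heat.
    """
    n = pop.n_rows
    alive = pop.alive[:n]
    ends = pop.state_end[:n]
    heat_done = alive & (pop.state[:n] == IN_HEAT) & (ends <= t1)
    idx = np.flatnonzero(heat_done)
    if idx.size:
        if np.any(alive & (pop.state[:n] == REPRODUCTIVE)):
            p = np.where(pop.confined[idx], p_heat[1], p_heat[0])
            conceive = rng.random(idx.size) < p
        else:
            conceive = np.zeros(idx.size, dtype=bool)
        c = idx[conceive]
        pop.state[c] = PREGNANT
        pop.conception[c] = pop.state_end[c]
        pop.state_end[c] = pop.conception[c] + params.gestation_years
        nc = idx[~conceive]
        pop.state[nc] = NOT_IN_HEAT
        pop.state_end[nc] = pop.state_end[nc] + params.interestrus_years
    rest_done = alive & (pop.state[:n] == NOT_IN_HEAT) & (ends <= t1)
    idx = np.flatnonzero(rest_done)
    if idx.size:
        pop.state[idx] = IN_HEAT
        pop.state_end[idx] = pop.state_end[idx] + params.heat_years


def migration_event(pop: Population, params: ParameterSet, t1: float,
                    rng: np.random.Generator,
                    phase: str) -> int:
    """Quarterly migration: ``phase='emigrate'`` removes each dog with the
    per-quarter emigration probability; ``phase='immigrate'`` adds a binomial
    number of intact puppies (fair-coin sex, Bernoulli confinement, age
    uniform below weaning) drawn against the current population size."""
    if phase == "emigrate":
        p = annual_prob_to_interval_prob(params.annual_emigration_prob,
                                         params.migration_period)
        if p == 0.0:
            return 0
        n = pop.n_rows
        idx = np.flatnonzero(pop.alive[:n])
        gone = idx[rng.random(idx.size) < p]
        pop.alive[gone] = False
        pop.tallies["emigrants"] += gone.size
        return int(gone.size)
    # immigration
    p = annual_prob_to_interval_prob(params.annual_immigration_prob,
                                     params.migration_period)
    k = int(rng.binomial(pop.size, p)) if p > 0 else 0
    if k == 0:
        return 0
    sexes = np.where(rng.random(k) < 0.5, FEMALE, MALE).astype(np.int8)
    conf = rng.random(k) < params.proportion_confined
    age = rng.random(k) * params.weaning_years
    maturity = np.full(k, params.adult_age_male_years)
    fem = sexes == FEMALE
    if fem.any():
        lo, hi = params.female_maturity_years
        maturity[fem] = lo + rng.random(int(fem.sum())) * (hi - lo)
    lifespan = np.empty(k)
    if fem.any():
        ls = np.asarray(draw_lifespan("female", False, params, rng,
                                      size=int(fem.sum())))
        lifespan[fem] = _redraw_above(ls, age[fem], "female", False, params, rng)
    if (~fem).any():
        ls = np.asarray(draw_lifespan("male", False, params, rng,
                                      size=int((~fem).sum())))
        lifespan[~fem] = _redraw_above(ls, age[~fem], "male", False, params, rng)
    pop.add_dogs(
        sex=sexes, confined=conf, birth=t1 - age, maturity=maturity,
        lifespan=lifespan,
        life_class=np.full(k, PUPPY, dtype=np.int8),
        state=np.full(k, IMMATURE, dtype=np.int8),
    )
    pop.tallies["immigrants"] += k
    return k


def _snapshot(pop: Population, t: float, times, totals, counts, tallies) -> None:
    n = pop.n_rows
    idx = np.flatnonzero(pop.alive[:n])
    code = (pop.sex[idx].astype(np.int32) * 3 + pop.life_class[idx]) * _N_STATES \
        + pop.state[idx]
    c = np.bincount(code, minlength=2 * 3 * _N_STATES).reshape(2, 3, _N_STATES)
    times.append(t)
    totals.append(idx.size)
    counts.append(c)
    tallies.append([pop.tallies[k] for k in TALLY_KEYS])


def run_simulation(
    pop: Population,
    params: ParameterSet,
    intervention: InterventionSpec | None = None,
    rng: np.random.Generator | int | None = None,
    record_every: float = 1.0,
) -> Trajectory:
    """Advance ``pop`` from t=0 to the horizon; returns yearly snapshots.

    The population object is mutated to its final state.  An extinct
    population simply stays at zero.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    params.validate()
    if intervention is not None and intervention.total_monthly == 0:
        intervention = None
    ticks, migration_set, surgery_set, record_set = _tick_times(
        params, intervention is not None, record_every)
    # (unconfined, confined) per-heat conception probabilities
    p_heat = (params.per_heat_conception_prob(False),
              params.per_heat_conception_prob(True))
    p_cache: dict = {}

    times: list = []
    totals: list = []
    counts: list = []
    tallies: list = []
    _snapshot(pop, 0.0, times, totals, counts, tallies)

    t0 = 0.0
    for t1 in ticks:
        t1f = float(t1)
        dt = t1f - t0
        migrate = round(t1f, _TIME_DECIMALS) in migration_set
        # events due strictly within (t0, t1]: hazards, scheduled deaths,
        # aging, whelping, cycle transitions
        mortality_process(pop, params, t1f, dt, rng, p_cache)
        age_transition(pop, params, t1f)
        whelp(pop, params, t1f, rng)
        female_cycle_step(pop, params, t1f, rng, p_heat)
        pop.clock = t1f
        # the census at time t reports the population before point events
        # (migration pulses, surgery rounds) scheduled at exactly t fire
        if round(t1f, _TIME_DECIMALS) in record_set:
            _snapshot(pop, t1f, times, totals, counts, tallies)
        if migrate:
            migration_event(pop, params, t1f, rng, "emigrate")
            migration_event(pop, params, t1f, rng, "immigrate")
        if intervention is not None and round(t1f, _TIME_DECIMALS) in surgery_set:
            sterilization_event(pop, intervention, t1f, rng, params)
        # bound memory: dead rows dominate after years of turnover
        if pop.n_rows > 8192 and pop.size * 2 < pop.n_rows:
            pop.compact()
        t0 = t1f

    return Trajectory(
        times=np.asarray(times),
        total=np.asarray(totals, dtype=np.int64),
        counts=np.asarray(counts, dtype=np.int64),
        tallies=np.asarray(tallies, dtype=np.int64),
        initial_size=pop.initial_size,
    )
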