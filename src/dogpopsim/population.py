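"""Starting-cohort synthesis and the array-backed population container.

The population is stored struct-of-arrays (one NumPy array per attribute,
rows appended as dogs are born or immigrate, a boolean ``alive`` mask instead
of row deletion) so the simulation engine can process whole event cohorts
with vectorized operations.  :class:`Dog` is a per-row view for inspection
and export; the engine never constructs it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import (
    InitialConditions,
    ParameterSet,
    ParameterError,
    TruncExpSpec,
)

# sex codes
FEMALE, MALE = 0, 1
# life-class codes
PUPPY, YOUNG, ADULT = 0, 1, 2
LIFE_CLASS_NAMES = {PUPPY: "puppy", YOUNG: "young", ADULT: "adult"}
# reproductive-state codes (one enum space for both sexes)
IMMATURE, IN_HEAT, PREGNANT, NOT_IN_HEAT, SPAYED, REPRODUCTIVE, NEUTERED = range(7)
STATE_NAMES = {
    IMMATURE: "immature",
    IN_HEAT: "in_heat",
    PREGNANT: "pregnant",
    NOT_IN_HEAT: "not_in_heat",
    SPAYED: "spayed",
    REPRODUCTIVE: "reproductive",
    NEUTERED: "neutered",
}
STERILIZED_STATES = (SPAYED, NEUTERED)

TALLY_KEYS = (
    "births",
    "newborn_removals",
    "deaths_age",
    "deaths_nonage",
    "immigrants",
    "emigrants",
    "sterilized_female_young",
    "sterilized_female_adult",
    "sterilized_male_young",
    "sterilized_male_adult",
)


@dataclass
class Dog:
    """One simulated animal (read-only row view of the population arrays)."""

    id: int
    sex: str
    confined: bool
    birth_time: float
    life_class: str
    repro_state: str
    maturity_age: float
    scheduled_lifespan: float
    state_entry_time: float
    conception_time: float  # NaN unless pregnant
    sterilized: bool


class Population:
    """All dogs plus the simulation clock and cumulative event tallies.

    The conservation identity
    ``size == initial + births - newborn_removals + immigrants - deaths - emigrants``
    (with ``births`` counting only litter members actually added) holds at
    every point the engine records.
    """

    _GROW = 1024

    def __init__(self, capacity_hint: int = 4096):
        n = max(int(capacity_hint), 16)
        self.n_rows = 0
        self._next_id = 0
        self.clock = 0.0
        self.initial_size = 0
        self.tallies = {k: 0 for k in TALLY_KEYS}
        self.id = np.zeros(n, dtype=np.int64)
        self.sex = np.zeros(n, dtype=np.int8)
        self.confined = np.zeros(n, dtype=bool)
        self.birth = np.zeros(n, dtype=np.float64)
        self.maturity = np.zeros(n, dtype=np.float64)
        self.lifespan = np.zeros(n, dtype=np.float64)
        self.life_class = np.zeros(n, dtype=np.int8)
        self.state = np.zeros(n, dtype=np.int8)
        self.state_end = np.full(n, np.inf, dtype=np.float64)
        self.conception = np.full(n, np.nan, dtype=np.float64)
        self.alive = np.zeros(n, dtype=bool)

    _ARRAYS = ("id", "sex", "confined", "birth", "maturity", "lifespan",
               "life_class", "state", "state_end", "conception", "alive")

    @property
    def size(self) -> int:
        return int(np.count_nonzero(self.alive[: self.n_rows]))

    def _ensure(self, extra: int) -> None:
        need = self.n_rows + extra
        cap = len(self.id)
        if need <= cap:
            return
        new_cap = max(need, cap + self._GROW)
        for name in self._ARRAYS:
            arr = getattr(self, name)
            grown = np.empty(new_cap, dtype=arr.dtype)
            grown[: self.n_rows] = arr[: self.n_rows]
            if name == "state_end":
                grown[self.n_rows:] = np.inf
            elif name == "conception":
                grown[self.n_rows:] = np.nan
            elif name == "alive":
                grown[self.n_rows:] = False
            else:
                grown[self.n_rows:] = 0
            setattr(self, name, grown)

    def add_dogs(
        self,
        *,
        sex: np.ndarray,
        confined: np.ndarray,
        birth: np.ndarray,
        maturity: np.ndarray,
        lifespan: np.ndarray,
        life_class: np.ndarray,
        state: np.ndarray,
        state_end: np.ndarray | None = None,
        conception: np.ndarray | None = None,
    ) -> np.ndarray:
        """Append dogs; returns their row indices. IDs are assigned serially."""
        k = len(sex)
        self._ensure(k)
        rows = np.arange(self.n_rows, self.n_rows + k)
        self.id[rows] = np.arange(self._next_id, self._next_id + k)
        self._next_id += k
        self.sex[rows] = sex
        self.confined[rows] = confined
        self.birth[rows] = birth
        self.maturity[rows] = maturity
        self.lifespan[rows] = lifespan
        self.life_class[rows] = life_class
        self.state[rows] = state
        self.state_end[rows] = np.inf if state_end is None else state_end
        self.conception[rows] = np.nan if conception is None else conception
        self.alive[rows] = True
        self.n_rows += k
        return rows

    def compact(self) -> None:
        """Drop dead rows (keeping order, hence id order) to bound memory."""
        n = self.n_rows
        keep = self.alive[:n]
        k = int(np.count_nonzero(keep))
        if k == n:
            return
        for name in self._ARRAYS:
            arr = getattr(self, name)
            arr[:k] = arr[:n][keep]
        self.n_rows = k

    def is_sterilized(self) -> np.ndarray:
        s = self.state[: self.n_rows]
        return (s == SPAYED) | (s == NEUTERED)

    def dog(self, row: int) -> Dog:
        return Dog(
            id=int(self.id[row]),
            sex="female" if self.sex[row] == FEMALE else "male",
            confined=bool(self.confined[row]),
            birth_time=float(self.birth[row]),
            life_class=LIFE_CLASS_NAMES[int(self.life_class[row])],
            repro_state=STATE_NAMES[int(self.state[row])],
            maturity_age=float(self.maturity[row]),
            scheduled_lifespan=float(self.lifespan[row]),
            state_entry_time=float("nan"),
            conception_time=float(self.conception[row]),
            sterilized=int(self.state[row]) in STERILIZED_STATES,
        )

    def to_dataframe(self, alive_only: bool = True) -> pd.DataFrame:
        n = self.n_rows
        mask = self.alive[:n] if alive_only else np.ones(n, dtype=bool)
        sex = np.where(self.sex[:n][mask] == FEMALE, "female", "male")
        return pd.DataFrame({
            "id": self.id[:n][mask],
            "sex": sex,
            "confined": self.confined[:n][mask],
            "age": self.clock - self.birth[:n][mask],
            "life_class": [LIFE_CLASS_NAMES[c] for c in self.life_class[:n][mask]],
            "state": [STATE_NAMES[s] for s in self.state[:n][mask]],
            "sterilized": np.isin(self.state[:n][mask], STERILIZED_STATES),
            "scheduled_lifespan": self.lifespan[:n][mask],
        })


# ---------------------------------------------------------------------------


def truncexp_ppf(u: np.ndarray | float, spec: TruncExpSpec) -> np.ndarray | float:
    """Inverse CDF of the exponential truncated to [min, max]."""
    a, b, lam = spec.min, spec.max, spec.effective_rate
    if a == b:
        return np.full_like(np.asarray(u, dtype=float), a) if np.ndim(u) else a
    z = -np.expm1(-lam * (b - a))  # 1 - exp(-lam*(b-a))
    return a - np.log1p(-np.asarray(u) * z) / lam


def draw_lifespan(
    sex: str,
    sterilized: bool,
    params: ParameterSet,
    rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray | float:
    """Draw age-at-death from the sex's truncated-exponential distribution.

    Sterilization stretches the whole distribution by
    ``sterilized_lifespan_scale`` (both bounds up, rate down), so a sterilized
    draw is distributed as ``scale`` times an intact one.
    """
    spec = params.lifespan_dist[sex]
    if sterilized:
        spec = spec.scaled(params.sterilized_lifespan_scale)
    u = rng.random(size) if size is not None else rng.random()
    return truncexp_ppf(u, spec)


def largest_remainder_counts(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Integer allocation of ``n`` over states: floor, then distribute the
    remainder to the largest fractional parts (ties broken by map order)."""
    keys = list(fractions)
    raw = np.array([fractions[k] * n for k in keys])
    base = np.floor(raw).astype(int)
    short = n - int(base.sum())
    if short > 0:
        # stable argsort descending on remainder preserves map order on ties
        order = np.argsort(-(raw - base), kind="stable")[:short]
        base[order] += 1
    return dict(zip(keys, base.tolist()))


def _redraw_above(
    lifespan: np.ndarray,
    floor: np.ndarray,
    sex: str,
    sterilized: bool,
    params: ParameterSet,
    rng: np.random.Generator,
) -> np.ndarray:
    """Redraw lifespans not exceeding ``floor`` (a live dog's current age)."""
    for _ in range(1000):
        bad = lifespan <= floor
        if not bad.any():
            return lifespan
        lifespan[bad] = draw_lifespan(sex, sterilized, params, rng,
                                      size=int(bad.sum()))
    raise ParameterError(  # pragma: no cover - degenerate configs only
        f"lifespan_dist.{sex}: support cannot exceed required minimum age")


def _draw_adult_age_and_lifespan(
    k: int,
    sex: str,
    sterilized: bool,
    maturity: np.ndarray,
    params: ParameterSet,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Adult ages uniform on [maturity, lifespan); lifespans below maturity
    are redrawn (an adult cannot have died before adulthood)."""
    lifespan = np.asarray(draw_lifespan(sex, sterilized, params, rng, size=k))
    lifespan = _redraw_above(lifespan, maturity, sex, sterilized, params, rng)
    age = maturity + rng.random(k) * (lifespan - maturity)
    return age, lifespan


def initialize_population(
    init: InitialConditions | None = None,
    params: ParameterSet | None = None,
    rng: np.random.Generator | int | None = None,
) -> Population:
    """Synthesize the starting cohort from the published state proportions.

    Per-sex state counts are the largest-remainder rounding of
    ``fraction * n``; each dog is independently confined with probability
    ``proportion_confined``.  Ages are drawn uniformly over each state's
    admissible range, reproductive clocks start at a uniformly random phase
    (so cycles are not synchronized at t=0), and every dog receives maturity
    and scheduled-lifespan draws.
    """
    init = init or InitialConditions()
    params = params or ParameterSet()
    init.validate()
    params.validate()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    pop = Population(capacity_hint=2 * (init.n_female + init.n_male) + 64)
    pop.initial_size = init.n_female + init.n_male

    f_counts = largest_remainder_counts(init.female_fractions, init.n_female)
    m_counts = largest_remainder_counts(init.male_fractions, init.n_male)

    wean = params.weaning_years
    mat_lo, mat_hi = params.female_maturity_years

    def _append(k, sex_code, life_class, state, age, maturity, lifespan,
                state_end=None, conception=None):
        if k == 0:
            return
        pop.add_dogs(
            sex=np.full(k, sex_code, dtype=np.int8),
            confined=rng.random(k) < params.proportion_confined,
            birth=-np.asarray(age, dtype=float),
            maturity=np.asarray(maturity, dtype=float),
            lifespan=np.asarray(lifespan, dtype=float),
            life_class=np.full(k, life_class, dtype=np.int8),
            state=np.full(k, state, dtype=np.int8),
            state_end=state_end,
            conception=conception,
        )

    # --- females -----------------------------------------------------------
    for state_name, k in f_counts.items():
        if k == 0:
            continue
        maturity = mat_lo + rng.random(k) * (mat_hi - mat_lo)
        if state_name == "puppy":
            age = rng.random(k) * wean
            lifespan = np.asarray(draw_lifespan("female", False, params, rng, k))
            lifespan = _redraw_above(lifespan, age, "female", False, params, rng)
            _append(k, FEMALE, PUPPY, IMMATURE, age, maturity, lifespan)
        elif state_name == "young":
            age = wean + rng.random(k) * (maturity - wean)
            lifespan = np.asarray(draw_lifespan("female", False, params, rng, k))
            lifespan = _redraw_above(lifespan, age, "female", False, params, rng)
            _append(k, FEMALE, YOUNG, IMMATURE, age, maturity, lifespan)
        elif state_name == "spayed":
            age, lifespan = _draw_adult_age_and_lifespan(
                k, "female", True, maturity, params, rng)
            _append(k, FEMALE, ADULT, SPAYED, age, maturity, lifespan)
        else:
            age, lifespan = _draw_adult_age_and_lifespan(
                k, "female", False, maturity, params, rng)
            if state_name == "in_heat":
                elapsed = rng.random(k) * params.heat_years
                state_end = -elapsed + params.heat_years
                _append(k, FEMALE, ADULT, IN_HEAT, age, maturity, lifespan,
                        state_end=state_end)
            elif state_name == "pregnant":
                conception = -rng.random(k) * params.gestation_years
                state_end = conception + params.gestation_years
                _append(k, FEMALE, ADULT, PREGNANT, age, maturity, lifespan,
                        state_end=state_end, conception=conception)
            else:  # not_in_heat
                elapsed = rng.random(k) * params.interestrus_years
                state_end = -elapsed + params.interestrus_years
                _append(k, FEMALE, ADULT, NOT_IN_HEAT, age, maturity, lifespan,
                        state_end=state_end)

    # --- males --------------------------------------------------------------
    male_mat = params.adult_age_male_years
    for state_name, k in m_counts.items():
        if k == 0:
            continue
        maturity = np.full(k, male_mat)
        if state_name == "puppy":
            age = rng.random(k) * wean
            lifespan = np.asarray(draw_lifespan("male", False, params, rng, k))
            lifespan = _redraw_above(lifespan, age, "male", False, params, rng)
            _append(k, MALE, PUPPY, IMMATURE, age, maturity, lifespan)
        elif state_name == "young":
            age = wean + rng.random(k) * (male_mat - wean)
            lifespan = np.asarray(draw_lifespan("male", False, params, rng, k))
            lifespan = _redraw_above(lifespan, age, "male", False, params, rng)
            _append(k, MALE, YOUNG, IMMATURE, age, maturity, lifespan)
        elif state_name == "reproductive":
            age, lifespan = _draw_adult_age_and_lifespan(
                k, "male", False, maturity, params, rng)
            _append(k, MALE, ADULT, REPRODUCTIVE, age, maturity, lifespan)
        else:  # neutered
            age, lifespan = _draw_adult_age_and_lifespan(
                k, "male", True, maturity, params, rng)
            _append(k, MALE, ADULT, NEUTERED, age, maturity, lifespan)

    return pop
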