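"""Model parameters, initial conditions, and rate/probability conversions.

All durations are stored in the units the field name declares (weeks, months,
days, years) and converted to years — the simulation's time unit — through the
constants below.  Default values are the published point estimates for the
owned-dog population of Villa de Tezontepec, Hidalgo, Mexico; every default is
overridable through :func:`load_parameters` with flat dotted keys
(``"annual_pregnancy_risk.confined"``), which is also how sensitivity sweeps
perturb single parameters.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

DAYS_PER_YEAR = 365.25
WEEKS_TO_YEARS = 7.0 / DAYS_PER_YEAR
MONTHS_TO_YEARS = 1.0 / 12.0
DAYS_TO_YEARS = 1.0 / DAYS_PER_YEAR

LIFE_CLASSES = ("puppy", "young", "adult")
CONFINEMENT = ("confined", "unconfined")


class ParameterError(ValueError):
    """Raised when a parameter override names an unknown key or violates a bound."""


@dataclass(frozen=True)
class TruncExpSpec:
    """Truncated-exponential lifespan distribution on [min, max] years.

    The rate is a free parameter; when ``None`` it defaults to
    ``1 / mean(min, max)``.  The printed skewness/kurtosis of the source
    distribution are carried as metadata only — a truncated exponential's
    shape is already fixed by (min, max, rate).
    """

    min: float
    max: float
    rate: float | None = None
    skewness: float | None = None
    kurtosis: float | None = None

    @property
    def effective_rate(self) -> float:
        if self.rate is not None:
            return self.rate
        return 2.0 / (self.min + self.max)

    def scaled(self, factor: float) -> "TruncExpSpec":
        """Distribution of ``factor * X``: bounds scale up, rate scales down."""
        return TruncExpSpec(
            min=self.min * factor,
            max=self.max * factor,
            rate=self.effective_rate / factor,
            skewness=self.skewness,
            kurtosis=self.kurtosis,
        )


@dataclass(frozen=True)
class ParameterSet:
    """Every model constant: demography, hazards, reproduction, migration.

    Unconfined hazards default to exactly twice their confined counterpart;
    sterilized dogs use a single non-age mortality rate (90% of the confined
    adult rate, doubled when unconfined) and a lifespan distribution stretched
    by ``sterilized_lifespan_scale``.
    """

    time_to_weaning: float = 8.0              # weeks
    female_maturity_range: tuple[float, float] = (6.0, 10.0)  # months, uniform
    male_maturity_age: float = 10.0           # months (recorded; reproduction
    #                                           is gated by adult_age_male)
    adult_age_male: float = 8.0               # months; male adult = reproductive
    heat_duration: float = 18.0               # days
    gestation: float = 65.0                   # days
    interestrus_interval: float = 7.0         # months, cycle end -> next proestrus
    litter_size: int = 4
    litter_sex_split: tuple[int, int] = (2, 2)  # (males, females)
    annual_pregnancy_risk: dict[str, float] = field(
        default_factory=lambda: {"confined": 0.26, "unconfined": 0.52}
    )
    nonage_mortality_annual: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "puppy": {"confined": 0.10, "unconfined": 0.20},
            "young": {"confined": 0.20, "unconfined": 0.40},
            "adult": {"confined": 0.03, "unconfined": 0.06},
        }
    )
    sterilized_nonage_mortality_annual: dict[str, float] = field(
        default_factory=lambda: {"confined": 0.027, "unconfined": 0.054}
    )
    lifespan_dist: dict[str, TruncExpSpec] = field(
        default_factory=lambda: {
            "male": TruncExpSpec(0.08, 14.00, skewness=2.27, kurtosis=10.24),
            "female": TruncExpSpec(0.50, 12.00, skewness=1.58, kurtosis=5.13),
        }
    )
    sterilized_lifespan_scale: float = 1.10
    annual_immigration_prob: float = 0.23
    annual_emigration_prob: float = 0.04
    migration_period: float = 0.25            # years
    community_capacity: int = 2924
    horizon: float = 20.0                     # years
    proportion_confined: float = 0.45
    hazard_step: float = 1.0                  # weeks; non-age mortality clock
    surgery_period: float = 1.0 / 12.0        # years; monthly quota events

    # ---- derived durations in years ----------------------------------------
    @property
    def weaning_years(self) -> float:
        return self.time_to_weaning * WEEKS_TO_YEARS

    @property
    def heat_years(self) -> float:
        return self.heat_duration * DAYS_TO_YEARS

    @property
    def gestation_years(self) -> float:
        return self.gestation * DAYS_TO_YEARS

    @property
    def interestrus_years(self) -> float:
        return self.interestrus_interval * MONTHS_TO_YEARS

    @property
    def adult_age_male_years(self) -> float:
        return self.adult_age_male * MONTHS_TO_YEARS

    @property
    def female_maturity_years(self) -> tuple[float, float]:
        lo, hi = self.female_maturity_range
        return (lo * MONTHS_TO_YEARS, hi * MONTHS_TO_YEARS)

    def per_heat_conception_prob(self, confined: bool) -> float:
        """Per-heat conception probability calibrated to the annual risk.

        A continuously cycling female completes one cycle every
        ``heat + interestrus`` years; the per-heat probability is chosen so
        that compounding over a year recovers the annual pregnancy risk.
        """
        key = "confined" if confined else "unconfined"
        cycle = self.heat_years + self.interestrus_years
        return annual_prob_to_interval_prob(self.annual_pregnancy_risk[key], cycle)

    def validate(self) -> None:
        probs = {
            "annual_pregnancy_risk.confined": self.annual_pregnancy_risk["confined"],
            "annual_pregnancy_risk.unconfined": self.annual_pregnancy_risk["unconfined"],
            "sterilized_nonage_mortality_annual.confined":
                self.sterilized_nonage_mortality_annual["confined"],
            "sterilized_nonage_mortality_annual.unconfined":
                self.sterilized_nonage_mortality_annual["unconfined"],
            "annual_immigration_prob": self.annual_immigration_prob,
            "annual_emigration_prob": self.annual_emigration_prob,
            "proportion_confined": self.proportion_confined,
        }
        for lc in LIFE_CLASSES:
            for conf in CONFINEMENT:
                probs[f"nonage_mortality_annual.{lc}.{conf}"] = \
                    self.nonage_mortality_annual[lc][conf]
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name}={p} outside [0, 1]")
        durations = {
            "time_to_weaning": self.time_to_weaning,
            "heat_duration": self.heat_duration,
            "gestation": self.gestation,
            "interestrus_interval": self.interestrus_interval,
            "adult_age_male": self.adult_age_male,
            "male_maturity_age": self.male_maturity_age,
            "migration_period": self.migration_period,
            "horizon": self.horizon,
            "hazard_step": self.hazard_step,
            "surgery_period": self.surgery_period,
        }
        for name, d in durations.items():
            if not d > 0:
                raise ParameterError(f"{name}={d} must be > 0")
        if self.community_capacity < 1:
            raise ParameterError(
                f"community_capacity={self.community_capacity} must be >= 1")
        if sum(self.litter_sex_split) != self.litter_size:
            raise ParameterError(
                f"litter_sex_split {self.litter_sex_split} does not sum to "
                f"litter_size {self.litter_size}")
        lo, hi = self.female_maturity_range
        if not 0 < lo <= hi:
            raise ParameterError(
                f"female_maturity_range {self.female_maturity_range} invalid")
        for sex, spec in self.lifespan_dist.items():
            if not spec.min <= spec.max:
                raise ParameterError(
                    f"lifespan_dist.{sex}: min {spec.min} > max {spec.max}")
            if spec.min < 0:
                raise ParameterError(f"lifespan_dist.{sex}.min {spec.min} < 0")
            if spec.effective_rate <= 0:
                raise ParameterError(f"lifespan_dist.{sex}.rate must be > 0")
        if self.sterilized_lifespan_scale <= 0:
            raise ParameterError("sterilized_lifespan_scale must be > 0")


@dataclass(frozen=True)
class InitialConditions:
    """Starting cohort composition: per-sex sizes and state proportions."""

    n_female: int = 1222
    n_male: int = 1702
    female_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "puppy": 0.04,
            "young": 0.11,
            "in_heat": 0.21,
            "pregnant": 0.06,
            "not_in_heat": 0.21,
            "spayed": 0.37,
        }
    )
    male_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "puppy": 0.06,
            "young": 0.16,
            "reproductive": 0.64,
            "neutered": 0.14,
        }
    )

    def validate(self) -> None:
        if self.n_female < 0 or self.n_male < 0:
            raise ParameterError("population sizes must be nonnegative")
        for name, fracs in (("female_fractions", self.female_fractions),
                            ("male_fractions", self.male_fractions)):
            total = sum(fracs.values())
            if abs(total - 1.0) > 1e-9:
                raise ParameterError(f"{name} sums to {total}, not 1.0")
            for key, f in fracs.items():
                if not 0.0 <= f <= 1.0:
                    raise ParameterError(f"{name}.{key}={f} outside [0, 1]")


def annual_prob_to_interval_prob(p_annual: float, interval: float) -> float:
    """Convert an annual probability to the equivalent over ``interval`` years.

    Uses constant-hazard compounding, ``1 - (1 - p)^interval``, the only
    convention under which per-year risks applied on a sub-year clock compose
    back to the printed annual value.
    """
    if not 0.0 <= p_annual <= 1.0:
        raise ParameterError(f"p_annual={p_annual} outside [0, 1]")
    if not interval > 0:
        raise ParameterError(f"interval={interval} must be > 0")
    return 1.0 - (1.0 - p_annual) ** interval


# ---------------------------------------------------------------------------
# Flat dotted-key override machinery


def _flatten(obj: Any, prefix: str = "") -> dict[str, Any]:
    out: dict[str, Any] = {}
    if isinstance(obj, Mapping):
        for k, v in obj.items():
            key = f"{prefix}.{k}" if prefix else str(k)
            out.update(_flatten(v, key))
    else:
        out[prefix] = obj
    return out


def _known_keys(params: ParameterSet) -> set[str]:
    keys: set[str] = set()
    for f in dataclasses.fields(params):
        value = getattr(params, f.name)
        if isinstance(value, Mapping):
            keys.update(_flatten(value, f.name))
        else:
            keys.add(f.name)
    # TruncExpSpec sub-fields are addressable individually
    for sex in params.lifespan_dist:
        for sub in ("min", "max", "rate", "skewness", "kurtosis"):
            keys.add(f"lifespan_dist.{sex}.{sub}")
        keys.discard(f"lifespan_dist.{sex}")
    # tuple fields addressable as .min/.max or index-free scalars
    keys.add("female_maturity_range.min")
    keys.add("female_maturity_range.max")
    keys.add("litter_sex_split.male")
    keys.add("litter_sex_split.female")
    return keys


def load_parameters(config: str | Mapping[str, Any] | None = None) -> ParameterSet:
    """Build a :class:`ParameterSet` from defaults overlaid with overrides.

    ``config`` may be ``None`` (pure defaults), a mapping (nested or flat
    dotted keys), or a YAML document / path to one.  Unknown keys and
    out-of-range values are fatal, naming the offending key — a sensitivity
    sweep must never silently no-op.
    """
    defaults = ParameterSet()
    if config is None:
        defaults.validate()
        return defaults
    if isinstance(config, str):
        import os
        if os.path.exists(config):
            with open(config) as fh:
                config = yaml.safe_load(fh) or {}
        else:
            config = yaml.safe_load(config) or {}
    if not isinstance(config, Mapping):
        raise ParameterError(f"config must be a mapping, got {type(config).__name__}")
    overrides = _flatten(dict(config))
    known = _known_keys(defaults)
    unknown = sorted(set(overrides) - known)
    if unknown:
        raise ParameterError(f"unknown parameter key(s): {', '.join(unknown)}")

    updates: dict[str, Any] = {}

    def _mut_map(name: str) -> Any:
        if name not in updates:
            value = getattr(defaults, name)
            if isinstance(value, dict):
                updates[name] = {
                    k: dict(v) if isinstance(v, dict) else v for k, v in value.items()
                }
            else:
                updates[name] = value
        return updates[name]

    for key, value in overrides.items():
        parts = key.split(".")
        name = parts[0]
        if name == "lifespan_dist" and len(parts) == 3:
            dists = _mut_map("lifespan_dist")
            spec = dists[parts[1]]
            if not isinstance(spec, dict):
                spec = dataclasses.asdict(spec)
            spec[parts[2]] = value
            dists[parts[1]] = spec
        elif name == "female_maturity_range":
            if len(parts) == 1:  # whole interval, e.g. from a YAML export
                updates[name] = tuple(value)
            else:
                lo, hi = updates.get(name, defaults.female_maturity_range)
                updates[name] = (value, hi) if parts[1] == "min" else (lo, value)
        elif name == "litter_sex_split":
            if len(parts) == 1:
                updates[name] = tuple(value)
            else:
                m, f = updates.get(name, defaults.litter_sex_split)
                updates[name] = (value, f) if parts[1] == "male" else (m, value)
        elif len(parts) == 1:
            updates[name] = value
        elif len(parts) == 2:
            _mut_map(name)[parts[1]] = value
        else:
            _mut_map(name)[parts[1]][parts[2]] = value

    if "lifespan_dist" in updates:
        updates["lifespan_dist"] = {
            sex: spec if isinstance(spec, TruncExpSpec) else TruncExpSpec(**spec)
            for sex, spec in updates["lifespan_dist"].items()
        }
    params = dataclasses.replace(defaults, **updates)
    params.validate()
    return params


def params_to_dict(params: ParameterSet) -> dict[str, Any]:
    """Nested plain-dict form of a ParameterSet, round-trippable via YAML."""
    out = dataclasses.asdict(params)
    out["lifespan_dist"] = {
        sex: dataclasses.asdict(spec) for sex, spec in params.lifespan_dist.items()
    }
    out["female_maturity_range"] = list(params.female_maturity_range)
    out["litter_sex_split"] = list(params.litter_sex_split)
    return out


def params_to_yaml(params: ParameterSet) -> str:
    return yaml.safe_dump(params_to_dict(params), sort_keys=True)
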