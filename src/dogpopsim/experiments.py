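"""Replicated scenario runs, Table-style summaries, and sensitivity sweeps.

A *scenario* is a parameter set plus an (optional) sterilization strategy;
its outcome is the distribution of final population sizes over seeded
replicates.  Replicate r of every scenario draws its random stream from
``SeedSequence(base_seed, spawn_key=(r,))`` — the same stream regardless of
scenario — so scenario and sensitivity comparisons are paired by seed and
differences are attributable to the intervention or the perturbed parameter
rather than to Monte Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import Trajectory, run_simulation
from .interventions import InterventionSpec, build_intervention
from .params import InitialConditions, ParameterSet, load_parameters
from .population import initialize_population

#: replicate count used in the source analysis; 200 is the desk-scale setting
FULL_REPLICATES = 1000
DESK_REPLICATES = 200

#: the thirteen standard scenarios: no intervention plus 4 strategies x 3 levels
TABLE_SCENARIOS: tuple[tuple[str, str | None, int | None], ...] = (
    ("base", None, None),
    *[(f"{s}.{l}", s, l) for s in "ABCD" for l in (1, 2, 3)],
)


@dataclass
class ReplicateSummary:
    """Aggregate of final population sizes over a scenario's replicates."""

    label: str
    n_replicates: int
    mean: float
    sd: float
    median: float
    min: int
    max: int
    pct_change_vs_base: float | None = None
    finals: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @classmethod
    def from_finals(cls, label: str, finals: Sequence[int]) -> "ReplicateSummary":
        arr = np.asarray(finals, dtype=int)
        sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
        return cls(
            label=label,
            n_replicates=int(arr.size),
            mean=float(arr.mean()),
            sd=sd,
            median=float(np.median(arr)),
            min=int(arr.min()),
            max=int(arr.max()),
            finals=arr,
        )


@dataclass(frozen=True)
class SensitivitySpec:
    """One parameter, a value grid, and the scenario it perturbs."""

    parameter: str
    grid: tuple[float, ...]
    strategy: str | None = None        # None = base case
    level: int | None = None
    n_replicates: int = DESK_REPLICATES

    def __post_init__(self):
        if len(self.grid) == 0:
            raise ValueError("sensitivity grid must be nonempty")


#: parameter sweeps mirroring the published sensitivity analysis ranges
SENSITIVITY_RANGES: dict[str, tuple[float, float]] = {
    "nonage_mortality_annual.puppy.confined": (0.05, 0.30),
    "nonage_mortality_annual.young.confined": (0.10, 0.30),
    "nonage_mortality_annual.adult.confined": (0.015, 0.075),
    "nonage_mortality_annual.puppy.unconfined": (0.05, 0.50),
    "nonage_mortality_annual.young.unconfined": (0.10, 0.60),
    "nonage_mortality_annual.adult.unconfined": (0.015, 0.09),
    "annual_pregnancy_risk.confined": (0.10, 0.40),
    "annual_pregnancy_risk.unconfined": (0.10, 0.66),
    "sterilized_nonage_mortality_annual.confined": (0.015, 0.036),
    "sterilized_nonage_mortality_annual.unconfined": (0.027, 0.06),
}


def replicate_rng(base_seed: int, replicate: int) -> np.random.Generator:
    """Deterministic, scenario-independent stream for one replicate."""
    ss = np.random.SeedSequence(base_seed, spawn_key=(replicate,))
    return np.random.default_rng(ss)


def run_replicate(
    params: ParameterSet,
    intervention: InterventionSpec | None,
    base_seed: int,
    replicate: int,
    init: InitialConditions | None = None,
    return_trajectory: bool = False,
) -> int | Trajectory:
    """One seeded 20-year run; returns the final population size (or the
    whole trajectory)."""
    rng = replicate_rng(base_seed, replicate)
    pop = initialize_population(init or InitialConditions(), params, rng)
    traj = run_simulation(pop, params, intervention, rng)
    return traj if return_trajectory else traj.final_size


def run_scenario(
    params: ParameterSet,
    intervention: InterventionSpec | None,
    n_replicates: int,
    base_seed: int,
    label: str = "scenario",
    init: InitialConditions | None = None,
) -> ReplicateSummary:
    """Replicated runs of one scenario, aggregated Table-3 style."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    finals = [
        run_replicate(params, intervention, base_seed, r, init=init)
        for r in range(n_replicates)
    ]
    return ReplicateSummary.from_finals(label, finals)


def compare_to_base(summary: ReplicateSummary,
                    base_summary: ReplicateSummary) -> float:
    """Percent change of a scenario's mean final size vs the base case."""
    if base_summary.mean <= 0:
        raise ValueError("base-case mean must be > 0")
    return 100.0 * (summary.mean - base_summary.mean) / base_summary.mean


def run_table3_suite(
    n_replicates: int = DESK_REPLICATES,
    base_seed: int = 0,
    params: ParameterSet | None = None,
    scenarios: Sequence[tuple[str, str | None, int | None]] = TABLE_SCENARIOS,
) -> tuple[pd.DataFrame, dict[str, ReplicateSummary]]:
    """Base case plus every strategy x capacity level, on shared seeds.

    Returns the tidy summary table (one row per scenario, percent change
    computed against the suite's own simulated base case) and the underlying
    summaries keyed by label.
    """
    params = params or ParameterSet()
    summaries: dict[str, ReplicateSummary] = {}
    for label, strategy, level in scenarios:
        iv = build_intervention(strategy, level) if strategy else None
        summaries[label] = run_scenario(
            params, iv, n_replicates, base_seed, label=label)
    base = summaries.get("base")
    rows = []
    for label, s in summaries.items():
        if base is not None:
            s.pct_change_vs_base = compare_to_base(s, base)
        _, strategy, level = next(
            sc for sc in scenarios if sc[0] == label)
        rows.append({
            "scenario": label,
            "level": level if level is not None else "",
            "reps": s.n_replicates,
            "mean": s.mean,
            "sd": s.sd,
            "median": s.median,
            "min": s.min,
            "max": s.max,
            "pct_change": s.pct_change_vs_base
            if s.pct_change_vs_base is not None else 0.0,
        })
    return pd.DataFrame(rows), summaries


def run_sensitivity(
    spec: SensitivitySpec,
    base_seed: int = 0,
    base_config: Mapping[str, Any] | None = None,
) -> tuple[pd.DataFrame, dict[float, ReplicateSummary]]:
    """One-at-a-time sweep: rerun the scenario at each grid value.

    Every grid value reuses the same replicate seed sequence, so differences
    along the grid are attributable to the parameter.  Out-of-range values
    are rejected by parameter validation.
    """
    iv = (build_intervention(spec.strategy, spec.level)
          if spec.strategy else None)
    summaries: dict[float, ReplicateSummary] = {}
    rows = []
    for value in spec.grid:
        config = dict(base_config or {})
        config[spec.parameter] = value
        params = load_parameters(config)
        s = run_scenario(params, iv, spec.n_replicates, base_seed,
                         label=f"{spec.parameter}={value}")
        summaries[value] = s
        rows.append({
            "parameter": spec.parameter,
            "value": value,
            "scenario": spec.strategy or "base",
            "level": spec.level if spec.level is not None else "",
            "reps": s.n_replicates,
            "mean": s.mean,
            "sd": s.sd,
            "median": s.median,
            "min": s.min,
            "max": s.max,
        })
    return pd.DataFrame(rows), summaries
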