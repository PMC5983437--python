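# dogpopsim

Stochastic, individual-based simulation of an owned-dog population under
surgical-sterilization interventions, parameterized for the community of
Villa de Tezontepec, Hidalgo, Mexico (≈2,924 owned dogs, 45% confined).

Communities with limited veterinary resources must decide *which* dogs to
sterilize: the regional government program performs 21 surgeries per month
spread over ages and sexes.  This package simulates every dog's life cycle —
aging, the female reproductive cycle, age-related and accident/disease
mortality, quarterly migration, and a community-capacity cap on recruitment —
and compares sterilization strategies that target different sex × age
classes at different monthly surgical capacities, using the 20-year
population size as the outcome.  It is written for epidemiological modellers
and animal-population researchers who want a transparent, fully seeded,
testable reimplementation of this class of companion-animal demographic
model.

## Model at a glance

- Individual dogs with sex, confinement, life class (puppy < 8 wk ≤ young <
  maturity ≤ adult), reproductive state, drawn maturity age (♀ ~ U(6, 10) mo;
  ♂ 8 mo) and drawn lifespan (sex-specific truncated exponential).
- Female cycle: heat 18 d → conception with per-heat probability calibrated
  so a cycling female compounds to the annual pregnancy risk (0.26/yr
  confined, 0.52/yr unconfined) → gestation 65 d → litter of 2♂ + 2♀ →
  interestrus 7 mo.  Conception requires ≥1 intact mature male.
- Mortality: deterministic death at the drawn lifespan, plus weekly
  non-age-related hazard by life class × confinement (unconfined = 2×
  confined); sterilized dogs get a 10% lifespan stretch and reduced hazard.
- Quarterly migration: per-dog emigration (0.04/yr), binomial immigration of
  intact puppies against current population size (0.23/yr).
- Community capacity 2924: newborns arriving at or above capacity are
  removed immediately (births only — immigration is exempt).
- Interventions: monthly quotas by sex × age class.  Strategy A (government
  mix: 6 adult ♂, 13 adult ♀, 1 young ♂, 1 young ♀), B (young only, 7♂:14♀),
  C (females only, 20 adult : 1 young), D (young females only), each at
  21/42/84 surgeries per month.  Females are eligible only between heats.

All probabilities printed "per year" are applied on sub-year clocks by
constant-hazard compounding, `p(Δt) = 1 − (1 − p_annual)^Δt`.

## Worked example

```python
from dogpopsim import ParameterSet, run_scenario, build_intervention, compare_to_base

params = ParameterSet()                      # published defaults
base = run_scenario(params, None, n_replicates=100, base_seed=0)
d3 = run_scenario(params, build_intervention("D", 3), 100, 0)
print(f"base: mean {base.mean:.1f} (SD {base.sd:.2f}), range {base.min}-{base.max}")
print(f"D.3 : mean {d3.mean:.1f}, change {compare_to_base(d3, base):+.1f}%")
```

prints

```
base: mean 2923.9 (SD 0.90), range 2916-2924
D.3 : mean 1243.6, change -57.5%
```

The base case is pinned at the community capacity: reproduction saturates
the cap, so every replicate ends the 20 years at (or a few dogs under) 2924.
Strategy D.3 — all 84 monthly surgeries on sexually immature females —
blocks enough female recruitment that the population is in sustained decline,
down ~57% at the 20-year horizon and still falling.  Under this
parameterization the lower-capacity strategies leave the population pinned;
see `docs/methods.md` for why outcomes are near-bistable and how that
depends on the unpublished lifespan rate and the immigration scaling.

The same analyses as scripts (tables under `results/`):

```bash
python analysis/01_base_case.py 100 0        # reps seed
python analysis/02_interventions.py 100 0    # 13-scenario suite + box plot
python analysis/03_sensitivity.py 60 0       # pregnancy/capacity/mortality sweeps
```

or from the CLI:

```bash
dogpopsim table3 --reps 200 --seed 0 --out results/table3.csv --plot
dogpopsim simulate --strategy D --level 1 --reps 1 --seed 7 --out results/
dogpopsim sensitivity --param annual_pregnancy_risk.confined --grid 0.10,0.26,0.40
dogpopsim params export
dogpopsim fixtures --kind capacity_edge --out results/fixtures
```

Every run writes a `manifest.yaml` (config snapshot, seed, version, outputs),
and every result is reproducible bit-for-bit from its seed: replicate *r*
always uses `SeedSequence(base_seed, spawn_key=(r,))`, independent of
scenario, so scenario and sensitivity comparisons are seed-paired.

## Layout

```
src/dogpopsim/      params, population, engine, interventions,
                    experiments, fixtures, plotting, cli
analysis/           numbered narrative drivers (simulate → compare → sweep)
tests/              pytest suite incl. acceptance criteria
scripts/acceptance.py
docs/methods.md     model description, assumptions, design choices, caveats
```
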