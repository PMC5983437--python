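# Methods

## The model

`dogpopsim` is a stochastic, individual-based model of the owned-dog
population of a single community (Villa de Tezontepec, Hidalgo, Mexico, in
the default parameterization).  Every dog is an agent with a sex, a
confinement status (confined dogs are never allowed to roam unsupervised;
unconfined dogs are), a life class (puppy, birth–8 weeks; young, 8 weeks to
sexual maturity; adult thereafter), a reproductive state, a drawn maturity
age, and a drawn scheduled lifespan.  The model is non-spatial: dogs do not
interact except through two global quantities, the community capacity and
the existence of at least one reproductive male.

**Female life cycle.**  A female matures at an age drawn uniformly on 6–10
months and immediately enters her first heat.  A heat lasts 18 days;
conception is resolved once per heat, provided at least one intact, mature
male exists anywhere in the population.  A conceiving female gestates for 65
days and then whelps a litter of four (two male, two female); whether or not
she conceives, she then waits one interestrus interval (7 months) before the
next heat.  Males mature at 8 months and move to the reproductive state
(the male state chart defines adulthood at 8 months; a separately recorded
10-month "sexual maturity" figure is carried as metadata but does not gate
reproduction).

**Conception probability.**  Pregnancy risk is given per year (0.26/yr
confined, 0.52/yr unconfined).  The per-heat probability is calibrated so
that a continuously cycling female — one cycle every 18 d + 7 mo ≈ 0.633 yr
— compounds to exactly the annual risk: `p_heat = 1 − (1 − p_annual)^cycle`
(≈ 0.173 confined).  A unit test audits this by simulation: the first-year
conception fraction of a cohort of cycling females matches a renewal-process
oracle and lands at ≈ 0.25–0.26.

**Mortality.**  Two independent processes.  (a) *Age-related*: each dog
draws a scheduled lifespan at creation from a sex-specific exponential
distribution truncated to [0.08, 14.0] yr (males) or [0.50, 12.0] yr
(females) and dies deterministically at that age.  The truncation bounds are
published; the rate is not, so it is a configurable parameter defaulting to
the reciprocal of the bounds' midpoint (the published skewness/kurtosis of
the source fit over-determine a two-parameter truncated exponential and are
stored as metadata only).  (b) *Non-age-related* (accidents, disease): a
weekly Bernoulli hazard per dog at the annual risk for its life class ×
confinement (puppy 0.10/0.20, young 0.20/0.40, adult 0.03/0.06 per year;
unconfined is always double confined).  Sterilized dogs of any age use the
sterilized rates (0.027/0.054 — 90% of the adult rate) and have their
scheduled lifespan stretched by a factor 1.10; the sterilized lifespan
distribution is the intact one scaled (both bounds ×1.1, rate ÷1.1), so the
quantile-preserving rescale at surgery is multiplication by 1.10.  The
printed minimum of 0.88 yr for sterilized males is treated as a slip of
1.1 × 0.08 = 0.088: the ×1.1 rule is applied uniformly.

**Rate conversions.**  All "per year" probabilities are applied on sub-year
clocks via constant-hazard compounding, `p(Δt) = 1 − (1 − p_annual)^Δt`,
the only convention under which quarterly/weekly applications compose back
to the printed annual value (round-trip tested to 1e-12).

**Community capacity.**  The community sustains at most 2924 owned dogs.
The cap binds *births only*: each newborn is checked sequentially at
whelping and removed immediately (tallied) if the population is at or above
capacity.  Immigration may push the population above capacity; this
asymmetry is deliberate.

**Migration.**  Every quarter, (i) each dog independently emigrates with the
quarter-equivalent of 0.04/yr; (ii) a binomial number of immigrants —
current population size × quarter-equivalent of 0.23/yr — enters as intact
puppies (fair-coin sex, Bernoulli(0.45) confinement, age uniform below 8
weeks, fresh maturity/lifespan draws).

**Interventions.**  Surgical sterilization is a monthly quota event.  Four
strategies at three capacities (21/42/84 surgeries per month; level n
multiplies level-1 cells by 2^(n−1)):

| strategy | adult M | adult F | young M | young F |
|---|---|---|---|---|
| A mixed age, mixed sex | 6 | 13 | 1 | 1 |
| B young only, mixed sex | 0 | 0 | 7 | 14 |
| C female only, mixed age | 0 | 20 | 0 | 1 |
| D young females only | 0 | 0 | 0 | 21 |

A's cells are the government program's observed monthly mix.  B and C are
not printed anywhere: B reallocates the 21 surgeries to young dogs at the
program's overall 7M:14F sex ratio; C splits 21 female surgeries at the
program's 13:1 adult:young ratio among females, scaled by largest remainder
to 20 + 1.  Eligibility: adult females only *between heats* (never in heat
or pregnant), adult males in the reproductive state, young dogs of either
sex if intact; puppies are never operated on.  Unused quota in a cell is
forfeited — not reallocated, not carried over — so the strategies' targeting
contrasts stay sharp.  Sterilized states are absorbing.

## Time advance

The engine is a vectorized tick loop over the union of a weekly hazard grid
and every exact event time (quarterly migration, monthly surgery, yearly
recording, the horizon).  Per-dog scheduled events — weaning, maturity, heat
end, whelping, scheduled death — carry exact due times and fire when the
clock first crosses them, so the 18-day and 65-day durations are honored
exactly even though hazards tick weekly.  Because hazards compound
multiplicatively, the variable tick widths introduced by merging the grids
are exactly equivalent to a pure weekly clock.  Within a tick, kinds execute
in a fixed order (deaths → emigration → aging → reproduction → immigration →
surgery; within a kind, dogs in id order; simultaneous whelps in whelp-time
order), which makes replay under a fixed seed bit-identical.  Events
pending for dead or emigrated dogs are discarded lazily via the alive mask.

**Census convention.**  Yearly snapshots record the population immediately
*before* point events (the migration pulse, the surgery round) scheduled at
exactly the recording instant.  Recording after the coincident quarterly
immigration pulse would make every yearly census ride on top of a fresh
pulse of ≈185 immigrants that the following quarter's mortality largely
absorbs, systematically inflating the census ≈160 dogs above capacity; the
convention chosen reports the settled population.

## Initialization

The 2924-dog cohort (1222 F, 1702 M) is allocated to states by
largest-remainder rounding of the published proportions (females: 4% puppy,
11% young, 21% in heat, 6% pregnant, 21% not in heat, 37% spayed; males: 6%
puppy, 16% young, 64% reproductive, 14% neutered), giving exactly 452
spayed females and 238 neutered males.  Confinement is independent
Bernoulli(0.45).  Ages are maximum-entropy draws consistent with each state:
puppies uniform on [0, 8 wk), young uniform on [8 wk, maturity), adults
uniform on [maturity, scheduled lifespan) with the lifespan redrawn if it
could not exceed the required age.  Reproductive clocks start at a uniformly
random phase of their state (elapsed heat, gestation, or interestrus time),
so cycles are not synchronized at t = 0.  Initially pregnant females whelp
under the same capacity rule as later litters.

## Experiments and reproducibility

A scenario summary aggregates final population sizes over seeded replicates
(mean, SD with ddof = 1, median, min–max, percent change vs the *simulated*
base case — never a hard-coded reference).  Replicate r of every scenario
draws its generator from `SeedSequence(base_seed, spawn_key=(r,))`,
independent of scenario, so scenario contrasts and sensitivity grids are
seed-paired and differences are attributable to the manipulated factor.
1000 replicates is the full-fidelity setting; the bundled analyses,
acceptance checks and tests use 200 (60 for secondary comparisons) to keep
a full run on one CPU in minutes.  Sensitivity sweeps perturb one dotted
parameter path at a time; unknown keys and out-of-range values are fatal,
never silently ignored.

## What the model shows — and a structural caveat

With the default parameters, the base case is robustly pinned at community
capacity (mean ≈ 2923, SD ≈ 2): reproduction saturates the capacity rule.
Under this parameterization, however, the sterilization quotas at 21–84
surgeries/month leave the population pinned in most scenarios: total
turnover (age + non-age mortality + emigration, ≈ 0.3/yr here) fixes the
recruitment rate into the sterilizable young classes at roughly
0.5 × turnover × N ≈ 500 females/yr at capacity — regardless of how the
immigration flux is specified, because capacity-blocked births are displaced
one-for-one by immigrants — and that recruitment exceeds every level-1
quota.  Two further mechanisms blunt the surgical pressure: a newly matured
female always gets one pre-eligibility heat (surgery is restricted to
females between heats), and immigrant recruits refill the breeding pool in
proportion to N.  Only the young-focused strategies at the higher capacities
(B.3, D.2, D.3) push the population into visible decline within 20 years
(D.3 ≈ −57% and still falling at the horizon).  Because every flow in the
model is proportional to N, outcomes are essentially bistable —
capacity-pinned or deep decline — and intermediate 20-year means arise only
as transients of a slow exponential decline.  Conclusions about the
*relative* merit of targeting young females (D declines first and fastest at
matched capacity) are robust; absolute 20-year effect sizes are highly
sensitive to the unpublished lifespan rate and to how the immigration flux
scales with population size, and should be read with that caveat.

## What the synthetic start does not capture

The initial cohort reproduces the published marginal composition only:
confinement is independent of age, sex and sterilization; there is no
household structure; initial ages within a state are maximum-entropy, not
survey-derived.  Real acquisition and relinquishment decisions (owner
behaviour, economics, strays) are outside the model, so passing tests
demonstrate internal consistency and faithfulness to the stated rates, not
predictive validity for the real community.

## Numerical choices

Time unit years with 365.25 d/yr, 1 mo = 1/12 yr; event times rounded to
1e-9 yr for grid deduplication.  Truncated-exponential sampling by inverse
CDF (`a − log1p(−u·(1−e^{−λ(b−a)}))/λ`), degenerate min = max handled as a
point mass; SciPy's `truncexpon` serves as the independent oracle in tests
(KS < 0.01 at 1e5 draws).  Populations are stored struct-of-arrays with an
alive mask; dead rows are compacted away when they outnumber the living.
An extinct population is valid and simply stays at zero.
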