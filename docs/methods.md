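# Methods

## The colony model

`colonyfit` models a *C. elegans* colony on a finite food patch as a
deterministic, stage-structured projection in discrete one-hour steps.
Each generation *g* (1 = the P0 founders, 2 = F1, 3 = F2, …) is a vector
of expected counts over hourly age classes: one class per hour of the EGG,
L1, L2, L3 and L4 stages, then one class per hour of adulthood up to a
terminal absorbing class. A single transition matrix — a pure aging chain
with a unit sub-diagonal and an absorbing terminal entry — advances every
generation; eggs laid by generation-*g* adults (hourly fecundity by adult
age) are credited to generation *g + 1* at egg age 0. There is no
mortality and no density dependence: worms past the reproductive span
persist and keep eating, which is exactly the futile consumption the
analysis quantifies.

Food accounting is a side ledger, not a feedback: every hour the colony
consumes stage-rate-weighted counts (EGG 0, L1 1, L2 2, L3 4, L4 8, adult
16 units/h) from a 10-million-unit patch, the trajectory runs over the
full 200-h horizon, and the **bust hour** is read off afterwards as the
first hour at which cumulative consumption reaches the patch size.
Colonies are founded by worms placed in the final hourly class of the L4
stage, so founders molt to adulthood after one step.

Because the projection is linear, counts (and hence bust times) scale
exactly with founder number, and the relative composition of the colony
at any fixed hour is founder-independent. Two consequences worth keeping
in mind when reading sweep outputs:

* bust time is non-increasing in founder number and non-decreasing in
  patch size, automatically;
* the hour at which one generation's L1 pool overtakes the previous
  generation's is a property of the life history alone — founder number
  only decides *where along that fixed timeline* the bust lands. With a
  170-egg brood and the stage rates above, a 10^7-unit patch cannot be
  exhausted by founders plus F1 alone before F2 larvae hatch, nor by a
  single founder's colony before F3 larvae hatch, for any stage durations
  that keep bust inside the 200-h horizon. The model therefore predicts
  the dauer-forming L1 pool to be F2 at high founder numbers and F3 at
  low ones: low-founder colonies traverse one more generation before
  bust, but the absolute generation labels sit one generation later than
  the labels usually quoted for this experimental design, and no
  parameterization of this model family can shift them back.

### Validation against an individual-based oracle

On configurations with integer hourly fecundity the expected-count
projection coincides exactly with explicit per-worm bookkeeping. The test
suite re-implements the dynamics as an event list (every worm and every
egg an explicit record) and requires bitwise-equal hourly counts per
(generation, age class) across randomized small configurations. This
catches off-by-one errors in stage boundaries, molt timing and egg
crediting that aggregate statistics would mask.

### Default life-history parameterization (25 °C)

The stage durations and egg-laying schedule are package defaults, fully
overridable from a YAML/JSON config; published stage timings at 25 °C
constrain them only loosely, so they were fixed once against the model's
calibration targets (strictly decreasing bust times over founders
1→200; the pre-dauer pool maximal at 50 founders and minimal at 3) and
then frozen:

| parameter | default | note |
|---|---|---|
| EGG | 9 h | embryogenesis to hatch; eggs do not feed |
| L1 | 14 h | |
| L2 / L3 | 8 h / 8 h | |
| L4 | 10 h | founders start in this stage's final hour |
| adult classes | 160 h | terminal class absorbing and post-reproductive |
| brood | 170 eggs | 200 founders × 170 = 34,000 F1 |
| reproductive span | 120 h (5 days) | |
| egg-laying shape | onset 8 h after the molt, linear ramp to a peak at adult age 30 h (day 2), exponential decay (28-h scale) | unimodal |

The 8-h oviposition onset reflects the lag between the adult molt and the
first laid egg; together with the day-2 peak it is what places the five
default bust hours (187, 166, 147, 124, 98 h for 1, 3, 10, 50, 200
founders) so that the pre-dauer pool ordering comes out as above. Up to
four generations are tracked; eggs of deeper generations are pooled into
the fourth with a logged warning (at the default horizon this only
happens well after bust).

### Structure statistics

`structure_at` aggregates age classes into stage × generation counts;
proportions are over hatched worms, with eggs tallied separately.
`dominant_l1_generation` is the argmax of L1 counts over generations
(ties to the lower generation), `predauer_pool` is L1 + L2. The
futile-consumption share is this package's operationalization of a verbal
concept: the fraction of pre-bust consumption due to (i)
post-reproductive adults at any hour plus (ii) all stages other than
L1/L2 during a final window before bust (default 10 h — roughly the time
an egg needs to reach L1, i.e. the stages that can no longer enter the
pre-dauer pool in time), counted without double-counting.

## The assay pipeline

Plate-level inputs follow the wet protocol: dauers are SDS-selected,
resuspended in a known volume, and counted in three 1-ml aliquots, so the
plate estimate is `mean(count1..3) × volume_ml`. The suspension volume has
no default — scaling is impossible without it. Contaminated plates are
excluded from every statistic. Group summaries are mean ± sample SD with
n; empty cells are reported as missing, never imputed.

Comparisons use one-way (founder) or two-way (founder × timepoint) ANOVA
via OLS, followed by Tukey's multiple comparisons. Pairwise tests use the
Tukey–Kramer studentized-range statistic q = |Δmean| / √(MSE/2·(1/nᵢ+1/nⱼ))
with the residual MSE and df pooled from the fitted model (for the
two-way design, comparisons between founder numbers are made within each
timepoint against the model-wide error term). The test suite checks both
F and q/p against an independent raw sums-of-squares computation to 1e-8
relative.

Peak identification in yield time courses takes the timepoint with the
maximal mean, ties toward the earlier timepoint (conservative about
post-peak dauer loss). The dauer-length recovery check computes
per-timepoint means, a one-way ANOVA, and flags a latest-vs-earliest mean
increase; groups under 15 worms warn but do not abort. Lawn QC summarizes
area (cm²) and OD600 with optional pass/fail tolerance bands. The
trade-off table ranks founder numbers by mean bust time (speed rank 1 =
fastest) and by mean yield at a reference timepoint (default 72 h); the
trade-off flag is raised when speed is monotone in founder number while
yield is not.

## The synthetic-data generator

The generator emulates the assay's raw data so the pipeline is fully
testable without the original measurement tables. Anchors are the printed
group statistics: bust means 159 h (1 founder) and 51 h (200), with
intermediate founder numbers interpolated log-linearly (only the ordering
is load-bearing); 72-h yield means 1540 / 2837 / 310 / 232 / 1050 for
founders 1 / 3 / 10 / 50 / 200; a time-course shape rising from 48 h to a
peak at 144 h and declining at 168 h; lawn area 9.9 ± 0.48 cm² and OD600
0.346 ± 0.020; dauer lengths around 400 µm (arbitrary µm-like scale) with
a +40 µm shift from 144 h on.

Noise is an emulation choice, declared rather than measured. Bust times
are normal (SD 5% of the mean) truncated at zero. Dauer yields vary
severalfold between trials, and that variation is attributed to trial
conditions, so the yield noise decomposes into a mean-one lognormal
between-replicate batch multiplier (CV 0.35) shared across a replicate's
whole time course plus a smaller within-plate lognormal factor (CV 0.15)
— total plate-level CV ≈ 0.39, consistent with the printed 72-h ranges
(e.g. 1400–4400 at 3 founders). Aliquot counts are Poisson at
yield/volume (default suspension volume 5 ml, arbitrary and declared).
All randomness flows through one seeded generator; identical seeds give
byte-identical CSVs.

What passing the round-trip tests shows — and what it does not: recovery
of the speed ordering, the trade-off flag and the 144-h peak demonstrates
that the pipeline is consistent and sensitive at the assay's replication
levels, under this noise model. It says nothing about unmodeled features
of the real assay (batch structure beyond a single multiplier, counting
biases, dauer burrowing or escape, correlations between bust time and
yield), and the generator deliberately does not couple the matrix model
to the synthetic yields: the mechanistic model does not predict the
empirical yield pattern, and pretending otherwise would launder a model
limitation through the data generator. At n = 3 replicates the peak is
recovered in ~90% of seeds; the orderings and the trade-off flag are
recovered essentially always.

## Numerical and interface choices

Counts are float64 expectations; no rounding is applied anywhere in the
projection. Time is integer hours throughout — hours since founding in
the simulation, hours post bust in the assay (`*_hr` columns; no mixed
clocks). Hour-t consumption is computed from the state at t−1 (hour 0
consumes nothing), making cumulative consumption at hour t the integral
over (0, t]. Degenerate inputs are handled explicitly: zero founders give
a valid all-zero trajectory; a patch of zero busts at hour 0; a colony
that never busts reports `bust_hr = None`; an all-adult colony has an
undefined dominant L1 generation (an error, not a silent 0). CSV schemas
are validated header-first (a bad header rejects the file, bad rows are
reported with row numbers), and every CLI run writes a JSON manifest with
a config digest and seed.

## Problem sizes used in tests

Oracle comparisons run on ≥20 randomized configurations with ≤5 founders
and ≤50-h horizons, where enumeration is exact and fast. Default-config
sweeps (5 founder numbers × 200 h × 4 generations × 204 age classes) take
well under a second. Large-sample parameter recovery uses 1000 synthetic
replicates per founder number with a 5% tolerance on recovered group
means.

## Known limitations

* No feedback of food scarcity or crowding on development, no mortality,
  no explicit dauer stage: dauer yield is proxied by the L1(+L2) pool at
  bust. Linearity is exact in founder number as a result.
* The absolute generation labels of the dominant L1 pool at bust are
  structurally pinned one generation later than the conventional labels
  for this assay (see above); the model's reliable prediction is the
  *relative* shift between low and high founder numbers.
* Default stage durations and egg-laying dynamics are calibration
  stand-ins at 25 °C, not literature measurements; all are overridable.
* The generator matches printed group means and ranges only; true
  replicate-level distributions of the original assay were not available
  to fit.
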