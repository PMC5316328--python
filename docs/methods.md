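# Methods

## Population model

The state is the spring abundance `N` (thousands) together with the current
DAYS covariate (count of days above freezing in May in Svalbard). One step
runs spring to spring in the order recruitment → harvest → natural
survival:

```
pre = N · (1 + r)
N'  = max(0, (pre − min(h, pre)) · s)            (deterministic core)
N'  ← N' · Lognormal(−σ_proc²/2, σ_proc)         (stochastic variant)
```

The ordering is a modelling choice (the annual monitoring cycle fixes what
is known when, not the accounting order): young are produced on the breeding
grounds in summer, the autumn hunting season removes birds from the
post-recruitment population, and overwinter natural mortality acts on the
remainder. Harvest is treated as fully additive — no compensatory mortality —
which is conservative and consistent with the weak density dependence
evident in this population at current sizes. The lognormal process error is
mean-corrected (log-mean −σ²/2) so the stochastic step is unbiased for the
deterministic core; this makes open-loop projections agree in expectation
with the deterministic recursion used in calibration.

Nine models form the 3×3 factorial over survival form × reproduction form,
each form one of {constant, DAYS, DAYS + density}:

```
logit s = α₀ + α₁·z·[DAYS] − α₂·(N/K)·[density]
log  r  = γ₀ + γ₁·z·[DAYS] − γ₂·(N/K)·[density]
```

with `z = (DAYS − mean)/sd` standardized against the climatology so that
coefficients are comparable across models, and density entering through
`N/K` with a negative sign (crowding can only depress the rates; α₂, γ₂ ≥ 0).
The factorial layout is the natural reading of "nine models spanning
temperature and density effects on survival and/or reproduction"; the
aggregate feature probabilities (density-dependent survival,
density-dependent reproduction, any DAYS effect) are sums over the
corresponding factorial margins (3, 3 and 8 of the 9 models respectively).
The models act on total N, with the adult/young split `A = N/(1+r)`,
`Y = N·r/(1+r)` derived where needed (the policy tree).

## Default parameters and calibration

One ParameterSet parameterizes all nine models (terms are simply dropped
where a form lacks them). Defaults, all configurable:

| parameter | default | why |
|---|---|---|
| survival s̄ (α₀ = logit s̄) | 0.95 /yr | long-lived goose; the calibration absorbs this choice into γ₀, so the projection anchors are insensitive to it |
| γ₀ | calibrated (r = 0.1698) | see below |
| α₁, γ₁ (DAYS, per SD) | 0.1, 0.2 | modest spring-advancement effects, reproduction more weather-sensitive than adult survival |
| α₂, γ₂ (density, per N/K) | 0.1, 0.1 | weak: little density dependence is evident at current population sizes |
| K | 80 thousand | density scale near the observed 2013 peak |
| σ_proc (process SD, log) | 0.05 | ~5% interannual environmental variability |
| obs CV | 0.05 | ground "total counts" are precise to a few percent in good years |
| climatology | mean 10, SD 4 days, integer support 0–26 | spread wide enough that DAYS is informative without dominating the dynamics |

`calibrate_defaults` anchors γ₀ to the published planning facts: the
deterministic baseline (constant-rates model) trajectory from 81.6 thousand
under a constant 11.3 thousand/yr harvest must first cross the 60-thousand
target after 8.5 years (midpoint of the published 8–9-year projection),
crossing time interpolated linearly between years. Crossing time is strictly
increasing in r, so a bracketed scan plus Brent root find on r ∈ (0, 1) is
well posed. The same parameter set then puts the deterministic crossing
under a 15 thousand/yr harvest at 3.6 years, inside the published
"after 3 years" claim without further tuning — the consistency of the two
claims under one parameter set is the point of the calibration.

## Weight updating

The observation model is multiplicative: observed = predicted · exp(ε),
ε ~ N(0, cv), i.e. a lognormal likelihood with log-sd equal to the count CV
and log-median at the model's prediction. Each model's prediction is the
deterministic transition from last spring's observed state under the
realized harvest; integrating the likelihood over process error is not done
(the process SD is small relative to the count CV at the default settings,
and the deterministic prediction keeps the annual update a closed-form
one-liner). Updates are exact Bayes with renormalization; weights below
1e-12 are floored to zero to avoid underflow over century-scale simulated
runs. A degenerate update (every density underflows to zero) raises; the
closed-loop simulator catches that one case and carries the prior forward a
year.

The update uses the spring count: the May survey is the last datum to
arrive before the June decision, and the one-step-ahead prediction targets
exactly that quantity.

## Utility and optimization

Utility over next spring's abundance is the Gaussian kernel
`exp(−(N−60)²/(2·8.493²))`, with the shape SD set so utility is exactly ½ at
the 50- and 70-thousand band edges. The objective is population-based only —
no harvest-yield term; the symmetric penalty already discourages quotas
beyond need. Multiplying the utility by a positive constant provably leaves
the argmax policy unchanged, so only the target and band matter.

The optimization is passive-adaptive: the policy is computed conditional on
the current weight vector and recomputed after each annual update; weights
are not part of the dynamic-programming state, which keeps the state space
two-dimensional, and there is no value-of-information (dual-control) term.
Value iteration runs on grids N = 0–150 by 2.5, DAYS = 0–24 by 2, quota
= 0–30 by 2.5 (thousands), discount 0.95, sup-norm tolerance 1e-6, max 1000
iterations (discounting guarantees geometric convergence; non-convergence
raises with the gap). Current DAYS is part of the decision state (known by
June); next year's DAYS is an independent climatology draw, so the
continuation value enters only through its DAYS-expectation — this is what
keeps the per-model transition kernels small enough to precompute once and
re-mix per year as the weights move. Process error is discretized by
lognormal bin masses at the midpoints between abundance nodes (the
deterministic limit splits the point mass linearly between bracketing
nodes); a zero deterministic core is absorbed at N = 0. State lookup snaps
to the nearest grid node, ties toward the lower node, out-of-hull states
clamped.

The policy tree is a greedy variance-reduction (CART) regression tree fit to
the (A, Y, DAYS) → quota samples of the full table, leaf values snapped to
the action grid. A and Y are derived from N at the calibrated mean
reproduction rate, so they are collinear by construction — the tree may
split on either, which mirrors how the field summary is read. At depth 6 the
tree reproduces ~98% of table entries under the default configuration.

## Assessment and decision support

Quotas cross the interface in individuals (rounding unit 100); optimization
runs in thousands. Allocation between Norway (30%) and Denmark (70%) uses
largest-remainder apportionment on rounding units, ties broken
alphabetically, so parts always sum to the rounded total — 6 700 splits to
exactly 2 000 / 4 700. The emergency closure fires when the standing block
quota is positive and the model-averaged expected next spring falls below
the threshold (default: the 60-thousand target itself, matching the 2015
decision narrative; the band floor is available via configuration). A zero
quota never triggers closure. Decisions are deterministic functions of
(record, weights, config) and the decision log is append-only: revised
counts enter only the next cycle, decisions already issued stand.

The Chapman mark–resight estimator `(M+1)(n+1)/(m+1) − 1` with its standard
variance provides the independent abundance check against neckband
resightings; it is finite at zero recaptures.

## Projection and closed-loop evaluation

Open-loop projections sample one structural model per trajectory from the
weight vector (between-trajectory spread then expresses structural
uncertainty, which is what makes the published projection fans wide);
per-step model averaging is available behind a flag. DAYS are i.i.d.
climatology draws and process error is applied each step. `years_to_target`
is the per-trajectory first year with N ≤ target (infinite when never
reached); the headline statistic is its median over trajectories. Realized
harvest equals the quota except for the truncation at the post-recruitment
population.

The closed-loop simulator plays truth model → noisy spring count → weight
update → quota decision → realized harvest, year over year, and scores
long-run mean abundance, the fraction of years inside the band, mean
harvest, closure frequency and the weight trajectory of the truth model.
Annual re-optimization reuses the precomputed per-model kernels and
warm-starts the value function from the previous year, so a 500-year
single-trajectory run with annual re-optimization takes seconds. Problem
sizes in the shipped tests and the acceptance script — 5 000 trajectories
for open-loop medians, one 500-year closed-loop trajectory, 2 000-trajectory
property checks — were chosen as the smallest sizes at which the reported
medians are stable to ±1 year across seeds.

## What the synthetic generator does and does not emulate

It reproduces the statistical structure the analysis assumes: true dynamics
under a chosen truth model, spring/autumn counts with lognormal error, an
optional per-year spring undercount (the range-shift "stumble"; the shipped
2015 scenario removes 16% of the spring count in one year, of the order of
the 11–12 thousand birds missed historically), proportion young from the
reproduction rate, and harvest split by the country shares. It does not
emulate site structure or the Finland/Sweden range shift itself (only its
undercount footprint), resighting-effort dynamics, partial controllability
of the harvest (hunters' realized kill equals the quota unless truncated),
or correlated DAYS sequences. Passing tests therefore demonstrate that the
pipeline recovers structure from data satisfying its own assumptions —
convergence of model weights on real monitoring data can be slower and can
stall where models make similar predictions near the target, as indeed the
closed-loop runs show once the population is regulated.

## Numerical choices and degenerate inputs

Negative abundance or harvest raise domain errors; harvest is truncated at
the post-recruitment population so the state stays non-negative. The
climatology folds normal tail mass into its end bins and renormalizes.
Value-iteration ties (equal Q) resolve to the smallest quota; grid-lookup
ties resolve to the lower node. The calibration raises when no reproduction
rate in (0, 1) can match the requested crossing time. All random draws flow
through `numpy.random.Generator` seeded at the call boundary; identical
seeds give bit-identical trajectories, decisions and metrics.

## Known limitations

Parameters are fixed per model — the system learns model weights, not
coefficients; there is no hierarchical estimation from ring-resighting
data. The objective has no harvest-yield or stability term, so the policy is
knife-edged near the target (mirrored in the real system's swings between
ample and closed seasons). The published 2016 tree thresholds and
model-weight time series depend on unpublished posteriors and are out of
scope; the acceptance anchors are the printed planning quantities instead.
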