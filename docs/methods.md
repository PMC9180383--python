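# Methods

## Scope and model

The package computes the monetary health benefit per gram of dioxin-like
compound (TEQ) emissions avoided, via a reduced-form impact pathway:
exposure dose → excess cancer risk → expected cancer deaths → monetized
mortality → per-gram benefit. It starts from a *given* dose table
(lifetime average daily dose, LADD, by age group and region): atmospheric
dispersion, settling and multimedia transport — the processes that produce
such dose tables — are out of scope, as are cost-side modelling and
cancer-type-specific dose–response.

Assumptions inherited from the reduced-form approach:

- **Uniform mixing.** A gram emitted anywhere in a region is assigned the
  same per-gram damage; regional heterogeneity enters only through each
  region's own dose table and emission base.
- **Linear, no-threshold dose–response.** Risk is `LADD × CSF` with a single
  cancer slope factor for all ages; age differentiation enters through the
  dose (dietary and inhalation patterns), not the slope.
- **Time-constant exposure.** Doses are keyed by (age group, region) only.
  All packaged dose tables are period-constant, and the projection keeps
  them fixed; only population, VSL and emissions vary over periods.
- **Static expected-value accounting.** Expected deaths are products of
  point-estimate risks with population counts; no cohort dynamics, latency
  or cessation lag.

## Parameters

| parameter | unit | default | notes |
|---|---|---|---|
| CSF | per (pg-TEQ/kg/day) | 1.0×10⁻⁴ | TCDD-based slope factor |
| mortality risk | — | 0.2278 | 1 − all-cancer survival rate (0.7722) |
| VSL base | 10⁶ USD | 11.79 | base-year hedonic-wage estimate |
| earnings elasticity ε_W | — | 0.2476 | applied to % wage change |
| wages (base→target) | USD/month | 1317.18 → 1385.64 | +5.20% |
| CPI (base→target) | 2015=100 | 98.93 → 102.55 | deflation factor 0.9647 |
| exchange rate | TWD/USD | 31.807 | applied only to TWD inputs |
| discount rate | /year | 0.02 | geometric, period-averaged |
| regional shares | — | 0.4448 / 0.2488 / 0.2770 / 0.0246 | sum 0.9952 |

The VSL transfer is `VSL_t = VSL_b × (1 + ε_W · %ΔW/100)` followed by CPI
deflation `× CPI_b / CPI_t`; both factors are multiplicative so their order
is irrelevant, and the composed factor is tested exactly.

### VSL schedules

Two conventions are supported. `geometric_annual` builds
`vsl[i,t] = base[i] × mean_{y∈t} (1+r)^−(y−y₀)` — the transparent choice for
synthetic scenarios. The packaged Taiwan scenario instead carries its
published per-period schedule verbatim (`fixture` convention): that
schedule embeds a per-age averaging within each group (its inter-period
decay is ≈0.76% per 5 years, much slower than 2%/yr compounding) whose
per-age inputs are not published, so it cannot be re-derived and is not
guessed. All downstream published values flow from the published schedule.

## The packaged Taiwan scenario

Five regions (northern, central, southern, eastern, plus the national
aggregate as a first-class region), three age groups, a 2020 base year and
ten 5-year periods to 2070. Emissions: 57.8 g TEQ/year nationally,
apportioned 5.7628 / 19.3798 / 31.9743 / 0.6832 g by the regional share of
simulated settling. The policy path halves emissions linearly by 2046–2050
and reaches 10% of base by 2066–2070; the baseline path holds 2020 levels.
All values are stored exactly as published (strings parsed once).

Two cells require care, both flagged in `fixtures/taiwan.py`:

- the national children's dose is stored back-derived as `risk / CSF`
  because the published dose value is inconsistent with its published risk
  (and with everything downstream of the risk);
- the northern children's monetized-mortality value for 2026–2030 was
  partially illegible in our source; the net-benefit table pins it to a
  ~US$30 interval and the surviving digits identify it uniquely (42,378).

### Reproduction mode: quantized expected deaths

The published monetized-mortality table was produced by rounding expected
deaths to 4 decimal places (10⁻⁴ persons) before multiplying by the VSL.
This is invisible where expected deaths are large, but dominates small
cells: the eastern children's base-year value (US$219) is 28% below the
continuous-chain value (US$305), and the eastern older-adults series jumps
38% between adjacent periods purely because 0.00025 rounds differently on
either side. `compute_monetized_mortality(..., deaths_decimals=4)`
reproduces every published cell to within US$1.16 (whole-dollar print
rounding); the package default keeps the chain continuous (fractional
expected deaths, no intermediate rounding), which is the better-behaved
estimator and differs from the published national headline by 0.002%.

## Benefit-per-gram engine

Group, region and national per-gram values divide the (summed) monetized
burden by the region's emissions in the period. The net per-gram benefit of
a reduction plan is `mdc × (1/E_policy − 1/E_baseline)` — the same burden
priced against both emission masses. It is zero when the paths coincide,
positive whenever the policy path is below baseline, strictly increasing in
reduction depth, homogeneous of degree −1 in emissions, and additive over
age groups; all five properties are tested, the first four on random
scenarios against a scalar-loop oracle at rel. 10⁻¹².

Cumulative values are plain arithmetic sums of per-period net values —
no discounting across periods beyond what the VSL schedule already embeds.

## Synthetic scenarios

`generate_scenario(SynthConfig(...))` draws: log-uniform doses (spanning
the orders of magnitude seen across real regions), uniform national
populations declined geometrically (default 2.8% per 5-year period,
matching a ~25% fall over 50 years), Dirichlet regional shares, sorted
uniform VSL bases (older adults valued highest) discounted geometrically,
uniform regional emission bases with the national base as their sum, and a
single linear reduction segment to a configurable fraction of base.
Identical seeds give bitwise-identical scenarios.

The generator emulates magnitudes and monotone structure only: it has no
cohort demography, no spatial correlation between dose and emissions, and
no VSL–income linkage. Passing property tests on synthetic scenarios
therefore demonstrates algebraic correctness of the pipeline, not
predictive validity on real data.

## Uncertainty sweeps

`run_sweep` perturbs exactly one parameter (VSL, population, CSF, mortality
risk or dose; optionally scoped to an age group and/or period, or an
absolute replacement population table), re-runs the full pipeline and
reports signed percent changes of a chosen per-gram value. Because the
chain is a product of the perturbed factors, uniform multiplicative sweeps
move the benefit exactly proportionally (a ±11.5% VSL interval maps to
±11.5% in BPT, assertable to machine precision), and scoped population
sweeps move it by the scoped cells' share of the monetized burden.
`tornado_summary` ranks parameters by largest absolute percent change,
ties broken alphabetically. High/low-variant population projections are
supported only as user-supplied replacement tables; none are packaged.

## Numerical choices

- Money is double-precision USD throughout; nothing is rounded until report
  formatting. Comparisons against published whole-dollar tables use
  relative tolerance 10⁻⁴ plus US$2 absolute slack per cell (print
  rounding); cumulative sums widen the absolute slack by US$2 per summed
  period.
- Emissions must be strictly positive wherever a per-gram value is formed;
  zero emissions raise a division-guard error rather than producing inf.
- Regional shares may sum below 1 (long-run averages rounded
  independently); validation warns only when the sum deviates from 1 by
  more than 0.01, and errors when it exceeds 1.
- Trajectory segments are continuous, non-increasing, and must tile the
  period axis; regional paths scale proportionally from regional bases.
- Scenario bundles round-trip losslessly (`%.17g` CSV floats, round-trip
  parsing).

## Known limitations

- Per-gram damages are spatially uniform within a region; relocating
  emissions between regions changes nothing at the national level.
- The dose tables are treated as exogenous and time-constant; any secular
  trend in exposure pathways is outside the model.
- The mortality risk is an all-cancer, all-age aggregate; no cause-specific
  or age-specific survival.
- Cumulative net benefits are undiscounted sums across periods, so they
  overweight distant periods relative to a present-value criterion.
- The packaged eastern-region published values are dominated by the
  deaths-quantization described above; analyses of small populations should
  use the continuous default, not the reproduction mode.
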