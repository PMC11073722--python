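# Methods

This note documents the models, numerical choices and limitations of
`fawphen`. It is written for users who need to know exactly what the
package computes before trusting its output.

## Temperature-response curves

All traits are deterministic functions of temperature in °C; rates are
per day. The catalog holds the curve families used for the fall
armyworm plus two baselines (a Taylor-type Gaussian rate curve and a
straight line) for model comparison:

| trait | curves | output |
|---|---|---|
| development rate | Logan-1, Logan-5, Hilbert–Logan-2, Taylor, linear | 1/day, clamped ≥ 0 |
| stage mortality | Wang-1, Wang-2, log-Gaussian | probability, clamped to [0, 1] |
| lifetime fecundity | simple Gaussian | eggs/female, clamped ≥ 0 |
| adult senescence | exponential, Hilbert–Logan-3 | 1/day, clamped ≥ 0 |
| oviposition timing | cubic-exponential O(E) on normalised age E | fraction in [0, 1] |
| development-time scatter | logit CDF in log time | probability |

Clamping matters because two of the shipped mortality fits are
degenerate at the edges: the egg-stage Wang-2 has nearly coincident
lower and upper thresholds (a plateau), and the pupal log-Gaussian
exceeds [0, 1] far from its centre.

**Domain convention.** Each curve carries a validity interval
`temp_domain`. Outside it, development and fecundity evaluate to 0 and
mortality to 1, so maps over extreme climates degrade gracefully
instead of extrapolating. The reference parameter set uses
[12, 35] °C: the lower developmental threshold reported for
*S. frugiperda* is typically 12–14 °C, and the fitted pupal rate
vanishes above its own T_max ≈ 33.2 °C. The experiments behind the
parameters cover only 20–32 °C, so everything outside that range is
model extrapolation tempered by this convention.

## Fitting

`fit_response` minimises weighted least squares with
`scipy.optimize.least_squares` (trust-region reflective, box bounds).
Logan-family surfaces are multimodal, so fitting is multi-start: 16
Latin-hypercube points in the catalog's data-driven parameter box plus
one heuristic start (e.g. x₀ ← argmax y for Gaussians,
T_max ← max T + 2 for Logan curves). All 17 starts get a cheap
exploration budget; the three best solutions are refined to
convergence (relative tolerance 1e-10, iteration cap 500·(k+1)
function evaluations). The Latin-hypercube seed is a package constant,
making every fit a deterministic function of its inputs.

Reported statistics: R² = 1 − RSS/TSS, AIC = n·ln(RSS/n) + 2k, and a
p-value from the F-test against the mean-only model. AIC dialects
differ between software packages; comparisons of absolute AIC values
across programs are not meaningful, rankings within one program are.

The plain Gaussian's amplitude is constrained positive during fitting:
in this catalog it models peaked responses (a thermal optimum), and
with only five temperature points an unconstrained fit can prefer an
inverted-well solution that is numerically better but biologically
wrong for fecundity. Troughs (minimum-mortality temperatures) are the
role of the Wang and log-Gaussian curves.

Model ranking is by ascending AIC, near-ties (ΔAIC < 0.01) broken by
descending R², non-converged fits last. A caution on model selection:
with few points AIC cannot reliably separate nested curves (the
4-parameter Gaussian contains the 3-parameter Taylor curve; at n = 9
the extra parameter wins by chance roughly 20% of the time). The
package's model-comparison property tests therefore use shape-distinct
candidate sets, and users comparing nested curves should expect
selection noise at small n.

**Development-time distribution.** Durations are modelled as
logistic in log time, i.e. F(x) = 1/(1+e^{−(a + b ln x)}) with median
e^{−a/b}. The fit is by maximum likelihood; in *absolute* mode one
slope b is shared across temperatures with a per-temperature intercept
a_i, in *normalized* mode times are first divided by the
per-temperature median and a single intercept (≈ 0) is fitted. A point
mass of durations sends the ML slope to infinity; it is capped at 1e4
and flagged degenerate.

## Cohort simulation and life-table parameters

**Mechanics (daily step).** Each individual accumulates physiological
age r_s(T_d) per day in stage s, transitioning when the accumulation
reaches its threshold — 1 in deterministic mode, a draw
θ = e^{z/b} (z standard logistic) from the stage's time distribution in
stochastic mode. Accumulation carries fractionally across stage
boundaries within a day, so total immature time at constant T is
Σ_s 1/r_s, not the sum of per-stage ceilings. Daily survival is
(1 − m_s(T_d))^{r_s(T_d)}; over a complete stage at constant
temperature the product is exactly 1 − m_s(T). Adults accumulate the
senescence rate and die at threshold (1 deterministic, sampled
otherwise); a female's day-d egg output is F(T_d)·[O(E_d) − O(E_{d−1})]
with E her senescence accumulation normalised by her threshold, so
oviposition compresses at warm temperatures. Sex is assigned at birth
with probability `sex_ratio` (default 0.5). Deterministic mode applies
stage mortality as a quota kill — round(n·m_stage) individuals removed
on the stage's completion day — so a fixed series is bit-reproducible
without random draws; stochastic mode is reproducible given its seed.

**Constant-temperature schedules.** For life-table parameters at
constant T the package skips individuals entirely and builds the
schedule in continuous age: immature duration Σ 1/r_s, survival
Π(1 − m_s), adult reproduction on a 0.1-day grid up to senescence 1.
This removes integer-day quantisation and makes r_m(T) smooth in T —
important because the λ(T) lookup and the unimodality of r_m(T) are
downstream consumers. For daily series the schedule walks the series
with fractional-day stage boundaries.

**Euler–Lotka.** r_m solves Σ e^{−r x} l_x m_x = 1 by bracket expansion
+ Brent, then a Newton polish; the residual at the root is < 1e-10.
The identities λ = e^{r_m}, D_t = ln 2/r_m, T_c = ln(Ro)/r_m hold by
construction on every output.

**Non-viable environments.** Where no schedule exists (no development,
certain death, or zero fecundity) the result is flagged `non-viable`
and r_m reports the cohort's exponential decline rate over a 180-day
horizon (a stage that cannot complete holds the cohort at its daily
mortality), floored so the value is finite. Maps need a finite λ
everywhere; the activity index additionally floors λ (below).

**Scope caveat.** Ro and GRR values reported by stochastic life-cycle
simulators depend on adult-survival bookkeeping conventions
(pre-oviposition discounting, how senescence couples to the fecundity
schedule) that differ between implementations and are rarely fully
documented. This package's Ro/GRR are internally consistent (GRR ≥ Ro,
identities exact) and its r_m(T) curve matches the published values
closely at 20/28/32 °C, but absolute Ro/GRR should not be compared
across implementations.

## Risk indices

Daily years are interpolated linearly between mid-month (15th) anchors,
wrapping December→January; tmean = (tmin+tmax)/2; 365-day year, no
leap handling.

* **ERI** = (1/365)·Σ I_i with I_i = 1 when every immature stage has
  positive development and survivable mortality at tmean_i. An
  alternative convention — the mean daily product of stage survivals —
  is available via `method="survival"`. The binary convention is the
  default because it is scale-free and reproduces the expected
  equatorial-belt pattern; the choice is a documented convention, not
  an empirical result.
* **GI** = Σ_x 1/T(x), where T(x) is the generation length started on
  Julian day x following the (cyclically wrapped) series: immature
  rate summation to completion plus adult senescence accumulation to
  the median-oviposition age E* (O(E*) = ½, solved once by Brent).
  Start days whose generation cannot finish within two years
  contribute 0. Lengths are continuous (fractional-day boundaries), so
  a constant series gives exactly GI = 365/T.
* **AI** = Σ_x log₁₀ λ(tmean_x). λ(T) comes from a precomputed
  constant-temperature lookup on a 0.5 °C grid with linear
  interpolation (AI changes < 0.1% at 0.25 °C), floored at
  λ_min = 0.5 (configurable) where the population is non-viable so a
  single arctic day cannot send AI to −∞.

Classification uses two cut points per index (defaults: ERI 1/3 and
2/3, GI 4 and 8 generations/yr, AI 10 and 25); the source study prints
no breaks, so classed maps are qualitative. Pixel areas use the
spherical approximation (111.320·Δlon)·(110.574·Δlat)·cos(lat) km².

Raster I/O uses the ESRI ASCII grid format (one text file per monthly
band) with plain WGS84 cell metadata — portable, diff-able and
readable by any GIS.

## Synthetic data

The generators exist so the whole pipeline is testable without any
external download, and they default to the study design: 100 neonates
per temperature at 20/25/28/30/32 °C and 30 adult pairs, with the
published fits as the truth model (shipped as a versioned JSON file).
Durations are logistic-in-log around the truth medians (matching the
logit CDF), deaths Bernoulli from the truth mortality curves, lifetime
fecundity negative-binomial (Gamma shape 5 — moderate overdispersion
typical of egg counts) around F(T) and allocated to days by ΔO(E), and
egg durations under one day are recorded as 0.5 d (sub-daily hatching).
Weather series add one Gaussian day-to-day anomaly to a mid-month
interpolated seasonal cycle (default: a coastal West African climate);
climate rasters carry a linear meridional gradient, a sinusoidal
seasonal cycle and an exact-count nodata mask.

What the generators do **not** emulate: instar structure, host-plant
and humidity effects, diurnal temperature cycles within a day,
correlated measurement error, or migration. Passing recovery tests
therefore show the estimation machinery is unbiased under the model's
own assumptions — not that the model captures everything in real
rearing data.

## Known limitations

* The five-parameter Logan-5 curve cannot be refitted from a
  five-temperature design (more parameters than degrees of freedom);
  the workflow then selects among the remaining development-rate
  curves.
* Development-rate curves evaluated under fluctuating temperatures
  feel rate averaging (Jensen's inequality): cohort statistics under a
  wide-amplitude series legitimately differ from constant-temperature
  expectations at the same mean.
* The daily step caps effective development at one stage boundary
  resolution; sub-daily temperature cycles are not modelled.
* λ(T) for the activity index is computed from the deterministic
  schedule; stochastic variation in λ is not propagated into maps.
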