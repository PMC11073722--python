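# fawphen

Temperature-driven phenology modelling and climate risk indices for the
fall armyworm, *Spodoptera frugiperda* (Lepidoptera: Noctuidae) — an
invasive pest of maize and other crops across Africa. The package is
aimed at quantitative entomologists and pest-risk analysts who want to
go from stage-structured life-table experiments at constant
temperatures to maps of where, and how strongly, a pest can establish
under a given climate.

## What it computes

**Temperature responses.** Each life-history trait is a parametric
curve in temperature *T* (°C): development rates follow Logan-type and
Hilbert–Logan models, e.g. Logan-1

    r(T) = Y·(e^{pT} − e^{pT_max − (T_max − T)/v}),

stage mortalities follow Wang or log-Gaussian wells, lifetime fecundity
a simple Gaussian F(T) = y₀ + a·exp(−½((T−x₀)/b)²), adult senescence
exponential or Hilbert–Logan curves, and the scatter of development
times a logit CDF in log time, F(x) = 1/(1 + e^{−(a + b ln x)}).
Curves are fitted to life-table summaries by multi-start nonlinear
least squares and ranked by AIC (= n·ln(RSS/n) + 2k) with an R² tie-break.

**Demography.** A cohort accumulates physiological age r_s(T_d) per day
(rate summation); daily survival is (1−m_s(T_d))^{r_s(T_d)}; adults age
at the senescence rate and lay F(T_d)·ΔO(E) eggs per day, with O(E) the
cumulative oviposition fraction at normalised reproductive age E. From
the resulting age schedule (x, l_x, m_x) the package computes the net
reproductive rate Ro = Σ l_x m_x, the gross reproductive rate
GRR = Σ M_x, the intrinsic rate of increase r_m solving the
Euler–Lotka equation Σ e^{−r_m x} l_x m_x = 1, and the derived
quantities T_c = ln(Ro)/r_m, λ = e^{r_m}, D_t = ln 2 / r_m.

**Risk indices.** From monthly tmin/tmax climate normals a daily year is
interpolated (mid-month anchors) and three annual indices computed per
pixel: ERI (fraction of days on which every immature stage is viable),
GI (Σ_x 1/T(x), potential generations per year), and
AI (Σ_x log₁₀ λ(tmean_x), the log of the annual product of daily finite
rates of increase). Surfaces are classified low/medium/high and class
areas accounted in km².

The published parameter estimates for *S. frugiperda* reared at
20–32 °C ship with the package (`fawphen.reference_model()`), and a
synthetic-data module generates life tables, weather series and climate
rasters with the study's statistical structure for testing.

## Worked example

```python
from fawphen import life_table_parameters, reference_model

model = reference_model()
for T in (20.0, 25.0, 28.0, 30.0, 32.0):
    p = life_table_parameters(model, T)
    print(f"{T:4.0f}  rm={p.rm:.4f}  Ro={p.Ro:6.1f}  Tc={p.Tc:5.2f}  "
          f"lambda={p.lam:.4f}  Dt={p.Dt:.3f}")
```

prints

```
  20  rm=0.1269  Ro= 216.8  Tc=42.38  lambda=1.1353  Dt=5.461
  25  rm=0.1988  Ro= 275.9  Tc=28.27  lambda=1.2199  Dt=3.487
  28  rm=0.2242  Ro= 150.9  Tc=22.38  lambda=1.2513  Dt=3.092
  30  rm=0.2109  Ro=  64.1  Tc=19.73  lambda=1.2348  Dt=3.286
  32  rm=0.1289  Ro=  12.0  Tc=19.29  lambda=1.1376  Dt=5.376
```

— population growth (r_m) peaks near 28 °C, where a population doubles
roughly every 3 days; net reproduction peaks cooler (25 °C) because
fecundity is maximal near 23 °C while development keeps accelerating to
~32 °C. The `examples/` directory holds one short script per
capability (curve evaluation, fecundity refitting, demography,
synthetic-data parameter recovery, risk mapping); each prints its
numbers with a line on what they mean. A thin CLI (`fawphen synth|fit|
simulate|validate|map`) wraps the same functions for shell use.

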