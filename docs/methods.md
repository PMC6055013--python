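# Methods

This note documents the models implemented in `cobenefits`, the defaults
of the synthetic-data generator, the numerical and statistical choices
made where the design was genuinely open, and the limits of what the test
suite establishes.

## Indicator chain

Each mitigation measure reported by a city carries an annual energy
saving `E_SAV` (MWh/y), a renewable production (MWh/y) and a CO2
reduction `EM_SAV` (tCO2-eq/y). Measures are categorised by which effort
fields are positive: ES (energy saving only), REP (renewable production
only), MIX (both), UNCLASSIFIED (neither; zero and missing are treated
identically). Only ES measures enter the air-quality analysis: for
renewables the sign of the air-quality effect depends on the fuel
replaced (biomass can worsen PM), so no AQB is assigned to REP/MIX.

ES measures claiming to save more energy than the whole consumption of
their target sector in the city inventory are physically inconsistent and
excluded; the rule is a strict inequality (`E_SAV > E_SEC`), equality is
kept. Measures whose sector is absent from the inventory are excluded and
logged separately.

For a retained ES measure in city X:

- `CCB = EM_SAV / EM_TOT,X` — dimensionless, ≥ 0, can exceed 1 only if a
  measure claims to remove more CO2 than the whole inventory.
- `AQB_p = (E_SAV / E_SEC,X) · (C_SEC,X / C_TOT,X)` for pollutant p ∈
  {PM2.5, NOx}. `C_SEC,X` is the fraction of the urban-background
  concentration attributable to the sector's urban emissions (a source
  contribution estimate), `C_TOT,X ∈ (0, 1]` the four-sector urban total;
  the remainder of the concentration is non-urban background. Both
  factors are in [0, 1] after the exclusion filter, hence AQB ∈ [0, 1].

The underlying proportionality assumption — precursor emissions scale
with sectoral activity at a fixed fuel/technology mix — is what lets an
energy quantity stand in for an emission change.

## Health impact

Only the PM2.5 chain is assessed (NOx contributions are computed because
they are approximately linear in emissions, but no NOx health outcome is
modelled). The concentration–response model is log-linear with relative
risk 1.062 per 10 µg/m³ of annual-mean PM2.5 (95% CI 1.04–1.083):

```
RF_X = rr10^(PM2.5,X / 10)
AF_X = (RF_X − 1) / RF_X
ΔPM2.5 = AQB_PM2.5 · C_TOT,X · PM2.5,X
PD     = ΔPM2.5 · DR_C · P30,C · AF_X          (per inhabitant per year)
YLS    = PD · YL_C
```

City totals multiply the per-inhabitant values by the full city
population (the over-30 restriction is already inside `DR_C · P30,C`).
Uncertainty bounds swap rr10 among {1.04, 1.062, 1.083}; no sampling.
Aggregate bounds are bound-by-bound sums over measures, which treats the
risk-coefficient uncertainty as perfectly correlated across measures —
the appropriate reading for a shared epidemiological parameter.

Two deliberate interpretation choices:

- The chain is implemented literally as the product above, in which a
  concentration change in µg/m³ multiplies a death rate; the alternative
  reading (`PD = AQB · C_TOT · DR · P30 · AF`, treating `AQB · C_TOT` as
  a fractional concentration reduction of the attributable death rate) is
  exposed as `eq3_interpretation="fractional"`. The package makes no
  claim about which is dimensionally "right"; the literal form is the
  default, the switch exists so the two can be compared (they differ by
  the factor `PM2.5,X`).
- `AF` is evaluated at the city's total PM2.5 level, i.e. the marginal
  benefit of a small concentration change at the current exposure, not a
  counterfactual re-evaluation at the reduced level. For the tiny ΔPM2.5
  of single measures the difference is second-order.

## Statistical layer

Every indicator is homogeneous of degree 1 in `E_SAV`, so indicator-vs-
indicator relations are fitted with a no-intercept model `Y = αX`:
`α̂ = Σxy/Σx²`, R² on the uncentered total sum of squares `Σy²` (the
centered convention can leave [0, 1] without an intercept; printed R²
values for such fits are conventionally uncentered).

Three interval methods are provided on `ThroughOriginRegression`:

- `classical` (default): `SE = √(RSS/(n−1)/Σx²)`, t interval on n−1 df.
  Correct under homoscedastic independent errors, e.g. additive Gaussian
  noise.
- `hc1`: White's heteroscedasticity-consistent estimator with the
  n/(n−1) factor.
- `cluster`: cluster-robust with the Bell–McCaffrey CR2 leverage
  adjustment and Satterthwaite degrees of freedom. For a single
  no-intercept regressor both have closed forms: the cluster score
  `Σ_{i∈g} x_i r_i` is divided by `√(1 − Σ_{i∈g} x_i² / Σx²)`, and
  `df = (Σx²)² / Σ_g (Σ_{i∈g} x_i²)²`, which equals the number of
  clusters when balanced and falls toward 1 when one cluster dominates.

The choice matters because co-benefit data are intrinsically
heteroscedastic and clustered: energies span five orders of magnitude
(multiplicative scatter), and all measures in one city share that city's
source-contribution fractions. Monte Carlo on the generator's own noise
model shows classical intervals covering a true slope only ~35–45% of
the time at nominal 95%, plain CR1 cluster intervals ~90%, and CR2
~93–95%; the end-to-end recovery test therefore uses `se_method="cluster"`
with the city as the cluster. Classical intervals remain the default
because they are exact in the homoscedastic setting and are what the
calibration test with Gaussian noise verifies (93–97% empirical coverage
at 1000 replicates).

One-way fixed-effects ANOVA (classical between/within decomposition) is
used to compare indicator distributions across sectors and across
city groups. CO2 reductions are compared on a log10 scale by default
(`anova_log_transform`), since raw values spanning five decades make the
raw-scale F test uninformative; AQB values are compared untransformed.
Type-I error under a simulated null is verified at 0.05 ± 0.02.

Segmentations partition the measures by a city-level variable: a fixed
population threshold (default 200,000 inhabitants, strictly greater is
"large") or the median over distinct cities for pollution levels
(strictly above the median is "high"; ties go low).

Integer-percent renderings of shares use largest-remainder
apportionment, which keeps printed percentages summing to exactly 100;
plain nearest-integer rounding does not (53.91/24.98/18.60/2.51 would
print as 54/25/19/3 = 101).

## Synthetic world

The real measure/inventory/source-contribution databases are not public,
so the generator emulates their published statistical shape. Defaults:

| parameter | default | basis |
|---|---|---|
| cities | 146, in 23 countries weighted by the published signatory counts | sample description |
| population | log10-normal, mean 5.2, sd 0.4, clipped to ~49k–7.1M | published range and median (~154k) |
| measures per city | Poisson, mean 28.9 | 4220 measures / 146 cities |
| sector shares of measures | 0.54 / 0.25 / 0.19 / 0.02 | published split |
| category mix | ES/REP/MIX/UNCL = 2721/526/205/768 of 4220 | published counts |
| energy saved | log-uniform over 10^0.5–10^5.5 MWh/y | ">5 orders of magnitude"; log-uniform chosen as the least-informative shape for a stated span |
| emission factors | Buildings 0.269, Traffic 0.248, Industry 0.409, Other 0.30 tCO2/MWh | published fitted coefficients (Other is unreported; 0.30 is a mid value) |
| CO2 noise | lognormal, σ = 0.10 | see below |
| sector energy mix | 0.50 / 0.25 / 0.20 / 0.05, identical across cities | simplification, see below |
| city energy | 25 MWh/y per capita × lognormal(σ=0.2) | typical European urban final energy |
| urban SCE shares, PM2.5 | 0.42 / 0.30 / 0.22 / 0.06 (Dirichlet, conc. 60) | heating+traffic dominated PM source apportionment |
| urban SCE shares, NOx | 0.16 / 0.62 / 0.18 / 0.04 | traffic-dominated NOx; makes the implied Traffic/Buildings slope ratio ≈ 8.4, matching the published contrast |
| urban total C_TOT | uniform 0.4–0.8 per pollutant | urban share < 1, non-urban background remainder |
| PM2.5, NOx levels | uniform 8–30, 15–70 µg/m³ | plausible European urban background |
| health params | DR 0.006–0.015 /y, P30 0.5–0.7, YLL 8–12 y | plausible European ranges (shape magnitudes only, never acceptance targets) |

Structural choices:

- Every city shares the same sectoral energy-mix profile and its total
  CO2 equals city energy × the mix-weighted mean emission factor. This
  makes each sector's AQB/CCB ratio a single well-defined quantity
  (`implied slope` in `GroundTruth`): mean urban SCE share divided by the
  sector's share of city CO2. Without this simplification the "true
  slope" would vary city by city and parameter recovery would have no
  exact target.
- Noise enters in exactly two places: a per-measure lognormal factor on
  reported CO2 (entering the regressor CCB, hence a mild attenuation of
  fitted slopes, ≈ e^(−σ²) − 1 ≈ −1% at σ = 0.10), and per-city Dirichlet
  variation of SCE shares (entering AQB, shared by all measures of a
  city — the reason intervals must be cluster-robust).
- σ = 0.10 for the CO2 noise is a deliberate compromise: large enough to
  exercise the noise paths, small enough that attenuation does not
  swamp slope recovery. Real reported data scatter far more (published
  CO2-vs-energy fits have R² ≈ 0.8, not ≈ 0.99 as here).
- Savings are capped at 0.95 × the sector's consumption; a configurable
  number of deliberate violators (default 0) is injected above the cap
  to exercise the exclusion filter.

What a green test suite does and does not establish: it shows the
indicator algebra is exact, the filters reproduce the published counting
identities, and the regression/ANOVA layer is calibrated on data with
this generator's noise structure. It does not validate the source
contribution estimates, the concentration–response function, or any
claim about real cities; the synthetic health totals (e.g. ~21,000
avoided deaths/y at the defaults) are properties of the synthetic world
— roughly 3× the published study total, mainly because the synthetic
Dirichlet SCE shares and uniform pollution levels are more generous than
the modelled ones — and should never be quoted as such.

## Numerical details and degenerate inputs

- Tolerances: algebraic identities are tested to 1e-12 relative; share
  sums to 1e-12 absolute; summary cross-foots to 1e-9 relative.
- A through-origin fit with a single observation returns the exact slope
  with a degenerate (NaN) interval; all-zero x is an error.
- ANOVA groups with fewer than two values are dropped with a warning;
  fewer than two surviving groups is an error. Zero within-group variance
  with zero between-group variance returns F = 0, p = 1.
- Indicators with zero denominators (sector energy, total CO2, total
  urban contribution) raise a distinct undefined-indicator error; in
  table building such measures are skipped and logged, never silently
  zeroed.
- Measures in unknown sectors are remapped to "Other" with a warning at
  read time; SCE tables may be given in percent (`sce_percent=True`).
- Duplicate measures (same city, sector, identical values) are kept: the
  source databases were cleaned upstream by an unspecified procedure, and
  dropping apparent duplicates would silently alter totals.

## Known limitations

- The literal health chain inherits the dimensional looseness discussed
  above; use the `fractional` switch for sensitivity.
- AQB for REP and MIX measures is out of scope by design.
- The generator draws city size, pollution level and measure size
  independently; any real correlation between them (larger cities being
  more polluted, say) is absent, so segmentation contrasts on synthetic
  data only test the mechanics, not realistic effect sizes.
- NO2 chemistry is not modelled; NOx is used precisely because its
  concentration response to emission changes is approximately linear.
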