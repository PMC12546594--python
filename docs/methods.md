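# Methods

## Transition model

The unit of state is a cell's technique-share vector
`(drip, sprinkler, flood)` on the 2-simplex, constrained by the cell's
crop-functional-type (CFT) composition `(f_drip, f_sprinkler, f_flood)`:
drip irrigation is only feasible on drip-suitable CFTs and sprinkler on
drip- plus sprinkler-suitable CFTs, so `drip ≤ f_drip`,
`sprinkler ≤ f_drip + f_sprinkler − drip` and `flood ≥ f_flood` at all
times. Paddy irrigation is folded into flood.

**Baseline downscaling.** Country-level 2010 shares are assigned to cells
by priority: drip first (onto drip CFTs; excess demand is demoted to
sprinkler, then flood — the demotion rule is this package's choice for a
case the priority description leaves open), then sprinkler (onto sprinkler
CFTs, overflowing onto remaining drip CFTs), then flood on whatever is
left. The same priority defines the per-CFT-class technique assignment
(`distribute_to_cfts`), whose CFT-weighted column sums reconstruct the
cell shares to 1e-9.

**Annual updating rate.** Every 5 years, each country's rate is

    r = r0 − h + s   [percentage points of flood share per year, r ≥ 0]

with default `r0 = 1 %/yr`. `s` comes from binning the country's
normalised first-principal-component score of four socioeconomic
indicators (GDP per capita, governance strength, urbanisation,
gender-inequality index); `h` from binning the normalised 20-year-mean
precipitation. The PCA is fitted once on the standardised 2010
cross-country baseline and frozen; the PC1 sign is fixed to correlate
positively with GDP. Normalisation is min-max against the historical
baseline (2010 for the socio score, the 1996–2010 window for
precipitation), so projected values may leave [0, 1] — an intentional
property: the reference example score is 1.25.

The shipped factor table

| socio_norm bin | < 0.25 | [0.25, 0.5) | [0.5, 0.75) | [0.75, 1) | ≥ 1 |
|---|---|---|---|---|---|
| s | 0 | 0.2 | 0.4 | 0.6 | 0.8 |

| hydro_norm bin | < 0.25 | [0.25, 0.5) | [0.5, 0.75) | ≥ 0.75 |
|---|---|---|---|---|
| h | 0 | 0.1 | 0.15 | 0.2 |

is a design choice constrained by three requirements: a neutral bottom bin
on both axes (an average country keeps `r0`), the reference points
`socio_norm = 1.25 → s = 0.8` and `hydro_norm = 0.45 → h = 0.1`, and a
wider factor range on the socio axis, reflecting its stronger association
with observed technique shares. Wetter climates get a larger `h`
(subtraction): abundant water weakens the incentive to save it. Bins are
left-closed/right-open. Users can supply their own `FactorTable`.

**Stepping and redistribution.** Over an `n`-year window the flood share
drops by `Δ = min(r·n/100, flood − f_flood)`, split between drip and
sprinkler proportionally to `f_drip : f_sprinkler`. The decrement is
absolute percentage points of the share (70 % → 61.5 % at 1.7 %/yr over
5 years), not a relative decay. If the drip increment would exceed the
drip cap the excess flows to sprinkler; the sprinkler cap cannot bind
independently while the flood floor holds, because
`drip + sprinkler ≤ 1 − f_flood = f_drip + f_sprinkler`. This closed form
is verified in the tests against an explicit 0.01-pp fine-step simulator
(agreement to 1e-6) on randomized cap-binding instances. 5-year node
values are interpolated linearly to annual resolution; node years are
reproduced exactly. Shares are stepped with the window's rate before any
land-use (AEI) update of the same year; CFT compositions are taken as
given per step (static in the toy world).

## Exposure diagnostics

Wet-bulb temperature uses the empirical arctangent fit from temperature
(°C) and relative humidity (%, valid roughly for φ ≥ 5 % and ordinary
surface temperatures at sea-level pressure). Two caveats of the fit, as
published, are worth recording: it is not strictly increasing in φ in a
small corner (T2m ≲ 3 °C with φ ≲ 9 %), and it can exceed the dry-bulb
temperature below about −10 °C and within ≈ 0.2 °C of saturation. Both
are fit artefacts outside or at the edge of its validity region; the
property tests therefore assert dominance and monotonicity over
T2m ∈ [5, 50] °C.

Extreme thresholds are per-cell empirical 99th percentiles (linear
interpolation between order statistics — the convention must be fixed
somewhere; only the ~1 % tail mass is constrained by the definition) over
the pooled historical no-irrigation ensemble (all members × all years).
Exposure is `3 h × #(blocks strictly above threshold)` per cell-year;
ties are measure-zero for continuous data. With a 365-day no-leap
calendar a year is exactly 2920 blocks, so exposure lies on the 3-hour
lattice in [0, 8760]. Evaluating the pooled defining sample against its
own threshold yields ≈ 87.6 h yr⁻¹ mean annual exceedance (1 % of 8760),
which the acceptance suite checks within the 1/√N sampling tolerance.

Forcing impacts are member-wise differences of mean-annual exposure
(irrigation: IRR − NOI within a period; all forcings: future IRR −
historical IRR; scenario: SSP3 − SSP1), averaged across members for maps;
the hatching mask requires all members to agree in direction with
magnitude ≥ 10 h yr⁻¹. Hotspots: *traditional* where the historically
irrigated fraction exceeds 0.2; *new* where it does not but the 2070
fraction does (the alternative reading — an AEI *increase* larger than
20 points — is not used). Withdrawal volumes are
`Σ depth[mm] × area[km²] × 10⁻⁶` km³ yr⁻¹; annual series are smoothed
with a Savitzky–Golay filter (order 2, window 7), endpoints by scipy's
`interp` policy (a single polynomial fitted to the edge window).

## The synthetic world

The toy world exists to make the pipeline falsifiable, not to look like
Earth. Defaults (chosen once for desk-scale determinism): 5 countries on
an 8×10 grid of 1000 km² cells, 3 ensemble members, 3-hourly steps, and 2
synthetic years per period (`WorldConfig.toy()`; the full 30 + 60-year
periods are the plain `WorldConfig` defaults behind the CLI
`--full-scale` flag).

* **Drivers.** The four socioeconomic indicators are generated from a
  latent per-country development level with small independent noise (GII
  loading negatively), because their strong mutual correlation is the
  premise that makes a single principal component meaningful; with
  independent draws the PC1 axis would be arbitrary. Both scenarios share
  history through 2010; from 2015 SSP1 grows GDP/governance/urbanisation
  faster and shrinks gender inequality, SSP3 the reverse. Precipitation
  is a per-country normal with a mild trend, identical across scenarios.
* **Land use.** Country blocks partition the grid. CFT compositions cycle
  pure-flood, pure-drip and Dirichlet-mixed cells. AEI is constant under
  SSP1; under SSP3 the designated emerging-hotspot country ramps from
  0.05 to 0.55 by 2070. The first country holds 0.25–0.5 (traditional
  hotspot).
* **Climate.** T2m = latitudinal base + seasonal (±8 °C) and diurnal
  (±4 °C) sinusoids + AR(1) noise (innovation sd 1.5 °C, ρ = 0.85) + a
  linear warming trend (0.01/0.02/0.05 °C yr⁻¹ for Hist/SSP1/SSP3); RH is
  analogous (anti-phased season, sd 4 %, ρ = 0.8), clipped to
  (0, 100]. The weather draw is keyed by (seed, scenario, member) only,
  so IRR and NOI cubes of a pair share it exactly (common random
  numbers): their difference is the injected signal plus its own noise,
  making the factorial differencing exactly testable. The injected
  irrigation effect defaults to δT = −1 °C and δRH = +5 % per unit AEI
  with Gaussian noise sd 0.5 °C / 1 %; `InjectedSignal.noiseless()`
  removes the noise for exactness tests.
* **Withdrawal.** The toy IWW depth is AEI × technique-share-weighted
  application depth (flood 700, sprinkler 500, drip 350 mm yr⁻¹ over
  irrigated area) — invented plumbing to exercise the aggregation and
  smoothing operations with realistic orders of magnitude.

What passing toy tests do **not** show: anything about real atmospheric
responses to irrigation (magnitude, sign heterogeneity, nonlinearity in
AEI), real land-use data, spherical geometry or leap years. They show
that, given inputs with a known embedded truth, every transformation in
the chain recovers it within stated tolerances.

## Numerical choices

Simplex membership is enforced to 1e-6 on input validation and the share
arithmetic preserves it to ~1e-12; reconstruction identities are checked
to 1e-9. Rates are floored at zero (no regression towards flood).
Degenerate inputs fail loudly: all-flood CFT cells raise a no-headroom
error for scalar weight queries (vectorised calls return zero weights,
their decrement being necessarily zero), constant PCA columns and
min = max normalisation baselines are rejected. All randomness flows from
a single integer seed through named `SeedSequence` spawn keys; rerunning
a pipeline with the same seed reproduces byte-identical outputs
(checksums recorded in the run manifest).

## Problem sizes

The default test-suite and pipeline runs use the toy configuration above
(≈ 5.8 k blocks × 80 cells × 6 experiments × 3 members), which keeps a
full run-all under ~10 s while leaving ≥ 10⁴ pooled blocks per cell for
the sampling-tolerance checks. Larger grids or the full 30/60-year
periods scale linearly in time dimension and are available through
`WorldConfig` directly.
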