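# Methods

## The model system

Physical work capacity (PWC) is the cumulative net energy expenditure a
worker produces in up to one hour of treadmill walking at a fixed heart
rate of 130 beats·min⁻¹, expressed as a percentage of the same quantity in
a cool 15 °C / 50 % RH reference climate.  The fixed-heart-rate paradigm
emulates self-pacing: as heat strain grows, a larger share of cardiac
output serves skin blood flow, and work output falls while strain stays
constant.

The decline of group-mean PWC with a heat-stress index *x* (°C) is
modelled as a fixed-asymptote sigmoid,

    PWC(x) = 100 / (1 + (PWC50/x)^HillSlope),

a dose-response form with plateaus pinned at 100 % (no heat effect) and
0 % (no work possible).  Only `PWC50` (the index value at half capacity)
and `HillSlope` (steepness; negative for heat indices) are free.  The
shipped parameter sets (JSON registry, `src/heatwork/data/parameters.json`)
cover heat index, humidex, aspirated wet bulb, indoor-estimated WBGT,
UTCI, and mean skin temperature, each with the validity range of the
calibration data; predictions outside that range are computed but flagged
as extrapolated, never refused (hard errors are reserved for
mathematically undefined inputs such as x ≤ 0).

For air temperature and humidity directly, `PWC50` and `HillSlope` are
replaced by linear functions of ln RH:

    PWC(Ta, RH) = 100 / (1 + ((a·ln RH + b)/Ta)^(c·ln RH + d)),

with shipped coefficients a = −12.28, b = 87.99, c = −2.21, d = 2.63,
valid for Ta 15–50 °C and RH 20–80 %.

## Index calculators

All calculators take dry-bulb temperature (°C) and relative humidity (%).

- **Ambient vapour pressure**: RH/100 × exp(18.956 − 4030.18/(Ta+235)).
  The exponential yields hectopascals (≈73.7 at 40 °C against the true
  saturation pressure of 7.37 kPa), so the implementation divides by 10 to
  obtain the kilopascals the wet-bulb coefficients require.  This
  correction is what reproduces the physically sensible wet-bulb range
  (10–39 °C) over the calibration climates; the uncorrected form remains
  available behind `as_printed=True`.
- **Aspirated wet bulb**: Twb = 0.376 + 5.79·Pa + (0.388 − 0.0465·Pa)·Tdb,
  a linearisation that is accurate inside its 10–39 °C output range.
  Outside it — very hot *and* near-saturated air — it can read above the
  dry bulb; the property tests therefore assert wet-bulb ≤ dry-bulb only
  where the output is in range.
- **Humidex**: Ta + 5/9·(e − 10) with its own embedded Magnus-type vapour
  pressure in hPa (deliberately not unified with the wet-bulb Pa).
- **Heat index**: the nine-term Rothfusz regression evaluated in °F and
  converted back.  The raw polynomial is used over the whole input domain
  with no low/high-humidity adjustment branches, keeping a single smooth
  formula down to the cool reference climate.  The regression is only
  monotone above its 80 °F (26.7 °C) applicability floor; below that it is
  a smooth extrapolation, which is how the tests treat it.
- **WBGT (indoor estimate)**: 0.7·Twb + 0.3·Tg with the aspirated wet bulb
  as the natural-wet-bulb proxy and Tg defaulting to Ta.  Valid for still
  indoor air without radiant load; results carry an `estimated` flag and a
  measured WBGT should be preferred when available.
- **UTCI**: a plug-in boundary.  The operational sixth-order polynomial is
  not re-implemented; callers supply either a precomputed value or an
  evaluator callable.  With neither, an explicit error is raised — air
  temperature is never silently substituted.

## Calibration data and pooling

The packaged table (`calibration_pwc.csv`, SHA-256 verified at load)
holds group-mean PWC ± SD for 22 air-temperature/humidity combinations
(25–50 °C, 20–80 %) under low (0.26 clo) and high (0.86 clo) clothing
coverage: 42 cells, two cells absent, and the two 50 °C high-clothing
cells are single-trial means without SD.  Pooling averages the two
clothing arms per condition with equal weight; conditions with one arm
keep that value.  Per-cell trial counts are unpublished, so no
n-weighting is attempted.

## Fitting procedure

`SigmoidCapacityModel.fit()` minimises unweighted absolute residuals with
scipy's trust-region-reflective least squares, PWC50 bounded positive,
starting from (median x, −4).  Standard errors come from the Gauss-Newton
covariance s²(JᵀJ)⁻¹.  R² is 1 − SSres/SStot; RMSE defaults to the
population form √(SSres/n) (an n−p option exists) — the calibration
software's convention is not documented, and the population form
reproduces the published RMSE values.

`TaRhCapacityModel.fit()` implements the three-step tuning procedure:

1. independent sigmoid fits of PWC against Ta within humidity strata
   (20/50/80 % by default; a configurable band tolerance admits inexact
   field humidities — conditions outside every stratum, e.g. RH 35/40/
   60/70, enter only step 3);
2. straight-line regressions of per-stratum PWC50 and HillSlope on ln RH,
   whose slopes/intercepts seed (a, b) and (c, d);
3. a joint four-parameter nonlinear fit on all conditions started from
   step 2.

All intermediate artifacts (per-stratum results, linear models, start
values) are retained on the results object.  Refitting the packaged table
recovers the shipped heat-index and humidex curves within ±2.5 % and the
Ta/RH coefficients a, b, c within ±10 %.  The wet-bulb HillSlope and the
Ta/RH d coefficient do not reproduce from nominal chamber conditions: the
least-squares optimum on nominal data (wet-bulb slope ≈ −4.2) fits better
than the published curve does on those same data, implying the original
fits used measured per-trial conditions that are not published.  The
refits are reported as computed, not adjusted.

## Trial processing

Per-minute walking metabolism uses the minimum-mechanics model,
VO₂net = 0.32·G + 3.28 + (1 + 0.19·G)·2.66·v² (mL·kg⁻¹·min⁻¹, G = grade
in %, v = speed in m·s⁻¹, level/uphill only), closed to kJ·min⁻¹ by
× body mass / 1000 × (19.61 + (RQ − 0.707)/0.293 × 1.51).  The mass
closure is implicit in the printed mass-specific form and applied
explicitly here; VO₂net is already net of rest, so no further resting
subtraction occurs.  RQ defaults to 0.85 when unrecorded.  Work EE is the
cumulative sum over completed minutes; trials truncate at the first
sensor gap (no interpolation), at rectal temperature ≥ 39.0 °C
(`core_39`), or at a stopped belt after minute 1 (`speed_zero`).  Mean
skin temperature is the Ramanathan 4-site weighting
0.3·(chest + arm) + 0.2·(thigh + calf), averaged over the trial.

## Synthetic trial generator

The generator is phenomenological — first-order relaxation dynamics with
hand-set time constants, not a thermophysiological model.  It emulates the
protocol's observable shape: heart rate relaxes from 88 to 130 ± 5
beats·min⁻¹ within ~10 min (τ = 3.5 min); skin temperature relaxes
(τ = 8 min) from 33 °C toward an equilibrium increasing in Ta
(0.22 °C/°C), RH (0.02 °C/%) and clothing (+0.3 °C for coveralls), capped
at 38.8 °C; the belt raises speed first and engages grade only above
6 km·h⁻¹; rectal temperature tracks cumulative work rate and crosses
39 °C only under extreme specifications.  The hot trial's work-rate
profile is the cool reference profile (saturating ramp to 13 mL·kg⁻¹·min⁻¹
net, scaled by a fitness factor) attenuated by exp(−β·ΔTskin(t)); β is
solved by bisection so cumulative energy expenditure hits the requested
target PWC through the *same* floor-and-termination semantics the trial
processor applies, making the closure exact at zero noise for targets the
physiology can reach (below ~25 % the belt stops early, and closure holds
to within one PWC point; below ~1 % it saturates).  With noise, the
realised target is drawn from N(target, noise_sd) and mild per-minute
jitter is added, all from a single seeded RNG stream recorded in the
trial metadata.

Passing generator-based tests therefore demonstrates pipeline
correctness — energy bookkeeping, termination rules, PWC arithmetic,
parameter recovery — not physiological realism: real trials have
participant-to-participant variability, sensor noise, transient pacing
oscillations and day effects the generator does not emulate.

## Numerical and design choices

- Temperatures are handled in °C everywhere except inside the heat-index
  polynomial, which converts to °F internally.
- Coefficient sets are data (versioned JSON registry with provenance
  strings), never hard-coded in logic; user/clothing-specific sets load
  without code changes.
- Extrapolation policy is compute-and-flag; the CLI's `--policy strict`
  converts flags into errors, `--policy warn` logs them.
- The matrix view flags cells predicting < 25 % PWC as extrapolated —
  below the lowest group mean observed in calibration — in addition to
  out-of-window cells; default grid Ta 15–50 step 1, RH 20–80 step 5.
- The thermal-sensation model (0.13·e^(0.15·Tskin)) is evaluated as
  published; its magnitude at warm skin temperatures reflects the
  modified numeric scale used during calibration, not a standard 9-point
  scale — treat its units as scale-specific.
- Test and acceptance problem sizes: 22-condition refits, 200-replicate
  Monte-Carlo recovery at σ = 5 PWC points, and a handful of 60-minute
  synthetic trials — all chosen to exercise the full pipeline at the
  study's own scale.

## Known limitations

- Calibrated on young adult males at one work modality and low air speed
  without solar load; the UTCI/WBGT curves are the only shipped sets
  meant for radiant environments, and wind/radiation corrections are out
  of scope.
- The models predict group means; individual workers vary widely with
  fitness and anthropometry.
- The Ta/RH curve is very mildly non-monotone in humidity below ~33 °C
  (< 1 PWC point, near the 100 % plateau) — an artifact of the fitted
  log-humidity parameterisation.
- Published validity ranges and several published coefficients derive
  from measured chamber conditions; refits from nominal set points land
  within a few percent but not exactly (see Fitting procedure).
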