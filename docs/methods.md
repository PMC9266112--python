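# Methods

## The index and its inputs

UTCI is defined through a multi-node human thermoregulation model; for
climatological scans the operational practice is a sixth-order
polynomial approximation of the offset `UTCI − Ta` in four variables:
air temperature `Ta` (−50…50 °C), wind speed at 10 m `va` (0.5…17 m/s),
water-vapour pressure `Pa` (kPa) and the radiant excess `D = Tmrt − Ta`
(−30…70 K).  The 210 published constants are stored in
`utciclim/_utci_coefficients.py` in the canonical ordering of the
operational source; the exponent tuples are *regenerated* from that
ordering rather than stored, so table and exponents cannot drift apart.
A SHA-256 checksum of the table is pinned by a unit test, and thirteen
reference input/output tuples across the validity box (anchored at the
published reference value 24.6 °C for `Ta = Tmrt = 25 °C`, `va = 1 m/s`,
50 % RH) guard the transcription to 0.1 °C.

Out-of-range policy: wind is clamped to the polynomial's validity range
and flagged (`wind_clamped`); temperature and radiant excess are never
clamped — the value is still returned but flagged
(`input_out_of_range`), and the climatology keeps flagged days by
default (configurable).

### Radiant budget

Daily mean radiant temperature comes from a three-flux budget:

- `Rp` — short-wave flux absorbed by an unclothed reference person,
  modelled as `Rp = α · fp(γ) · Rg` with absorption coefficient
  `α = 0.7`, the standing-person projected-area factor
  `fp(γ) = 0.308 cos[γ(0.998 − γ²/50000)]`, and the solar elevation at
  local noon `γ` as the representative daily elevation.  This component
  is deliberately pluggable (`rp_from_global(..., area_factor=...)`):
  the mapping from daily-mean global radiation to the personal
  short-wave load has no single canonical daily-scale form, and any
  callable with the same signature can replace the default.
- `Lg = 5.5·10⁻⁸ (273 + Tg)⁴` — ground long-wave emission at ground
  temperature `Tg` (falls back to `Ta`, flagged, when missing).
- `La = 5.5·10⁻⁸ (273 + Ta)⁴ (0.82 − 0.25·10^(−0.094 e))` — atmospheric
  long-wave emission with a vapour-pressure-dependent emissivity that
  saturates at 0.82 (`e` in hPa).

`Tmrt = [(Rp + 0.5 Lg + 0.5 La)/(0.95 σ)]^¼ − 273` with
`σ = 5.667·10⁻⁸ W m⁻² K⁻⁴` and body emissivity 0.95.  Vapour pressure
is carried in hPa throughout the engine and divided by 10 exactly once,
at the polynomial boundary (which expects kPa).

### Classification

Ten contiguous categories with breakpoints −40, −27, −13, 0, 9, 26, 32,
38, 46 °C; category 1 is the hottest.  The printed interval bounds touch
without stating inclusivity, so intervals are half-open `[lower, upper)`
(closed below): 26.0 °C already counts as moderate heat stress.  Yearly
and seasonal (default summer = June–August) day counts conserve the
number of days per window by construction, and a test enforces it.

## Radiation models and calibration

All four empirical models are calibrated by minimising the sum of
squared *flux* residuals (unweighted, in W/m²).  Angstrom, Ogelman and
Hargreaves are linear in their coefficients, so the calibration is an
exact linear least-squares solve; a test verifies that generic
nonlinear least squares on the same objective agrees to 1e−6.  Bristow
is fitted by bounded trust-region least squares from the starting point
(a, b, c) = (0.2, 0.5, 1.5) with `a ≤ 1.5`, `b, c > 0`.  `ΔT` is the
same-day `Tmax − Tmin`.  Constant predictors (all-equal sunshine
fraction or `ΔT`) raise an identifiability error rather than returning
arbitrary coefficients.  Predictions are clamped at 0 (Hargreaves can
go negative when `b < 0`) and polar-night days return 0 with a flag.

Extraterrestrial radiation and astronomical day length follow the
FAO-56 daily formulation (solar constant 0.0820 MJ m⁻² min⁻¹), with the
sunset-hour-angle argument clipped to [−1, 1] for polar day/night.  All
radiation is expressed as daily-mean flux density in W/m² (FAO-56
MJ m⁻² day⁻¹ divided by 0.0864).

The ML harness trains a 10-hidden-unit feed-forward network (L2 weight
decay 0.01, L-BFGS) or an RBF-kernel SVR (cost 1, gamma 0.125) on
standardised features and target, behind the same predict/evaluate path
as the empirical models.  Feature pruning drops a candidate whose
absolute Pearson correlation with an already-kept feature exceeds 0.8,
visiting features in a documented priority order (daily-mean
temperature before the redundant extremes and vapour pressure); the
sunshine trio `{Re, S, S0}` is always retained and never causes drops,
because the radiation signal lives there.

## Skill metrics and trends

`NSE = 1 − Σ(O−S)²/Σ(O−Ō)²`, `MAPE = (100/n) Σ|（O−S)/O|` with
zero-observation terms excluded and counted, `RMSE` in data units, and
slope/intercept from OLS of estimated on observed.  Constant
observations make NSE undefined and raise.

Theil–Sen is the median of all pairwise slopes (exact all-pairs
enumeration; an exhaustive brute-force oracle checks every length ≤ 12).
Mann–Kendall uses the tie-corrected variance and continuity correction
`z = (S − sign S)/√Var(S)`; both corrections are configurable.
Significance tiers use two-sided normal quantiles 1.645/1.960/2.576 for
90/95/99 %.  Period comparison reports, per category, the mean shift of
annual day counts between two disjoint year ranges plus an optional
Gaussian-KDE density (degenerate samples get none, without error).

## Synthetic weather generator

The generator emulates a temperate mid-latitude station (defaults:
annual-mean 12 °C, seasonal amplitude 14 °C peaking mid-July, AR(1)
anomalies with persistence 0.7 and innovation sd 2 °C).  Sunshine
fraction is truncated-Gaussian (mean 0.55, sd 0.25) in [0, 1]; diurnal
range is `5 + 8·(S/S0)` °C plus noise, tying `ΔT` positively to
sunshine so the temperature-based models have signal.  Relative
humidity stays in [20, 100] % (drier on sunny days), dew point is the
exact inverse of the vapour-pressure formula, ground temperature is air
temperature plus 3 °C per unit clearness index, and radiation is
`Re·(a + b S/S0)` times `1 + cv·N(0,1)` noise, clipped to `[0, Re]`.
The default generating coefficients `a = 0.161`, `b = 0.528` are the
average calibrated Angstrom values reported for Chinese radiation
stations, with `cv = 0.10` — a realistic relative error for daily
sunshine-based estimates.  An optional linear `warming_per_year` term
supports trend-detection studies.  All randomness flows from one
integer seed.

Gap handling restores a single missing day as the mean of its
neighbours and generalises to linear interpolation for longer runs
(edge gaps take the nearest value); imputed rows are flagged.  The
masking rate is capped below 5 %, matching the near-complete archives
the workflow targets.

What the generator does *not* emulate: spatial covariance between
stations, weather-regime persistence beyond AR(1), skewed or
heavy-tailed radiation errors, instrument drift, and hourly structure.
Passing tests therefore demonstrate the correctness of the computational
chain and its statistical behaviour under the stated noise model — not
the skill of any model on real observations.

## Problem sizes and determinism

Tests and the acceptance script run on deliberately small problems: one
to twelve synthetic years per station for unit and pipeline tests,
twenty seeded replicates of ten years for coefficient recovery, twenty
noise seeds for the error-propagation bound, and 200 replicates for the
trend type-I/power checks.  The end-to-end pipeline is byte-identical
for a fixed config and seed; every run's manifest records the config
hash, the seed and the UTCI constants checksum.

## Known limitations

- The daily-scale category counts inherit the categories' hourly-scale
  definition; a daily mean near a boundary hides hours beyond it, so
  extreme categories are systematically undercounted at daily scale.
- The default `Rp` model is a documented stand-in; site-specific
  radiant-load models should replace it through the pluggable hook
  where fidelity matters.
- Mann–Kendall is applied without prewhitening; for strongly
  autocorrelated annual series the nominal error rates are optimistic.
- The calibration/validation split is chronological (first two-thirds /
  last third by default), which is the honest protocol for trend-bearing
  series but means validation skill reflects any regime drift.
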