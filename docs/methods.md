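# Methods

This note records the models behind `thermidx`, the numerical choices made
where the underlying definitions leave room, and what the synthetic-data
tests do and do not demonstrate.

## Solar geometry

Declination and the equation of time are Fourier-series fits in the
fractional year (the classical 7- and 5-coefficient series, coefficients
recorded verbatim in `solar.py` so results are reproducible bit for bit).
The hour angle follows the mean-solar-time construction: true solar time =
UTC + 4 min/deg · longitude + equation of time, with the convention h = 0 at
solar noon, negative mornings. The zenith cosine is

cos θ = sin δ sin φ + cos δ cos φ cos h.

Because the direct-beam flux is divided by cos θ, the instantaneous value at
an accumulation endpoint overestimates the beam near sunrise/sunset. We use
the interval-averaged clipped cosine instead: the mean of max(cos θ, 0) over
the hourly accumulation interval, sampled at the midpoints of `n_substeps`
sub-intervals (default 60, i.e. 1-minute sampling; midpoint sampling
converges quadratically, and 60 vs 3600 sub-steps agree to better than
1e-4). An interval entirely in darkness yields exactly 0.

The projected area factor of a rotationally symmetric standing person,

f_p = 0.308 · cos{(π/2 − θ)[1 − (90 − 180θ/π)²/48402]},

is evaluated at the *interval-mean* sun position θ̄ = arccos(mean cos θ), so
f_p and the direct beam refer to the same effective sun elevation (the
alternative — the endpoint zenith angle — is inconsistent with the averaged
beam; this was a genuinely open choice). Angles outside [0, π/2] are clamped
with a warning: a sun below the horizon contributes no beam.

Atmospheric refraction and topographic shading are ignored (sub-0.01
effects at the zenith angles where the beam carries energy, and outside the
product's scope respectively).

## Humidity and wind

Vapour pressure uses the Magnus form over water with the WMO constant set
(6.112 hPa, 17.62, 243.12 °C) — the standard operational choice; the
constants are module-level so a different psychrometric fit can be swapped
in. RH = 100·e(Td)/e(Ta), capped at 100%: gridded products occasionally
carry dewpoints marginally above the air temperature, and clipping (with a
log count) is preferable to failing on physically sound data. Wind at
body-relevant height (1.2 m, needed by the net effective temperature) comes
from the logarithmic profile with roughness length z₀ = 0.01 m, making the
1.2-m/10-m ratio a constant ≈ 0.693.

## Radiation handling

Reanalysis radiation arrives as accumulations (J m⁻²). Two conventions are
supported: accumulation-since-daily-reset (`era5land`; hourly increment =
first difference within each 24-step window, first step passes through) and
per-step accumulation (`era5`; pass-through). For inherently non-negative
fluxes a decreasing accumulated series beyond round-off is a data-quality
error, and negative increments are clipped to zero and counted. Net thermal
radiation is exempt from both rules: its increments are legitimately
negative (net = downward − upward, and the surface is warmer than the sky).

The five components of the radiant load are algebraic identities of the
stored variables: diffuse = global − direct (horizontal), reflected =
global − net shortwave, downwelling longwave stored directly, upwelling =
downwelling − net longwave, and the beam normal to the sun =
direct-horizontal / mean cos θ. The division is guarded: below a mean
cosine of ε = 0.01 the beam is set to zero rather than amplified by a
vanishing cosine (the interval average mitigates but does not remove the
twilight blow-up). Clip tolerances distinguish physical inconsistencies
(counted, logged) from float round-off at the 1e-9 level (silently clipped).

## Mean radiant temperature

MRT inverts the Stefan–Boltzmann law on the absorbed flux of a standing
body on an unshaded plain: solid-angle factors f_a = 0.5 for sky and
surface, shortwave absorption α_k = 0.7, body emissivity ε_p = 0.97. The
Kelvin→Celsius offset is **273.5**, reproducing the convention of the
archived dataset this pipeline mirrors; it is almost certainly a rounding
of 273.15, so `BodyRadiationConstants(kelvin_offset=273.15)` switches to
the exact value (default off for fidelity — daily fields would otherwise
shift by a uniform 0.35 °C).

## UTCI

The operational 6th-order polynomial approximation replaces the multinode
thermoregulation model: UTCI = Ta + f(Ta, va, pa, ΔMRT) with pa in kPa and
ΔMRT = MRT − Ta. The 210 coefficients live in
`data/utci_coefficients.csv` (exponent quadruple + coefficient, sha256
checked at import); evaluation is a vectorized dot product over cached
power tables. A second, deliberately naive straight-line transcription of
the operational program (`utci_reference.py`) serves as a cross-check: the
two paths agree to ~1e-12 °C on a factorial grid spanning the validity
region, and the polynomial reproduces the defining reference-environment
property (UTCI ≈ Ta at MRT = Ta, va = 0.5 m/s, RH 50% / e = 20 hPa) to
within 1 °C across −30…40 °C.

Inputs are clamped to the published validity region — Ta ∈ [−50, 50] °C,
va ∈ [0.5, 17] m/s, e ≤ 50 hPa, ΔMRT ∈ [−30, 70] K — rather than masked,
because a continuous gridded product is more useful than one with holes;
every clamp is recorded in a QC mask. The indoor/shaded variants substitute
MRT = Ta (and va = 0.5 m/s) *before* clamping; 0.5 m/s is itself the lower
validity bound, so the order is immaterial for wind.

## Empirical indices

AT, ESI, Humidex, NET, simplified WBGT, Stull WBT and WCT are the printed
regression formulas, evaluated exactly (WCT converts wind to km/h
internally; HI works in °F and converts back). The heat index evaluates the
simple average formula first and switches to the Rothfusz regression where
the simple result reaches 80 °F, applying the low-RH (RH < 13%, 80–112 °F)
and high-RH (RH > 85%, 80–87 °F) adjustments in their windows — the
standard branching order. WCT is computed everywhere, year-round, matching
the dataset convention; its physical validity is limited to cold, windy
conditions. Note a property of Stull's WBT fit surfaced by our grid scans:
within its stated validity box (RH 5–99%, Ta −20…50 °C) the fitted WBT can
exceed the air temperature by up to 2.4 °C in the cold/dry corner; above
0 °C the excess stays below 0.05 °C.

## Gridded pipeline

Processing order: (1) nearest-neighbour regrid of the coarse direct beam
onto the fine grid — nearest cell center in plain lat/lon coordinates,
separable on regular grids, ties toward the lower index, values copied
never interpolated; (2–3) de-accumulation and conversion to W m⁻²; (4–5)
hourly MRT and the twelve indices; (6) daily mean/max/min per cell.

Days are **UTC calendar days** (the forcing's native axis; the alternative,
fixed local-offset days, is a config choice away but not default). The time
dialect is timestamps 00..23 with a value stamped t covering [t, t+1); the
fine-grid accumulations reset at the day's first stamp. A cell missing at
any hour poisons all three daily statistics for that cell (conservative;
partial-day means would mix biased samples). Output files are
`HiTiSEA_YYYY-MM-DD.nc` (classic NetCDF), 36 variables
`<Index>_mean/_max/_min`, int16 with scale factor 0.01 °C and fill value
−32767; a lossless float64 encoding is available via config. Writes carry
no timestamps or history attributes, so re-runs are byte-identical.

## Station validation

Stations report 3-hourly synoptic records (Ta, Td, 10-m wind, pressure);
any record missing one of the four is excluded. Pressure is ingested only
for the exclusion rule — no index formula uses it. The nine indices
computable without radiation are derived from the observations and from the
collocated (nearest-cell) grid forcing *at the same synoptic instants*;
this avoids the 8-obs-vs-24-hour daily-statistics mismatch, which is
documented and available as an alternative mode rather than the default.
RMSE and bias are per station and per month; yearly scores pool the year's
pairs rather than averaging monthly RMSEs (the two differ whenever error
magnitude varies seasonally). Daily maximum-radiation observations are
paired with synoptic records by rounding the time of maximum to the nearest
3-hour slot, dropping (and counting) days without a complete match. Score
tables are exported as one tab-separated file per period with station id,
coordinates, per-index RMSE/bias and pair counts.

## Synthetic forcing

The generator emulates the *structure* of the real forcing, not its
climatology: a sinusoidal diurnal temperature cycle phased to local solar
time over a smooth spatial anomaly field; constant-in-time dewpoint
depression (2–6 °C), cloud-transmittance, diffuse-fraction, albedo
(0.12–0.30) and wind fields (smooth seeded Gaussian-filtered noise);
shortwave driven by the same interval-averaged solar geometry the pipeline
uses, zeroed below a mean cosine of 0.015 to stay clear of the twilight
guard; longwave from a sky-emissivity closure with a Stefan–Boltzmann
surface term. The coarse direct-beam field is the *minimum* of the fine
direct beam over each coarse cell's nearest-neighbour footprint, which
guarantees the regridded beam never exceeds the local global shortwave —
by construction the forcing passes every decomposition precondition with
zero clip events. Default domain for tests: 2 days on ~1°–2° boxes at 0.1°
(a few hundred cells), sizes chosen so the full suite runs in seconds while
exercising day/night, twilight and both accumulation conventions.

Station records are the collocated forcing at synoptic hours plus optional
Gaussian noise and field-level missingness. With zero noise the validation
recovers RMSE = bias = 0 to machine precision (residuals ~1e-13 °C reflect
summation-order differences in the 210-term polynomial, not model error);
with σ = 1 °C noise on Ta the Humidex RMSE converges to 1 °C (its Ta
sensitivity is exactly 1) within sampling error.

What passing these tests shows: the computation chain is internally
consistent, deterministic, convention-conformant and exact on its defining
identities. What it does not show: agreement with real station networks —
the synthetic fields have no weather systems, no spatial error correlation
between grid and station, and no representativeness mismatch, so the
recovery RMSEs say nothing about the accuracy of any reanalysis product.

## Known limitations

- Real ERA5-Land stamps accumulations at interval *end* (01:00…00:00+1d);
  the pipeline's dialect labels the same interval by its start. Ingesting
  native files therefore needs a one-label time shift upstream.
- The UTCI coefficients are transcribed, not fetched; the checksum guards
  corruption, and the dual-transcription cross-check guards typos, but both
  transcriptions share one published source.
- No CDS/remote retrieval: inputs are local NetCDF files only.
- NetCDF output is classic format (scipy backend), not NetCDF-4; files are
  small enough per day that chunking/compression is immaterial at test
  scale.
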