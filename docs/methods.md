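# Methods

This note documents the models, defaults, and numerical choices behind
`uvidose`, and what the synthetic-data validation does and does not
demonstrate about real station data.

## Solar geometry

Solar zenith angle (SZA, θ) and local solar noon come from the standard
low-precision Fourier-series ephemeris: a truncated series in the fractional
year for solar declination and the equation of time, combined with the hour
angle. Accuracy is a few hundredths of a degree over the 1950–2100 validity
window (checked in the test suite against an independent Meeus-style
apparent-position oracle with a 0.5° tolerance), which is far tighter than
anything the pipeline needs: the SZA enters through a 45° gate and through a
smooth power law. Refraction is ignored — it only matters within a degree or
two of the horizon, where the clear-sky UVI is already essentially zero.

All timestamps are UTC internally. Station-local civil time (the
`utc_offset` field, +3 h for the default station) is applied only when
grouping into local days or minutes-of-day. This matters at the default
site: civil time (UTC+3) differs from mean solar time (~UTC+2.9), so "noon"
is ambiguous unless one is explicit. Solar noon is always computed, never
assumed to be 12:00.

## Clear-sky UVI

The clear-sky model is the analytic power law

    UVI_cs = c · μ₀^p · (Ω/300)^q,    c = 12.50, p = 2.42, q = −1.23,

with μ₀ = cos θ and Ω the total ozone column in Dobson units. The form
captures the two dominant controls on surface erythemal UV — solar elevation
and ozone absorption — to within a few percent of full radiative-transfer
results for cloudless, low-aerosol skies at sea level. The coefficients are
fields of `ClearSkyParams`, not hard-coded: a station with persistent
aerosol load can recalibrate `c` or fold the effect into the constant
`clear_factor` (default 1.0).

Altitude enters as a linear rate: UVI × (1 + r·z) with r = 0.06 per km by
default (the UV altitude effect is usually quoted at 5–8 %/km; the rate is
configurable in [0, 0.25]). This replaces any layer-resolved treatment; over
the 0–2.4 km range of interest the linearisation error is negligible
compared with the power law's own accuracy.

Degenerate inputs: θ ≥ 90° returns exactly 0 (sun below horizon); Ω ≤ 0 is
rejected. The daily profile generator evaluates the law on a 1440-minute
grid covering the station-local calendar day, so the bell curve is unimodal
with its maximum at solar noon by construction.

## Sky classification

Two methods, deliberately independent of one another:

**Automatic filter (AF).** A minute is *clear* iff the nearest
cloud-fraction sample within ±2 minutes satisfies cf_total < threshold and
θ < 45°; *unknown* if no cloud-fraction sample lies within the matching
tolerance; otherwise *cloudy*. The ±2-minute tolerance is a design choice:
camera and radiometer clocks are nominally synchronous at 1-min cadence, so
anything beyond two minutes indicates a genuine coverage gap rather than
clock skew.

**Bell-shape filter (MF).** Automates the manual practice of inspecting each
daily profile against the clear-sky bell curve. A sliding window (default 60
minutes) is declared clear when at least `min_frac = 0.9` of its minutes
have relative deviation |UVI − UVI_cs| / UVI_cs ≤ `rel_tol = 0.10`; a minute
is clear if it belongs to any clear window. Minutes with UVI_cs below
ε = 0.5 UVI (twilight, night) are *unknown*: relative deviation is
meaningless when the denominator vanishes. The one-hour window reflects the
practice of selecting hour-long clear periods; `min_frac` < 1 tolerates
single-minute glitches without breaking an otherwise clear hour.

**Threshold selection.** The AF threshold is chosen from a grid (default
0.05…0.95 in steps of 0.05) by maximising agreement with the MF mask, ties
broken toward the smaller (stricter) threshold. Agreement is the fraction of
coinciding labels over minutes that neither mask marks unknown, and —
specifically for threshold selection — restricted to minutes inside the AF's
SZA gate. The restriction is deliberate: outside the gate the AF cannot call
a minute clear by construction, so including those minutes would measure the
gate, not the cloud threshold. `agreement()` itself accepts any restriction
mask, so both the all-minute and the gated figures are available.

On a 90-day two-regime simulation (clear cf < 0.1, cloudy cf > 0.5) the
selected threshold falls in the separation gap and the two methods agree on
~97 % of gated minutes — the expected behaviour when the regimes are truly
separable. On real data with a continuum of broken-cloud conditions the
agreement will be lower and the selected threshold less sharply identified.

## Doses and exposure

Unit conventions: 1 UVI = 0.025 W m⁻² erythemally weighted
(irradiance = UVI/40); 1 SED = 100 J m⁻². Each 1-minute sample is treated as
the mean irradiance over its minute; windows (default 60 s) tile the
station-local day from local midnight, which makes the daily total exactly
invariant to the window size on gap-free data.

Gap policy: gaps of at most 10 minutes are linearly interpolated; longer
gaps contribute zero dose and mark the day "partial"
(`result.attrs["partial_days"]`). Short interpolation keeps single missing
minutes from punching holes in an otherwise smooth bell; zeroing long gaps
biases the dose low rather than inventing sky conditions, and the partial
flag lets downstream consumers exclude those days.

The cumulative dose (CSED) is a per-local-day prefix sum. Phototype
exceedance reports, per day and per Fitzpatrick phototype, the first window
whose CSED reaches the tolerance. The default tolerance table
(I = 2.0, II = 2.5, III = 3.0, IV = 4.5, V = 6.0, VI = 10.0 SED/day) is on
the usual minimal-erythemal-dose scale; it is explicit configuration
(`PhototypeThresholds`) and is validated to be positive and nondecreasing
from I to VI. A threshold of zero is treated as crossing at the first
window with nonzero dose.

WHO exposure categories use half-open, lower-inclusive bins
[0,3) [3,6) [6,8) [8,11) [11,∞). Published descriptions of the scale vary
in where "high" ends and "very high" begins (6–8 vs 6–9, 8–11 vs 9–11);
this package follows the 6–8 / 8–11 convention of the WHO colour scale.

## Colocation and comparison

Space gate first (haversine distance to the station, mean Earth radius
6371 km — sub-1 % error, irrelevant at a 10-km gate), then a time gate
(nearest ground minute within 60 s). Multiple estimates surviving both gates
at one ground minute — e.g. several pixels of one overpass — are averaged
into a single pair.

Statistics: RD = 100·(estimate − ground)/ground [%], AD = estimate − ground
[UVI], means, medians, sample standard deviations, Pearson r and r². Pairs
with ground UVI below `rd_floor = 0.5` are excluded from RD statistics only:
near-zero denominators make RD diverge at twilight while AD remains well
defined. Both r and r² are reported since validation tables in this field
quote either; with fewer than two pairs, or a degenerate series, they are
NaN rather than a fabricated value.

The clear-sky stratum keeps pairs whose ground minute carries a `clear`
label; the all-sky stratum keeps every pair. When pixel-scale mismatch noise
affects only cloudy minutes — as the simulator can arrange — the clear
stratum's r² necessarily exceeds the all-sky one, which is the
qualitative pattern ground-vs-satellite validations show.

## Climatology

Monthly boxplot statistics: quartiles by linear interpolation, outliers
outside [q25 − 1.5·IQR, q75 + 1.5·IQR], whiskers at the most extreme
non-outlier points. The 1.5·IQR fence is the standard equivalent of the
"±2.7 σ" description for normal data and, unlike a σ-based fence, does not
let the outliers themselves inflate the fence on skewed UVI distributions.
Daily values are extracted at local solar noon (or noon + a configurable
overpass offset, default 60 min) as the nearest sample within ±5 minutes,
else missing. Diurnal cycles are keyed on station-local civil minute-of-day;
counts sum to the number of non-missing samples by construction.

## Synthetic-data generator

The generator's defaults emulate a west-coast tropical island station at
11.708° S, 43.247° E, 12 m a.s.l., UTC+3:

* **Ozone:** a seasonal sinusoid, 260 ± 15 DU peaking in austral spring —
  plausible magnitudes for ~12° S, exposed as configuration and never
  asserted as measurements.
* **Clouds (diurnal process):** a piecewise-linear baseline with ~0.55 total
  CF at dawn, a late-morning dip to ~0.45, and a maximum of ~0.8 near 17:00
  local; an AR(1) perturbation (φ = 0.95, innovation σ = 0.03) supplies
  minute-scale persistence; wet-season months (Nov–Apr) scale the baseline
  by 1.1, dry-season months by 0.9. A thin-cloud deck of 0.15 is present
  from 08:00 local onward; thick cloud is the remainder of the total.
* **Clouds (two-regime process):** alternating 120-minute blocks, clear with
  probability 0.5; clear minutes draw cf uniformly below 0.1, cloudy minutes
  uniformly above 0.5. This is the validation setting for the sky filters:
  the truth is unambiguous and the separation gap is known.
* **Cloud modification:** CMF = 1 − a·cf^b with a = 0.75, b = 2 — overcast
  skies remove 75 % of the clear-sky UVI, small cloud fractions attenuate
  mildly. On broken-cloud minutes (0.2 < cf < 0.7) the CMF is redrawn in
  (1, 1.2] with probability 0.05, modelling broken-cloud enhancement of up
  to 20 %. The functional form is a modelling choice constrained only by
  those attenuation/enhancement bounds; all parameters are configuration.
* **Sensor noise:** multiplicative Gaussian, σ = 2 %. Output is clipped to
  [0, UVI_cs × 1.2], so the generated series respects the physical bounds
  the rest of the package assumes.
* **Estimates:** satellite mode samples one instant per day at solar noon +
  60 min; model mode samples fixed forecast hours (03/06/09/12 UTC);
  sampled mode draws n random daylight minutes. The estimate is the truth
  smoothed over a ±15-minute window (a surrogate for coarse-pixel spatial
  mismatch; optionally applied only to cloudy minutes), scaled by a bias,
  plus Gaussian noise, with coordinates jittered uniformly within 8 km of
  the station.

Determinism: every generator takes an explicit integer seed; multi-day
campaigns spawn one child generator per day from a `SeedSequence`, so
identical seeds give identical campaigns regardless of platform.

**What passing tests show — and don't.** The simulator produces the right
orders of magnitude (clear-day noon UVI ~14 in austral summer, daily
clear-sky CSED of ~75 SED within the 40–80 SED envelope) and the right
qualitative structure (diurnal cloud cycle, cloud–UVI anticorrelation,
clear-stratum superiority in colocation). It does not reproduce real cloud
morphology, 3-D radiative effects, aerosol episodes, instrument drift, or
calibration error. A filter or statistic validated here is validated as an
algorithm — correctness against known truth — not as a claim about its
quantitative performance on any particular real station record.

## Problem sizes and tolerances

The validation suites use 90-day campaigns at 1-minute resolution (~130 k
minutes) for filter calibration and colocation, 300 days for
law-of-large-numbers checks of the cloud baseline (±0.02 per minute), and
3-day cloud-free campaigns for dose properties; these sizes give stable
statistics while keeping any single check in the seconds range. Dose
conservation is asserted to 10⁻⁶ across window sizes and 10⁻⁹ against a
second-by-second integration oracle; solar geometry to 0.5° against an
independent ephemeris; threshold selection must land in the generator's
separation gap [0.1, 0.5] with gated method agreement ≥ 0.90; bias recovery
to a median RD in [8 %, 12 %] for a true 10 % bias.

## Known limitations

* The clear-sky law has no aerosol or albedo physics beyond a constant
  factor; episodic aerosol would be misread as cloud by the bell filter.
* The bell filter's ε-floor leaves twilight minutes unknown; statistics
  near sunrise/sunset rely on the AF only.
* CSV is the only supported interchange format; native satellite formats
  must be extracted to overpass tables upstream.
* The equation-of-time-based noon is accurate to well under a minute, but
  noon *extraction* takes the nearest sample within ±5 minutes — on strongly
  broken-cloud days the extracted "noon UVI" can be a cloud-affected sample.
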