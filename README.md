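# uvidose

Analysis toolkit for ground-based erythemal UV-index (UVI) monitoring at
tropical stations: clear-sky UVI modelling, cloud-based sky classification,
standard erythemal dose (SED) accumulation against skin-phototype tolerances,
ground-vs-satellite colocation statistics, and climatological aggregation —
plus a fully deterministic synthetic-station simulator so the entire pipeline
can be exercised and validated without any data downloads.

The package is aimed at researchers operating UV radiometers alongside
all-sky cameras (which supply a per-minute cloud fraction, CF), who need to

* separate clear-sky from cloudy minutes reproducibly,
* convert UVI time series into health-relevant dose quantities, and
* validate satellite or model UVI estimates against the ground record.

## The model

**Clear-sky UVI.** An analytic power law in the cosine of the solar zenith
angle θ (μ₀ = cos θ) and the total ozone column Ω (Dobson units):

```
UVI_cs = 12.50 · μ₀^2.42 · (Ω / 300 DU)^(−1.23)          (θ < 90°, else 0)
```

with a linear altitude brightening of 6 %/km and an optional constant factor
for aerosols/albedo. All coefficients are configuration
(`ClearSkyParams`), not constants. Solar geometry comes from the standard
low-precision Fourier-series ephemeris (declination + equation of time),
accurate to well under the 0.5° this application needs.

**Sky classification.** Two independent methods produce a per-minute label
`clear / cloudy / unknown`:

* *automatic filter (AF)* — clear iff the matched cloud fraction is below a
  threshold **and** θ < 45°;
* *bell-shape filter (MF)* — an automated version of manually inspecting each
  daily UVI profile against the clear-sky bell curve: one-hour sliding
  windows are clear when ≥ 90 % of their minutes lie within 10 % of the
  reference.

The CF threshold of the automatic filter is selected by maximising agreement
between the two methods over a candidate grid.

**Doses.** 1 UVI = 0.025 W m⁻² of erythemally weighted irradiance;
1 SED = 100 J m⁻². Doses accumulate per window (default one minute), the
cumulative daily dose (CSED) resets at station-local midnight, and first
crossing times of Fitzpatrick phototype tolerances (I palest … VI darkest)
are reported per day. WHO exposure categories use the bins
[0,3) low, [3,6) moderate, [6,8) high, [8,11) very high, [11,∞) extreme.

**Colocation.** Estimates within 10 km (haversine) and 60 s of a ground
minute are paired (coincident estimates averaged); statistics are the mean
and median relative difference RD = 100·(estimate − ground)/ground, absolute
difference AD = estimate − ground, their spreads, and Pearson r / r².

## Worked example

```python
import uvidose as uv

station = uv.MORONI                     # 11.708° S, 43.247° E, 12 m, UTC+3
noon = uv.local_solar_noon(station, "2020-01-12")
sza = uv.solar_zenith_angle(station, noon).sza
print(noon, round(sza, 2), round(uv.clearsky_uvi(sza, 260.0), 2))
# 2020-01-12 09:14:29+00:00  10.08  14.35

# 30-day synthetic campaign with well-separated cloud regimes
cfg = uv.SyntheticConfig(seed=7, n_days=30, start_date="2020-01-01")
truth = uv.generate_campaign(cfg, regime=True)
thr, score = uv.select_cf_threshold(truth.uvi, truth.cf, truth.references, station)
print(thr, f"{100 * score:.2f}%")
# 0.1  97.64%

est = uv.generate_estimates(truth, cfg, "SAT", seed=8, bias=1.10, noise_sd=0.1,
                            mode="sampled", n_samples=200, smooth_cloudy_only=True)
pairs = uv.match(truth.uvi, est, station)
stats = uv.compare(uv.stratify_by_sky(pairs, truth.labels)["clear"])
print(f"median RD {stats.median_rd:.1f}%  r2 {stats.r2:.3f}  n {stats.n}")
# median RD 9.8%  r2 1.000  n 109
```

Reading the numbers: mid-January solar noon at the station is 09:14 UTC
(12:14 civil time) at a zenith angle of 10°, giving a clear-sky UVI of 14.4 —
"extreme" on the WHO scale. On the synthetic campaign the agreement-maximising
cloud-fraction threshold (0.1) falls inside the generator's clear/cloudy
separation gap, the two filtering methods agree on 97.6 % of gated minutes,
and the injected 10 % satellite bias is recovered as a 9.8 % median relative
difference with near-perfect correlation in the clear-sky stratum.

A command-line interface mirrors the library
(`uvidose simulate | filter | dose | compare | climatology`); see
`uvidose --help`.

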