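# Methods

## Analysis model

The quantity of interest is the conditional exceedance probability of soil
respiration,

    P_ex(c) = P(Rs > r* | c),   r* = site-mean hourly Rs,

for conditioning events c built from a heat state and, optionally, a
soil-moisture regime. Because the conditioning events are discrete, the
conditional density f(Rs | c) — formally a ratio of event-intersected
densities — is computed simply as the density of the Rs subsample
satisfying c; the two formulations are probabilistically identical for
event-type conditioning.

Two estimators of P_ex are produced. The **empirical** proportion
#(Rs > r*)/n is the headline number: it is distribution-free and satisfies
the law of total probability exactly, i.e.
P_ex(all) = P_ex(HW)·f_HW + P_ex(NHW)·(1 − f_HW) to machine precision on a
fully labelled record. The **KDE-integrated** value (trapezoid integral of
the fitted density above r*) is retained as a diagnostic because exceedance
is usually displayed as a shaded density area; the two agree within ~0.01
by n = 10⁵. Whether published percentages of this kind are counts or areas
is generally not stated, which is why both are reported.

### Heatwave definition

An hour is a heatwave hour (HW) when its air temperature **strictly
exceeds** the q-th percentile (default q = 0.85) of the long-term hourly
record pooled across years within its (month, hour-of-day) cell — 24
thresholds per month, at most 288 cells. Ties at the threshold are NHW
("exceeds" is read strictly). Quantiles use the linear-interpolation
order-statistic estimator at zero-based position (n−1)q, fixed so results
are bit-reproducible; the same estimator is used everywhere quantiles
appear. Feb 29 pools into February. Cells with fewer than `min_samples`
(default 30, one per required year) observations are left unpopulated, and
hours falling in unpopulated cells are excluded from analysis rather than
defaulted. The record must span at least 30 years (overridable for small
fixtures). The climatology is trained on the full station record including
the study period.

Classification is per-hour exceedance with no duration criterion: although
heatwaves are colloquially runs of consecutive hot days, the operational
rule here is hourly, and an optional `min_run_hours` parameter (default 1)
exists only for sensitivity analyses. Applied back to its own stationary
training record, the rule flags ≈ 1 − q of hours (0.15 ± 0.02 at q = 0.85),
which is the package's self-consistency check.

### Moisture regimes

Site-specific thresholds are the 30th (dry) and 70th (wet) quantiles of the
study-period soil-moisture record, fitted **after** temporal alignment with
the flux record; the neutral band between them is excluded from dry/wet
contrasts rather than merged into either tail, because only the tails are
contrasted. Strict inequalities on both sides (an hour exactly at a
threshold is neutral). Hours without a moisture observation are `unknown`
and never qualify for a moisture-conditioned event.

### Minimum-sample rule and KS test

Any conditioning subsample with fewer than 50 points yields an
"insufficient" result that is excluded from reports — small panels
misrepresent the underlying distribution. Distributional differences
between HW and NHW samples are tested with the two-sample
Kolmogorov–Smirnov test (asymptotic p-value, α = 0.05).

### KDE settings

Gaussian kernel, Silverman's rule bandwidth h, 512-point grid spanning
[min − 3h, max + 3h]. No boundary correction is applied at Rs = 0, so the
fitted density can leak slightly below zero for fluxes concentrated near
zero; this is a known limitation affecting the diagnostic KDE estimate
only, not the empirical one.

### Ingestion and alignment

Sub-hourly flux is averaged into hour-beginning bins [H:00, H+1:00); the
per-hour contributing count is retained. Timestamps are local standard time
with a fixed per-site UTC offset and no daylight-saving adjustment, because
the climatology is keyed by local clock hour. Flux and temperature are
joined by a strict inner match on clock hour (no nearest-neighbour
tolerance — whether published matching allowed any clock tolerance is
unstated, so exact matching is assumed); moisture attaches where available.
Gaps are dropped, never imputed. Readers drop and count unparseable rows,
support a configurable missing-value sentinel (NOAA-style archives), and
de-duplicate repeated hours keeping the first record with a warning.

### Diel cycle

Matched hours are grouped by local clock hour and heat state; mean, median
and quartiles are computed per cell from hourly means (not raw sub-hourly
records, for consistency with the rest of the pipeline). The "peak window"
— the shortest contiguous window containing all hours within 5% of the
cycle maximum, computed over all 24 rotations so it may wrap midnight — is
an artifact definition formalising what is usually read off a plot by eye;
a flat cycle degenerates to the full day.

### Multi-site synthesis

Cross-site means are unweighted arithmetic means over the sites where a
condition is populated (no weighting scheme is justified by the data
design), with the contributing site count attached. The relative change is
100·(mean_HW − mean_NHW)/mean_NHW rounded to the nearest percent. The
wet-vs-dry contrast is reported both as a ratio of cross-site means and as
a mean of per-site ratios, since either convention is defensible. The
annualised excess flux uses

    excess = (Rs_HW − Rs_NHW) × heat_fraction × 31,557,600 s yr⁻¹
             × 44.01×10⁻⁶ g μmol⁻¹   [g CO₂ m⁻² yr⁻¹]

with a Julian year and the molar mass of CO₂. No published formula exists
for this annualisation; this explicit duty-cycle convention is the
package's own and is printed wherever the number is reported. No
uncertainty is propagated across sites.

## Synthetic generator

The generator emulates a semi-arid site with a Mediterranean climate and a
one-year study record embedded at the end of a 30-year station record. One
master seed spawns named substreams (temperature noise, heat episodes,
precipitation, flux noise, missingness), so every component is
independently reproducible and the full chain is deterministic per seed.

**Temperature** (hourly, °C):
T(t) = 17 + 6·cos(2π(doy−201)/365.25) + 5·cos(2π(hour−15)/24) + AR(1) noise
(ρ = 0.8, innovation sd 1.5 °C, stationary initialisation), plus a +6 °C
boost over heat episodes arriving as a Poisson process (12 yr⁻¹) with
geometric duration (mean 48 h). The closed-form expectation per
(month, hour) cell is the harmonic mean function plus the episode
contribution rate·duration·boost/8766 ≈ 0.39 °C, which the tests verify.

**Soil moisture** (hourly, m³/m³): exponential drydown toward a floor of
0.18 with e-folding time 120 h (a realistic surface-soil drying scale of
~5 days), instantaneous pulses of 0.08 at Poisson precipitation arrivals
(0.008 h⁻¹ ≈ 70 yr⁻¹), a saturation ceiling at 0.37, and a small pre-dawn
dew bump (amplitude 0.005, peaking at 04:00). These bounds mirror the
0.18–0.37 m³/m³ range reported for semi-arid chamber sites.

**Respiration** (μmol CO₂ m⁻² s⁻¹):

    Rs(t) = R_ref · Q10^((T_lag(t) − T_ref)/10) · g(SM(t)) + ε(t)

with R_ref = 1.45 at T_ref = 17 °C, Q10 = 2, ε ~ N(0, 0.15²), and T_lag a
6-hour trailing mean of air temperature standing in for soil thermal
buffering. The moisture limitation g rises linearly from 0.4 at the
moisture floor to 1 at a saturation point of 0.33 m³/m³ (the field-capacity
value reported for such sites) and is flat above it — respiration
unresponsive to further wetting. R_ref is calibrated so the long-run mean
Rs sits near 1.1 μmol m⁻² s⁻¹, the documented magnitude for the semi-arid
reference site; this calibration is documentation, not a fitted or asserted
value. Records can be emitted 5× per hour (sub-hourly mode), and 7% of
records are removed uniformly at random, matching typical instrument-outage
rates.

**Ground truth.** `ground_truth_all_conditions` regenerates a long clean
realisation (default 10⁶ hours ≈ 114 years, no missingness), computes
thresholds, labels and r* directly with numpy — independent of the analysis
modules — and returns Monte-Carlo P_ex per condition with binomial standard
errors. The pipeline, run on ten independent one-year study records
(~8,000 matched hours each after missingness), recovers these oracle values
within ±0.03 for all six conditions.

**What the generator does not emulate**, and hence what passing tests do
not demonstrate about real data: precipitation seasonality and realistic
storm climatology; radiative/energy-balance coupling between temperature
and moisture (the two drivers are independent by construction, so
confounded real-world heat–drought covariance is absent); instrument drift
and autocorrelated observation error; spatial heterogeneity; phenology and
substrate-supply dynamics. Recovery results show the estimators are
unbiased under the stated stochastic structure, not that the Q10-moisture
model is the right model of any field site.

## Numerical choices and degenerate inputs

- Quantile estimator everywhere: linear interpolation between order
  statistics (deterministic, bit-reproducible).
- Strict ">" at every threshold (heat, moisture, exceedance); ties never
  qualify.
- Empty joins, empty label sets and sub-minimum subsamples raise or flag
  explicitly rather than returning defaults.
- A constant (zero-variance) subsample cannot support a KDE and is flagged
  insufficient for density purposes; its empirical exceedance is still
  defined.
- Every stochastic test fixes its seed; the one-year study size (~8,000
  matched records), the 5·10⁴-record null check, and the 10⁶-hour oracle
  are the problem sizes used throughout the test suite and the
  reproduction script.

## Known limitations

- No KDE boundary correction at Rs = 0.
- The annualised excess-flux formula is a stated convention, not a
  published derivation; treat cross-study comparisons of that number with
  care.
- Exact-hour matching may discard data from stations whose reporting times
  are offset from the flux logger's clock.
- The per-hour heatwave rule, without a duration criterion, counts isolated
  hot hours as heatwave hours; `min_run_hours` exists to probe sensitivity.
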