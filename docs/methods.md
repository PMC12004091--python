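# Methods

`ppafire` detects persistent positive anomalies (PPAs) of 500 hPa
geopotential height — the synoptic signature of blocking highs — in gridded
daily data, computes surface fire-weather indices, and quantifies the
association between PPA exposure and wildfire activity. This note records
the model, the numerical choices, and what the synthetic experiments do and
do not demonstrate.

## PPA detection

**Anomalies.** Daily Z500 anomalies are departures from a per-calendar-day
climatology (cross-year mean, no additional smoothing — the later 5-day
moving mean already suppresses day-level noise; a configurable climatology
smoothing window exists for short records). Anomalies are smoothed with a
centered 5-day moving mean (window shrinks at season edges and never
crosses the March–October season boundary) and scaled by
`sin(45°)/sin(lat)`. The latitude correction is the standard convention of
the persistent-anomaly literature: quasi-stationary height-anomaly
amplitude scales with the Coriolis parameter, so one magnitude criterion
can serve the whole domain.

**Threshold.** The magnitude threshold for calendar day *d* is built from
the *unsmoothed* latitude-corrected anomalies: pool every day whose
day-of-season index falls in a 28-day window centered on *d*, across all
years; take the per-cell sample standard deviation of that pool; average
over the domain. This yields one scalar per calendar day ("mean standard
deviation"), low in summer when gradients are weak. Two deliberate choices:

* *Unsmoothed* input. Had the threshold been the s.d. of the smoothed
  anomaly it would shrink by roughly √5 while the smoothed series gains
  strong day-to-day correlation; ~16 % of cell-days would then exceed
  "1 s.d." and five-day runs would be ubiquitous even in temporally white
  noise. With the raw-anomaly s.d., white-noise worlds produce essentially
  zero events (measured: 0 events in 20 null seasons), which is the
  behaviour a persistence detector must have.
* *Domain-mean* aggregation (scalar threshold). A per-cell variant is
  available behind `per_cell_threshold=True`.

**Flagging and tracking.** A cell-day is a PPA cell-day iff it lies in a
run of ≥ 5 consecutive days with smoothed, latitude-corrected anomaly
≥ 1 × threshold. Flagged cells are clustered per day (8-connectivity by
default; diagonal contiguity is standard for synoptic features). Clusters
on consecutive days are linked when they share ≥ 1 cell; merges continue
the largest-area parent, splits continue in the largest-area child, other
branches start new tracks carrying a parent link; a one-day interruption
ends a track (persistence is already enforced per cell). A track becomes a
**PPA event** when its daily area (spherical cell areas, R = 6371 km) ever
reaches 40 000 km².

**Durations.** The catalog reports two durations. `duration_days` is the
full track lifespan, including days before the size criterion is first met
(the "labelled object" reading). `qualifying_days` counts only days on
which the daily area meets the size criterion. The lifespan measure is
sensitive to single-cell appendages: any one member cell whose noise
extends its suprathreshold run by a day extends the whole track, and with
tens of member cells this inflates lifespans by ~2–3 days on synthetic
worlds. Recovery experiments therefore score duration with
`qualifying_days`, which matches injected durations to about ±1 day.

## Fire weather

VPD uses the Magnus saturation vapour pressure
`e_s(T) = 6.112·exp(17.67 T/(T+243.5))` hPa with `VPD = e_s·(1 − RH/100)`.
The Canadian Fire Weather Index System is implemented from the standard
published equations — FFMC (16 h lag), DMC (15 d), DC (52 d), then ISI,
BUI, FWI — driven by noon weather (°C, %, km/h, 24 h mm). Start-up codes
are FFMC 85 / DMC 6 / DC 15 at each season start, with no overwintering of
DC; day-length tables are the standard monthly values (46°N reference).
The step reproduces the system's canonical worked example to the printed
precision and agrees with an independently coded scalar transcription to
within 0.1 code units across randomized weather. HDWI is
`max(VPD) × max(wind)` over the supplied near-surface levels (maxima may
come from different levels; wind in m/s, conversions are explicit).
Extreme fire weather (FWIx) flags days whose FWI strictly exceeds the 95th
percentile (linear interpolation) of that cell's pooled values for that
calendar month.

## Association statistics

Each analysed cell-day is classified by exposure × outcome. A day is
*exposed* iff a PPA event covered the cell that day or within the
preceding 7 days of the same season (day-anchored reading: it partitions
days cleanly so a+b+c+d equals the number of analysed days, and is
symmetric with the zero-lag FWIx construction; the alternative
PPA-anchored reading of the no-fire category is not implemented). Outcomes
are fire-ignition days (7-day lag) or FWIx days (zero lag). Counts
accumulate per cell per calendar month across years; a day's month is its
own calendar month.

The odds ratio is `(a+k)(d+k)/((b+k)(c+k))` with the partial Haldane
correction k = 2 applied to all four cells of every table (k configurable:
0 gives the raw cross-product, 0.5 the classical Haldane). Cell-months
with no outcome days at all (a + c = 0) are flagged insufficient and carry
no OR; cells with no fire anywhere in the record are excluded from the
fire analysis. Regional summaries report mean, median, quartiles and the
share of ORs > 1 per region × month and pooled; the headline figure is the
mean of the regional means. Burned-area attribution is the percentage of
hectares falling on exposed cell-days, per region and pooled, plus a
histogram of burned area by days-since-last-PPA.

With k = 2 the per-cell-month ORs are strongly shrunk toward 1 for sparse
cells and right-skewed for zero-c cells; regional means of cell-level ORs
therefore sit above the pooled-table OR. The pooled-table estimator is the
one validated against ground truth (below).

## Diagnostics

The lead–lag composite freezes each event's footprint at its
maximum-strength day (strength = anomaly × area summed over member cells,
gpm·km²; ties break to the earliest day) and averages each surface anomaly
over that footprint at offsets −15…+15 days, then averages across events;
lags outside the season are dropped per event and contributing-event
counts are reported. The PPA-effect statistic is the t-statistic of the
slope from OLS of the daily anomaly on a PPA/non-PPA indicator per
cell-month — algebraically the pooled two-sample t (verified to 1e-10
relative) — so values are comparable across cells. Residual normality is
screened with Shapiro–Wilk on a cell sample and logged, never enforced.

## Synthetic worlds

The generator provides ground truth for every stage; it emulates
statistical structure, not atmospheric physics.

* **Background**: AR(1) in time (ρ = 0.8 by default, restarted each
  season) of spatially smoothed Gaussian noise (Gaussian kernel, length
  2 cells, periodic boundaries so marginal variance is uniform), scaled to
  marginal s.d. σ_z = 80 gpm — typical of summer mid-latitude Z500
  variability. Empirical normalization of the innovations keeps the
  per-cell s.d. within sampling error of σ_z (domain mean within ~2 % at
  20 seasons).
* **Events**: Gaussian bumps of radius 3–5 cells, duration 8–15 days,
  peak amplitude 1.5–3 × the *realized* seasonal threshold (the threshold
  is computed on the background world first, and the injection divides out
  the latitude correction, so detectability is controlled regardless of
  background parameters). The bump is truncated at its 1 × threshold
  contour — no sub-threshold skirt of marginal cells — and modulated by a
  temporal intensity arc (0.8 → 1.0 → 0.8, half amplitude on the first and
  last day) so the smoothed signal crosses the threshold at the true event
  boundaries and the maximum-strength day is well defined. Events are
  placed so that footprints can never touch, including across years when
  their calendar windows overlap — otherwise the cross-year climatology
  absorbs the injected amplitude.
* **Surface coupling**: on event cell-days, +4 °C, −15 % RH, wind × 0.7,
  each scaled by the intensity arc; wet-day probability × 0.3 during the
  event and for 3 days after (subsidence and dried fuels outlast the
  height anomaly — this is also the physical basis of the 7-day fire
  exposure lag).
* **Fires**: daily per-cell Bernoulli with baseline p₀ = 0.01; on exposed
  days (lag rule on the truth mask) the odds are multiplied by OR_true
  (default 3). Burned areas are log-normal (median 100 ha) — irrelevant to
  OR recovery but exercising the attribution sums.

Everything is deterministic under a fixed seed.

**Study conditions by experiment.** Detection-recovery and null-world
experiments use *fully i.i.d.* background (ρ = 0, no spatial smoothing), the
regime in which a persistence detector's false-positive behaviour is
meaningfully bounded; recovery events use amplitude 2.2–3 × threshold,
radius 3–4.5 cells (footprints of ~200 000 km², far above the size gate)
and duration 8–15 days over 4 seasons × 20 seeds. Odds-ratio recovery uses
the truth mask directly (6 events/season on a 20×25 grid, two years,
245 000 classified cell-days per replicate, 20 seeds per OR level). The
default autocorrelated world is used for the end-to-end pipeline run; note
that in red noise the detector legitimately finds many blocking-like
noise events — their surface couplings are null, which dilutes but does
not displace composite peaks.

**What passing does not show.** The generator's bumps are compact,
isolated and non-interacting; real blocks deform, split and interact with
the storm track, and real fire occurrence is zero-inflated, seasonal and
human-driven. Recovery results validate the machinery (thresholding,
clustering, tracking, classification, estimation), not climatological
realism; headline numbers from real reanalysis/burned-area data depend on
inputs this package does not ship.

## Numerical details and edge cases

* Missing values are NaN throughout and excluded from means, s.d. pools
  and percentiles; an all-missing regrid block stays missing.
* Cell ownership is half-open, `[center − res/2, center + res/2)`, so
  rasterization is a total partition and burned area is conserved up to
  the logged out-of-bounds records.
* Percentiles use linear interpolation between order statistics;
  "exceeding" is strictly greater, so a constant pool flags nothing.
* Event identifiers order by start date, then west-to-east centroid;
  max-strength ties break to the earliest day.
* Leap days cannot occur inside March–October; calendar days are keyed by
  (month, day).
* Degenerate t-statistics (empty group or zero residual variance) are
  flagged and carry no value rather than ±inf.
* Problem sizes in the test-suite and acceptance experiments (grids of
  18×22 to 24×36 cells, 2–4 seasons, 6–20 seeds) were chosen as the
  smallest at which the Monte-Carlo error of each recovery statistic is
  several times smaller than its acceptance band.

## Known limitations

* No negative-anomaly (cut-off low) detection, no hemispheric wraparound,
  no gap-bridging in tracks, no overwintering of the drought code.
* The scalar domain-mean threshold treats the domain as one variance
  regime; strong meridional variance gradients argue for the per-cell
  variant.
* Confidence intervals for ORs are not reported (a Woolf log-OR standard
  error would be straightforward but is deliberately out of scope), and
  t-statistic maps carry no multiple-testing correction — they are
  descriptive surfaces.
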