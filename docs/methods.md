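# Methods

`mobimood` re-implements a smartphone digital-phenotyping analysis: raw
duty-cycled GPS streams and twice-daily ordinal mood self-reports (EMA) go
in; daily mobility features, weekly feature–mood correlations, and
bidirectional day-lagged association models come out. Because no
participant data are deposited for studies of this kind, the package ships
a synthetic cohort generator whose defaults mirror the study design it
emulates, and every claim the package makes about itself is demonstrated on
that generator.

## GPS cleaning and imputation

Raw fixes (timestamp, UTC time, latitude, longitude, altitude, accuracy)
arrive as hourly CSV chunks. Cleaning follows a five-step protocol:

1. **Accuracy filter.** Keep fixes with reported accuracy strictly below
   51 m. Retention is logged; lowering the threshold can only reduce the
   number of retained fixes (a tested monotonicity property).
2. **10-second binning.** Fixes collapse onto a 10-s grid aligned to local
   midnight (UTC+8 by default; all daily aggregation uses the local
   calendar). Cell position is the mean of its fixes, which damps the
   speed spikes GPS drift produces at 1 Hz.
3. **Motion states.** A cell adjacent (10 s) to another observed cell is
   *moving* when the displacement strictly exceeds √10 m, otherwise a pause
   candidate; an observed cell with no observed neighbor is *undefined*;
   empty cells are *missing*. The four states partition the 8,640-cell day.
4. **Pause events.** Pause-candidate runs merge into one pause event when
   separated by ≤ 300 s and < 60 m (time-weighted centroids). Distances
   throughout are Euclidean in the spherical-Mercator plane, rescaled by
   cos(mean latitude); uncorrected Web-Mercator lengths would be ~10%
   inflated at 25° N. The corrected distance agrees with the haversine
   great-circle distance to < 0.5% for pairs under 10 km at that latitude
   (tested against an independent haversine oracle).
5. **Hot-deck imputation.** Duty cycling (1 min recorded per 10-min cycle)
   leaves ~91% of cells missing. Each gap is filled per realization:
   gaps whose flanking observations agree within 60 m become a pause at the
   flank midpoint; short (≤ 300 s) disagreeing gaps become one linear
   flight; longer disagreeing gaps get a flight connecting the endpoints at
   a speed resampled from the participant's own observed moving steps
   (donor pools split by half of day), placed at a random offset in the
   gap. Observed cells are never altered. `n_sim` (default 10)
   independent realizations are generated and daily features averaged over
   them; a day with no observations at all is flagged unimputable and its
   features are null with a reason code.

Sub-seeds for imputation derive deterministically from one master seed, so
a run is bit-reproducible.

## Daily mobility features

Location clusters are discovered **once per participant over the whole
study** — duration-weighted k-means on pause-event centroids, k grown until
every event lies within `d_max` (500 m) of its centroid — so homestay and
entropy are comparable across days. Home is the cluster holding the most
00:00–06:00 pause time over the study (falling back to the largest cluster
when there are no nocturnal pauses). Per day, per realization, then
averaged:

- **location variance**: ln(var(lat) + var(lon)) over all defined cells,
  in degrees² (a floor of 1e-12 keeps a motionless day finite); a switch
  restricts it to pause cells only.
- **speed mean / variance** over moving cells (displacement per 10 s).
- **total distance**: sum of adjacent 10-s displacements. On a complete
  (imputed) grid this is the whole path; unfilled gaps are *not* bridged —
  recovering that distance is the imputation's job.
- **transition time**: moving cells / defined cells.
- **number of clusters**: clusters holding pause time that day.
- **normalized entropy**: −Σ pᵢ ln pᵢ over the distribution of pause time
  across clusters, divided by ln(clusters visited); defined 0 when ≤ 1
  cluster. Transit time belongs to no location, so the time base is pause
  time.
- **homestay**: pause time in the home cluster / defined time.

Internally each realization is run-length compressed (pauses are long
constant stretches) and all statistics are computed run-weighted; a test
verifies exact agreement with a naive cell-by-cell recomputation.

## EMA handling

Four items (fatigue, depressed, elated/manic, irritable) on a 1–5 ordinal
scale, prompted at 12:45 and 17:00. The 12:45 response is the analysis
series; an unanswered 12:45 leaves the day missing (no fallback).
Between-prompt agreement is quantified with a two-way, absolute-agreement,
single-measure intraclass correlation — ICC(A,1) — computed within each
participant over dates with both prompts and averaged across participants;
the implementation matches pingouin's ICC(A,1) to 6 decimals in tests.
Missingness is reported per participant (fraction of follow-up days without
an analysis response) and pooled as an adherence percentage.

## Statistics

- **Weekly screen.** Per participant, consecutive 7-day blocks from the
  first feature day; a block counts when both series have ≥ 4 valid days.
  Features are summarized by the weekly mean, moods by the rounded mean
  category. The default uses the first qualifying block (`window="all"`
  averages every block). Feature–mood association uses the **polyserial
  correlation**: thresholds of the latent normal from inverse-normal
  cumulative proportions, then maximum likelihood for the latent ρ with
  thresholds fixed (the conventional two-step estimator — stable when
  ordinal cells are sparse), two-sided p from the observed information.
- **Day pairs.** Rows (participant, day 1, day 2 = day 1 + 1) with day-1
  levels, day-2 levels, and day-2 − day-1 changes for every feature and
  mood; incomplete rows drop per model (complete-pair analysis).
- **Lag models.** For each direction and (feature, mood) pair, a marginal
  linear GEE of the day-2 outcome on {Δ predictor, age, sex, predictor's
  day-1 level}, clustered by participant with an AR(1) working correlation
  and robust sandwich SEs. Sex is coded 1 = male, 0 = female. The AR(1)
  uses statsmodels' grid form (successive pairs within a cluster treated as
  one day-lag apart); with a few percent of days missing this only perturbs
  the nuisance correlation parameter, which the sandwich SEs do not rely
  on, and it is orders of magnitude faster than the generic
  distance-based form. With an independence working correlation the fit
  reproduces pooled OLS exactly (tested).
- **Power.** Fisher-z: required n = ((z₁₋α/₂ + z_power)/atanh ρ)² + 3
  rounded to the nearest integer (the rounding used by the standard
  tables: 29 at ρ = 0.5, 80% power; 38 at 90%), and achieved power
  Φ(|atanh ρ|·√(n−3) − z₁₋α/₂). Because required n rounds to nearest,
  power at the returned n can undershoot the target by up to ~0.005.

## The synthetic cohort

Defaults are the emulated study's conditions: 38 participants
(10 healthy controls, 11 bipolar, 17 major depression), 180 days, homes
within a few km of 25.04° N 121.56° E — a latitude chosen so that a wrong
Mercator convention would be visible. Per participant: a home plus 3
sites (office 1–6 km, others 0.5–4 km); each day a semi-Markov
pause/flight schedule with night at home, wake ~08:00, return by ~22:00,
log-normal stay durations, walking (1.4 m/s) or vehicle (8 m/s) flights.
The observation layer samples 1-min-on/10-min-off windows at 8 fixes per
window (~1,050 fixes/day, the order of magnitude such apps record), adds
GPS error as a per-window bias (σ 8 m) plus fix-level jitter (σ 1.5 m) —
i.i.d. noise per fix would fake motion between adjacent cells — and draws
accuracy values from a log-normal with ~95% below 47.6 m and ~4% above the
51 m filter threshold.

Mood: four latent AR(1) series (φ = 0.5, innovation σ 0.8) thresholded to
1–5. Coupling is planted bidirectionally **on the true features**, so
recovery error isolates the estimation pipeline: the day's change in true
location variance and homestay drives the latents (ΔLV→depressed −0.25
per log-unit; ΔHS→{fatigue, depressed, irritability} +2.0/+2.0/+1.5 per
unit homestay), and yesterday's latent changes shift today's homestay
target (+0.04/+0.04/+0.03 per unit of depressed/fatigue/irritability) and
far-site bias (−0.40/−0.25 per unit of depressed/fatigue). Effect sizes
are set for reliable *sign* recovery at study scale; the magnitudes of the
original models belong to data this package cannot see. Couplings apply to
the patient groups only, matching an analysis that fits lag models on
patients. EMA days go missing completely at random at rate 6.5% (the
study-reported range is ~3–8%); the 17:00 prompt is answered 95% of the
time with latent noise σ 0.3, giving realistic between-prompt ICCs.

What the generator does **not** emulate: hospitalization-driven dropout,
weekday/weekend structure, multi-day trips, indoor GPS loss, device
heterogeneity. Passing recovery tests therefore demonstrates the
estimation chain is sound under duty-cycled sampling and noise — not that
every real-world failure mode is handled.

## Validation experiments and problem sizes

`mobimood.experiments` packages the standard self-checks; the test suite
and `scripts/acceptance.py` both drive them.

- **Sign recovery**: 20 replicates of the full generate → preprocess →
  features → lag-model chain at study scale (38 × 180 days). Only the 28
  patients are materialized — per-participant seed substreams make their
  data identical whether or not controls are generated, and only patient
  data enter the lag models — with one imputation realization per day
  (realization averaging changes feature variance, not coupling signs).
  A replicate takes ~25 s on one CPU.
- **Null calibration**: 100 zero-coupling replicates at 15 × 60, fit on
  the generator's true features (the measurement layer cannot induce a
  dependence that is absent by construction), probing the GEE's type-I
  behavior.
- **Imputation benefit**: 20 duty-cycled days, comparing the
  10-realization average of daily total distance and the observed-only
  value against the continuous-path truth.

## Known limitations

- The motion-state threshold (√10 m / 10 s ≈ 0.32 m/s) sits close to the
  displacement noise of consumer GPS; transition time and speed features
  are therefore noise-sensitive (the generator reproduces this), while
  location variance, homestay, entropy and total distance track truth
  with correlations ≳ 0.97.
- Imputed flights are straight lines at donor speeds; road geometry is not
  modeled, so imputed total distance is a lower bound on true travel
  within a gap.
- The weekly polyserial screen treats the rounded weekly mood category as
  ordinal; with very low mood variance a participant's item can be
  constant and that pair drops out.
- ICC pooling (per participant, then averaged) is one of several defensible
  conventions; it is fixed and documented rather than configurable.
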