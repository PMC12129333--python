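# Methods

## Solar model

Declination and the equation of time use the Spencer (1971) Fourier
series, the same series behind the NOAA low-precision solar calculator
(declination accurate to ~0.1–0.3°, equation of time to well under a
minute). The test suite cross-validates it against an independently
implemented classical solar-position algorithm (geometric mean
longitude/anomaly with the equation of centre and true obliquity).
This precision is orders of magnitude finer than threshold geolocation
itself (100–500 km), so a full ephemeris would add nothing.

Times are decimal hours UTC; a sunset may exceed 24 h so that a
twilight pair stays ordered at far-east longitudes. Latitude from day
length is solved by bisection on φ after a 0.25° bracketing scan
(tolerance 10⁻⁴ °). Days with |δ| < 3.5° (≈ ±9 days around each
equinox) are flagged equinox-degenerate and withheld from latitude
estimation; the analysis-level ±7-day equinox window is applied
downstream by `flag_equinox`. Latitude search is bounded to [−40°, 80°],
the plausible envelope of an Afro-Palearctic system (configurable).

## Synthetic data: what it emulates, and what it does not

`simulate_track` draws an annual cycle that mirrors the study design:
tagging in early January at the Nigerian (9.87°N, 8.97°E) or Liberian
(8.12°N, −9.98°E) site (3:1 ratio); spring departure around 9 April
(Nigeria ~8 days later); stopovers spaced so legs average ~2,000 km
(duration from a ~27.5 km/h ground speed, rounded to the half day);
breeding at 45–70°N for ~109 days; an autumn return whose stopovers are
shifted east of the spring corridor (7.8° for Nigeria, 2.8° for
Liberia — the loop-migration signal); return by late
September/October. A quarter of birds use a secondary sub-Saharan
non-breeding site ~504 km from the main site before spring departure —
west-southwest for Nigerian birds, northward for Liberian birds.
Consecutive route sites are kept ≥ 4.2° of longitude apart, the
smallest relocation observed in this study system and about the limit
of what twilight curves resolve. Cohorts reproduce the study's
completeness mix exactly at n = 64 (41 full, 9 to breeding, 13 failed
in spring, 1 in autumn).

Twilight noise is one-sided: shading can only delay apparent sunrise
and advance apparent sunset, modelled as exponential with mean 8 min
per twilight plus a small symmetric jitter (σ = 2 min, clipped at 4σ).
The shading distribution is a free parameter of the generator, not an
empirical claim. Clock drift is linear over the deployment. The raw
light-log renderer writes full darkness as the logger floor value −1,
so the conventional threshold of −1 treats any reading above the floor
as genuine daylight (false positives are unlikely for an open-country
bird; false negatives from shading are common and handled by the noise
model).

Not emulated: wind and weather, fuel-dependent flight speeds,
behavioural variation in departure decisions, within-day light-curve
shapes (the log is a rectangle function), and revisits/backtracking
between non-breeding sites. Passing tests therefore show that the
estimators recover the *geometric and temporal* structure of tracks
under realistic twilight noise, not that they are robust to every
behavioural pattern in real tag data.

## Segmentation

The decision signal is the *longitude proxy*: twilight midpoint plus
the equation of time, in minutes — constant for a stationary bird in
any season (1° of longitude = 4 min). Boundaries are found by binary
segmentation under an L1 piecewise-constant cost, which is robust to
the heavy-tailed one-sided noise. The split penalty (25 minute-days)
was calibrated against the generator's noise model: pure-noise splits
have a 99th-percentile gain of ~30 minute-days, while a 17-min
relocation (the observed minimum, 4.2° of longitude) into a 3-day stay
gains ≥ 26 in 95% of draws — so the smallest observed relocations are
found for stays of three days and up, and false splits stay rare (and
are healed, below). Latitude-only relocations are detected separately
as steps of the EoT-corrected sunrise/sunset against a short linear
trend (threshold 30 min, two consecutive same-sign days); the trend
absorbs seasonal day-length drift, which reaches ~10 min/day at high
latitudes.

Post-processing: (a) false splits are healed by merging adjacent
segments whose longitude level is continuous and whose day-length step
across the join (a shared-trend + step fit, robust to outliers) is
below the latitude threshold — with two special cases: segments bridged
purely by midnight-sun days merge on longitude alone, and a short
fragment whose days are *shorter* than its neighbour's is a shading
artefact however large the step (shading can only shorten days);
(b) segments whose proxy drifts end-to-end beyond 30 min (slow
continuous migration) are relabelled migrating, as are short segments
sitting mid-way along a large longitude step with matching drift;
(c) edge days deviating from the segment core toward a neighbouring
level are trimmed back into the leg. Runs shorter than 2 stationary
days become migration days. Contiguous midnight-sun blocks attach to
the stationary period they abut (continuous light pins the bird to a
high-Arctic site even when no twilights exist), while missing days
never extend a period.

After threshold geolocation, boundaries are refined once more with the
forward model: days in a ±5-day window around each boundary are
reassigned by comparing observed twilights with the pairs predicted at
either period's location (L1, both twilights, in minutes), with a
fixed per-day cost of 30 min for staying a migration day and a stricter
0.6× threshold for *adding* days to a period than for shedding them
(near-arrival leg days are observationally close to the destination).
This exploits the latitude signal that the longitude proxy cannot see.

## Calibration and location

The sun elevation angle is calibrated by grid search (−9° to +3°, 0.1°
steps) minimising the *median* great-circle distance between the daily
threshold positions and the tagging site over the first 30 days of the
deployment, when the bird is known to be there. The median (not mean)
is used throughout for daily-position aggregation, for robustness to
residual shading outliers. A single calibrated angle per tag is applied
to all periods, so between-period comparisons are unbiased even though
individual locations carry error. Standard errors are sd/√n per axis.
Polar-day days are excluded from all location arithmetic (an Arctic
breeder is located from the shoulder days of its breeding period);
equinox-degenerate days are excluded from latitude only.

## Event tables and classification

Distances are haversine on a 6371.0-km sphere; durations are kept in
half days (boundaries at sunrise = .0, sunset = .5). The first period
of a deployment is always the main non-breeding site (the tag was
fitted there — the one certain location), as is the post-breeding
return within 250 km (or 2.5° of longitude with a sub-Saharan latitude:
longitude is the reliable axis). Secondary non-breeding sites are
sub-Saharan periods (< 18°N) at least 250 km from the tagging site
before the Sahara crossing, lasting ≥ 2 days. The breeding site is the
longest period north of 35°N (a configurable floor chosen for a
European breeding range). Spring runs from the departure from the last
sub-Saharan site to breeding arrival; earlier sub-Saharan moves are
intra-African and join the spring totals only when the include-
sub-Saharan toggle is on.

## Population statistics

Migratory spread is the mean over all unordered pairs of breeding
locations; its CI takes the 250th and 9,750th order statistics of
10,000 random pair draws (with replacement from the distinct unordered
pairs, seeded). Convex hulls and overlaps are computed on a Lambert
azimuthal equal-area projection centred on the points' centroid
(closed-form spherical projection feeding shapely), so km² areas are
comparable at the million-km² scale without spherical-polygon
machinery. The loop-migration statistic is the mean over birds of
(mean autumn stopover longitude − mean spring stopover longitude);
significance comes from permuting season labels within each bird
(seeded, two-sided, observed statistic included in the null set) —
a deliberate design choice over mixed-model inference, which preserves
the statistic while avoiding distributional assumptions.

Flight-time partitioning assumes a 43 km/h airspeed (radar-measured for
chat-sized passerines; 43.1 km/h where the worked example uses it) and
a linear fuel rule of 25 g per 5,000 km. The "further 12 g" of the
fastest-bird example implies departure reserves of ~13 g rather than a
full 25-g load, and the printed 13%/day deposition rate implies a lean
mass of ~13 g; both are therefore explicit parameters
(`departure_load`, `lean_mass`) with no hidden defaults.

## Problem sizes and numerical choices

The test suite and the acceptance script validate recovery on cohorts
of 40 full annual tracks at default noise (the pipeline tests use the
full 64-tag study mix once), with 10,000-draw randomization CIs,
199–1,000 permutations per test and 500 null runs for the
permutation-size study. Forward–inverse solar consistency is checked on
1,000 random configurations. All randomness is seeded; two runs of the
pipeline with the same seed produce byte-identical artifacts.

## Known limitations

* **Small relocations are invisible in principle.** A purely northward
  move of ~500 km at 8–12°N changes longitude by < 1.5° (< 6 min) and
  day length by ~8–13 min — at or below the noise floor of one-sided
  shading (σ ≈ 8–11 min/twilight) even when averaged over weeks.
  Synthetic Liberian-style northward secondary non-breeding sites are
  therefore frequently merged into the main site, and segmentation
  boundary recovery on the full synthetic cohort plateaus around
  80–85% rather than the 90% aspired to: roughly half the shortfall is
  these physically undetectable sites (each missed site costs two
  periods), the rest is ±2-day boundary ambiguity on legs whose
  longitude drift per day is smaller than the daily noise. Real
  analyses face the same wall; a relocation below ~4° of longitude was
  never *observed* in this study system precisely because it cannot be
  seen.
* Slow legs can contain 2-day stretches indistinguishable from genuine
  2-day stopovers; about one such spurious short "stopover" per track
  remains at default noise (the glossary point that legs may include
  daily rests below the 2-day detection limit, seen from the other
  side).
* Latitude carries a systematic error of 1–3° away from the calibration
  season, because a single calibrated sun-elevation angle maps shading
  onto different latitude biases as declination changes; classification
  rules that involve latitude therefore lean on longitude wherever
  possible.
* The equal-area projection treats polygons' edges as straight lines in
  the projected plane, adequate at continental scale but not for
  hemispheric polygons.
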