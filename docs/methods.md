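# Methods

## Annotation data model

The unit of observation is one species' calling within one annotated minute
of an hourly PAM recording: site, ISO date, month (`YYYY-MM`), hour (0–23),
minute index within the hourly record (1–5), species (empty for a silent
minute), calls per minute, the measured per-call features (dominant
frequency in Hz, number of notes, number of pulses, optional duration), band
SPLs at 1–5 kHz in dBFS, and a categorical rain index (0 none, 1 light,
2 heavy). Silent minutes are first-class records: acoustic-presence
percentages and per-hour mean call rates need them in their denominators.
Daylight is defined as hours 6–18 inclusive (dawn and dusk included),
night as 19–23 and 0–5; the two sets must partition the day.

The on-disk format is a single UTF-8 CSV with one row per (minute, species)
and per-call features serialized as `freq:notes:pulses[:duration]` triples
joined by semicolons. Floats are written with `repr` so the round trip is
lossless. Rows violating the data model are rejected with file row numbers.

## Resource classes and niche breadth

Call structure occupies 25 classes in three blocks: 9 frequency classes
(500 Hz wide over 500–5000 Hz), 5 note classes (1–5 notes) and 11 pulse
classes (class 0 for tonal calls, nine classes of width 3 for 1–27 pulses,
one class for >27). Every measured call contributes one count to each
block, and the blocks are normalized to carry 1/3 of the profile mass each;
otherwise the 11-class pulse block would dominate breadth and overlap simply
by having more classes. Features outside the binning range (the field
screening window is wider than the class range) are clamped to the nearest
edge class with a warning rather than dropped, because silent truncation
would bias profiles invisibly.

The diel profile is the normalized vector of mean call rate per hour
(silent minutes included in the means); the seasonal profile the analogue
per study month, with the class list taken from the site's survey design —
a site lacking a usable month has correspondingly fewer seasonal classes
(6 instead of 7 at the lower of the two packaged sites).

Breadth is inverse Simpson, NB = 1/Σp², standardized as
NB\* = (NB − 1)/(r − 1). A species with zero recorded activity has an
*undefined* profile, and every downstream computation refuses it explicitly
— treating it as zeros would fabricate a specialist.

The total niche is the weighted concatenation of the three dimension
profiles (default weights 1/3 each), standardized by
r_total = 25 + 24 + r_seasonal. This additive model reduces exactly to a
single dimension under degenerate weights. Cross-site totals are only
comparable on a shared class scheme, so cross-site overlap and clustering
recompute seasonal profiles on the union of the sites' month lists, with
unsampled months contributing zero use.

## Overlap, null model, and comparison statistics

Overlap defaults to Schoener's proportional similarity
1 − ½Σ|p − q| — bounded, symmetric, equal to 1 iff the profiles coincide —
with Pianka's product-moment index available by flag. The community matrix
reports the mean and the *sample* (n − 1) standard deviation of the
off-diagonal upper triangle.

The no-partitioning null draws each overlap value as the mean of 10
independent uniform(0, 1) numbers (expectation 1/2, sd √(1/120) ≈ 0.0913).
Whether the 10-draw averaging is replicated per pair or per community is a
free parameter (`reps`); all draws flow from one explicit seed. Empiric and
null samples are compared with the classical pooled-variance two-sample *t*
(Welch by flag; the choice matters little at these sample sizes) and a
variance-ratio *F* oriented as larger/smaller variance with the orientation
reported alongside.

`equal_partition_breadth(n)` = 1/n is the standardized breadth each species
would hold if the standardized niche space were split exclusively and
equally — the natural reference point for a saturated community of n
species.

## Clustering and rarefaction

Overlap is converted to the dissimilarity 1 − NO (not necessarily metric —
no triangle inequality is claimed) and clustered agglomeratively with
complete linkage, implemented directly (naive O(n³), adequate for community
sizes) with deterministic lexicographic tie-breaking on sorted leaf labels.
Complete linkage guarantees non-decreasing merge heights; the dendrogram
exports to JSON and to an ultrametric Newick whose node depths equal merge
heights. The independent cross-check in the test suite is
`scipy.cluster.hierarchy` via cophenetic distances on random instances.

Rarefaction codes species as incidence per sample unit — a calendar date at
a site, or a single annotated minute — within one period (daylight/night),
then averages the accumulation of richness over randomized sample orders
(default 100, seeded). The 95% band is mean ± 1.96 sd over randomizations,
i.e. the spread of the randomization procedure itself rather than an
analytic (Mao tau style) variance; at the full sample count every
randomization returns the observed richness exactly.

## Band SPL and noise–activity models

Band SPL uses a 1024-point FFT with a Blackman–Harris window and 50%
overlap; the band value is the single bin nearest the requested center
frequency (the annotation convention is "level at f kHz", not an integration
bandwidth), power-averaged over frames. Levels are referenced to digital
full scale (a full-scale sine at a bin center reads 0 dBFS; coherent-gain
normalization) with a numeric floor of −120 dB, because the absolute
calibration of autonomous recorders is generally unknown — all SPL values
are relative noise proxies. The 1 kHz band proxies geophony (rain, wind),
the mean of the 4 and 5 kHz bands the daytime bird chorus.

Calling activity (CA) is related to noise by OLS either of √CA on SPL
(reported as CA = (a + b·SPL)², the square-root-y model; note the algebraic
sign ambiguity of the square root — on data where a + b·x < 0 throughout,
the magnitude line is recovered and the squared fit is identical) or of CA
on SPL (linear model). R² and the slope p-value are reported on the fitted
scale. Rain contrasts are stratum means of per-minute call rate under
rain index < 2 vs = 2, counting minutes where the species was silent as
zeros so that suppression shows up as a lower mean rather than a smaller
denominator.

## Synthetic community generator

The generator emulates the survey design (two sites, 7 and 6 study months,
hourly 5-minute records, a configurable number of days per month — default
3, matching the handful of fully analyzed days per site-month in this kind
of campaign). Per hour, rain occurs i.i.d. with configurable probability
and severity split; band SPLs are a baseline plus rain increments
(1 kHz-dominated), a daylight dry-weather bird increment (4–5 kHz) and
Gaussian jitter. Per minute and species, the call count is Poisson with
mean

    diel_rate[hour] × seasonal_mult[month] × site_mult[site]
      × max(0, 1 + day_bird_response)   (daylight hours)
      × rain_suppression                (heavy rain)

and one call's features are drawn per active minute (truncated-normal
frequency via inverse-CDF, categorical notes and pulses), mirroring the
field protocol of measuring the first recognizable call per species per
minute. All randomness flows from one `numpy` Generator seeded explicitly.

Because every ingredient is analytic, `expected_profiles` returns the
implied niche profiles without simulation: frequency-class mass from the
truncated-normal CDF (edge classes absorb the clamped tails), note/pulse
mass from the categorical laws, the diel profile proportional to
`diel_rate × bird factor` (the rain factor scales all hours equally and
cancels under normalization), and the seasonal profile proportional to the
monthly multipliers (per-month *mean* rates make the number of days per
month cancel). Parameter-recovery tests generate ≈54,600 minutes (35 days
per site-month) and require every per-dimension NB\* and every pairwise
total-niche overlap to land within ±0.02 of these expectations — a
tolerance that presupposes on the order of a thousand measured calls per
species, so the recovery configuration gives every species a floor of
activity in all hours and months. The packaged
`virunga_community_config` instead mirrors the study community
qualitatively — a dominant nocturnal high-frequency caller that calls by
day mainly at the high site, a diurnal tonal species concentrated at the
low site, two low-frequency pulsed species, a broadband day-and-night
caller, and a genuinely rare species — whose scarce data are *not*
expected to recover to ±0.02, exactly as a field rarity would not.

What the generator does **not** emulate: chorusing correlation between
individuals and species (counts are independent Poisson, so call-rate
magnitudes and presence percentages cannot both match field values — rates
were calibrated to presence levels), bimodal dominant-frequency
distributions (a wide unimodal truncated normal stands in for the
broadband species), within-day weather persistence, moonlight and
temperature effects. Passing recovery tests therefore demonstrates the
correctness of the estimation chain under the stated sampling laws, not the
realism of any particular field dataset.

## Numerical and design choices

- Profiles must sum to 1 within 1e-9; overlap matrices must be symmetric
  with unit diagonal to 1e-12.
- Tie-breaks: clustering merges the lexicographically smallest tied pair.
- Stage seeds in the pipeline derive from the root seed and the stage name
  via `SeedSequence([seed, crc32(name)])`, so stages are independently
  reproducible and reruns are byte-identical.
- The degenerate-input policy is to raise (empty strata, zero-variance
  regressors, undefined niches, fewer than two species), never to return a
  silently imputed value; the one deliberate exception is clamping of
  out-of-range call features, which warns.
- The pipeline skips the empiric-vs-null t/F comparison for communities
  with a single species pair (one empiric value has no variance) and says
  so in the log.

## Known limitations

- The additive total-niche model is one defensible choice among several;
  published per-dimension and total breadths from field studies are not, in
  general, mutually consistent under any simple concatenation model, so
  total-niche values should be compared only within a fixed weighting.
- 1 − overlap is not a metric; complete linkage does not require it, but
  ordination methods that do should not consume these distances.
- Band SPL in dBFS is comparable within a recorder/gain setting only.
- Rarefaction confidence bands reflect randomization spread, not sampling
  variance of the underlying community.
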