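# anuraniche

Acoustic niche partitioning analysis for anuran (frog) communities surveyed
by passive acoustic monitoring (PAM).

Male frogs advertise acoustically, and mixed-species choruses are expected to
partition the acoustic resource space — call structure (dominant frequency,
notes, pulses), time of day, and season — so that interference and
competition are reduced. `anuraniche` implements the community-level
statistics used to test that expectation on per-minute call-annotation
tables: standardized niche breadth, pairwise niche overlap with a
randomization null, cross-site niche clustering, sample-based rarefaction of
acoustic species richness, and band-SPL noise proxies with noise–activity
regressions. A synthetic community generator with closed-form expectations
makes the whole chain testable end to end without field recordings.

## The statistics

For a species' resource-use proportion vector *p* over *r* resource classes:

- **Niche breadth** is the inverse Simpson concentration
  NB = 1 / Σᵢ pᵢ², standardized to NB\* = (NB − 1)/(r − 1) ∈ [0, 1]
  (0 = specialist using a single class, 1 = generalist using all classes
  uniformly).
- **Resource classes**: call structure uses 25 classes — 9 dominant-frequency
  classes (500 Hz wide, 500–5000 Hz), 5 note-count classes (1–5), and 11
  pulse-count classes (tonal, nine 3-pulse-wide classes for 1–27 pulses,
  and >27 pulses). The diel dimension uses 24 hourly classes of mean call
  rate, the seasonal dimension one class per study month at the site. The
  total acoustic niche is the additive (weighted concatenation) combination
  of the three dimensions.
- **Niche overlap** between species *p* and *q* defaults to Schoener's
  proportional similarity, NO = 1 − ½ Σᵢ |pᵢ − qᵢ| (Pianka's index by flag).
- **Randomization null**: in the absence of partitioning, a null overlap
  value is the mean of 10 uniform(0, 1) draws — expectation 0.5, standard
  deviation √(1/120) ≈ 0.091. Empiric and null distributions are compared
  with a pooled two-sample *t* and a variance-ratio *F*.
- **Cross-site comparison**: overlap is turned into the dissimilarity
  1 − NO and clustered by complete linkage; conspecific niches from
  different sites clustering together indicates that call structure, not
  local activity timing, anchors the niche.
- **Rarefaction**: species are coded as incidence per sample unit (day or
  minute), and richness accumulation is averaged over randomized sample
  orders with a 95% band from the randomization spread.

## Worked example

```python
from anuraniche import (virunga_community_config, generate_dataset, to_frame,
                        acoustic_presence, niche_breadth, call_structure_profile,
                        community_overlap_matrix, random_overlap_null,
                        empiric_vs_random_test)
from anuraniche.pipeline import site_total_profiles

cfg = virunga_community_config(seed=1, days_per_month=3)   # 6 species, 2 sites
df = to_frame(generate_dataset(cfg))

for period in ("daylight", "night"):
    print(f"Sandi {period} presence: {acoustic_presence(df, 'Sandi', period):.1f}%")

totals = site_total_profiles(df, "Sandi", cfg.design)
for sp in sorted(totals):
    b = niche_breadth(call_structure_profile(df, sp, "Sandi"))
    bt = niche_breadth(totals[sp])
    print(f"{sp:28s} NB*_call={b.nb_star:.2f}  NB*_total={bt.nb_star:.2f}")

m = community_overlap_matrix(totals)
null = random_overlap_null(len(m.upper_triangle()), reps=667, seed=1)
tf = empiric_vs_random_test(m.upper_triangle(), null.values)
print(f"overlap mean {m.mean():.2f} ± {m.sd():.2f}; "
      f"null {null.mean:.2f} ± {null.sd:.2f}; t = {tf.t:.2f}, F = {tf.f:.2f}")
```

prints

```
Sandi daylight presence: 84.6%
Sandi night presence: 100.0%
amietia_desaegeri            NB*_call=0.08  NB*_total=0.12
hyperolius_castaneus         NB*_call=0.15  NB*_total=0.30
hyperolius_glandicolor       NB*_call=0.10  NB*_total=0.27
leptopelis_karissimbensis    NB*_call=0.09  NB*_total=0.25
leptopelis_kivuensis         NB*_call=0.16  NB*_total=0.31
phrynobatrachus_bequaerti    NB*_call=0.64  NB*_total=0.49
overlap mean 0.48 ± 0.15; null 0.50 ± 0.09; t = -0.65, F = 2.64
```

Calling is concentrated at night; call-structure niches are narrow
(NB\* ≈ 0.1) for the frequency specialists and broad for the broadband
caller; the community overlap scatter is well below the null scatter
(F > 1 with the empiric sample as numerator here refers to orientation —
see `TFResult.f_numerator`).

## Command line

```sh
anuraniche simulate --seed 1 --out data.csv        # synthetic survey
anuraniche validate data.csv
anuraniche presence data.csv --site Sandi --period night
anuraniche niche data.csv --site Sandi --out breadth.csv
anuraniche overlap data.csv --site Sandi --seed 7 --out overlap.csv
anuraniche cluster overlap.csv --out dend.json --newick dend.nwk
anuraniche rarefy data.csv --site Sandi --period night --seed 7 --out curve.csv
anuraniche spl recording.wav
anuraniche run --config run.yaml                   # full pipeline + manifest
```

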