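# Methods

## The categorical framework

The pipeline re-assesses the extinction risk of North American shorebird
taxa by layering climate-driven risk on top of the U.S. Shorebird
Conservation Plan (USSCP) ordinal categories (1 = Not at Risk … 5 = Highly
Imperiled). Six factors are scored per taxon, each on a small fixed menu of
levels; a level carries both a PIF-style score and a signed arrow count
(`src/shorebird_risk/factor_model.py` is the single source of truth for the
menus):

| factor | levels (score / arrows) |
|---|---|
| breeding, wintering, migration habitat | 5/+2, 3/+1, 0/0, −3/−1, −5/−2 |
| ecological synchronicity | 5/+2, 3/+1, 0/0 |
| migration distance (rank 1–5 = score) | 5/+2, 4/+1, 3/+1, 2/0, 1/0 |
| habitat specialization | 5/+2, 4/+2, 3/+1, 0/0 |

All factors carry equal weight. Two properties of the menus matter
downstream: scores determine arrows uniquely, but arrows determine scores
only up to a choice for two menus (distance +1 → score 4 or 3; distance 0 →
2 or 1; specialization +2 → 5 or 4). Published assessment tables print
arrows, so when reading arrow cells the package maps each arrow count to the
*highest* score carrying it. This convention is documented rather than
consequential: only arrows enter the transition rule, and total scores are
descriptive output.

## Transition rule

With net arrows `A` (algebraic sum over the six factors; an up-arrow and a
down-arrow cancel) and threshold `T` arrows per category step:

    delta   = sign(A) * floor(|A| / T)
    revised = clamp(current + delta, 1, 6)

The source framework states the single-step criterion (4 net arrows shift
one category) and a two-step worked example; the floor rule is the unique
simple extension consistent with every row of the published table —
verified exhaustively in the test suite, 52/52 rows at `T = 4`. Category 6
(Critical) is an absorbing cap; no higher category is ever created, and the
*realized* delta reported per taxon is `revised − current` after clamping
(a Highly Imperiled taxon with 8 net arrows therefore realizes +1, not +2 —
this is how the published change histogram of 7/33/12 counts it). Downward
revision is permitted by the rule; no taxon in the bundled data triggers
it, but six carry at least one down-arrow.

Arrows, not scores, drive transitions. A total score of 10 can arise from
2, 3 or 4 arrows, so a score-thresholded rule is ill-defined; the arrow
rule reproduces the published table exactly.

## Sensitivity analysis and reconciliation

`sensitivity.sweep` recomputes the assessment at thresholds 7, 6, 5, 4, 3
(most to least conservative) and tabulates category distributions against
the current-category baseline. The published sensitivity table is bundled
as reference data (`PUBLISHED_SENSITIVITY`); six of its cells do not
reconcile with its own per-taxon arrow data (the 6-arrow column's High
Concern/Critical cells and the Highly Imperiled/Critical cells at 4 and 3
arrows, each off by one or two). The baseline and 7-arrow columns reconcile
cell-for-cell and serve as hard test targets; the divergent cells are
emitted in a reconciliation report and never asserted. Recomputation from
the row data is authoritative throughout, which is why the package reports
45 taxa (87%) increasing risk and 14 Critical at `T = 4` even where summary
prose elsewhere rounds differently.

## Migration geometry

Migration distance is the great-circle distance between the centers of the
breeding and wintering ranges. Numerical choices:

* **Earth model**: sphere, R = 6371.0 km, haversine distance. The 5-rank
  classification is far coarser than the sphere/ellipsoid difference
  (< 0.6%), so ellipsoidal geodesy is deliberately out of scope.
* **Range center**: the spherical center of mass — the surface integral of
  the unit position vector over the polygon, normalized. For polygons
  bounded by great-circle arcs the integral reduces exactly to the boundary
  sum `½ Σ_e n̂_e Δσ_e` (edge-plane unit normal × arc length), so no
  triangulation or sampling error enters; the tests validate it against an
  independent Monte-Carlo surface-sampling oracle. Multi-part ranges sum
  the unnormalized integrals, i.e. parts are area-weighted. Degenerate
  inputs (zero area, antipodal symmetry) raise rather than return an
  arbitrary point. Polygons spanning a pole are outside the supported
  domain.
* **Classification**: Jenks/Fisher natural breaks (exact dynamic program
  minimizing within-class sum of squared deviations; brute-force-verified
  for n ≤ 12), boundaries placed midway between adjacent-class extremes,
  ranks half-open `[b_{r−1}, b_r)`.
* **Default breaks**: the source framework defines its five distance
  classes only graphically; the calibrated defaults (2000, 4500, 7000,
  9500 km) are chosen once so that the single numerically stated distance
  (7886 km, rank 4) classifies correctly, and are configurable everywhere
  breaks are accepted.
* **Known-distance overrides**: taxa whose wintering range falls outside
  the range database (Bristle-thighed Curlew, Bar-tailed Godwit) get their
  rank set directly (`override_rank`), with the replacement recorded in the
  profile's notes.

## Bundled data

`data/usscp_climate_table.csv` holds the 52-taxon assessment (49 species;
Willet, Piping and Snowy Plover split into coastal/inland or east/west
populations), with per-factor arrow responses, the current USSCP category,
and each taxon's independent State of the Birds 2010 score. Scientific-name
spellings are copied as printed in the source table (including the Killdeer
misspelling "Charadrius vociferous"); the bundle is integrity-checked by
sha256 and row count at load. Arrow cells are stored in the ASCII dialect;
I/O accepts unicode arrow runs, ASCII signed integers, and a letter
shorthand interchangeably. Per-factor confidence scores (1–5) are carried
through I/O when present but never enter any computation — the framework
defines no arithmetic over them.

## Synthetic data

The generator exists so every stage is testable without proprietary range
maps or additional field data.

* `generate_profiles` draws factor levels independently per factor from
  configurable categorical distributions; the defaults are the empirical
  level frequencies of the bundled table, so a default cohort matches the
  study population marginally. What it does **not** emulate: within-taxon
  correlation between factors (real coastal specialists share habitat
  responses), phylogenetic structure, and the hand-assigned nature of real
  levels. Passing tests on synthetic cohorts therefore demonstrate the
  *mechanics* (validity, determinism, aggregation arithmetic), not that the
  framework's judgments generalize.
* An optional linear link (`ExternalScoreModel`) couples an external 0–5
  score to net arrows with Gaussian noise, rounded and clipped; it exists
  to verify that the concordance statistic recovers strong/weak coupling
  monotonically. Rounding alone caps r² below 1 even at zero noise.
* `generate_range_pair` builds approximately circular range polygons
  (geodesic radius with ±8% seeded radial jitter, ≥ 8 vertices) around
  requested centroids, so centroid separation is known by construction;
  recovery is ~0.1° in centroid position and well within 1% in distance at
  the default 24 vertices.

All randomness flows from one integer seed through one
`numpy.random.default_rng` stream per call; outputs are bit-reproducible.

## External concordance

`concordance_r2` is the squared Pearson correlation (scipy). Paired with
net arrows the bundled data give r² ≈ 0.22, and paired with realized delta
≈ 0.24 — loose agreement with the external State of the Birds scores, of
the same order as the originally reported 0.27, whose exact variable
pairing is unstated. This quantity is exploratory; the estimator itself is
validated on closed-form cases.

## Problem sizes and determinism

The assessment is a 52-row categorical computation; everything printed by
the analysis drivers and the acceptance script recomputes in well under a
second. Test-suite simulations use cohorts of 20 000 draws for the
mean-net-arrows calibration check (3-standard-error band against exact
enumeration of the 7 500-combination level grid) and 4 × 10⁵ Monte-Carlo
samples for the centroid oracle; these sizes keep sampling error an order
of magnitude below the tolerances they check.

## Known limitations

* Confidence scores are metadata only; no uncertainty propagates into the
  revised categories.
* The transition rule treats arrows as interval-scaled within a factor and
  additive across factors — inherent to the source framework, not a
  modeling choice made here.
* Polygons crossing themselves, enclosing a pole, or spanning more than a
  hemisphere are rejected rather than handled.
* The bundled table is the printed assessment; where its own summary prose
  disagrees with its row data, the row data win and the disagreement is
  reported, not reconciled.
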