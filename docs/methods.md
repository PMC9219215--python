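# Methods

## Data model and coordinate conventions

The unit of observation is a dendritic spine followed across N ≥ 2
imaging sessions of the same dendritic segment. Positions are arc
length in µm from the segment's proximal end, measured along the trace
of the dendritic shaft (base of neck to base of the next spine's neck);
every inter-spine distance used anywhere in the package is |Δ arc
length|, never a Euclidean straight line. The distance from a spine to
the nearest amyloid-plaque edge is a pre-measured 3-D scalar supplied in
the annotation table — raw image analysis (registration, detection,
3-D distance measurement) is upstream and out of scope. Spine identity
across sessions is the annotator's: one row with a presence vector.
A lost-then-reappeared spine may be encoded either as a single row with
presence (1,0,1) or as two rows (lost + new); the restoration module
resolves the second encoding by distance matching.

## Fate classification and turnover

Over interval (tᵢ, tᵢ₊₁): presence (1,1) → survived; (1,0) →
eliminated; (0,1) → formed. Survivors split by cohort: a spine first
present at tᵢ (with i ≥ 1) was formed in the preceding interval and is
*survived_new*; all other survivors are *survived_old*. Formation and
elimination rates use the number of spines present at the interval's
first session as denominator — the standard convention in longitudinal
spine imaging; with an empty denominator the rates are flagged
undefined rather than reported as zero. The animal-level rate is the
unweighted mean of the animal's segment rates ("averaged per animal");
weighting by spine count is available via
`AnalysisConfig.weight_animal_mean_by_spines` but off by default, so
short segments are not silently down-weighted.

## Plaque zones

Events with a plaque distance d map to: proximal (d < 25 µm),
intermediate (25 ≤ d ≤ 60 µm, both bounds inclusive because the range
is quoted inclusively while proximal is quoted strictly), unassigned
(60 < d ≤ 100 µm) and distal (d > 100 µm). The 60–100 µm band belongs
to no named zone in that scheme and is deliberately kept as its
own category instead of being merged into either neighbour. Spines
without a plaque distance (plaque-free genotypes) form a `no_plaque`
category that the analysis treats as distal-equivalent by default
(`missing_plaque_to_distal`). A secondary two-bin scheme (< 25 µm vs
> 25 µm) is used for survival summaries.

## Cluster statistic and its null

Two or more same-type events (formations, or eliminations) whose
consecutive arc-length spacings are each ≤ 5 µm form a dynamic cluster
(maximal chains; the ≤ is inclusive, so a pair exactly 5 µm apart
clusters). The clustered proportion is |events in any cluster| / |all
events of that type in the segment and interval|.

The null model re-places dynamic events on the *observed spine
positions* of the segment (every spine present at either session of the
interval) rather than on a continuum: spines insert at realizable sites,
and a continuum null would require an arbitrary spatial measure.
Placement is without replacement — one spine per site. Per replicate,
one dynamic event (the anchor, cycling through the events replicate by
replicate so each is held fixed equally often) keeps its observed
position; all other dynamic events are re-assigned uniformly at random
to the remaining sites, and the clustered proportion is recomputed.
30,000 replicates are summarized by a Gaussian fit — sample mean and SD,
SEM = SD/√n — and a two-sided 99.9% interval mean ± z₀.₉₉₉₅·SD. The
verdict is `clustered_above_chance` / `below_chance` when the observed
proportion leaves the interval, `random` otherwise; an exact tie with a
bound is conservatively `random`. Tests with fewer than two dynamic
events are undefined and skipped with a log entry.

`exhaustive_null` enumerates every anchor × every without-replacement
assignment (bounded at 10⁶ placements) and provides the exact null
expectation; the Monte-Carlo implementation is validated against it on
small instances. Because the anchor stream stratifies replicates across
anchors, the Monte-Carlo mean is slightly more precise than the nominal
SEM suggests.

**Statistical geometry worth knowing.** At realistic spine densities
(0.3–0.5/µm) and the 5 µm window, chance clustering is substantial
(null means of 0.3–0.6 for a handful of events), and for a single
segment the 99.9% band's upper limit usually exceeds 1 — a per-segment
test can then *never* declare clustering above chance, whatever the
true effect; its z is capped near (1 − null mean)/SD ≈ 2. The test is
correctly calibrated (conservative) but powerless at that scale.
Detection requires pooling: `pooled_permutation_null` aggregates the
(segment, interval) groups of one animal, re-placing events within
their own segment while computing the proportion over all events. With
the three-session design and 10–20 segments per animal, pooled z values
of 4–5 are reached at moderate generator clustering. Both levels are
exposed; per-segment results remain useful as inputs to per-animal
averaging.

## Restoration statistic and its null

Spines eliminated in a loss interval are paired one-to-one with spines
formed in a later interval (by default the immediately following one;
`restore_lookahead` widens the search). Matching is greedy globally
nearest-first, chosen over optimal assignment for transparency — each
reported pair is the nearest available — with minimum-total-distance
assignment available via `optimal_matching` (scipy's Hungarian
algorithm). Distance ties break on the smaller spine id. A pair at
distance < 2 µm (strict) is a restoration; at ≥ 2 µm, and for any
reappearance without a lost partner, the new spine is de novo. The
strict threshold is the conservative resolution of a rule stated as
"< 2 restored, > 2 de novo" with 2 exactly unspecified.

The null re-places each reappeared spine independently and uniformly on
the segment's candidate spine positions, re-classifying it against its
matched lost position; 10,000 replicates, same Gaussian/99.9%-interval
summary. The null mean has a closed form — the average over reappeared
spines of the fraction of candidate sites within the threshold of the
matched lost position — which the tests verify.

## Synthetic generator

The generator is the simplest process matching the analysis
assumptions, with defaults set to typical in vivo conditions:

| parameter | default | meaning |
|---|---|---|
| `segment_length_um` | 60 | segment length (realistic range 30–100 µm) |
| `spine_density_per_um` | 0.4 | initial Poisson density (range 0.3–0.5) |
| `n_sessions` | 3 | the three-session imaging design |
| `p_elim_base`, `p_form_base` | 0.10 | per-interval rates (range 5–20%) |
| `clustering_strength` | 0 | fraction of dynamic events placed as partners ≤ 5 µm from a same-type event |
| `p_restore` | 0 | probability an eliminated spine reappears < 2 µm away two sessions later |
| `plaque_field.plaque_spacing_um` | 260 | plaques on a regular 1-D grid; segments drop at a random offset so plaque distances span 0–130 µm and populate all zones |
| `plaque_field.elim_multiplier_proximal` | 1.5 | elimination scaling < 25 µm |
| `plaque_field.form_multiplier_intermediate` | 2.0 | formation scaling 25–60 µm |
| `min_spine_gap_um` | 0.2 | annotation resolvability floor between spines |

Eliminations are independent Bernoulli draws per spine (zone-scaled),
which fixes the marginal rate exactly; under clustering the drawn
*count* is kept but re-dealt so that a `clustering_strength` fraction
of picks falls within 5 µm of an already-picked elimination. Formations
arrive as a Poisson count with mean p_form × N(present) × (arc-averaged
zone weight); each new spine is either a partner (offset uniform within
± 5 µm of a previous formation of the interval) or an independent seed
with density proportional to the zone weight. Restorations are
scheduled at elimination time and land uniformly within < 2 µm of the
lost position, encoded as new spine rows so the matcher must re-derive
identity. Ground truth (formed / eliminated / restored, with origin
spine) is emitted alongside.

The plaque multipliers are only qualitatively constrained by the
emulated observations (elevated elimination near plaques, elevated
formation in the intermediate zone); the defaults 1.5/2.0 are moderate
effect sizes exposed in config.

What the generator does **not** emulate: imaging noise and detection
errors, annotator misidentification, heterogeneity between animals
beyond sampling noise, correlated elimination of neighbouring spines
other than via the partner mechanism, plaque growth over sessions, and
3-D geometry (plaque distance is reduced to a 1-D scalar because
downstream code consumes only distances). Passing tests therefore show
the *estimators and nulls* behave correctly under the stated model, not
that real imaging data meets those assumptions.

## Numerical and design choices

* Randomness: `numpy.random.default_rng` throughout; one seeded
  generator per test/run; every result object records its seed. Derived
  per-test seeds are spaced with a prime stride from the config seed.
* The permutation core is vectorized: a (replicates × sites) uniform
  matrix with the anchor column masked, `argpartition` for
  without-replacement sampling, and a sorted-gap scan for cluster
  membership (chain rule specialized for the default minimum cluster
  size of 2, generic fallback otherwise).
* Confidence intervals are not clipped to [0, 1]; an upper bound above
  1 is informative (it proves the test cannot reject upward at that
  sample size).
* Degenerate inputs: zero denominators, empty cohorts, single dynamic
  events and empty zones are flagged (`None` / skipped with a log
  entry), never silently zero.
* The run manifest contains no timestamps (they live in `run.log`), so
  identical config + seed reproduce a byte-identical manifest; SVG
  output uses a fixed hash salt and stripped date metadata for the same
  reason.
* Validation problem sizes: 200 enumeration-vs-Monte-Carlo instances,
  500 segments for calibration and rate recovery, 15 animals × 20
  segments per clustering level for the power sweep — sizes at which
  the binomial/Monte-Carlo error of each checked quantity is well below
  the asserted tolerance.

## Known limitations

* The cluster null conditions on the observed spine positions; it does
  not model uncertainty in spine detection or position measurement.
* Greedy matching can differ from optimal assignment when losses and
  reappearances interleave densely; both are exposed, only totals of
  matched distance are guaranteed comparable.
* Per-segment cluster tests at realistic densities are conservative to
  the point of zero upward power (see above); conclusions about
  clustering should rest on the pooled tests.
* Group-level statistics (ANOVA, post-hoc comparisons between
  genotypes/treatments) are intentionally not implemented; the tidy
  per-animal tables are the interface to standard statistical routines.
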