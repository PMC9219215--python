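# spinedyn

Analysis of longitudinal dendritic-spine dynamics from repeated in vivo
two-photon imaging, for studies that follow identified spines across
imaging sessions — in particular amyloid-pathology models where spine
turnover is stratified by distance to the nearest plaque.

The package consumes tidy annotation tables (one row per spine: arc-length
position along the dendritic segment, per-session presence flags, optional
pre-measured 3-D distance to the nearest amyloid-plaque edge) and provides:

* **Fate classification** — per inter-session interval each spine is
  *formed*, *eliminated*, *survived (pre-existing)* or *survived (newly
  formed in the preceding interval)*; rates are expressed as % of spines
  present at the interval start, and averaged per animal.
* **Plaque-zone stratification** — events binned into proximal (< 25 µm),
  intermediate (25–60 µm) and distal (> 100 µm) zones (60–100 µm is kept
  as its own unassigned stratum), plus a two-bin < 25 / > 25 µm scheme;
  a "dendrospinogram" table/plot maps every event by plaque distance.
* **Cluster statistic** — two or more same-type events chained at ≤ 5 µm
  of arc length form a dynamic cluster; the *clustered proportion* is the
  number of clustered events over all events of that type. Chance level
  comes from a randomized-placement null: one event (the anchor, rotated
  replicate by replicate) keeps its observed position while all others are
  re-assigned uniformly, without replacement, to the observed spine
  positions of the segment; 30,000 replicates are summarized by a Gaussian
  fit (mean ± SEM) and a 99.9% interval (mean ± z₀.₉₉₉₅·SD), giving a
  three-way verdict: clustered above chance / random / below chance.
  An exact enumeration oracle (`exhaustive_null`) verifies the Monte-Carlo
  null on small instances, and a pooled per-animal variant aggregates
  segments (re-placement stays within each segment).
* **Restoration statistic** — a spine that reappears < 2 µm from a
  previously eliminated spine is a *restoration*, otherwise *de novo*.
  Lost and reappearing spines are paired one-to-one (greedy nearest, or
  optimal assignment via config); the null re-places each reappearance
  uniformly on the segment's spine positions, 10,000 replicates, same
  Gaussian/99.9%-interval summary.
* **Synthetic data** — a generator with known ground truth (Poisson spine
  placement, Bernoulli elimination, Poisson formation, partner-placement
  clustering, plaque-modulated rates, scheduled restorations) so every
  estimate can be validated without access to in vivo data.

## Worked example

```python
from spinedyn import SimulationConfig, AnalysisConfig, PlaqueField
from spinedyn.pipeline import run_pipeline

sim = SimulationConfig(n_animals=3, segments_per_animal=10, seed=11,
                       p_restore=0.4, clustering_strength=0.5,
                       plaque_field=PlaqueField())
run_pipeline("out", sim=sim, ana=AnalysisConfig(seed=11))
```

This simulates 30 segments (three sessions each), classifies every fate,
and writes tidy tables plus `report.md`, which for this seed contains:

```
| animal | interval | formation % | elimination % | form:elim |
| m001 | s1->s2 | 15.00 | 11.55 | 1.341 |
| m001 | s2->s3 | 18.90 | 10.36 | 2.065 |
...
## Restoration
- lost spines: 77
- reappeared: 141 (restored 39, de novo 102)
- pooled restored proportion: 0.277
```

Formation exceeds the 10% base rate because the plaque field doubles
formation in the intermediate zone and restored spines re-enter as
formations. The per-animal pooled cluster tests in
`cluster_test_summary.json` show, e.g., animal m001 interval s1→s2 with
observed clustered proportion 0.784 against a null of 0.458 (z = 3.49,
verdict `clustered_above_chance`) — the generator placed half of all
formations as partners within 5 µm of another formation. Note that single
short segments almost never reach significance on their own (the observed
proportion is capped at 1 while the 99.9% band of a handful of events
typically extends beyond 1); detecting clustering needs the pooled test.

The same stages are available as a CLI:

```sh
spinedyn simulate --seed 11 --out sim/
spinedyn analyze sim/annotations.csv --out tables/
spinedyn cluster-test sim/annotations.csv --kind formed --n-perm 30000 --seed 11 --out ct/
spinedyn restore-test sim/annotations.csv --threshold 2 --seed 11 --out rt/
spinedyn run --seed 11 --out full/        # everything + manifest.json
```

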