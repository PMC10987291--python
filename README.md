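# tmaquant

Automated scoring of chromogen-stained tissue-microarray (TMA) cores and
the survival analytics built on top of the resulting scores.

Histochemical probes (here: glycan-binding receptors such as CD301 or
LSECtin, visualized with DAB on hematoxylin-counterstained breast-cancer
TMAs) are classically read out by eye on an ordinal scale. `tmaquant`
implements the quantitative alternative end to end:

1. **Stain separation** — RGB → optical density (`OD = −log10 I/I0`),
   per-image estimation of the two unit-norm stain absorbance vectors via
   the singular-plane / angle-percentile method, per-pixel least-squares
   unmixing into hematoxylin and DAB concentration maps.
2. **Cell geometry** — nucleus detection on the hematoxylin map, then a
   nucleus-seeded watershed that places cell boundaries halfway between
   neighboring nuclei, with a 10 µm radius cap. Nuclei-free DAB deposits
   (e.g. stained mucus) seed no cell and cannot create false positives.
3. **Scoring** — a cell is positive when its summed DAB intensity
   (normalized units × pixels, 0.25 µm grid) strictly exceeds 4; the
   per-patient score is the positive/negative cell-count ratio.
4. **Survival statistics** — constrained minimum-p cutpoint search (50
   equidistant thresholds, both risk groups ≥ 15% of patients, raw
   log-rank p reported together with the number of tests), Kaplan–Meier /
   log-rank, subgroup re-tests, Harrell's concordance against 4-level
   manual reads, percentile-bootstrap CIs of per-category medians.
5. **Synthetic data** — a Beer–Lambert forward renderer with exact ground
   truth and a survival-cohort simulator with a planted score–hazard
   effect, so every stage is testable without patient data.

The package is a library first (`import tmaquant`); `examples/` holds one
narrative script per capability, and a thin `tmaquant` CLI wraps the
pipeline for shell use (`simulate`, `unmix`, `segment`, `score`,
`survival`, `concord`, `run-all`).

## Worked example

Running `python examples/03_cutpoint_search.py` — a 400-patient simulated
cohort with a planted hazard ratio of 3 above a score of 0.25 — prints:

```
cohort: 400 patients, 292 events
thresholds evaluated: 50 (9 admissible under the 15% rule)
best threshold: 0.2628 (planted: 0.25)
raw log-rank p at best threshold: 1.3e-20
note: minimum-p over a grid is anti-conservative; the result records 9 tests for that reason
KM median, high-score group: 23.5 months
KM median, low-score group:  64.5 months
```

The search recovers the planted cutpoint to within one grid step; the
high-score group's shorter Kaplan–Meier median reflects the planted
threefold hazard. The p-value is raw by design: selecting the minimum over
a grid inflates significance under the null, so the number of tests is
part of the result.

`python examples/02_segment_and_score.py` runs the imaging half on a
rendered core (30 cells, 40% positive, two DAB-stained mucus blobs):

```
detected 30 nuclei (planted: 30)
positive cells: 12 (planted: 12)
negative cells: 18
positive/negative ratio: 0.667  fraction positive: 0.400
all mucus pixels outside any cell: True
```

All 30 nuclei and all 12 planted positives are recovered, and every mucus
pixel stays outside the cell partition — stained mucus cannot flip a cell
positive because no nucleus seeds a region there.

See `docs/methods.md` for the models, parameter defaults and their
rationale, numerical choices, and known limitations.

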