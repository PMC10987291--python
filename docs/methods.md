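# Methods

`tmaquant` quantifies chromogen (DAB) staining of tissue-microarray cores in
a fully automated way and turns the resulting per-patient scores into
survival statistics. This note documents the models, the parameters that
matter, the synthetic data the package validates itself against, and the
numerical choices made where the design was open.

## Stain model and color deconvolution

Brightfield absorption follows the Beer–Lambert law per RGB channel c:

    I_c = I0_c · 10^(−(C_H s_H,c + C_D s_D,c))

where `I0` is the white point (default 255 per channel), `s_H` and `s_D` are
unit-norm absorbance vectors of hematoxylin and DAB, and `C_H`, `C_D` are
the per-pixel stain concentrations in normalized units (1.0 = reference
saturated optical density of the stain).

The optical-density transform is `OD_c = −log10(max(I_c, 1)/I0_c)`, clipped
at zero. The one-grey-level floor exists only to avoid `log 0`; any
intensity of at least one grey-level transforms exactly, which is what makes
the noise-free render → OD → unmix round trip exact to ~1e−15.

The stain matrix is estimated per image with the singular-plane /
angle-percentile method: OD pixels with max-channel OD ≤ β are discarded as
background, the rest are projected onto the plane of their top two singular
vectors, and the directions at the α and 100−α angle percentiles become the
stain vectors. Defaults α = 1 (percentile), β = 0.15 (OD floor) are the
originating method's standard values; both are arguments. The column with
the *smaller* blue-channel absorbance is labeled hematoxylin — the
counterstain looks blue precisely because it absorbs little blue light.
Degenerate images (fewer than 100 foreground pixels, or extreme directions
less than 5° apart) raise typed errors and callers fall back to the fixed
Ruifrok hematoxylin/DAB reference matrix; the pipeline does this
automatically. Whether one matrix should be fitted per core or per array is
not determined here; the package fits per core and accepts a caller-supplied
matrix.

Unmixing solves `OD = S·C` per pixel by least squares (pseudo-inverse of the
3×2 matrix) and clips negative concentrations to zero. Matrices with
condition number above 1e3 are rejected.

**Identifiability.** The angle-percentile estimator can only recover a
stain direction that is actually present (nearly pure) somewhere in the
image. Nuclei provide a near-pure hematoxylin population, but if every
DAB-positive pixel also carries cytoplasmic hematoxylin, the most extreme
direction in the data is the *mixture* direction, and the estimated DAB
vector is biased by several degrees. That bias leaks hematoxylin into the
chromogen map — about 0.008 normalized units per nucleus pixel at a 5°
error — which summed over a cell clears the positivity threshold by
itself. Real chromogen-stained cores contain stain-saturated structures
(granular deposits, stained mucus) that pin the DAB direction; the
synthetic cores used by the default pipeline therefore include
stain-saturated mucus blobs, which restores estimation accuracy to a
fraction of a degree. For material without any near-pure chromogen region
the fixed reference matrix is the better choice, and `process_core`
accepts a caller-supplied matrix for exactly that reason.

## Cell geometry

Nuclei are detected on the hematoxylin concentration map. The default
detector is classical — Gaussian smoothing (0.25 µm), Otsu threshold over
above-floor pixels, small-object removal, distance-transform watershed to
split touching nuclei with peaks at least one nucleus radius apart. The
detector is a pluggable callable; an adapter for the pretrained star-convex
neural detector is provided for users who install it, but the default keeps
the package self-contained and deterministic.

Cell bodies are approximated by a seeded watershed on the
distance-to-nearest-nucleus field, restricted to the tissue mask, so the
boundary between two neighboring cells falls halfway between their nuclei.
Two caps apply:

- `max_radius_um` (default 10 µm, a typical epithelial cell radius): pixels
  farther than this from their seed's nucleus centroid stay unassigned.
  Without the cap an isolated nucleus would claim arbitrarily much tissue.
- tissue mask: pixels with `C_H + C_D` at or below a floor (default 0.05)
  are not tissue. Negative cells stay inside the mask because real cytoplasm
  carries a faint hematoxylin wash, which the synthetic renderer reproduces
  (default 0.15).

Regions with no nucleus — background and, importantly, DAB-positive mucus
pools — keep label 0 and therefore contribute to no cell. This is the
mechanism that excludes nuclei-free chromogen deposits from the counts:
mucus can be strongly stained, but with no nucleus to seed a region it can
never produce a positive *cell*.

## Positivity criterion and core score

A cell is positive when the sum of its chromogen intensities strictly
exceeds 4, where each pixel contributes `clip(C_D, 0, 1)` (zero when below
the intensity floor, next paragraphs) and the grid is 0.25 µm/pixel (40×
scanning). Under these units the three boundary cases —
0.25 µm² at 100% intensity (4 px · 1.0), 0.5 µm² at 50% (8 px · 0.5),
1 µm² at 25% (16 px · 0.25) — all sum to exactly 4 and are classified
negative; one more pixel or one more grey-level of intensity flips them.
The 0.25 µm pixel pitch is the unique grid on which those three exemplars
coincide at the threshold, which is why it is fixed as the default.

Per core, positive and negative cells are counted; the prognostic measure
is the ratio `n_positive / n_negative`. The ratio is undefined (NaN, with a
flag) when no cell is negative, so the bounded companion
`fraction_positive` is always emitted as well. Cores with no cells at all
are flagged uninterpretable, mirroring TMA spot dropout. No control-core
subtraction is performed.

**Background sensitivity and the intensity floor.** The threshold
corresponds to less than 1 µm² of saturated stain while a cell covers
~100–500 µm² (thousands of pixels), so the criterion presumes an
essentially clean chromogen channel inside negative cells. Two residues
violate that in practice: (i) unmixing clips negative concentrations to
zero, so zero-mean sensor noise leaves a positive residue of roughly
σ/(I·ln10·√2π) per pixel, and (ii) even a 0.3° error in the estimated
hematoxylin vector leaks several thousandths of a unit per saturated
nucleus pixel into the chromogen map. Summed over a cell, either residue
can cross the threshold on its own. `ScoringParams.intensity_floor`
(default 0.02) therefore treats per-pixel intensities below 2% of
saturation — well below the weakest printed staining level of 25%, and
above both residues by design — as unstained. The floor leaves every
boundary-exemplar computation untouched and makes the end-to-end pipeline
robust to realistic estimation error; it is the one scoring parameter with
no printed counterpart. The synthetic default sensor noise is σ = 0.5
grey-levels (a modern 40× scanner); smooth tissue-wide background is not
modeled, and material with genuine diffuse chromogen background would
require re-examining both the floor and the threshold.

## Synthetic data

The generator renders what the pipeline must invert: non-overlapping disk
cells (cytoplasm hematoxylin 0.15, nucleus 1.0), DAB at `positive_intensity`
(default 0.8) on positive cytoplasm, nuclei-free mucus blobs at
`mucus_intensity`, rendered through the Beer–Lambert model with truncated
Gaussian sensor noise, all with exact ground truth (centroids, label maps,
concentration maps). Images are float64 in memory; 8-bit quantization is an
I/O concern only. Placement is random sequential: requests above ~55%
exclusion-disk coverage are refused with a density error. Mucus blobs keep
a 5 µm clearance beyond the cell rim so that, with the default 10 µm cell
cap, no cell region can reach into a blob and the false-positive-exclusion
ground truth is unambiguous. The renderer does not attempt H&E morphology
realism, scanner artifacts, chromatic aberration, or overlapping/irregular
cell shapes — passing tests show the *algorithms* invert their own forward
model and satisfy their geometric and statistical contracts, not that the
classical nucleus detector matches a trained detector on real histology.

Cohorts are simulated with per-patient scores from a configurable family
(default lognormal with median 0.25 and σ = 0.6: a positive/negative count
ratio is positive and right-skewed), exponential event times with hazard
`baseline_hazard · hazard_ratio^[score > true_cutpoint]` (defaults 0.01
per month, ratio 3, cutpoint 0.25 — at the score median), independent
exponential censoring (0.003 per month) plus an administrative cap at 120
months, reflecting a ten-year follow-up horizon. Optional 4-level manual
categories bin a multiplicative-lognormal-noise copy of the score
(σ = 0.5) at its cohort quartiles, emulating an ordinal observer.
Proportional hazards are exact by construction; real disease-free-survival
data would violate them in ways this generator does not probe.

## Survival statistics

- **Kaplan–Meier**: product-limit estimator; censoring at an event time is
  counted at risk for that event. Greenwood variance is carried along. The
  implementation is cross-checked against an established survival library
  to 1e−12 in the tests; the library is never the implementation.
- **Log-rank**: two-group observed-minus-expected with hypergeometric
  variance summed over distinct event times, χ² with 1 df. Degenerate
  inputs (no events, zero variance) return statistic 0, p = 1.
- **Cutpoint search**: 50 equidistant thresholds spanning the *open*
  interval between the observed score extremes (endpoints excluded — they
  produce empty groups). High-risk = score strictly greater than the
  threshold. A threshold is admissible only if **both** groups hold at
  least 15% of patients: a one-sided reading of the constraint would admit
  a 99.9%/0.1% split, which is not a risk group in any useful sense. The
  best threshold minimizes the raw log-rank p among admissible candidates;
  ties break toward the more balanced split, then the lower threshold, for
  determinism. No multiplicity correction is applied — deliberately — and
  the result object carries the number of tests performed, because the
  minimum-p over K tests is anti-conservative under the null (the test
  suite demonstrates this by simulation). Non-finite scores are excluded
  before the grid is formed and before any split.
- **Subgroup re-test**: the selected threshold is re-evaluated within each
  subgroup (KM pair + log-rank). Subgroups entirely on one side of the
  threshold are flagged not evaluable. When the threshold was selected on
  independent data, subgroup p-values are uniform under the null (verified
  by simulation with a Kolmogorov–Smirnov check).
- **Concordance**: Harrell's C over all patient pairs with different
  manual categories; algorithmic-score ties count one half; manual ties are
  excluded. Invariant under strictly monotone transforms of the score.
- **Bootstrap medians**: percentile bootstrap, default 10,000 resamplings,
  95% level, seeded generator for reproducibility.

## Problem sizes

The test suite and examples run at deliberately modest scale: cores of
256–768 px (64–192 µm) with 12–100 cells, cohorts of 60–10,000 patients,
100-replicate cutpoint-recovery and 500-replicate calibration simulations,
and 1,000-replicate type-I-error and bootstrap-coverage checks. These sizes
give the quoted statistical checks comfortable resolution while keeping a
full run in tens of seconds.

## Reproducibility

Every stochastic component takes an explicit seed; pipeline runs derive all
per-core seeds from the single global seed, and a rerun with an identical
configuration reproduces CSV outputs byte for byte. The run manifest
records package versions, the seed, and a hash of the full configuration.
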