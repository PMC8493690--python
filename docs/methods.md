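# Methods

This note documents the models, algorithms and numerical choices
behind `sarcoscreen`, in the order the pipeline runs them.

## 1. Synthetic plate model (`sarcoscreen.simulate`)

The simulator exists because commercial high-content analyzers ship
unpublished segmentation algorithms and screening image sets are
rarely public: every downstream stage is validated by parameter
recovery against simulated ground truth instead.

### Imaging geometry

Two acquisition modes mirror the assay conventions:

| mode | pixel size | field | fields/well | cells/well |
|---|---|---|---|---|
| `sarcomere_60x` | 0.25 μm/px | 512×512 px (128 μm) | 9 | ≈ 200 |
| `yap_4x` | 1.6 μm/px | 1024×1024 px (1.6 mm) | 6 | ≈ 4000 |

Pixel sizes are not dictated by the assay itself; 0.25 μm/px
resolves the ~0.8 μm Z-line width at 60×, and 1.6 μm/px reproduces
the cell-count-per-field arithmetic at 4×. Both are configurable.

### Cells

Cells are mononuclear (the screening assumption for these
cardiomyocyte preparations) elliptical territories placed by
Poisson-disc dart throwing with a minimum centroid spacing (16 μm at
60×, 27 μm at 4×) and a margin keeping whole cells inside the field.
The per-field count is Poisson(mean) clamped at a packing capacity
(0.44 × field area / spacing disc area — comfortably below the
random-sequential-adsorption saturation of ~0.547, so placement
always succeeds); a configuration requesting a mean above capacity
raises immediately. Because of the clamp, realized wells average
slightly below the nominal 200 cells (≈ 190–200).

Per cell, a Bernoulli(healthy_fraction) draw decides the phenotype:

* **Healthy**: parallel Z-line stripes perpendicular to the cell's
  major axis, one per 1.9 μm of sarcomere periodicity, each with a
  length drawn from the healthy distribution (default N(5.0, 0.6²) μm,
  truncated to fit the ellipse) and width 0.8 μm.
* **Disrupted**: ~15 short puncta (capsules with lengths from
  N(1.0, 0.25²) μm, random orientation) scattered in the footprint.

The length distributions are placeholders chosen to straddle the
3.1 μm classification cutoff with a wide margin — they are **not**
estimates of real Z-line length distributions, which are unpublished.
Consequently, recovery tests demonstrate the pipeline measures what
was rendered; they cannot certify accuracy on real stain morphology.

Stripes and puncta are drawn as anti-aliased capsules: the true
length is the center-line (endpoint-to-endpoint) distance and round
caps extend width/2 beyond each endpoint. In YAP mode the marker
channel instead renders the cell footprint at a cytoplasmic level C
and overwrites the nuclear ellipse with ratio·C, the ratio drawn from
the localized (default N(2.0, 0.3²), floor 1.35) or cytosolic
(N(1.0, 0.12²)) distribution according to a
Bernoulli(yap_nuclear_fraction) flag.

### Noise and determinism

Signal + constant background pass through Poisson shot noise
(`photon_scale` electrons per intensity unit, default 0.5), additive
Gaussian read noise (sd 10), and 16-bit quantization. Every
(group, well, field) gets an independent `numpy` SeedSequence stream
derived from the master seed, so any field can be regenerated alone,
and identical configurations give bit-identical plates.

Per-cell truth (healthy flag, segment lengths, YAP ratio, centroid)
and exact per-well truth fractions are written beside the images.

What the simulator deliberately omits: PSF convolution and
z-sectioning, channel bleed-through, multinucleation, touching or
overlapping monolayer growth, myofibril curvature, focus drift and
illumination gradients. Passing recovery tests therefore bound
algorithmic error, not robustness to those real-data effects.

## 2. Segmentation (`sarcoscreen.segment`)

All parameters are in micrometers and scaled by the field's pixel
size, so the same defaults serve both modes.

**Nuclei.** Gaussian smooth (σ = 1 μm) → Otsu threshold → hole fill →
distance-transform watershed seeded at distance peaks (minimum peak
separation = half the 9 μm nominal nucleus diameter) → area filter
(25 μm²) → consecutive relabeling. Otsu always returns *a* threshold,
so a guard rejects it when it fails to clear the background median by
4 robust (MAD-based) sigmas — a blank or noise-only field yields zero
nuclei rather than hallucinated objects.

**Territories.** A watershed on the distance transform away from the
nuclei partitions the field into nearest-nucleus basins (one
territory per nucleus — the mononuclear assumption), clipped at a
30 μm reach; the marker-positive foreground intersected with this
partition gives the per-cell territory, and the unrestricted
partition assigns detached structures (Z-line segments) to cells by
component centroid. Centroid membership is cheap, deterministic, and
cannot tie.

**Z-line segments.** White top-hat with a disk sized to twice the
Z-line width (removes the smooth background, keeps ridge-like
striations) → guarded Otsu → 8-connected components (≥ 3 px).
Components touching the field border are excluded by default (their
true extent is unknowable). Each component's length is estimated as

    max( polyline(longest skeleton path, stride 4) − 0.5 px ,
         max Feret diameter − width − 1 px ) × pixel size

The longest geodesic path through the skeleton (unit/√2 step weights,
double-Dijkstra sweep — exact on trees; branch fusions resolve to the
single longest linear structure) measured as a raw step sum
overestimates length by up to ~4% at intermediate orientations (the
8-connected staircase effect), so the path is re-measured as a
polyline subsampled every 4 pixels; the half-pixel trim accounts for
end-pixel centers. For short, nearly straight objects thinning erodes
the skeleton into the caps, so the Feret-based lower bound (exact for
a straight capsule up to digitization) takes over. On noiseless
rendered stripes of 1–8 μm at any orientation the combined estimator
is unbiased within ±0.02 μm on average with a worst case of
±0.4 μm ≈ 1.6 px. Segments shorter than 0.5 μm are discarded as
noise.

**YAP intensities.** Nuclear mean over the nucleus pixels;
cytoplasmic mean over the territory minus all nuclei dilated by 1 μm,
after eroding the territory foreground by one pixel — the
anti-aliased cell rim otherwise depresses the cytoplasmic mean and
inflates the nuclear/cytoplasmic ratio by ~15–20%. The median
(configurable percentile) of non-territory pixels is subtracted from
both as background. Cells with fewer than 8 cytoplasmic pixels after
erosion are flagged unmeasurable and leave the index denominator.

## 3. Scoring (`sarcoscreen.score`)

A cell with no detected Z-line has an *undefined* mean length: it
stays in the well's denominator but can never be well-organized (the
cell count comes from nuclei, not from marker detections). Both
classifications are strict inequalities, so raising a threshold can
only lower an index (a property the tests assert). Percent of
control is the ratio of group means — not the mean of per-well
ratios — so the control group is exactly 100 by construction.
`optimize_cutoff` scans a grid (default 1.0–6.0 μm, step 0.1) for the
maximum Youden-style separation `frac_control(c) − frac_positive(c)`
using the same strict classifier, breaking ties toward the smaller
cutoff and warning (grid minimum) when no cutoff separates the
populations. The pipeline itself uses the fixed 3.1 μm default; the
search is an auxiliary tool.

## 4. Trend statistics (`sarcoscreen.trend`)

Wells are the replication unit. The expected direction must be
declared per endpoint (decreasing for a toxicant suppressing HSI or
YAP localization; increasing for a rescue arm tested against the
toxicant-alone group).

**Gate.** Bartlett's test across all groups at α = 0.05 selects
Williams (homogeneous) or Shirley-Williams (heterogeneous). A group
with zero variance — common when high doses drive every well's index
to the floor — makes Bartlett undefined and falls back to the rank
test; all-identical data is trivially homogeneous (p = 1).

**Williams' step-down.** Groups ordered control, dose 1…K. At each
step (highest remaining dose k) the statistic is

    t̄_k = ( M̂_k − x̄_0 ) / sqrt( s² (1/n_k + 1/n_0) )

where M̂_k is the isotonic (PAVA-amalgamated) estimate at the top
position over doses 1..k — computed by the closed form
max_u Σ_{i=u..k} n_i x̄_i / Σ n_i — and s² the pooled within-group
variance over all groups. Testing proceeds downward and stops at the
first non-significance, so a lower dose can never be flagged after a
non-significant higher dose (asserted structurally). PAVA itself is
delegated to `scipy.optimize.isotonic_regression` behind
`pava_isotonic_means` (weighted-mean-conserving, verified against a
brute-force block-partition oracle).

**Shirley-Williams.** At each step the control and the doses still in
play are re-ranked jointly (midranks for ties); amalgamated mean
ranks replace the group means and the scale is the rank variance
N(N+1)/12 with the standard tie correction.

**Critical values.** Published tables only cover equal-n designs, so
one-sided critical values are estimated by seeded Monte-Carlo
(100 000 replicates, cached per design): normal group means plus a
χ²-distributed pooled variance for Williams; ranked continuous null
samples for Shirley-Williams (making that null distribution-free and
small-sample exact up to MC error). At k = 1 the Williams value
reduces analytically to the one-sided Student t quantile, which
anchors the simulation. Measured familywise error under the complete
null is 2.4–2.6% at the nominal α = 0.025 for both tests.

Significance stars follow the screening convention: α, α/5, α/50
(0.025/0.005/0.0005 for trend tests).

**Two-group comparison.** `two_group_test` defaults to an F-test gate
(two-sided, 0.05) choosing Student's t or the Wilcoxon rank-sum test
(exact for small tie-free samples); either can be forced. α = 0.05.

## 5. Pipeline and presets (`sarcoscreen.pipeline`, `.presets`)

Stages communicate only through the documented CSV contracts, so a
plate simulated to disk and re-analyzed from its TIFFs reproduces the
in-memory run exactly. The three presets encode the assay's standard
experiment designs with severities chosen to mirror the qualitative
ordering of a sunitinib screen (strong dose-dependent disruption;
recovery after washout — complete at 144 h, where all groups equal
the control healthy fraction of 0.8; partial rescue by MST1/2
inhibition) — deliberately not calibrated to any particular
experiment's percentages. Washout timepoints are independent plates:
cells are fixed before imaging, so there is no longitudinal tracking
to model.

## 6. Problem sizes and runtime

The default designs (4 groups × 5 wells × 9 fields at 60×;
2–4 groups × 6 wells × 6 fields at 4×) were chosen to match the
assay's stated conventions while keeping a full scenario run at a few
minutes on one CPU; the unit-test suite uses smaller fields
(256–320 px) for speed, and the trend-test operating characteristics
use 10 000 Monte-Carlo replicates.

## 7. Known limitations

* The 3.1 μm cutoff is fixed globally; whether per-experiment
  re-optimization is preferable cannot be decided from simulation.
* "Significantly more intense" nuclear YAP1 is operationalized as a
  fixed ratio threshold (1.3), not a per-cell statistical test.
* Segment-border handling (exclude components touching the field
  edge) is a convention; real pipelines may differ.
* The null-design caveat: a trend test on a truly flat design still
  rejects at its nominal 2.5% rate — "no significance" statements are
  per-experiment observations, not guarantees.
* Nothing here addresses batch effects, illumination correction or
  plate-edge artifacts in real data.
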