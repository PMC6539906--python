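# Methods

## Model and assumptions

The detector is a color-threshold classifier made illumination-aware by
region decomposition. Its assumptions, in decreasing order of importance:

1. **Local color separability.** Within a patch of approximately uniform
   illumination, fruit and background occupy disjoint (or nearly disjoint)
   intervals in at least one dimension of some 3-D color space.
2. **Illumination acts regionally.** Lighting varies across the image
   (sun, shade, canopy gaps) but is roughly constant within small regions,
   so a quadtree split on grayscale standard deviation isolates it.
3. **Background majority.** Images contain more background than fruit;
   the direction-learning heuristic and the overexposure rule both rely
   on this.
4. **Smooth threshold drift.** The optimal threshold varies continuously
   with a region's light level, so linear interpolation between the three
   learned per-group thresholds is adequate between anchors.

Four color spaces are supported. NDI (`(X−Y)/(X+Y)` per channel pair) is
exactly invariant to multiplicative gain and is the natural choice when
illumination is the dominant nuisance; RGB/HSI/LAB trade that invariance
for other separability structure (LAB's opponent axes are the most robust
to additive sensor noise). HSI here means the classical polar
(hue, saturation, intensity) decomposition; the hexcone HSV variant is
exposed through `to_hsi(..., variant="hsv")` because the two families are
routinely conflated in the literature and differ numerically.

## Parameters

| parameter | units | default | role |
|---|---|---|---|
| `std_stop` | gray levels | tuned (grid) | stop splitting when region STD falls below it; smaller → more, purer regions, but regions can lose one of the two classes |
| `t1`, `t2` | gray levels | tuned (15th/85th percentile) | light-group cutoffs; the 15/70/15 rule keeps all three groups populated on any database |
| `t_over` | gray levels | 250 | regions brighter than this are treated as washed out: excluded from training, emitted as background at test time |
| `min_side` | px | 16 | smallest splittable region side; guards against single-class sub-images |
| `n_levels` | – | 256 | ROC sweep granularity, matching 8-bit source precision |
| `objective_weight` | – | `None` (F-score) | optional w in `w·TPR + (1−w)·(1−FPR)` to re-bias the detector toward recall or precision |
| opening / closing element | px | 11×11 / 5×5 | square structuring elements (no prior fruit orientation); opening removes false-positive speckle, closing bridges split fruit |
| `train_fraction`, `repeats` | – | 0.70, 5 | evaluation protocol: repeated random 70/30 splits, metrics averaged over test folds |
| noise / threshold / STD perturbations | – | 5–30%, ±5–15%, 5–10% | sensitivity protocol grids |

Tuning cutoffs are estimated from square tiles covering ~1% of each
image's pixels; percentiles use linear interpolation between order
statistics. The STD grid search reuses the same sampled train/test splits
for every candidate (a paired comparison), breaking exact ties toward the
larger candidate, which splits less and is cheaper.

## Numerical choices

- **Threshold tie-break.** When several ROC candidates achieve the same
  objective, the *middle* tied candidate is selected. On separable data
  the tied plateau spans the gap between the class supports; a mid-gap
  cutoff leaves margin on both sides, which matters because thresholds are
  later *interpolated across groups*: an edge-of-support cutoff learned in
  one group can cross another image's background values after
  interpolation.
- **Interpolation.** Standard two-point linear interpolation between group
  anchors — exact at anchors, continuous between them; levels outside the
  anchor span clamp to the nearest group. A `literal` mode implementing
  the reversed weight ordering (which exchanges the endpoints and is
  discontinuous at anchors) is kept for comparison.
- **Group anchors.** The anchor light level of each group is the mean
  light level of its training regions (not fixed constants), so anchors
  always sit inside the tuned group intervals.
- **Empty buckets.** A group with no two-class pixels inherits the nearest
  populated group's thresholds with a warning and is anchored at the
  midpoint of its light interval; if no group is populated for a
  dimension, fitting fails loudly.
- **Degenerate inputs.** Zero NDI denominators map to 0; achromatic pixels
  get hue = saturation = 0; `F(0, 1) := 0`; constant light-level samples
  raise on cutoff tuning and report shape statistics as 0 with a
  degeneracy flag.
- **Conventions.** Grayscale is BT.601 luminance; LAB is sRGB/D65;
  classification is strict (`>` / `<`); group boundaries belong to the
  upper group; quadrant splits use floor midpoints; sample std uses the
  n−1 convention, skewness/kurtosis the plain moment estimators (kurtosis
  excess).
- **Randomness.** Every stochastic routine takes an explicit seed;
  per-repeat and per-image generators are derived from it, so all results
  are bit-reproducible.

## Synthetic scenes

The generator renders elliptical "fruits" of a jittered color on a
differently colored background with per-pixel multiplicative brightness
texture, applies a multiplicative illumination field, and optionally adds
Gaussian sensor noise (σ = percent of full scale, clipped to [0, 255]).
The illumination field is either a smooth ramp or discrete constant-gain
zones whose edges follow successive halving (1/2, 3/4, …) of the axis, so
zone borders coincide with quadrant-split lines and a three-zone scene
cleanly emulates a dominant shaded area plus progressively sunnier strips.

Defaults: 256×256 canvas, 4 fruits with semi-axes 20–32 px, red fruit
(200, 30, 30) ± 10 per channel on green background (40, 160, 40) ± 10,
5% brightness texture, no additive noise. Fruit size is chosen so fruits
are several times larger than the 11×11 structuring element, as real
fruit are at camera resolution; the experiment scale (20 images, 5×
70/30 cross-validation) mirrors the small-database regime the method is
designed for while keeping a full protocol run in seconds.

What the generator does **not** emulate: occlusion by leaves and wires,
specular highlights, mixed boundary pixels (ground truth is pixel-exact by
construction), chromatic illumination (gain is equal across channels), and
in-class color variety beyond uniform jitter. Consequently, passing the
synthetic protocol demonstrates the mechanics of the pipeline — regional
thresholds beating a global one under illumination gradients, exact NDI
gain invariance, morphology removing speckle — but says nothing about
performance on real crops with green-on-green contrast or heavy occlusion,
which are known hard cases for purely color-based detection.

## Limitations

- Color thresholds only: no texture or shape features, so crops that match
  their background chromatically (green grapes on green leaves) cap well
  below the performance of distinctly colored fruit.
- The direction heuristic fails when a color dimension's background is not
  the majority class on its side of the probe threshold; the combination
  selector then routes around that dimension, but it cannot repair all
  three failing at once.
- Thresholds interpolate across, but not within, regions; a region
  straddling an abrupt illumination edge is thresholded at its mean level.
- Morphological opening removes any true fruit smaller than the 11×11
  element and shaves rasterized boundaries; with pixel-exact synthetic
  truth this is the only residual error on separable scenes.
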