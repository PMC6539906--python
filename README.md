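# fruitseg

Pixel-level fruit detection for agricultural imagery by **dynamic adaptive
thresholding with automatic parameter tuning**. The package targets the
small-data regime of orchard and greenhouse vision — a handful of labeled
images per crop, captured under highly variable natural lighting — where
training a deep detector is not an option but color still separates fruit
from foliage within any locally homogeneous patch of illumination.

## The algorithm

An image is recursively split into quadrants until each region's grayscale
standard deviation drops below a stop value `STD`, giving rectangular
sub-images with approximately homogeneous illumination. Each region's
*light level* `x` (mean grayscale value) assigns it to an illumination
group with two tuned cutoffs:

```
low:     0 < x < T1
medium: T1 ≤ x < T2
high:   T2 ≤ x ≤ T_over     (x > T_over: overexposed, excluded)
```

Training pools pixel values per (group, dimension) for a chosen 3-D color
space — RGB, HSI, LAB, or NDI, where `NDI1 = (R−G)/(R+G)` etc. is invariant
to multiplicative illumination gain — and learns **nine thresholds**
(3 groups × 3 dimensions) by sweeping an ROC per bucket and maximizing

```
F(TPR, FPR) = 2·TPR·(1−FPR) / (TPR + (1−FPR))
```

At test time a region at light level `x` gets its three thresholds by
linear interpolation between the two bracketing group anchors `LL`:

```
T = [T(LL_i)·(LL_{i+1}−x) + T(LL_{i+1})·(x−LL_i)] / (LL_{i+1}−LL_i)
```

Per-dimension binary masks are stitched region by region; the best of the
seven mask combinations (3 singles + 4 intersections, chosen on the
training set) is cleaned by morphological opening (11×11 square) and
closing (5×5 square) to give the final mask. The tuning stage learns
`T1`/`T2` (15th/85th percentiles of sampled tile light levels, leaving
15% / 70% / 15% of sub-images low/medium/high), `STD` (grid search
maximizing cross-validated F), and the per-dimension classification-rule
direction (whether fruit lies above or below the threshold, via a
70%-background majority heuristic).

## Worked example

Twenty synthetic scenes of red elliptical fruit on green textured foliage
under a harsh three-zone illumination field (gains 0.2 / 0.7 / 1.2 —
deep shade to full sun), evaluated by 5× repeated 70/30 cross-validation
in RGB space, against the same pipeline with splitting disabled (one
global threshold set per image):

```python
from fruitseg import (SceneSpec, IlluminationSpec, generate_dataset,
                      ExperimentConfig, cross_validate)

scenes = generate_dataset(
    SceneSpec(illumination=IlluminationSpec(min_gain=0.2, max_gain=1.2, zones=3)),
    20,
)
adaptive = cross_validate(scenes, ExperimentConfig(seed=0, std_stop=10.0), "rgb")
global_only = cross_validate(scenes, ExperimentConfig(seed=0, std_stop=1e6), "rgb")
print(f"adaptive : TPR={adaptive.mean_tpr:.4f}  FPR={adaptive.mean_fpr:.4f}  F={adaptive.mean_f:.4f}")
print(f"global   : TPR={global_only.mean_tpr:.4f}  FPR={global_only.mean_fpr:.4f}  F={global_only.mean_f:.4f}")
```

prints

```
adaptive : TPR=0.9933  FPR=0.0003  F=0.9965
global   : TPR=0.9941  FPR=0.2034  F=0.8810
```

The global detector is forced to accept dark-zone fruit and bright-zone
background on the same side of one cutoff and pays with a 20% false
positive rate; the regional model thresholds each illumination zone on its
own terms and removes almost all of it. (The residual 0.3% F gap of the
adaptive model is the morphological opening shaving rasterized fruit
boundaries, not misclassification.)

The same workflow is available from the shell:

```sh
fruitseg synth --out data --n 20
fruitseg tune  --images data/images --masks data/masks --space ndi --out tuning.json
fruitseg train --images data/images --masks data/masks --tuning tuning.json --space ndi --out model.json
fruitseg detect --image data/images/scene_000.png --model model.json --out mask.png
fruitseg experiment --images data/images --masks data/masks --protocol cv --space ndi --out cv.csv
```

## Documentation

`docs/methods.md` describes the model assumptions, every tunable parameter
with its default and rationale, what the synthetic scene generator does and
does not emulate, and the package's numerical choices and limitations.
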