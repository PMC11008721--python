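# rownav

Toolkit for maize crop-row navigation-line extraction: low-light image
enhancement, gap-aware weighted least-squares row fitting with central
navigation-line construction, reference implementations of lightweight
detection-network building blocks and losses, and the matching evaluation
metrics — all testable end to end on synthetic field scenes with exact
ground truth.

Intended for researchers and engineers building vision guidance for
inter-row machinery (weeders, sprayers) who have a plant detector and need
the stages around it: preprocessing for night/low-light capture, geometry
from detections to a steering line, and quantitative evaluation.

## What it computes

**Enhancement.** An RGB image is decomposed by the Retinex model
`I_c = R_c · L` into reflectance and a smooth luminance field; the
luminance histogram's weighted CDF defines a per-level gamma exponent

    γ(l) = 1 − Σ_{v≤l} P_w(v) / sp,    P_w(l) = (P(l) − P_min)/(P_max − P_min),

and `L_en = L^γ` (brightening-only) is recombined with the reflectance.

**Row fitting.** Detection boxes become centre points `(x_i, y_i)`,
split into left/right rows, audited for missing-plant gaps
(`D_{i,i+1} > D_thresh`), and fitted per row by weighted least squares
minimising `S = Σ w_i (y_i − (m x_i + b))²`, with Gaussian weights in the
robust-scaled perpendicular distance to a preliminary fit. The navigation
line passes through the row-line intersection with slope
`m_c = tan((arctan m1 + arctan m2)/2)`.

**Blocks & losses.** Deterministic numpy forwards for ECA (adaptive kernel
`k = |(log2 C + 1)/2|_odd`), coordinate attention, SPPF (5/9/13 max-pool
pyramid via sequential 5×5 pools), Focus slicing, the CIoU box loss
`1 − IoU + ρ²/c² + αv`, and the composite detection loss.

**Metrics.** Greedy VOC-style matching, precision/recall/F1 (percent), AP
as the area under the monotone PR envelope, and the line angular error
`Δθ = |arctan a1 − arctan a2|`.

## Worked example

```python
import numpy as np
from rownav import synthfield, rowfit, metrics

# a 640x640 scene: 20 plants/row, 2 px centre jitter, one gap per row
cfg = synthfield.SceneConfig(seed=11, jitter_sigma=2.0, gap_left=(9,))
scene = synthfield.generate_scene(cfg)

# imperfect detections: 3 clutter boxes from off-row weeds
dets = synthfield.perturb_detections(scene, sigma_center=0.0, n_false=3, seed=11)

res = rowfit.fit_rows_pipeline(dets, rowfit.RowFitConfig())
err = metrics.angular_difference(res.nav.mc, scene.gt_nav.mc, degrees=True)
print(f"nav slope {res.nav.mc:+.4f} (truth {scene.gt_nav.mc:+.4f}), "
      f"angular error {err:.3f} deg, gaps flagged {res.left_gaps.flagged}")
```

prints

```
nav slope -0.0009 (truth +0.0000), angular error 0.051 deg, gaps flagged [11]
```

— the fitted navigation line is within a twentieth of a degree of the true
centerline despite jitter and clutter (the default scene is symmetric, so
the true central slope is exactly zero), and the missing plant in the left
row was flagged from its doubled vertical spacing (index 11 in the row's
y-sorted point list, which also contains clutter points).

The same stages are scriptable from the shell:

```
rownav synth --n 5 --seed 3 --out scenes/
rownav enhance scenes/scene_0000.png bright.png --dump-gamma-table tab.csv
rownav fit scenes/scene_0000.png scenes/scene_0000.txt -o nav.json
rownav eval --dets scenes/ --gts scenes/ -o report.json
rownav blocks self-test
```

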