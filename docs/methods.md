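# Methods

This note documents the models and procedures implemented in `rownav`, the
assumptions behind them, the parameters that matter, and the design choices
made where the underlying method left the design open.

## Problem setting

Inter-row weeding machinery steering between two maize seedling rows needs a
navigation line: the central line between the left and right crop rows in a
forward-facing camera view. The toolkit covers the stages around a plant
detector (which it does not train): preprocessing low-light imagery,
converting per-plant detections into fitted row lines and a navigation line,
reference implementations of the detector's building blocks and losses, and
evaluation metrics — all exercisable on synthetic scenes with exact ground
truth.

## Low-light enhancement (illumination)

**Model.** The image is treated as a pixel-wise product of a smooth
illumination field and per-channel reflectance, `I_c = R_c · L` (Retinex
assumption). Only `L` is modified, which preserves hue.

**Illumination estimate.** `L` is the Gaussian low-pass (reflected borders)
of the per-pixel channel maximum, clamped to `[eps_floor, 1]`. The
max-channel convention avoids biasing the strongly green vegetation pixels;
any smooth estimator would serve, and `blur_sigma` (default 15 px for
640-px imagery) controls the illumination/texture split: smaller values push
texture into `L` and flatten it after correction.

**Adaptive gamma.** Luminance is quantized to `B = 256` levels (matching
8-bit sources) with `level(x) = floor(min(x, 1−ulp)·B)`. From level counts
`n_l` and probabilities `P(l) = n_l / n_p`, min-max weights
`P_w(l) = (P(l) − P_min)/(P_max − P_min)` are accumulated into a weighted
CDF normalised by `sp = Σ_l P_w(l)`, and each level receives the exponent

    γ(l) = 1 − Σ_{v≤l} P_w(v) / sp  ∈ [0, 1],

applied as `L_en = L^γ(level(L))`. Since `γ ≤ 1` and `L ≤ 1` this is
brightening-only, monotone nonincreasing in level, and reaches `γ = 0` at
the top occupied level. Degenerate histograms — a flat one, or a single
occupied level, where the min-max weights carry no ordering information —
yield the identity transform; in particular a uniform image is returned
unchanged. Recomposition `R_c · L_en` is clamped to `[0, 1]` by default
(reflectance exceeds 1 wherever `I_c > L`).

**What this transform does and does not do.** It raises mean brightness,
moves histogram mass into the middle levels, and sharply reduces the
fraction of near-black pixels — the properties the tests assert. It does
*not* equalise a multiplicative illumination falloff in ratio terms: the
darkest levels sit at the bottom of the weighted CDF (`γ ≈ 1`, nearly
unchanged) while bright levels saturate toward 1, so the max/min ratio of
mean brightness along the falloff axis can increase even as absolute
darkness shrinks. Repeated application is empirically contractive: a second
pass changes the image less than the first.

## Row fitting and the navigation line (rowfit)

**Pipeline.** Detections → box centre points → margin filter (outer 5% of
the image discarded) and vertical-midline split into left/right rows → gap
audit → preliminary unweighted fit → robust weights → weighted fit per row →
navigation line. Each step is deterministic.

**Gap detection.** Within a row sorted by y (ties by x), the vertical
separation `D_{i,i+1} = |y_{i+1} − y_i|` above a threshold `D_thresh`
(default 50 px ≈ 1.8× the default plant spacing) flags point `i+1` as the
start of a missing-plant gap. Flagged points are *retained* in fitting by
default — a gap start is a real plant — with `drop_gap_points` available.

**Weighted least squares.** The fit minimises
`S = Σ w_i (y_i − (m x_i + b))²` via the 2×2 weighted normal equations.
Because rows in forward views are near-vertical, `y = mx + b` is
ill-conditioned; in the default `auto` form the fit swaps to `x = m'y + b'`
whenever the row's x-spread (MAD) is below 10% of its y-spread, and converts
parameters back, reporting slope/intercept in y-of-x form. MAD rather than
variance decides the swap so that a single off-row false detection cannot
flip a near-vertical row into the ill-conditioned form — with variances,
one clutter box occasionally produced navigation errors of ~25°; with MAD
the same scenes fit to ~0.1°. An exactly vertical row has no y-of-x form
and raises. Explicit `form="y_of_x"`/`"x_of_y"` overrides exist for callers
that need a fixed objective.

**Weights.** From the preliminary fit, each point's perpendicular distance
`d_i` gives `w_i = exp(−d_i²/(2σ²))` with `σ = max(1.4826·median|d_i|,
σ_min)` (`σ_min = 1 px` keeps collinear rows from collapsing σ). One
reweighting pass is used; the Gaussian kernel is a choice — any kernel
monotone nonincreasing in distance preserves the scheme's intent of
down-weighting off-centre seedlings and weeds.

**Navigation line.** With row lines `y = m1 x + b1` and `y = m2 x + b2`,
the intersection `x_i = (b2 − b1)/(m1 − m2)` anchors the central line, whose
slope is the tangent of the mean row angle,
`m_c = tan((arctan m1 + arctan m2)/2)` — the angle bisector — and
`b_c = y_i − m_c x_i`. Slopes within 1e-9 take the parallel path:
`m_c = m1`, `b_c = (b1 + b2)/2`. Note the bisector of two lines at angles
±θ is horizontal under this formula; converging crop rows viewed
symmetrically therefore yield a near-zero central slope, and both the
fitted and ground-truth navigation lines are computed with the same
convention, so angular errors compare like with like.

## Network building blocks (netblocks)

Training-free, pure-numpy reference forwards over C×H×W tensors; attention
parameters are drawn deterministically from a seed, and tests rely only on
structural properties, never on learned values.

- **ECA kernel rule:** `k = |(log2 C + 1)/2|_odd`, nearest odd with exact
  midpoints rounding to the larger odd, minimum 1.
- **ECA forward:** channel means → circularly padded 1D convolution across
  channels → sigmoid → per-channel scaling.
- **Coordinate attention:** width-pooled (C×H) and height-pooled (C×W)
  descriptors concatenated, mixed by a shared 1×1 conv to `⌈C/r⌉` channels
  with ReLU, split, expanded per branch and squashed to factors in (0, 1)
  applied as `out = in ⊙ a_h(y) ⊙ a_w(x)`. All-zero parameters give the
  closed-form ×0.25 scaling used as a structural test.
- **SPPF:** stride-1 max pools with 5/9/13 receptive fields realised as
  one/two/three sequential 5×5 pools (an exact identity), concatenated to 4C
  and optionally projected back to C by a 1×1 conv.
- **Focus:** 2×2 space-to-depth, sub-grids in TL/TR/BL/BR order.
- **CIoU loss:** `L = 1 − IoU + ρ²/c² + αv` with `v` the arctan aspect
  term and `α = v/((1−IoU)+v)` (set to 0 at the 0/0 point). Zero-overlap
  IoU is defined as 0; `c` is the tight enclosing-box diagonal. The loss is
  invariant under translation and uniform scaling and bounded by
  `1 − IoU ≤ L < 3`.
- **Composite loss:** `(1/N_pos)[CE_cls,pos + λ1·BCE_obj,all +
  λ2·ΣCIoU_pos + λ3·ΣL1_pos]` with defaults λ = (1, 5, 1) (the weighting is
  not pinned down by the method; these are configurable). Categorical CE for
  the single-class scores, binary CE for objectness over all anchors
  (non-positives are treated as negatives), and the L1 offset term gated by
  `l1_enabled` as it applies only late in training.

## Evaluation metrics (metrics)

Matching is greedy one-to-one in descending confidence at `IoU ≥ 0.5`
(VOC-style; the counts never exceed the optimal assignment and agree with
it on ≥95% of small random instances). P, R and F1 are reported as
percentages with a warn-and-zero convention for empty denominators. AP is
the area under the monotone precision envelope (all-points interpolation; a
fixed-grid variant via `n_interp=101`). The angular error is
`Δθ = |arctan a1 − arctan a2|` wrapped to `[0, π/2]` since lines are
undirected — without the wrap, two near-vertical lines of opposite slope
sign would read as ~180° apart. Fit times are wall-clock around the fitting
pipeline, reported but never asserted (hardware-dependent).

## Synthetic scenes (synthfield)

**What is emulated.** Two converging rows of green Gaussian-profile blobs
(σ = radius/2) at fixed vertical spacing on a noisy soil-toned background;
missing-plant gaps at chosen indices; off-row weed blobs; Gaussian centre
jitter; and a linear multiplicative illumination falloff from `illum_min`
at the top edge to 1 at the bottom, mimicking distance from a floodlight.
Defaults: 640×640 scene, 20 plants/row at 28 px spacing, radius 10 px, rows
converging from 230 px apart at the bottom to 102 px at the top. Detector
imperfection is modelled separately: centre jitter, independent misses with
probability `p_miss`, uniform clutter boxes, confidences uniform in
(0.3, 1).

**What is not emulated** — leaf morphology and occlusion, straw residue,
perspective-correct blob scaling, sensor noise structure, and any
correlation between detection confidence and correctness. Passing tests
therefore demonstrate the geometry and photometry of the algorithms, not
detector performance on real fields; the detection P/R/F1/AP numbers the
acceptance script reports characterise the chosen perturbation model, not
any trained network.

**Augmentation.** The six single-image operations (colour shift ±10/255,
brightness ±0.15, contrast gain 0.8/1.2, Gaussian noise σ = 0.02, rotation
±10°, horizontal mirror) expand a dataset exactly sevenfold
(originals + 6 variants); magnitudes are fixed defaults since only the
operation names are prescribed. The 2×2 mosaic composite is available but
excluded from the expansion count, which is what makes 800 → 5600 exact.
Splitting is largest-remainder apportionment of 8:1:1 after a seeded
shuffle (5600 → 4480/560/560). Every generator operation is a pure
function of (config, seed).

## Problem sizes and numerical choices

The acceptance script reproduces the expansion count at 800 stand-in images
(64×64 resolution, sufficient for counting and validity), the line-fit
study at 100 seeded scenes (20 plants/row, 2 px jitter, one gap per row,
3 clutter boxes; mean |Δθ| ≈ 0.12°, weighted beating unweighted in ~95% of
seeds), and the detection study at 30 scenes. Tolerances: reflectance
round-trip 1e-9; gamma-table equality vs a loop-based recomputation exact
to 1e-12; WLS vs normal-equation oracle 1e-9 and vs a zooming grid search
1e-3; parallel-slope threshold 1e-9. Ties in gap sorting break by x
ascending; zero-weight points are excluded from fits; degenerate geometry
(no spread along the fitting axis in either form) raises rather than
returning an ill-conditioned line.

## Known limitations

Single-scale Retinex only; straight rows only (no curvature, exactly two
rows); the gap rule is the only planting-anomaly detector (seedling offset
detection is not formalised); the attention/pooling blocks are reference
forwards, not a trainable network; timing figures depend on the host and
are excluded from all assertions.
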