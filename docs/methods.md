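# Methods notes

This note records the model behind `mangovol`, the choices made where
the design was genuinely open, and the numerical behavior a user should
know before trusting the outputs.

## 1. Measurement model

A fruit is treated as a solid whose volume is to be inferred from two
orthogonal silhouettes.  The imaging protocol poses the fruit
consistently: side view with the calyx toward the right image edge,
bottom view resting in a holder.  Three object classes are segmented per
image — fruit body, calyx, marker — as binary masks (255 = foreground).
The calyx is *removed* from the body before any measurement: its lobes
are irregular protrusions that otherwise inflate areas and rectangle
dimensions with fruit-to-fruit noise that no downstream regression can
remove.

Per-image metric calibration divides the marker's known physical area
(900 mm² for the default 30 mm square) by its pixel count:
`R_area = 900 / A_marker` (mm²/px) and `R_length = √R_area` (mm/px).
The square root is the only dimensionally consistent length ratio under
isotropic scaling.  Calibrating each image independently makes every
feature invariant to camera distance — this invariance is a tested
property, not an assumption (see §5).

The nine features and the ellipsoid fusion
`V_e = (4/3)π (h/2)(w/2)((d1+d2)/4)` are described in the README.  Two
conventions deserve mention:

* **Dimension assignment.**  In both views the rotated-rectangle sides
  are assigned larger→(`h` or `w`), smaller→(`d1` or `d2`).  The rule is
  symmetric across views and matches a consistently posed fruit whose
  depth axis is its smallest.  If the pose convention is violated (depth
  axis larger than height), `V_e` no longer estimates the ellipsoid
  volume; the synthetic generator therefore draws the depth semi-axis
  as the smallest of the three (§3).
* **Power-law features.**  `A_s15`/`A_b15` are *derived properties*,
  recomputed from the stored areas on every access (and recomputed from
  clamped areas after augmentation).  They can never drift out of sync.

## 2. Regression suite

Models B/G/I/M/N are written as pure proportionality forms
(`V ≈ k·x`, `V ≈ k₁x₁ + k₂x₂ [+ k₃x₃]`) and are fitted by ordinary
least squares **without intercept**, matching their written form; an
explicit `fit_intercept` switch exists because the convention is not
forced.  Model L is the standard degree-2 polynomial expansion
{x₁, x₂, x₁², x₁x₂, x₂²} *with* intercept.  Models O (gradient
boosting: 300 trees, depth 3, learning rate 0.05) and P (RBF-kernel
SVR: C = 10, ε = 0.1, gamma = 'scale') ship with fixed documented
defaults and are reported for completeness; on small geometric tables
they over-fit and are excluded from headline analysis.

Negative predictions are returned unchanged — clipping would hide
exactly the misbehavior the residual diagnostics exist to expose; the
count of negative training predictions is kept in `fit_diagnostics_`.
Rank-deficient designs fall back to the least-norm solution with a
warning.  Fewer rows than parameters is an error.

Evaluation follows the conventions listed in `evaluation.py`'s module
docstring; the two that differ between toolkits are (a) MAPE uses the
denominator `y + ε` with ε = 1e-6 (volumes are positive; for negative
truths this differs from the `|y|` convention), and (b) the both-empty
IoU is defined as 1 (two predictions agreeing on absence).  The paired
t-test compares per-sample absolute errors; identical error magnitudes
return (t=0, p=1), while a zero-variance *nonzero* difference is a
degenerate-case error.  Levene's test uses classic mean centering
(median centering available as the Brown–Forsythe variant).

## 3. What the synthetic generator emulates — and what it does not

`make_fruit_population` draws analytic volumes from a truncated-at-zero
normal (defaults: mean 51.52 cm³, SD 10.61 cm³, matching the cleaned
reference population), splits each volume into three semi-axes with
multiplicative jitter (default ±10%) renormalized to preserve the
volume exactly, assigns the smallest axis to depth (§1), and gives each
fruit a mass at a density uniform in [1.00, 1.15] g/cm³ — the
post-filter physical band for a fruit denser than water.  The calyx is
4–7 overlapping disks (radius ≈ 0.55 cm, outward offset ≈ 0.35 cm, each
jittered ±30%) centered on the right-facing silhouette; calyx pixels
are rendered strictly outside the body, so the class masks are
disjoint by construction.  In the bottom view the lobes point toward
the camera and project inside the silhouette, so the bottom calyx mask
is empty.

Rasterization rule: a pixel is foreground iff its center
`(r + 0.5, c + 0.5)` lies strictly inside the analytic shape.  This
makes areas asymptotically unbiased and makes the marker arithmetic
exact whenever `marker_side_mm / mm_per_px` is an integer (e.g. 60 px
and 3600 px² at 0.5 mm/px).

The generator emulates *geometry only*.  It does not emulate:
segmentation errors (mask boundaries are exact to the rasterization
rule), lighting/texture/occlusion effects, non-ellipsoidal body shapes
(ribbing, asymmetric shoulders), perspective distortion, or calyx
morphology beyond disk lobes.  Consequently, passing tests demonstrate
that the *pipeline* is correct and well-conditioned — they say nothing
about how well an ellipsoid-plus-areas model fits real fruit, and the
near-perfect R² values on noiseless renders must not be read as
field accuracy.  On real data the same pipeline reports much larger
errors, dominated by biological shape deviation and segmentation noise.

## 4. Numerical behavior of the rectangle descriptor

The min-area rotated rectangle is fitted to the convex hull of the
boundary pixels *expanded by the four half-pixel corner offsets* (the
hull of the pixel squares).  Spans measured center-to-center are biased
−1 px per dimension; the corner expansion makes the extent of an
axis-aligned rasterized ellipse unbiased (error `1 − δ₁ − δ₂` with
δ ~ U(0,1)).  Side lengths are kept sub-pixel and converted
px → mm → cm only at feature assembly.  The rectangle operates on the
largest connected component's outer contour; holes are ignored.  A
single-pixel mask yields a 1 px × 1 px square — a documented degenerate,
not an error.

Two intrinsic limitations, found by analysis and confirmed by
measurement, bound the descriptor's stability:

* **Orientation conditioning.**  For a near-circular silhouette with
  axis ratio 1 + e, the rectangle-area objective varies only by a
  factor ≈ 1 + e²/2 between the axis-aligned and 45° orientations, so
  for small e sub-pixel noise can flip the fitted angle and trade the
  long/short sides by up to ~e/2 — at *any* resolution.  The fused
  `V_e` is robust to such flips (the product h·d1 tracks the preserved
  rectangle area), but individual dimensions are not.  Dimension-level
  stability claims therefore apply to distinctly triaxial shapes;
  `make_triaxial_population` (axis ratios 1.25 : 1 : 0.8, ±3% jitter)
  exists to generate them.
* **Marker quantization.**  A 30 mm marker at 0.7 mm/px is 42.857 px
  and must rasterize to 43 px per side, a fixed −0.67% bias in the area
  ratio and hence ≈ 1% in `A^1.5` and `V_e` relative to a resolution
  where the marker divides evenly.  This floor is inherent to
  pixel-count calibration, shrinks with marker size in pixels, and is
  part of the error budget of any cross-resolution comparison.

The scale-invariance check (0.3 vs 0.7 mm/px, every feature within 2%)
is accordingly run on large triaxial shapes (volume ≈ 8000 cm³, i.e.
≳ 195 px smallest projected diameter at the coarser scale — well above
the 80 px floor below which rectangle quantization alone could consume
the band).  Both choices follow from the error budget above, not from
the biology: the property under test is the calibration, and the
fixture is sized so the two intrinsic floors stay well inside the band.

## 5. Dataset operations

* **Density filter.**  `ρ = mass / V_true < 1.00 g/cm³` (strictly less)
  discards a record as a measurement error; equality is kept.  Both
  partitions are returned so audits can verify conservation.  Density
  is always recomputed, never stored.
* **Augmentation.**  Synthetic rows are drawn from a multivariate
  normal fitted to (`A_s`, `A_b`, `h`, `w`, `d1`, `d2`, `V_e`,
  `V_true`).  Including the target in the joint distribution is the
  only self-consistent way for synthetic rows to carry training labels
  that co-vary with their features; it is flagged here because the
  choice is not forced.  Every component is clamped at 0.01 to stay
  physically plausible; power-law features are recomputed from clamped
  areas.  Synthetic rows have no mass (density filtering precedes
  augmentation).  A singular covariance receives a ridge of
  1e-8 × mean diagonal, recorded in the dataset's seed log.
* **Split.**  Uniform random partition, `|train| = round(f·N)`,
  deterministic per seed.  Quartiles everywhere use linear
  interpolation between closest ranks (the numpy default).

All randomness flows through explicit seeds — the generator, placement
jitter, augmentation and splitting each take one, and the pipeline
derives per-stage seeds from a single run seed by hashing; there is no
global random state.  Re-running a pipeline config is byte-identical.

## 6. Known limitations

* The renderer draws axis-aligned ellipses; in-plane fruit rotation is
  not simulated (the rectangle descriptor itself is rotation-capable
  and is tested on rotated rasterized rectangles).
* Calyx lobes are circular disks; real calyx geometry is leafier and
  partially occludes the body in side views, which the generator never
  does.
* The confidence/largest-instance selection logic accepts segmenter
  outputs as files; no neural inference is embedded, and segmentation
  quality metrics (IoU, F1) are provided for evaluating an external
  segmenter, not produced by one here.
* Single 80:20 split, as in the underlying protocol — no
  cross-validation.  Model uncertainty is characterized by the
  diagnostic battery, not by resampling.
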