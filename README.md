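# mangovol

Non-destructive fruit volume estimation from ordinary 2D images, for
mangosteen (*Garcinia mangostana* L.) and other composite fruits whose
lobed calyx breaks naive silhouette models.  The package is aimed at
post-harvest phenotyping and grading work: it turns per-class binary
instance masks (fruit body / calyx / fiducial marker, two orthogonal
views) into calibrated geometric features and regression-based volume
estimates, and ships a synthetic scene renderer so the whole chain is
testable without a camera or a neural segmenter.

## The method

Each fruit is photographed from a **side** and a **bottom** view with a
30 mm × 30 mm fiducial marker in frame.  Per image, the marker's pixel
area `A_marker` gives the metric scale

    R_area = 900 mm² / A_marker   (mm²/px),    R_length = √R_area   (mm/px),

which removes any dependence on camera distance.  After subtracting the
calyx mask from the fruit-body mask, nine descriptors are extracted
(areas in cm², lengths in cm):

| feature | meaning |
|---|---|
| `A_s`, `A_b` | projected fruit area, side / bottom view |
| `A_s15`, `A_b15` | `A^1.5` power laws (scale like volumes) |
| `h`, `d1` | long / short side of the side view's min-area rotated rectangle |
| `w`, `d2` | long / short side of the bottom view's rectangle |
| `V_e` | ellipsoid fusion `V_e = (4/3)·π·(h/2)·(w/2)·((d1+d2)/4)` |

Volume models are linear forms fitted without intercept (plus a
degree-2 polynomial variant and two reference ML regressors):
side-only `V ≈ k·A_s^1.5` (B), bottom-only (G), multi-view additive (I),
polynomial (L), ellipsoid `V ≈ k·V_e` (M), and the hybrid
`V ≈ k₁A_s^1.5 + k₂A_b^1.5 + k₃V_e` (N).  Models are evaluated on a held
out split with R², ε-guarded MAPE, RMSE and mean bias, plus paired
t-tests, Levene's variance test and Bland–Altman agreement analysis.

Because no public image set exists for this task, the package includes a
parametric scene generator: ellipsoidal fruit bodies with analytic
ground-truth volume, lobed calyx protrusions, and an exact square
marker, rasterized with a pixel-center rule.  The generator's defaults
reproduce the measured population statistics of the reference dataset
(volume mean 51.52 cm³, SD 10.61 cm³).

## Worked example

```python
import numpy as np
from mangovol.synth import make_fruit_population, render_views
from mangovol.data import dataset_from_scenes, augment_mvn, split_train_test
from mangovol.models import fit_model, fit_and_compare

fruits = make_fruit_population(n=200, volume_mean=51.52, volume_sd=10.61, seed=1)
rng = np.random.default_rng(2)
pairs = [render_views(f, mm_per_px=0.5, rng=rng) for f in fruits]
dataset = dataset_from_scenes(pairs)            # masks -> 9 features per fruit
augmented = augment_mvn(dataset, n_synth=200, seed=3)
train, test = split_train_test(augmented, train_fraction=0.8, seed=4)
model = fit_model("N", train)
print(model.coef_)
print(fit_and_compare(["B", "G", "I", "L", "M", "N"], train, test))
```

prints (abridged):

```
Model N coefficients: {'A_s15': 0.0278, 'A_b15': 0.0368, 'V_e': 0.9166}
   Category                                    Model     R2   MAPE   RMSE    Bias
Single-View                     B: Side-Only (A_s15) 0.9157 4.1824 2.5449 -0.2187
Single-View                   G: Bottom-Only (A_b15) 0.8978 4.8310 2.8015 -0.0583
 Multi-View            I: Geo combined (A_s15+A_b15) 0.9903 1.4045 0.8649 -0.0400
 Multi-View                      L: Poly-Geo (deg=2) 0.9904 1.4055 0.8567  0.0629
  Ellipsoid                           M: V_ellipsoid 0.9984 0.5744 0.3520 -0.0694
     Hybrid N: Combined Linear (areas + V_ellipsoid) 0.9986 0.5424 0.3291 -0.0643
```

On these noiseless synthetic scenes the ellipsoid feature is nearly
exact (the fitted `k` for Model M is 1.000 ± sub-percent), so the hybrid
model N leans on `V_e` (k₃ ≈ 0.92) and the multi-view models clearly
beat the single-view ones — the qualitative ordering the method is built
around.  MAPE here reflects only rasterization error; real imagery adds
segmentation and measurement noise on top.

The same chain is available from the shell:

```sh
mangovol run-all --out runs/demo            # full pipeline, default config
mangovol simulate --n 50 --out scenes/      # just render scenes
mangovol extract-features --scenes scenes/ --out features.csv
```

Every run directory contains the per-stage CSV/JSON artifacts, a
`config.yaml`, and a `manifest.json` with seeds, row counts and file
hashes; re-running the same config is byte-identical.

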