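# bonereg

Expert-supervised rigid registration of bone surface models for serial
imaging of the knee.

## The problem

Quantitative knee imaging often acquires the same joint several times -
CT then MRI, or repeated CT - and each acquisition is segmented and
analysed on its own. Relating parameters across image sets (bone density
from CT, cartilage from MRI) needs the bone models from one acquisition
positioned inside the other. Intensity-based registration is not always
trustworthy when protocols are tuned to specific tissues, so this toolkit
implements an expert-supervised alternative: an operator places a sparse
set of **attraction points** on the bone edges visible in the target
image, and the triangulated bone model built from the source segmentation
is positioned on those points automatically. It is aimed at researchers in
musculoskeletal image analysis who need a transparent, scriptable
registration pipeline with a built-in evaluation harness.

## The method

* Segmentations are per-slice closed B-spline contours, lofted into
  closed, manifold triangle meshes (`bonereg.contours`).
* Positioning is rigid **coherent point drift** (CPD): farthest-point
  samples of the model act as Gaussian-mixture centroids with shared
  variance `sigma^2` and uniform outlier weight `w`; EM alternates soft
  correspondence with a closed-form SVD rotation update. A point-to-plane
  polish against the exact triangle surface removes the sampling
  discretisation floor. (`bonereg.registration`, statsmodels-style:
  `RigidCPD(fixed, moving, config).fit()` returns a result object with
  `summary()`.)
* Two reference registrations for evaluation: corresponding-point
  least-squares on embedded **fiducial markers** (gold standard) and
  whole-model CPD (substitution gold standard).
* Registration error is quantified by the symmetric **mean absolute
  surface distance** (MAD, mm) and the volumetric **Dice** index
  `2|A&B|/(|A|+|B|)` on a shared voxel grid (`bonereg.metrics`).
* Because the original imaging data are not public, `bonereg.synthetic`
  generates bone-like ground-truth cases (known rigid truth, interoperator
  segmentation perturbation, operator placement noise, embedded
  fiducials), and `bonereg.experiments` reproduces the evaluation designs:
  the attraction-point-count study (32..1024 points, Wilcoxon rank-sum
  with Bonferroni correction) and the method comparisons (Wilcoxon
  signed-rank), reported as median (Q1, Q3).

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```
$ bonereg simulate --kind femur --seed 3 --detail coarse --out-dir case3/
wrote case femur-3 to case3

$ python - <<'PY'
import numpy as np
from bonereg.io import read_mesh, read_points, read_transform
from bonereg.registration import register_model_to_points, CpdConfig
from bonereg.experiments import subsample_points
from bonereg.metrics import compare_models, MetricSettings
from bonereg.geometry import transform_discrepancy

model = read_mesh("case3/model.ply")
pool = read_points("case3/candidates.csv")
truth = read_transform("case3/truth.json")

pts = subsample_points(pool, 128, seed=7)          # expert places 128 points
res = register_model_to_points(model, pts, CpdConfig(seed=1))
rot, tr = transform_discrepancy(res.transform, truth)
print(f"rotation error {rot:.3f} deg, translation error {tr:.3f} mm")

registered = model.transformed(res.transform, "target")
reference = read_mesh("case3/reference.ply")
rep = compare_models(registered, reference, MetricSettings(0.5, 5000, 0))
print(f"MAD {rep.mad_mm:.3f} mm, Dice {rep.dice:.3f}")
PY
rotation error 0.925 deg, translation error 0.013 mm
MAD 0.243 mm, Dice 0.984
```

The rotation/translation errors compare the estimated pose with the
generator's known truth: with 128 operator points at 0.3 mm placement
noise the pose is recovered to about a degree (dominated by the weakly
constrained shaft-axis mode) and to a few hundredths of a millimetre of
translation. The MAD of ~0.25 mm against the reference
model is dominated by the simulated interoperator segmentation difference
(0.3 mm RMS), not by the registration itself - the same behaviour the
fiducial gold standard shows on these cases - and the Dice of ~0.98
indicates near-complete volumetric overlap.

The full study harness is available from the CLI as well:

```
bonereg study points --n-cases 10 --seed 0 --out results/points/
bonereg study methods --regime inter --seed 0 --out results/inter/
```

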