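# landreg

Unsupervised spatial-landmark detection and thin-plate-spline
registration for tissue sections and spatial omics.

Registering histology sections, serial z-stacks and spot-based
transcriptomics into a common coordinate framework usually requires
manually annotated landmarks. `landreg` removes that bottleneck: a
small convolutional heatmap network learns, with no labels, to place K
ordered landmarks on each section, and the *only* alignment machinery
is an analytically solved thin-plate spline (TPS)

```
f(x, y) = a₁ + aₓx + a_y y + Σᵢ wᵢ U(‖(xᵢ, yᵢ) − (x, y)‖),   U(r) = r² log₂ r
```

fitted per output axis through the augmented linear system
`[[K + λI, P], [Pᵀ, 0]]`. Because the spline is closed-form and cannot
memorize images, an MS-SSIM registration loss can only be reduced by
landmarks that genuinely correspond across sections — that pressure is
the whole training signal. Three regimes are supported:

* **pairwise** — `L = L_base + 0.1·L_consistency`, registering
  augmented variants of a section plus a second section;
* **z-stack** — `L = (1−dA)·D(X_jᵀᴾˢ, X_iᵀᴾˢ) + dA·D(X_jᵀᴾˢ, X_iʳⁱᵍ)`,
  where the TPS area change dA gates toward a rigid Kabsch–Umeyama
  alignment, turning landmarks into planar anchor points for 3-D
  reconstruction;
* **multimodal** — `L = L_base + 10·L_intra + 0.1·L_inter`, with
  `L_inter` the RMSE between first-layer network latents of two
  modalities after cross-registration.

Everything differentiable (conv net → spatial soft-argmax → TPS linear
solve → bilinear warp → MS-SSIM) runs on a compact numpy reverse-mode
autodiff core (`landreg._autodiff`), so the package needs no tensor
framework. The library also ships Visium-style spot ingestion
(filtering, normalization, Leiden/t-statistic gene selection,
rasterization, PCA channel reduction), the benchmark metrics
(consistency, forward/backward regression errors, TRE/ATRE, k-NN
region accuracy), and a synthetic tissue generator with exact ground
truth.

Intended users: computational biologists aligning serial sections or
multimodal spatial data at desk scale, and anyone needing a clean,
fully-tested TPS/landmark registration stack in pure scientific
Python.

## Worked example: 3-D stack alignment

Train anchor-point landmarks on a synthetic 12-section z-stack and
measure the target-registration error (TRE) on held-out ground-truth
points:

```python
import numpy as np
from landreg import (
    DetectorConfig, SyntheticSpec, TrainConfig, AugmentConfig,
    build_detector, tps_fit, tps_transform_points, train_stack,
)
from landreg.synthetic import make_stack
from landreg.evaluation import tre

spec = SyntheticSpec(image_size=64, n_sections=12, seed=0)
stack = make_stack(spec)
detector = build_detector(
    DetectorConfig(n_landmarks=8, input_size=64, scale="reduced"), seed=0
)

def mean_tre(det):
    errs = []
    for i in range(11):
        m = tps_fit(det.detect(stack.sections[i]),
                    det.detect(stack.sections[i + 1]), lam=1e-6)
        pred = tps_transform_points(m, stack.target_points[i])
        errs.append(tre(pred, stack.target_points[i + 1]))
    return float(np.mean(errs))

print(f"TRE before training: {mean_tre(detector):.2f} px")
cfg = TrainConfig(learning_rate=1e-3, batch_size=12,
                  iterations_per_epoch=2, max_epochs=8, seed=0)
aug = AugmentConfig(target_size=64, elastic_sigma_range=(3.0, 3.0),
                    elastic_grid_range=(3, 4))
detector, history = train_stack(stack.sections, detector, cfg, aug)
print(f"loss: {history['total'][0]:.3f} -> {history['total'][-1]:.3f}")
print(f"TRE after training: {mean_tre(detector):.2f} px")
```

Output (about a minute on one CPU):

```
TRE before training: 2.56 px
loss: 0.378 -> 0.140
TRE after training: 0.99 px
```

The untrained detector's landmarks carry no correspondence, so
TPS point transfer between consecutive sections misses the held-out
target points by ~2.6 px; eight short epochs of the area-gated stack
loss cut that error to under a pixel — the landmarks have become
consistent anchors along the stack.

## Command line

Each command is seeded and byte-reproducible:

```bash
landreg simulate stack --size 64 --sections 12 --seed 0 --out data/
landreg train-pairwise  --data data/ --out run/ --seed 0 --config config.yaml
landreg train-stack     --data data/ --out run/ --seed 0
landreg detect    --checkpoint run/detector.npz --data data/ --out landmarks.csv
landreg evaluate tre --landmarks pred.csv --annotations truth.csv --out report.json
landreg preprocess --counts counts.csv --coords coords.csv --out pp/
landreg rasterize  --counts pp/counts_filtered.csv --coords coords.csv \
                   --genes pp/selected_genes.txt --out channels.tif
```

The training config YAML has `detector`, `train`, `augment` and `loss`
blocks mirroring `DetectorConfig`, `TrainConfig`, `AugmentConfig` and
`LossWeights`; every run writes a `manifest.json` with all resolved
hyperparameters.

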