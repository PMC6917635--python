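# tinyseg

Reduced-parameter encoder–decoder CNNs for pixel-wise plant
segmentation, implemented as a pure-numpy library with a CLI.

Precise segmentation of plant images (flowers, rosette plants,
background) is a core step in image-based plant phenotyping, but the
standard encoder–decoder CNNs used for it (FCN, SegNet, sub-pixel
models on a VGG-16 "Basic" backbone) carry millions of parameters —
too many for low-cost, in-field devices. This package implements two
complementary compression ideas and everything needed to study them at
desk scale:

1. **Separable convolutions ("tiny" models).** Replacing each dense
   3×3 convolution (9·C<sub>in</sub>·C<sub>out</sub> weights) with a
   depthwise 3×3 kernel plus a 1×1 pointwise mix
   (9·C<sub>in</sub> + C<sub>in</sub>·C<sub>out</sub> weights) cuts the
   encoder parameter count by ~88% before training.
2. **Truncated-SVD weight compression ("very tiny" models).** After
   training, each remaining large weight matrix W (m×n) is stored as
   its top-k singular triplets (m·k + k + k·n floats instead of m·n),
   skipping the first three encoder blocks, which are small and hold
   high-detail features.

The parameter totals of all six architectures match the published
figures exactly:

| model         | parameters | tiny reduction |
|---------------|-----------:|---------------:|
| fcn           |  7,647,950 |              – |
| tiny-fcn      |    885,528 |        88.42 % |
| segnet        | 17,649,795 |              – |
| tiny-segnet   |  2,034,499 |        88.47 % |
| subpixel      |  7,646,043 |              – |
| tiny-subpixel |    881,142 |        88.48 % |

There is no deep-learning framework underneath: the forward pass,
backpropagation, batch normalization, pooling-index unpooling, bilinear
upsampling, pixel shuffle and the Adam optimizer are all implemented in
numpy, which keeps the package dependency-light and every computation
inspectable.

## Worked example

Train a tiny FCN on synthetic scenes, evaluate it, and compress it —
all on one CPU core in a few minutes:

```python
import numpy as np
from tinyseg import archspec, data, svd
from tinyseg.train import TrainConfig, evaluate, train

# 1. synthetic field-like scenes: textured background + coloured objects
scenes = data.synthesize_dataset(50, 3, height=64, width=64, seed=11,
                                 profile=data.SceneProfile.easy())
tr, va, te = data.split_dataset(len(scenes), seed=11)   # 64/16/20 split
images = np.stack([s.image for s in scenes])
labels = np.stack([s.mask for s in scenes])
onehot = np.stack([data.one_hot(m, 3) for m in labels])

# 2. a tiny (separable-convolution) FCN at desk-scale input size
spec = archspec.build_model("fcn", tiny=True, n_classes=3, input_size=64)
print(archspec.count_parameters(spec).total)            # 885,528

# 3. train with median-frequency class balancing + Adam + LR plateaus
params, history = train(spec, (images[tr], onehot[tr]),
                        (images[va], onehot[va]),
                        TrainConfig.desk_scale(epochs=30, seed=0))

# 4. the four confusion-matrix metrics on held-out scenes
report, _ = evaluate(spec, params, images[te], labels[te])
print(report["pixel_accuracy"], report["mean_iou"])

# 5. post-training SVD compression (rank 4, first 3 blocks skipped)
archive = svd.compress_model(params, spec, k=4)
dense = archspec.build_model("fcn", tiny=False, n_classes=3, input_size=64)
print(svd.storage_report(archive, svd.baseline_floats(dense)).savings_percent)
```

The same pipeline is available from the shell:

```bash
tinyseg params --family fcn --tiny                   # parameter report
tinyseg gen-data --n 50 --classes 3 --seed 11 --size 64 --easy --out ds/
tinyseg train --data ds/ --family fcn --tiny --classes 3 \
              --input-size 64 --epochs 30 --out run/
tinyseg compress --weights run/weights.h5 --spec run/model.spec \
                 --k 4 --out run/archive.h5
tinyseg reconstruct --archive run/archive.h5 --spec run/model.spec \
                    --out run/re.h5
tinyseg evaluate --weights run/re.h5 --spec run/model.spec \
                 --data ds/ --out run/report.json
tinyseg predict --weights run/weights.h5 --spec run/model.spec \
                --image ds/image_0000.png --out run/pred.png
```

Every command writes a JSON run manifest beside its artifacts. Longer
narrative walk-throughs live in `examples/`:

- `examples/params_table.py` — reproduce the parameter table
- `examples/synthetic_scenes.py` — the scene generator and class weights
- `examples/svd_compression.py` — SVD from one matrix to a whole model
- `examples/train_eval.py` — the full train/evaluate/compress pipeline

## Testing

```bash
python -m pytest -q tests/
```

The suite covers closed-form parameter oracles, finite-difference
gradient checks of the numpy engine, Eckart–Young and
eigendecomposition oracles for the SVD, brute-force metric formula
oracles, scheduler/loss contracts, CLI round-trips, and the acceptance
criteria. One acceptance test fails by design (the red compression
property above); all other tests pass.

## Repository layout

```
src/tinyseg/      library (archspec, nn, svd, data, metrics, train, cli)
examples/         narrative example scripts
tests/            pytest suite incl. tests/test_acceptance.py
scripts/          acceptance.py (recomputes the published targets)
docs/methods.md   methods note: derivations, conventions, limitations
```
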