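# pcmseg

Trainable segmentation and growth monitoring for phase-contrast
micrographs of adherent cell cultures.

Adherent cultures — stem-cell colonies on feeder layers, co-cultures in
microfabricated bioreactors — are hard to quantify from phase-contrast
microscopy (PCM): the cells are transparent, intensity thresholds fail,
halos ring every object, and fabrication artifacts (scratches, dust) look
like cells to naive pipelines.  `pcmseg` implements a texture-based,
trainable alternative: a user scribbles a few *definitely cell* /
*definitely not cell* regions on one image, and a random-forest pixel
classifier learns to segment every subsequent frame, feeding confluency
curves and colony-level event tracking (migration, merging, wash-out
under perfusion).

## Method

1. **Basic image features (BIFs).**  Each pixel is classified into one of
   seven local-symmetry classes — flat, gradient, dark/light blob,
   dark/light line, saddle — from scale-normalized derivative-of-Gaussian
   responses $s_{ij} = \sigma^{i+j}\,(G^{(i,j)}_\sigma * I)$.  With
   $\lambda = s_{20}+s_{02}$ and
   $\gamma = \sqrt{(s_{20}-s_{02})^2 + 4 s_{11}^2}$ the class is the
   argmax of the scores
   $\{\varepsilon s_{00},\; 2\sqrt{s_{10}^2+s_{01}^2},\; \lambda,\;
   -\lambda,\; (\gamma+\lambda)/\sqrt2,\; (\gamma-\lambda)/\sqrt2,\;
   \gamma\}$.
   Labels are computed at four scales, $\sigma \in \{0.7, 1.4, 2.8, 5.6\}$ px.
2. **Local histograms.**  For every pixel, the frequencies of the seven
   labels in the 25 × 25 window around it are concatenated over the four
   scales into a 28-element feature vector.
3. **Random forest.**  A 50-tree forest (bootstrap samples, √d features
   per split, majority vote, ties → background) is trained on the
   annotated pixels only — unspecified regions are simply left out — and
   predicts a binary cell/background mask.
4. **Quantification.**  Confluency = fraction of the culture area
   occupied by cells, per field and across stitched tile scans; colonies
   are 8-connected components tracked frame-to-frame by pixel overlap
   into move / merge / split / appear / disappear events.

A seeded synthetic scene generator (textured colonies, phase halos,
illumination bias, scratches and dust, logistic growth, drift and
scripted wash-outs) provides exact pixel-level ground truth, so the whole
pipeline is testable without any image downloads.

## Worked example

```python
import numpy as np
from pcmseg import (SceneParams, generate_scene, annotations_from_truth,
                    PixelSegmenter, confluency)

scene = generate_scene(SceneParams(seed=0))          # 256x256, ~30% confluency
ann = annotations_from_truth(scene.truth_mask, fraction=0.10, seed=0)

model = PixelSegmenter.from_image(scene.image, ann)  # 28-feature encoding
results = model.fit(n_trees=50, seed=0)
print(results.summary())

mask = results.predict_mask(model.features)
print(f"true confluency      {scene.truth_mask.mean():.3f}")
print(f"estimated confluency {confluency(mask):.3f}")
held = ann == 0
print(f"held-out accuracy    {(mask[held] == scene.truth_mask[held]).mean():.3f}")
```

prints

```
Random-forest pixel segmenter
=============================
trees:               50
features per split:  sqrt(n_features)
feature length:      28
training pixels:     negative=4341, positive=1590
out-of-bag accuracy: 0.9981
seed:                0
class order:         ('background', 'cell')
scales (sigma, px):  (0.7, 1.4, 2.8, 5.6)
epsilon:             0.1
histogram window:    25

true confluency      0.300
estimated confluency 0.285
held-out accuracy    0.970
```

With 10% of the safely annotatable pixels scribbled, the forest recovers
the ground-truth mask with 97% held-out accuracy and estimates confluency
within 1.5 percentage points of truth.

## Command line

The same stages are available as batch commands for stored images:

```bash
pcmseg simulate  --config run.json --out frames/       # synthetic fixtures
pcmseg annotate-template --image frames/frame000.tif --out ann.png
pcmseg train     --config run.json --image frames/frame000.tif \
                 --annotations ann.png --out model.joblib
pcmseg segment   --config run.json --model model.joblib \
                 --manifest frames/manifest.json --out masks/
pcmseg confluency --config run.json --masks masks/ --out confluency.csv
pcmseg track      --config run.json --masks masks/ --out events.csv
pcmseg report     --series confluency.csv --out growth.png
```

All randomness flows from the config seed; every output carries a sidecar
with the producing config hash, and two runs from one config are
byte-identical.

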