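# chestcad

Rib-suppressed lung-nodule detection for chest radiographs.

Most nodules missed on chest films are partly obscured by overlying bone —
ribs and clavicles whose quasi-periodic bright bands both hide nodules and
spawn false positives.  `chestcad` implements a complete computer-aided
detection (CAD) chain built around a learned bone suppressor, for
researchers studying rib suppression and candidate classification who need
every stage measurable against exact ground truth:

1. **Synthetic chest phantoms** (`chestcad.phantom`) — additive
   x-ray = soft tissue + bone + noise images with paired bone-only and
   soft-tissue-only truth, two-lobe lung masks, oblique rib / clavicle bands
   of controllable contrast, and circular nodules (default diameter
   17.8 mm) in five subtlety grades.
2. **Lossless multi-resolution pyramid** (`chestcad.pyramid`) — 2x2
   block-mean downsampling with pixel-replication upsampling; the
   difference-plus-base representation inverts exactly:
   `reconstruct(decompose(I, L)) == I`.
3. **Massive-training suppressor** (`chestcad.mann`) — one small
   patch-in/pixel-out regressor per pyramid level (81–20–1, sigmoid hidden,
   linear output) trained by seeded mini-batch gradient descent to predict
   the bone image from x-ray patches; soft-tissue synthesis
   `f = g − w_c · f_b · n` with the rib-contrast weight `w_c ∈ [0, 1]`, and
   a sensitivity sweep to locate the optimal `w_c`.
4. **Lung fields & detrending** (`chestcad.lungfield`) — a point-
   distribution active shape model over segment-labelled boundary landmarks,
   and second-order bivariate background-trend correction
   `F(x,y) = ax² + by² + cxy + dx + ey + f`.
5. **Candidate detection** (`chestcad.detect`) — two-scale top-hat nodule
   enhancement into [0, 1] likelihood maps, watershed catchment basins, and
   saddle-rule basin clustering into candidates.
6. **Features** (`chestcad.features`) — 31 features per image domain
   (position/likelihood, shape, gray-level region-vs-surround, eight-sector
   gradient concentration, quartic-surface principal curvatures, GLCM
   texture, boundary/edge overlap), computed on both the x-ray and
   soft-tissue images for 62 values per candidate, plus a conventional
   14-feature baseline set and the circularity index `4πA/R²`.
7. **Classification & FROC** (`chestcad.classify`) — Gaussian-kernel SVM
   with image-grouped cross-validation, a gradient-descent MLP baseline,
   and free-response ROC analysis with a greedy 25 mm distance hit
   criterion.

`chestcad.pipeline` chains the stages end to end and runs the two-arm
experiment (suppression vs. none) that quantifies what the suppressor buys.

## Worked example

```python
from dataclasses import replace
from chestcad import phantom as ph
from chestcad.detect import DetectorConfig
from chestcad.mann import (SuppressorHyperparams, sweep_rib_contrast,
                           train_suppressor)
from chestcad.pipeline import PipelineConfig, compare_pipelines

base = ph.default_config(256, seed=7)          # 256 px, 1.4 mm pixels
mix = {g: 1.0 for g in range(1, 6)}            # uniform subtlety grades
under_rib = replace(base, n_nodules=1, nodules_under_ribs=True)

train = ph.generate_dataset(1, 3, replace(under_rib, seed=100), mix)
model = train_suppressor(train, n_levels=3,
                         hyperparams=SuppressorHyperparams(seed=7))

det = DetectorConfig(scales=(3.0, 8.0))        # disk radii at 256 px scale
heldout = ph.generate_dataset(0, 10, replace(under_rib, seed=2000), mix)
sweep = sweep_rib_contrast(model, heldout, [0.0, 0.2, 0.4, 0.6, 0.8, 1.0], det)
print("sweep:", sweep.points, "best w_c =", sweep.best_wc)

study = ph.generate_dataset(20, 40, replace(under_rib, seed=5000), mix)
report = compare_pipelines(
    study, model, PipelineConfig(detector=det, w_c=sweep.best_wc, seed=3))
for arm, entry in report["arms"].items():
    print(f"{arm}: sensitivity @ 1 FP/image = {entry['sensitivity_at_fp']:.3f}")
```

Output on this machine:

```
sweep: [(0.0, 0.2), (0.2, 0.1), (0.4, 0.2), (0.6, 0.3), (0.8, 0.5), (1.0, 0.3)] best w_c = 0.8
no_suppression: sensitivity @ 1 FP/image = 0.400
suppression: sensitivity @ 1 FP/image = 0.500
```

Reading the numbers: the sweep's candidate-stage localization score rises
with the rib-contrast weight until over-subtraction begins to erode nodule
contrast (the interior peak at 0.8), and at a matched one false positive
per image suppression lifts sensitivity from 0.40 to 0.50 on phantoms whose
nodules all hide under ribs and whose subtlety grades span down to the
noise floor.  Absolute values are specific to the phantom's contrast/noise
settings; the *comparison* is the point.

A command-line interface mirrors the library:

```bash
chestcad phantom generate --out study/ --size 256 --n-nodule 3 --seed 1
chestcad mann train --samples study/ --out model --seed 1
chestcad run --seed 11 --out results/
```

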