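# octfluid

Confidence-map characterization of retinal fluid in OCT B-scans.

Diabetic macular edema (DME) leaks fluid into the retina in three clinically
distinct forms — cystoid macular edema (**CME**), diffuse retinal thickening
(**DRT**) and serous retinal detachment (**SRD**). DRT in particular has no
crisp boundary, so segmentation-style methods break down exactly where early
diagnosis matters most. `octfluid` implements the *diffuse* paradigm
instead: a convolutional classifier labels small windows of the retina, and
overlapping windows vote pixel by pixel to produce per-class **confidence
maps** over the retinal region of interest (ROI, the band between the ILM
and the RPE). The package is aimed at researchers in retinal image analysis
who want a fully testable, CPU-runnable reference implementation of this
pipeline.

## What it does

* **`octfluid.phantom`** — synthetic layered-retina phantoms with label and
  ROI masks (curved retinal band, per-class texture, speckle, uncertainty
  halos), so every stage is exercisable without clinical data.
* **`octfluid.dataset`** — 64×64 window sampling (25 windows per label
  present per image, mirror-completed at borders), image-level 6-fold
  partitioning and the 60 train(3)/val(2)/test(1) fold-role experiments,
  imbalance-inverting class weights.
* **`octfluid.backbone`** — the densely connected patch classifier
  (full DenseNet-161 shape or a reduced desk-scale variant) with
  Kaiming/uniform initialization and bit-exact classifier-head replacement.
* **`octfluid.training`** — AdamW+AMSGrad loop (reduce-on-plateau ×0.66
  after 10 stagnant epochs, early stop after 25, best-validation snapshot)
  and three regimes: scratch baseline, generalist transfer, and the
  two-stage **uncertainty-aware transfer** (binary healthy-vs-pathological
  pretraining that pools uncertainty windows into the pathological class,
  then a 4-class fine-tune on defined labels).
* **`octfluid.metrics`** — per-class one-vs-rest accuracy / precision /
  recall / F1 / MCC and tie-aware Mann–Whitney–Wilcoxon AUC, with a
  support-weighted overall row.
* **`octfluid.confmap`** — overlapping-window voting (64 px windows, 60 px
  overlap): a pixel's confidence for a class is the fraction of covering
  windows voting for it; cold-to-warm rendering with steep mid-range
  gradients.
* **`octfluid.map_analysis`** — per-connected-component maximum confidence
  vs component size, with a sliding-median trend (1000 px windows, step 10)
  smoothed by a degree-3 b-spline.

The neural network runs on a compact numpy engine (`octfluid.nn`) with
explicit forward/backward passes, verified against finite differences in
the test suite; everything is deterministic given a seed.

## Worked example

Train the baseline and the uncertainty-transfer regime on 12 synthetic
phantoms over 2 of the 60 fold combinations and aggregate test metrics:

```python
from octfluid.phantom import PhantomConfig, generate_dataset
from octfluid.orchestrator import run_experiment_grid
from octfluid.training import TrainConfig
from octfluid.backbone import BackboneConfig

images = generate_dataset(12, PhantomConfig.high_contrast(), seed=7)
summary, per_split, manifest = run_experiment_grid(
    images=images, approaches=("baseline", "uncertainty"), n_splits=2,
    profile="desk", seed=1,
    train_config=TrainConfig(max_epochs=20, seed=1),
    backbone_config=BackboneConfig(seed=1))
cols = ["approach", "class", "accuracy_mean", "accuracy_std",
        "auc_mean", "f1_mean", "mcc_mean"]
print(summary[cols].round(3).to_string(index=False))
```

prints

```
   approach   class  accuracy_mean  accuracy_std  auc_mean  f1_mean  mcc_mean
   baseline     CME          0.911         0.052     0.985    0.780     0.757
   baseline     DRT          0.911         0.096     0.998    0.860     0.821
   baseline     SRD          0.995         0.007     0.999    0.990     0.986
   baseline healthy          0.964         0.007     0.989    0.925     0.903
   baseline overall          0.945         0.033     0.993    0.889     0.867
uncertainty     CME          0.938         0.044     0.984    0.880     0.839
uncertainty     DRT          0.964         0.007     0.999    0.925     0.906
uncertainty     SRD          0.979         0.015     0.999    0.958     0.944
uncertainty healthy          0.932         0.022     0.980    0.864     0.822
uncertainty overall          0.953         0.022     0.991    0.907     0.878
```

Each row is a one-vs-rest evaluation on held-out test-fold windows
(mean ± std over the two splits); `overall` is the support-weighted mean
across the four classes. On these controlled-contrast phantoms both regimes
separate the classes well; note the uncertainty-pretrained model's higher
CME and DRT rows — the classes most entangled with weakly labeled regions.

The same pipeline is available from the shell:

```bash
octfluid run --profile desk --approaches baseline,uncertainty --out runs/demo --maps
octfluid phantom --n 24 --out phantoms/ --seed 1
octfluid dataset --images phantoms/ --n-per-label 25 --folds 6 --out ds/
```

(`octfluid map` and `octfluid analyze` generate confidence maps and
connected-component trend plots from a saved model checkpoint and a phantom
directory; see `octfluid --help`.)

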