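# jawdx

Two-branch classification + segmentation of jaw cysts and tumors on
panoramic-radiograph-like images, with healthy-only contrastive pretraining
and a Grad-CAM position-consistency constraint — implemented end to end on
synthetic phantom radiographs.

## The problem

Odontogenic cysts and tumors (dentigerous cysts, periapical cysts,
ameloblastomas, keratocystic odontogenic tumors) present as radiolucent
regions on panoramic radiographs and are hard to tell apart, yet their
treatments differ radically. Annotated lesion radiographs are scarce while
healthy radiographs are abundant. `jawdx` implements a pipeline built
around that asymmetry, for people who want to study its mechanisms with
full control of the data:

1. **Phantom generation** — synthetic panoramic frames with per-image
   "anatomy" (curved jaw band, two dental arches, bone-density patches) and
   class-coded radiolucent lesions with exact pixel masks, since clinical
   radiographs are not redistributable.
2. **Self-supervised pretraining** — momentum contrast (query/key encoders,
   key queue, InfoNCE) on healthy frames only.
3. **Joint two-branch training** — a shared residual encoder feeds a
   classification head (softmax over {DC, PC, AB, KCOT, healthy} or
   lesion/healthy) and a U-Net-style decoder predicting the lesion mask,
   trained with

   `L = L_CE + L_MSE + w·L_constrain`,

   where `L_CE` is cross-entropy, `L_MSE = (1/K) Σ_k ‖M̄_k − M_k‖²` on
   masks, and the position-consistency constraint on the rectified
   Grad-CAM response `R_k` with the dilated ground-truth mask `M_k^d`
   (disk radius drawn uniformly per sample) is

   `L_constrain = (1/K) Σ_k [ Σ_n (1 − M_k^d[n])·R_k[n] − Σ_n M_k^d[n]·R_k[n] ]`,

   pushing class evidence into the lesion area and out of the background.
4. **Lesion-aware augmentation** — horizontal flip, cut-and-paste of lesion
   pixels onto healthy frames, and patch-covering: 20 gray-patch variants
   per lesion sample, half fully occluding the lesion (relabeled healthy,
   mask emptied), half occluding healthy tissue only (label kept), with
   patch sizes drawn from a survey of lesion bounding-box extents.
5. **Evaluation** — one-vs-rest classification metrics with macro means,
   ROC/AUC, pooled pixel segmentation metrics, and mask-to-box detection
   with all-point interpolated average precision.

Everything runs on a small numpy autodiff core (no GPU framework needed),
deterministically, at desk scale. See `docs/methods.md` for the models,
parameters and design choices, including known desk-scale limitations of
the contrastive pretraining stage.

## Worked example

```python
from jawdx.config import default_config, run_pipeline

report = run_pipeline(default_config("tiny", seed=5), "out/demo")
macro = report.to_dict()["classification"]["macro"]
print(report.to_dict()["extras"]["overall_accuracy"])
print(macro)
```

This generates a 264-frame phantom dataset (25 lesions per class,
132 + 16 + 16 healthy frames), pretrains the encoder on the healthy
pretraining split, trains both branches for 28 epochs in five-class mode,
and evaluates on the held-out test split, printing for example

```
75.0
{'accuracy': 90.0, 'precision': 49.05, 'sensitivity': 53.33,
 'specificity': 94.4, 'f1': 49.33}
```

— the overall test accuracy (percent, 20 test frames) and the macro-mean
one-vs-rest metrics over the five classes. `out/demo/` contains the
dataset, the pretrained encoder, the best-validation checkpoint, per-epoch
training logs, and `metrics.json` with the full report (per-class metrics,
AUC, pixel segmentation and detection tables). Rerunning with the same
seed reproduces the report bit for bit.

The same stages are exposed on the command line:

```bash
jawdx pipeline --profile tiny --out out/demo --seed 5
jawdx generate --profile tiny --out out/data --seed 1
jawdx survey --manifest out/data/manifest.csv
jawdx predict --checkpoint out/demo/checkpoint.npz \
              --image out/data/images/DC_00000.png --out out/pred
```

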