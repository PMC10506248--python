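# bcseg — body-composition CT segmentation

`bcseg` implements a complete segmentation toolkit for the 3-slice CT
body-composition protocol, in which a single axial slice is acquired at the
level of the liver, the abdomen and the thigh. From those three slices the
toolkit segments the tissues that drive body-composition analysis: liver and
spleen; visceral (VAT) and subcutaneous (SAT) adipose tissue with their
sub-depots — intraperitoneal (IPAT) vs. retroperitoneal (RPAT) fat, and deep
(DSAT) vs. superficial (SSAT) subcutaneous fat separated by the fascia of
Scarpa; skeletal muscle and intermuscular adipose tissue (IMAT); and
cortical bone and bone marrow. It is written for imaging researchers who
need automated, objective segmentations at cohort scale.

The package contains four parts:

1. **Four convolutional segmentation architectures** — ResUNET, UNET++,
   Ghost-UNET and Ghost-UNET++ — with a uniform contract: a preprocessed
   H×W×1 grid in, an H×W×1 sigmoid probability map y = F(X; Θ) out, channel
   widths [16, 32, 64, 128, 256] per resolution level, batch normalization
   before every ReLU and zero padding throughout. UNET++ is the nested
   topology whose node X^(i,j) receives the concatenation of X^(i,0..j−1)
   and the upsampled X^(i+1,j−1). Ghost-UNET++ replaces every node's
   convolution block with a ghost bottleneck (two stacked ghost modules,
   which generate part of their output channels with cheap depthwise
   convolutions), giving 15 bottlenecks at 5 levels and about a sixth of the
   UNET++ parameter count. The networks run on a small self-contained numpy
   engine (`bcseg.ndnn`) with reverse-mode autodiff and an Adam optimizer,
   so the package has no deep-learning-framework dependency.
2. **The preprocessing chain**: Hounsfield-unit windowing (liver
   [−25, 125], abdomen [−219, 190], thigh [−198, 189]; skeletal muscle and
   spine bone marrow [−181, 216]), adaptive median filtering, and image-wise
   z-score normalization.
3. **A classical (non-learned) bone pipeline** for the thigh: cortical bone
   by thresholding at 400 HU plus small-object removal and hole filling;
   bone marrow as the filled cortical shell minus the shell; automated QC
   that expects exactly two marrow cavities. Adipose sub-depots are derived
   by exact mask arithmetic: RPAT = VAT ∩ raw-RPAT, IPAT = VAT \ RPAT, and
   likewise DSAT/SSAT from SAT, so the sub-depots always partition their
   parent depot.
4. **A phantom generator** producing seeded, CT-like liver/abdomen/thigh
   slices with paired ground-truth masks for every target, which makes the
   whole stack trainable and testable without access-restricted cohort data.

The training loss is the smoothed Dice complement

    DiceLoss(A, B) = 1 − (2|A∩B| + s) / (|A| + |B| + s),   s = 1,

optimized with Adam (learning rate 1e-4, batch size 2, at most 100 epochs
with early stopping), one binary model per target, evaluated with tenfold
cross-validation; a 10% test split is reserved only when more than 100
samples are available.

## Worked example

```python
from bcseg import (PhantomSpec, gen_thigh, dice_score,
                   ArchitectureCfg, build_model, count_trainable_parameters)
from bcseg.bonepipe import run_pipeline

# parameter budgets of the four architectures at the protocol widths
for name in ("resunet", "unetpp", "ghost_unet", "ghost_unetpp"):
    n = count_trainable_parameters(build_model(ArchitectureCfg(name), seed=0))
    print(f"{name:13s} {n:9,d} parameters ({n/1e6:.2f} M)")

# classical bone pipeline on a noise-free two-femur phantom
sample = gen_thigh(PhantomSpec(seed=7).noiseless())
cortical, marrow, qc = run_pipeline(sample.slice)
print("cortical Dice:", dice_score(cortical, sample.masks["cortical_bone"]))
print("marrow   Dice:", dice_score(marrow, sample.masks["bone_marrow"]))
print("marrow cavities found:", qc.marrow_cavities)
```

prints

```
resunet         808,241 parameters (0.81 M)
unetpp        2,293,505 parameters (2.29 M)
ghost_unet      286,773 parameters (0.29 M)
ghost_unetpp    346,953 parameters (0.35 M)
cortical Dice: 1.0
marrow   Dice: 1.0
marrow cavities found: 2
```

The parameter counts show the efficiency ordering that motivates the ghost
variants (Ghost-UNET++ needs ~15% of the UNET++ parameters at the same
widths), and the bone pipeline solves a noise-free phantom exactly, with the
QC finding one marrow cavity per femur.

Training runs the same way through the harness, e.g. a small Ghost-UNET++
on 60 thigh phantoms with an 80/20 split:

```python
from bcseg import PhantomSpec, gen_dataset, make_plan, train_model, evaluate, TrainConfig
from bcseg.harness import prepare_arrays

samples = gen_dataset(PhantomSpec(), n=60, seed=7)
arch = ArchitectureCfg("ghost_unetpp", widths=(8, 16, 32), input_size=(128, 128))
plan = make_plan(60, k=5, seed=7, target="thigh_sat", arch=arch)
X, Y = prepare_arrays(samples, plan)
model, hist = train_model(plan, 0, samples, TrainConfig(max_epochs=30, seed=7),
                          arrays=(X, Y))
print(sum(evaluate(model, X[plan.folds[0]], Y[plan.folds[0]])) / 12)
# 0.9858... — held-out mean Dice on the SAT target after <= 30 epochs
```

A `bcseg` command-line tool wraps the same functionality (`bcseg phantom`,
`bcseg preprocess`, `bcseg count-params`, `bcseg bone`, `bcseg depots`,
`bcseg train`, `bcseg cv`, `bcseg predict`); every command prints its
`--help`.

## Scope and method notes

See `docs/methods.md` for the model descriptions, parameter-budget
reconciliation, phantom design, numerical choices and known limitations.
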