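# wbcseg — leukocyte segmentation with adaptive retinex correction

`wbcseg` segments leukocytes (white blood cells) in stained blood-smear
micrographs. Such images suffer from uneven illumination, and leukocytes are
easily confused with the far more numerous pale cells around them. The
package implements a two-stage pipeline plus everything needed to validate
it without any external dataset:

1. **Adaptive retinex correction.** Classic multiscale retinex with colour
   restoration (MSRCR) enhances each channel as
   `stretch(c_i · MSR_i)` with the colour-recovery gain
   `c_i = α·log(β·S_i/Σ_i S_i)` (α = 46, β = 125). The adaptive variant
   works in HSV space and makes β local: the H and S planes are tiled into
   k×k blocks, each block's Michelson contrast
   `C_M = (I_max − I_min)/(I_max + I_min)` sets its gain
   `β = γ·exp(C_M)` (γ = 125), so high-contrast blocks (cells against
   background) are amplified while uniform blocks fall back exactly to the
   classic constant-β recovery. V receives retinex illumination removal
   only. The result: evenly bright backgrounds and sharper
   leukocyte/distractor colour separation.
2. **Encoder-decoder segmentation.** A U-shaped network (five-level
   VGG-style encoder, upsample-and-concatenate decoder, per-pixel softmax
   classifier) implemented in pure NumPy with explicit backpropagation —
   no deep-learning framework required — with a freeze/thaw training
   schedule, per-pixel cross-entropy (optional soft-Dice term) and Adam.
3. **Evaluation and counting.** Dice, mean IoU, mean pixel accuracy,
   accuracy-at-IoU>0.8, and leukocyte counting by connected components.
4. **Synthetic smear generator.** Seeded, exactly-annotated blood-smear-like
   images (uneven illumination, pale distractor cells, darker saturated
   leukocytes) so the whole pipeline is testable at desk scale.

Intended users: image-analysis researchers and students who want a
self-contained, fully reproducible reference implementation of
contrast-adaptive retinex preprocessing for microscopy segmentation.

## Worked example

Run the full pipeline on synthetic smears (simulate → correct → train →
predict → evaluate → count):

```sh
wbcseg run --seed 1 --n 24 --epochs 20 --out runs/demo
```

which takes under a minute on one CPU and prints the metric report for the
held-out half of the images:

```json
{
 "dice": 0.9787343257314659,
 "miou": 0.977594695406186,
 "mpa": 0.9926933864610286,
 "accuracy": 1.0,
 "iou_threshold": 0.8
}
```

Here `dice` is the overlap `2|X∩Y|/(|X|+|Y|)` between predicted and true
leukocyte pixels over the test images, `miou` averages intersection-over-
union over the background and leukocyte classes, `mpa` is the mean of the
per-class recalls, and `accuracy` is the fraction of test images whose
leukocyte IoU exceeds 0.8. `runs/demo/` contains the corrected images,
predicted masks, per-epoch loss curve (`loss_curve.csv`), per-image counts
(`counts.json`) and the resolved configuration (`run_config.json`).

Each stage is also available standalone:

```sh
wbcseg simulate --n 8 --seed 3 --out data/            # images + masks + manifest
wbcseg correct --input data/smear_0000.png --output corr.png --k 32 --gamma 125
wbcseg train --data data/ --out model.npz --seed 0
wbcseg predict --model model.npz --input corr.png --out pred.png
wbcseg evaluate --pred preds/ --truth truths/ --out report.json
wbcseg count --mask pred.png --connectivity 8 --out annotated.png
```

or from Python:

```python
import wbcseg as w

img, mask, meta = w.generate_smear(w.SmearConfig(seed=7))
corrected = w.adaptive_retinex_correct(img)          # byte-domain RGB image
labeling = w.count_components(mask)                  # labeling.count == 3
```

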