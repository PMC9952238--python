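# cine2tag

Tools for simulating tagged cardiac MR images from annotated cine images, and
for training and evaluating myocardium segmentation on the result.

Tagged CMR imprints a grid of dark *tag lines* on the myocardium whose
deformation over the cardiac cycle encodes regional muscle motion — but
expert-annotated tagged images are scarce, while annotated bSSFP *cine*
datasets (ACDC, M&Ms, SCD, ...) are plentiful. `cine2tag` bridges the gap
with a physics-driven appearance transformation: it converts a cine image's
contrast toward a gradient-echo look (element-wise square root after min-max
normalisation) and multiplies in a tag-grid modulation obtained by Bloch
simulation of a 1-3-3-1 binomially weighted SPAMM preparation (default:
5-pixel tag spacing, 70° total flip, 45° grid rotation). Because the
transformation changes appearance but not anatomy, the cine segmentation mask
transfers to the tagged-appearing output unchanged — yielding labelled
pseudo-tagged training data for free.

The package also provides, as plain evaluable functions:

- the **boundary-aware shape loss**.  With φ(m) the signed normalized
  Euclidean distance map of a binary mask m (positive inside, scaled to
  [−1, 1]) and H(x) = 1/(1+e^(−x/k)) a softened step, the shape information
  map is SI(m) = H(1−φ(m)) where φ(m) ≥ 0 and 0 elsewhere, and

      L_S(g, p) = (1/C) Σ_c (1/Σ_i g_ci) Σ_{i∈Ω} | p_ci − SI(g_c)_i |

  The combined segmentation loss is
  L = (1 − softDice(g, p)) + CE(g, p) + γ·L_S(g, p), defaults k = 0.2,
  γ = 0.05;
- the **evaluation metrics**: Dice coefficient 2|G∩P|/(|G|+|P|) and the
  symmetric 95th-percentile Hausdorff distance between mask contours in
  millimetres;
- a deterministic **augmentation stack** (flips, noise, blur, affine,
  elastic) plus the 256×256 / (x−0.456)/0.224 input preprocessing;
- a **synthetic short-axis phantom** (bright blood pool, mid-intensity
  myocardial annulus, dark background, 25-frame contraction cycle) so every
  component runs and is testable without clinical data.

## Worked example

```python
import numpy as np
import cine2tag as c2t

# 1. synthesise one end-diastolic short-axis cine frame
cfg = c2t.PhantomConfig(image_size=256, n_frames=25, seed=0)
cine, mask = c2t.generate_phantom_frame(cfg, frame_index=0)

# 2. transform it into its tagged-appearing counterpart
tagged, tagged_mask = c2t.transform_cine_to_tagged(cine, mask)
print("tag-line period (px):", round(c2t.measure_tag_period(tagged), 2))
print("mask transferred unchanged:", np.array_equal(tagged_mask.data, mask.data))

# 3. score an imperfect prediction against the ground truth
pred = np.roll(mask.channel(0), 2, axis=1)       # 2-px misregistration
print("DSC :", round(c2t.dice_coefficient(mask.channel(0), pred), 3))
print("HD95:", round(c2t.hausdorff95(mask.channel(0), pred, spacing_mm=(1.0, 1.0)), 3), "mm")

# 4. evaluate the boundary-aware training loss for the same pair
p_soft = 0.98 * pred + 0.01                      # sigmoid-like confidence map
loss_cfg = c2t.LossConfig(k=0.2, gamma=0.05)
print("L_S :", round(c2t.shape_loss(mask.channel(0), p_soft, k=0.2), 4))
print("L   :", round(c2t.combined_loss(mask.channel(0), p_soft, loss_cfg), 4))
```

prints

```
tag-line period (px): 5.0
mask transferred unchanged: True
DSC : 0.929
HD95: 2.0 mm
L_S : 0.2796
L   : 1478.0882
```

The measured tag spacing equals the configured 5 px; a 2-pixel shift of the
annulus costs about 7 Dice points and shows up as a 2 mm boundary error.
L_S is the per-foreground-pixel deviation from the boundary-peaked shape
target; the combined loss is dominated by the cross-entropy term, which by
definition sums (not averages) over pixels, so misplacing a few hundred
foreground pixels at low confidence is expensive.

## Command line

```
cine2tag phantom   --out data/cine --n-subjects 2 --frames 25 --seed 0
cine2tag transform --in data/cine --out data/tagged            # physics transform + mask transfer
cine2tag eval      --pred preds/ --gt gts/ --pixel-mm 1.0 --out report.csv
cine2tag loss      --gt gt.png --pred pred.png --gamma 0.05 --k 0.2
cine2tag augment-preview --in data/cine --out preview/ --seed 1
```

`transform` reads ACDC-style NIfTI (image + `_gt` label companion;
`--format nifti-acdc --myo-label 2`) or flat PNG pairs (`<id>.png` +
`<id>_mask.png`) and writes tagged PNGs, untouched masks and a CSV manifest.

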