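# renalseg

Automatic whole-kidney and renal-compartment (medulla/cortex) segmentation
for 4D dynamic contrast-enhanced MRI (DCE-MRI), with a synthetic phantom
generator that makes the whole pipeline buildable and testable without
clinical data.

## Who this is for

DCE-MRI acquires a 3D abdominal volume every few seconds after a
gadolinium-based contrast injection, producing a 4D series `V = {V_1 … V_T}`
with `V_t ∈ R^(H×W×D)`. The signal change over time tracks contrast transit
through the kidney, from which clinically important markers — per-kidney
glomerular filtration rate (GFR), cortical and medullary time–intensity
curves — can be computed. All of them require segmenting the kidney
parenchyma first, and manual delineation of 4D paediatric scans is slow and
observer-dependent. `renalseg` automates the chain for researchers working
with such data:

1. **Localisation** — a 3D residual U-Net (encoder of 4 blocks, bottleneck,
   decoder of 5 blocks; additive identity shortcuts per block) classifies
   each voxel of a 64³, 5-channel reduced volume as background / right /
   left kidney and derives a minimum 3D bounding box per kidney. An absent
   kidney is encoded as a single-voxel box.
2. **Whole-kidney segmentation** — a 3D fully convolutional DenseNet
   (six dense blocks of 4/5/7/10/12/15 layers down, five of 12/10/7/5/4 up,
   growth rate 12) predicts kidney vs non-kidney inside each cropped box.
3. **Compartment segmentation** — a rule-based contrast-maximisation
   cascade run per coronal slice and per time point: intensity shift
   `s ← s − a_min` on central slices, gamma correction
   `G(s) = (s/255)^γ · 255` on peripheral slices, sigmoidal enhancement
   `E(s) = 1 / (1 + exp(δ(μ − s)))`, Otsu thresholding (maximising the
   between-class variance `σ_b²(τ)`), and label fusion over time around a
   reference frame `t_x = x·T`, with cortex refinement at the kidney rim.
4. **Evaluation and curves** — Dice similarity `DSC = 2|G∩S|/(|G|+|S|)`,
   precision `|S∩G|/|S|`, recall `|S∩G|/|G|`, cohort summaries, and
   relative-enhancement time–intensity curves `(I_t − I_0)/I_0` per side
   and compartment.

Both networks train with a class-weighted cross-entropy

```
L = −(1/N) Σ_i w_i [ ŷ_i log p_i + (1 − ŷ_i) log(1 − p_i) ]
```

summed over voxels and output channels, with `w_i` inversely proportional
to the voxel prior of the true class (background weight 1), compensating
the extreme background/kidney imbalance. The networks run on a compact
numpy tensor engine bundled with the package (`renalseg.nn`): reverse-mode
autodiff with 3D convolutions realised as shifted GEMMs, batch
normalisation, dropout, max-pooling and Adam — single-CPU, deterministic
under a fixed seed.

Because clinical 4D data cannot ship with a library, `renalseg.phantom`
generates seeded 4D phantoms with exact ground truth: ellipsoidal kidneys
with a bright cortical shell and darker medullary lobes, cortex enhancing
earlier than medulla, optional noise, streak/blur artefacts, and abnormal
variants (missing kidney, dilated collecting system).

## Worked example

Rule-based compartment segmentation of a noisy phantom with known masks:

```python
from renalseg.phantom import PhantomConfig, generate
from renalseg.compartments import CompartmentParams, segment_compartments
from renalseg.metrics import score_labels

truth = generate(PhantomConfig(shape=(16, 64, 64), T=12, noise_sigma=4.0, seed=42))
pred = segment_compartments(truth.series, [truth.left_mask, truth.right_mask],
                            CompartmentParams())
for name, s in score_labels(truth.labels.data, pred.data).items():
    print(f"{name:8s} DSC={s['dsc']:.3f}  PC={s['pc']:.3f}  RC={s['rc']:.3f}")
```

prints

```
medulla  DSC=0.821  PC=0.703  RC=0.987
cortex   DSC=0.952  PC=0.997  RC=0.912
kidney   DSC=1.000  PC=1.000  RC=1.000
```

The whole kidney is recovered exactly (the masks were supplied); under
additive noise the cortex stays near-perfect while the medulla — the
harder compartment, whose thin lobes border cortex everywhere — degrades
first, the same ordering reported for clinical cohorts (on a noise-free
phantom both compartments are recovered exactly). Extracting curves from
the predicted labels of the same phantom places the cortical peak at
t = 50 s against a configured time-to-peak of 40 s (within one 25 s
frame), with the medullary peak following at 75 s.

The command-line interface mirrors the pipeline:
`renalseg phantom`, `renalseg train-localizer`, `renalseg train-segmenter`,
`renalseg localize`, `renalseg segment-kidney`,
`renalseg segment-compartments`, `renalseg curves`, `renalseg evaluate`,
and `renalseg run` for the full YAML-configured pipeline.

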