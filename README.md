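# pvscade

Cascaded deep-learning assessment of **enlarged perivascular spaces (ePVS)**
in the basal ganglia on T2-weighted MRI: a learned image-enhancement stage
that selectively brightens ePVS, followed by a count-regression stage, with
the full evaluation protocol (CNR, Potter grading, subject-level
aggregation, MAE, accuracy, ICC, subject-level 4-fold cross-validation) and
a seeded synthetic phantom cohort so the entire pipeline is trainable and
testable without patient data.

## Who this is for

Neuroimaging researchers quantifying small-vessel-disease burden. ePVS
appear on T2 as small CSF-bright puncta in the basal ganglia; clinical
practice grades their burden per hemisphere and slice on Potter's five-point
scale (0: none; 1: 1–10; 2: 11–20; 3: 21–40; 4: >40), taking a subject's
grade as the maximum over six parts (3 axial slices × 2 hemispheres).
Manual counting is slow and confounded by similar-looking bright structures
(vessels, lacunes), which motivates the two-stage design.

## The method

**Stage 1 — enhancement.** A U-Net (two 3×3 conv + batch-norm + ReLU blocks
per level, max-pooling down, transpose-conv up, skip concatenations) is
trained as an image *regressor* with MSE loss. Its target for a normalized
part image `x ∈ [0,1]^{80×96}` with binary ePVS mask `M` is

    t = minmax(x + M)

so every ePVS pixel sits at the top of the intensity range while the rest of
the anatomy keeps its relative contrast. Enhancement quality is measured by
the contrast-to-noise ratio

    CNR = |μ_signal − μ_surround| / σ_background

with the surround a 3-px ring around the mask and σ estimated in a frame at
the part border.

**Stage 2 — quantification.** A five-layer CNN (64, 64, 128, 128, 256
filters at full width; batch norm + ReLU; global average pooling; one linear
unit) regresses the *enhanced* image onto the normalized count `y = c / 48`
with MAE loss; predictions are clipped to [0,1] and mapped back to counts by
multiplying by 48, then graded on Potter's scale.

Training follows Adam (lr 1e-4), batch 45, 500/300 epochs, with x/y flips,
scaling 0.9–1.1 and rotation ±15° (the `paper` preset); `desk` and `mini`
presets scale the networks and schedules to a single CPU. Evaluation is
subject-level 4-fold cross-validation: all six parts of a subject share a
fold, the enhancer and the quantifier for fold *k* are trained only on fold
*k*'s training subjects, and pooled test predictions feed MAE, image/subject
grade accuracy and ICC(2,1) with a 95% CI.

## Worked example

```sh
pvscade simulate --n-subjects 8 --seed 1 --desk-scale --out cohort/
pvscade run-cv --method dl   --manifest cohort/manifest.csv \
               --preset mini --seed 1 --size 40x48 --out cv-dl/
pvscade run-cv --method none --manifest cohort/manifest.csv \
               --preset mini --seed 1 --size 40x48 --out cv-none/
```

The same experiment through the library (12 subjects, as one seeded study):

```python
>>> from pvscade import evaluate
>>> study = evaluate.run_cascade_study(n_subjects=12, seed=1)
>>> {k: round(v, 2) for k, v in study["mean_cnr"].items()}
{'none': 1.35, 'dl': 4.33, 'tophat': 2.27, 'clahe': 2.17, 'laplacian': 3.25}
>>> round(study["pooled_mae"]["dl"], 2), round(study["pooled_mae"]["none"], 2)
(2.76, 3.62)
>>> round(study["predict_mean_mae"], 2)
7.75
```

Reading: the learned enhancer raises the mean CNR of held-out parts well
above the raw images and the three algorithmic baselines (white top-hat,
CLAHE, Laplacian sharpening), and counting from the enhanced images lowers the
cross-validated mean absolute count error relative to counting from raw
images (2.76 vs 3.62 counts; predicting the training mean gives 7.75) — the cascade benefit, at CPU scale, on synthetic data whose
difficulty regime (dim puncta among brighter vessel-like confounders)
mirrors the clinical one.

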