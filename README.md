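# deftrus — deformation-aware unpaired MR → TRUS image translation

In low-dose-rate prostate brachytherapy, treatment planning happens on
transrectal ultrasound (TRUS), but lesions are delineated on MRI: the two
modalities differ both in intensity response (high-contrast MR vs. noisy,
low-contrast, speckled ultrasound) and in geometry, because the endorectal
probe deforms the anatomy. `deftrus` synthesizes TRUS-like images from MR
input so that transferring MR contours to intra-operative TRUS reduces to a
rigid registration — no manual intra-operative contouring.

The package is aimed at medical-image-analysis researchers who want a fully
tested, dependency-light reference implementation of this translation recipe,
exercised end-to-end on a built-in synthetic pelvic phantom (no clinical data
required). The networks run on a compact NumPy reverse-mode autodiff engine
included in the package (`deftrus.nn`).

## Method

Two resnet generators translate in opposite directions, G: MR→TRUS and
H: TRUS→MR, trained unpaired with per-direction patch discriminators.
Instead of cycle consistency (which penalizes the legitimate probe-induced
deformation), consistency comes from a patch-contrastive (NCE) loss over
encoder features

&nbsp;&nbsp;&nbsp;&nbsp;L<sub>NCE</sub> = −log [ e^{sim(v,v⁺)} / (e^{sim(v,v⁺)} + Σₙ e^{sim(v,vₙ⁻)}) ],&nbsp;&nbsp; sim = cosine,

where v/v⁺ are features of the translated and input image at the same
location and the negatives come from other locations. Anatomical structure
is enforced only where it matters, inside an image-independent ROI mask c₀
(the average of pre-annotated organ contours, elastically re-perturbed every
iteration on a 3×3 grid with σ = 20): masked edge maps (Canny at threshold
300, or Sobel) of the prostate (from the MR input) and the rectum (from real
TRUS) feed two small edge discriminators D_P and D_R. Intensity-aware
normalization re-standardizes the source bottleneck features to the target
domain's per-channel statistics, Norm(x) = σ(y)·(x−μ(x))/σ(x) + μ(y). The
generator totals are

&nbsp;&nbsp;&nbsp;&nbsp;L_H = λ₁L_adv + λ₂L_NCE + λ₃L_idt,&nbsp;&nbsp;&nbsp;
L_G = λ₄L_adv + λ₅L_NCE + λ₆L_idt + λ₇(L_p + L_r),

with λ₁=0.5, λ₂=λ₃=0.25, λ₄=0.5, λ₅=λ₆=0.25, λ₇=0.01, plus a patchwise
moment-matching style term. Evaluation covers PSNR, SSIM (global and
ROI-restricted), NCC, a Fréchet distance over a pluggable embedding, and
registration transfer: rigid-align synthetic→real TRUS, move the MR prostate
contour, score Dice overlap (DSC) and centroid target registration error
(TRE).

## Worked example

```python
from deftrus import PhantomSpec, make_cohort, MRToTRUSTranslator, evaluate_cohort

cohort = make_cohort("cohort", n_train_mr=4, n_train_trus=4, n_paired_eval=3,
                     seed=1, base_spec=PhantomSpec.for_size(64, n_slices=2))
est = MRToTRUSTranslator(iterations=200, batch_size=2, n_res=4,
                         base_channels=8, seed=1).fit(cohort)
report = evaluate_cohort(est, cohort)
print({k: round(v, 3) for k, v in report.summary.items()
       if not k.endswith("_sd")})
```

On this desk-scale smoke run the report prints (seed 1):

```
{'psnr': 25.827, 'ssim': 0.588, 'ncc': 0.956, 'fid': 0.0,
 'dsc': 99.19, 'tre_mm': 0.158, ...}
```

PSNR ≈ 25.8 dB and NCC ≈ 0.96 say the synthetic TRUS matches the paired
ground-truth rendering closely in intensity; DSC ≈ 99% and TRE ≈ 0.16 mm say
the rigid registration transfer recovers the prostate contour almost exactly
on this low-variance phantom cohort (clinical images are far harder; these
numbers characterize the pipeline, not clinical performance). Masked-ROI
PSNR of the translation exceeds the raw-MR identity baseline by ≈ 10 dB.

The same pipeline is scriptable from the shell:

```bash
deftrus phantom --out cohort --seed 1 --image-size 64
deftrus train --data cohort --out run --seed 1 --iterations 200
deftrus translate --ckpt run/checkpoint.npz --in cohort/eval_mr_008.nii.gz --out fake.nii.gz
deftrus evaluate --ckpt run/checkpoint.npz --data cohort --out report
deftrus ablate --data cohort --variant "w/o NCE"
```

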