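# sute-ac

Segmented-UTE attenuation correction for simultaneous PET/MR brain imaging.

## The problem

Quantitative PET reconstruction needs a map of 511 keV linear attenuation
coefficients μ (cm⁻¹), but MR gives no direct handle on electron density:
with conventional sequences, cortical bone and air are both dark, and
misclassifying the skull biases reconstructed brain activity by several
percent. Ultrashort-echo-time (UTE) imaging captures bone signal at
TE₁ ≈ 0.07 ms before T2\* decay destroys it, while at TE₂ ≈ 2.46 ms bone has
decayed away — this dual-echo contrast lets bone, soft tissue and air be
separated from MR alone.

`sute-ac` implements a template-guided segmentation approach to this
problem, end to end:

1. **Template/TPM construction** — the UTE₁ template is the voxel-wise mean
   of aligned first-echo images; per-class masks are averaged into tissue
   probability maps (TPMs) over {air, soft, bone, GM, WM, CSF}, with air and
   bone protected during the unit-sum renormalization.
2. **Segmentation** — a Gaussian mixture model fit by EM on the first-echo
   intensities with the TPMs as voxel-wise priors:
   `p(k|x) ∝ TPM_k(x) · Σ_j w_kj N(I(x); μ_kj, σ²_kj)`.
   Hard labels: air posterior > 0.1 → air, bone posterior > 0.2 → bone,
   remainder soft.
3. **R2\* mapping** — `R2* = (ln I₁ − ln I₂)/(TE₂ − TE₁)` in 1/ms.
4. **AC map assembly** — air 0, soft 0.100 cm⁻¹; bone either a fixed
   0.151 cm⁻¹ (*sUTE-fix*) or a monotone cubic calibration of R2\*
   (*sUTE-cont*); an optional six-class variant (*mcAC*) assigns GM/WM/CSF
   0.099/0.099/0.096 cm⁻¹. Maps are smoothed with a 2-mm FWHM Gaussian.
   CT volumes convert via a bilinear HU model; classification rules for CT
   (−500/300 HU) and vendor UTE maps (μ = 0.151 / 0 exactly) support the
   comparisons.
5. **PET simulation** — a desk-scale 2-D parallel-beam simulator (Joseph
   ray-driven sparse projector, Poisson emission, per-LOR attenuation
   factors `exp(−∫μ dl)`) and an OSEM reconstructor (default 3 iterations,
   21 subsets, 5-mm post-filter) propagate AC-map errors into PET bias.
6. **Evaluation** — per-tissue Dice/FP/FN, Diff/AbsDiff between μ-maps,
   voxel-wise relative error `R = 100·(PET_ref − PET_x)/PET_ref` with
   regional summaries, 150-bin SVD representative histograms, and
   Mann-Whitney U tests (exact for small samples).

Because no suitable public dataset pairs dual-echo UTE with ground-truth
tissue labels, the package ships a first-class synthetic phantom module: a
digital head (scalp, closed skull shell, GM/WM/CSF brain, air sinuses) with
simulated echoes `I = PD·exp(−TE·R2*)`, Rician noise, an FDG-like activity
map and a region atlas, so every stage is testable against known truth.

## Worked example

```sh
sute-ac run-all --seed 17 --out runs/demo
```

runs the full workflow on the synthetic cohort — five jittered phantoms
build the template and TPMs, a held-out phantom is segmented and
reconstructed with each candidate AC map — and prints

```
report written to runs/demo; full-brain RE% (sUTE-fix vs ref) = -0.02
```

Key numbers from `runs/demo/report.json` (seed 17, fast profile):

| quantity | value | meaning |
|---|---|---|
| `segmentation.bone.dice` | 1.00 | skull recovered voxel-exact on this phantom |
| `pet.nobone.re_pct_x_minus_ref` | −4.94 | ignoring bone underestimates brain activity by ~5% |
| `pet.sutefix.re_pct_x_minus_ref` | −0.02 | the sUTE-fix map is essentially unbiased |
| `pet.sutecont.re_pct_x_minus_ref` | −2.49 | noise-floored R2\* underestimates bone μ |
| `mcac.periventricular_reduction_pct` | +2.12 | lower CSF/brain μ reduces periventricular activity ~2% |

The signs follow the tabulated convention `100·(PET_x − PET_ref)/PET_ref`
for per-method bias; the mcAC effect is reported as a positive *reduction*
(`100·(PET_ref − PET_x)/PET_ref`). Each stage is also available as a library
call (`sute_ac.fit_gmm_with_priors`, `sute_ac.make_ac_map`,
`sute_ac.reconstruct`, ...) and as individual CLI subcommands
(`phantom`, `segment`, `r2star`, `make-acmap`, `simulate-pet`, `evaluate`).

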