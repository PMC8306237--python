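# ivimhsi

Unsupervised breast-tumor detection and quantification on multi-b-value
intravoxel-incoherent-motion (IVIM) diffusion MRI, treating the b-value
stack as a hyperspectral image cube.

## The problem and the approach

A diffusion-weighted acquisition with B diffusion weightings yields one
image per b-value. Stacking them gives an H×W×B cube in which every pixel
is a spectral vector — formally identical to a hyperspectral remote-sensing
scene, so hyperspectral subpixel target detection applies directly. The
package implements four unsupervised detectors over that cube and then
quantifies the detected lesion with the IVIM bi-exponential model.

**Signal model.** For a voxel with perfusion fraction PF, diffusion
coefficient D and pseudo-diffusion coefficient D\*:

```
S_b / S_0 = (1 − PF)·exp(−b·D) + PF·exp(−b·D*)
```

The apparent diffusion coefficient (ADC) is the mono-exponential rate
`ln(S_b/S_0) = −b·ADC`; it equals D when PF = 0.

**Detection.**

* *Band expansion (BEP)*: the B bands are augmented with their elementwise
  squares and pairwise products, (B² + 3B)/2 bands in total (13 → 104),
  exposing second-order band statistics.
* *CEM* (constrained energy minimization): the linear filter
  `w = R⁻¹d / (dᵀR⁻¹d)` with unit response to a target signature d and
  minimum average output energy over the image; R is the sample
  autocorrelation matrix. The target signature is found unsupervised:
  ATGP (successive orthogonal projections) proposes candidate pixels, the
  candidate brightest at high b is taken as the tumor seed, and spectra
  within a spectral-angle (SAM) threshold of the seed are averaged.
* *I-CEM* iterates CEM: each round resamples 10% of the detected pixels
  into the training pool and re-runs the filter until the binary map
  changes by ≤ 1% of the breast pixels.
* *K-CEM* runs the same constrained filter in a Gaussian-RBF feature
  space via the kernel trick.
* *K-means / fuzzy C-means* cluster the pixel spectra (k = 3 by default);
  ATGP identifies the cluster holding the tumor.

Every score map is binarized with Otsu's threshold. Masks are scored
against ground truth with Dice, Jaccard and confusion-matrix rates, and
the lesion ROI is quantified with ADC, linear signal-decay slope, D, D\*
and PF.

Because clinical breast DWI is not redistributable, the package ships a
phantom simulator (`ivimhsi.phantom`) producing single-slice cubes with
known lesion masks and parameters: per-class bi-exponential decay, Rician
noise, a smooth multiplicative bias field and per-band translations, so
every stage is testable end to end against known truth.

## Worked example

```python
import ivimhsi as hs
from ivimhsi import phantom as ph

spec = hs.PhantomSpec(noise_sigma=2.0, bias_amplitude=0.3,
                      shifts=ph.default_shifts(13, max_shift=3, seed=5), seed=0)
res = hs.run_pipeline(hs.RunConfig(method="all", phantom_spec=spec, seed=1))
for m, rep in res.evaluation.items():
    print(m, round(rep["dice"], 3))
print(res.params.to_string(index=False))
```

prints

```
icem 0.991
kcem 0.991
kmeans 1.0
fcm 0.991
Method      ADC  SignalDecaySlope    Dstar        D       PF
  icem 0.000995         -0.000376 0.006474 0.000878 0.192854
  kcem 0.000967         -0.000369 0.006418 0.000827 0.231788
kmeans 0.000980         -0.000373 0.006143 0.000844 0.218558
   fcm 0.000984         -0.000373 0.006106 0.000848 0.218819
```

All four detectors recover the simulated 109-pixel mass lesion (Dice ≥
0.99) after bias correction and registration, and the fitted parameters
sit near the simulator's mass preset (D = 0.84×10⁻³ mm²/s, D\* =
6.10×10⁻³ mm²/s, PF = 23%). The `examples/` directory holds one short
script per capability (simulation, CEM detection, clustering detection,
quantification/evaluation).

A thin CLI wraps the same pipeline:

```
ivimhsi simulate --seed 0 -o sim/
ivimhsi detect --method icem --cube sim/cube.nii.gz --bvals sim/bvals.txt \
               --truth sim/truth_mask.nii.gz --seed 1 -o det/
ivimhsi quantify --cube sim/cube.nii.gz --bvals sim/bvals.txt --mask det/mask_icem.nii.gz
ivimhsi evaluate --pred det/mask_icem.nii.gz --truth sim/truth_mask.nii.gz
```

Cubes and masks travel as NIfTI with a plain-text b-value side-car;
reports as CSV/JSON.

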