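# Methods

This note documents the models, the simulator, the numerical choices and
the known limitations of `ivimhsi`, in the spirit of the methods sections
of the mature simulation/analysis packages it resembles.

## 1. Signal model and quantification

A voxel's normalized diffusion signal follows the bi-exponential IVIM
model

S_b/S_0 = (1 − PF)·exp(−b·D) + PF·exp(−b·D\*),

with D the pure water-diffusion coefficient (mm²/s), D\* the
pseudo-diffusion coefficient of capillary microcirculation (mm²/s,
several-fold larger than D in tissue) and PF ∈ [0, 1] the perfusion
fraction. Five quantities are reported per lesion ROI:

* **ADC** — the through-origin log-linear rate: minimize
  Σ(ln y_i + b_i·ADC)², i.e. ADC = −Σb_i·ln y_i / Σb_i². The model has no
  intercept, so none is fitted. ADC = D when PF = 0 and ADC > D whenever
  PF > 0 (the perfusion term steepens the early decay).
* **Signal decay slope** — the ordinary least-squares slope of the
  *linear-domain* normalized signal against b. A log-domain slope would
  simply re-derive −ADC; the linear-domain definition is the one whose
  magnitudes (~−1.6×10⁻⁴ … −4×10⁻⁴ per s/mm² over b ∈ [0, 2500]) match
  how this quantity is conventionally tabulated. This is an
  interpretation — the quantity has no universal definition — and is
  flagged as such.
* **D, D\*, PF** — segmented fit: (i) OLS of ln y on b over b ≥ b_split
  (default 200 s/mm², the first weighting beyond the perfusion-dominated
  regime of the 13-value protocol) gives D from the slope and
  PF = 1 − exp(intercept); (ii) bounded nonlinear least squares
  (`scipy.optimize.least_squares`, trf, tolerances 1e−14) over
  (D, D\*, PF) on the full curve, initialized from stage (i) with
  D\* = 10·D, bounds D ∈ [0, 5×10⁻³], D\* ∈ [0, 0.5], PF ∈ [0, 1]. If the
  refinement fails to converge the stage-(i) estimate is returned with a
  flag.

Fitting operates on the **ROI-mean decay curve** (mean intensity over the
mask per band, normalized by the b = 0 mean). Per-pixel fitting of noisy
13-point curves is substantially less stable and is deliberately not the
default. Noise-free round trips recover all four lesion presets to
≤ 1e−4 relative error (machine precision in practice); at 2% Rician noise
the 200-replicate Monte-Carlo in the test suite keeps median relative
errors near 1% for D and 2% for PF. D\* is the ill-conditioned parameter
of this model; its tolerance is accordingly loose (40% in the tests).

## 2. Detection

**Band expansion.** B bands are extended with the B elementwise squares
and B(B−1)/2 pairwise products — (B² + 3B)/2 bands, 104 for B = 13 —
ordered originals, autos, crosses in lexicographic (i, j). Inputs are
cast to float64 before multiplication so integer inputs cannot overflow.
A per-band min-max rescale to [0, 1] is available
(`expand_bands(..., normalize=True)`) but **off by default**: CEM is
exactly invariant to per-band scaling (substituting x → Sx, d → Sd leaves
y = wᵀx unchanged for any invertible diagonal S), so the products' larger
dynamic range is harmless, while the rescale's offset subtraction
distorts spectral angles and its equal weighting of noise-dominated
product bands measurably degrades detection (on the study phantom,
end-to-end I-CEM Dice drops from ≈1.0 to ≈0.55 with normalization on).

**Target seeding.** ATGP: the first target is the max-norm pixel; each
next target maximizes the residual norm after projecting out the span of
the targets found so far (Gram–Schmidt with re-orthogonalization; ties
break to the lowest flat index; the process stops early if the residuals
hit numerical rank). Among the default 5 candidates, the tumor seed is
the one with the highest mean intensity over the high-b half of the
original bands — tumors remain hyperintense at high b because their
diffusion is restricted. The training signature is the mean of all
breast pixels within 0.10 rad (SAM) of the seed; on this phantom family
that pool is essentially the lesion class.

**CEM.** w = R⁻¹d/(dᵀR⁻¹d) with R = XᵀX/N + ridge·I,
ridge = 1e−6·tr(R)/L by default (numerical stabilization only). The
unity constraint wᵀd = 1 is asserted at run time. CEM is sharp but
brittle: if d sits off the class centroid, the filter treats the class's
own variability as clutter to suppress — which motivates both the pooled
seed and the iterative variant.

**I-CEM.** Iterate: filter → Otsu binarize → draw ⌈10%⌉ of the positive
pixels (seeded RNG) → update the signature → repeat, stopping when the
fraction of breast pixels whose label changed is ≤ 1% (or after 50
iterations). The sampled spectra **join a cumulative training pool**
whose mean is the next signature. The alternative reading — the fresh
sample alone replaces the signature — is available
(`cumulative=False`) but documented as unstable for small lesions: a
~10-spectrum average is too noisy a target for CEM, and the loop
random-walks. The difference rate always uses the breast-pixel count as
denominator, so rates are comparable across iterations.

**K-CEM.** CEM in a kernel feature space. With a seeded pixel subsample
S (|S| = min(N, 1000)), Gram matrix K over S and k_v = [k(s, v)]_{s∈S},
the regularized feature-space filter response is computed through the
Woodbury identity:

y(r) = [k(d,r) − k_dᵀ(K/M + εI)⁻¹k_r/M] / [k(d,d) − k_dᵀ(K/M + εI)⁻¹k_d/M].

This form satisfies y(d) = 1 exactly for any ε and reduces **exactly** to
linear CEM (same ridge) for the linear kernel — the equivalence is a
test oracle. The RBF width σ defaults to the median pairwise distance of
the subsample; ε defaults to 1% of the mean kernel diagonal, a genuinely
regularizing value: the feature-space autocorrelation is near-singular,
and at the 1e−6-style stabilization ridge the filter nulls the target
class's own variability (Dice 0.31 vs 0.99 on the study phantom). In the
σ → ∞ limit the map converges, but to the affine-kernel map, not the
pure linear one (the constant and norm terms of the expansion do not
vanish); the small-σ limit localizes the response to the target itself.

**Clustering.** K-means is Lloyd's algorithm from a seeded k-means++
initialization; the per-iteration within-cluster sum of squares is
recorded (non-increasing by construction) — a hand loop rather than
`sklearn.KMeans` only because the objective trace is part of the result
contract; sklearn is the cross-check in the tests. FCM uses the standard
Bezdek updates with fuzziness m = 2, stopping when the largest membership
change is below 1e−5; a pixel exactly on a centroid takes crisp
membership there. k = c = 3 by default (lesion, parenchyma, dark rim).
Cluster labels are arbitrary, so the tumor cluster is identified by
ATGP: the cluster containing the most target-like pixel. For FCM the
final mask is the Otsu-binarized membership map of that cluster (the
grayscale-to-binary step); for K-means the hard cluster is already
binary. An Otsu split of the *within-cluster* intensities was considered
and rejected: when the cluster already coincides with the lesion it
bisects a near-constant set and halves the mask.

**Binarization.** `skimage.filters.threshold_otsu` over a 256-bin
histogram; the mask is {score > threshold}. The tests verify it against
an exhaustive between-class-variance search; the comparison is on the
achieved objective because the empty inter-mode valley typically yields
a plateau of maximizers equal to the last floating-point bit.

## 3. Preprocessing stand-ins

The clinical chain (N3 non-uniformity correction, commercial rigid
registration, manual breast cropping) is replaced by documented
phantom-grade stand-ins, applied in the fixed order bias → registration →
breast extraction:

* **Bias correction**: a 2-D polynomial (order 2 by default) is fit to
  the log of the b = 0 band over Otsu foreground, with one robust re-fit
  that drops pixels deviating by > 2.5 robust standard deviations (this
  keeps lesion contrast out of the field estimate); all bands are divided
  by the exponentiated fit normalized to mean 1 over the foreground. The
  overall gain is unidentifiable and irrelevant downstream. This is not
  N3 (no B-spline field, no histogram sharpening) and is sufficient only
  for smooth low-order non-uniformity like the simulator's.
* **Registration**: exhaustive integer-translation search
  (±5 px default) maximizing normalized cross-correlation of each band's
  overlap interior with the b = 0 reference; the maximizing shift is
  applied inversely. Sub-pixel and rotational motion are out of scope.
* **Breast extraction**: Otsu foreground on the b = 0 band → largest
  connected component → hole filling → 1-px erosion (strips the rim).

## 4. The phantom: what it emulates, and what it does not

A single 64×64 slice over the 13-weighting protocol
(b = 0, 15, 30, 45, 60, 100, 200, 400, 600, 1000, 1500, 2000, 2500
s/mm²). Tissue classes: air background (S0 = 0), normal parenchyma, and
one lesion. Lesion presets use the tabulated ROI-level parameters of the
four lesion types (mass D = 0.84×10⁻³, D\* = 6.10×10⁻³, PF = 23%;
non-mass 1.03×10⁻³ / 7.53×10⁻³ / 31%; fibroadenoma 1.26×10⁻³ / 4.09×10⁻³
/ 45%; cyst 1.36×10⁻³ / 4.38×10⁻³ / 52%). Normal parenchyma is nowhere
tabulated; the package fixes S0 = 60 against lesion S0 = 100 (lesions
are DWI-hyperintense), D = 1.8×10⁻³, D\* = 9.0×10⁻³, PF = 0.05 —
configurable, and flagged as an editorial choice. Mass lesions are
compact ellipses; non-mass lesions are several small blobs at lower S0
(80), reproducing the observation that scattered lesions are harder.

Degradations: Rician noise (magnitude of a complex Gaussian
perturbation, σ in S0 units; default 2.0 = 2% of lesion S0), a smooth
quadratic multiplicative bias field with mean exactly 1 and peak
deviation exactly the requested amplitude, and per-band integer
translations (b = 0 never shifted; it is the registration reference).
Everything is seeded and bit-reproducible.

Not emulated: k-space/pulse-sequence physics, coil profiles beyond the
polynomial field, 3-D or deformable motion, partial volume at lesion
boundaries, chest wall/muscle anatomy, DCE-T1 contrast (ground truth is
the simulator's own label map). Passing tests therefore demonstrate
algorithmic correctness and noise robustness at clinically plausible
SNR on geometrically simple anatomy — not clinical performance.

## 5. Study sizes and defaults

End-to-end experiments run on one 64×64 slice (≈2100 breast pixels,
≈110-pixel lesion), the Monte-Carlo recovery on 200 ROI-mean replicates
of a 110-pixel ROI: small enough to iterate on quickly, large enough
that every method's behavior (including CEM's brittleness and its
remedies) is visible. Key defaults: SAM pool threshold 0.10 rad; ATGP
targets 5; I-CEM resample fraction 0.10, tolerance 0.01, max 50
iterations; K-CEM subsample 1000, σ = median pairwise distance,
ε = 1% of mean kernel diagonal; k = c = 3, m = 2; Otsu 256 bins;
b_split = 200 s/mm².

## 6. Known limitations

* K-CEM on scattered low-contrast (non-mass) lesions is weak: in the raw
  BEP feature space the Euclidean class contrast is smaller than the
  signal-dependent noise radii, and the RBF response at the pooled
  signature collapses (Dice ≈ 0.03 on the non-mass phantom, vs 0.95–1.0
  for mass). Per-pixel L2 scaling helps only partially (≈0.57). The
  clustering detectors and I-CEM handle the same phantom at Dice ≥ 0.9.
* The bias-correction stand-in assumes a low-order field; it cannot
  represent N3-grade fields and will under-correct high-frequency
  non-uniformity.
* The Rician noise floor biases ROI means upward at high b; at the
  default 2% noise this shifts ROI-level fits by well under the
  Monte-Carlo tolerances, but per-pixel fits at high noise inherit the
  bias fully.
* `decay_slope` is a linear-domain OLS slope by definition here; other
  groups may tabulate a different quantity under the same name.
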