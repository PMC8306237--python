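"""Detect the lesion by clustering pixel spectra (K-means and FCM).

Breast-pixel spectra are clustered into k = 3 groups (lesion, parenchyma,
residual dark rim).  ATGP identifies which cluster holds the tumor: the
cluster containing the most target-like pixel.  For FCM the fuzzy
membership map of that cluster is Otsu-binarized into the final mask.
"""

import ivimhsi as hs
from ivimhsi import phantom as ph

spec = hs.PhantomSpec(
    noise_sigma=2.0, bias_amplitude=0.3,
    shifts=ph.default_shifts(13, max_shift=3, seed=5), seed=0,
)
out = hs.generate_phantom(spec)
cube, breast, _ = hs.preprocess(out.cube)

for method in ("kmeans", "fcm"):
    det = hs.cluster_detect(cube, breast.mask, method=method, k=3, seed=1)
    d = hs.dice(det.mask, out.truth_mask)
    print(f"{method}: {int(det.mask.sum())} px detected, Dice {d:.3f}")

# a scattered "non-mass" lesion is the harder case: several small blobs
# with lower contrast
spec_nm = hs.PhantomSpec(
    lesion=ph.BlobLesion(centers=((24, 24), (28, 42), (42, 26), (40, 40)),
                         radius=3.0),
    lesion_class="non-mass", noise_sigma=2.0, seed=0,
)
out_nm = hs.generate_phantom(spec_nm)
cube_nm, breast_nm, _ = hs.preprocess(out_nm.cube)
det = hs.cluster_detect(cube_nm, breast_nm.mask, method="fcm", k=3, seed=1)
print(f"non-mass, fcm: Dice {hs.dice(det.mask, out_nm.truth_mask):.3f}")
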