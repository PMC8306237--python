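"""The CEM detector family.

Constrained energy minimization (CEM) is a linear subpixel target detector:
given a target spectral signature d, it finds the filter w with unit
response to d (w'd = 1) that minimizes the average output energy
(1/N) sum_r (w'x_r)^2 over the image pixels.  With R the sample
autocorrelation matrix, the closed form is

    w = R^-1 d / (d' R^-1 d).

Around it sit the pieces that make the detector unsupervised on breast DWI:
ATGP target seeding, spectral-angle pooling of the training signature, the
iterative I-CEM refinement loop, the kernel (RBF) variant K-CEM, and Otsu
binarization of the detection map.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve
from scipy.spatial.distance import cdist
from skimage.filters import threshold_otsu

from .bep import expand_bands
from .cube import BValueCube
from .errors import (
    DegenerateInputError,
    EmptyDetectionError,
    InvalidSpecError,
)


# ---------------------------------------------------------------------------
# ATGP and SAM

def atgp(pixels: np.ndarray, n_targets: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Automatic target generation process.

    The first target is the max-norm pixel; each subsequent target is the
    pixel with the largest residual norm after projecting out the span of
    the targets found so far.  Ties break to the lowest flat index
    (np.argmax convention).

    Returns (indices, signatures (k, L), residual_norms).  Stops early with
    a warning when the remaining residuals are numerically zero (rank
    exhausted).
    """
    if n_targets < 1:
        raise InvalidSpecError("n_targets must be >= 1")
    X = np.asarray(pixels, float)
    resid = X.copy()
    idxs: list[int] = []
    norms: list[float] = []
    basis: list[np.ndarray] = []
    scale = np.linalg.norm(X) + 1e-300
    for _ in range(n_targets):
        r2 = np.einsum("ij,ij->i", resid, resid)
        i = int(np.argmax(r2))
        if math.sqrt(r2[i]) <= 1e-10 * scale:
            warnings.warn(
                f"ATGP rank exhausted after {len(idxs)} targets", stacklevel=2
            )
            break
        idxs.append(i)
        norms.append(float(math.sqrt(r2[i])))
        q = resid[i].copy()
        for b in basis:  # re-orthogonalize against existing basis
            q -= (q @ b) * b
        q /= np.linalg.norm(q)
        basis.append(q)
        resid -= np.outer(resid @ q, q)
    return np.asarray(idxs), X[idxs], np.asarray(norms)


def sam_angle(x: np.ndarray, d: np.ndarray) -> float:
    """Spectral angle mapper: the angle (radians) between two spectra."""
    x = np.asarray(x, float)
    d = np.asarray(d, float)
    nx, nd = np.linalg.norm(x), np.linalg.norm(d)
    if nx == 0 or nd == 0:
        raise InvalidSpecError("SAM is undefined for a zero spectrum")
    c = float(np.dot(x, d) / (nx * nd))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def pool_training_signature(
    pixels: np.ndarray, seed_signature: np.ndarray, angle_threshold: float
) -> np.ndarray:
    """Average the pixels within the SAM angle threshold of the seed.

    The seed is part of the pool: when it is itself an image pixel it is
    already among the members (angle 0) and is not double counted; when it
    is an external signature it is appended, and it alone defines the pool
    if no pixel passes the threshold.
    """
    X = np.asarray(pixels, float)
    d = np.asarray(seed_signature, float)
    nd = np.linalg.norm(d)
    if nd == 0:
        raise InvalidSpecError("seed signature is the zero vector")
    norms = np.linalg.norm(X, axis=1)
    ok = norms > 0
    cosines = np.zeros(X.shape[0])
    cosines[ok] = (X[ok] @ d) / (norms[ok] * nd)
    angles = np.arccos(np.clip(cosines, -1.0, 1.0))
    angles[~ok] = np.pi  # zero pixels never pool
    members = X[angles <= angle_threshold]
    if members.size == 0:
        return d.copy()
    seed_is_member = bool(np.any(np.all(members == d, axis=1)))
    if not seed_is_member:
        members = np.vstack([d[None, :], members])
    return members.mean(axis=0)


# ---------------------------------------------------------------------------
# CEM and K-CEM filters

def default_ridge(R: np.ndarray) -> float:
    """Default Tikhonov ridge: 1e-6 * trace(R) / L."""
    return 1e-6 * float(np.trace(R)) / R.shape[0]


def cem_weights(pixels: np.ndarray, d: np.ndarray, ridge: float | None = None) -> np.ndarray:
    """The CEM filter weights w = R^-1 d / (d' R^-1 d)."""
    X = np.asarray(pixels, float)
    d = np.asarray(d, float)
    N, L = X.shape
    if d.shape != (L,):
        raise InvalidSpecError(f"target length {d.shape} != band count {L}")
    R = (X.T @ X) / N
    if ridge is None:
        ridge = default_ridge(R)
    if ridge < 0:
        raise InvalidSpecError("ridge must be >= 0")
    if ridge > 0:
        R = R + ridge * np.eye(L)
    try:
        Rd = solve(R, d, assume_a="pos")
    except np.linalg.LinAlgError as exc:
        raise DegenerateInputError(
            "autocorrelation matrix is singular; pass a positive ridge"
        ) from exc
    denom = float(d @ Rd)
    if denom == 0:
        raise DegenerateInputError("d' R^-1 d = 0; target orthogonal to data span")
    return Rd / denom


def cem_filter(pixels: np.ndarray, d: np.ndarray, ridge: float | None = None) -> np.ndarray:
    """CEM detection scores y_r = w' x_r for every pixel row."""
    X = np.asarray(pixels, float)
    w = cem_weights(X, d, ridge)
    assert abs(w @ np.asarray(d, float) - 1.0) < 1e-8, "unity constraint violated"
    return X @ w


def _kernel(A: np.ndarray, Bm: np.ndarray, kind: str, sigma: float) -> np.ndarray:
    if kind == "rbf":
        d2 = cdist(A, Bm, "sqeuclidean")
        return np.exp(-d2 / (2.0 * sigma * sigma))
    if kind == "linear":
        return A @ Bm.T
    raise InvalidSpecError(f"unknown kernel {kind!r}")


def median_pairwise_distance(X: np.ndarray, cap: int = 500, seed: int = 0) -> float:
    """Median Euclidean distance between rows (subsampled above ``cap``)."""
    rng = np.random.default_rng(seed)
    if X.shape[0] > cap:
        X = X[rng.choice(X.shape[0], cap, replace=False)]
    d = cdist(X, X)
    vals = d[np.triu_indices_from(d, k=1)]
    vals = vals[vals > 0]
    return float(np.median(vals)) if vals.size else 1.0


def kcem(
    pixels: np.ndarray,
    d: np.ndarray,
    kernel: str = "rbf",
    sigma: float | str = "median",
    sample_size: int = 1000,
    ridge: float | None = None,
    seed: int | None = 0,
) -> np.ndarray:
    """Kernel CEM detection scores.

    CEM is carried out in the kernel feature space on a seeded pixel
    subsample S (|S| = min(N, sample_size)).  With K the Gram matrix over S
    and k_v = [k(s, v)]_{s in S}, the regularized feature-space filter
    response, obtained through the Woodbury identity, is

        y(r) = [k(d,r) - k_d' (K/M + eps I)^-1 k_r / M]
             / [k(d,d) - k_d' (K/M + eps I)^-1 k_d / M],

    which satisfies y(d) = 1 exactly and reduces to linear CEM (same ridge)
    for the linear kernel.
    """
    X = np.asarray(pixels, float)
    d = np.asarray(d, float)
    N = X.shape[0]
    if sample_size < 1:
        raise InvalidSpecError("sample_size must be >= 1")
    rng = np.random.default_rng(seed)
    M = min(N, sample_size)
    sel = rng.choice(N, M, replace=False) if M < N else np.arange(N)
    S = X[sel]
    if kernel == "rbf":
        if sigma == "median":
            sigma = median_pairwise_distance(S)
        sigma = float(sigma)
        if sigma <= 0:
            raise InvalidSpecError("RBF sigma must be > 0")
    else:
        sigma = float(sigma) if sigma != "median" else 1.0

    K = _kernel(S, S, kernel, sigma)
    B = K / M
    if ridge is None:
        # shrink at 1% of the mean kernel self-similarity: strong enough to
        # keep the near-singular feature-space autocorrelation from nulling
        # within-class variability, scale-aware for any kernel
        ridge = 1e-2 * float(np.mean(np.diag(K)))
    if ridge <= 0:
        ridge = 1e-12 * max(float(np.trace(B)) / M, 1.0)
    A = B + ridge * np.eye(M)
    kd = _kernel(S, d[None, :], kernel, sigma)[:, 0]
    a = solve(A, kd, assume_a="pos")
    kdd = float(_kernel(d[None, :], d[None, :], kernel, sigma)[0, 0])
    denom = kdd - float(kd @ a) / M
    if denom <= 0:
        raise DegenerateInputError("kernel CEM denominator non-positive; increase ridge")
    Kr = _kernel(X, S, kernel, sigma)  # (N, M)
    krd = _kernel(X, d[None, :], kernel, sigma)[:, 0]
    return (krd - (Kr @ a) / M) / denom


# ---------------------------------------------------------------------------
# Otsu binarization

def otsu_threshold(values: np.ndarray) -> float:
    """Otsu threshold of a value sample over a 256-bin histogram."""
    values = np.asarray(values, float).ravel()
    if np.unique(values).size < 2:
        raise DegenerateInputError("Otsu needs at least two distinct values")
    return float(threshold_otsu(values, nbins=256))


def binarize(values: np.ndarray) -> tuple[float, np.ndarray]:
    """Otsu threshold and the boolean mask {value > threshold}."""
    thr = otsu_threshold(values)
    return thr, np.asarray(values) > thr


# ---------------------------------------------------------------------------
# Full detectors on cubes

def _seed_scores(cube: BValueCube) -> np.ndarray:
    """Per-pixel tumor plausibility: mean intensity over the high-b half of
    the original bands (tumors stay hyperintense at high b)."""
    half = cube.n_bands // 2
    return cube.data[:, :, half:].mean(axis=2).ravel()


def _prepare_pixels(
    cube: BValueCube, breast_mask: np.ndarray, use_bep: bool
) -> tuple[np.ndarray, np.ndarray]:
    X, idx = cube.pixels(breast_mask)
    if use_bep:
        X = expand_bands(X, normalize=False).data
    return X, idx


def seed_target_signature(
    cube: BValueCube,
    breast_mask: np.ndarray,
    use_bep: bool = True,
    n_targets: int = 5,
    sam_threshold: float = 0.10,
) -> tuple[np.ndarray, int]:
    """Unsupervised target signature: ATGP candidates, tumor seed picked as
    the candidate with the highest mean high-b intensity, SAM-pooled mean.

    Returns (signature, flat image index of the seed pixel).
    """
    X, idx = _prepare_pixels(cube, breast_mask, use_bep)
    t_idx, _, _ = atgp(X, n_targets)
    scores = _seed_scores(cube)[idx[t_idx]]
    seed_local = int(t_idx[int(np.argmax(scores))])
    d = pool_training_signature(X, X[seed_local], sam_threshold)
    return d, int(idx[seed_local])


@dataclass
class IterationLog:
    """Per-iteration record of the I-CEM loop."""

    iteration: int
    threshold: float
    positives: int
    difference_rate: float | None


@dataclass
class DetectionResult:
    """A detector's output: scores, mask, and provenance."""

    map: np.ndarray          # H x W detection scores (0 outside breast)
    mask: np.ndarray         # H x W boolean tumor mask
    threshold: float
    log: list[IterationLog] = field(default_factory=list)
    seed: int | None = None


def _scatter(shape: tuple[int, int], idx: np.ndarray, values: np.ndarray) -> np.ndarray:
    out = np.zeros(shape[0] * shape[1], dtype=values.dtype)
    out[idx] = values
    return out.reshape(shape)


def icem(
    cube: BValueCube,
    breast_mask: np.ndarray,
    use_bep: bool = True,
    n_targets: int = 5,
    sam_threshold: float = 0.10,
    resample_fraction: float = 0.10,
    diff_tol: float = 0.01,
    max_iter: int = 50,
    ridge: float | None = None,
    seed: int | None = 0,
    cumulative: bool = True,
) -> DetectionResult:
    """Iterative CEM.

    Starting from the ATGP/SAM-pooled signature, repeat: CEM filter, Otsu
    binarize, randomly resample ``resample_fraction`` of the positive
    pixels as new training samples, and average the training pool into the
    next target signature.  With ``cumulative`` (default) the sampled
    spectra join the existing pool, so the signature is refined by a
    growing sample; with ``cumulative=False`` the signature is the mean of
    the freshly sampled spectra alone, which is noisy for small lesions
    (a 10% draw from a ~100-pixel tumor averages ~10 spectra).  The
    difference rate between consecutive binary maps (denominator: breast
    pixel count) drives convergence; iteration stops when it drops to
    ``diff_tol`` (default 1%) or ``max_iter`` is hit.
    """
    if not 0 < resample_fraction <= 1:
        raise InvalidSpecError("resample_fraction must be in (0, 1]")
    breast_mask = np.asarray(breast_mask, bool)
    X, idx = _prepare_pixels(cube, breast_mask, use_bep)
    t_idx, _, _ = atgp(X, n_targets)
    scores = _seed_scores(cube)[idx[t_idx]]
    seed_local = int(t_idx[int(np.argmax(scores))])
    seed_sig = X[seed_local]
    d = pool_training_signature(X, seed_sig, sam_threshold)
    # running training pool for the cumulative signature update
    norms = np.linalg.norm(X, axis=1)
    nd = np.linalg.norm(seed_sig)
    cosines = np.zeros(X.shape[0])
    ok = norms > 0
    cosines[ok] = (X[ok] @ seed_sig) / (norms[ok] * nd)
    in_pool = np.arccos(np.clip(cosines, -1.0, 1.0)) <= sam_threshold
    in_pool &= ok
    in_pool[seed_local] = True  # seed always pools (angle 0 to itself)
    pool_sum = X[in_pool].sum(axis=0)
    pool_n = int(in_pool.sum())

    rng = np.random.default_rng(seed)
    n_mask = idx.size
    prev = None
    logs: list[IterationLog] = []
    y = np.zeros(n_mask)
    binm = np.zeros(n_mask, bool)
    thr = 0.0
    for it in range(1, max_iter + 1):
        y = cem_filter(X, d, ridge)
        thr, binm = binarize(y)
        pos = np.flatnonzero(binm)
        if pos.size == 0:
            raise EmptyDetectionError(
                f"I-CEM iteration {it}: Otsu produced an empty positive set"
            )
        diff = None if prev is None else float(np.mean(binm != prev)) * 1.0
        logs.append(IterationLog(it, float(thr), int(pos.size), diff))
        if diff is not None and diff <= diff_tol:
            break
        n_draw = math.ceil(resample_fraction * pos.size)
        draw = rng.choice(pos, n_draw, replace=False)
        if cumulative:
            pool_sum = pool_sum + X[draw].sum(axis=0)
            pool_n += n_draw
            d = pool_sum / pool_n
        else:
            d = X[draw].mean(axis=0)
        prev = binm
    shape = cube.shape
    return DetectionResult(
        map=_scatter(shape, idx, y),
        mask=_scatter(shape, idx, binm).astype(bool),
        threshold=float(thr),
        log=logs,
        seed=seed,
    )


def kcem_detect(
    cube: BValueCube,
    breast_mask: np.ndarray,
    use_bep: bool = True,
    n_targets: int = 5,
    sam_threshold: float = 0.10,
    kernel: str = "rbf",
    sigma: float | str = "median",
    sample_size: int = 1000,
    ridge: float | None = None,
    seed: int | None = 0,
) -> DetectionResult:
    """K-CEM end to end: seed signature -> kernel CEM -> Otsu binarization."""
    breast_mask = np.asarray(breast_mask, bool)
    X, idx = _prepare_pixels(cube, breast_mask, use_bep)
    d, _ = seed_target_signature(cube, breast_mask, use_bep, n_targets, sam_threshold)
    y = kcem(X, d, kernel=kernel, sigma=sigma, sample_size=sample_size, ridge=ridge, seed=seed)
    thr, binm = binarize(y)
    if not binm.any():
        raise EmptyDetectionError("K-CEM: Otsu produced an empty positive set")
    shape = cube.shape
    return DetectionResult(
        map=_scatter(shape, idx, y),
        mask=_scatter(shape, idx, binm).astype(bool),
        threshold=float(thr),
        seed=seed,
    )
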