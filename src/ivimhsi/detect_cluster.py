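"""Clustering-based detection: K-means and fuzzy C-means over pixel
spectra, with ATGP-guided identification of the tumor cluster.

With k = 3 (the default) the breast pixels split into roughly tumor,
normal parenchyma and the residual dark rim; the cluster containing the
ATGP tumor seed pixel is taken as the lesion.  Cluster labels are
arbitrary up to permutation, so downstream logic is anchored on the seed
pixel, never on a fixed label index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import kmeans_plusplus

from .cube import BValueCube
from .detect_cem import DetectionResult, atgp, binarize, _prepare_pixels, _scatter, _seed_scores
from .errors import InvalidSpecError


@dataclass
class ClusterResult:
    """Hard labels, optional fuzzy memberships, centroids and the
    objective trace of the fit."""

    labels: np.ndarray                 # (N,) in {0..k-1}
    centroids: np.ndarray              # (k, L)
    objective_trace: list[float] = field(default_factory=list)
    memberships: np.ndarray | None = None  # (N, k), FCM only

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def _sq_dists(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    # (N, k) squared Euclidean distances
    return (
        np.einsum("ij,ij->i", X, X)[:, None]
        - 2.0 * X @ C.T
        + np.einsum("ij,ij->i", C, C)[None, :]
    ).clip(min=0.0)


def kmeans_cluster(
    pixels: np.ndarray,
    k: int = 3,
    seed: int | None = 0,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> ClusterResult:
    """Lloyd's algorithm from a seeded k-means++ initialization.

    The per-iteration within-cluster sum of squares is recorded; the trace
    is non-increasing by Lloyd's monotonicity.
    """
    X = np.asarray(pixels, float)
    N = X.shape[0]
    if k < 1:
        raise InvalidSpecError("k must be >= 1")
    if N < k:
        raise InvalidSpecError(f"need at least k={k} pixels, got {N}")
    C, _ = kmeans_plusplus(X, n_clusters=k, random_state=seed)
    trace: list[float] = []
    labels = np.zeros(N, int)
    for _ in range(max_iter):
        d2 = _sq_dists(X, C)
        labels = np.argmin(d2, axis=1)
        trace.append(float(d2[np.arange(N), labels].sum()))
        newC = C.copy()
        for j in range(k):
            members = X[labels == j]
            if members.size:
                newC[j] = members.mean(axis=0)
        shift = float(np.linalg.norm(newC - C))
        C = newC
        if shift < tol:
            break
    d2 = _sq_dists(X, C)
    labels = np.argmin(d2, axis=1)
    trace.append(float(d2[np.arange(N), labels].sum()))
    return ClusterResult(labels=labels, centroids=C, objective_trace=trace)


def fcm_cluster(
    pixels: np.ndarray,
    c: int = 3,
    m: float = 2.0,
    seed: int | None = 0,
    max_iter: int = 300,
    tol: float = 1e-5,
) -> ClusterResult:
    """Fuzzy C-means with fuzziness exponent m (default 2).

    Alternates the standard membership and centroid updates
        u_ij = 1 / sum_l (||x_i - v_j|| / ||x_i - v_l||)^(2/(m-1)),
        v_j  = sum_i u_ij^m x_i / sum_i u_ij^m,
    stopping when the largest membership change falls below ``tol``.  A
    pixel exactly on a centroid receives membership 1 there (crisp limit).
    """
    X = np.asarray(pixels, float)
    N = X.shape[0]
    if c < 1:
        raise InvalidSpecError("c must be >= 1")
    if m <= 1:
        raise InvalidSpecError("fuzziness m must be > 1")
    if N < c:
        raise InvalidSpecError(f"need at least c={c} pixels, got {N}")
    V, _ = kmeans_plusplus(X, n_clusters=c, random_state=seed)
    U = _fcm_memberships(X, V, m)
    trace: list[float] = []
    for _ in range(max_iter):
        Um = U**m
        V = (Um.T @ X) / Um.sum(axis=0)[:, None]
        newU = _fcm_memberships(X, V, m)
        d2 = _sq_dists(X, V)
        trace.append(float((newU**m * d2).sum()))
        change = float(np.abs(newU - U).max())
        U = newU
        if change < tol:
            break
    labels = np.argmax(U, axis=1)
    return ClusterResult(labels=labels, centroids=V, objective_trace=trace, memberships=U)


def _fcm_memberships(X: np.ndarray, V: np.ndarray, m: float) -> np.ndarray:
    d2 = _sq_dists(X, V)
    on_centroid = d2 <= 0
    U = np.zeros_like(d2)
    hit = on_centroid.any(axis=1)
    if hit.any():
        # crisp limit: all mass on the (first) coincident centroid
        first = np.argmax(on_centroid[hit], axis=1)
        U[np.flatnonzero(hit), first] = 1.0
    rest = ~hit
    if rest.any():
        p = 1.0 / (m - 1.0)
        inv = d2[rest] ** -p  # (||x-v_j||^2)^(-1/(m-1)) = (||x-v_j||)^(-2/(m-1))
        U[rest] = inv / inv.sum(axis=1, keepdims=True)
    return U


def pick_tumor_cluster(
    result: ClusterResult,
    pixels: np.ndarray,
    seed_scores: np.ndarray,
    n_targets: int = 5,
) -> tuple[int, np.ndarray]:
    """Identify the tumor cluster via ATGP on the same pixel matrix.

    ATGP proposes ``n_targets`` candidate pixels; the tumor seed is the
    candidate with the highest ``seed_scores`` value (mean high-b
    intensity).  The tumor cluster is the one containing that pixel.
    Returns (cluster index, boolean membership of each pixel row).
    """
    X = np.asarray(pixels, float)
    t_idx, _, _ = atgp(X, n_targets)
    seed_px = int(t_idx[int(np.argmax(np.asarray(seed_scores)[t_idx]))])
    cluster = int(result.labels[seed_px])
    if result.k == 1:
        warnings.warn("single cluster: tumor mask degenerates to the whole region",
                      stacklevel=2)
    return cluster, result.labels == cluster


def cluster_detect(
    cube: BValueCube,
    breast_mask: np.ndarray,
    method: str = "kmeans",
    k: int = 3,
    m: float = 2.0,
    use_bep: bool = False,
    seed: int | None = 0,
    refine: bool = True,
) -> DetectionResult:
    """K-means or FCM detection end to end.

    Clustering runs on the breast-mask spectra (original bands by default;
    BEP expansion opt-in).  The ATGP-anchored cluster is the lesion.  For
    FCM the grayscale membership map of that cluster is Otsu-binarized
    (the grayscale-to-binary step); the K-means partition is already
    binary.
    """
    breast_mask = np.asarray(breast_mask, bool)
    X, idx = _prepare_pixels(cube, breast_mask, use_bep)
    if method == "kmeans":
        res = kmeans_cluster(X, k=k, seed=seed)
    elif method == "fcm":
        res = fcm_cluster(X, c=k, m=m, seed=seed)
    else:
        raise InvalidSpecError(f"unknown clustering method {method!r}")
    scores = _seed_scores(cube)[idx]
    cluster, member = pick_tumor_cluster(res, X, scores)
    shape = cube.shape
    if method == "fcm" and refine and res.memberships is not None:
        grey = res.memberships[:, cluster]
        try:
            thr, binm = binarize(grey)
        except Exception:
            thr, binm = 0.5, member
        if not binm.any():
            thr, binm = 0.5, member
        score_map = _scatter(shape, idx, grey)
    else:
        thr, binm = 0.5, member
        score_map = _scatter(shape, idx, member.astype(float))
    return DetectionResult(
        map=score_map,
        mask=_scatter(shape, idx, binm).astype(bool),
        threshold=float(thr),
        seed=seed,
    )
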