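"""Band expansion process (BEP).

A B-band cube is augmented with second-order statistics: the B elementwise
auto-correlation bands x_i * x_i and the B(B-1)/2 cross-correlation bands
x_i * x_j (i < j), for a total of (B^2 + 3B) / 2 bands.  For the 13-b-value
protocol this expands 13 bands to 104 (13 original + 13 auto + 78 cross),
turning the multispectral stack into a hyperspectral one and exposing the
nonlinear band correlations that subpixel detectors exploit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidSpecError


def expanded_band_count(B: int) -> int:
    """Number of BEP output bands: B original + B auto + B(B-1)/2 cross."""
    if B < 1:
        raise InvalidSpecError("band count must be >= 1")
    return (B * B + 3 * B) // 2


def band_labels(B: int) -> list[str]:
    """Output band tags in canonical order: originals, autos, crosses (i<j)."""
    labels = [f"original({i})" for i in range(B)]
    labels += [f"auto({i})" for i in range(B)]
    labels += [f"cross({i},{j})" for i in range(B) for j in range(i + 1, B)]
    return labels


@dataclass
class ExpandedCube:
    """H x W x L expanded stack with per-band provenance tags."""

    data: np.ndarray
    band_labels: list[str]

    @property
    def n_bands(self) -> int:
        return self.data.shape[-1]


def expand_bands(data: np.ndarray, normalize: bool = False) -> ExpandedCube:
    """Apply the BEP to an H x W x B array (or N x B pixel matrix).

    Band order is originals, then autos, then crosses in lexicographic
    (i, j).  With ``normalize=True`` every output band is min-max scaled
    to [0, 1] independently.  The default keeps the raw products: min-max
    rescaling equal-weights noise-dominated product bands and its offsets
    distort spectral angles, both of which measurably degrade CEM
    detection (CEM itself is invariant to per-band scaling, so the
    products' larger dynamic range is harmless).
    """
    arr = np.asarray(data, dtype=float)
    squeeze = arr.ndim == 2
    if squeeze:  # pixel matrix: treat as 1 x N x B
        arr = arr[None]
    if arr.ndim != 3:
        raise InvalidSpecError("expected H x W x B array or N x B matrix")
    B = arr.shape[2]
    L = expanded_band_count(B)
    out = np.empty(arr.shape[:2] + (L,), dtype=float)
    out[:, :, :B] = arr
    out[:, :, B : 2 * B] = arr * arr
    k = 2 * B
    for i in range(B):
        for j in range(i + 1, B):
            out[:, :, k] = arr[:, :, i] * arr[:, :, j]
            k += 1
    if normalize:
        flat = out.reshape(-1, L)
        lo = flat.min(axis=0)
        rng = flat.max(axis=0) - lo
        rng[rng == 0] = 1.0
        out = (out - lo) / rng
    if squeeze:
        out = out[0]
    return ExpandedCube(out, band_labels(B))


def labels_to_csv(labels: list[str]) -> str:
    """Band-label table (index, tag) as CSV text."""
    lines = ["band_index,label"]
    lines += [f"{i},{lab}" for i, lab in enumerate(labels)]
    return "\n".join(lines) + "\n"
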