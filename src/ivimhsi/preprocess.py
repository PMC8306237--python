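"""Pre-processing chain: bias-field correction, inter-band registration,
breast-region extraction.

These are deliberately simple, fully documented stand-ins for the heavier
clinical tools usually applied at this stage (N3 non-uniformity correction,
commercial rigid registration, manual breast cropping): a log-domain
polynomial field fit, an exhaustive integer-translation search maximizing
normalized cross-correlation, and Otsu foreground extraction.  The stage
order is fixed: bias correction -> registration -> breast extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion, binary_fill_holes, label as cc_label
from skimage.filters import threshold_otsu

from .cube import BValueCube
from .errors import InvalidSpecError, NoForegroundError
from .phantom import translate


def _poly_design(rr: np.ndarray, cc: np.ndarray, order: int) -> np.ndarray:
    cols = [np.ones_like(rr)]
    for total in range(1, order + 1):
        for py in range(total + 1):
            px = total - py
            cols.append(rr**py * cc**px)
    return np.stack(cols, axis=-1)


def correct_bias(
    cube: BValueCube, polynomial_order: int = 2
) -> tuple[BValueCube, np.ndarray]:
    """Estimate and remove a smooth multiplicative intensity field.

    A 2-D polynomial (default order 2) is fit to the log-intensity of the
    b=0 band over foreground pixels; one robust re-fit discards pixels whose
    residual is large (lesions, partial volume) so only the slowly varying
    field is captured.  All bands are divided by the field normalized to
    mean 1 over the foreground.
    """
    if polynomial_order not in (1, 2, 3):
        raise InvalidSpecError("polynomial_order must be 1, 2 or 3")
    b0 = cube.band(0)
    if not np.any(b0 > 0):
        raise NoForegroundError("b=0 band is identically zero")
    if np.ptp(b0) == 0:  # constant image: nothing to correct
        return BValueCube(cube.data.copy(), cube.bvalues), np.ones(cube.shape)
    thr = threshold_otsu(b0, nbins=256)
    fg = b0 > max(thr, 0)
    if not fg.any():
        raise NoForegroundError("no foreground above the Otsu threshold")

    h, w = cube.shape
    rr, cc = np.mgrid[0:h, 0:w]
    rn = (rr - (h - 1) / 2) / max(h - 1, 1)
    cn = (cc - (w - 1) / 2) / max(w - 1, 1)
    A_full = _poly_design(rn, cn, polynomial_order)

    y = np.log(b0[fg])
    A = A_full[fg]
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    # one robust pass: drop pixels that deviate strongly (lesion contrast)
    scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    if scale > 0:
        keep = np.abs(resid - np.median(resid)) <= 2.5 * scale
        if keep.sum() >= A.shape[1]:
            coef, *_ = np.linalg.lstsq(A[keep], y[keep], rcond=None)

    logfield = A_full @ coef
    field = np.exp(logfield - logfield[fg].mean())  # mean-1 in the log sense
    field /= field[fg].mean()
    corrected = cube.data / field[:, :, None]
    return BValueCube(np.clip(corrected, 0, None), cube.bvalues), field


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def register_bands(
    cube: BValueCube, reference_band: int = 0, max_shift: int = 5
) -> tuple[BValueCube, list[tuple[int, int]]]:
    """Undo per-band integer translations against the b=0 reference.

    For every band, the (dy, dx) in [-max_shift, max_shift]^2 maximizing
    the normalized cross-correlation with the reference band (over the
    overlap interior) is found exhaustively and applied inversely.
    """
    if max_shift < 0:
        raise InvalidSpecError("max_shift must be >= 0")
    ref = cube.band(reference_band)
    m = max_shift
    h, w = ref.shape
    interior = (slice(m, h - m), slice(m, w - m)) if m else (slice(None), slice(None))
    ref_in = ref[interior]
    out = cube.data.copy()
    shifts: list[tuple[int, int]] = []
    for j in range(cube.n_bands):
        if j == reference_band or m == 0:
            shifts.append((0, 0))
            continue
        band = cube.band(j)
        if band.std() == 0:
            warnings.warn(f"band {j} is flat; assuming shift (0, 0)", stacklevel=2)
            shifts.append((0, 0))
            continue
        best, best_score = (0, 0), -np.inf
        for dy in range(-m, m + 1):
            for dx in range(-m, m + 1):
                cand = band[m + dy : h - m + dy, m + dx : w - m + dx]
                score = _ncc(ref_in, cand)
                if score > best_score:
                    best_score, best = score, (dy, dx)
        shifts.append(best)
        out[:, :, j] = translate(band, -best[0], -best[1])
    return BValueCube(out, cube.bvalues), shifts


@dataclass
class BreastMask:
    """Binary breast-region mask on the image grid."""

    mask: np.ndarray

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def extract_breast_mask(cube: BValueCube, erosion_px: int = 1) -> BreastMask:
    """Segment the breast from the b=0 band.

    Otsu foreground -> largest connected component -> hole filling ->
    optional erosion (default 1 px) stripping the bright skin rim.
    """
    b0 = cube.band(0)
    if not np.any(b0 > 0):
        raise NoForegroundError("image has no non-zero pixels")
    try:
        thr = threshold_otsu(b0, nbins=256)
    except ValueError as exc:
        raise NoForegroundError("b=0 band is constant") from exc
    fg = b0 > max(thr, 0)
    if not fg.any():
        raise NoForegroundError("no pixels above the Otsu threshold")
    comps, n = cc_label(fg)
    if n > 1:
        sizes = np.bincount(comps.ravel())[1:]
        fg = comps == (1 + int(np.argmax(sizes)))
    fg = binary_fill_holes(fg)
    if erosion_px > 0:
        fg = binary_erosion(fg, iterations=erosion_px)
    if not fg.any():
        raise NoForegroundError("breast mask empty after erosion")
    return BreastMask(fg)


def preprocess(
    cube: BValueCube,
    polynomial_order: int = 2,
    max_shift: int = 5,
    erosion_px: int = 1,
) -> tuple[BValueCube, BreastMask, dict]:
    """Full chain in the fixed order; returns (cube, breast mask, log)."""
    cube, field = correct_bias(cube, polynomial_order)
    cube, shifts = register_bands(cube, max_shift=max_shift)
    mask = extract_breast_mask(cube, erosion_px=erosion_px)
    log = {
        "estimated_shifts": [list(s) for s in shifts],
        "bias_field_range": [float(field.min()), float(field.max())],
        "breast_pixels": mask.n_pixels,
    }
    return cube, mask, log
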