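"""The multi-b-value image cube and its NIfTI / plain-text I/O.

A diffusion-weighted acquisition with B diffusion weightings is held as an
H x W x B array together with its ordered b-value list, exactly the way a
hyperspectral cube holds one image per spectral band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError

#: The 13-weighting protocol emulated throughout the package (s/mm^2).
DEFAULT_BVALUES: tuple[float, ...] = (
    0, 15, 30, 45, 60, 100, 200, 400, 600, 1000, 1500, 2000, 2500,
)


@dataclass
class BValueCube:
    """An H x W x B stack of diffusion-weighted intensities.

    Parameters
    ----------
    data:
        Non-negative intensities, shape ``(H, W, B)``.
    bvalues:
        Strictly increasing diffusion weightings starting at 0, length B.
    """

    data: np.ndarray
    bvalues: np.ndarray = field(default_factory=lambda: np.asarray(DEFAULT_BVALUES, float))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.bvalues = np.asarray(self.bvalues, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(f"cube data must be H x W x B, got shape {self.data.shape}")
        if self.data.shape[2] != self.bvalues.size:
            raise FormatError(
                f"cube has {self.data.shape[2]} bands but {self.bvalues.size} b-values"
            )
        if self.bvalues.size and self.bvalues[0] != 0:
            raise FormatError("first b-value must be 0 (the unweighted reference)")
        if np.any(np.diff(self.bvalues) <= 0):
            raise FormatError("b-values must be strictly increasing")
        if np.any(self.data < 0):
            raise FormatError("cube intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band(self, i: int) -> np.ndarray:
        return self.data[:, :, i]

    def pixels(self, mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Flatten the cube to an (N, B) pixel matrix.

        Returns the matrix and the flat indices (into H*W) of its rows so
        detection maps can be scattered back onto the grid.
        """
        h, w, b = self.data.shape
        flat = self.data.reshape(h * w, b)
        if mask is None:
            idx = np.arange(h * w)
        else:
            idx = np.flatnonzero(np.asarray(mask, bool).ravel())
        return flat[idx], idx


def read_bvalues(path: str | Path) -> np.ndarray:
    """Read a plain-text b-value file, one value per line."""
    vals = [float(line) for line in Path(path).read_text().split()]
    return np.asarray(vals, float)


def write_bvalues(bvalues: np.ndarray, path: str | Path) -> None:
    Path(path).write_text("\n".join(f"{b:g}" for b in np.asarray(bvalues)) + "\n")


def read_cube(nifti_path: str | Path, bvalue_path: str | Path) -> BValueCube:
    """Load a cube from a 3-D/4-D NIfTI plus its side-car b-value file."""
    img = nib.load(str(nifti_path))
    arr = np.asanyarray(img.dataobj, dtype=float)
    if arr.ndim == 4:
        if arr.shape[2] != 1:
            raise FormatError(
                f"4-D cube must be H x W x 1 x B (single slice), got {arr.shape}"
            )
        arr = arr[:, :, 0, :]
    if arr.ndim != 3:
        raise FormatError(f"expected 3-D or 4-D NIfTI, got {arr.ndim}-D")
    bvalues = read_bvalues(bvalue_path)
    if arr.shape[2] != bvalues.size:
        raise FormatError(
            f"NIfTI has {arr.shape[2]} bands but b-value file lists {bvalues.size}"
        )
    return BValueCube(arr, bvalues)


def write_cube(cube: BValueCube, nifti_path: str | Path, bvalue_path: str | Path) -> None:
    """Write a cube as H x W x 1 x B NIfTI (4th axis = b index) + b-value file."""
    arr = cube.data[:, :, None, :]
    nib.save(nib.Nifti1Image(arr, affine=np.eye(4)), str(nifti_path))
    write_bvalues(cube.bvalues, bvalue_path)


def read_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj) > 0.5


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine=np.eye(4)), str(path))
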