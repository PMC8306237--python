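"""Synthetic IVIM phantom: b-value cubes with known lesions and parameters.

The clinical data this pipeline targets are restricted, so every stage is
exercised on simulated single-slice phantoms: a tissue label map (air
background, normal parenchyma, one lesion class), per-class bi-exponential
IVIM signal decay, Rician noise, a smooth multiplicative bias field and
small per-band translations emulating breathing drift.

The bi-exponential IVIM model for the normalized signal at diffusion
weighting b is

    S_b / S_0 = (1 - PF) * exp(-b * D) + PF * exp(-b * D*),

with D the pure water diffusion coefficient, D* the pseudo-diffusion
coefficient of capillary microcirculation and PF the perfusion fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cube import DEFAULT_BVALUES, BValueCube
from .errors import ConfigurationError, InvalidSpecError

# Integer codes used in label maps.
BACKGROUND = 0
NORMAL = 1
LESION = 2


@dataclass(frozen=True)
class TissueClassParams:
    """IVIM parameters of one tissue class.

    S0 is the unweighted signal (arbitrary units), D and Dstar in mm^2/s,
    PF dimensionless in [0, 1].
    """

    name: str
    S0: float
    D: float
    Dstar: float
    PF: float

    def __post_init__(self) -> None:
        if self.S0 < 0:
            raise InvalidSpecError(f"{self.name}: S0 must be >= 0")
        if self.D < 0 or self.Dstar < 0:
            raise InvalidSpecError(f"{self.name}: D and D* must be >= 0")
        if not 0 <= self.PF <= 1:
            raise InvalidSpecError(f"{self.name}: PF must be in [0, 1]")

    def signal(self, bvalues: np.ndarray) -> np.ndarray:
        """Noise-free bi-exponential decay at the given b-values."""
        b = np.asarray(bvalues, float)
        return self.S0 * (
            (1 - self.PF) * np.exp(-b * self.D) + self.PF * np.exp(-b * self.Dstar)
        )


# Lesion presets: ROI-level quantitative values reported for the four tumor
# types (D, D* in mm^2/s, PF as a fraction).  S0 values are simulator
# choices: lesions are hyperintense on DWI relative to parenchyma.
MASS = TissueClassParams("mass", S0=100.0, D=0.84e-3, Dstar=6.10e-3, PF=0.23)
NON_MASS = TissueClassParams("non-mass", S0=80.0, D=1.03e-3, Dstar=7.53e-3, PF=0.31)
FIBROADENOMA = TissueClassParams("fibroadenoma", S0=100.0, D=1.26e-3, Dstar=4.09e-3, PF=0.45)
CYST = TissueClassParams("cyst", S0=100.0, D=1.36e-3, Dstar=4.38e-3, PF=0.52)
# Normal parenchyma is not tabulated anywhere; this is the package's fixed
# choice (documented in the methods note): dimmer than lesions, faster
# diffusion, low perfusion.
NORMAL_TISSUE = TissueClassParams("normal", S0=60.0, D=1.8e-3, Dstar=9.0e-3, PF=0.05)
AIR = TissueClassParams("background", S0=0.0, D=0.0, Dstar=0.0, PF=0.0)

LESION_PRESETS = {p.name: p for p in (MASS, NON_MASS, FIBROADENOMA, CYST)}


@dataclass(frozen=True)
class EllipseLesion:
    """A compact (mass-like) elliptical lesion: center (row, col), semi-axes."""

    center: tuple[float, float]
    axes: tuple[float, float]


@dataclass(frozen=True)
class BlobLesion:
    """A scattered (non-mass-like) lesion: several small circular blobs."""

    centers: tuple[tuple[float, float], ...]
    radius: float


@dataclass(frozen=True)
class Ellipse:
    center: tuple[float, float]
    axes: tuple[float, float]

    def contains(self, rr: np.ndarray, cc: np.ndarray) -> np.ndarray:
        return (
            ((rr - self.center[0]) / self.axes[0]) ** 2
            + ((cc - self.center[1]) / self.axes[1]) ** 2
        ) <= 1.0


@dataclass
class PhantomSpec:
    """Full description of one synthetic slice.

    ``shifts`` is a list of per-band integer (dy, dx) translations; the b=0
    band is the registration reference and is never shifted.
    """

    shape: tuple[int, int] = (64, 64)
    bvalues: np.ndarray = field(default_factory=lambda: np.asarray(DEFAULT_BVALUES, float))
    lesion: EllipseLesion | BlobLesion = EllipseLesion(center=(32, 32), axes=(5, 7))
    lesion_class: str = "mass"
    breast_region: Ellipse | None = None
    noise_sigma: float = 2.0
    bias_amplitude: float = 0.0
    shifts: list[tuple[int, int]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.breast_region is None:
            h, w = self.shape
            self.breast_region = Ellipse(
                center=(h / 2, w / 2), axes=(0.42 * h, 0.42 * w)
            )


@dataclass
class PhantomOutput:
    """A simulated cube plus everything needed to grade downstream stages."""

    cube: BValueCube
    labels: np.ndarray
    truth_mask: np.ndarray
    truth_params: dict[str, TissueClassParams]
    breast_region: Ellipse
    bias_field: np.ndarray | None = None
    shifts: list[tuple[int, int]] | None = None


def make_label_map(
    shape: tuple[int, int],
    lesion: EllipseLesion | BlobLesion,
    breast_region: Ellipse,
) -> np.ndarray:
    """Rasterize background / normal / lesion labels on a pixel grid.

    The lesion must lie strictly inside the breast ellipse, which must in
    turn lie inside the frame.
    """
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    breast = breast_region.contains(rr, cc)
    if (
        breast_region.center[0] - breast_region.axes[0] < 0
        or breast_region.center[0] + breast_region.axes[0] > h
        or breast_region.center[1] - breast_region.axes[1] < 0
        or breast_region.center[1] + breast_region.axes[1] > w
    ):
        raise InvalidSpecError("breast region extends outside the image frame")

    if isinstance(lesion, EllipseLesion):
        if lesion.axes[0] <= 0 or lesion.axes[1] <= 0:
            raise InvalidSpecError("lesion ellipse axes must be positive")
        les = Ellipse(lesion.center, lesion.axes).contains(rr, cc)
    elif isinstance(lesion, BlobLesion):
        if lesion.radius <= 0 or not lesion.centers:
            raise InvalidSpecError("blob lesion needs a positive radius and >= 1 center")
        les = np.zeros(shape, bool)
        for cy, cx in lesion.centers:
            les |= ((rr - cy) ** 2 + (cc - cx) ** 2) <= lesion.radius**2
    else:  # pragma: no cover - defensive
        raise InvalidSpecError(f"unknown lesion descriptor {lesion!r}")

    if not les.any():
        raise InvalidSpecError("lesion rasterizes to zero pixels")
    if (les & ~breast).any():
        raise InvalidSpecError("lesion extends outside the breast region")

    labels = np.full(shape, BACKGROUND, dtype=np.int8)
    labels[breast] = NORMAL
    labels[les] = LESION
    return labels


def rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-MRI noise: |signal + g1 + i*g2| with iid N(0, sigma) parts."""
    if sigma == 0:
        return signal.copy()
    g1 = rng.normal(0.0, sigma, signal.shape)
    g2 = rng.normal(0.0, sigma, signal.shape)
    return np.hypot(signal + g1, g2)


def simulate_cube(
    labels: np.ndarray,
    params: dict[int, TissueClassParams],
    bvalues: np.ndarray,
    noise_sigma: float = 0.0,
    seed: int | None = 0,
) -> BValueCube:
    """Render a label map into a noisy bi-exponential b-value cube."""
    if noise_sigma < 0:
        raise InvalidSpecError("noise_sigma must be >= 0")
    present = np.unique(labels)
    missing = [int(c) for c in present if int(c) not in params]
    if missing:
        raise ConfigurationError(f"no tissue parameters for label(s) {missing}")
    bvalues = np.asarray(bvalues, float)
    h, w = labels.shape
    clean = np.zeros((h, w, bvalues.size), float)
    for code in present:
        clean[labels == code] = params[int(code)].signal(bvalues)
    rng = np.random.default_rng(seed)
    return BValueCube(rician(clean, noise_sigma, rng), bvalues)


def make_bias_field(
    shape: tuple[int, int], amplitude: float, seed: int | None = 0
) -> np.ndarray:
    """A smooth quadratic multiplicative field with mean 1 and peak
    deviation exactly ``amplitude``."""
    if not 0 <= amplitude < 1:
        raise InvalidSpecError("bias amplitude must be in [0, 1)")
    h, w = shape
    if amplitude == 0:
        return np.ones(shape)
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]
    y = (yy - (h - 1) / 2) / max(h - 1, 1) * 2  # [-1, 1]
    x = (xx - (w - 1) / 2) / max(w - 1, 1) * 2
    terms = np.stack([y, x, y * x, y**2, x**2])
    coeffs = rng.uniform(-1, 1, terms.shape[0])
    p = np.tensordot(coeffs, terms, axes=1)
    p -= p.mean()
    peak = np.abs(p).max()
    if peak == 0:  # pragma: no cover - measure-zero draw
        return np.ones(shape)
    return 1.0 + amplitude * p / peak


def apply_bias_field(
    cube: BValueCube, bias_amplitude: float, seed: int | None = 0
) -> tuple[BValueCube, np.ndarray]:
    """Multiply every band by the same smooth field; returns (cube, field)."""
    fld = make_bias_field(cube.shape, bias_amplitude, seed)
    return BValueCube(cube.data * fld[:, :, None], cube.bvalues), fld


def apply_shifts(
    cube: BValueCube,
    shifts: list[tuple[int, int]],
    fill: float = 0.0,
    max_shift: int = 5,
) -> BValueCube:
    """Translate each band by integer (dy, dx); edges filled with ``fill``.

    The b=0 band is the registration reference and is forced to (0, 0).
    Shifts beyond ``max_shift`` are clipped with a warning.
    """
    import warnings

    if len(shifts) != cube.n_bands:
        raise InvalidSpecError(
            f"{len(shifts)} shifts for {cube.n_bands} bands"
        )
    out = np.empty_like(cube.data)
    for j, (dy, dx) in enumerate(shifts):
        if j == 0:
            dy = dx = 0
        if abs(dy) > max_shift or abs(dx) > max_shift:
            warnings.warn(
                f"band {j}: shift ({dy},{dx}) clipped to +/-{max_shift}", stacklevel=2
            )
            dy = int(np.clip(dy, -max_shift, max_shift))
            dx = int(np.clip(dx, -max_shift, max_shift))
        out[:, :, j] = translate(cube.band(j), dy, dx, fill)
    return BValueCube(out, cube.bvalues)


def translate(img: np.ndarray, dy: int, dx: int, fill: float = 0.0) -> np.ndarray:
    """Integer translation with constant fill (no wrap-around)."""
    h, w = img.shape
    out = np.full_like(img, fill)
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ys_src = slice(max(-dy, 0), min(h - dy, h))
    xs_src = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = img[ys_src, xs_src]
    return out


def generate_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Run the full simulator: label map -> signal -> noise -> bias -> shifts."""
    lesion_params = LESION_PRESETS.get(spec.lesion_class)
    if lesion_params is None:
        raise ConfigurationError(
            f"unknown lesion class {spec.lesion_class!r}; choose from {sorted(LESION_PRESETS)}"
        )
    labels = make_label_map(spec.shape, spec.lesion, spec.breast_region)
    params = {BACKGROUND: AIR, NORMAL: NORMAL_TISSUE, LESION: lesion_params}
    cube = simulate_cube(labels, params, spec.bvalues, spec.noise_sigma, spec.seed)
    bias = None
    if spec.bias_amplitude > 0:
        cube, bias = apply_bias_field(cube, spec.bias_amplitude, spec.seed + 1)
    if spec.shifts is not None:
        cube = apply_shifts(cube, spec.shifts)
    return PhantomOutput(
        cube=cube,
        labels=labels,
        truth_mask=labels == LESION,
        truth_params={p.name: p for p in params.values()},
        breast_region=spec.breast_region,
        bias_field=bias,
        shifts=spec.shifts,
    )


def default_shifts(
    n_bands: int, max_shift: int = 3, seed: int | None = 0
) -> list[tuple[int, int]]:
    """Random per-band breathing-drift translations; band 0 fixed at (0, 0)."""
    rng = np.random.default_rng(seed)
    shifts = [(0, 0)]
    for _ in range(n_bands - 1):
        shifts.append(tuple(int(v) for v in rng.integers(-max_shift, max_shift + 1, 2)))
    return shifts


def with_seed(spec: PhantomSpec, seed: int) -> PhantomSpec:
    return replace(spec, seed=seed)
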