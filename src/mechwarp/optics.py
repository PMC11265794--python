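"""Forward optical model of the layered elastic microcavity.

The sensing element is a Fabry-Perot microcavity: a soft, transparent
elastomer layer (8-12 um thick) sandwiched between two semi-transparent gold
mirrors on a glass support.  Local indentation changes the cavity length and
shifts the cavity resonances; everything downstream (ERISM thickness mapping,
WARP video-rate displacement mapping) reduces to reading those shifts back
out of reflectance images.

This module provides the forward model only: normal-incidence transfer-matrix
reflectance of an arbitrary layer stack, resonance-minimum extraction from a
sampled spectrum, thickness lookup tables, and the two-wavelength (WARP)
response.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "OpticalMaterial",
    "LayerStack",
    "SpectrumGrid",
    "ThicknessLookup",
    "InvalidMaterialError",
    "AmbiguityError",
    "default_materials",
    "default_stack",
    "compute_reflectance",
    "compute_reflectance_transmittance",
    "reflectance_spectrum",
    "find_resonance_minima",
    "build_thickness_lookup",
    "warp_response",
    "wavelength_pair_phase",
    "pair_within_same_fsr",
    "DEFAULT_LAMBDA_PAIR",
]

#: WARP illumination pair [nm]: a 633 nm line plus a second line detuned to
#: 628 nm by tilting an identical bandpass filter, chosen so the cavity
#: round-trip phase difference is ~90 degrees while staying inside one FSR.
DEFAULT_LAMBDA_PAIR = (633.0, 628.0)

_MIN_REAL_INDEX = 1e-6


class InvalidMaterialError(ValueError):
    """Refractive index is non-physical (real part below the positive bound)."""


class AmbiguityError(ValueError):
    """Requested sampling cannot uniquely resolve a cavity resonance order."""


@dataclass(frozen=True)
class OpticalMaterial:
    """A medium with a (possibly complex, dispersive) refractive index.

    ``index`` maps wavelength [nm] to a complex refractive index n + ik.
    Dielectrics have real part >= 1; metals may have a large imaginary part.
    """

    name: str
    index: Callable[[np.ndarray], np.ndarray]

    def __call__(self, wavelength_nm):
        n = np.asarray(self.index(np.asarray(wavelength_nm, dtype=float)), dtype=complex)
        if np.any(n.real < _MIN_REAL_INDEX):
            raise InvalidMaterialError(
                f"material {self.name!r}: refractive index real part < {_MIN_REAL_INDEX}"
            )
        return n

    @classmethod
    def constant(cls, name: str, n: float, k: float = 0.0) -> "OpticalMaterial":
        value = complex(n, k)
        if value.real < _MIN_REAL_INDEX:
            raise InvalidMaterialError(f"material {name!r}: real part must be positive")
        return cls(name, lambda wl, _v=value: np.full(np.shape(wl), _v, dtype=complex))

    @classmethod
    def from_table(
        cls, name: str, wavelength_nm: Sequence[float], n: Sequence[float], k: Sequence[float]
    ) -> "OpticalMaterial":
        """Tabulated dispersion, linearly interpolated in both n and k."""
        wl = np.asarray(wavelength_nm, dtype=float)
        nn = np.asarray(n, dtype=float)
        kk = np.asarray(k, dtype=float)
        if wl.ndim != 1 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength table must be strictly increasing")

        def _interp(q, _wl=wl, _n=nn, _k=kk):
            q = np.asarray(q, dtype=float)
            return np.interp(q, _wl, _n) + 1j * np.interp(q, _wl, _k)

        return cls(name, _interp)


def _load_table(resource: str) -> np.ndarray:
    ref = importlib.resources.files("mechwarp.data").joinpath(resource)
    with ref.open("rb") as fh:
        return np.loadtxt(fh, delimiter=",", skiprows=1)


def default_materials() -> dict[str, OpticalMaterial]:
    """Standard material set for the fabricated device.

    Metal dispersions are tabulated literature values (linearly interpolated);
    dielectrics use constant indices.  Absolute index accuracy only affects the
    absolute thickness scale -- the pipeline self-calibrates, so round trips are
    insensitive to it.  All values are overridable through the config layer.
    """
    au = _load_table("gold_n_k.csv")
    cr = _load_table("chromium_n_k.csv")
    return {
        "gold": OpticalMaterial.from_table("gold", au[:, 0], au[:, 1], au[:, 2]),
        "chromium": OpticalMaterial.from_table("chromium", cr[:, 0], cr[:, 1], cr[:, 2]),
        "sio2": OpticalMaterial.constant("sio2", 1.46),
        "elastomer": OpticalMaterial.constant("elastomer", 1.41),
        "glass": OpticalMaterial.constant("glass", 1.52),
        "water": OpticalMaterial.constant("water", 1.33),
    }


@dataclass(frozen=True)
class LayerStack:
    """Ordered optical description of the microcavity.

    ``ambient`` is the medium of incidence.  The device is illuminated in
    epi-configuration through the glass support, so for the default stack the
    ambient is glass and the exit medium (``substrate``) is the aqueous bath
    above the top mirror.  ``cavity_layer_index`` addresses the elastomer layer
    whose thickness varies with indentation.
    """

    ambient: OpticalMaterial
    layers: tuple[tuple[OpticalMaterial, float], ...]
    substrate: OpticalMaterial
    cavity_layer_index: int

    def __post_init__(self):
        if not self.layers:
            raise ValueError("stack needs at least one layer")
        for mat, d in self.layers:
            if d <= 0:
                raise ValueError(f"layer {mat.name!r}: thickness must be > 0 nm")
        if not 0 <= self.cavity_layer_index < len(self.layers):
            raise ValueError("cavity_layer_index out of range")

    @property
    def cavity_material(self) -> OpticalMaterial:
        return self.layers[self.cavity_layer_index][0]

    def cavity_index(self, wavelength_nm: float) -> complex:
        return complex(self.cavity_material(wavelength_nm))

    def with_cavity_length(self, cavity_length_nm: float) -> "LayerStack":
        layers = list(self.layers)
        mat, _ = layers[self.cavity_layer_index]
        layers[self.cavity_layer_index] = (mat, float(cavity_length_nm))
        return LayerStack(self.ambient, tuple(layers), self.substrate, self.cavity_layer_index)


def default_stack(materials: dict[str, OpticalMaterial] | None = None) -> LayerStack:
    """The fabricated device: glass / Cr 0.5 / Au 10 / SiO2 50 / elastomer / Au 15 / water.

    The elastomer thickness stored here (9000 nm) is a placeholder; every
    forward computation takes the cavity length as an explicit argument.
    """
    m = materials or default_materials()
    return LayerStack(
        ambient=m["glass"],
        layers=(
            (m["chromium"], 0.5),
            (m["gold"], 10.0),
            (m["sio2"], 50.0),
            (m["elastomer"], 9000.0),
            (m["gold"], 15.0),
        ),
        substrate=m["water"],
        cavity_layer_index=3,
    )


@dataclass(frozen=True)
class SpectrumGrid:
    """Strictly increasing wavelength sampling [nm]. Default: 550-750 nm, 1 nm."""

    wavelengths: np.ndarray = field(
        default_factory=lambda: np.arange(550.0, 750.0 + 0.5, 1.0)
    )

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be a strictly increasing 1-D sequence")
        object.__setattr__(self, "wavelengths", wl)

    def __len__(self) -> int:
        return self.wavelengths.size


# ---------------------------------------------------------------------------
# transfer-matrix core


def _characteristic(stack: LayerStack, wavelength_nm: float, cavity_length_nm):
    """Characteristic-matrix elements (B, C) of the full stack at normal incidence.

    ``cavity_length_nm`` may be an ndarray; the returned B, C broadcast with it.
    """
    wl = float(wavelength_nm)
    if wl <= 0:
        raise ValueError("wavelength must be > 0 nm")
    L = np.asarray(cavity_length_nm, dtype=float)
    if np.any(L <= 0):
        raise ValueError("cavity length must be > 0 nm")

    # materials supply n + ik; the characteristic-matrix formulae below follow
    # the n - ik (Macleod) convention, so conjugate on entry
    eta0 = np.conj(complex(stack.ambient(wl)))
    etas = np.conj(complex(stack.substrate(wl)))

    # running product of layer matrices applied to the substrate vector (1, eta_s)
    b = np.ones_like(L, dtype=complex) if L.ndim else np.array(1.0 + 0j)
    c = np.full_like(b, etas)
    for i in reversed(range(len(stack.layers))):
        mat, d = stack.layers[i]
        eta = np.conj(complex(mat(wl)))
        thick = L if i == stack.cavity_layer_index else d
        delta = 2.0 * np.pi * eta * thick / wl
        cd, sd = np.cos(delta), np.sin(delta)
        b, c = cd * b + 1j * sd / eta * c, 1j * eta * sd * b + cd * c
    return eta0, etas, b, c


def compute_reflectance(stack: LayerStack, wavelength_nm: float, cavity_length_nm):
    """Reflected intensity fraction of the stack at normal incidence.

    ``cavity_length_nm`` may be a scalar or an ndarray (pixelwise evaluation);
    the result has the same shape.
    """
    eta0, _, b, c = _characteristic(stack, wavelength_nm, cavity_length_nm)
    r = (eta0 * b - c) / (eta0 * b + c)
    out = np.abs(r) ** 2
    return float(out) if out.ndim == 0 else out


def compute_reflectance_transmittance(stack: LayerStack, wavelength_nm: float, cavity_length_nm):
    """(R, T) pair; for all-lossless stacks R + T = 1 to numerical tolerance."""
    eta0, etas, b, c = _characteristic(stack, wavelength_nm, cavity_length_nm)
    denom = eta0 * b + c
    r = (eta0 * b - c) / denom
    R = np.abs(r) ** 2
    T = 4.0 * eta0.real * etas.real / np.abs(denom) ** 2
    if R.ndim == 0:
        return float(R), float(T)
    return R, T


def reflectance_spectrum(stack: LayerStack, grid: SpectrumGrid, cavity_length_nm):
    """Reflectance sampled on a wavelength grid.

    Returns shape ``(n_wavelengths,) + shape(cavity_length_nm)``.
    """
    L = np.asarray(cavity_length_nm, dtype=float)
    out = np.empty((len(grid),) + L.shape, dtype=float)
    for i, wl in enumerate(grid.wavelengths):
        out[i] = compute_reflectance(stack, wl, L)
    return out


# ---------------------------------------------------------------------------
# resonance minima


def find_resonance_minima(spectrum) -> np.ndarray:
    """Sub-grid resonance-minimum wavelengths of a sampled reflection spectrum.

    ``spectrum`` is a sequence of (wavelength, reflectance) pairs or a pair of
    arrays.  Interior local minima are refined by 3-point parabolic
    interpolation; plateau ties break toward the shorter wavelength; boundary
    samples are never reported.  Returns a sorted (possibly empty) array [nm].
    """
    arr = np.asarray(spectrum, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 2:
        wl, r = arr[:, 0], arr[:, 1]
    elif arr.ndim == 2 and arr.shape[0] == 2:
        wl, r = arr[0], arr[1]
    else:
        raise ValueError("spectrum must be pairs of (wavelength, reflectance)")
    if wl.size < 3:
        raise ValueError("need at least 3 samples")
    if np.any(np.diff(wl) <= 0):
        raise ValueError("wavelengths must be strictly increasing")
    return _minima_1d(wl, r)


def _minima_mask(r: np.ndarray) -> np.ndarray:
    """Boolean mask of interior local minima along the last axis.

    Strict descent from the left, non-strict on the right, so a flat plateau
    is credited to its shortest-wavelength sample.
    """
    mask = np.zeros(r.shape, dtype=bool)
    mask[..., 1:-1] = (r[..., 1:-1] < r[..., :-2]) & (r[..., 1:-1] <= r[..., 2:])
    return mask


_XI5 = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
_VAND5_INV = np.linalg.inv(np.vander(_XI5, 5, increasing=True))


def _refine_minima(wl: np.ndarray, sample, idx: np.ndarray) -> np.ndarray:
    """Sub-grid minimum positions around grid indices ``idx``.

    ``sample(o)`` returns the reflectance at index offset ``o`` for every
    candidate.  A 3-point parabola seeds the estimate; where a 5-point window
    exists, the exact quartic through it is polished by Newton iterations,
    which removes the parabola's bias on asymmetric resonance dips.
    """
    y0, y1, y2 = sample(-1), sample(0), sample(1)
    denom = y0 - 2.0 * y1 + y2
    shift = np.where(np.abs(denom) > 0, 0.5 * (y0 - y2) / np.where(denom == 0, 1.0, denom), 0.0)
    shift = np.clip(shift, -0.5, 0.5)
    interior = (idx >= 2) & (idx <= wl.size - 3)
    if np.any(interior):
        Y = np.stack([sample(o) for o in (-2, -1, 0, 1, 2)], axis=-1)[interior]
        c = Y @ _VAND5_INV.T  # quartic coefficients in local grid units
        x = shift[interior]
        for _ in range(6):
            p1 = c[:, 1] + 2 * c[:, 2] * x + 3 * c[:, 3] * x**2 + 4 * c[:, 4] * x**3
            p2 = 2 * c[:, 2] + 6 * c[:, 3] * x + 12 * c[:, 4] * x**2
            x = np.clip(x - p1 / np.where(np.abs(p2) > 1e-300, p2, 1.0), -0.6, 0.6)
        refined = np.where(p2 > 0, x, shift[interior])
        out = shift.copy()
        out[interior] = refined
        shift = out
    # local grid spacing (uniform grids dominate; use midpoint spacing otherwise)
    step = 0.5 * (wl[np.minimum(idx + 1, wl.size - 1)] - wl[np.maximum(idx - 1, 0)])
    return wl[idx] + shift * step


def _minima_1d(wl: np.ndarray, r: np.ndarray) -> np.ndarray:
    idx = np.nonzero(_minima_mask(r))[0]
    if idx.size == 0:
        return np.empty(0)
    return np.sort(_refine_minima(wl, lambda o: r[np.clip(idx + o, 0, r.size - 1)], idx))


# ---------------------------------------------------------------------------
# thickness lookup


@dataclass(frozen=True)
class ThicknessLookup:
    """Modelled resonance minima and WARP response tabulated over thickness.

    ``minima_padded`` is (n_thickness, max_minima) with NaN padding;
    ``warp_response`` is the two-wavelength ratio W(L) on the same grid.
    """

    thickness_grid: np.ndarray
    minima_padded: np.ndarray
    warp_response: np.ndarray
    grid: SpectrumGrid
    stack: LayerStack
    lambda_pair: tuple[float, float]

    @property
    def minima_positions(self) -> list[np.ndarray]:
        return [row[~np.isnan(row)] for row in self.minima_padded]

    @property
    def step_nm(self) -> float:
        return float(self.thickness_grid[1] - self.thickness_grid[0])

    def fsr_nm(self, reference_wavelength_nm: float | None = None) -> float:
        """Free spectral range expressed as a thickness interval [nm]."""
        wl = reference_wavelength_nm or 0.5 * (self.lambda_pair[0] + self.lambda_pair[1])
        n = self.stack.cavity_index(wl).real
        return wl / (2.0 * n)


def build_thickness_lookup(
    stack: LayerStack,
    grid: SpectrumGrid,
    thickness_range: tuple[float, float] = (8000.0, 12000.0),
    step: float = 1.0,
    lambda_pair: tuple[float, float] = DEFAULT_LAMBDA_PAIR,
) -> ThicknessLookup:
    """Tabulate modelled resonance minima and WARP response over cavity thickness.

    ``step`` must resolve one free spectral range of thickness, otherwise the
    resonance order would alias between rows (AmbiguityError).
    """
    lo, hi = map(float, thickness_range)
    if not lo < hi:
        raise ValueError("thickness_range must satisfy lo < hi")
    if step <= 0:
        raise ValueError("step must be > 0")
    wl_min = float(grid.wavelengths[0])
    fsr_thickness = wl_min / (2.0 * stack.cavity_index(wl_min).real)
    if step > fsr_thickness:
        raise AmbiguityError(
            f"step {step} nm exceeds one thickness free spectral range ({fsr_thickness:.1f} nm)"
        )
    thickness = np.arange(lo, hi + 0.5 * step, step)

    spectra = reflectance_spectrum(stack, grid, thickness)  # (n_wl, n_thick)
    r = spectra.T  # (n_thick, n_wl)
    mask = _minima_mask(r)
    counts = mask.sum(axis=1)
    max_m = int(counts.max())
    padded = np.full((thickness.size, max_m), np.nan)
    rows, cols = np.nonzero(mask)
    n_wl = grid.wavelengths.size
    refined = _refine_minima(
        grid.wavelengths, lambda o: r[rows, np.clip(cols + o, 0, n_wl - 1)], cols
    )
    # scatter into padded array, per-row running position
    pos = np.concatenate([np.arange(c) for c in counts]) if rows.size else np.empty(0, int)
    padded[rows, pos] = refined
    padded.sort(axis=1)  # NaNs go last

    w = warp_response(stack, thickness, lambda_pair)
    return ThicknessLookup(thickness, padded, w, grid, stack, tuple(lambda_pair))


# ---------------------------------------------------------------------------
# two-wavelength (WARP) response and phase design


def warp_response(stack: LayerStack, cavity_length_nm, lambda_pair=DEFAULT_LAMBDA_PAIR):
    """Modelled WARP ratio W = (R_l1 - R_l2) / (R_l1 + R_l2) at a cavity length."""
    r1 = compute_reflectance(stack, lambda_pair[0], cavity_length_nm)
    r2 = compute_reflectance(stack, lambda_pair[1], cavity_length_nm)
    return (r1 - r2) / (r1 + r2)


def wavelength_pair_phase(
    cavity_length_nm: float, index: float, lambda_1: float, lambda_2: float
) -> float:
    """|round-trip phase difference| of the wavelength pair, in degrees.

    Delta phi = 4 pi n L (1/lambda_2 - 1/lambda_1).
    """
    if min(cavity_length_nm, index, lambda_1, lambda_2) <= 0:
        raise ValueError("all arguments must be > 0")
    dphi = 4.0 * np.pi * index * cavity_length_nm * (1.0 / lambda_2 - 1.0 / lambda_1)
    return float(abs(np.degrees(dphi)))


def pair_within_same_fsr(
    cavity_length_nm: float, index: float, lambda_1: float, lambda_2: float
) -> bool:
    """Design check: the pair stays within the same free spectral range band
    when the round-trip phase difference is below one full order (360 deg)."""
    return wavelength_pair_phase(cavity_length_nm, index, lambda_1, lambda_2) < 360.0
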