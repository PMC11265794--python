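"""Displacement-to-stress inversion and substrate stiffness calibration.

The microcavity's elastomer behaves as a linear elastic layer of finite
thickness h bonded to a rigid support (the glass/mirror base).  For a normal
surface traction with in-plane wavevector q, the surface normal displacement
response is diagonal in the Fourier domain:

    u_z(q) = C(q) sigma_z(q),
    C(q)   = 2 (1 - nu^2) / (E q) * g(q h, nu)

with the bonded-layer factor (plane-strain Airy solution, layer clamped at
z = h)

    g(x) = [(3-4nu) - 4x e^{-2x} + (4nu-3) e^{-4x}]
           / [(3-4nu) + (4x^2 + 16nu^2 - 24nu + 10) e^{-2x} + (3-4nu) e^{-4x}]

which tends to 1 for qh -> inf (Boussinesq half-space) and gives the confined
compression compliance C(0) = h (1+nu)(1-2nu) / (E (1-nu)) at q = 0.  Stress
maps are recovered by Tikhonov-regularised Fourier division; ground reaction
forces, contact areas and displaced volumes are integrals over contact ROIs.

Substrate stiffness itself is calibrated from AFM force-distance curves with
a spherical probe, using the Hertz force law with the finite-thickness
correction for a bonded, incompressible sample (Dimitriadis-type polynomial
in chi = sqrt(R delta)/h).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage, optimize

from .erism import DisplacementMap

__all__ = [
    "SubstrateMechanics",
    "StressMap",
    "ForceDistanceCurve",
    "HertzFitResult",
    "layer_compliance",
    "stress_from_displacement",
    "displacement_from_stress",
    "integrate_grf",
    "displaced_volume",
    "contact_area",
    "hertz_force_bonded",
    "fit_hertz_height_corrected",
    "fit_grf_area_polynomial",
]

# bonded incompressible thin-sample correction coefficients (chi, chi^2, ...)
_BONDED_COEFFS = (1.133, 1.497, 1.469, 0.755)


@dataclass(frozen=True)
class SubstrateMechanics:
    """Mechanical description of the elastomer layer."""

    youngs_modulus: float  # Pa
    poisson_ratio: float = 0.495  # near-incompressible siloxane elastomer
    layer_thickness: float = 10000.0  # nm
    pixel_size: float = 1.0  # um / pixel

    def __post_init__(self):
        if self.youngs_modulus <= 0:
            raise ValueError("youngs_modulus must be > 0")
        if not 0 <= self.poisson_ratio < 0.5:
            raise ValueError("poisson_ratio must be in [0, 0.5)")
        if self.layer_thickness <= 0 or self.pixel_size <= 0:
            raise ValueError("layer_thickness and pixel_size must be > 0")


@dataclass(frozen=True)
class StressMap:
    """Vertical stress [Pa]; negative = pushing into the substrate."""

    values: np.ndarray
    pixel_size: float
    valid: np.ndarray


@dataclass(frozen=True)
class ForceDistanceCurve:
    """AFM indentation curve: indentation [nm] vs force [nN]."""

    indentation: np.ndarray
    force: np.ndarray
    probe_radius: float  # um
    sample_thickness: float  # um

    def __post_init__(self):
        d = np.asarray(self.indentation, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if d.shape != f.shape or d.ndim != 1:
            raise ValueError("indentation and force must be matching 1-D arrays")
        if np.any(np.diff(d) < 0):
            raise ValueError("indentation must be monotone non-decreasing")
        if self.probe_radius <= 0 or self.sample_thickness <= 0:
            raise ValueError("probe_radius and sample_thickness must be > 0")
        object.__setattr__(self, "indentation", d)
        object.__setattr__(self, "force", f)


# ---------------------------------------------------------------------------
# layer response and Fourier inversion


def layer_compliance(q, youngs_modulus, poisson_ratio, thickness_m):
    """Normal-load surface compliance C(q) [m/Pa] of a bonded elastic layer.

    ``q`` in rad/m, ``thickness_m`` in m.  Vectorised over q; the q = 0 entry
    returns the confined (oedometer) compliance h(1+nu)(1-2nu)/(E(1-nu)).
    """
    q = np.asarray(q, dtype=float)
    E, nu, h = youngs_modulus, poisson_ratio, thickness_m
    x = q * h
    c34 = 3.0 - 4.0 * nu
    with np.errstate(divide="ignore", invalid="ignore"):
        e2 = np.exp(-2.0 * np.clip(x, 0, 350.0))
        e4 = e2 * e2
        num = c34 - 4.0 * x * e2 - c34 * e4
        den = c34 + (4.0 * x * x + 16.0 * nu * nu - 24.0 * nu + 10.0) * e2 + c34 * e4
        g = num / den
        C = 2.0 * (1.0 - nu * nu) / (E * q) * g
    # small-x series avoids cancellation; exact value at q = 0
    small = x < 1e-4
    if np.any(small):
        g_lin = (0.5 - nu) / (1.0 - nu) ** 2
        C = np.where(small, 2.0 * (1.0 - nu * nu) * h * g_lin / E, C)
    return C


def _fourier_kernel(shape, mech: SubstrateMechanics):
    px = mech.pixel_size * 1e-6
    qy = 2.0 * np.pi * np.fft.fftfreq(shape[0], d=px)
    qx = 2.0 * np.pi * np.fft.fftfreq(shape[1], d=px)
    q = np.hypot(qy[:, None], qx[None, :])
    return layer_compliance(q, mech.youngs_modulus, mech.poisson_ratio, mech.layer_thickness * 1e-9)


def _padded_shape(shape):
    from scipy.fft import next_fast_len

    return tuple(next_fast_len(2 * s) for s in shape)


def displacement_from_stress(stress_pa: np.ndarray, mech: SubstrateMechanics) -> np.ndarray:
    """Forward model: surface displacement [nm] produced by a stress map [Pa]."""
    s = np.asarray(stress_pa, dtype=float)
    ps = _padded_shape(s.shape)
    pad = np.zeros(ps)
    pad[: s.shape[0], : s.shape[1]] = s
    C = _fourier_kernel(ps, mech)
    u = np.fft.ifft2(np.fft.fft2(pad) * C).real[: s.shape[0], : s.shape[1]]
    return u * 1e9  # m -> nm


def stress_from_displacement(
    d: DisplacementMap,
    mech: SubstrateMechanics,
    regularisation: float = 1e-3,
    infill_masked: bool = True,
) -> StressMap:
    """Invert a displacement map into a vertical stress map [Pa].

    Tikhonov-regularised Fourier division against the bonded-layer response:
    sigma(q) = C(q) u(q) / (C(q)^2 + alpha^2) with alpha = regularisation *
    max C.  ``regularisation`` is therefore a dimensionless damping relative to
    the softest (longest-wavelength) mode; raise it for noisy maps.
    """
    if regularisation <= 0:
        raise ValueError("regularisation must be > 0")
    if min(d.values.shape) < 16:
        raise ValueError("analysis window must be at least 16x16 pixels")
    u = np.asarray(d.values, dtype=float) * 1e-9  # nm -> m
    if not d.valid.all():
        if not infill_masked:
            raise ValueError("displacement map has masked pixels; in-fill or crop first")
        _, (ir, ic) = ndimage.distance_transform_edt(~d.valid, return_indices=True)
        u = u[ir, ic]
    ps = _padded_shape(u.shape)
    pad = np.zeros(ps)
    pad[: u.shape[0], : u.shape[1]] = u
    C = _fourier_kernel(ps, mech)
    alpha = regularisation * float(np.max(C))
    sigma = np.fft.ifft2(np.fft.fft2(pad) * C / (C * C + alpha * alpha)).real
    sigma = sigma[: u.shape[0], : u.shape[1]]
    # windowing the displacement field biases the near-DC modes (the layer's
    # long-range surface bulge is cut off), which shows up as a uniform
    # stress background; the median removes it robustly because the true
    # stress map is zero outside sparse contact regions
    sigma -= np.median(sigma)
    return StressMap(sigma, d.pixel_size, d.valid.copy())


# ---------------------------------------------------------------------------
# ROI integrals


def _roi_mask(values: np.ndarray, roi) -> np.ndarray:
    if roi is None:
        return np.ones(values.shape, dtype=bool)
    m = np.asarray(roi, dtype=bool)
    if m.shape != values.shape:
        raise ValueError("ROI mask shape must match the map")
    return m


def integrate_grf(s: StressMap, roi=None) -> float:
    """Ground reaction force [nN]: |integral of negative stress| over the ROI."""
    m = _roi_mask(s.values, roi)
    if not m.any():
        warnings.warn("empty ROI; GRF = 0", stacklevel=2)
        return 0.0
    pixel_area_m2 = (s.pixel_size * 1e-6) ** 2
    load = np.minimum(s.values[m], 0.0).sum() * pixel_area_m2  # N (negative)
    return float(abs(load) * 1e9)


def displaced_volume(d: DisplacementMap, roi=None) -> float:
    """Indented volume [um^3]: integral of max(0, -displacement) over the ROI."""
    m = _roi_mask(d.values, roi)
    depth_nm = np.maximum(0.0, -d.values[m]).sum()
    return float(depth_nm * 1e-3 * d.pixel_size**2)  # nm*um^2 -> um^3


def contact_area(d: DisplacementMap, roi=None, threshold: float = 0.0):
    """Contact area [um^2] and mask: pixels indented below ``threshold`` [nm]."""
    if threshold > 0:
        raise ValueError("threshold must be <= 0 nm")
    m = _roi_mask(d.values, roi)
    contact = m & (d.values < threshold) & d.valid
    return float(contact.sum() * d.pixel_size**2), contact


# ---------------------------------------------------------------------------
# height-corrected Hertz fit


def hertz_force_bonded(
    indentation_nm,
    youngs_modulus_pa: float,
    probe_radius_um: float,
    sample_thickness_um: float,
) -> np.ndarray:
    """Spherical-indenter force [nN] on a bonded, incompressible finite layer.

    F = (16/9) E sqrt(R) delta^{3/2} (1 + 1.133 chi + 1.497 chi^2
        + 1.469 chi^3 + 0.755 chi^4),   chi = sqrt(R delta) / h.

    The prefactor is the classical Hertz force for nu = 1/2; the polynomial is
    the bonded thin-sample correction, valid to chi ~ 3.
    """
    delta = np.maximum(np.asarray(indentation_nm, dtype=float), 0.0) * 1e-9
    R = probe_radius_um * 1e-6
    h = sample_thickness_um * 1e-6
    chi = np.sqrt(R * delta) / h
    corr = 1.0 + sum(c * chi ** (i + 1) for i, c in enumerate(_BONDED_COEFFS))
    force_n = (16.0 / 9.0) * youngs_modulus_pa * np.sqrt(R) * delta**1.5 * corr
    return force_n * 1e9


class HertzFitResult(NamedTuple):
    youngs_modulus: float  # Pa
    contact_point: float  # nm (shift of the contact point along the ramp)
    r_squared: float
    chi_max: float


class HertzFitError(RuntimeError):
    """The height-corrected Hertz fit failed to converge."""


def fit_hertz_height_corrected(curve: ForceDistanceCurve) -> HertzFitResult:
    """Least-squares fit of the height-corrected Hertz model to an AFM curve.

    Young's modulus and the contact point are fitted jointly.  Emits a warning
    when the correction leaves its validity range (chi > 3).
    """
    z = curve.indentation
    f = curve.force
    if z.size < 20:
        raise ValueError("need at least 20 samples past contact")

    def model(zz, E, z0):
        return hertz_force_bonded(zz - z0, E, curve.probe_radius, curve.sample_thickness)

    # initial guesses: contact point at first positive force, E from the endpoint
    pos = np.nonzero(f > 0.05 * f.max())[0]
    z0_init = z[pos[0]] if pos.size else z[0]
    delta_end = max(z[-1] - z0_init, 1.0)
    f_end = max(f[-1], 1e-6)
    E_init = f_end / max(
        hertz_force_bonded(delta_end, 1.0, curve.probe_radius, curve.sample_thickness), 1e-30
    )
    try:
        popt, _ = optimize.curve_fit(
            model, z, f, p0=[E_init, z0_init], maxfev=10000,
            bounds=([1e-3, z[0] - (z[-1] - z[0])], [1e12, z[-1]]),
        )
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - diagnostics path
        raise HertzFitError(
            f"Hertz fit did not converge (E_init={E_init:.3g} Pa, z0_init={z0_init:.3g} nm)"
        ) from exc
    E_hat, z0_hat = float(popt[0]), float(popt[1])
    resid = f - model(z, *popt)
    ss_tot = float(((f - f.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    delta_max = max(z[-1] - z0_hat, 0.0) * 1e-9
    chi_max = float(
        np.sqrt(curve.probe_radius * 1e-6 * delta_max) / (curve.sample_thickness * 1e-6)
    )
    if chi_max > 3.0:
        warnings.warn(
            f"chi = {chi_max:.2f} exceeds the validity of the thin-sample correction",
            stacklevel=2,
        )
    return HertzFitResult(E_hat, z0_hat, r2, chi_max)


# ---------------------------------------------------------------------------
# GRF vs contact area


def fit_grf_area_polynomial(series) -> tuple[np.ndarray, float]:
    """OLS second-order polynomial GRF = a2 area^2 + a1 area + a0.

    Returns (coefficients highest-first, adjusted R^2 with the usual n, p
    correction for p = 2 predictors).
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("series must be (area, grf) pairs")
    x, y = arr[:, 0], arr[:, 1]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 points")
    if np.unique(x).size < 3:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    coeffs = np.polyfit(x, y, 2)
    resid = y - np.polyval(coeffs, x)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    p = 2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return coeffs, float(adj)
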