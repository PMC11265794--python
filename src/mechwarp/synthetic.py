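"""Ground-truth generator for the whole pipeline.

Simulates a soft-bodied peristaltic crawler on the elastic microcavity:
segmentally repeating protopodia indent the substrate with Hertz-type
axisymmetric profiles whose depth follows a programmed footfall cycle (stance,
swing initiation, swing, swing termination).  Landings spread posterior-first
along the anteroposterior axis and midline-first along the mediolateral axis
with programmed per-row delays; a transient tripod contact precedes each wave
at the posterior terminus, and an optional positive-displacement annulus
emulates the water droplet carried by the animal.

The simulator emits internally consistent ground truth (thickness and
displacement series, per-frame per-protopodium GRF / contact area / displaced
volume computed by direct summation over the truth maps, and an event table),
plus forward-rendered raw interference stacks (spectral or two-wavelength
mode), synthetic AFM force-distance curves and synthetic landmark track
tables.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .erism import SpectralStack
from .kinematics import TrackTable, WaveAnnotation
from .mechanics import ForceDistanceCurve, hertz_force_bonded
from .optics import DEFAULT_LAMBDA_PAIR, LayerStack, SpectrumGrid, compute_reflectance
from .warp import InterleavedStack

__all__ = [
    "CrawlScenario",
    "GroundTruthBundle",
    "ScenarioError",
    "simulate_crawl",
    "render_interference",
    "simulate_afm_curve",
    "simulate_tracks",
    "simulate_grf_area_points",
    "hertz_indentation_profile",
    "layer_indentation_profile",
    "scenario_waves",
]


class ScenarioError(ValueError):
    """The crawl scenario is geometrically or temporally inconsistent."""


@dataclass(frozen=True)
class CrawlScenario:
    """Parameters of a synthetic peristaltic crawl on the microcavity.

    Geometry is µm / nm; timing in seconds.  Defaults describe a ~1 mm larva
    imaged at x4 magnification on an E = 28 kPa cavity: six protopodia whose
    peak ground reaction forces land in the single-micronewton range, a
    ~1.2 s forward wave, posterior-first landing spread of a few tens of
    milliseconds per denticle row, and a tripod contact leading each wave by
    0.66 s.
    """

    n_protopodia: int = 6
    indenter_radius_um: float = 100.0  # effective Hertz sphere radius
    peak_depths_nm: tuple[float, ...] | None = None  # default: 1000..1400 ramp
    spacing_um: float = 30.0  # centre-to-centre along AP
    step_length_um: float = 6.0  # forward displacement per wave
    # series start: the animal settles onto the resting cavity first
    start_at_rest: bool = True
    settle_time_s: float = 0.05
    # wave timing
    wave_start_s: float = 0.9
    wave_duration_s: float = 1.2
    n_waves: int = 1
    wave_rest_s: float = 0.4
    direction: str = "forward"
    swing_fraction: float = 0.35  # swing period / wave duration
    release_time_s: float = 0.25  # lift-off ramp after SI
    landing_rise_s: float = 0.30  # local depth ramp after contact onset
    # sub-protopodial landing spread
    ap_landing_delay_s: float = 0.05  # per denticle row, posterior-first
    ap_row_spacing_um: float = 3.0
    ml_landing_delay_s: float = 0.03  # per ml_spacing_um from the midline
    ml_spacing_um: float = 3.0
    # programmed row latencies for the kinematic tracks
    si_latency_fraction: float = 0.10  # AP SI latency / wave duration
    st_latency_fraction: float = 0.05
    # tripod
    tripod_enabled: bool = True
    tripod_lead_s: float = 0.66  # tripod contact precedes A7 swing initiation
    tripod_depth_nm: float = 500.0
    tripod_radius_um: float = 10.0
    tripod_offset_um: tuple[float, float] = (15.0, 14.0)  # posterior, lateral
    tripod_ramp_s: float = 0.2  # deploy / detach ramp
    timing_jitter_s: float = 0.0  # jitter of tripod contact times
    # water droplet
    droplet_enabled: bool = False
    droplet_radius_um: float = 70.0
    droplet_amplitude_nm: float = 60.0
    droplet_width_um: float = 6.0
    # force law and truth definitions
    grf_area_law: tuple[float, float, float] | None = None  # nN vs um^2, high->low
    contact_threshold_nm: float = -20.0
    substrate_E_pa: float = 28000.0  # cavity stiffness the depths are tuned for
    # substrate / imaging
    rest_thickness_nm: float = 10000.0
    shape: tuple[int, int] = (128, 224)  # rows (ML) x cols (AP)
    pixel_size_um: float = 1.0
    map_rate: float = 60.0  # displacement maps / s
    intensity_noise: float = 0.0  # multiplicative, on rendered images
    displacement_jitter_nm: float = 0.0  # roughness added to rendered thickness
    seed: int = 0

    def __post_init__(self):
        if self.n_protopodia < 1:
            raise ScenarioError("need at least one protopodium")
        if self.direction not in ("forward", "backward"):
            raise ScenarioError("direction must be 'forward' or 'backward'")
        for name in ("indenter_radius_um", "spacing_um", "wave_duration_s", "map_rate",
                     "pixel_size_um", "rest_thickness_nm"):
            if getattr(self, name) <= 0:
                raise ScenarioError(f"{name} must be > 0")
        a_max = np.sqrt(self.indenter_radius_um * max(self.depths) * 1e-3)
        if self.n_protopodia > 1 and self.spacing_um < 2 * a_max + self.step_length_um:
            raise ScenarioError(
                f"protopodia overlap: spacing {self.spacing_um} um < "
                f"2 x contact radius ({a_max:.1f} um) + step ({self.step_length_um} um)"
            )
        # a landing (or the initial settle) must finish before the next
        # lift-off, otherwise the programmed depth field would jump
        landing_span = (
            self.landing_rise_s
            + self.ap_landing_delay_s * 2.0 * a_max / self.ap_row_spacing_um
            + self.ml_landing_delay_s * a_max / self.ml_spacing_um
        )
        if self.start_at_rest and self.wave_start_s < self.settle_time_s + landing_span:
            raise ScenarioError(
                f"wave_start_s={self.wave_start_s} s is before the initial settling "
                f"completes ({self.settle_time_s + landing_span:.2f} s)"
            )
        if self.n_waves > 1:
            gap = (1.0 + self.wave_rest_s / self.wave_duration_s - self.swing_fraction)
            if gap * self.wave_duration_s < landing_span:
                raise ScenarioError("waves overlap: landing does not finish before the next lift")

    @property
    def depths(self) -> np.ndarray:
        if self.peak_depths_nm is not None:
            d = np.asarray(self.peak_depths_nm, dtype=float)
            if d.size != self.n_protopodia:
                raise ScenarioError("peak_depths_nm length must equal n_protopodia")
            return d
        if self.n_protopodia == 1:
            return np.array([1000.0])
        return np.linspace(1000.0, 1400.0, self.n_protopodia)

    @property
    def centres(self) -> np.ndarray:
        """Initial (x, y) centres [um], index 0 = most posterior."""
        h, w = self.shape
        x0 = 0.5 * (w * self.pixel_size_um - (self.n_protopodia - 1) * self.spacing_um
                    - self.n_waves * self.step_length_um)
        x = x0 + np.arange(self.n_protopodia) * self.spacing_um
        y = np.full(self.n_protopodia, 0.5 * h * self.pixel_size_um)
        return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# programmed timings


def scenario_waves(sc: CrawlScenario) -> list[dict]:
    """Programmed per-wave timings: SI/ST per protopodium and tripod contact.

    SI is lift-off (movement begins), ST is swing termination = contact onset
    of the posterior row at the new position.
    """
    n = sc.n_protopodia
    swing = sc.swing_fraction * sc.wave_duration_s
    delta = (
        (1.0 - sc.swing_fraction) * sc.wave_duration_s / max(n - 1, 1)
    )
    waves = []
    for w in range(sc.n_waves):
        start = sc.wave_start_s + w * (sc.wave_duration_s + sc.wave_rest_s)
        order = np.arange(n) if sc.direction == "forward" else np.arange(n)[::-1]
        si = np.empty(n)
        si[order] = start + np.arange(n) * delta
        st = si + swing
        a7 = 1 if n > 1 else 0  # segment leading the wave after the terminal one
        waves.append(
            {
                "wave_id": w,
                "start": start,
                "duration": sc.wave_duration_s,
                "si": si,
                "st": st,
                "tripod_contact": si[a7] - sc.tripod_lead_s,
            }
        )
    return waves


# ---------------------------------------------------------------------------
# indentation profile


def hertz_indentation_profile(
    r_um, depth_nm: float, indenter_radius_um: float, taper_width_um: float = 3.0
) -> np.ndarray:
    """Surface displacement [nm] of a rigid sphere pressed into the substrate.

    Inside the contact circle (a = sqrt(R delta)) the classical Hertz
    half-space profile delta - r^2/(2R); outside, the analytic decay
    (1/pi)[(2 delta - r^2/R) asin(a/r) + a sqrt(r^2-a^2)/R], multiplied by a
    Gaussian taper of width ``taper_width_um`` (hard zero beyond 3 widths)
    that emulates the localisation of a thin bonded layer.  Negative values =
    indentation.
    """
    r = np.asarray(r_um, dtype=float)
    delta_um = depth_nm * 1e-3
    if delta_um <= 0:
        return np.zeros_like(r)
    R = indenter_radius_um
    a = np.sqrt(R * delta_um)
    u = np.empty_like(r)
    inside = r <= a
    u[inside] = delta_um - r[inside] ** 2 / (2.0 * R)
    ro = np.maximum(r[~inside], a)
    u[~inside] = (
        (2.0 * delta_um - ro**2 / R) * np.arcsin(a / ro) + a * np.sqrt(ro**2 - a**2) / R
    ) / np.pi
    tail = np.maximum(r - a, 0.0)
    taper = np.where(tail < 3.0 * taper_width_um, np.exp(-((tail / taper_width_um) ** 2)), 0.0)
    return -u * taper * 1e3  # um -> nm, negative = indentation


_LAYER_PROFILE_CACHE: dict = {}


def layer_indentation_profile(
    depth_nm: float,
    indenter_radius_um: float,
    youngs_modulus_pa: float,
    layer_thickness_nm: float,
    sub_px_um: float = 0.5,
):
    """Radial displacement profile of a Hertz pressure patch on the bonded layer.

    The Hertzian contact pressure p0 sqrt(1 - r^2/a^2) (a = sqrt(R delta)) is
    pushed through the finite-thickness layer response by Hankel-transform
    quadrature -- the patch spectrum is closed form, P(q) = 2 pi p0 a^2
    (sin qa - qa cos qa)/(qa)^3 -- and the result is scaled so the peak
    indentation equals ``depth_nm``.  Returns (r_um grid, u_nm profile, total
    force in nN).  Using the layer's own response makes the simulated
    displacement, the truth stress and the inversion mutually consistent, and
    gives the physical upward ring around contacts (incompressible layer).
    Results are cached per parameter set.
    """
    from scipy.special import j0

    from .mechanics import layer_compliance

    key = (round(depth_nm, 6), indenter_radius_um, youngs_modulus_pa,
           layer_thickness_nm, sub_px_um)
    if key in _LAYER_PROFILE_CACHE:
        return _LAYER_PROFILE_CACHE[key]
    a_um = np.sqrt(indenter_radius_um * depth_nm * 1e-3)
    h_um = layer_thickness_nm * 1e-3
    reach = a_um + 3.0 * h_um
    a = a_um * 1e-6
    r = np.arange(0.0, reach + sub_px_um, sub_px_um) * 1e-6  # m
    q = np.linspace(1e-8, 60.0 / a, 6000)  # rad/m
    C = layer_compliance(q, youngs_modulus_pa, 0.495, layer_thickness_nm * 1e-9)
    qa = q * a
    spectrum = (np.sin(qa) - qa * np.cos(qa)) / qa**3  # patch shape transform
    kern = C * spectrum * q  # per unit p0, before the a^2 prefactor
    u = a**2 * np.trapezoid(kern[None, :] * j0(q[None, :] * r[:, None]), q, axis=1)
    # u is in m per Pa of peak pressure; scale so the peak equals depth_nm
    p0 = depth_nm * 1e-9 / max(u.max(), 1e-300)  # Pa (u > 0 = indentation here)
    u_nm = -u * p0 * 1e9
    force_nn = p0 * (2.0 / 3.0) * np.pi * a**2 * 1e9  # exact patch integral
    r_grid = r * 1e6
    u_nm[r_grid > reach] = 0.0
    out = (r_grid, u_nm, float(force_nn))
    _LAYER_PROFILE_CACHE[key] = out
    return out


# ---------------------------------------------------------------------------
# crawl simulation


@dataclass(frozen=True)
class GroundTruthBundle:
    """Everything the rest of the pipeline can be validated against.

    Truth GRF / contact area / displaced volume are direct summations over the
    truth stress / displacement maps within each protopodium ROI -- by
    definition, not via the inversion pipeline.
    """

    scenario: CrawlScenario
    times: np.ndarray  # (T,) s
    thickness: np.ndarray  # (T, H, W) nm
    displacement: np.ndarray  # (T, H, W) nm
    stress: np.ndarray  # (T, H, W) Pa
    rois: np.ndarray  # (P, H, W) bool
    grf: np.ndarray  # (T, P) nN
    area: np.ndarray  # (T, P) um^2
    volume: np.ndarray  # (T, P) um^3
    events: pd.DataFrame  # protopodium, wave_id, si_time, st_time
    tripod_contacts: np.ndarray  # (n_waves,) s
    waves: list = field(default_factory=list)  # kinematics.WaveAnnotation

    @property
    def pixel_size(self) -> float:
        return self.scenario.pixel_size_um


def _pressure_patch(rr_um: np.ndarray, a_um: float) -> np.ndarray:
    """Hertz pressure shape sqrt(1 - r^2/a^2), zero outside contact."""
    x = 1.0 - (rr_um / a_um) ** 2
    return np.sqrt(np.maximum(x, 0.0))


def _landing_onset(xx, yy, centre, a_um, st_time, sc: CrawlScenario, sign: float):
    """Per-pixel contact onset time: posterior-first along AP, midline-first ML.

    The delays grow across the contact disc only; the elastic skirt outside it
    follows the nearest contact row rather than acquiring delays of its own.
    """
    edge = centre[0] - sign * a_um  # posterior edge of the new footprint
    ap = np.clip(sign * (xx - edge), 0.0, 2.0 * a_um) * (
        sc.ap_landing_delay_s / sc.ap_row_spacing_um
    )
    ml = np.minimum(np.abs(yy - centre[1]), a_um) * (
        sc.ml_landing_delay_s / sc.ml_spacing_um
    )
    return st_time + ap + ml


def simulate_crawl(scenario: CrawlScenario) -> GroundTruthBundle:
    """Render the ground-truth thickness/displacement/stress series of a crawl."""
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    h, w = sc.shape
    px = sc.pixel_size_um
    n = sc.n_protopodia
    depths = sc.depths
    R = sc.indenter_radius_um
    a = np.sqrt(R * depths * 1e-3)  # contact radii, um
    centres = sc.centres
    sign = 1.0 if sc.direction == "forward" else -1.0
    step = sign * sc.step_length_um

    waves = scenario_waves(sc)
    if sc.timing_jitter_s > 0:
        for wv in waves:
            wv["tripod_contact"] += rng.normal(0.0, sc.timing_jitter_s)

    tail = sc.landing_rise_s + 2 * a.max() * sc.ap_landing_delay_s / sc.ap_row_spacing_um + 0.2
    t_end = waves[-1]["start"] + sc.wave_duration_s + tail
    n_frames = int(np.ceil(t_end * sc.map_rate))
    times = np.arange(n_frames) / sc.map_rate

    ygrid = (np.arange(h) + 0.5) * px
    xgrid = (np.arange(w) + 0.5) * px
    disp = np.zeros((n_frames, h, w), dtype=np.float32)
    stress = np.zeros((n_frames, h, w), dtype=np.float32)

    def window(centre, radius):
        r0 = max(int((centre[1] - radius) / px) - 1, 0)
        r1 = min(int((centre[1] + radius) / px) + 2, h)
        c0 = max(int((centre[0] - radius) / px) - 1, 0)
        c1 = min(int((centre[0] + radius) / px) + 2, w)
        return slice(r0, r1), slice(c0, c1)

    # Each indentation is the bonded layer's own (discrete-operator) response
    # to a Hertz pressure patch, so truth stress, truth displacement and the
    # downstream inversion are mutually consistent on stance frames.
    from .mechanics import SubstrateMechanics, displacement_from_stress

    h_um = sc.rest_thickness_nm * 1e-3
    mech_sub = SubstrateMechanics(sc.substrate_E_pa, 0.495, sc.rest_thickness_nm, px)
    field_cache: dict = {}

    def patch_fields(centre, depth, radius_um):
        """Global pressure [Pa] and displacement [nm] fields of one patch."""
        key = (round(centre[0], 3), round(centre[1], 3), round(depth, 3), radius_um)
        if key not in field_cache:
            a_loc = np.sqrt(radius_um * depth * 1e-3)
            rr = np.hypot(xgrid[None, :] - centre[0], ygrid[:, None] - centre[1])
            p = _pressure_patch(rr, a_loc)
            u_unit = displacement_from_stress(-p * 1000.0, mech_sub)  # nm per nN/um^2
            scale = depth / max(-u_unit.min(), 1e-12)
            field_cache[key] = (
                (p * scale * 1000.0).astype(np.float32),  # Pa
                (u_unit * scale).astype(np.float32),  # nm
                float(p.sum() * scale * px**2),  # nN
            )
        return field_cache[key]

    specs = {}
    for i in range(n):
        if depths[i] <= 0:
            continue
        specs[i] = {"a": a[i], "depth": depths[i], "R": R, "reach": a[i] + 3.0 * h_um}
    if sc.tripod_enabled:
        a_t = np.sqrt(sc.tripod_radius_um * sc.tripod_depth_nm * 1e-3)
        tripod_spec = {
            "a": a_t, "depth": sc.tripod_depth_nm, "R": sc.tripod_radius_um,
            "reach": a_t + 3.0 * h_um,
        }

    def add_patch(frame, centre, spec, factor):
        """Superpose one indentation patch; ``factor`` is a scalar or field
        (fields are defined on the patch window; the tiny tail beyond it is
        modulated by the window-mean factor)."""
        p_pa, u_nm, _F = patch_fields(centre, spec["depth"], spec["R"])
        rs, cs = window(centre, spec["reach"])
        if np.isscalar(factor) or np.ndim(factor) == 0:
            if factor <= 0:
                return
            disp[frame] += u_nm * np.float32(factor)
            stress[frame] -= p_pa * np.float32(factor)
            return
        disp[frame, rs, cs] += u_nm[rs, cs] * factor.astype(np.float32)
        stress[frame, rs, cs] -= p_pa[rs, cs] * factor.astype(np.float32)
        outside = np.float32(np.mean(factor))
        if outside > 0:
            tail = u_nm.copy()
            tail[rs, cs] = 0.0
            disp[frame] += tail * outside

    # footfall cycle: per frame each protopodium is in exactly one state
    # (stance -> lift after SI -> airborne -> landing from ST, which saturates
    # into the next stance)
    onset_cache: dict[tuple[int, int], tuple] = {}

    def landing_factor(i, key, centre, st_time, t):
        if key not in onset_cache:
            rs, cs = window(centre, specs[i]["reach"])
            onset_cache[key] = (
                rs,
                cs,
                _landing_onset(
                    xgrid[cs][None, :], ygrid[rs][:, None], centre, a[i], st_time, sc, sign
                ),
            )
        rs, cs, onset = onset_cache[key]
        return np.clip((t - onset) / sc.landing_rise_s, 0.0, 1.0)

    for i in range(n):
        if depths[i] <= 0:
            continue
        si_all = np.array([wv["si"][i] for wv in waves])
        st_all = np.array([wv["st"][i] for wv in waves])
        for f, t in enumerate(times):
            w_idx = int(np.searchsorted(si_all, t, side="right")) - 1
            if w_idx < 0:
                # before the first wave: settle onto the resting cavity (a
                # landing-style spread), then stance at the initial position
                if not sc.start_at_rest:
                    add_patch(f, centres[i], specs[i], 1.0)
                    continue
                factor = landing_factor(i, (i, -1), centres[i], sc.settle_time_s, t)
                if np.any(factor > 0):
                    add_patch(f, centres[i], specs[i], factor)
                continue
            pos_old = centres[i] + np.array([step * w_idx, 0.0])
            pos_new = pos_old + np.array([step, 0.0])
            if t < st_all[w_idx]:  # swing: lift ramp then airborne
                lift = 1.0 - (t - si_all[w_idx]) / sc.release_time_s
                if lift > 0:
                    add_patch(f, pos_old, specs[i], lift)
                continue
            factor = landing_factor(i, (i, w_idx), pos_new, st_all[w_idx], t)
            add_patch(f, pos_new, specs[i], factor)

    # tripod: two papillae beside the terminal protopodium
    tripod_contacts = np.array([wv["tripod_contact"] for wv in waves])
    if sc.tripod_enabled:
        dx, dy = sc.tripod_offset_um
        for wv in waves:
            base = centres[0] + np.array([step * wv["wave_id"], 0.0])
            pads = [base + np.array([-sign * dx, dy]), base + np.array([-sign * dx, -dy])]
            t_on = wv["tripod_contact"]
            t_off = wv["si"][0]
            ramp = sc.tripod_ramp_s
            for f, t in enumerate(times):
                if t_on <= t < t_off:
                    fac = min((t - t_on) / ramp, 1.0)
                elif t_off <= t < t_off + ramp:
                    fac = max(1.0 - (t - t_off) / ramp, 0.0)
                else:
                    continue
                for pad in pads:
                    add_patch(f, pad, tripod_spec, fac)

    if sc.droplet_enabled:
        cx, cy = 0.5 * w * px, 0.5 * h * px
        rr = np.hypot(xgrid[None, :] - cx, ygrid[:, None] - cy)
        ring = sc.droplet_amplitude_nm * np.exp(
            -(((rr - sc.droplet_radius_um) / sc.droplet_width_um) ** 2)
        )
        disp += ring.astype(np.float32)[None]

    # per-protopodium ROIs: AP strips centred between old and new footprints,
    # bounded in ML to ~2 contact radii (a wide-open ROI would pick up the
    # spread-out ringing of the downstream stress inversion)
    rois = np.zeros((n, h, w), dtype=bool)
    xx_pix = (np.arange(w) + 0.5) * px
    yy_pix = (np.arange(h) + 0.5) * px
    for i in range(n):
        lo = centres[i][0] - sc.spacing_um / 2 + step / 2
        hi = centres[i][0] + sc.spacing_um / 2 + step * (len(waves) - 0.5)
        lo, hi = min(lo, hi), max(lo, hi)
        half_ml = max(2.0 * a[i], 12.0) if depths[i] > 0 else sc.spacing_um / 2
        cols = (xx_pix >= lo) & (xx_pix < hi)
        rows = np.abs(yy_pix - centres[i][1]) <= half_ml
        rois[i][np.ix_(rows, cols)] = True

    # truth summaries by direct summation (definitionally the ground truth)
    grf = np.zeros((n_frames, n))
    area = np.zeros((n_frames, n))
    volume = np.zeros((n_frames, n))
    for i in range(n):
        m = rois[i]
        for f in range(n_frames):
            d = disp[f][m].astype(float)
            s = stress[f][m].astype(float)
            grf[f, i] = abs(np.minimum(s, 0.0).sum()) * (px * 1e-6) ** 2 * 1e9
            area[f, i] = np.count_nonzero(d < sc.contact_threshold_nm) * px**2
            volume[f, i] = np.maximum(-d, 0.0).sum() * 1e-3 * px**2

    # optional re-scaling of truth stress to a programmed GRF(area) law
    if sc.grf_area_law is not None:
        law = np.asarray(sc.grf_area_law, dtype=float)
        for i in range(n):
            m = rois[i]
            for f in range(n_frames):
                if grf[f, i] > 0:
                    target = float(np.polyval(law, area[f, i]))
                    stress[f][m] *= target / grf[f, i]
                    grf[f, i] = target

    events = pd.DataFrame(
        [
            {
                "protopodium": i,
                "wave_id": wv["wave_id"],
                "si_time": wv["si"][i],
                "st_time": wv["st"][i],
            }
            for wv in waves
            for i in range(n)
            if depths[i] > 0
        ],
        columns=["protopodium", "wave_id", "si_time", "st_time"],
    )
    annotations = [
        WaveAnnotation(wv["wave_id"], sc.direction, sc.wave_duration_s) for wv in waves
    ]

    thickness = sc.rest_thickness_nm + disp
    return GroundTruthBundle(
        scenario=sc,
        times=times,
        thickness=thickness,
        displacement=disp,
        stress=stress,
        rois=rois,
        grf=grf,
        area=area,
        volume=volume,
        events=events,
        tripod_contacts=tripod_contacts,
        waves=annotations,
    )


# ---------------------------------------------------------------------------
# raw interference rendering


def render_interference(
    thickness_nm: np.ndarray,
    stack: LayerStack,
    mode: str = "spectral",
    grid: SpectrumGrid | None = None,
    lambda_pair: tuple[float, float] = DEFAULT_LAMBDA_PAIR,
    noise_fraction: float = 0.0,
    seed: int | None = None,
    pixel_size_um: float = 1.0,
    map_rate: float = 60.0,
    counts: float = 1000.0,
    jitter_nm: float = 0.0,
):
    """Forward-render raw interference images for a thickness map or series.

    ``mode='spectral'`` takes a single (H, W) thickness map and returns a
    :class:`~mechwarp.erism.SpectralStack` (one frame per grid wavelength).
    ``mode='two_wavelength'`` takes a (T, H, W) series and returns an
    :class:`~mechwarp.warp.InterleavedStack` (lambda frame first, camera frame
    rate = 2 x map rate).  Multiplicative Gaussian intensity noise of the given
    fraction is applied; ``jitter_nm`` adds frozen Gaussian thickness roughness.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(thickness_nm, dtype=float)

    if mode == "spectral":
        if grid is None:
            raise ValueError("spectral mode needs a SpectrumGrid")
        if t.ndim != 2:
            raise ValueError("spectral mode renders a single (H, W) thickness map")
        if jitter_nm > 0:
            t = t + rng.normal(0.0, jitter_nm, t.shape)
        frames = np.empty((len(grid),) + t.shape)
        for i, wl in enumerate(grid.wavelengths):
            frames[i] = compute_reflectance(stack, wl, t) * counts
        if noise_fraction > 0:
            frames *= 1.0 + rng.normal(0.0, noise_fraction, frames.shape)
        return SpectralStack(np.maximum(frames, 0.0), grid, pixel_size_um)

    if mode == "two_wavelength":
        if t.ndim != 3:
            raise ValueError("two_wavelength mode renders a (T, H, W) thickness series")
        if jitter_nm > 0:
            t = t + rng.normal(0.0, jitter_nm, t.shape[1:])[None]
        lam, theta = lambda_pair
        frames = np.empty((2 * t.shape[0],) + t.shape[1:])
        for i in range(t.shape[0]):
            frames[2 * i] = compute_reflectance(stack, lam, t[i]) * counts
            frames[2 * i + 1] = compute_reflectance(stack, theta, t[i]) * counts
        if noise_fraction > 0:
            frames *= 1.0 + rng.normal(0.0, noise_fraction, frames.shape)
        return InterleavedStack(np.maximum(frames, 0.0), 2.0 * map_rate, "lambda")

    raise ValueError("mode must be 'spectral' or 'two_wavelength'")


# ---------------------------------------------------------------------------
# AFM curves, tracks, GRF-area points


def simulate_afm_curve(
    youngs_modulus_pa: float,
    probe_radius_um: float = 8.0,
    sample_thickness_um: float = 10.0,
    max_force_nn: float = 30.0,
    noise_fraction: float = 0.0,
    seed: int | None = None,
    n_samples: int = 200,
    pre_contact_nm: float = 100.0,
) -> ForceDistanceCurve:
    """Synthetic spherical-probe indentation curve up to ``max_force_nn``.

    The force law is the height-corrected Hertz model (bonded incompressible
    layer); additive Gaussian force noise has standard deviation
    ``noise_fraction * max_force_nn``.
    """
    from scipy.optimize import brentq

    if min(youngs_modulus_pa, probe_radius_um, sample_thickness_um, max_force_nn) <= 0:
        raise ValueError("all physical parameters must be > 0")
    rng = np.random.default_rng(seed)
    delta_max = brentq(
        lambda d: hertz_force_bonded(d, youngs_modulus_pa, probe_radius_um, sample_thickness_um)
        - max_force_nn,
        1e-3,
        3e3 * sample_thickness_um,
    )
    z = np.linspace(-pre_contact_nm, delta_max, n_samples)
    f = hertz_force_bonded(z, youngs_modulus_pa, probe_radius_um, sample_thickness_um)
    if noise_fraction > 0:
        f = f + rng.normal(0.0, noise_fraction * max_force_nn, f.shape)
    return ForceDistanceCurve(z, f, probe_radius_um, sample_thickness_um)


def simulate_tracks(
    scenario: CrawlScenario,
    points_per_band: int = 2,
    noise_um: float = 0.0,
    seed: int | None = None,
    track_step_um: float = 12.0,
    row_gap_um: float = 6.0,
) -> TrackTable:
    """Landmark trajectories of posterior/anterior denticle rows per band.

    Each band moves ``track_step_um`` during its swing at constant speed; the
    anterior row starts and stops after the posterior row by the programmed
    AP latencies (sign flipped for backward waves at SI).  Gaussian positional
    noise of ``noise_um`` is added.
    """
    if points_per_band < 2:
        raise ValueError("points_per_band must be >= 2 (posterior and anterior rows)")
    sc = scenario
    rng = np.random.default_rng(sc.seed if seed is None else seed)
    waves = scenario_waves(sc)
    t_end = waves[-1]["start"] + sc.wave_duration_s + 0.4
    times = np.arange(int(np.ceil(t_end * sc.map_rate))) / sc.map_rate
    sign = 1.0 if sc.direction == "forward" else -1.0
    si_lat = sign * sc.si_latency_fraction * sc.wave_duration_s
    st_lat = sc.st_latency_fraction * sc.wave_duration_s

    rows = []
    offsets = np.linspace(-row_gap_um / 2, row_gap_um / 2, points_per_band)
    for i in range(sc.n_protopodia):
        x0, y0 = sc.centres[i]
        for j, off in enumerate(offsets):
            frac = j / (points_per_band - 1)  # 0 = posterior row, 1 = anterior row
            lat_si = frac * si_lat
            lat_st = frac * st_lat
            x = np.full_like(times, x0 + off)
            for wv in waves:
                si = wv["si"][i] + lat_si
                st = wv["st"][i] + lat_st
                moved = np.clip((times - si) / max(st - si, 1e-9), 0.0, 1.0)
                x = x + sign * track_step_um * moved
            x = x + rng.normal(0.0, noise_um, x.shape) if noise_um > 0 else x
            y = np.full_like(times, y0)
            y = y + rng.normal(0.0, noise_um, y.shape) if noise_um > 0 else y
            if frac == 0:
                label = f"p{i}_post"
            elif frac == 1:
                label = f"p{i}_ant"
            else:
                label = f"p{i}_r{j}"
            rows.append(
                pd.DataFrame({"time_s": times, "point_id": label, "x_um": x, "y_um": y})
            )
    return TrackTable(pd.concat(rows, ignore_index=True), sc.map_rate)


def simulate_grf_area_points(
    law: Sequence[float],
    n_points: int = 120,
    area_range: tuple[float, float] = (50.0, 350.0),
    noise_sd: float | None = None,
    target_r2: float = 0.85,
    seed: int | None = None,
) -> np.ndarray:
    """(area, GRF) samples from a quadratic law with additive Gaussian noise.

    With ``noise_sd=None`` the noise is matched analytically to a target R^2:
    sd = std(signal) * sqrt(1/R^2 - 1).
    """
    rng = np.random.default_rng(seed)
    areas = rng.uniform(*area_range, n_points)
    y = np.polyval(np.asarray(law, dtype=float), areas)
    if noise_sd is None:
        noise_sd = float(np.std(y) * np.sqrt(1.0 / target_r2 - 1.0))
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, y.shape)
    return np.column_stack([areas, y])
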