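"""WARP mode: video-rate displacement mapping from two-wavelength stacks.

WARP trades the full spectral scan of ERISM for two rapidly alternating
illumination wavelengths (lambda and lambda_theta, detuned by ~90 degrees of
cavity round-trip phase).  The normalised ratio of the two reflectance images

    W = (I_lambda - I_lambda_theta) / (I_lambda + I_lambda_theta)

is a periodic function of local cavity thickness with period equal to one free
spectral range (FSR).  A calibration against a region of known thickness
gradient turns W back into a thickness offset within one FSR; the integer FSR
branch is then chosen by spatial continuity (flood fill from the resting
border) in the first frame and temporal continuity afterwards.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .erism import DisplacementMap, ThicknessMap

__all__ = [
    "InterleavedStack",
    "WarpCalibration",
    "CalibrationError",
    "DemuxResult",
    "demux",
    "warp_ratio",
    "calibrate",
    "reconstruct_displacement",
    "process_video",
]


class CalibrationError(ValueError):
    """Calibration data cannot produce an unambiguous W -> thickness mapping."""


@dataclass(frozen=True)
class InterleavedStack:
    """Video frames alternating between the two illumination wavelengths."""

    frames: np.ndarray  # (n_frames, H, W)
    frame_rate: float  # frames / s
    first_frame_label: str = "lambda"  # "lambda" | "lambda_theta"

    def __post_init__(self):
        f = np.asarray(self.frames, dtype=float)
        if f.ndim != 3 or f.shape[0] < 2:
            raise ValueError("frames must be (n_frames >= 2, H, W)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.first_frame_label not in ("lambda", "lambda_theta"):
            raise ValueError("first_frame_label must be 'lambda' or 'lambda_theta'")
        object.__setattr__(self, "frames", f)


class DemuxResult(NamedTuple):
    lambda_frames: np.ndarray  # (n_pairs, H, W)
    theta_frames: np.ndarray  # (n_pairs, H, W)
    map_rate: float  # displacement maps / s = frame_rate / 2


def demux(stack: InterleavedStack) -> DemuxResult:
    """Split an interleaved stack into time-aligned lambda / lambda_theta stacks.

    Pairs are formed from consecutive frames; an odd trailing frame is dropped
    with a warning.  The effective map rate is half the camera frame rate.
    """
    frames = stack.frames
    n = frames.shape[0]
    if n % 2:
        warnings.warn("odd trailing frame dropped during demux", stacklevel=2)
        frames = frames[: n - 1]
    a, b = frames[0::2], frames[1::2]
    if stack.first_frame_label == "lambda":
        lam, theta = a, b
    else:
        lam, theta = b, a
    return DemuxResult(lam, theta, stack.frame_rate / 2.0)


def warp_ratio(I_a: np.ndarray, I_b: np.ndarray, noise_floor: float | None = None):
    """Normalised difference ratio W = (I_a - I_b)/(I_a + I_b) with masking.

    Pixels whose summed intensity falls below ``noise_floor`` (default: 1% of
    the 99th percentile of I_a + I_b) are masked rather than divided.
    Returns (W, valid).
    """
    a = np.asarray(I_a, dtype=float)
    b = np.asarray(I_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("intensities must be >= 0")
    total = a + b
    floor = noise_floor if noise_floor is not None else 0.01 * np.percentile(total, 99)
    valid = total > max(floor, 0.0)
    W = np.zeros_like(total)
    np.divide(a - b, total, out=W, where=valid)
    return W, valid


# ---------------------------------------------------------------------------
# calibration


@dataclass(frozen=True)
class WarpCalibration:
    """Empirical mapping between the WARP ratio and thickness within one FSR.

    ``offset_grid``/``w_curve`` sample the periodic response W(offset) densely
    over one FSR starting at ``anchor_thickness``.  ``branches`` are the
    monotone segments of that curve, each as (W ascending, offset) knot arrays;
    the longest branch is the canonical strictly monotone ``response_curve``.
    """

    fsr_nm: float
    anchor_thickness: float
    offset_grid: np.ndarray
    w_curve: np.ndarray
    branches: tuple[tuple[np.ndarray, np.ndarray], ...]
    #: normalised summed-intensity response S(offset) (same grid as w_curve);
    #: S is in quadrature with W and disambiguates the two W branches
    s_curve: np.ndarray | None = None

    def __post_init__(self):
        if self.fsr_nm <= 0:
            raise ValueError("fsr_nm must be > 0")
        if not self.branches:
            raise CalibrationError("no monotone branch in calibration curve")

    @property
    def _main_branch(self):
        return max(self.branches, key=lambda br: br[0].size)

    def response_curve(self, w):
        """Monotone W -> thickness-offset mapping (principal branch) [nm]."""
        wb, ob = self._main_branch
        return np.interp(np.asarray(w, dtype=float), wb, ob)

    def candidate_offsets(self, w):
        """All within-FSR thickness offsets consistent with ratio values ``w``.

        Returns an array of shape (n_branches,) + w.shape; offsets from a
        branch whose W range does not cover a value are still produced by
        clipping (they then sit at the branch end, nearest the true fold).
        """
        w = np.asarray(w, dtype=float)
        return np.stack([np.interp(w, wb, ob) for wb, ob in self.branches])

    def predicted_sum(self, offset):
        """Normalised summed intensity expected at a within-FSR offset [nm]."""
        if self.s_curve is None:
            raise CalibrationError("calibration carries no summed-intensity curve")
        grid = np.concatenate([self.offset_grid, [self.offset_grid[0] + self.fsr_nm]])
        vals = np.concatenate([self.s_curve, self.s_curve[:1]])
        return np.interp(np.mod(np.asarray(offset, dtype=float), self.fsr_nm), grid, vals)


def _phase_fold_period(t: np.ndarray, w: np.ndarray, candidates: np.ndarray, bins: int = 48):
    """Phase-dispersion score of folding w(t) at each candidate period."""
    scores = np.empty(candidates.size)
    var = w.var() + 1e-30
    for i, p in enumerate(candidates):
        phase = np.mod(t, p) / p
        idx = np.minimum((phase * bins).astype(int), bins - 1)
        sums = np.bincount(idx, weights=w, minlength=bins)
        counts = np.bincount(idx, minlength=bins)
        sq = np.bincount(idx, weights=w * w, minlength=bins)
        good = counts > 1
        within = (sq[good] - sums[good] ** 2 / counts[good]).sum()
        scores[i] = within / ((counts[good].sum()) * var)
    return scores


def estimate_fsr(thickness: np.ndarray, w: np.ndarray, search: tuple[float, float] = (80.0, 400.0)):
    """Estimate the FSR [nm] from the periodicity of W versus thickness.

    Phase-dispersion minimisation over a candidate period grid, refined on a
    fine local grid.  Needs the calibration region to span at least about one
    period to lock on.
    """
    t = thickness - thickness.min()
    span = float(t.max())
    lo, hi = search
    hi = min(hi, 2.0 * span)
    if hi <= lo:
        raise CalibrationError("calibration thickness range too small to estimate the FSR")
    coarse = np.arange(lo, hi, 1.0)
    s = _phase_fold_period(t, w, coarse)
    best = coarse[int(np.argmin(s))]
    fine = np.arange(best - 1.5, best + 1.5, 0.02)
    s2 = _phase_fold_period(t, w, fine)
    return float(fine[int(np.argmin(s2))])


def _fold_bin(values: np.ndarray, idx: np.ndarray, n_knots: int) -> np.ndarray:
    """Bin-average ``values`` over fold-phase bins, in-filling empty bins periodically."""
    sums = np.bincount(idx, weights=values, minlength=n_knots)
    counts = np.bincount(idx, minlength=n_knots)
    curve = np.full(n_knots, np.nan)
    filled = counts > 0
    curve[filled] = sums[filled] / counts[filled]
    if not filled.all():
        grid = np.arange(n_knots)
        curve = np.interp(grid, grid[filled], curve[filled], period=n_knots)
    return curve


def calibrate(
    W_cal: np.ndarray,
    thickness_ref: ThicknessMap,
    n_knots: int = 256,
    valid: np.ndarray | None = None,
    fsr_nm: float | None = None,
    sum_cal: np.ndarray | None = None,
) -> WarpCalibration:
    """Build a WARP calibration from a co-registered ratio image and thickness map.

    The calibration region must contain a thickness gradient spanning at least
    half a free spectral range.  Pixels are folded by thickness modulo the
    (estimated or given) FSR and bin-averaged into a dense periodic response
    curve, which is then split into monotone branches.
    """
    w = np.asarray(W_cal, dtype=float).ravel()
    t = np.asarray(thickness_ref.values, dtype=float).ravel()
    m = np.asarray(thickness_ref.valid).ravel()
    if valid is not None:
        m = m & np.asarray(valid).ravel()
    if w.size != t.size:
        raise ValueError("W_cal and thickness_ref must be co-registered")
    w, t = w[m], t[m]
    if w.size < 4 * n_knots:
        raise CalibrationError("too few valid calibration pixels")
    span = t.max() - t.min()
    if fsr_nm is None:
        fsr_nm = estimate_fsr(t, w)
    if span < 0.5 * fsr_nm:
        raise CalibrationError(
            f"calibration region spans {span:.0f} nm < 0.5 FSR ({fsr_nm:.0f} nm)"
        )

    anchor = float(t.min())
    phase = np.mod(t - anchor, fsr_nm)
    idx = np.minimum((phase / fsr_nm * n_knots).astype(int), n_knots - 1)
    curve = _fold_bin(w, idx, n_knots)

    def _smooth(c):
        k = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
        k /= k.sum()
        return np.convolve(np.concatenate([c[-2:], c, c[:2]]), k, mode="same")[2:-2]

    # light circular smoothing keeps branch detection stable under noise
    smooth = _smooth(curve)
    offsets = (np.arange(n_knots) + 0.5) / n_knots * fsr_nm

    s_curve = None
    if sum_cal is not None:
        s = np.asarray(sum_cal, dtype=float).ravel()[m]
        s_curve = _smooth(_fold_bin(s / np.median(s), idx, n_knots))

    branches = _monotone_branches(offsets, smooth, fsr_nm)
    return WarpCalibration(float(fsr_nm), anchor, offsets, smooth, branches, s_curve)


def _monotone_branches(offsets, curve, fsr_nm):
    """Split a periodic response curve into its monotone segments."""
    n = curve.size
    d = np.diff(np.concatenate([curve, curve[:1]]))  # circular differences
    sign = np.sign(d)
    sign[sign == 0] = 1
    turns = np.nonzero(sign != np.roll(sign, 1))[0]
    if turns.size == 0:
        raise CalibrationError("response curve is constant; degenerate calibration region")
    if turns.size > 2:
        # tolerate micro-wiggles but refuse a genuinely folded response
        amp = curve.max() - curve.min()
        spans = []
        for i, start in enumerate(turns):
            stop = turns[(i + 1) % turns.size]
            seg = np.arange(start, stop if stop > start else stop + n) % n
            spans.append(np.abs(curve[seg[-1]] - curve[seg[0]]))
        if np.sum(np.asarray(spans) > 0.2 * amp) > 2:
            raise CalibrationError("non-monotone folded response; separate FSR branches first")
    branches = []
    for i, start in enumerate(turns):
        stop = turns[(i + 1) % turns.size]
        seg = np.arange(start, stop if stop > start else stop + n) % n
        if seg.size < 3:
            continue
        wseg = curve[seg]
        oseg = offsets[seg].copy()
        # keep offsets continuous along the circular path
        wrap = np.nonzero(np.diff(oseg) < 0)[0]
        if wrap.size:
            oseg[wrap[0] + 1 :] += fsr_nm
        order = np.argsort(wseg)
        wsorted = wseg[order]
        keep = np.concatenate([[True], np.diff(wsorted) > 0])
        branches.append((wsorted[keep], oseg[order][keep]))
    branches = [br for br in branches if br[0].size >= 3]
    if not branches:
        raise CalibrationError("no usable monotone branch in calibration curve")
    return tuple(branches)


# ---------------------------------------------------------------------------
# reconstruction


def _nearest_candidate(cand_offsets, reference, anchor, fsr, penalty=None):
    """Absolute thickness candidates nearest a per-pixel reference.

    ``cand_offsets``: (B,) + shape array of within-FSR offsets.  ``penalty``
    (same shape) biases the choice, e.g. by summed-intensity disagreement.
    Returns the chosen thickness and its W-space distance to the reference.
    """
    rel = np.asarray(reference - anchor, dtype=float)
    k = np.round((rel[None] - cand_offsets) / fsr)
    t = anchor + cand_offsets + k * fsr
    dist = np.abs(t - reference)
    score = dist if penalty is None else dist + penalty
    j = np.argmin(score, axis=0)
    t_best = np.take_along_axis(t, j[None], axis=0)[0]
    d_best = np.take_along_axis(dist, j[None], axis=0)[0]
    return t_best, d_best


def _flood_fill_first_frame(cand, baseline, fsr, spread_tol, dist_tol_fraction=0.25,
                            penalty=None):
    """Assign FSR branches in the first frame by flood fill from the border.

    The image border is assumed at rest (reference = baseline).  Interior
    pixels take the mean of already-assigned neighbours as reference.  A pixel
    is masked, and does not propagate, when its assigned neighbours disagree
    by more than ``spread_tol`` or when its best candidate sits further than
    ``dist_tol_fraction`` of an FSR from the reference -- an aliased
    discontinuity that must be flagged rather than wrapped to the nearest
    order.  Regions reachable only through masked pixels stay masked.
    """
    h, w = baseline.shape
    dist_tol = dist_tol_fraction * fsr
    thickness = np.full((h, w), np.nan)
    state = np.zeros((h, w), dtype=np.int8)  # 0 unvisited, 1 assigned, 2 masked
    queue = deque()

    border = [(r, c) for r in (0, h - 1) for c in range(w)] + [
        (r, c) for c in (0, w - 1) for r in range(1, h - 1)
    ]
    pen = (lambda r, c: None) if penalty is None else (lambda r, c: penalty[:, r, c])
    for r, c in border:
        t, d = _nearest_candidate(cand[:, r, c], baseline[r, c], 0.0, fsr, pen(r, c))
        if d > dist_tol:
            state[r, c] = 2
            continue
        thickness[r, c] = t
        state[r, c] = 1
        queue.append((r, c))

    neigh = ((-1, 0), (1, 0), (0, -1), (0, 1))
    while queue:
        r, c = queue.popleft()
        for dr, dc in neigh:
            rr, cc = r + dr, c + dc
            if not (0 <= rr < h and 0 <= cc < w) or state[rr, cc]:
                continue
            refs = [
                thickness[rr + er, cc + ec]
                for er, ec in neigh
                if 0 <= rr + er < h and 0 <= cc + ec < w and state[rr + er, cc + ec] == 1
            ]
            if not refs:
                continue
            refs = np.asarray(refs)
            if refs.max() - refs.min() > spread_tol:
                state[rr, cc] = 2
                continue
            t, d = _nearest_candidate(cand[:, rr, cc], refs.mean(), 0.0, fsr, pen(rr, cc))
            if d > dist_tol:
                state[rr, cc] = 2
                continue
            thickness[rr, cc] = t
            state[rr, cc] = 1
            queue.append((rr, cc))

    return thickness, state == 1


def reconstruct_displacement(
    W_stack: np.ndarray,
    cal: WarpCalibration,
    baseline: ThicknessMap,
    valid_stack: np.ndarray | None = None,
    pixel_size: float | None = None,
    spread_tol_fraction: float = 0.45,
    sum_stack: np.ndarray | None = None,
) -> list[DisplacementMap]:
    """Turn a series of WARP ratio images into displacement maps [nm].

    Per pixel and frame the thickness is anchor + offset(W) + k * FSR.  The
    within-FSR branch of the folded W response is disambiguated by the summed
    intensity (``sum_stack``, in quadrature with W) when the calibration
    carries it; the integer order k follows spatial continuity (flood fill
    from the resting border) in the first frame and per-pixel temporal
    continuity afterwards.  Displacement is thickness minus the resting
    baseline map.
    """
    W_stack = np.asarray(W_stack, dtype=float)
    if W_stack.ndim != 3:
        raise ValueError("W_stack must be (n_frames, H, W)")
    base = np.asarray(baseline.values, dtype=float)
    if W_stack.shape[1:] != base.shape:
        raise ValueError("baseline shape mismatch")
    px = pixel_size if pixel_size is not None else baseline.pixel_size
    fsr = cal.fsr_nm
    spread_tol = spread_tol_fraction * fsr
    use_sum = sum_stack is not None and cal.s_curve is not None
    gain = None

    out: list[DisplacementMap] = []
    running = base.copy()  # last known thickness per pixel
    velocity = np.zeros_like(base)  # nm / frame, for constant-velocity prediction
    for i in range(W_stack.shape[0]):
        # candidate thicknesses modulo FSR, expressed on the absolute scale
        cand = cal.candidate_offsets(W_stack[i]) + cal.anchor_thickness
        if use_sum:
            s_pred = cal.predicted_sum(cand - cal.anchor_thickness)  # (B, H, W)
        if i == 0:
            penalty = None
            if use_sum:
                # provisional gain from the resting border ties the video's
                # intensity scale to the calibration's normalised sum curve
                s0 = np.asarray(sum_stack[0], dtype=float)
                s_base = cal.predicted_sum(base - cal.anchor_thickness)
                ring = np.zeros(base.shape, dtype=bool)
                ring[0, :] = ring[-1, :] = ring[:, 0] = ring[:, -1] = True
                gain = float(np.median(s0[ring] / s_base[ring]))
                penalty = 1.5 * fsr * np.abs(s0[None] / gain - s_pred)
            thickness, ok = _flood_fill_first_frame(cand, base, fsr, spread_tol,
                                                    penalty=penalty)
            if use_sum and ok.any():
                # refine the gain over all anchored pixels
                s_at = cal.predicted_sum(thickness - cal.anchor_thickness)
                gain = float(np.median(s0[ok] / s_at[ok]))
        else:
            # temporal references: the last value catches motion reversals,
            # the constant-velocity prediction catches sustained rates
            # approaching half an FSR per frame
            pred = running + np.clip(velocity, -0.4 * fsr, 0.4 * fsr)
            k1 = np.round((running[None] - cand) / fsr)
            k2 = np.round((pred[None] - cand) / fsr)
            t_opts = np.concatenate([cand + k1 * fsr, cand + k2 * fsr])
            d_opts = np.minimum(
                np.abs(t_opts - running[None]), np.abs(t_opts - pred[None])
            )
            score = d_opts.copy()
            if use_sum:
                # quadrature discrimination: penalise candidates whose
                # predicted summed intensity disagrees with the observation
                s_obs = np.asarray(sum_stack[i], dtype=float) / gain
                s_err = np.abs(s_obs[None] - s_pred)
                score += 1.5 * fsr * np.concatenate([s_err, s_err])
            j = np.argmin(score, axis=0)
            t = np.take_along_axis(t_opts, j[None], axis=0)[0]
            dist = np.take_along_axis(d_opts, j[None], axis=0)[0]
            # spatial consistency pass: a pixel that leaves BOTH its
            # neighbourhood and its own temporal track by more than a third
            # of an FSR took a wrong branch; pull it back to the candidate
            # nearest the local median.  (Narrow genuine features are spared
            # by the temporal condition.)
            med = ndimage.median_filter(t, size=3)
            stray = (np.abs(t - med) > 0.35 * fsr) & (np.abs(t - running) > 0.35 * fsr)
            if np.any(stray):
                t_fix, dist_fix = _nearest_candidate(
                    cand[:, stray], med[stray], 0.0, fsr
                )
                t[stray] = t_fix
                dist[stray] = dist_fix
            ok = dist <= 0.5 * fsr
            thickness = np.where(ok, t, np.nan)
        if valid_stack is not None:
            ok = ok & np.asarray(valid_stack[i], dtype=bool)
        ok = ok & np.asarray(baseline.valid)
        t_now = np.nan_to_num(thickness, nan=0.0)
        # exponentially smoothed rate: damps single-frame spikes from the
        # ill-conditioned fold regions of the response curve
        velocity = (
            np.where(ok, 0.5 * velocity + 0.5 * (t_now - running), 0.0) if i > 0 else velocity
        )
        running = np.where(ok, t_now, running)
        disp = np.where(ok, t_now - base, 0.0)
        out.append(DisplacementMap(disp, px, (0.0, 0.0, 0.0), ok))
    return out


def process_video(
    stack: InterleavedStack,
    cal: WarpCalibration,
    baseline: ThicknessMap,
    noise_floor: float | None = None,
) -> tuple[list[DisplacementMap], float]:
    """Demux an interleaved video and reconstruct its displacement series.

    Returns (displacement maps, effective map rate in maps/s).
    """
    dm = demux(stack)
    ratios = np.empty_like(dm.lambda_frames)
    valid = np.empty(dm.lambda_frames.shape, dtype=bool)
    for i in range(ratios.shape[0]):
        ratios[i], valid[i] = warp_ratio(dm.lambda_frames[i], dm.theta_frames[i], noise_floor)
    sums = dm.lambda_frames + dm.theta_frames
    maps = reconstruct_displacement(ratios, cal, baseline, valid_stack=valid, sum_stack=sums)
    return maps, dm.map_rate
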