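"""ERISM mode: cavity thickness and displacement maps from a spectral scan.

A spectral scan images the microcavity at every wavelength of a grid
(classically 550-750 nm in 1 nm steps, 201 frames).  Each pixel's reflection
spectrum shows a comb of cavity resonance minima; matching the observed comb
against the forward optical model tabulated over thickness yields the local
cavity length.  Subtracting a reference plane anchored on the (undisturbed)
image corners converts thickness into displacement, with negative values
denoting indentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .optics import SpectrumGrid, ThicknessLookup, _minima_mask, _refine_minima

__all__ = [
    "SpectralStack",
    "ThicknessMap",
    "DisplacementMap",
    "ReferencePlaneError",
    "reconstruct_thickness",
    "subtract_reference_plane",
    "mean_cavity_length",
]


class ReferencePlaneError(ValueError):
    """A corner reference region holds no valid pixels."""


@dataclass(frozen=True)
class SpectralStack:
    """Image stack with one frame per wavelength of ``grid``."""

    frames: np.ndarray  # (n_wavelengths, H, W)
    grid: SpectrumGrid
    pixel_size: float  # um / pixel

    def __post_init__(self):
        f = np.asarray(self.frames, dtype=float)
        if f.ndim != 3:
            raise ValueError("frames must be (n_wavelengths, H, W)")
        if f.shape[0] != len(self.grid):
            raise ValueError("frame count must equal wavelength count")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        object.__setattr__(self, "frames", f)


@dataclass(frozen=True)
class ThicknessMap:
    """Per-pixel cavity length [nm]; ``valid`` flags pixels with a usable fit."""

    values: np.ndarray
    pixel_size: float
    valid: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        m = np.asarray(self.valid, dtype=bool)
        if v.shape != m.shape or v.ndim != 2:
            raise ValueError("values and valid must be matching 2-D arrays")
        if np.any(v[m] < 0):
            raise ValueError("negative thickness")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "valid", m)


@dataclass(frozen=True)
class DisplacementMap:
    """Deviation from the resting plane [nm]; negative = indentation."""

    values: np.ndarray
    pixel_size: float
    baseline_plane: tuple[float, float, float]  # values ~ a*x + b*y + c removed
    valid: np.ndarray


# ---------------------------------------------------------------------------
# thickness reconstruction


def _pixel_minima(stack: SpectralStack, depth_fraction: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel resonance minima, NaN-padded to (n_pixels, max_minima).

    Local minima shallower than ``depth_fraction`` of the pixel's spectral
    range are discarded: genuine cavity resonances are deep dips, whereas
    intensity noise creates shallow spurious minima on the background.
    """
    wl = stack.grid.wavelengths
    n_wl, h, w = stack.frames.shape
    r = stack.frames.reshape(n_wl, h * w).T  # (P, n_wl)
    mask = _minima_mask(r)
    lo = r.min(axis=1, keepdims=True)
    hi = r.max(axis=1, keepdims=True)
    mask &= r < lo + depth_fraction * (hi - lo)
    counts = mask.sum(axis=1)
    max_m = max(int(counts.max()), 1)
    padded = np.full((h * w, max_m), np.nan)
    rows, cols = np.nonzero(mask)
    refined = _refine_minima(wl, lambda o: r[rows, np.clip(cols + o, 0, wl.size - 1)], cols)
    pos = np.concatenate([np.arange(c) for c in counts]) if rows.size else np.empty(0, int)
    padded[rows, pos] = refined
    padded.sort(axis=1)
    return padded, counts


def _distance_table(lookup: ThicknessLookup, query_step: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """D[t, q] = distance from query wavelength q to the nearest modelled minimum
    of thickness row t, sampled on a dense wavelength grid."""
    wl = lookup.grid.wavelengths
    query = np.arange(wl[0], wl[-1] + 0.5 * query_step, query_step)
    lut = lookup.minima_padded
    T = lut.shape[0]
    D = np.empty((T, query.size), dtype=np.float32)
    for t in range(T):
        mins = lut[t][~np.isnan(lut[t])]
        if mins.size == 0:
            D[t] = np.inf
            continue
        idx = np.searchsorted(mins, query)
        left = mins[np.clip(idx - 1, 0, mins.size - 1)]
        right = mins[np.clip(idx, 0, mins.size - 1)]
        D[t] = np.minimum(np.abs(query - left), np.abs(query - right))
    return query, D


def _match_cost(obs: np.ndarray, query: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Mean absolute wavelength discrepancy per thickness row for each pixel.

    ``obs``: (P, K) NaN-padded observed minima.  Returns (P,) argmin rows.
    """
    qs = query[1] - query[0]
    idx = np.clip(np.round((np.nan_to_num(obs, nan=query[0]) - query[0]) / qs), 0, query.size - 1)
    idx = idx.astype(np.int32)
    weight = (~np.isnan(obs)).astype(np.float32)  # (P, K)
    P, K = obs.shape
    T = D.shape[0]
    best = np.zeros(P, dtype=np.int64)
    chunk = max(1, int(4e7 / max(T, 1)))
    for s in range(0, P, chunk):
        w = weight[s : s + chunk]
        cost = np.zeros((T, w.shape[0]), dtype=np.float32)
        for k in range(K):  # accumulate one minima column at a time
            cost += D[:, idx[s : s + chunk, k]] * w[:, k][None, :]
        best[s : s + chunk] = np.argmin(cost / np.maximum(w.sum(axis=1), 1.0)[None, :], axis=0)
    return best


def _refine_thickness(
    obs: np.ndarray, lookup: ThicknessLookup, rows: np.ndarray
) -> np.ndarray:
    """First-order thickness refinement around the best lookup row.

    Each resonance wavelength moves with thickness as d(lambda)/dL ~ lambda/L,
    so the matched residuals convert to a thickness correction
    dL_k = (obs_k - model_k) * L / lambda_k, averaged over matched minima.
    """
    lut = lookup.minima_padded[rows]  # (P, M)
    L0 = lookup.thickness_grid[rows]  # (P,)
    # nearest modelled minimum per observed one
    diff = obs[:, :, None] - lut[:, None, :]  # (P, K, M)
    with np.errstate(invalid="ignore"):
        nearest = np.nanargmin(np.abs(np.where(np.isnan(diff), np.inf, diff)), axis=2)
    matched = np.take_along_axis(lut, nearest, axis=1)  # (P, K)
    dL = (obs - matched) * (L0[:, None] / np.where(np.isnan(obs), 1.0, obs))
    with np.errstate(invalid="ignore"):
        corr = np.nanmean(dL, axis=1)
    return L0 + np.nan_to_num(corr)


def reconstruct_thickness(
    stack: SpectralStack,
    lookup: ThicknessLookup,
    fill_invalid: bool = False,
) -> ThicknessMap:
    """Per-pixel cavity thickness by correlating observed resonance minima with
    the modelled lookup table (minimum mean absolute wavelength discrepancy).

    Pixels with no detected minimum are masked.  Pixels with a single minimum
    cannot resolve the resonance order on their own; they are assigned the
    thickness branch nearest the median of the multi-minima pixels.  With
    ``fill_invalid`` masked pixels are in-filled by nearest-neighbour values
    (they remain flagged invalid).
    """
    if not np.array_equal(stack.grid.wavelengths, lookup.grid.wavelengths):
        raise ValueError("stack and lookup use different wavelength grids")
    h, w = stack.frames.shape[1:]
    obs, counts = _pixel_minima(stack)
    query, D = _distance_table(lookup)

    thickness = np.full(h * w, np.nan)
    valid = counts >= 1
    multi = counts >= 2
    if np.any(multi):
        rows = _match_cost(obs[multi], query, D)
        thickness[multi] = _refine_thickness(obs[multi], lookup, rows)

    single = counts == 1
    if np.any(single):
        anchor = np.nanmedian(thickness[multi]) if np.any(multi) else float(
            np.median(lookup.thickness_grid)
        )
        rows = _single_minimum_rows(obs[single], lookup, query, D, anchor)
        thickness[single] = _refine_thickness(obs[single], lookup, rows)

    thickness = thickness.reshape(h, w)
    valid = valid.reshape(h, w)
    thickness[~valid] = np.nan
    if fill_invalid and valid.any() and not valid.all():
        _, (ir, ic) = ndimage.distance_transform_edt(~valid, return_indices=True)
        thickness = thickness[ir, ic]
    return ThicknessMap(np.nan_to_num(thickness, nan=0.0), stack.pixel_size, valid)


def _single_minimum_rows(obs, lookup, query, D, anchor_nm) -> np.ndarray:
    """Resolve single-minimum pixels to the thickness branch nearest ``anchor_nm``."""
    qs = query[1] - query[0]
    idx = np.clip(
        np.round((obs[:, 0] - query[0]) / qs).astype(int), 0, query.size - 1
    )
    cost = D[:, idx].T  # (P, T)
    # candidate rows: local minima of the cost along thickness
    c = cost
    local = np.zeros_like(c, dtype=bool)
    local[:, 1:-1] = (c[:, 1:-1] <= c[:, :-2]) & (c[:, 1:-1] <= c[:, 2:])
    penalty = np.abs(lookup.thickness_grid[None, :] - anchor_nm)
    penalty = np.where(local & (c < 1.0), penalty, np.inf)
    rows = np.argmin(penalty, axis=1)
    # fall back to plain best match if no acceptable branch
    none = ~np.isfinite(penalty[np.arange(len(rows)), rows])
    if np.any(none):
        rows[none] = np.argmin(cost[none], axis=1)
    return rows


# ---------------------------------------------------------------------------
# reference plane and cavity statistics


def _corner_regions(shape: tuple[int, int], corner_fraction: float):
    h, w = shape
    ch = max(1, int(round(h * corner_fraction)))
    cw = max(1, int(round(w * corner_fraction)))
    return [
        (slice(0, ch), slice(0, cw)),
        (slice(0, ch), slice(w - cw, w)),
        (slice(h - ch, h), slice(0, cw)),
        (slice(h - ch, h), slice(w - cw, w)),
    ]


def subtract_reference_plane(t: ThicknessMap, corner_fraction: float = 0.05) -> DisplacementMap:
    """Remove the linear plane through the four corner-region mean thicknesses.

    The corners are assumed undisturbed, so after subtraction their means are
    ~0 and the remainder is local displacement (negative = indentation).
    """
    if not 0 < corner_fraction <= 0.25:
        raise ValueError("corner_fraction must be in (0, 0.25]")
    h, w = t.values.shape
    xs, ys, zs = [], [], []
    for rows, cols in _corner_regions((h, w), corner_fraction):
        m = t.valid[rows, cols]
        if not m.any():
            raise ReferencePlaneError("corner reference region is fully masked")
        region = t.values[rows, cols]
        zs.append(region[m].mean())
        # centroid of the valid pixels (plane mean over a region = plane at centroid)
        rr, cc = np.mgrid[rows, cols]
        xs.append(cc[m].mean())
        ys.append(rr[m].mean())
    A = np.column_stack([xs, ys, np.ones(4)])
    coef, *_ = np.linalg.lstsq(A, np.asarray(zs), rcond=None)
    a, b, c = (float(v) for v in coef)
    xx, yy = np.meshgrid(np.arange(w), np.arange(h))
    disp = t.values - (a * xx + b * yy + c)
    disp[~t.valid] = 0.0
    return DisplacementMap(disp, t.pixel_size, (a, b, c), t.valid.copy())


def mean_cavity_length(maps, rois) -> float:
    """Grand mean thickness over all (map, ROI) combinations.

    ``rois`` are (row_start, row_stop, col_start, col_stop) rectangles applied
    to every map, mirroring the corner-image protocol used to characterise a
    cavity's static length.
    """
    means = []
    for m in maps:
        h, w = m.values.shape
        for r0, r1, c0, c1 in rois:
            if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
                raise ValueError("ROI outside image bounds")
            region = m.values[r0:r1, c0:c1]
            mask = m.valid[r0:r1, c0:c1]
            if not mask.any():
                raise ValueError("ROI holds no valid pixels")
            means.append(region[mask].mean())
    if not means:
        raise ValueError("no maps/ROIs given")
    return float(np.mean(means))
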