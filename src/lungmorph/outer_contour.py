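"""Outer-contour segmentation of the whole explant.

The explant is separated from the culture background by maximum-entropy
(Kapur-style) global thresholding.  Low-contrast images with rim shadows
defeat a single global level, so the initial object is refined: eight rays
cast from the object centroid locate contour points, a local entropy
threshold is computed in a disc around each, and the eight local levels are
interpolated into a smooth per-pixel threshold surface by multilevel cubic
B-spline approximation.  The final contour is Gaussian-smoothed, which also
removes thin spurs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._util import disk_offsets, largest_component, quantize_u8
from .errors import (
    DegenerateHistogramError,
    InvalidInputError,
    MissingIntersectionError,
    OverSmoothingError,
    RayOriginError,
    SegmentationFailureError,
)

log = logging.getLogger(__name__)

__all__ = [
    "RayFan",
    "ThresholdField",
    "entropy_threshold",
    "object_polarity",
    "segment_global",
    "cast_rays",
    "fit_threshold_field",
    "refine_outer_mask",
    "smooth_contour",
]

N_RAYS = 8  # 0°..315° in 45° steps


def entropy_threshold(img: np.ndarray, roi: np.ndarray | None = None) -> int:
    """Maximum-entropy threshold level of a grayscale image.

    For each candidate level t the pixels split into a background class
    (intensity <= t) and an object class (> t); the returned t maximizes the
    sum of the Shannon entropies of the two class-normalized histograms
    (Kapur's criterion).  All 256 levels are scanned; levels leaving either
    class empty are not candidates; ties resolve to the smallest maximizing
    level.
    """
    img = np.asarray(img)
    if img.size == 0:
        raise InvalidInputError("empty image")
    values = img[np.asarray(roi, dtype=bool)] if roi is not None else img.ravel()
    if values.size == 0:
        raise InvalidInputError("empty ROI")
    hist = np.bincount(quantize_u8(values), minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("fewer than 2 distinct intensities")
    p = hist / hist.sum()
    plogp = p * np.log2(np.where(p > 0, p, 1.0))
    cum_p = np.cumsum(p)
    cum_s = np.cumsum(plogp)
    p_lo = cum_p[:-1]  # mass of class <= t for t = 0..254
    p_hi = 1.0 - p_lo
    s_lo = cum_s[:-1]
    s_hi = cum_s[-1] - s_lo
    valid = (p_lo > 0) & (p_hi > 0)
    p_lo_safe = np.where(p_lo > 0, p_lo, 1.0)
    p_hi_safe = np.where(p_hi > 0, p_hi, 1.0)
    h_lo = np.log2(p_lo_safe) - s_lo / p_lo_safe
    h_hi = np.log2(p_hi_safe) - s_hi / p_hi_safe
    e_total = np.where(valid, h_lo + h_hi, -np.inf)
    return int(np.argmax(e_total))  # argmax takes the first (smallest) maximizer


def object_polarity(img: np.ndarray, t: int) -> str:
    """Decide which threshold class is the object: ``"above"`` or ``"below"``.

    The object class is the one whose mean intensity differs most from the
    mean intensity of the one-pixel image border (assumed to sample the
    background).  Handles both bright-on-dark and dark-on-bright conditions.
    """
    img = np.asarray(img, dtype=float)
    border = np.concatenate([img[0, :], img[-1, :], img[1:-1, 0], img[1:-1, -1]])
    border_mean = border.mean()
    above = img > t
    mean_above = img[above].mean() if above.any() else border_mean
    mean_below = img[~above].mean() if (~above).any() else border_mean
    return "above" if abs(mean_above - border_mean) >= abs(mean_below - border_mean) else "below"


def _postprocess(fg: np.ndarray) -> np.ndarray:
    if not fg.any():
        raise SegmentationFailureError("empty foreground after thresholding")
    mask = largest_component(fg)
    return ndimage.binary_fill_holes(mask)


def segment_global(img: np.ndarray) -> np.ndarray:
    """Segment the explant with a single global maximum-entropy threshold.

    Thresholds at :func:`entropy_threshold`, picks the object polarity via
    :func:`object_polarity`, keeps the largest 8-connected component and
    fills interior holes (the dark epithelium inside a bright explant is part
    of the object).
    """
    try:
        t = entropy_threshold(img)
    except DegenerateHistogramError as exc:
        raise SegmentationFailureError("image has no contrast to segment") from exc
    fg = img > t if object_polarity(img, t) == "above" else img <= t
    return _postprocess(fg)


@dataclass(frozen=True)
class RayFan:
    """Eight rays cast from the object centroid to the contour.

    ``angles`` are in degrees, 0° pointing toward increasing column,
    counter-clockwise in standard x/y orientation (decreasing row).
    """

    centroid: tuple[float, float]
    angles: tuple[float, ...]
    intersections: tuple[tuple[float, float], ...]
    distances: tuple[float, ...]

    @property
    def mean_distance(self) -> float:
        return float(np.mean(self.distances))

    def directions(self) -> np.ndarray:
        """Unit (row, col) direction vectors of the rays."""
        ang = np.deg2rad(self.angles)
        return np.stack([-np.sin(ang), np.cos(ang)], axis=1)


def cast_rays(mask: np.ndarray, n_rays: int = N_RAYS) -> RayFan:
    """Cast ``n_rays`` equally spaced rays from the mask centroid.

    Each ray is sampled at half-pixel steps; the intersection C_i is the LAST
    foreground→background transition along the ray (robust to interior
    holes), with leaving the frame counting as background.  D_i is the
    Euclidean distance from the centroid to C_i.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InvalidInputError("empty mask")
    h, w = mask.shape
    cr, cc = ndimage.center_of_mass(mask)
    if not mask[int(round(cr)), int(round(cc))]:
        raise RayOriginError("mask centroid lies outside the foreground")
    angles = tuple(360.0 * k / n_rays for k in range(n_rays))
    max_len = math.hypot(h, w)
    ts = np.arange(0.0, max_len, 0.5)
    inters: list[tuple[float, float]] = []
    dists: list[float] = []
    for ang in angles:
        a = math.radians(ang)
        drow, dcol = -math.sin(a), math.cos(a)
        rows = cr + ts * drow
        cols = cc + ts * dcol
        inb = (rows >= -0.5) & (rows < h - 0.5) & (cols >= -0.5) & (cols < w - 0.5)
        ri = np.clip(np.rint(rows), 0, h - 1).astype(int)
        ci = np.clip(np.rint(cols), 0, w - 1).astype(int)
        vals = mask[ri, ci] & inb
        if not vals.any():
            raise MissingIntersectionError(f"ray at {ang}° never meets the foreground")
        last_fg = int(np.nonzero(vals)[0][-1])
        t = ts[last_fg]
        inters.append((cr + t * drow, cc + t * dcol))
        dists.append(float(t))
    return RayFan((float(cr), float(cc)), angles, tuple(inters), tuple(dists))


@dataclass(frozen=True)
class ThresholdField:
    """Smooth per-pixel threshold surface with its scattered control points."""

    values: np.ndarray
    control_points: tuple[tuple[tuple[float, float], float], ...] = field(default=())


def _bspline_weights(t: np.ndarray) -> np.ndarray:
    """Uniform cubic B-spline basis values B_0..B_3 at fractional position t."""
    t2 = t * t
    t3 = t2 * t
    return np.stack(
        [
            (1 - t) ** 3 / 6.0,
            (3 * t3 - 6 * t2 + 4) / 6.0,
            (-3 * t3 + 3 * t2 + 3 * t + 1) / 6.0,
            t3 / 6.0,
        ],
        axis=0,
    )


def _ba_lattice(points: np.ndarray, z: np.ndarray, shape: tuple[int, int], m: int, n: int) -> np.ndarray:
    """One B-spline approximation pass: fit an (m+3)x(n+3) control lattice."""
    h, w = shape
    phi_num = np.zeros((m + 3, n + 3))
    phi_den = np.zeros((m + 3, n + 3))
    sy = points[:, 0] * m / max(h - 1, 1)
    sx = points[:, 1] * n / max(w - 1, 1)
    iy = np.clip(np.floor(sy).astype(int), 0, m - 1)
    ix = np.clip(np.floor(sx).astype(int), 0, n - 1)
    wy = _bspline_weights(sy - iy)  # (4, P)
    wx = _bspline_weights(sx - ix)
    for p in range(points.shape[0]):
        wkl = np.outer(wy[:, p], wx[:, p])  # (4,4)
        sw2 = (wkl**2).sum()
        if sw2 <= 0:
            continue
        contrib = wkl * z[p] / sw2
        sl_y = slice(iy[p], iy[p] + 4)
        sl_x = slice(ix[p], ix[p] + 4)
        phi_num[sl_y, sl_x] += wkl**2 * contrib
        phi_den[sl_y, sl_x] += wkl**2
    with np.errstate(invalid="ignore"):
        phi = np.where(phi_den > 0, phi_num / np.where(phi_den > 0, phi_den, 1.0), 0.0)
    return phi


def _eval_lattice(phi: np.ndarray, shape: tuple[int, int], m: int, n: int) -> np.ndarray:
    """Evaluate a control lattice on the full pixel grid."""
    h, w = shape
    sy = np.arange(h) * m / max(h - 1, 1)
    sx = np.arange(w) * n / max(w - 1, 1)
    iy = np.minimum(np.floor(sy).astype(int), m - 1)
    ix = np.minimum(np.floor(sx).astype(int), n - 1)
    wy = _bspline_weights(sy - iy)  # (4, H)
    wx = _bspline_weights(sx - ix)  # (4, W)
    out = np.zeros((h, w))
    for k in range(4):
        for l in range(4):
            out += wy[k][:, None] * wx[l][None, :] * phi[iy + k][:, ix + l]
    return out


def _eval_lattice_at(phi: np.ndarray, points: np.ndarray, shape: tuple[int, int], m: int, n: int) -> np.ndarray:
    h, w = shape
    sy = points[:, 0] * m / max(h - 1, 1)
    sx = points[:, 1] * n / max(w - 1, 1)
    iy = np.clip(np.floor(sy).astype(int), 0, m - 1)
    ix = np.clip(np.floor(sx).astype(int), 0, n - 1)
    wy = _bspline_weights(sy - iy)
    wx = _bspline_weights(sx - ix)
    out = np.zeros(points.shape[0])
    for k in range(4):
        for l in range(4):
            out += wy[k] * wx[l] * phi[iy + k, ix + l]
    return out


def fit_threshold_field(
    points: list[tuple[float, float]],
    values: list[float],
    shape: tuple[int, int],
    control_grid: int = 4,
    tol: float = 1.0,
    max_levels: int = 10,
) -> ThresholdField:
    """Fit a smooth surface through scattered (location, level) control points.

    Multilevel B-spline approximation: a coarse ``control_grid`` x
    ``control_grid`` cubic lattice captures the trend, then the lattice is
    repeatedly doubled and refit on the residuals until every control point
    is matched within ``tol`` intensity units (or ``max_levels`` is reached).
    The accumulated surface is globally smooth by construction.
    """
    pts = np.asarray(points, dtype=float)
    z = np.asarray(values, dtype=float)
    field_vals = np.zeros(shape)
    resid = z.copy()
    m = n = max(control_grid, 1)
    for _ in range(max_levels):
        phi = _ba_lattice(pts, resid, shape, m, n)
        field_vals = field_vals + _eval_lattice(phi, shape, m, n)
        resid = resid - _eval_lattice_at(phi, pts, shape, m, n)
        if np.abs(resid).max() <= tol:
            break
        m *= 2
        n *= 2
    return ThresholdField(field_vals, tuple((tuple(p), float(v)) for p, v in zip(points, values)))


def local_thresholds(
    img: np.ndarray, fan: RayFan, radius: float, min_class_frac: float = 0.05
) -> list[int]:
    """Entropy threshold inside a disc of the given radius at each ray contour point.

    Falls back to the global threshold (logged) when a disc is degenerate or
    when the local level isolates a sliver class (< ``min_class_frac`` of the
    disc on either side) — a threshold that does not actually partition the
    local content is no basis for contour refinement.
    """
    h, w = img.shape
    t_global = entropy_threshold(img)
    offsets = disk_offsets(max(radius, 2.0))
    levels = []
    for (pr, pc) in fan.intersections:
        rows = np.clip(np.rint(pr + offsets[:, 0]), 0, h - 1).astype(int)
        cols = np.clip(np.rint(pc + offsets[:, 1]), 0, w - 1).astype(int)
        roi = np.zeros((h, w), dtype=bool)
        roi[rows, cols] = True
        try:
            t_loc = entropy_threshold(img, roi)
        except DegenerateHistogramError:
            log.warning("degenerate local histogram at (%.1f, %.1f); using global level", pr, pc)
            levels.append(t_global)
            continue
        vals = img[roi]
        frac_lo = float((vals <= t_loc).mean())
        if min(frac_lo, 1.0 - frac_lo) < min_class_frac:
            log.warning("local level %d at (%.1f, %.1f) isolates a sliver; using global level",
                        t_loc, pr, pc)
            levels.append(t_global)
        else:
            levels.append(t_loc)
    return levels


def refine_outer_mask(
    img: np.ndarray,
    initial: np.ndarray,
    control_grid: int = 4,
) -> np.ndarray:
    """Refine a global-threshold mask with locally adaptive entropy thresholds.

    Eight rays from the centroid of ``initial`` locate contour points; at
    each, an entropy threshold is computed inside a disc of radius D̄/4
    (D̄ = mean ray length).  The eight (location, level) pairs are spread
    into a smooth :class:`ThresholdField` by multilevel B-spline
    approximation and the image is re-thresholded pixelwise against the
    field.  The largest component, hole-filled, is returned.
    """
    fan = cast_rays(initial)
    radius = fan.mean_distance / 4.0
    levels = local_thresholds(img, fan, radius)
    field_ = fit_threshold_field(list(fan.intersections), [float(v) for v in levels], img.shape,
                                 control_grid=control_grid)
    # the spline is only constrained at the 8 contour points; keep its
    # extrapolation within the range the local thresholds span
    values = np.clip(field_.values, min(levels), max(levels))
    t_global = entropy_threshold(img)
    polarity = object_polarity(img, t_global)
    fg = img > values if polarity == "above" else img <= values
    return _postprocess(fg)


def smooth_contour(mask: np.ndarray, sigma_smooth: float = 2.0) -> np.ndarray:
    """Gaussian-smooth a binary mask's indicator and re-binarize at 0.5.

    Produces the slight shrinking effect expected of contour smoothing:
    convex shapes lose area, corners round off, and 1-px spurs disappear.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InvalidInputError("empty mask")
    sm = ndimage.gaussian_filter(mask.astype(float), sigma_smooth) > 0.5
    if not sm.any():
        raise OverSmoothingError("smoothing removed the entire component")
    return largest_component(sm)
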