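"""Automated quantification of microtubule alignment in fluorescence images.

Pipeline (per image): maximum-project a z-stack, stretch contrast by
clipping 0.5% of pixels at each intensity extreme, convolve with a pair of
5x5 Sobel operators to get per-pixel gradient magnitude M and direction D,
then for each cell (label mask) build a magnitude-weighted direction
histogram: keep pixels with M >= 22% of the cell's maximum, rotate the
gradient directions by 90 degrees (a gradient is perpendicular to the
filament that produced it), bin at 4 degrees and normalize.  An axial von
Mises fit of that histogram yields the MT main direction (mu) and the MTSD
(sigma); the MTDEV is the acute angle between mu and the cell's long axis
from its moment-ellipse fit.

Angles follow the package convention: degrees counter-clockwise from the
image x axis with y up, modulo 180.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .circstats import AngularHistogram, fit_axial_von_mises, mtdev
from .geometry import EllipseFit, InvalidMaskError, fit_ellipse_to_mask

SOBEL_SMOOTH = np.array([1.0, 4.0, 6.0, 4.0, 1.0])
SOBEL_DERIV = np.array([-1.0, -2.0, 0.0, 2.0, 1.0])
MAG_THRESHOLD = 0.22
BIN_DEG = 4.0
CLIP_FRACTION = 0.005
EDGE_ERODE_PX = 2     # half-width of the 5x5 kernels
MIN_CELL_PIXELS = 50


def max_project(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection of a (z, y, x) stack; 2D images pass
    through unchanged (as a float copy)."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return stack.astype(float, copy=True)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must be 2D or (z, y, x) with >= 1 slice")
    return stack.max(axis=0).astype(float)


def stretch_contrast(img: np.ndarray, clip: float = CLIP_FRACTION) -> np.ndarray:
    """Linear contrast stretch to [0, 1] with percentile clipping.

    Pixels at or below the ``clip`` quantile map to 0, at or above the
    ``1 - clip`` quantile to 1.  A constant image is returned unchanged
    (as floats) with a warning.
    """
    img = np.asarray(img, dtype=float)
    if img.size == 0:
        raise ValueError("image is empty")
    lo, hi = np.quantile(img, [clip, 1.0 - clip])
    if hi <= lo:
        warnings.warn("constant image: contrast stretch is a no-op", stacklevel=2)
        return img.copy()
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


@dataclass
class GradientField:
    """Per-pixel gradient responses of the 5x5 Sobel pair.

    ``gx``/``gy`` are the raw responses along columns and rows,
    ``magnitude`` = sqrt(gx^2 + gy^2), and ``direction`` is the gradient
    direction in degrees in [0, 180) (y-up convention); it is meaningful
    only where the magnitude is positive.
    """

    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray
    direction: np.ndarray


def sobel_5x5(img: np.ndarray) -> GradientField:
    """Convolve with separable 5x5 Sobel operators.

    The kernels are smoothing [1, 4, 6, 4, 1] in one axis times derivative
    [-1, -2, 0, 2, 1] in the other; ``gx`` responds positively to intensity
    increasing along +x (columns), ``gy`` along +rows.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or min(img.shape) < 5:
        raise ValueError("image must be 2D and at least 5x5")
    gx = ndimage.correlate1d(img, SOBEL_DERIV, axis=1, mode="reflect")
    gx = ndimage.correlate1d(gx, SOBEL_SMOOTH, axis=0, mode="reflect")
    gy = ndimage.correlate1d(img, SOBEL_DERIV, axis=0, mode="reflect")
    gy = ndimage.correlate1d(gy, SOBEL_SMOOTH, axis=1, mode="reflect")
    mag = np.hypot(gx, gy)
    # y-up: a gradient along +rows points toward -y
    direction = np.degrees(np.arctan2(-gy, gx)) % 180.0
    return GradientField(gx=gx, gy=gy, magnitude=mag, direction=direction)


def cell_direction_histogram(
    field: GradientField,
    mask: np.ndarray,
    bin_deg: float = BIN_DEG,
    mag_threshold: float = MAG_THRESHOLD,
    erode_px: int = EDGE_ERODE_PX,
) -> AngularHistogram:
    """Magnitude-weighted filament-direction histogram of one cell.

    The mask is eroded by the kernel half-width so mask edges do not inject
    spurious directions; pixels below ``mag_threshold`` of the cell's
    maximum magnitude are discarded; the surviving gradient directions are
    rotated by 90 degrees onto filament directions, binned and normalized.
    An all-background (or fully thresholded) cell yields an empty histogram,
    which downstream fits report as unaligned (sigma = 90).
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != field.magnitude.shape:
        raise ValueError("mask and gradient field shapes differ")
    if erode_px > 0:
        mask = ndimage.binary_erosion(mask, iterations=erode_px)
    m = field.magnitude[mask]
    edges = np.arange(0.0, 180.0 + bin_deg / 2, bin_deg)
    if m.size == 0 or m.max() <= 0:
        return AngularHistogram(bin_edges=edges, weights=np.zeros(len(edges) - 1), normalized=True)
    keep = m >= mag_threshold * m.max()
    d = (field.direction[mask][keep] + 90.0) % 180.0
    w, _ = np.histogram(d, bins=edges, weights=m[keep])
    hist = AngularHistogram(bin_edges=edges, weights=w.astype(float))
    return hist.normalize()


@dataclass
class CellQuant:
    """Per-cell shape and microtubule-organization record."""

    cell_id: int
    ellipse: EllipseFit
    mt_main_direction: float  # mu, degrees in [0, 180) (NaN if no signal)
    mtsd: float               # degrees in [0, 90]
    mtdev: float              # degrees in [0, 90] (NaN if mu undefined)
    n_pixels_used: int
    included: bool            # False when fewer than MIN_CELL_PIXELS survive


_TABLE_COLUMNS = [
    "cell_id", "centroid_x", "centroid_y", "area_px", "eccentricity",
    "aspect_ratio", "orientation_deg", "mt_main_direction_deg", "mtsd_deg",
    "mtdev_deg", "n_pixels_used", "included",
]


def cells_to_table(cells: list[CellQuant]) -> pd.DataFrame:
    """One row per cell, in the canonical column order used for CSV output."""
    rows = []
    for c in cells:
        rows.append(
            {
                "cell_id": c.cell_id,
                "centroid_x": c.ellipse.centroid[0],
                "centroid_y": c.ellipse.centroid[1],
                "area_px": c.ellipse.n_pixels,
                "eccentricity": c.ellipse.eccentricity,
                "aspect_ratio": c.ellipse.aspect_ratio,
                "orientation_deg": c.ellipse.orientation,
                "mt_main_direction_deg": c.mt_main_direction,
                "mtsd_deg": c.mtsd,
                "mtdev_deg": c.mtdev,
                "n_pixels_used": c.n_pixels_used,
                "included": c.included,
            }
        )
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def _quantify_mask(field: GradientField, mask: np.ndarray, cell_id: int,
                   bin_deg: float, mag_threshold: float, erode_px: int) -> CellQuant:
    ellipse = fit_ellipse_to_mask(mask)
    hist = cell_direction_histogram(field, mask, bin_deg, mag_threshold, erode_px)
    n_used = _surviving_pixels(field, mask, mag_threshold, erode_px)
    fit = fit_axial_von_mises(hist)
    dev = mtdev(fit.mu, ellipse.orientation) if np.isfinite(fit.mu) else float("nan")
    return CellQuant(
        cell_id=cell_id,
        ellipse=ellipse,
        mt_main_direction=fit.mu,
        mtsd=fit.sigma,
        mtdev=dev,
        n_pixels_used=n_used,
        included=n_used >= MIN_CELL_PIXELS,
    )


def _surviving_pixels(field: GradientField, mask: np.ndarray,
                      mag_threshold: float, erode_px: int) -> int:
    mask = np.asarray(mask).astype(bool)
    if erode_px > 0:
        mask = ndimage.binary_erosion(mask, iterations=erode_px)
    m = field.magnitude[mask]
    if m.size == 0 or m.max() <= 0:
        return 0
    return int(np.count_nonzero(m >= mag_threshold * m.max()))


def quantify_cells(
    img: np.ndarray,
    labels: np.ndarray,
    clip: float = CLIP_FRACTION,
    bin_deg: float = BIN_DEG,
    mag_threshold: float = MAG_THRESHOLD,
    erode_px: int = EDGE_ERODE_PX,
) -> list[CellQuant]:
    """Cell-by-cell shape and MT-alignment quantification.

    ``img`` is a 2D grayscale image (or 3D stack, max-projected first);
    ``labels`` an integer label mask (0 = background, one positive label per
    cell).  Gradients are computed once on the stretched full image; each
    cell then contributes its masked, thresholded direction histogram.
    Cells whose masks cannot be fit (too small, fragmented) are skipped;
    cells with fewer than 50 surviving pixels are flagged ``included=False``.
    """
    img = max_project(img)
    labels = np.asarray(labels)
    if labels.shape != img.shape:
        raise ValueError("image and label mask shapes differ")
    stretched = stretch_contrast(img, clip)
    field = sobel_5x5(stretched)
    out: list[CellQuant] = []
    for lab in np.unique(labels):
        if lab <= 0:
            continue
        mask = labels == lab
        try:
            out.append(_quantify_mask(field, mask, int(lab), bin_deg, mag_threshold, erode_px))
        except InvalidMaskError:
            continue
    return out


def quantify_field(
    img: np.ndarray,
    mask: np.ndarray | None = None,
    clip: float = CLIP_FRACTION,
    bin_deg: float = BIN_DEG,
    mag_threshold: float = MAG_THRESHOLD,
    erode_px: int = EDGE_ERODE_PX,
) -> CellQuant:
    """Whole-field quantification: the same pipeline with one region.

    With no mask the entire frame is the region and the magnitude threshold
    is relative to the field maximum.  Returns a :class:`CellQuant` whose
    ellipse describes the region (for a full frame this is the frame's own
    moment ellipse; its MTDEV is then not biologically meaningful).
    """
    img = max_project(img)
    if mask is None:
        mask = np.ones(img.shape, dtype=bool)
    stretched = stretch_contrast(img, clip)
    field = sobel_5x5(stretched)
    return _quantify_mask(field, np.asarray(mask).astype(bool), 0, bin_deg, mag_threshold, erode_px)


def quantify_frames(
    stack: np.ndarray,
    labels: np.ndarray,
    **kwargs,
) -> pd.DataFrame:
    """Apply :func:`quantify_cells` to each frame of a time-lapse.

    ``stack`` is (t, y, x); ``labels`` either one mask shared by all frames
    or a (t, y, x) stack of per-frame masks.  Returns the per-cell table
    with a leading ``frame`` column.  This is how growing plus-end
    trajectory images (one per time point) are quantified: each frame runs
    the standard pipeline independently; no tracking is involved.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (t, y, x)")
    labels = np.asarray(labels)
    tables = []
    for f in range(stack.shape[0]):
        lab = labels[f] if labels.ndim == 3 else labels
        tab = cells_to_table(quantify_cells(stack[f], lab, **kwargs))
        tab.insert(0, "frame", f)
        tables.append(tab)
    return pd.concat(tables, ignore_index=True)


def fourier_directionality(img: np.ndarray, bin_deg: float = BIN_DEG) -> AngularHistogram:
    """Spectral orientation histogram — the independent cross-check.

    A Hann-windowed 2D power spectrum is binned by spectral orientation,
    rotated 90 degrees onto real-space filament direction.  Only the
    inscribed frequency disc is used (the spectrum's corners would
    over-weight diagonal orientations) and the lowest radii are excluded as
    windowing leakage.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or min(img.shape) < 32:
        raise ValueError("image must be 2D and at least 32x32")
    h, w = img.shape
    win = np.outer(np.hanning(h), np.hanning(w))
    f = np.fft.fftshift(np.fft.fft2((img - img.mean()) * win))
    power = np.abs(f) ** 2
    v = -(np.arange(h) - h // 2)  # y-up
    u = np.arange(w) - w // 2
    uu, vv = np.meshgrid(u, v)
    radius = np.hypot(uu / (w / 2.0), vv / (h / 2.0))
    keep = (radius <= 1.0) & (np.hypot(uu, vv) >= 3.0)
    spectral_angle = np.degrees(np.arctan2(vv, uu)) % 180.0
    direction = (spectral_angle + 90.0) % 180.0
    edges = np.arange(0.0, 180.0 + bin_deg / 2, bin_deg)
    wts, _ = np.histogram(direction[keep], bins=edges, weights=power[keep])
    return AngularHistogram(bin_edges=edges, weights=wts.astype(float)).normalize()
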