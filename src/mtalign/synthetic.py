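"""Synthetic fixtures with machine-readable ground truth.

Three generators close the validation loop between the simulator and the
image pipeline:

* :func:`generate_line_image` draws straight filaments through random
  anchor points inside an elliptical cell, with axial angles from a wrapped
  normal of known standard deviation — the quantifier's recovery benchmark.
* :func:`render_simulation` rasterizes a simulation's final polymer so the
  image pipeline can be run on the simulator's own output.
* :func:`generate_cell_field` tiles many such cells with a controllable
  dispersion of long-axis orientations, emulating an epithelial field for
  the cell-by-cell versus whole-field comparison.

Every generated image ships with a label mask and a :class:`LineSet`
(JSON-serializable ground truth), so quantifier error is always computable.
Rendering uses unit-width anti-aliased lines with additive intensity where
filaments overlap.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import line_aa, polygon as draw_polygon

from .circstats import AngularHistogram, fit_axial_von_mises
from .simulator import SimResult


@dataclass
class LineSet:
    """Ground truth for one synthetic cell: the exact filaments drawn.

    Angles are axial degrees (mod 180, y-up convention); lengths and
    anchors are in pixels.  ``generating_sigma`` is the standard deviation
    of the normal distribution the angles were sampled from.
    """

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    eccentricity: float
    cell_orientation: float
    anchors: np.ndarray            # (n, 2) pixel coords (x, y-up offsets from center)
    angles: np.ndarray             # (n,) degrees mod 180
    lengths: np.ndarray            # (n,) pixels
    intensities: np.ndarray        # (n,)
    generating_sigma: float
    mean_angle: float
    rng_seed: int
    line_mode: str = "fixed"

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "LineSet":
        d = json.loads(text)
        for k in ("anchors", "angles", "lengths", "intensities"):
            d[k] = np.asarray(d[k], dtype=float)
        d["center"] = tuple(d["center"])
        return cls(**d)


def ground_truth_mtsd(lines: LineSet, bin_deg: float = 1.0) -> float:
    """Length-weighted axial von Mises sigma of the true line angles.

    This mirrors how simulated filaments are summarized (a histogram of
    filament length against direction, fitted with the axial von Mises
    distribution) and is the oracle the image pipeline is judged against.
    """
    if len(lines.angles) < 2:
        raise ValueError("need at least 2 lines")
    hist = AngularHistogram.from_angles(lines.angles, weights=lines.lengths, bin_deg=bin_deg)
    return fit_axial_von_mises(hist).sigma


def _ellipse_chord_halves(x0: float, y0: float, ang_rad: float,
                          a: float, b: float) -> tuple[float, float]:
    """Distances from (x0, y0) to the ellipse boundary along +/- direction."""
    dx, dy = np.cos(ang_rad), np.sin(ang_rad)
    A = (dx / a) ** 2 + (dy / b) ** 2
    B = 2.0 * (x0 * dx / a**2 + y0 * dy / b**2)
    C = (x0 / a) ** 2 + (y0 / b) ** 2 - 1.0
    disc = B * B - 4 * A * C
    if disc <= 0:
        return 0.0, 0.0
    r = np.sqrt(disc)
    t1 = (-B - r) / (2 * A)
    t2 = (-B + r) / (2 * A)
    return max(-t1, 0.0), max(t2, 0.0)


def generate_line_image(
    eccentricity: float,
    sigma_deg: float,
    n_lines: int = 100,
    mean_angle: float | None = None,
    img_size: int = 256,
    rng_seed: int = 0,
    line_mode: str = "fixed",
    line_length: float | None = None,
    intensity: float = 1.0,
    noise_sigma: float = 0.0,
    cell_orientation: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, LineSet]:
    """Render straight filaments with known angular statistics in one cell.

    ``n_lines`` anchors are drawn uniformly inside an ellipse of the given
    eccentricity (semi-major axis 0.45 * img_size); each filament's axial
    angle is Normal(mean_angle, sigma_deg) wrapped to [0, 180).  The default
    ``mean_angle`` is the cell's long-axis orientation.

    ``line_mode`` "fixed" centres a segment of ``line_length`` pixels
    (default: the minor-axis diameter) on the anchor, clipped to the cell;
    "chord" draws the full chord through the anchor.  Fixed length is the
    default because chord lengths depend on the angle in an elongated cell,
    which would length-weight the angular statistics away from the
    generating sigma.

    Returns (image float64, label mask uint16 with the cell as label 1,
    LineSet ground truth).
    """
    if not 0.0 <= eccentricity < 1.0:
        raise ValueError("eccentricity must be in [0, 1)")
    if sigma_deg < 0 or n_lines < 1:
        raise ValueError("sigma_deg must be >= 0 and n_lines >= 1")
    if line_mode not in ("fixed", "chord"):
        raise ValueError("line_mode must be 'fixed' or 'chord'")
    rng = np.random.default_rng(rng_seed)
    a = 0.45 * img_size
    b = a * np.sqrt(1.0 - eccentricity**2)
    if mean_angle is None:
        mean_angle = cell_orientation
    if line_length is None:
        line_length = 2.0 * b

    # uniform anchors inside the (unrotated) ellipse
    r = np.sqrt(rng.uniform(size=n_lines))
    phi = rng.uniform(0, 2 * np.pi, size=n_lines)
    ax = a * r * np.cos(phi)
    ay = b * r * np.sin(phi)
    angles = (rng.normal(mean_angle, sigma_deg, size=n_lines)) % 180.0

    cx = cy = img_size / 2.0
    cos_o, sin_o = np.cos(np.radians(cell_orientation)), np.sin(np.radians(cell_orientation))

    img = np.zeros((img_size, img_size))
    lengths = np.empty(n_lines)
    anchors = np.column_stack([ax, ay])
    for i in range(n_lines):
        ang_cell = np.radians(angles[i] - cell_orientation)  # in ellipse frame
        t_neg, t_pos = _ellipse_chord_halves(ax[i], ay[i], ang_cell, a, b)
        if line_mode == "fixed":
            t_neg = min(t_neg, line_length / 2.0)
            t_pos = min(t_pos, line_length / 2.0)
        lengths[i] = t_neg + t_pos
        if lengths[i] <= 0:
            continue
        dxc, dyc = np.cos(ang_cell), np.sin(ang_cell)
        exs = (ax[i] - t_neg * dxc, ax[i] + t_pos * dxc)
        eys = (ay[i] - t_neg * dyc, ay[i] + t_pos * dyc)
        # rotate to image frame, convert y-up to rows
        pts = []
        for xe, ye in zip(exs, eys):
            xi = cx + xe * cos_o - ye * sin_o
            yi = cy - (xe * sin_o + ye * cos_o)
            pts.append((yi, xi))
        rr, cc, val = line_aa(
            int(round(pts[0][0])), int(round(pts[0][1])),
            int(round(pts[1][0])), int(round(pts[1][1])),
        )
        ok = (rr >= 0) & (rr < img_size) & (cc >= 0) & (cc < img_size)
        img[rr[ok], cc[ok]] += intensity * val[ok]

    # label mask of the (rotated) cell: rotate image-frame offsets (y-up)
    # back into the ellipse frame
    yy, xx = np.mgrid[0:img_size, 0:img_size]
    ox = xx - cx
    oy = -(yy - cy)
    xr = ox * cos_o + oy * sin_o
    yr = -ox * sin_o + oy * cos_o
    mask = ((xr / a) ** 2 + (yr / b) ** 2 <= 1.0).astype(np.uint16)

    if noise_sigma > 0:
        img = np.clip(img + rng.normal(0, noise_sigma, img.shape), 0, None)

    lineset = LineSet(
        center=(cx, cy),
        semi_major=a,
        semi_minor=b,
        eccentricity=float(eccentricity),
        cell_orientation=float(cell_orientation),
        anchors=anchors,
        angles=angles,
        lengths=lengths,
        intensities=np.full(n_lines, float(intensity)),
        generating_sigma=float(sigma_deg),
        mean_angle=float(mean_angle),
        rng_seed=int(rng_seed),
        line_mode=line_mode,
    )
    return img, mask, lineset


def render_simulation(
    result: SimResult, nm_per_px: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize a simulation's final microtubule polylines.

    Returns (image, label mask); intensity is additive, so bundles (which
    are collinear overlapping polylines) render brighter in proportion to
    their occupancy.  ``nm_per_px`` must resolve the cell width with at
    least 3 pixels.
    """
    dom = result.domain
    if dom.width / nm_per_px < 3:
        raise ValueError("nm_per_px too coarse: fewer than 3 px across the cell width")
    margin = 4
    w_px = int(np.ceil(dom.length / nm_per_px)) + 2 * margin
    h_px = int(np.ceil(dom.width / nm_per_px)) + 2 * margin

    def to_px(p):
        # domain (0,0) is the centre; y-up nm -> row-down pixels
        col = p[0] / nm_per_px + w_px / 2.0
        row = h_px / 2.0 - p[1] / nm_per_px
        return row, col

    img = np.zeros((h_px, w_px))
    for pts in result.polylines:
        if len(pts) < 2:
            continue
        for p0, p1 in zip(pts[:-1], pts[1:]):
            if np.hypot(*(p1 - p0)) <= 0:
                continue
            r0, c0 = to_px(p0)
            r1, c1 = to_px(p1)
            rr, cc, val = line_aa(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
            ok = (rr >= 0) & (rr < h_px) & (cc >= 0) & (cc < w_px)
            img[rr[ok], cc[ok]] += val[ok]

    rows, cols = [], []
    for v in dom.vertices:
        r, c = to_px(v)
        rows.append(r)
        cols.append(c)
    mask = np.zeros((h_px, w_px), dtype=np.uint16)
    rr, cc = draw_polygon(rows, cols, shape=mask.shape)
    mask[rr, cc] = 1
    return img, mask


def generate_cell_field(
    n_cells: int,
    eccentricity_range: tuple[float, float] = (0.75, 0.95),
    orientation_sigma_deg: float = 0.0,
    sigma_deg: float = 25.0,
    n_lines_per_cell: int = 60,
    cell_size_px: int = 96,
    rng_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Tile ``n_cells`` elliptical cells with per-cell filament sets.

    Cell long axes are Normal(0, orientation_sigma_deg); with zero
    dispersion the field behaves like one coherent cell sheet, with large
    dispersion the whole-field histogram mixes misaligned cells and its
    MTSD exceeds the mean cell-by-cell MTSD.  Labels 1..n_cells partition
    the foreground (cells never overlap: one per tile).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(rng_seed)
    ncol = int(np.ceil(np.sqrt(n_cells)))
    nrow = int(np.ceil(n_cells / ncol))
    img = np.zeros((nrow * cell_size_px, ncol * cell_size_px))
    labels = np.zeros_like(img, dtype=np.uint16)
    for idx in range(n_cells):
        rr, cc = divmod(idx, ncol)
        ecc = rng.uniform(*eccentricity_range)
        ori = rng.normal(0.0, orientation_sigma_deg) % 180.0
        sub_img, sub_mask, _ = generate_line_image(
            eccentricity=ecc,
            sigma_deg=sigma_deg,
            n_lines=n_lines_per_cell,
            img_size=cell_size_px,
            rng_seed=int(rng.integers(2**31 - 1)),
            cell_orientation=ori,
        )
        sl = (slice(rr * cell_size_px, (rr + 1) * cell_size_px),
              slice(cc * cell_size_px, (cc + 1) * cell_size_px))
        img[sl] += sub_img
        labels[sl][sub_mask > 0] = idx + 1
    return img, labels
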