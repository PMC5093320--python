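"""Cell-shape geometry: ellipse fits of label masks, eccentricity math,
simulation domains and seed placement.

Conventions
-----------
Angles are degrees, measured counter-clockwise from the image/domain x axis
with y pointing *up* (so an image viewed conventionally — row 0 on top — has
its visually counter-clockwise rotations positive).  Filament and cell-axis
orientations are axial quantities, defined modulo 180°.

Simulation coordinates are continuous nanometres; image coordinates are
pixel centres with 0-based indexing (``x`` = column, ``y`` = row).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class InvalidMaskError(ValueError):
    """Raised when a mask is empty, too small, or not a single object."""


def eccentricity_to_aspect_ratio(e: float) -> float:
    """Aspect ratio (major/minor) of an ellipse with eccentricity ``e``.

    ``AR = 1 / sqrt(1 - e^2)``; e must lie in [0, 1).
    """
    e = float(e)
    if not 0.0 <= e < 1.0:
        raise ValueError(f"eccentricity must be in [0, 1), got {e}")
    return 1.0 / np.sqrt(1.0 - e * e)


def aspect_ratio_to_eccentricity(ar: float) -> float:
    """Inverse of :func:`eccentricity_to_aspect_ratio` (``ar`` >= 1)."""
    ar = float(ar)
    if ar < 1.0:
        raise ValueError(f"aspect ratio must be >= 1, got {ar}")
    return float(np.sqrt(1.0 - 1.0 / (ar * ar)))


@dataclass(frozen=True)
class EllipseFit:
    """Moment-equivalent ellipse of a pixel set.

    Axis lengths follow the usual moments convention (full axis length =
    4 * sqrt of the corresponding eigenvalue of the pixel covariance), so a
    filled rendering of the ellipse reproduces the mask's second moments.
    """

    centroid: tuple[float, float]  # (x, y_row) in pixels
    major_axis_len: float
    minor_axis_len: float
    orientation: float  # degrees in [0, 180), CCW from x axis (y up)
    eccentricity: float
    aspect_ratio: float
    n_pixels: int = 0


def fit_ellipse_to_mask(mask: np.ndarray) -> EllipseFit:
    """Fit the moment-equivalent ellipse to a binary mask.

    The mask must contain a single connected component of at least 8
    foreground pixels.  The fit uses the second central moments of the
    foreground pixel centres.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise InvalidMaskError("mask must be 2D")
    n = int(mask.sum())
    if n < 8:
        raise InvalidMaskError(f"mask needs >= 8 foreground pixels, got {n}")
    _, ncomp = ndimage.label(mask)
    if ncomp != 1:
        raise InvalidMaskError(f"mask must be one connected component, got {ncomp}")

    rows, cols = np.nonzero(mask)
    x = cols.astype(float)
    y = -rows.astype(float)  # y-up convention
    cx, cy = x.mean(), y.mean()
    mu20 = np.mean((x - cx) ** 2)
    mu02 = np.mean((y - cy) ** 2)
    mu11 = np.mean((x - cx) * (y - cy))

    # eigenvalues of [[mu20, mu11], [mu11, mu02]]
    tr = mu20 + mu02
    det = mu20 * mu02 - mu11 * mu11
    disc = max(tr * tr / 4.0 - det, 0.0)
    l1 = tr / 2.0 + np.sqrt(disc)
    l2 = max(tr / 2.0 - np.sqrt(disc), 1e-12)

    orientation = np.degrees(0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)) % 180.0
    eccentricity = float(np.sqrt(max(1.0 - l2 / l1, 0.0)))
    return EllipseFit(
        centroid=(float(cx), float(-cy)),
        major_axis_len=float(4.0 * np.sqrt(l1)),
        minor_axis_len=float(4.0 * np.sqrt(l2)),
        orientation=float(orientation),
        eccentricity=eccentricity,
        aspect_ratio=float(np.sqrt(l1 / l2)),
        n_pixels=n,
    )


@dataclass(frozen=True)
class CellDomain:
    """2D simulation arena: a convex polygon of prescribed width and
    eccentricity, long axis along x, centred on the origin.

    ``width`` is the shortest dimension in nm; ``length`` is derived from the
    eccentricity of the moment-equivalent ellipse: L = W / sqrt(1 - e^2).
    """

    shape_kind: str
    width: float  # nm, shortest dimension
    eccentricity: float
    length: float  # nm, along the long (x) axis
    vertices: np.ndarray = field(repr=False)  # (k, 2) CCW, closed implicitly

    @property
    def area(self) -> float:
        v = self.vertices
        x, y = v[:, 0], v[:, 1]
        return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def perimeter(self) -> float:
        d = np.roll(self.vertices, -1, axis=0) - self.vertices
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))

    @property
    def edges(self) -> np.ndarray:
        """(k, 4) array of edge endpoints (x1, y1, x2, y2), CCW order."""
        v2 = np.roll(self.vertices, -1, axis=0)
        return np.hstack([self.vertices, v2])

    def contains(self, points: np.ndarray, tol: float = 1e-6) -> np.ndarray:
        """True for points inside or on the boundary (convex CCW polygon)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        inside = np.ones(len(p), dtype=bool)
        for x1, y1, x2, y2 in self.edges:
            cross = (x2 - x1) * (p[:, 1] - y1) - (y2 - y1) * (p[:, 0] - x1)
            inside &= cross >= -tol * max(self.width, 1.0)
        return inside if np.asarray(points).ndim == 2 else inside[0]


def build_cell_domain(
    width_nm: float,
    eccentricity: float,
    shape_kind: str = "rectangle",
    taper: float = 0.2,
) -> CellDomain:
    """Construct the simulation domain.

    ``rectangle`` (default): width_nm x (width_nm / sqrt(1 - e^2)), the
    aspect ratio of the moment-equivalent ellipse at that eccentricity.
    ``area_matched``: rectangle whose length follows L = 0.632 W / (1 - e^2),
    the law recovered from the cell areas the reference simulations report
    (area x (1 - e^2) is constant across the stated eccentricity range for
    both cell widths); at high eccentricity these cells are about twice as
    elongated as the moment-ellipse mapping.
    ``trapezoid``: isosceles trapezoid with the same height and mean length
    as ``rectangle``; the parallel sides have lengths L(1 +/- taper).
    """
    if width_nm <= 0:
        raise ValueError("width_nm must be positive")
    if not 0.0 <= eccentricity < 1.0:
        raise ValueError("eccentricity must be in [0, 1)")
    if shape_kind == "area_matched":
        length = 0.632 * width_nm * eccentricity_to_aspect_ratio(eccentricity) ** 2
    else:
        length = width_nm * eccentricity_to_aspect_ratio(eccentricity)
    w2 = width_nm / 2.0
    if shape_kind in ("rectangle", "area_matched"):
        l2 = length / 2.0
        verts = np.array(
            [[-l2, -w2], [l2, -w2], [l2, w2], [-l2, w2]], dtype=float
        )
    elif shape_kind == "trapezoid":
        if not 0.0 <= taper < 1.0:
            raise ValueError("taper must be in [0, 1)")
        lb = length * (1.0 + taper) / 2.0
        lt = length * (1.0 - taper) / 2.0
        verts = np.array(
            [[-lb, -w2], [lb, -w2], [lt, w2], [-lt, w2]], dtype=float
        )
    else:
        raise ValueError(f"unsupported shape_kind {shape_kind!r}")
    return CellDomain(
        shape_kind=shape_kind,
        width=float(width_nm),
        eccentricity=float(eccentricity),
        length=float(length),
        vertices=verts,
    )


@dataclass(frozen=True)
class SeedSite:
    """A microtubule nucleation site on the domain boundary."""

    position: tuple[float, float]  # nm
    wall_tangent: tuple[float, float]  # unit, CCW along the boundary
    inward_normal: tuple[float, float]  # unit, into the domain


def place_seeds(domain: CellDomain, n: int, phase: float | None = None) -> list[SeedSite]:
    """Place ``n`` seeds at equal arc-length spacing along the perimeter.

    ``phase`` is the arc-length offset of the first seed from the first
    vertex; the default (half the seed gap) keeps seeds off the corners.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    perim = domain.perimeter
    gap = perim / n
    if phase is None:
        phase = gap / 2.0
    edges = domain.edges
    elens = np.hypot(edges[:, 2] - edges[:, 0], edges[:, 3] - edges[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(elens)])
    seeds: list[SeedSite] = []
    for i in range(n):
        s = (phase + i * gap) % perim
        j = int(np.searchsorted(cum, s, side="right")) - 1
        j = min(j, len(elens) - 1)
        x1, y1, x2, y2 = edges[j]
        t = np.array([x2 - x1, y2 - y1]) / elens[j]
        frac = (s - cum[j]) / elens[j]
        pos = (x1 + frac * (x2 - x1), y1 + frac * (y2 - y1))
        normal = (-t[1], t[0])  # interior is left of a CCW boundary
        seeds.append(
            SeedSite(
                position=(float(pos[0]), float(pos[1])),
                wall_tangent=(float(t[0]), float(t[1])),
                inward_normal=(float(normal[0]), float(normal[1])),
            )
        )
    return seeds
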