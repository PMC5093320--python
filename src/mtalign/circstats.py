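"""Axial circular statistics shared by the simulator and the image pipeline.

Filament directions are axial (a microtubule has no head or tail), so all
statistics use the standard double-angle transform: angles are doubled onto
the full circle, the weighted circular moments are computed there, and the
mean and dispersion are mapped back by halving.  With this convention the
reported dispersion ``sigma`` (the "MTSD") exactly inverts a wrapped-normal
generator: axial angles drawn with standard deviation sigma degrees give a
doubled resultant length ``Rbar = exp(-2 sigma_rad^2)`` and hence
``sigma = (1/2) sqrt(-2 ln Rbar)`` back in degrees.

An empty or perfectly uniform histogram is reported with the unaligned
sentinel ``sigma = 90`` and an undefined (NaN) mean direction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

UNALIGNED_SIGMA = 90.0
_RBAR_TOL = 1e-12


def axial_difference(a: float | np.ndarray, b: float | np.ndarray) -> float | np.ndarray:
    """Acute axial angle between two directions in degrees: min(d, 180 - d)."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 180.0
    out = np.minimum(d, 180.0 - d)
    return float(out) if out.ndim == 0 else out


def mtdev(mu: float, cell_orientation: float) -> float:
    """Deviation of the MT main direction from the cell's long axis, [0, 90]."""
    return float(axial_difference(mu, cell_orientation))


@dataclass
class AngularHistogram:
    """Weighted axial (180-degree-periodic) direction histogram.

    ``bin_edges`` spans [0, 180] with uniform width (1 degree for the
    simulator, 4 degrees for the image pipeline); ``weights`` are
    non-negative per-bin masses (polymer length or gradient magnitude).
    """

    bin_edges: np.ndarray
    weights: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.bin_edges) - 1:
            raise ValueError("weights must have one entry per bin")
        width = np.diff(self.bin_edges)
        if not np.allclose(width, width[0]):
            raise ValueError("bins must have uniform width")
        if abs(180.0 % width[0]) > 1e-9 and abs(width[0] - 180.0 % width[0]) > 1e-9:
            raise ValueError("bin width must divide 180 exactly")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")

    @classmethod
    def from_angles(
        cls,
        angles_deg: np.ndarray,
        weights: np.ndarray | None = None,
        bin_deg: float = 1.0,
    ) -> "AngularHistogram":
        angles = np.asarray(angles_deg, dtype=float) % 180.0
        edges = np.arange(0.0, 180.0 + bin_deg / 2, bin_deg)
        w, _ = np.histogram(angles, bins=edges, weights=weights)
        return cls(bin_edges=edges, weights=w.astype(float))

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total(self) -> float:
        return float(self.weights.sum())

    def normalize(self) -> "AngularHistogram":
        tot = self.total
        if tot <= 0:
            return replace(self, normalized=True)
        return replace(self, weights=self.weights / tot, normalized=True)


@dataclass(frozen=True)
class VonMisesFit:
    """Moment fit of an axial von Mises distribution.

    ``mu`` is the MT main direction in [0, 180); ``sigma`` the MTSD in
    degrees, capped at 90; ``kappa`` the concentration of the doubled
    distribution; ``resultant_length`` the doubled mean resultant length.
    """

    mu: float
    kappa: float
    sigma: float
    resultant_length: float


def _kappa_from_rbar(rbar: float) -> float:
    """Invert A(kappa) = I1(kappa)/I0(kappa) = rbar (Fisher's approximations,
    refined by a few Newton steps on the exact Bessel ratio)."""
    if rbar <= 0.0:
        return 0.0
    if rbar >= 1.0 - 1e-12:
        return float("inf")
    if rbar < 0.53:
        k = 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    elif rbar < 0.85:
        k = -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    else:
        k = 1.0 / (rbar**3 - 4 * rbar**2 + 3 * rbar)

    from scipy.special import i0e, i1e

    def f(kk: float) -> float:
        return i1e(kk) / i0e(kk) - rbar

    try:
        k = optimize.brentq(f, max(k / 4, 1e-8), k * 4 + 1.0, xtol=1e-10)
    except ValueError:
        pass  # bracketing failed at extreme rbar; keep the approximation
    return float(k)


def axial_resultant(
    angles_deg: np.ndarray, weights: np.ndarray | None = None
) -> tuple[float, float]:
    """Weighted doubled-angle mean direction (deg, in [0,180)) and resultant
    length of axial data."""
    a = 2.0 * np.radians(np.asarray(angles_deg, dtype=float))
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    tot = w.sum()
    if tot <= 0:
        return float("nan"), 0.0
    c = float(np.sum(w * np.cos(a)) / tot)
    s = float(np.sum(w * np.sin(a)) / tot)
    rbar = float(np.hypot(c, s))
    mu = float(np.degrees(0.5 * np.arctan2(s, c)) % 180.0)
    return mu, rbar


def sigma_from_rbar(rbar: float) -> float:
    """Axial circular s.d. (deg) from the doubled resultant length, capped at 90."""
    if rbar <= _RBAR_TOL:
        return UNALIGNED_SIGMA
    return float(min(UNALIGNED_SIGMA, np.degrees(0.5 * np.sqrt(-2.0 * np.log(rbar)))))


def fit_axial_von_mises(hist: AngularHistogram) -> VonMisesFit:
    """Fit an axial von Mises distribution to a weighted direction histogram.

    Uses the closed-form (moment) estimator on the doubled bin centres.
    An empty histogram returns the unaligned sentinel (mu = NaN, sigma = 90).
    """
    if np.any(hist.weights < 0):
        raise ValueError("histogram weights must be non-negative")
    mu, rbar = axial_resultant(hist.bin_centers, hist.weights)
    sigma = sigma_from_rbar(rbar)
    kappa = _kappa_from_rbar(rbar) if rbar > _RBAR_TOL else 0.0
    if rbar <= _RBAR_TOL:
        mu = float("nan")
    return VonMisesFit(mu=mu, kappa=kappa, sigma=sigma, resultant_length=rbar)


def fit_axial_von_mises_from_angles(
    angles_deg: np.ndarray, weights: np.ndarray | None = None
) -> VonMisesFit:
    """Moment fit straight from raw axial angles (no binning)."""
    mu, rbar = axial_resultant(angles_deg, weights)
    sigma = sigma_from_rbar(rbar)
    kappa = _kappa_from_rbar(rbar) if rbar > _RBAR_TOL else 0.0
    if rbar <= _RBAR_TOL:
        mu = float("nan")
    return VonMisesFit(mu=mu, kappa=kappa, sigma=sigma, resultant_length=rbar)


@dataclass(frozen=True)
class LinearFitComparison:
    """Extra-sum-of-squares F test of one shared line vs per-dataset lines."""

    f_statistic: float
    p_value: float
    shared_slope: float
    shared_intercept: float
    ss_shared: float
    ss_separate: float
    df_shared: int
    df_separate: int


def _line_ss(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS slope, intercept and residual sum of squares for one line."""
    A = np.column_stack([x, np.ones_like(x)])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def compare_linear_fits(datasets: list[tuple[np.ndarray, np.ndarray]]) -> LinearFitComparison:
    """Test whether several (x, y) datasets are consistent with one shared line.

    Mirrors the classic shared-fit comparison: the null model fits one line
    to the pooled data, the alternative fits each dataset its own line, and
    F = ((SS_shared - SS_sep) / (df_shared - df_sep)) / (SS_sep / df_sep)
    is referred to the F distribution.  Large p: one line suffices.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets")
    xs, ys = [], []
    ss_sep = 0.0
    for x, y in datasets:
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if len(x) < 3 or len(x) != len(y):
            raise ValueError("each dataset needs >= 3 (x, y) points")
        if np.ptp(x) <= 0:
            raise ValueError("x values are degenerate (zero variance)")
        _, _, ss = _line_ss(x, y)
        ss_sep += ss
        xs.append(x)
        ys.append(y)
    x_all = np.concatenate(xs)
    y_all = np.concatenate(ys)
    slope, intercept, ss_shared = _line_ss(x_all, y_all)
    n = len(x_all)
    df_shared = n - 2
    df_sep = n - 2 * len(datasets)
    if df_sep <= 0:
        raise ValueError("not enough points for per-dataset fits")
    dfn = df_shared - df_sep
    if ss_sep <= 1e-300:
        perfect_shared = ss_shared <= 1e-300 or np.isclose(ss_shared, ss_sep)
        f_stat = 0.0 if perfect_shared else float("inf")
        p = 1.0 if perfect_shared else 0.0
    else:
        f_stat = max((ss_shared - ss_sep) / dfn / (ss_sep / df_sep), 0.0)
        p = float(stats.f.sf(f_stat, dfn, df_sep))
    return LinearFitComparison(
        f_statistic=float(f_stat),
        p_value=float(p),
        shared_slope=slope,
        shared_intercept=intercept,
        ss_shared=ss_shared,
        ss_separate=ss_sep,
        df_shared=df_shared,
        df_separate=df_sep,
    )


@dataclass(frozen=True)
class OnePhaseDecayFit:
    """y = (y0 - plateau) * exp(-k x) + plateau, least squares."""

    y0: float
    plateau: float
    k: float
    ss_residual: float
    converged: bool
    message: str = ""


def fit_one_phase_decay(x: np.ndarray, y: np.ndarray) -> OnePhaseDecayFit:
    """Least-squares exponential one-phase decay fit.

    Degenerate inputs (constant y) and optimizer failures are returned as
    flagged results rather than raised, so sweeps over many datasets can
    proceed and report diagnostics.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) < 4 or len(x) != len(y):
        raise ValueError("need >= 4 (x, y) points")
    if np.ptp(y) <= 1e-12 * max(1.0, np.abs(y).max()):
        return OnePhaseDecayFit(
            y0=float(y.mean()),
            plateau=float(y.mean()),
            k=float("nan"),
            ss_residual=float(np.sum((y - y.mean()) ** 2)),
            converged=False,
            message="constant y: decay rate unidentifiable",
        )

    def model(xx, y0, plateau, k):
        return (y0 - plateau) * np.exp(-k * xx) + plateau

    order = np.argsort(x)
    y_first, y_last = y[order[0]], y[order[-1]]
    span = np.ptp(x) if np.ptp(x) > 0 else 1.0
    p0 = (y_first, y_last, np.log(2.0) / (span / 2.0))
    try:
        popt, _ = optimize.curve_fit(model, x, y, p0=p0, maxfev=20000)
    except (RuntimeError, optimize.OptimizeWarning) as exc:  # pragma: no cover
        return OnePhaseDecayFit(
            y0=float("nan"), plateau=float("nan"), k=float("nan"),
            ss_residual=float("inf"), converged=False, message=str(exc),
        )
    resid = y - model(x, *popt)
    return OnePhaseDecayFit(
        y0=float(popt[0]),
        plateau=float(popt[1]),
        k=float(popt[2]),
        ss_residual=float(resid @ resid),
        converged=True,
    )
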