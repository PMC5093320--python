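"""Stochastic simulation of microtubule self-organization in 2D cells.

The model: a fixed number of seeds on the cell boundary, each nucleating a
microtubule that grows along a straight line and switches stochastically
between polymerizing (A_n) and depolymerizing (B_n) states of a
continuous-time Markov chain.  A polymerizing MT of length n dimers adds a
dimer at non-dimensional rate alpha or undergoes catastrophe (to B_{n-1}) at
rate beta_prime; a depolymerizing one loses a dimer at rate beta or is
rescued (to A_{n+1}) at rate alpha_prime.  Multiplying the non-dimensional
rates by the factor R (fixed by the observed growth speed) recovers per-second
rates.  Collisions of the growing tip with other MTs or the cell boundary are
resolved by one of four rule sets; under the full, angle-dependent rules
shallow hits zip (the tip bends parallel to the obstacle, forming bundles),
steep hits cross or trigger catastrophe.

Alignment is summarized as the MTSD: the axial von Mises sigma of the
length-weighted direction histogram of all polymer, sampled on a regular
grid and averaged over the final time window.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _simcore as core
from .circstats import (
    AngularHistogram,
    VonMisesFit,
    axial_difference,
    compare_linear_fits,
    fit_axial_von_mises,
    LinearFitComparison,
    UNALIGNED_SIGMA,
)
from .geometry import CellDomain, SeedSite, build_cell_domain, place_seeds

RULE_SETS = ("stabilize_no_cross", "cross_stabilize", "cross_boundary_cat", "angle_dependent")
_RULE_CODE = {name: i for i, name in enumerate(RULE_SETS)}
_OUTCOME_NAMES = np.array(["zip", "cross", "catastrophe", "stabilize"])
_TARGET_NAMES = np.array(["boundary", "microtubule"])

NOT_CONVERGED = float("nan")


@dataclass
class SimParams:
    """All CTMC and collision-rule parameters (non-dimensional rates)."""

    alpha: float = 1000.0          # polymerization
    beta: float = 3500.0           # depolymerization
    alpha_prime: float = 4.0       # rescue
    beta_prime: float = 1.0        # catastrophe
    R: float = 0.01829             # dimensional factor, s^-1
    dimer_len: float = 8.2         # nm per tubulin dimer
    p_cat: float = 0.01            # crossing-catastrophe probability
    theta_critical: float = 30.0   # degrees
    n_seeds: int = 220
    rule_set: str = "angle_dependent"
    t_end: float = 10.0            # non-dimensional time
    sample_dt: float = 0.01
    avg_window: float = 2.5
    rng_seed: int = 0
    # If True, a collision-induced catastrophe depolymerizes the MT
    # completely (no rescue until re-nucleation) instead of entering the
    # ordinary rescuable shrinking state.  Exploratory variant; the default
    # keeps every catastrophe on the same CTMC footing.
    collapse_on_collision: bool = False
    # A fully depolymerized MT re-nucleates with a fresh uniformly random
    # inward angle.  Set False to quench each seed's angle at setup.
    redraw_angle_on_renucleation: bool = True
    # Fate of a fully depolymerized MT: "rescue_wait" parks it in state B_0
    # of the chain until a rescue event (rate alpha_prime) regrows it, the
    # literal reading of the two-state chain; "instant" re-enters the
    # growing state immediately.
    renucleation: str = "rescue_wait"

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "alpha_prime", "beta_prime", "R", "dimer_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.p_cat <= 1.0:
            raise ValueError("p_cat must be in [0, 1]")
        if not 0.0 < self.theta_critical <= 90.0:
            raise ValueError("theta_critical must be in (0, 90]")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if self.rule_set not in RULE_SETS:
            raise ValueError(f"rule_set must be one of {RULE_SETS}")
        if self.t_end < 0 or self.sample_dt <= 0:
            raise ValueError("t_end must be >= 0 and sample_dt > 0")
        if self.renucleation not in ("rescue_wait", "instant"):
            raise ValueError("renucleation must be 'rescue_wait' or 'instant'")

    def replace(self, **kw) -> "SimParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class DimensionalRates:
    """Per-second rates and times recovered from the non-dimensional model.

    ``R`` is quoted (and applied) at four significant figures, the precision
    at which the dimensional factor is conventionally reported; ``R_exact``
    keeps full precision.
    """

    R: float
    R_exact: float
    growth_speed_um_s: float
    alpha_dim: float
    beta_dim: float
    alpha_prime_dim: float
    beta_prime_dim: float

    def seconds(self, t_nondim: float | np.ndarray):
        """Convert non-dimensional time to seconds."""
        return np.asarray(t_nondim, dtype=float) / self.R


def dimensionalize(params: SimParams, growth_speed_um_s: float = 0.15) -> DimensionalRates:
    """Solve for R from growth_speed = alpha * dimer_len * R and tabulate the
    dimensional rates (rate_dim = rate_nondim * R)."""
    if growth_speed_um_s <= 0:
        raise ValueError("growth speed must be positive")
    speed_nm_s = growth_speed_um_s * 1000.0
    r_exact = speed_nm_s / (params.alpha * params.dimer_len)
    r = float(f"{r_exact:.4g}")
    return DimensionalRates(
        R=r,
        R_exact=float(r_exact),
        growth_speed_um_s=float(growth_speed_um_s),
        alpha_dim=params.alpha * r,
        beta_dim=params.beta * r,
        alpha_prime_dim=params.alpha_prime * r,
        beta_prime_dim=params.beta_prime * r,
    )


def resolve_collision(
    angle: float,
    target: str,
    rule_set: str,
    u: float,
    p_cat: float = 0.01,
    theta_critical: float = 30.0,
) -> str:
    """Outcome of one collision: 'zip', 'cross', 'catastrophe' or 'stabilize'.

    ``angle`` is the acute axial collision angle in (0, 90]; ``target`` is
    'boundary' or 'microtubule'; ``u`` a uniform draw in [0, 1).  The outcome
    is a pure function of its arguments (the same compiled rule the event
    loop uses).
    """
    if not 0.0 < angle <= 90.0:
        raise ValueError(f"collision angle must be in (0, 90], got {angle}")
    if not 0.0 <= u < 1.0:
        raise ValueError("u must be in [0, 1)")
    tcode = {"boundary": core.T_BOUNDARY, "microtubule": core.T_MT}[target]
    code = core.resolve_collision_code(
        float(angle), tcode, _RULE_CODE[rule_set], float(u),
        float(p_cat), float(theta_critical),
    )
    return str(_OUTCOME_NAMES[code])


class SimState:
    """Mutable simulation state: arrays shared with the compiled kernel."""

    def __init__(self, domain: CellDomain, params: SimParams):
        self.domain = domain
        self.params = params
        self.t = 0.0
        n = params.n_seeds

        seeds = place_seeds(domain, n)
        self.seeds: list[SeedSite] = seeds
        self.seed_x = np.array([s.position[0] for s in seeds])
        self.seed_y = np.array([s.position[1] for s in seeds])
        self.seed_tx = np.array([s.wall_tangent[0] for s in seeds])
        self.seed_ty = np.array([s.wall_tangent[1] for s in seeds])
        self.seed_nx = np.array([s.inward_normal[0] for s in seeds])
        self.seed_ny = np.array([s.inward_normal[1] for s in seeds])
        self.seed_dx0 = np.zeros(n)
        self.seed_dy0 = np.zeros(n)

        edges = domain.edges
        self.edge_x1 = np.ascontiguousarray(edges[:, 0])
        self.edge_y1 = np.ascontiguousarray(edges[:, 1])
        self.edge_x2 = np.ascontiguousarray(edges[:, 2])
        self.edge_y2 = np.ascontiguousarray(edges[:, 3])
        self.edge_len = np.hypot(self.edge_x2 - self.edge_x1, self.edge_y2 - self.edge_y1)
        self.edge_tx = (self.edge_x2 - self.edge_x1) / self.edge_len
        self.edge_ty = (self.edge_y2 - self.edge_y1) / self.edge_len

        self.state = np.zeros(n, dtype=np.int64)
        self.ndim = np.zeros(n, dtype=np.int64)
        self.nseg = np.zeros(n, dtype=np.int64)
        self.sox = np.zeros((n, core.MAXSEG))
        self.soy = np.zeros((n, core.MAXSEG))
        self.sdx = np.zeros((n, core.MAXSEG))
        self.sdy = np.zeros((n, core.MAXSEG))
        self.slen = np.zeros((n, core.MAXSEG))
        self.tipx = np.zeros(n)
        self.tipy = np.zeros(n)
        self.dirx = np.zeros(n)
        self.diry = np.zeros(n)
        self.bminx = np.zeros(n)
        self.bmaxx = np.zeros(n)
        self.bminy = np.zeros(n)
        self.bmaxy = np.zeros(n)

        ss = np.random.SeedSequence(params.rng_seed)
        rng_state = ss.generate_state(2, np.uint64)
        rng_state[rng_state == 0] = 0x9E3779B97F4A7C15
        self.rng = rng_state

        # all MT lengths start at zero, with uniformly random inward angles
        # (drawn here and quenched unless redraw_angle_on_renucleation)
        for i in range(n):
            core._reset_mt(
                i, True, False, self.seed_dx0, self.seed_dy0,
                self.seed_x, self.seed_y, self.seed_tx, self.seed_ty,
                self.seed_nx, self.seed_ny, self.state, self.ndim, self.nseg,
                self.sox, self.soy, self.sdx, self.sdy, self.slen,
                self.tipx, self.tipy, self.dirx, self.diry,
                self.bminx, self.bmaxx, self.bminy, self.bmaxy, self.rng,
            )

    # -- inspection helpers -------------------------------------------------
    def polylines(self) -> list[np.ndarray]:
        """Current polyline (vertex array, nm) of every microtubule."""
        out = []
        for i in range(self.params.n_seeds):
            k = self.nseg[i]
            pts = np.empty((k + 1, 2))
            pts[0] = self.sox[i, 0], self.soy[i, 0]
            for j in range(k):
                pts[j + 1, 0] = self.sox[i, j] + self.sdx[i, j] * self.slen[i, j]
                pts[j + 1, 1] = self.soy[i, j] + self.sdy[i, j] * self.slen[i, j]
            out.append(pts)
        return out

    def total_polymer_nm(self) -> float:
        return float(sum(self.slen[i, : self.nseg[i]].sum() for i in range(self.params.n_seeds)))

    def length_histogram(self) -> AngularHistogram:
        """Length-weighted axial direction histogram of the current polymer."""
        row = np.zeros(180)
        core._sample_hist(row, self.nseg, self.sdx, self.sdy, self.slen)
        return AngularHistogram(bin_edges=np.arange(181.0), weights=row)

    def _kernel_args(self):
        return (
            self.edge_x1, self.edge_y1, self.edge_x2, self.edge_y2,
            self.edge_len, self.edge_tx, self.edge_ty,
            self.seed_x, self.seed_y, self.seed_tx, self.seed_ty,
            self.seed_nx, self.seed_ny,
            self.seed_dx0, self.seed_dy0, self.params.redraw_angle_on_renucleation,
            self.params.renucleation == "rescue_wait",
            self.state, self.ndim, self.nseg,
            self.sox, self.soy, self.sdx, self.sdy, self.slen,
            self.tipx, self.tipy, self.dirx, self.diry,
            self.bminx, self.bmaxx, self.bminy, self.bmaxy, self.rng,
        )


def gillespie_step(sim: SimState, n_events: int = 1) -> float:
    """Apply up to ``n_events`` exact-Gillespie events to ``sim`` in place.

    The waiting time is exponential with the aggregate rate (growing MTs
    contribute alpha + beta_prime, shrinking alpha_prime + beta, paused
    beta_prime); one MT is selected proportionally to its rate.  Returns the
    elapsed non-dimensional time.
    """
    p = sim.params
    hist = np.zeros((0, 180))
    ev_t = np.zeros(0)
    ev_mt = np.zeros(0, np.int32)
    ev_target = np.zeros(0, np.int8)
    ev_angle = np.zeros(0, np.float32)
    ev_outcome = np.zeros(0, np.int8)
    t0 = sim.t
    t, _, _, _ = core.run_core(
        *sim._kernel_args(),
        p.alpha, p.beta, p.alpha_prime, p.beta_prime, p.p_cat,
        p.theta_critical, p.dimer_len, _RULE_CODE[p.rule_set],
        p.collapse_on_collision,
        t0, np.inf, n_events,
        p.sample_dt, hist, 0,
        ev_t, ev_mt, ev_target, ev_angle, ev_outcome, 0,
    )
    sim.t = t
    return t - t0


@dataclass
class SimResult:
    """Output of one simulation run."""

    params: SimParams
    domain: CellDomain
    times: np.ndarray                  # non-dimensional sample times
    histograms: np.ndarray             # (n_samples, 180) length-weighted
    mtsd_series: np.ndarray            # degrees, per sample
    mtsd: float                        # final MTSD (last-window average)
    main_direction: float              # mu of the final fit, degrees
    fit: VonMisesFit
    events: pd.DataFrame
    polylines: list[np.ndarray] = field(repr=False, default_factory=list)
    n_events: int = 0

    @property
    def mtdev(self) -> float:
        """Deviation of the final main direction from the long (x) axis."""
        if np.isnan(self.main_direction):
            return float("nan")
        return float(axial_difference(self.main_direction, 0.0))

    def times_seconds(self, R: float | None = None) -> np.ndarray:
        return self.times / (self.params.R if R is None else R)

    def mtsd_series_windowed(self) -> np.ndarray:
        """MTSD series from trailing length-averaged histograms (window =
        ``avg_window``), the estimator used for convergence detection."""
        win = max(1, int(round(self.params.avg_window / self.params.sample_dt)))
        return mtsd_series_from_histograms(self.histograms, window_samples=win)

    def convergence_time_s(self, tol: float = 0.10) -> float:
        """Seconds until the length-averaged MTSD series enters and stays
        within ``tol`` of its convergence value (see
        :func:`detect_convergence`)."""
        return detect_convergence(
            self.times_seconds(),
            self.mtsd_series_windowed(),
            window_s=self.params.avg_window / self.params.R,
            tol=tol,
        )


def mtsd_series_from_histograms(
    histograms: np.ndarray, window_samples: int = 1
) -> np.ndarray:
    """Axial von Mises sigma (degrees) per sample of length histograms.

    With ``window_samples`` > 1 each sample's histogram is the trailing mean
    over up to that many samples (shorter early on), mirroring the
    length-averaging convention used for the final MTSD estimate; this is
    the series convergence detection should use, since the instantaneous
    histogram of a few hundred filaments is a noisy sigma estimator.
    """
    if window_samples > 1 and len(histograms):
        nrow = len(histograms)
        padded = np.vstack([np.zeros((1, histograms.shape[1])), np.cumsum(histograms, axis=0)])
        start = np.maximum(0, np.arange(1, nrow + 1) - window_samples)
        counts = np.arange(1, nrow + 1) - start
        histograms = (padded[1:] - padded[start]) / counts[:, None]
    ang2 = 2.0 * np.radians(np.arange(0.5, 180.0, 1.0))
    w = histograms.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = histograms @ np.cos(ang2)
        s = histograms @ np.sin(ang2)
        rbar = np.where(w > 0, np.hypot(c, s) / np.where(w > 0, w, 1.0), 0.0)
        sigma = np.where(
            rbar > 1e-12,
            np.minimum(UNALIGNED_SIGMA, np.degrees(0.5 * np.sqrt(-2.0 * np.log(np.maximum(rbar, 1e-300))))),
            UNALIGNED_SIGMA,
        )
    return sigma


def run_simulation(
    domain: CellDomain,
    params: SimParams,
    log_events: bool = True,
    event_capacity: int = 1_500_000,
) -> SimResult:
    """Run the microtubule simulation from empty seeds to ``t_end``.

    Fully reproducible: the same ``params.rng_seed`` gives a bit-identical
    event log and trajectories.
    """
    sim = SimState(domain, params)
    p = params
    n_samples = int(round(p.t_end / p.sample_dt))
    hist = np.zeros((n_samples, 180))
    cap = event_capacity if log_events else 1
    ev_t = np.zeros(cap)
    ev_mt = np.zeros(cap, np.int32)
    ev_target = np.zeros(cap, np.int8)
    ev_angle = np.zeros(cap, np.float32)
    ev_outcome = np.zeros(cap, np.int8)

    t, sample_idx, ev_count, n_applied = core.run_core(
        *sim._kernel_args(),
        p.alpha, p.beta, p.alpha_prime, p.beta_prime, p.p_cat,
        p.theta_critical, p.dimer_len, _RULE_CODE[p.rule_set],
        p.collapse_on_collision,
        0.0, p.t_end, 2**62,
        p.sample_dt, hist, 0,
        ev_t, ev_mt, ev_target, ev_angle, ev_outcome, 0,
    )
    sim.t = t

    times = (np.arange(n_samples) + 1) * p.sample_dt
    mtsd_series = mtsd_series_from_histograms(hist)

    window = min(p.avg_window, p.t_end)
    in_window = times > p.t_end - window + 1e-12
    if n_samples and in_window.any():
        final_hist = hist[in_window].mean(axis=0)
    else:
        final_hist = np.zeros(180)
    fit = fit_axial_von_mises(AngularHistogram(bin_edges=np.arange(181.0), weights=final_hist))

    stored = min(ev_count, cap) if log_events else 0
    events = pd.DataFrame(
        {
            "t": ev_t[:stored],
            "mt": ev_mt[:stored],
            "target": _TARGET_NAMES[ev_target[:stored]],
            "angle_deg": ev_angle[:stored].astype(float),
            "outcome": _OUTCOME_NAMES[ev_outcome[:stored]],
        }
    )
    return SimResult(
        params=params,
        domain=domain,
        times=times,
        histograms=hist,
        mtsd_series=mtsd_series,
        mtsd=fit.sigma,
        main_direction=fit.mu,
        fit=fit,
        events=events,
        polylines=sim.polylines(),
        n_events=n_applied,
    )


def detect_convergence(
    times_s: np.ndarray,
    mtsd: np.ndarray,
    window_s: float,
    tol: float = 0.10,
) -> float:
    """First time (seconds) the MTSD enters and remains within ``tol``
    (relative) of its convergence value, defined as the mean over the final
    ``window_s`` seconds.  Returns 0.0 if the whole series is within the
    band and NaN if the series never settles.
    """
    times_s = np.asarray(times_s, dtype=float)
    mtsd = np.asarray(mtsd, dtype=float)
    if len(times_s) != len(mtsd) or len(times_s) == 0:
        raise ValueError("times and series must be equal-length and non-empty")
    conv = mtsd[times_s > times_s[-1] - window_s].mean()
    band = tol * abs(conv)
    outside = np.abs(mtsd - conv) > band
    if not outside.any():
        return 0.0
    last_bad = int(np.nonzero(outside)[0][-1])
    if last_bad == len(mtsd) - 1:
        return NOT_CONVERGED
    return float(times_s[last_bad + 1])


@dataclass
class SweepResult:
    runs: pd.DataFrame
    summary: pd.DataFrame
    comparison: LinearFitComparison | None


def sweep_eccentricity(
    widths: list[float],
    eccentricities: list[float],
    params: SimParams,
    runs_per_point: int = 3,
    log_events: bool = False,
    shape_kind: str = "area_matched",
) -> SweepResult:
    """MTSD-versus-eccentricity sweep: ``runs_per_point`` independent runs per
    (width, eccentricity), plus the shared-vs-separate linear-fit comparison
    between widths when more than one width is given.

    The default cell geometry is the ``area_matched`` rectangle, whose
    length law reproduces the reference simulations' printed cell areas.
    """
    if runs_per_point < 1:
        raise ValueError("runs_per_point must be >= 1")
    rows = []
    for wi, width in enumerate(widths):
        for ei, ecc in enumerate(eccentricities):
            domain = build_cell_domain(width, ecc, shape_kind)
            for run in range(runs_per_point):
                seed = params.rng_seed * 1_000_003 + wi * 99_991 + ei * 1_009 + run
                res = run_simulation(domain, params.replace(rng_seed=seed), log_events=log_events)
                rows.append(
                    {
                        "width_nm": width,
                        "eccentricity": ecc,
                        "run": run,
                        "rng_seed": seed,
                        "mtsd_deg": res.mtsd,
                        "mtdev_deg": res.mtdev,
                        "convergence_s": res.convergence_time_s(),
                    }
                )
    runs = pd.DataFrame(rows)
    summary = (
        runs.groupby(["width_nm", "eccentricity"])["mtsd_deg"]
        .agg(mean_mtsd="mean", sd="std", n="count")
        .reset_index()
    )
    summary["sem"] = summary["sd"] / np.sqrt(summary["n"])
    comparison = None
    if len(widths) >= 2:
        datasets = [
            (g["eccentricity"].to_numpy(), g["mean_mtsd"].to_numpy())
            for _, g in summary.groupby("width_nm")
        ]
        comparison = compare_linear_fits(datasets)
    return SweepResult(runs=runs, summary=summary, comparison=comparison)


ANGLE_CATEGORIES = ["10-30", "31-60", "61-90"]


def collision_angle_summary(events: pd.DataFrame) -> pd.DataFrame:
    """Outcome frequencies by collision-angle category (10-30, 31-60, 61-90
    degrees), tabulated separately for boundary and microtubule targets.
    Events shallower than 10 degrees are excluded (unresolvable in the live
    imaging this mirrors)."""
    if events.empty:
        return pd.DataFrame(columns=["target", "category", "outcome", "count", "frequency"])
    ev = events.copy()
    ev["category"] = pd.cut(
        ev["angle_deg"],
        bins=[10.0, 30.0, 60.0, 90.0],
        labels=ANGLE_CATEGORIES,
        include_lowest=True,
    )
    ev = ev.dropna(subset=["category"])
    counts = (
        ev.groupby(["target", "category", "outcome"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    totals = counts.groupby(["target", "category"], observed=True)["count"].transform("sum")
    counts["frequency"] = counts["count"] / totals
    return counts
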