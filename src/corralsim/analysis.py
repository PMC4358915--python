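"""Trajectory analysis: depletion kinetics, PMFs, diffusion, burial.

The central observable is the pool concentration C(t): the number of
spheres still inside the corral (x < corral boundary), converted to a
surface concentration via the area per lipid.  Decay curves are fit by
the stretched exponential

    C(t) = (C0 - Cinf) exp[-(t/tau)^beta] + Cinf,       C0 = 6%

whose mean relaxation time is <tau> = (tau/beta) Gamma(1/beta).  Fence
quality is the ratio xi = <tau_free>/<tau>: 1 for free diffusion, 0 for
complete blockade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import gamma as gamma_fn

from .constants import BOLTZMANN_KCAL
from .fences import FenceAtoms
from .integrator import Trajectory
from .model_core import SystemGeometry

__all__ = [
    "DepletionSeries",
    "StretchedExpFit",
    "PMFProfile",
    "depletion_series",
    "fit_stretched_exponential",
    "mean_relaxation_time",
    "relaxation_ratio",
    "pmf_1d",
    "msd_diffusion",
    "burial_histogram",
]

DEFAULT_AREA_PER_LIPID = 65.0  # A^2; reproduces the reference particle counts


@dataclass
class DepletionSeries:
    """Pool concentration (%) vs time, per replica and averaged."""

    times: np.ndarray
    per_replica: np.ndarray  # (n_replicas, n_times) %
    mean: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.per_replica = np.atleast_2d(np.asarray(self.per_replica, dtype=float))
        self.mean = self.per_replica.mean(axis=0)

    @property
    def n_replicas(self) -> int:
        return self.per_replica.shape[0]

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame({"time": self.times, "mean": self.mean})
        for r in range(self.n_replicas):
            df[f"replica_{r}"] = self.per_replica[r]
        return df


@dataclass
class StretchedExpFit:
    """Parameters of Eq. C(t) = (C0-Cinf) exp[-(t/tau)^beta] + Cinf."""

    c0: float
    c_inf: float
    tau: float
    beta: float
    residual_norm: float
    converged: bool
    t_span: float = np.inf

    @property
    def mean_tau(self) -> float:
        return mean_relaxation_time(self.tau, self.beta)

    def __post_init__(self) -> None:
        if self.converged:
            if self.tau <= 0:
                raise ValueError("tau must be positive")
            if not (0 < self.beta <= 2):
                raise ValueError("beta must lie in (0, 2]")


def stretched_exponential(t: np.ndarray, c_inf: float, tau: float, beta: float, c0: float = 6.0) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return (c0 - c_inf) * np.exp(-np.power(np.maximum(t, 0.0) / tau, beta)) + c_inf


def concentration_percent(count, area: float, area_per_lipid: float = DEFAULT_AREA_PER_LIPID):
    """Convert a particle count in a region of ``area`` A^2 to mol% of lipids."""
    return 100.0 * np.asarray(count, dtype=float) * area_per_lipid / area


def depletion_series(
    trajectories: list[Trajectory],
    geometry: SystemGeometry,
    area_per_lipid: float = DEFAULT_AREA_PER_LIPID,
) -> DepletionSeries:
    """Pool concentration C(t) from a set of replica trajectories."""
    if not trajectories:
        raise ValueError("no trajectories supplied")
    times = trajectories[0].times
    per_rep = []
    for traj in trajectories:
        if traj.positions.size == 0:
            raise ValueError("trajectory has no snapshots")
        if len(traj.times) != len(times):
            raise ValueError("replicas must share the snapshot schedule")
        counts = (traj.positions[:, :, 0] < geometry.corral_boundary_x).sum(axis=1)
        per_rep.append(concentration_percent(counts, geometry.corral_area, area_per_lipid))
    return DepletionSeries(times=times, per_replica=np.array(per_rep))


def fit_stretched_exponential(
    series: DepletionSeries,
    c0: float = 6.0,
    c_inf_guess: float | None = None,
) -> StretchedExpFit:
    """Least-squares stretched-exponential fit of the mean decay curve.

    C0 is held fixed; (Cinf, tau, beta) are free.  Initialization is
    multi-start over beta in {0.4, 0.7, 1.0, 1.3} with tau seeded from
    the time at which the curve reaches halfway to the plateau guess;
    the best residual wins (ties to smallest beta).  A fit that fails
    every start is returned flagged, never raised silently.
    """
    t = series.times
    y = series.mean
    if len(t) < 10:
        raise ValueError("need at least 10 time points to fit")
    if c_inf_guess is None:
        c_inf_guess = max(float(y[-len(y) // 10 :].mean()), 0.0)

    halfway = 0.5 * (c0 + c_inf_guess)
    below = np.nonzero(y <= halfway)[0]
    tau_guess = float(t[below[0]]) if len(below) else float(t[-1])
    tau_guess = max(tau_guess, float(t[1] - t[0]))

    best = None
    for beta0 in (0.4, 0.7, 1.0, 1.3):
        try:
            popt, _ = curve_fit(
                lambda tt, ci, ta, be: stretched_exponential(tt, ci, ta, be, c0),
                t,
                y,
                p0=(c_inf_guess, tau_guess, beta0),
                bounds=([0.0, 1e-12, 0.05], [c0, np.inf, 2.0]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        resid = float(np.linalg.norm(y - stretched_exponential(t, *popt, c0)))
        if best is None or resid < best[0] - 1e-12 or (
            abs(resid - best[0]) <= 1e-12 and popt[2] < best[1][2]
        ):
            best = (resid, popt)
    if best is None:
        return StretchedExpFit(
            c0=c0, c_inf=float(y[-1]), tau=1.0, beta=1.0,
            residual_norm=np.inf, converged=False, t_span=float(t[-1] - t[0]),
        )
    resid, (c_inf, tau, beta) = best
    return StretchedExpFit(
        c0=c0, c_inf=float(c_inf), tau=float(tau), beta=float(beta),
        residual_norm=resid, converged=True, t_span=float(t[-1] - t[0]),
    )


def mean_relaxation_time(tau: float, beta: float) -> float:
    """<tau> = (tau/beta) * Gamma(1/beta)."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    if tau <= 0:
        raise ValueError("tau must be positive")
    return tau / beta * float(gamma_fn(1.0 / beta))


BLOCKADE_SPAN_FACTOR = 100.0


MIN_DECAY_FRACTION = 0.2


def relaxation_ratio(
    fit: StretchedExpFit,
    free_fit: StretchedExpFit,
    min_decay_fraction: float = MIN_DECAY_FRACTION,
) -> tuple[float, bool]:
    """xi = <tau_free>/<tau>, with the blockade convention.

    A fence is reported as a complete blockade (xi = 0, flagged True)
    when its curve never really decays: the fit failed to converge, the
    fitted mean relaxation time exceeds 100x the simulated span, or the
    fitted decay amplitude (C0 - Cinf) is below ``min_decay_fraction``
    of the free-diffusion amplitude (a flat curve makes tau
    unidentifiable, so the amplitude is the reliable signature).
    """
    if not free_fit.converged:
        raise ValueError("free-diffusion fit did not converge")
    tau_free = free_fit.mean_tau
    amplitude = fit.c0 - fit.c_inf
    free_amplitude = free_fit.c0 - free_fit.c_inf
    if (
        not fit.converged
        or fit.mean_tau > BLOCKADE_SPAN_FACTOR * fit.t_span
        or amplitude < min_decay_fraction * free_amplitude
    ):
        return 0.0, True
    if fit.mean_tau == 0:
        raise ValueError("mean relaxation time is zero")
    return tau_free / fit.mean_tau, False


@dataclass
class PMFProfile:
    """1D potential of mean force from Boltzmann-inverted concentrations."""

    x: np.ndarray  # bin centers, A
    w: np.ndarray  # kcal/mol
    concentration: np.ndarray  # %
    reference_concentration: float
    capped: np.ndarray  # bool per bin: empty bin, W capped


EMPTY_BIN_CAP = 10.0  # kcal/mol


def pmf_1d(
    trajectories: list[Trajectory],
    geometry: SystemGeometry,
    bin_width: float = 5.0,
    reference_concentration: float = 2.0,
    temperature: float = 300.0,
    area_per_lipid: float = DEFAULT_AREA_PER_LIPID,
    equilibration_fraction: float = 0.0,
) -> PMFProfile:
    """Boltzmann inversion of the equilibrium concentration profile.

    W(x) = -k_B T ln[C_eq(x)/C_ref]: bins depleted relative to the
    reference concentration carry a positive free-energy barrier.
    Empty bins are capped at +10 kcal/mol and flagged.
    """
    edges = np.arange(geometry.box_x_lo, geometry.box_x_hi + bin_width / 2, bin_width)
    if len(edges) < 3:
        raise ValueError("bin width too large for the box")
    counts = np.zeros(len(edges) - 1)
    n_frames = 0
    for traj in trajectories:
        start = int(equilibration_fraction * traj.n_frames)
        xs = traj.positions[start:, :, 0].ravel()
        counts += np.histogram(xs, bins=edges)[0]
        n_frames += traj.n_frames - start
    if counts.sum() == 0:
        raise ValueError("no samples in any bin")
    bin_area = bin_width * (geometry.box_y_hi - geometry.box_y_lo)
    conc = concentration_percent(counts / n_frames, bin_area, area_per_lipid)
    kT = BOLTZMANN_KCAL * temperature
    with np.errstate(divide="ignore"):
        w = -kT * np.log(conc / reference_concentration)
    capped = conc == 0
    w[capped] = EMPTY_BIN_CAP
    centers = 0.5 * (edges[:-1] + edges[1:])
    return PMFProfile(
        x=centers, w=w, concentration=conc,
        reference_concentration=reference_concentration, capped=capped,
    )


def msd_diffusion(
    trajectory: Trajectory,
    fit_window: tuple[float, float] | None = None,
    friction: float | None = None,
) -> float:
    """In-plane diffusion constant (cm^2/s) from the MSD slope / 4.

    The MSD is averaged over particles using the trajectory start as the
    single time origin (free diffusion only).  ``fit_window`` selects
    the lag-time range of the linear fit; it must start well past the
    velocity-relaxation time 1/gamma.
    """
    t = trajectory.times - trajectory.times[0]
    if fit_window is None:
        fit_window = (0.1 * t[-1], 0.8 * t[-1])
    lo, hi = fit_window
    if friction is not None and friction > 0 and hi - lo < 10.0 / friction:
        raise ValueError("fit window shorter than 10/gamma")
    dt_frame = t[1] - t[0] if len(t) > 1 else 0.0
    if dt_frame <= 0:
        raise ValueError("trajectory needs at least two frames")
    xy = trajectory.positions[:, :, :2]
    lags = np.arange(1, len(t))
    lag_t = lags * dt_frame
    sel = (lag_t >= lo) & (lag_t <= hi)
    if sel.sum() < 2:
        raise ValueError("fit window contains fewer than two points")
    # average over all time origins as well as particles
    msd = np.array(
        [((xy[ell:] - xy[:-ell]) ** 2).sum(axis=-1).mean() for ell in lags[sel]]
    )
    slope = np.polyfit(lag_t[sel], msd, 1)[0]  # A^2/ps
    return float(slope / 4.0 * 1e-4)  # 1 A^2/ps = 1e-4 cm^2/s


def burial_histogram(
    atoms: FenceAtoms,
    hydrophobic_boundary: float = -5.0,
    bin_width: float = 1.0,
    charged_residues: tuple[str, ...] = ("ASP", "GLU", "LYS", "ARG"),
) -> tuple[np.ndarray, np.ndarray]:
    """Charged residues below the hydrophobic boundary, per 1 A Z-bin.

    The boundary sits below the phosphate plane by the headgroup
    allowance (default plane - 5 A).  Each charged residue is
    represented by its charge-carrying atom.  Returns (bin lower edges
    measured downward from the boundary, counts).
    """
    if not atoms.residues:
        raise ValueError("atoms carry no residue labels")
    sel = np.array(
        [r in charged_residues for r in atoms.residues], dtype=bool
    ) & (atoms.charges != 0)
    z = atoms.coords[sel, 2]
    depths = hydrophobic_boundary - z[z < hydrophobic_boundary]
    if len(depths) == 0:
        max_depth = bin_width
    else:
        max_depth = float(np.ceil(depths.max() / bin_width) * bin_width) + bin_width
    edges = np.arange(0.0, max_depth + bin_width / 2, bin_width)
    counts = np.histogram(depths, bins=edges)[0]
    return edges[:-1], counts
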