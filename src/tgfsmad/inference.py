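"""Parameter estimation and profile-likelihood identifiability.

The objective is a weighted sum of squared residuals over a long-format
dataset of (dose, time, observable, value, sd) rows; model observables are
simulated per dose from the candidate's own ligand-free steady state.
Estimation is multi-start trust-region least squares in log10-parameter
space with box bounds; identifiability is assessed by profile likelihood
(re-optimizing the remaining parameters along a grid for each one) against
a chi-square-style threshold (default 3.84, pointwise 95%).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DomainError, EstimationFailedError, SimulationError
from .pathway_model import PathwayParams, presimulation_steady_state, simulate

__all__ = [
    "OBSERVABLE_MAP", "FitProblem", "FitResult", "ProfileCurve",
    "objective", "residuals", "fit_multistart", "profile_likelihood",
]

log = logging.getLogger(__name__)

# dataset observable name -> function of a TimeCourse row (state vector dict)
OBSERVABLE_MAP = {
    "medium_tgfb": lambda tc: tc["L"],
    "psmad2_total": lambda tc: tc["pS2c"] + tc["pS2n"],
    "smad2_cyt": lambda tc: tc["S2c"],
    "psmad2_cyt": lambda tc: tc["pS2c"],
    "smad2_nuc": lambda tc: tc["S2n"],
    "psmad2_nuc": lambda tc: tc["pS2n"],
}

# residual assigned to every row when a candidate's simulation fails;
# large but finite so optimizers can move away from the failing region
PENALTY_RESIDUAL = 1e6

DEFAULT_FREE = ("ka", "k_NFR", "kphos", "kdephos", "kin", "kex", "kin_p",
                "ki", "kr")


@dataclass(frozen=True)
class FitProblem:
    """A least-squares estimation problem over a subset of parameters.

    ``bounds`` are (log10 lo, log10 hi) per free parameter, defaulting to
    +/- 2 decades around the base parameter value.
    """

    base: PathwayParams
    dataset: pd.DataFrame  # columns: dose, time, observable, value, sd
    free_params: tuple = DEFAULT_FREE
    bounds: dict = field(default_factory=dict)
    rtol: float = 1e-6

    def __post_init__(self):
        required = {"dose", "time", "observable", "value", "sd"}
        missing = required - set(self.dataset.columns)
        if missing:
            raise DomainError(f"dataset missing columns: {sorted(missing)}")
        unknown = set(self.dataset["observable"]) - set(OBSERVABLE_MAP)
        if unknown:
            raise DomainError(f"unmapped observables: {sorted(unknown)}")
        for name in self.free_params:
            if not hasattr(self.base, name):
                raise DomainError(f"unknown free parameter {name!r}")
            if getattr(self.base, name) <= 0:
                raise DomainError(f"free parameter {name!r} needs a positive base value")
        if np.any(self.dataset["sd"] <= 0):
            raise DomainError("all sd values must be > 0")

    def log_bounds(self):
        lo, hi = [], []
        for name in self.free_params:
            if name in self.bounds:
                b = self.bounds[name]
            else:
                c = math.log10(getattr(self.base, name))
                b = (c - 2.0, c + 2.0)
            lo.append(b[0])
            hi.append(b[1])
        return np.array(lo), np.array(hi)

    def params_from_log10(self, theta) -> PathwayParams:
        vals = {n: 10.0 ** float(v) for n, v in zip(self.free_params, theta)}
        return replace(self.base, **vals)

    def log10_truth(self) -> np.ndarray:
        return np.array([math.log10(getattr(self.base, n)) for n in self.free_params])


@dataclass(frozen=True)
class FitResult:
    """Best multistart optimum (log10 scale estimates also retained)."""

    estimates: dict  # name -> fitted value (linear scale)
    objective: float
    n_starts: int
    converged_starts: int
    best_start_seed: int
    theta_log10: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class ProfileCurve:
    """Profile likelihood of one parameter around its fitted value."""

    param: str
    grid: np.ndarray  # parameter values (linear scale)
    objective_profile: np.ndarray
    threshold: float
    global_objective: float
    classification: str  # identifiable | practically-non-identifiable-left/right | structurally-flat

    @property
    def crosses_left(self) -> bool:
        return bool(np.any(self.objective_profile[self.grid < self._opt()]
                           > self.global_objective + self.threshold))

    @property
    def crosses_right(self) -> bool:
        return bool(np.any(self.objective_profile[self.grid > self._opt()]
                           > self.global_objective + self.threshold))

    def _opt(self):
        return self.grid[int(np.argmin(self.objective_profile))]


def _grouped(fp: FitProblem):
    """Pre-group dataset rows by dose for fast residual evaluation."""
    groups = []
    for dose, g in fp.dataset.groupby("dose", sort=True):
        times = np.unique(g["time"].to_numpy(dtype=float))
        if np.any(times <= 0):
            raise DomainError("data times must be > 0 (t=0 is the steady state)")
        t_grid = np.concatenate(([0.0], times))
        t_index = {t: i for i, t in enumerate(t_grid)}
        rows = [(r.observable, t_index[float(r.time)], float(r.value), float(r.sd))
                for r in g.itertuples()]
        groups.append((float(dose), t_grid, rows))
    return groups


def residuals(fp: FitProblem, theta_log10, _groups=None) -> np.ndarray:
    """Weighted residual vector (model - value)/sd for a log10 candidate.

    Simulation failure yields PENALTY_RESIDUAL for every affected row
    (flagged at warning level).
    """
    p = fp.params_from_log10(theta_log10)
    groups = _groups if _groups is not None else _grouped(fp)
    out = []
    for dose, t_grid, rows in groups:
        try:
            tc = simulate(p, dose, t_grid, rtol=fp.rtol,
                          y0=presimulation_steady_state(p))
        except (SimulationError, Exception) as exc:  # noqa: BLE001 - penalty path
            log.warning("simulation failed at dose %s: %s; penalty applied",
                        dose, exc)
            out.extend([PENALTY_RESIDUAL] * len(rows))
            continue
        series = {obs: fn(tc) for obs, fn in OBSERVABLE_MAP.items()}
        for obs, ti, value, sd in rows:
            out.append((float(series[obs][ti]) - value) / sd)
    return np.asarray(out)


def objective(fp: FitProblem, theta_log10) -> float:
    """Weighted SSR: sum of ((model - value)/sd)^2 over dataset rows."""
    r = residuals(fp, theta_log10)
    return float(np.dot(r, r))


def fit_multistart(
    fp: FitProblem,
    n_starts: int = 20,
    seed: int = 0,
    max_nfev: int = 300,
    polish_nfev: int = 600,
) -> FitResult:
    """Multi-start bounded least squares in log10-parameter space.

    Starts are log-uniform within bounds drawn from ``seed``; each runs a
    budgeted TRF solve, and the best start is polished with a larger
    budget.  Deterministic given the seed.
    """
    if n_starts < 1:
        raise DomainError("n_starts must be >= 1")
    lo, hi = fp.log_bounds()
    rng = np.random.default_rng(seed)
    starts = rng.uniform(lo, hi, size=(n_starts, len(lo)))
    groups = _grouped(fp)

    def res(theta):
        return residuals(fp, theta, _groups=groups)

    best = None
    converged = 0
    for k in range(n_starts):
        try:
            sol = least_squares(res, starts[k], bounds=(lo, hi), method="trf",
                                x_scale="jac", diff_step=1e-5,
                                ftol=1e-10, xtol=1e-10, gtol=1e-10,
                                max_nfev=max_nfev)
        except Exception as exc:  # noqa: BLE001
            log.warning("start %d failed: %s", k, exc)
            continue
        converged += 1
        obj = float(2.0 * sol.cost)
        if best is None or obj < best[0]:
            best = (obj, sol.x, k)
    if best is None:
        raise EstimationFailedError(f"all {n_starts} starts failed")
    _, x_best, k_best = best
    sol = least_squares(res, x_best, bounds=(lo, hi), method="trf",
                        x_scale="jac", diff_step=1e-5,
                        ftol=1e-12, xtol=1e-12, gtol=1e-12,
                        max_nfev=polish_nfev)
    obj = float(2.0 * sol.cost)
    estimates = {n: 10.0 ** float(v) for n, v in zip(fp.free_params, sol.x)}
    return FitResult(estimates=estimates, objective=obj, n_starts=n_starts,
                     converged_starts=converged, best_start_seed=k_best,
                     theta_log10=sol.x)


def profile_likelihood(
    fp: FitProblem,
    fit: FitResult,
    param: str,
    half_width_decades: float = 1.0,
    n_points: int = 11,
    threshold: float = 3.84,
    max_nfev: int = 150,
    flat_fraction: float = 0.01,
) -> ProfileCurve:
    """Profile one parameter, re-optimizing the others along the grid.

    The grid is log-spaced around the fitted value; points are visited
    outward from the optimum with warm starts.  Classification:
    ``identifiable`` if the profile exceeds objective+threshold on both
    sides, ``practically-non-identifiable-left/right`` if only one side
    crosses, ``structurally-flat`` if the total rise is below
    ``flat_fraction * threshold``.
    """
    if param not in fp.free_params:
        raise DomainError(f"{param!r} is not a free parameter")
    if n_points < 5:
        raise DomainError("n_points must be >= 5")
    idx = list(fp.free_params).index(param)
    others = [i for i in range(len(fp.free_params)) if i != idx]
    lo, hi = fp.log_bounds()
    groups = _grouped(fp)
    center = fit.theta_log10[idx]
    grid_log = np.linspace(center - half_width_decades,
                           center + half_width_decades, n_points)
    grid_log = np.clip(grid_log, lo[idx], hi[idx])

    prof = np.full(n_points, np.nan)

    def solve_at(fixed_log, warm):
        if not others:
            theta = np.array([fixed_log])
            r = residuals(fp, theta, _groups=groups)
            return float(np.dot(r, r)), np.array([])

        def res(sub):
            theta = np.empty(len(fp.free_params))
            theta[idx] = fixed_log
            theta[others] = sub
            return residuals(fp, theta, _groups=groups)

        sol = least_squares(res, np.clip(warm, lo[others], hi[others]),
                            bounds=(lo[others], hi[others]), method="trf",
                            x_scale="jac", diff_step=1e-5,
                            ftol=1e-10, xtol=1e-10, gtol=1e-10,
                            max_nfev=max_nfev)
        return float(2.0 * sol.cost), sol.x

    order_center = int(np.argmin(np.abs(grid_log - center)))
    # outward sweeps, warm-started from the previous grid point
    for direction in (range(order_center, n_points),
                      range(order_center, -1, -1)):
        warm = fit.theta_log10[others].copy()
        for j in direction:
            if not math.isnan(prof[j]):
                continue
            try:
                prof[j], sub = solve_at(grid_log[j], warm)
                if len(sub):
                    warm = sub
            except Exception as exc:  # noqa: BLE001
                log.warning("profile point %s=%g failed: %s", param,
                            10.0 ** grid_log[j], exc)
                prof[j] = np.nan
    # repair the doubly-visited center point if it was skipped
    if math.isnan(prof[order_center]):
        prof[order_center], _ = solve_at(grid_log[order_center],
                                         fit.theta_log10[others].copy())

    base = min(fit.objective, np.nanmin(prof))
    rise = np.nanmax(prof) - base
    left = np.any(prof[:order_center] > base + threshold) if order_center > 0 else False
    right = (np.any(prof[order_center + 1:] > base + threshold)
             if order_center < n_points - 1 else False)
    if rise < flat_fraction * threshold:
        classification = "structurally-flat"
    elif left and right:
        classification = "identifiable"
    elif left:
        classification = "practically-non-identifiable-right"
    elif right:
        classification = "practically-non-identifiable-left"
    else:
        classification = "practically-non-identifiable-both"
    return ProfileCurve(param=param, grid=10.0 ** grid_log,
                        objective_profile=prof, threshold=threshold,
                        global_objective=fit.objective,
                        classification=classification)
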