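"""Synthetic dataset generators with stored ground truth.

Every generator emulates one of the study-style measurement tables —
multi-dose immunoblot time courses, siRNA receptor-knockdown dose
responses, and single-cell imaging quantifications — by simulating a known
truth model and applying multiplicative log-normal measurement noise
(mean-1 factors), so downstream recovery tests compare against the exact
truth carried in sidecar metadata rather than re-deriving it from noisy
tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dose_response import DoseResponseDataset, predict_knockdown_response
from .errors import DomainError
from .inference import OBSERVABLE_MAP
from .observables import n2c_fold_change
from .pathway_model import PathwayParams, presimulation_steady_state, simulate
from .single_cell import draw_population, simulate_population

__all__ = [
    "SyntheticSpec", "gen_timecourse_dataset", "sirna_knockdown_curve",
    "gen_knockdown_dataset", "gen_single_cell_dataset",
    "DEFAULT_TIMECOURSE_LAYOUT",
]

# Default 102-row layout: 6 observables x 17 (dose, time) pairs.
# Times in minutes per dose (nM); the low dose omits the earliest time.
DEFAULT_TIMECOURSE_LAYOUT = {
    0.01: (30.0, 60.0, 120.0, 240.0, 480.0),
    0.1: (15.0, 30.0, 60.0, 120.0, 240.0, 480.0),
    1.0: (15.0, 30.0, 60.0, 120.0, 240.0, 480.0),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Truth model plus sampling layout and noise settings."""

    truth: PathwayParams
    doses: tuple = tuple(DEFAULT_TIMECOURSE_LAYOUT)
    times: dict = field(default_factory=lambda: dict(DEFAULT_TIMECOURSE_LAYOUT))
    noise_model: str = "multiplicative-lognormal"
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not self.doses:
            raise DomainError("doses must be non-empty")
        for d in self.doses:
            if d not in self.times or not len(self.times[d]):
                raise DomainError(f"no times configured for dose {d}")
        if self.noise_model not in ("multiplicative-lognormal", "additive-gaussian"):
            raise DomainError(f"unknown noise model {self.noise_model!r}")
        if self.noise_cv < 0:
            raise DomainError("noise_cv must be >= 0")

    def metadata(self) -> dict:
        """JSON-ready sidecar: truth parameters, layout, noise, seed."""
        from dataclasses import asdict

        return {
            "truth": asdict(self.truth),
            "doses": list(self.doses),
            "times": {str(d): list(t) for d, t in self.times.items()},
            "noise_model": self.noise_model,
            "noise_cv": self.noise_cv,
            "seed": self.seed,
        }


def _noise_factors(rng, cv, n):
    """Mean-1 multiplicative log-normal factors with sd/mean = cv."""
    if cv == 0:
        return np.ones(n)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2), size=n)


def gen_timecourse_dataset(spec: SyntheticSpec, rtol: float = 1e-8) -> pd.DataFrame:
    """Long-format fit-ready table (dose, time, observable, value, sd).

    With the default layout this is exactly 102 rows: 6 observables over 17
    (dose, time) pairs.  ``sd`` is noise_cv * value, floored at noise_cv
    times 1% of the observable's per-dose maximum (so weights stay finite
    near zero-crossing observables); a 5% floor of the dynamic range is
    used when noise_cv is 0.
    """
    rng = np.random.default_rng(spec.seed)
    y0 = presimulation_steady_state(spec.truth)
    rows = []
    for dose in spec.doses:
        times = np.asarray(sorted(spec.times[dose]), dtype=float)
        t_grid = np.concatenate(([0.0], times))
        tc = simulate(spec.truth, dose, t_grid, rtol=rtol, y0=y0)
        for obs, fn in OBSERVABLE_MAP.items():
            series = fn(tc)
            obs_max = float(np.max(series)) if np.max(series) > 0 else 1.0
            for i, t in enumerate(times):
                value = float(series[i + 1])
                cv = spec.noise_cv if spec.noise_cv > 0 else 0.05
                sd = max(cv * value, cv * 0.01 * obs_max)
                rows.append((dose, t, obs, value, sd))
    df = pd.DataFrame(rows, columns=["dose", "time", "observable", "value", "sd"])
    if spec.noise_cv > 0:
        if spec.noise_model == "multiplicative-lognormal":
            df["value"] *= _noise_factors(rng, spec.noise_cv, len(df))
        else:
            df["value"] += rng.normal(0.0, 1.0, len(df)) * df["sd"]
    return df


def sirna_knockdown_curve(concs, kd_max: float = 0.95, kd_ic50: float = 1.0,
                          kd_n: float = 1.0) -> np.ndarray:
    """Receptor fold change remaining at each siRNA concentration (nM).

    fc(c) = 1 - kd_max * c^n / (kd_ic50^n + c^n); fc(0) = 1 and
    fc -> 1 - kd_max as c -> infinity.
    """
    concs = np.asarray(concs, dtype=float)
    if np.any(concs < 0):
        raise DomainError("siRNA concentrations must be >= 0")
    if not 0.0 <= kd_max <= 1.0:
        raise DomainError("kd_max must be in [0, 1]")
    if kd_ic50 <= 0 or kd_n <= 0:
        raise DomainError("kd_ic50 and kd_n must be > 0")
    cn = np.power(concs, kd_n)
    return 1.0 - kd_max * cn / (kd_ic50 ** kd_n + cn)


def gen_knockdown_dataset(
    truth: PathwayParams,
    receptor: str,
    concs=(0.08, 0.4, 2.0, 10.0, 20.0, 50.0, 100.0),
    kd_max: float = 0.95,
    kd_ic50: float = 1.0,
    kd_n: float = 1.0,
    n_replicates: int = 3,
    noise_cv: float = 0.05,
    dose: float = 0.1,
    t_eval: float = 60.0,
    seed: int = 0,
    rtol: float = 1e-8,
):
    """siRNA-style dose-response table with replicates and truth EC50.

    Returns (DataFrame with columns receptor_fc, response_fc, replicate;
    metadata dict carrying the noiseless curve and the ground-truth EC50
    found by root-finding on the noiseless model response).
    """
    if n_replicates < 1:
        raise DomainError("n_replicates must be >= 1")
    fcs = sirna_knockdown_curve(concs, kd_max, kd_ic50, kd_n)
    fold_changes = sorted(set(np.concatenate(([1.0], fcs))), reverse=True)
    ds = predict_knockdown_response(truth, receptor, fold_changes,
                                    dose=dose, t_eval=t_eval, rtol=rtol)
    x, y = ds.arrays()

    # ground-truth EC50: fold change where the noiseless response crosses 0.5,
    # located on the continuous model response by bisection
    def resp_minus_half(log_fc):
        d = predict_knockdown_response(truth, receptor, [10.0 ** log_fc],
                                       dose=dose, t_eval=t_eval, rtol=rtol)
        return float(d.arrays()[1][0]) - 0.5

    truth_ec50 = None
    if y.min() < 0.5 < y.max():
        lo = math.log10(x[int(np.argmin(y))])
        truth_ec50 = 10.0 ** brentq(resp_minus_half, lo, 0.0, xtol=1e-10)

    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        fx = _noise_factors(rng, noise_cv, len(x))
        fy = _noise_factors(rng, noise_cv, len(y))
        for xi, yi, fxi, fyi in zip(x, y, fx, fy):
            rows.append((xi * fxi, yi * fyi, rep))
    df = pd.DataFrame(rows, columns=["receptor_fc", "response_fc", "replicate"])
    meta = {
        "receptor": receptor,
        "kd_max": kd_max, "kd_ic50": kd_ic50, "kd_n": kd_n,
        "noise_cv": noise_cv, "seed": seed, "dose": dose, "t_eval": t_eval,
        "noiseless_fc": list(map(float, x)),
        "noiseless_response": list(map(float, y)),
        "truth_ec50": truth_ec50,
    }
    return df, meta


def gen_single_cell_dataset(
    truth: PathwayParams,
    n_cells: int = 102,
    cv: float = 0.1,
    tie_receptors: bool = True,
    dose: float = 0.1,
    times=(20.0, 60.0),
    intensity_noise_cv: float = 0.05,
    seed: int = 0,
    rtol: float = 1e-8,
):
    """Imaging-style per-cell table: reporter intensity + N2C fold changes.

    Reporter intensity is proportional to the cell's total type II receptor
    with multiplicative noise; fold-change columns carry measurement noise
    except at t=0 where normalization makes the value exactly 1.
    Returns (DataFrame, metadata dict).
    """
    if n_cells < 1:
        raise DomainError("n_cells must be >= 1")
    pop = draw_population(truth, cv=cv, n_cells=n_cells,
                          tie_receptors=tie_receptors, seed=seed)
    resp = simulate_population(pop, dose=dose, response_times=times, rtol=rtol)
    rng = np.random.default_rng(seed + 1)
    df = resp.copy()
    df["reporter_intensity"] = (df["R2_0"].to_numpy()
                                * _noise_factors(rng, intensity_noise_cv, len(df)))
    df["n2c_fc_0min"] = 1.0
    for t in times:
        col = f"n2c_fc_{float(t):g}min"
        df[col] = df[col].to_numpy() * _noise_factors(rng, intensity_noise_cv, len(df))
    meta = {
        "n_cells": n_cells, "cv": cv, "tie_receptors": tie_receptors,
        "dose": dose, "times": [float(t) for t in times],
        "intensity_noise_cv": intensity_noise_cv, "seed": seed,
    }
    return df, meta
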