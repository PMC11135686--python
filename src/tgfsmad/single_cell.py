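"""Single-cell heterogeneity simulations and correlation analysis.

Cell-to-cell variability is modelled by drawing receptor production rates,
total SMAD2 and the negative-feedback constant k_NFR per cell from
log-normal distributions whose arithmetic mean equals the population value
(times an optional fold multiplier) and whose coefficient of variation is
configurable (0.1 by default).  Each cell is simulated independently from
its own ligand-free steady state under constant ligand (no shared-medium
depletion), and the N2C fold-change response is correlated (Pearson, raw
values) against per-cell protein abundances and k_NFR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, SimulationError
from .observables import n2c_fold_change
from .pathway_model import PathwayParams, presimulation_steady_state, simulate

__all__ = ["CellPopulation", "CorrelationReport", "draw_population",
           "simulate_population", "correlate", "COVARIATES"]

VARIED = ("pR1", "pR2", "s2_tot", "k_NFR")
COVARIATES = ("R1_0", "R2_0", "S2_0", "k_NFR")


@dataclass(frozen=True)
class CellPopulation:
    """Per-cell kinetic parameter draws around a population model."""

    base: PathwayParams
    params: np.ndarray  # shape (n_cells, 4): pR1, pR2, s2_tot, k_NFR
    cv: float
    mean_multipliers: dict
    tie_receptors: bool
    seed: int

    @property
    def n_cells(self) -> int:
        return self.params.shape[0]

    def cell_params(self, i: int) -> PathwayParams:
        pr1, pr2, s2, knfr = self.params[i]
        return replace(self.base, pR1=pr1, pR2=pr2, s2_tot=s2, k_NFR=knfr)


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson correlations of a response against per-cell covariates."""

    response_time: float
    covariates: tuple  # of (name, pearson_r, p_value); r is nan if undefined
    n_cells: int

    def r(self, name: str) -> float:
        for nm, r, _ in self.covariates:
            if nm == name:
                return r
        raise KeyError(name)


def _lognormal_mu_sigma(mean: float, cv: float):
    """(mu, sigma) of a log-normal with given arithmetic mean and cv."""
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def draw_population(
    p: PathwayParams,
    cv: float = 0.1,
    n_cells: int = 1000,
    mean_multipliers: dict | None = None,
    tie_receptors: bool = False,
    seed: int = 0,
) -> CellPopulation:
    """Draw per-cell (pR1, pR2, s2_tot, k_NFR) from log-normals.

    Each parameter's distribution mean equals the population value times
    its entry in ``mean_multipliers`` (default 1).  ``tie_receptors`` forces
    pR1 == pR2 in every cell (single shared draw); combined with equal base
    production this yields a per-cell receptor ratio of exactly 1.
    """
    if cv < 0:
        raise DomainError("cv must be >= 0")
    if n_cells < 1:
        raise DomainError("n_cells must be >= 1")
    mm = {k: 1.0 for k in VARIED}
    if mean_multipliers:
        unknown = set(mean_multipliers) - set(VARIED)
        if unknown:
            raise DomainError(f"unknown mean_multipliers keys: {sorted(unknown)}")
        mm.update(mean_multipliers)
    rng = np.random.default_rng(seed)
    cols = []
    draws = {}
    for name in VARIED:
        mean = getattr(p, name) * mm[name]
        if cv == 0 or mean == 0:
            draws[name] = np.full(n_cells, mean)
        else:
            mu, sigma = _lognormal_mu_sigma(mean, cv)
            draws[name] = rng.lognormal(mu, sigma, size=n_cells)
    if tie_receptors:
        # single ratio keeps the per-cell R1:R2 ratio exact (1.0 when the
        # population means coincide)
        ratio = (p.pR2 * mm["pR2"]) / (p.pR1 * mm["pR1"])
        draws["pR2"] = draws["pR1"] * ratio
    cols = np.column_stack([draws[n] for n in VARIED])
    return CellPopulation(base=p, params=cols, cv=cv, mean_multipliers=mm,
                          tie_receptors=tie_receptors, seed=seed)


def simulate_population(
    pop: CellPopulation,
    dose: float = 0.1,
    response_times=(60.0, 480.0),
    rtol: float = 1e-8,
    deplete_ligand: bool = False,
) -> pd.DataFrame:
    """Per-cell covariates and N2C fold-change responses.

    Returns one row per cell with columns cell_id, R1_0, R2_0, S2_0, k_NFR,
    ok, and ``n2c_fc_<t>min`` per requested time.  Ligand is a constant
    boundary per cell unless ``deplete_ligand`` is set.  Cells whose
    simulation fails are flagged ``ok=False`` with NaN responses.
    """
    response_times = sorted(float(t) for t in response_times)
    if not response_times or response_times[0] <= 0:
        raise DomainError("response times must be positive")
    t_grid = np.unique(np.concatenate(([0.0], response_times)))
    rows = []
    for i in range(pop.n_cells):
        pi = pop.cell_params(i)
        if not deplete_ligand:
            pi = replace(pi, med_scale=0.0)
        row = {"cell_id": i, "k_NFR": pi.k_NFR, "ok": True}
        try:
            y0 = presimulation_steady_state(pi)
            row.update(R1_0=y0.r1_total, R2_0=y0.r2_total, S2_0=y0.smad2_total)
            tc = simulate(pi, dose, t_grid, rtol=rtol, y0=y0)
            fc = n2c_fold_change(tc)
            for t in response_times:
                row[f"n2c_fc_{t:g}min"] = fc.at(t)
        except SimulationError:
            row["ok"] = False
            for t in response_times:
                row[f"n2c_fc_{t:g}min"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def correlate(responses: pd.DataFrame, response_time: float) -> CorrelationReport:
    """Pearson r and two-sided p of N2C fold change vs each covariate.

    Covariates and responses enter untransformed.  A zero-variance
    covariate yields r = nan, p = nan for that entry.
    """
    col = f"n2c_fc_{response_time:g}min"
    if col not in responses.columns:
        raise DomainError(f"no response column {col!r}")
    df = responses[responses.get("ok", True) & responses[col].notna()]
    if len(df) < 3:
        raise DomainError("need at least 3 cells with finite responses")
    out = []
    y = df[col].to_numpy()
    for name in COVARIATES:
        x = df[name].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out.append((name, float("nan"), float("nan")))
            continue
        r, pval = stats.pearsonr(x, y)
        out.append((name, float(r), float(pval)))
    return CorrelationReport(response_time=response_time,
                             covariates=tuple(out), n_cells=len(df))
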