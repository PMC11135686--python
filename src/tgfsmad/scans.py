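"""Expression-space sampling and response landscapes.

Receptor production rates and total SMAD2 are scaled by log-uniform random
multipliers (receptors over 5 decades by default, SMAD2 over 2), each draw
is re-equilibrated ligand-free and stimulated, and the scale-free readouts
are collected at a fixed evaluation time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DomainError, SimulationError
from .observables import n2c_fold_change, relative_psmad2
from .pathway_model import PathwayParams, presimulation_steady_state, simulate

__all__ = [
    "ExpressionDraws",
    "LandscapeResult",
    "sample_expression_space",
    "landscape",
    "bin_landscape",
    "contour_crossing",
    "variance_explained",
]

PROTEINS = ("r1", "r2", "s2")


@dataclass(frozen=True)
class ExpressionDraws:
    """Per-draw multiplicative scale factors for (pR1, pR2, total SMAD2)."""

    multipliers: np.ndarray  # shape (n, 3), strictly positive
    seed: int

    def __post_init__(self):
        if self.multipliers.ndim != 2 or self.multipliers.shape[1] != 3:
            raise DomainError("multipliers must have shape (n, 3)")
        if np.any(self.multipliers <= 0):
            raise DomainError("multipliers must be strictly positive")

    @property
    def n(self) -> int:
        return self.multipliers.shape[0]


@dataclass(frozen=True)
class LandscapeResult:
    """Scale-free readouts per expression draw at a fixed time and dose."""

    draws: ExpressionDraws
    rel_psmad2_at_t: np.ndarray
    n2c_fc_at_t: np.ndarray
    t_eval: float
    dose: float

    def to_frame(self) -> pd.DataFrame:
        m = self.draws.multipliers
        return pd.DataFrame(
            {
                "r1_mult": m[:, 0],
                "r2_mult": m[:, 1],
                "s2_mult": m[:, 2],
                "rel_psmad2": self.rel_psmad2_at_t,
                "n2c_fc": self.n2c_fc_at_t,
            }
        )


def sample_expression_space(
    n: int,
    seed: int,
    decades_r: float = 5.0,
    decades_s: float = 2.0,
    center: float = 1.0,
) -> ExpressionDraws:
    """Independent log-uniform draws of (r1, r2, s2) multipliers.

    Each span is centered (in log10) on ``center``; receptor axes share
    ``decades_r``, SMAD2 uses ``decades_s``.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    if decades_r < 0 or decades_s < 0:
        raise DomainError("spans must be >= 0")
    if center <= 0:
        raise DomainError("center must be positive")
    rng = np.random.default_rng(seed)
    c = np.log10(center)
    lo = np.array([c - decades_r / 2, c - decades_r / 2, c - decades_s / 2])
    hi = np.array([c + decades_r / 2, c + decades_r / 2, c + decades_s / 2])
    logs = rng.uniform(lo, hi, size=(n, 3))
    return ExpressionDraws(multipliers=10.0 ** logs, seed=seed)


def landscape(
    draws: ExpressionDraws,
    p: PathwayParams,
    dose: float = 0.1,
    t_eval: float = 60.0,
    rtol: float = 1e-8,
) -> LandscapeResult:
    """Simulate each draw from its own ligand-free steady state.

    ``dose`` in nM, ``t_eval`` in minutes.  Readouts are relative P-SMAD2
    and N2C fold change at ``t_eval``.
    """
    t_grid = np.array([0.0, t_eval / 2.0, t_eval])
    rel = np.empty(draws.n)
    fc = np.empty(draws.n)
    for i, (m1, m2, m3) in enumerate(draws.multipliers):
        pi = replace(p, pR1=p.pR1 * m1, pR2=p.pR2 * m2, s2_tot=p.s2_tot * m3)
        try:
            tc = simulate(pi, dose, t_grid, rtol=rtol,
                          y0=presimulation_steady_state(pi))
        except SimulationError as exc:
            raise SimulationError(f"draw {i}: {exc}", t_fail=exc.t_fail) from exc
        rel[i] = relative_psmad2(tc).at(t_eval)
        fc[i] = n2c_fold_change(tc).at(t_eval)
    return LandscapeResult(draws=draws, rel_psmad2_at_t=rel, n2c_fc_at_t=fc,
                           t_eval=t_eval, dose=dose)


def bin_landscape(result: LandscapeResult, n_bins: int = 25) -> pd.DataFrame:
    """Median-aggregate scattered draws onto a 2-D log-spaced receptor grid."""
    df = result.to_frame()
    lx = np.log10(df["r1_mult"])
    ly = np.log10(df["r2_mult"])
    bx = np.linspace(lx.min(), lx.max(), n_bins + 1)
    by = np.linspace(ly.min(), ly.max(), n_bins + 1)
    df = df.assign(
        ix=np.clip(np.digitize(lx, bx) - 1, 0, n_bins - 1),
        iy=np.clip(np.digitize(ly, by) - 1, 0, n_bins - 1),
    )
    g = df.groupby(["ix", "iy"], as_index=False).agg(
        r1_mult=("r1_mult", "median"),
        r2_mult=("r2_mult", "median"),
        rel_psmad2=("rel_psmad2", "median"),
        n2c_fc=("n2c_fc", "median"),
        n=("rel_psmad2", "size"),
    )
    return g.drop(columns=["ix", "iy"])


def contour_crossing(
    result: LandscapeResult,
    level: float,
    abundant_log10_range: tuple,
    scarce: str = "r1",
    n_bins: int = 15,
    min_per_bin: int = 3,
) -> float:
    """Scarce-receptor multiplier at which the response crosses ``level``.

    Restricts draws to a slice of the abundant receptor's log10 multiplier,
    keeps those where the scarce receptor is the smaller one, bins the
    response along the scarce axis (median per bin), and interpolates the
    crossing.  Tracking this across abundant-receptor slices measures how
    L-shaped the iso-response contours are: for a minimum-rule landscape
    the crossing barely moves while the abundant receptor spans decades.
    """
    if scarce not in ("r1", "r2"):
        raise DomainError("scarce must be 'r1' or 'r2'")
    abundant = "r2" if scarce == "r1" else "r1"
    df = result.to_frame()
    la = np.log10(df[f"{abundant}_mult"])
    lo, hi = abundant_log10_range
    sub = df[(la >= lo) & (la < hi)
             & (df[f"{scarce}_mult"] < df[f"{abundant}_mult"])]
    if len(sub) < 5 * min_per_bin:
        raise DomainError("too few draws in the requested slice")
    sub = sub.sort_values(f"{scarce}_mult")
    lx = np.log10(sub[f"{scarce}_mult"].to_numpy())
    y = sub["rel_psmad2"].to_numpy()
    edges = np.linspace(lx.min(), lx.max(), n_bins)
    idx = np.digitize(lx, edges)
    bx, by = [], []
    for b in np.unique(idx):
        m = idx == b
        if m.sum() >= min_per_bin:
            bx.append(lx[m].mean())
            by.append(float(np.median(y[m])))
    if len(bx) < 3 or not (min(by) <= level <= max(by)):
        raise DomainError("level not bracketed by the binned response")
    return float(10.0 ** np.interp(level, np.asarray(by), np.asarray(bx)))


def variance_explained(covariate: np.ndarray, response: np.ndarray,
                       n_bins: int = 10) -> float:
    """Fraction of response variance explained by quantile-binning a covariate."""
    covariate = np.asarray(covariate, dtype=float)
    response = np.asarray(response, dtype=float)
    if response.var() == 0:
        return 0.0
    q = pd.qcut(covariate, n_bins, duplicates="drop")
    means = pd.Series(response).groupby(q, observed=True).transform("mean")
    return float(means.var() / response.var())
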