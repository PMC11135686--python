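"""Mass-action ODE model of the TGF-beta/SMAD2 pathway.

Compartments: extracellular medium (ligand, nM), cell surface and endosomes
(receptors and ligand-receptor complexes, abundance-units), cytoplasm and
nucleus (SMAD2 pools, abundance-units).  Reactions:

* receptor synthesis to the surface (pR1, pR2)
* internalization ki and recycling kr of free receptors; complexes are
  internalized but not recycled
* constitutive receptor degradation kdeg from both surface and endosomal
  pools (so total receptor at the ligand-free steady state is p/kdeg)
* one-step ternary complex formation ka*L*R1m*R2m consuming one receptor of
  each type and depleting medium ligand by med_scale per complex formed
* ligand-induced degradation of the endosomal complex, k_NFR*LRCe
  (the negative-feedback stand-in)
* SMAD2 phosphorylation kphos*LRCe*S2c, nucleocytoplasmic shuttling
  (kin, kex for SMAD2; kin_p import-only for P-SMAD2) and nuclear
  dephosphorylation kdephos returning nuclear SMAD2

State variables are amounts; the nuclear:cytoplasmic volume ratio enters
only when converting to intensity-style N2C ratios (observables module).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

from .errors import ConvergenceError, DomainError, SimulationError

__all__ = [
    "SPECIES",
    "PathwayParams",
    "PathwayState",
    "DoseSchedule",
    "TimeCourse",
    "default_params",
    "rhs",
    "presimulation_steady_state",
    "simulate",
    "dose_convert",
]

SPECIES = (
    "L", "R1m", "R2m", "R1e", "R2e", "LRCm", "LRCe",
    "S2c", "S2n", "pS2c", "pS2n",
)
_IDX = {name: i for i, name in enumerate(SPECIES)}

_RATE_FIELDS = (
    "pR1", "pR2", "pS2", "kdeg_R1", "kdeg_R2", "kdeg_S2", "ki", "kr",
    "ka", "k_NFR", "kphos", "kdephos", "kin", "kex", "kin_p",
)


@dataclass(frozen=True)
class PathwayParams:
    """Kinetic parameters of the extended model.

    Rates are per minute; ``ka`` in 1/(nM*abundance*min); ``kphos`` in
    1/(abundance*min); ``med_scale`` in nM per abundance-unit of complex
    formed; ``mw_ligand`` in kDa.  ``s2_tot`` is the total SMAD2 amount
    used in conservation mode (``pS2 == kdeg_S2 == 0``).
    """

    pR1: float
    pR2: float
    kdeg_R1: float
    kdeg_R2: float
    ki: float
    kr: float
    ka: float
    k_NFR: float
    kphos: float
    kdephos: float
    kin: float
    kex: float
    kin_p: float
    s2_tot: float
    pS2: float = 0.0
    kdeg_S2: float = 0.0
    vol_ratio_nc: float = 1.0 / 3.0
    med_scale: float = 0.0
    mw_ligand: float = 25.0

    def __post_init__(self):
        for name in _RATE_FIELDS + ("s2_tot", "med_scale"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise DomainError(f"{name} must be finite and >= 0, got {v}")
        if self.vol_ratio_nc <= 0:
            raise DomainError("vol_ratio_nc must be > 0")
        if self.mw_ligand <= 0:
            raise DomainError("mw_ligand must be > 0")

    @property
    def conservation_mode(self) -> bool:
        """True when SMAD2 has no synthesis or turnover (total conserved)."""
        return self.pS2 == 0.0 and self.kdeg_S2 == 0.0

    @staticmethod
    def kdeg_from_half_life(t_half_min: float) -> float:
        """First-order degradation constant from a half-life in minutes."""
        if t_half_min <= 0:
            raise DomainError("half-life must be positive")
        return math.log(2.0) / t_half_min


@dataclass(frozen=True)
class PathwayState:
    """One compartmental state of the pathway (amounts; L in nM)."""

    L: float
    R1m: float
    R2m: float
    R1e: float
    R2e: float
    LRCm: float
    LRCe: float
    S2c: float
    S2n: float
    pS2c: float
    pS2n: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "PathwayState":
        return cls(**{s: float(y[i]) for i, s in enumerate(SPECIES)})

    @property
    def r1_total(self) -> float:
        return self.R1m + self.R1e

    @property
    def r2_total(self) -> float:
        return self.R2m + self.R2e

    @property
    def smad2_total(self) -> float:
        return self.S2c + self.S2n + self.pS2c + self.pS2n


@dataclass(frozen=True)
class DoseSchedule:
    """Ligand additions to the medium: (time_min, added_nM) steps."""

    events: tuple = ()

    @classmethod
    def bolus(cls, dose_nM: float, at_min: float = 0.0) -> "DoseSchedule":
        return cls(events=((float(at_min), float(dose_nM)),))

    def __post_init__(self):
        ev = tuple(sorted((float(t), float(d)) for t, d in self.events))
        object.__setattr__(self, "events", ev)
        for t, d in ev:
            if t < 0 or d < 0:
                raise DomainError("dose events need time >= 0 and dose >= 0")


@dataclass(frozen=True)
class TimeCourse:
    """A simulated trajectory on a fixed time grid (minutes)."""

    t: np.ndarray
    states: np.ndarray  # (len(t), len(SPECIES))
    dose_schedule: DoseSchedule
    params: PathwayParams = field(repr=False, default=None)

    def __post_init__(self):
        if self.states.shape[0] != len(self.t):
            raise DomainError("states row count must equal len(t)")
        if np.any(np.diff(self.t) <= 0):
            raise DomainError("t must be strictly increasing")

    def __getitem__(self, species: str) -> np.ndarray:
        return self.states[:, _IDX[species]]

    def state_at(self, t: float) -> PathwayState:
        i = int(np.argmin(np.abs(self.t - t)))
        if abs(self.t[i] - t) > 1e-9 * max(1.0, abs(t)):
            raise DomainError(f"time {t} not on the simulation grid")
        return PathwayState.from_array(self.states[i])

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(SPECIES))
        df.insert(0, "t_min", self.t)
        return df


def default_params(preset: str = "hacat_like") -> PathwayParams:
    """Packaged parameter presets.

    ``hacat_like`` is a balanced-receptor epithelial-like cell: equal
    receptor production, receptor half-life ~4 h, and rate constants tuned
    so a sustained 100 pM ligand input gives a total P-SMAD2 peak near 1 h
    followed by feedback-driven decline.  ``r1_rich`` / ``r2_rich`` are the
    same cell with a 25-fold production imbalance between receptor types.
    """
    kdeg_r = math.log(2.0) / 240.0  # 4 h receptor half-life
    base = dict(
        pR1=kdeg_r * 1.0,       # receptor totals normalized to 1 abundance-unit
        pR2=kdeg_r * 1.0,
        kdeg_R1=kdeg_r,
        kdeg_R2=kdeg_r,
        ki=0.033,               # internalization, ~30 min surface residence
        kr=0.033,
        ka=3.0,
        k_NFR=0.03,
        kphos=0.3,
        kdephos=0.04,
        kin=0.01,
        kex=0.05,
        kin_p=0.05,
        s2_tot=10.0,
        vol_ratio_nc=1.0 / 3.0,
        med_scale=0.002,
        mw_ligand=25.0,
    )
    if preset == "hacat_like":
        return PathwayParams(**base)
    if preset == "r1_rich":
        return PathwayParams(**{**base, "pR1": base["pR1"] * 25.0})
    if preset == "r2_rich":
        return PathwayParams(**{**base, "pR2": base["pR2"] * 25.0})
    raise DomainError(f"unknown preset {preset!r}")


def rhs(t: float, y: np.ndarray, p: PathwayParams) -> np.ndarray:
    """Mass-action right-hand side, d(state)/dt."""
    L, R1m, R2m, R1e, R2e, LRCm, LRCe, S2c, S2n, pS2c, pS2n = y
    v_bind = p.ka * L * R1m * R2m
    v_phos = p.kphos * LRCe * S2c

    dL = -p.med_scale * v_bind
    dR1m = p.pR1 - (p.ki + p.kdeg_R1) * R1m + p.kr * R1e - v_bind
    dR2m = p.pR2 - (p.ki + p.kdeg_R2) * R2m + p.kr * R2e - v_bind
    dR1e = p.ki * R1m - (p.kr + p.kdeg_R1) * R1e
    dR2e = p.ki * R2m - (p.kr + p.kdeg_R2) * R2e
    dLRCm = v_bind - p.ki * LRCm
    dLRCe = p.ki * LRCm - p.k_NFR * LRCe
    dS2c = p.pS2 - p.kdeg_S2 * S2c - v_phos - p.kin * S2c + p.kex * S2n
    dS2n = p.kin * S2c - p.kex * S2n + p.kdephos * pS2n
    dpS2c = v_phos - p.kin_p * pS2c
    dpS2n = p.kin_p * pS2c - p.kdephos * pS2n
    return np.array(
        [dL, dR1m, dR2m, dR1e, dR2e, dLRCm, dLRCe, dS2c, dS2n, dpS2c, dpS2n]
    )


def presimulation_steady_state(p: PathwayParams, tol: float = 1e-10) -> PathwayState:
    """Ligand-free steady state used as t=0 for every simulation.

    The ligand-free subsystem is linear and solved in closed form; the
    result is verified against ``rhs`` and refined numerically if the
    residual exceeds ``tol`` (relative to the largest pool).
    """
    # receptors: p = (ki+kdeg)*Rm - kr*Re ; ki*Rm = (kr+kdeg)*Re
    def _receptor(prod, kdeg):
        if prod == 0.0:
            return 0.0, 0.0
        if kdeg == 0.0:
            raise ConvergenceError(
                "no ligand-free receptor steady state with kdeg == 0 and production > 0"
            )
        rm = prod * (p.kr + kdeg) / (kdeg * (p.ki + p.kr + kdeg))
        re = p.ki * rm / (p.kr + kdeg)
        return rm, re

    r1m, r1e = _receptor(p.pR1, p.kdeg_R1)
    r2m, r2e = _receptor(p.pR2, p.kdeg_R2)

    if p.conservation_mode:
        s2c = p.s2_tot * p.kex / (p.kin + p.kex)
        s2n = p.s2_tot * p.kin / (p.kin + p.kex)
    else:
        # degradation acts on the cytoplasmic pool
        s2c = p.pS2 / p.kdeg_S2 if p.kdeg_S2 > 0 else 0.0
        s2n = p.kin * s2c / p.kex if p.kex > 0 else 0.0

    y = np.array([0.0, r1m, r2m, r1e, r2e, 0.0, 0.0, s2c, s2n, 0.0, 0.0])
    scale = max(1.0, float(np.max(y)))
    if np.max(np.abs(rhs(0.0, y, p))) > tol * scale:
        sol = fsolve(lambda v: rhs(0.0, np.concatenate(([0.0], v)), p)[1:],
                     y[1:], full_output=True)
        v, _, ier, msg = sol
        if ier != 1:
            raise ConvergenceError(f"steady-state refinement failed: {msg}")
        y = np.concatenate(([0.0], v))
        if np.max(np.abs(rhs(0.0, y, p))) > tol * scale:
            raise ConvergenceError("steady-state residual above tolerance")
    return PathwayState.from_array(y)


def simulate(
    p: PathwayParams,
    dose,
    t_grid,
    rtol: float = 1e-8,
    atol_scale: float = 1e-10,
    y0: PathwayState | None = None,
) -> TimeCourse:
    """Integrate the model from the ligand-free steady state.

    ``dose`` is a DoseSchedule or a scalar (nM bolus at t=0).  ``t_grid``
    is in minutes, starting at 0.  Absolute tolerance is
    ``atol_scale * max pool size``; a stiff-capable solver (LSODA) is used.
    """
    if np.isscalar(dose):
        dose = DoseSchedule.bolus(float(dose))
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0.0:
        raise DomainError("t_grid must start at 0")
    if np.any(np.diff(t_grid) <= 0):
        raise DomainError("t_grid must be strictly increasing")

    state0 = y0 if y0 is not None else presimulation_steady_state(p)
    y = state0.to_array()

    biggest = max(float(np.max(y)), p.s2_tot, 1.0)
    atol = atol_scale * biggest

    # segment boundaries: dose event times within the grid span
    t_end = float(t_grid[-1])
    events = [(t, d) for t, d in dose.events if t <= t_end]
    boundaries = sorted({0.0, t_end, *(t for t, _ in events)})

    out = np.empty((len(t_grid), len(SPECIES)))
    filled = np.zeros(len(t_grid), dtype=bool)

    for t, d in events:
        if t == 0.0:
            y[_IDX["L"]] += d

    for a, b in zip(boundaries[:-1], boundaries[1:]):
        for t, d in events:
            if t == a and t != 0.0:
                y[_IDX["L"]] += d
        mask = (t_grid >= a) & (t_grid <= b) & ~filled
        t_eval = t_grid[mask]
        sol = solve_ivp(
            rhs, (a, b), y, args=(p,), method="LSODA",
            t_eval=t_eval if len(t_eval) else None,
            rtol=rtol, atol=atol,
        )
        if not sol.success:
            t_fail = float(sol.t[-1]) if len(sol.t) else a
            raise SimulationError(f"integration failed at t={t_fail}: {sol.message}",
                                  t_fail=t_fail)
        if len(t_eval):
            out[mask] = sol.y.T
            filled[mask] = True
        y = sol.y[:, -1] if len(sol.t) else y
        if not np.isclose(sol.t[-1] if len(sol.t) else a, b):
            # integrate remainder without output points
            sol2 = solve_ivp(rhs, (float(sol.t[-1]), b), y, args=(p,),
                             method="LSODA", rtol=rtol, atol=atol)
            if not sol2.success:
                raise SimulationError(
                    f"integration failed at t={sol2.t[-1]}: {sol2.message}",
                    t_fail=float(sol2.t[-1]))
            y = sol2.y[:, -1]

    if not np.all(filled):
        raise SimulationError("internal error: grid points not covered")
    if np.min(out) < -atol * 10:
        raise SimulationError(f"negative pool beyond tolerance: {np.min(out)}")
    np.clip(out, 0.0, None, out=out)
    return TimeCourse(t=t_grid, states=out, dose_schedule=dose, params=p)


def dose_convert(value: float, direction: str, mw: float = 25.0) -> float:
    """Convert ligand doses between pM and ng/mL.

    ``ng/mL = pM * mw(kDa) / 1000``; e.g. 100 pM of a 25 kDa ligand is
    2.5 ng/mL.
    """
    if mw <= 0:
        raise DomainError("molar mass must be positive")
    if value < 0:
        raise DomainError("dose must be >= 0")
    if direction in ("pM->ng/mL", "pM→ng/mL"):
        return value * mw / 1000.0
    if direction in ("ng/mL->pM", "ng/mL→pM"):
        return value * 1000.0 / mw
    raise DomainError(f"unknown direction {direction!r}")
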