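"""Two-reaction minimal model of receptor-limited TGF-beta signaling.

The model has a single binding reaction forming a ternary ligand-receptor
complex (LRC) from the ligand and one receptor of each type, and a single
phosphorylation equilibrium converting inactive SMAD to active SMAD driven
by the complex.  Both admit a closed-form steady state:

    LRC = K1 * L * (R1tot - LRC) * (R2tot - LRC)
    Sa  = Stot * K2 * LRC / (1 + K2 * LRC)

The physically admissible LRC is the smaller root of the quadratic, the
only one in [0, min(R1tot, R2tot)].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import DomainError, UndefinedElasticityError

__all__ = [
    "MinimalParams",
    "MinimalScanResult",
    "lrc_equilibrium",
    "signaling_activity",
    "receptor_grid_scan",
    "log_elasticity",
]

# Below this product the quadratic is linearized to avoid cancellation.
_LINEARIZE_BELOW = 1e-300


@dataclass(frozen=True)
class MinimalParams:
    """Constants and totals of the two-reaction model.

    Units: receptors and SMAD in arbitrary abundance-units; ``L`` in nM;
    ``K1`` in 1/(nM * abundance-unit); ``K2`` in 1/abundance-unit.
    """

    L: float
    K1: float
    K2: float
    R1tot: float
    R2tot: float
    Stot: float = 1.0

    def __post_init__(self):
        for name in ("L", "K1", "K2", "R1tot", "R2tot", "Stot"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise DomainError(f"{name} must be finite and >= 0, got {v}")
        if self.K1 <= 0 or self.K2 <= 0:
            raise DomainError("K1 and K2 must be strictly positive")


@dataclass(frozen=True)
class MinimalScanResult:
    """Signaling activity over a 2-D grid of receptor totals."""

    r1_axis: np.ndarray
    r2_axis: np.ndarray
    sa_matrix: np.ndarray  # shape (len(r1_axis), len(r2_axis))

    def __post_init__(self):
        if self.sa_matrix.shape != (len(self.r1_axis), len(self.r2_axis)):
            raise DomainError("sa_matrix shape must be (len(r1_axis), len(r2_axis))")


def lrc_equilibrium(p: MinimalParams) -> float:
    """Steady-state ligand-receptor complex abundance.

    Returns the unique root of ``LRC = K1*L*(R1tot-LRC)*(R2tot-LRC)`` in
    ``[0, min(R1tot, R2tot)]`` using the numerically stable smaller-root
    formula.  ``K1*L == 0`` returns 0.
    """
    a = p.K1 * p.L
    if a == 0.0 or p.R1tot == 0.0 or p.R2tot == 0.0:
        return 0.0
    s = p.R1tot + p.R2tot
    prod = p.R1tot * p.R2tot
    if a * prod < _LINEARIZE_BELOW:
        # linearized solution: LRC << receptors
        return a * prod / (1.0 + a * s)
    # quadratic a*x^2 - (1 + a*s)*x + a*prod = 0; smaller root via 2c/(-b+sqrt(D))
    b = -(1.0 + a * s)
    c = a * prod
    # D = (1 + a*s)^2 - 4*a^2*prod = 1 + 2*a*s + a^2*(R1-R2)^2, always >= 1
    disc = 1.0 + 2.0 * a * s + (a * (p.R1tot - p.R2tot)) ** 2
    root = 2.0 * c / (-b + math.sqrt(disc))
    # guard fp noise at the saturated boundary
    return min(root, min(p.R1tot, p.R2tot))


def signaling_activity(p: MinimalParams, as_fraction: bool = False) -> float:
    """Steady-state signaling activity Sa = Stot * K2*LRC / (1 + K2*LRC).

    With ``as_fraction=True`` returns Sa/Stot regardless of Stot.
    """
    lrc = lrc_equilibrium(p)
    frac = p.K2 * lrc / (1.0 + p.K2 * lrc)
    return frac if as_fraction else p.Stot * frac


def receptor_grid_scan(
    p: MinimalParams,
    n_per_axis: int,
    decades: float,
    center: float = 100.0,
) -> MinimalScanResult:
    """Evaluate Sa on a log-spaced (R1tot, R2tot) grid.

    The grid spans ``decades`` orders of magnitude centered (in log space)
    on ``center``, with ``n_per_axis`` points per axis.
    """
    if n_per_axis < 2:
        raise DomainError("n_per_axis must be >= 2")
    if decades < 1:
        raise DomainError("decades must be >= 1")
    if center <= 0:
        raise DomainError("grid center must be positive")
    half = decades / 2.0
    axis = np.logspace(math.log10(center) - half, math.log10(center) + half, n_per_axis)
    sa = np.empty((n_per_axis, n_per_axis))
    for i, r1 in enumerate(axis):
        for j, r2 in enumerate(axis):
            sa[i, j] = signaling_activity(replace(p, R1tot=float(r1), R2tot=float(r2)))
    return MinimalScanResult(r1_axis=axis, r2_axis=axis.copy(), sa_matrix=sa)


def log_elasticity(p: MinimalParams, receptor: str, rel_step: float = 0.01) -> float:
    """Central finite-difference estimate of d(ln Sa)/d(ln Rtot).

    ``receptor`` is "R1" or "R2".  The step is symmetric in log space:
    the receptor total is multiplied and divided by ``1 + rel_step``.
    """
    if receptor not in ("R1", "R2"):
        raise DomainError(f"receptor must be 'R1' or 'R2', got {receptor!r}")
    if not 0.0 < rel_step <= 0.5:
        raise DomainError("rel_step must be in (0, 0.5]")
    if signaling_activity(p) == 0.0:
        raise UndefinedElasticityError("Sa is zero at the evaluation point")
    field = "R1tot" if receptor == "R1" else "R2tot"
    base = getattr(p, field)
    f = 1.0 + rel_step
    sa_hi = signaling_activity(replace(p, **{field: base * f}))
    sa_lo = signaling_activity(replace(p, **{field: base / f}))
    if sa_hi == 0.0 or sa_lo == 0.0:
        raise UndefinedElasticityError("Sa vanished at a displaced point")
    return (math.log(sa_hi) - math.log(sa_lo)) / (2.0 * math.log(f))
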