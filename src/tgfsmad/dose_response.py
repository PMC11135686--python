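"""Receptor-knockdown dose responses and Hill/EC50 fitting.

Knockdowns are modelled by scaling one receptor's production rate,
re-equilibrating ligand-free, stimulating, and reading relative P-SMAD2 at
a fixed time; both axes are normalized to the unperturbed (fold change 1,
"ntc") condition.  The resulting curve is fitted with a Hill function
``y = A * x^n / (K^n + x^n)`` by multi-start least squares, and the EC50 is
reported as the fold change where the fitted curve crosses 0.5 (half the
control response) — equal to K only when A = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DomainError, EC50OutOfRangeError, NonIdentifiableEC50Error
from .observables import relative_psmad2
from .pathway_model import PathwayParams, presimulation_steady_state, simulate

__all__ = ["DoseResponseDataset", "HillFit", "predict_knockdown_response",
           "fit_hill", "hill"]


@dataclass(frozen=True)
class DoseResponseDataset:
    """ntc-normalized (receptor fold change, response fold change) points."""

    points: tuple  # of (receptor_fold_change, rel_psmad2_fc)
    receptor: str  # "R1" | "R2"

    def __post_init__(self):
        if self.receptor not in ("R1", "R2"):
            raise DomainError("receptor must be 'R1' or 'R2'")
        for fc, _y in self.points:
            if fc <= 0:
                raise DomainError("receptor fold changes must be > 0")

    def arrays(self):
        pts = np.asarray(self.points, dtype=float)
        return pts[:, 0], pts[:, 1]

    def to_frame(self) -> pd.DataFrame:
        x, y = self.arrays()
        return pd.DataFrame({"receptor_fc": x, "response_fc": y})


@dataclass(frozen=True)
class HillFit:
    """Least-squares Hill fit and its half-of-control EC50."""

    ec50: float
    hill_n: float
    amplitude: float
    rss: float

    def predict(self, x):
        return hill(np.asarray(x, dtype=float), self.amplitude, self.hill_n,
                    self._k)

    _k: float = float("nan")  # fitted K (midpoint of the Hill term)


def hill(x, amplitude, n, k):
    """Hill function A * x^n / (K^n + x^n)."""
    x = np.asarray(x, dtype=float)
    xn = np.power(x, n)
    return amplitude * xn / (k ** n + xn)


def predict_knockdown_response(
    p: PathwayParams,
    receptor: str,
    fold_changes,
    dose: float = 0.1,
    t_eval: float = 60.0,
    rtol: float = 1e-8,
) -> DoseResponseDataset:
    """Model-predicted ntc-normalized response per receptor fold change.

    Each fold change scales the receptor's production rate before
    re-equilibration (a knockdown established prior to stimulation); the
    response is relative P-SMAD2 at ``t_eval`` divided by its value at
    fold change 1.
    """
    if receptor not in ("R1", "R2"):
        raise DomainError("receptor must be 'R1' or 'R2'")
    fold_changes = [float(f) for f in fold_changes]
    if any(f <= 0 for f in fold_changes):
        raise DomainError("fold changes must be > 0")
    field = "pR1" if receptor == "R1" else "pR2"
    t_grid = np.array([0.0, t_eval / 2.0, t_eval])

    def response(fc):
        pi = replace(p, **{field: getattr(p, field) * fc})
        tc = simulate(pi, dose, t_grid, rtol=rtol,
                      y0=presimulation_steady_state(pi))
        return relative_psmad2(tc).at(t_eval)

    ref = response(1.0)
    if ref <= 0:
        raise DomainError("control response is zero; cannot normalize")
    points = tuple((fc, response(fc) / ref if fc != 1.0 else 1.0)
                   for fc in fold_changes)
    return DoseResponseDataset(points=points, receptor=receptor)


_DEFAULT_START_GRID = tuple(
    (a, n, k)
    for a in (0.8, 1.0, 1.2)
    for n in (0.5, 1.0, 2.0, 4.0)
    for k in (0.05, 0.2, 0.5, 1.0)
)


def fit_hill(ds: DoseResponseDataset, start_grid=None) -> HillFit:
    """Multi-start least-squares Hill fit with a half-of-control EC50.

    Raises NonIdentifiableEC50Error for flat data (response range < 0.1)
    and EC50OutOfRangeError when the fitted curve never reaches 0.5.
    """
    x, y = ds.arrays()
    if len(x) < 4:
        raise DomainError("need at least 4 points")
    if np.log10(x.max() / x.min()) < 1.0:
        raise DomainError("points must span at least one decade of fold change")
    if np.ptp(y) < 0.1:
        raise NonIdentifiableEC50Error(
            f"response range {np.ptp(y):.3g} < 0.1; EC50 not identifiable")

    starts = tuple(start_grid) if start_grid is not None else _DEFAULT_START_GRID
    lx = np.log(x)

    def residual(theta):
        a, ln_n, ln_k = theta
        return hill(x, a, math.exp(ln_n), math.exp(ln_k)) - y

    best = None
    for a0, n0, k0 in starts:
        try:
            sol = least_squares(residual, [a0, math.log(n0), math.log(k0)],
                                bounds=([0.0, math.log(0.05), lx.min() - 7],
                                        [10.0, math.log(20.0), lx.max() + 7]),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except ValueError:
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        raise NonIdentifiableEC50Error("all Hill fits failed")
    rss, (a, ln_n, ln_k) = best
    n, k = math.exp(ln_n), math.exp(ln_k)
    if a <= 0.5:
        raise EC50OutOfRangeError(
            f"fitted amplitude {a:.3g} <= 0.5; curve never reaches half of control",
            bracket=(0.0, a))
    # A x^n/(K^n+x^n) = 0.5  =>  x = K * (0.5/(A-0.5))^(1/n)
    ec50 = k * (0.5 / (a - 0.5)) ** (1.0 / n)
    return HillFit(ec50=float(ec50), hill_n=float(n), amplitude=float(a),
                   rss=rss, _k=float(k))
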