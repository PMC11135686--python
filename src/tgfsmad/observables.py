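"""Derived signaling readouts from simulated trajectories.

Two scale-free readouts are used throughout: relative P-SMAD2 (phosphorylated
over total SMAD2, the whole-lysate immunoblot analogue) and the
nuclear-to-cytoplasmic (N2C) SMAD2 intensity ratio normalized to its
pre-stimulation value, the live-imaging analogue.  Both are invariant under
a uniform rescaling of all SMAD2 pools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, UndefinedObservableError
from .pathway_model import TimeCourse

__all__ = ["ObservableSeries", "relative_psmad2", "n2c_ratio", "n2c_fold_change"]


@dataclass(frozen=True)
class ObservableSeries:
    """A dimensionless readout on a time grid (minutes)."""

    t: np.ndarray
    value: np.ndarray
    kind: str  # relative_psmad2 | n2c | n2c_fold_change

    def at(self, t: float) -> float:
        i = int(np.argmin(np.abs(self.t - t)))
        if abs(self.t[i] - t) > 1e-9 * max(1.0, abs(t)):
            raise DomainError(f"time {t} not on the series grid")
        return float(self.value[i])


def relative_psmad2(tc: TimeCourse) -> ObservableSeries:
    """(pS2c + pS2n) / total SMAD2 per time point, in [0, 1]."""
    phos = tc["pS2c"] + tc["pS2n"]
    total = tc["S2c"] + tc["S2n"] + phos
    if np.any(total <= 0):
        raise UndefinedObservableError("total SMAD2 is zero at some time point")
    return ObservableSeries(t=tc.t, value=phos / total, kind="relative_psmad2")


def n2c_ratio(tc: TimeCourse, vol_ratio_nc: float | None = None) -> ObservableSeries:
    """Nuclear/cytoplasmic SMAD2 concentration (intensity-style) ratio.

    Amounts are converted to concentrations with the nuclear:cytoplasmic
    volume ratio (default from the simulation's parameters).
    """
    if vol_ratio_nc is None:
        vol_ratio_nc = tc.params.vol_ratio_nc if tc.params is not None else 1.0 / 3.0
    if vol_ratio_nc <= 0:
        raise DomainError("vol_ratio_nc must be > 0")
    nuc = tc["S2n"] + tc["pS2n"]
    cyt = tc["S2c"] + tc["pS2c"]
    if np.any(cyt <= 0):
        raise UndefinedObservableError("cytoplasmic SMAD2 is zero at some time point")
    # N2C = (nuc/Vn) / (cyt/Vc) = (nuc/cyt) / vol_ratio_nc
    return ObservableSeries(t=tc.t, value=(nuc / cyt) / vol_ratio_nc, kind="n2c")


def n2c_fold_change(tc: TimeCourse, vol_ratio_nc: float | None = None) -> ObservableSeries:
    """N2C ratio normalized to its value at t=0 (exactly 1 there).

    The volume ratio cancels in the normalization.
    """
    if tc.t[0] != 0.0:
        raise DomainError("fold change requires t=0 on the grid")
    ratio = n2c_ratio(tc, vol_ratio_nc)
    base = ratio.value[0]
    if base <= 0:
        raise UndefinedObservableError("N2C at t=0 is zero")
    value = ratio.value / base
    value[0] = 1.0
    return ObservableSeries(t=tc.t, value=value, kind="n2c_fold_change")
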