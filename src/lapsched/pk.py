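"""Lapatinib pharmacokinetics: oral dose -> serum -> tumor concentration.

Serum peaks follow a logarithmic absorption law ``serum = tau0 + tau1 *
ln(oral mg)``; the fitted coefficients place the result on the ug/mL scale,
so it is rescaled by 1000 to ng/mL (the published peak table is consistent
with this reading).  Tumor concentration in nM is a linear conversion of
the serum peak using the mean tumor/serum ratio 0.61 and the lapatinib
molecular weight 943.5 g/mol:

    tumor (nM) = ratio * serum (ng/mL) * 1000 / MW.

The time-resolved tumor concentration for a schedule is built from one
pulse per treatment day: a linear rise from 0 to the tumor peak over the
4 h time-to-peak, then exponential decay with a 24 h half-life.  By default
pulses from successive doses superpose additively (the standard PK
accumulation assumption); a reset mode keeping only the most recent dose is
available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["PKParams", "Schedule", "ConcentrationSignal",
           "oral_to_serum", "serum_to_tumor", "build_signal"]

CYCLE_DAYS = 5.0


@dataclass(frozen=True)
class PKParams:
    tau0: float = -2.1987
    tau1: float = 0.4959
    tumor_serum_ratio: float = 0.61
    molecular_weight: float = 943.5  # g/mol
    t_cmax: float = 4.0 / 24.0      # days to peak after a dose
    half_life: float = 1.0          # days

    def __post_init__(self) -> None:
        if not 0 < self.tumor_serum_ratio <= 1:
            raise ValueError("tumor/serum ratio must lie in (0, 1]")
        if self.t_cmax <= 0 or self.half_life <= 0:
            raise ValueError("t_cmax and half_life must be positive")


def oral_to_serum(oral_mg: float, params: PKParams | None = None) -> float:
    """Peak serum concentration (ng/mL) after an oral dose (mg)."""
    params = params or PKParams()
    if oral_mg <= 0:
        raise ValueError("oral dose must be positive")
    serum = (params.tau0 + params.tau1 * np.log(oral_mg)) * 1000.0
    if serum <= 0:
        raise ValueError(f"dose {oral_mg} mg is below the support of the absorption model")
    return float(serum)


def serum_to_tumor(serum_ng_ml, params: PKParams | None = None):
    """Tumor concentration (nM) from a serum concentration (ng/mL); linear."""
    params = params or PKParams()
    serum = np.asarray(serum_ng_ml, dtype=float)
    if np.any(serum < 0):
        raise ValueError("serum concentration must be non-negative")
    out = params.tumor_serum_ratio * serum * 1000.0 / params.molecular_weight
    return float(out) if out.ndim == 0 else out


def tumor_to_serum(tumor_nM, params: PKParams | None = None):
    """Exact inverse of :func:`serum_to_tumor`."""
    params = params or PKParams()
    return np.asarray(tumor_nM, dtype=float) * params.molecular_weight / (
        params.tumor_serum_ratio * 1000.0)


@dataclass(frozen=True)
class Schedule:
    """A per-cycle treatment design with its peak drug concentrations."""

    name: str
    treatment_days: tuple  # subset of {1..5}, days of the 5-day cycle dosed
    oral_mg: float
    serum_peak: float      # ng/mL
    tumor_peak: float      # nM

    def __post_init__(self) -> None:
        if not self.treatment_days:
            raise ValueError("schedule must have at least one treatment day")
        if any(d not in (1, 2, 3, 4, 5) for d in self.treatment_days):
            raise ValueError("treatment days must lie in 1..5")
        if len(set(self.treatment_days)) != len(self.treatment_days):
            raise ValueError("duplicate treatment days")
        if self.oral_mg <= 0 or self.serum_peak <= 0 or self.tumor_peak <= 0:
            raise ValueError("doses and peaks must be positive")

    @classmethod
    def from_oral(cls, name: str, treatment_days: Sequence[int], oral_mg: float,
                  params: PKParams | None = None) -> "Schedule":
        """Build a schedule from the oral dose via the absorption model."""
        serum = oral_to_serum(oral_mg, params)
        return cls(name=name, treatment_days=tuple(treatment_days), oral_mg=oral_mg,
                   serum_peak=serum, tumor_peak=serum_to_tumor(serum, params))


class ConcentrationSignal:
    """Piecewise tumor lapatinib concentration L(t), in nM, t in days.

    Callable on scalars or arrays; continuous and non-negative.  ``peaks``
    may be a scalar (same peak for every dose) or one value per dose time.
    """

    def __init__(self, dose_times: Sequence[float], peaks, t_cmax: float,
                 half_life: float, horizon: float, cycle_length: float = CYCLE_DAYS,
                 superpose: bool = True):
        self.dose_times = np.sort(np.asarray(dose_times, dtype=float))
        if np.any(self.dose_times < 0):
            raise ValueError("dose times must be non-negative")
        self.peaks = np.broadcast_to(np.asarray(peaks, dtype=float),
                                     self.dose_times.shape).copy()
        if np.any(self.peaks < 0):
            raise ValueError("peaks must be non-negative")
        self.t_cmax = float(t_cmax)
        self.half_life = float(half_life)
        self.horizon = float(horizon)
        self.cycle_length = float(cycle_length)
        self.superpose = bool(superpose)

    def _pulse(self, u: np.ndarray, peak) -> np.ndarray:
        rise = u / self.t_cmax
        decay = np.exp2(-(u - self.t_cmax) / self.half_life)
        return peak * np.where(u < 0, 0.0, np.where(u < self.t_cmax, rise, decay))

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        tt = np.atleast_1d(t)
        if self.superpose:
            u = tt[:, None] - self.dose_times[None, :]
            out = self._pulse(u, self.peaks[None, :]).sum(axis=1)
        else:
            idx = np.searchsorted(self.dose_times, tt, side="right") - 1
            valid = idx >= 0
            out = np.zeros_like(tt)
            if valid.any():
                j = idx[valid]
                out[valid] = self._pulse(tt[valid] - self.dose_times[j], self.peaks[j])
        return float(out[0]) if scalar else out

    def scaled(self, factor: float) -> "ConcentrationSignal":
        """Signal with every peak multiplied by ``factor`` (e.g. a BBB factor)."""
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return ConcentrationSignal(self.dose_times, self.peaks * factor, self.t_cmax,
                                   self.half_life, self.horizon, self.cycle_length,
                                   self.superpose)

    def sample(self, step: float = 1.0 / 24.0) -> pd.DataFrame:
        """Sampled (t, L) table, e.g. for CSV export."""
        t = np.arange(0.0, self.horizon + step / 2, step)
        return pd.DataFrame({"t_days": t, "L_nM": self(t)})


def build_signal(schedule: Schedule, params: PKParams | None = None,
                 n_cycles: int = 20, superpose: bool = True,
                 peak_scale: float = 1.0) -> ConcentrationSignal:
    """Tumor concentration signal over ``n_cycles`` 5-day cycles.

    One pulse per treatment day at the schedule's tumor peak; ``peak_scale``
    rescales the peaks (patient-specific absorption, blood-brain-barrier
    attenuation).
    """
    params = params or PKParams()
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    dose_times = [CYCLE_DAYS * c + (day - 1) for c in range(n_cycles)
                  for day in sorted(schedule.treatment_days)]
    return ConcentrationSignal(dose_times, schedule.tumor_peak * peak_scale,
                               params.t_cmax, params.half_life,
                               horizon=CYCLE_DAYS * n_cycles, superpose=superpose)


def control_signal(n_cycles: int = 20) -> ConcentrationSignal:
    """The untreated control: L(t) = 0."""
    return ConcentrationSignal([0.0], 0.0, t_cmax=4.0 / 24.0, half_life=1.0,
                               horizon=CYCLE_DAYS * n_cycles)
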