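"""Packaged parameter fixtures.

Small published parameter tables ship with the package so the pipeline runs
without any download: the fitted dose-response and pharmacokinetic
coefficients, the three clinical maximum-tolerated-dose (MTD) points, and
the five MTD / fixed-total-dose treatment schedules with their serum and
tumor peak concentrations.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

from .invitro import DoseResponseParams
from .pk import PKParams, Schedule
from .toxicity import ToxicityPoint

__all__ = [
    "dose_response_params",
    "pk_params",
    "toxicity_points",
    "toxicity_coefficients",
    "mtd_schedules",
    "fixed_total_dose_schedules",
]


@lru_cache(maxsize=None)
def _load(name: str) -> dict:
    with resources.files("lapsched.data").joinpath(name).open() as fh:
        return json.load(fh)


def dose_response_params() -> DoseResponseParams:
    """Published point estimates of the exponential dose-response laws."""
    dr = _load("params.json")["dose_response"]
    return DoseResponseParams(
        b0=dr["b0"]["estimate"], b1=dr["b1"]["estimate"],
        d0=dr["d0"]["estimate"], d1=dr["d1"]["estimate"],
        se={k: v["se"] for k, v in dr.items()},
        pvalues={k: v["p"] for k, v in dr.items()},
    )


def pk_params() -> PKParams:
    pk = _load("params.json")["pk"]
    return PKParams(
        tau0=pk["tau0"]["estimate"], tau1=pk["tau1"]["estimate"],
        tumor_serum_ratio=pk["tumor_serum_ratio"],
        molecular_weight=pk["molecular_weight_g_per_mol"],
        t_cmax=pk["t_cmax_days"], half_life=pk["half_life_days"],
    )


def toxicity_points() -> list[ToxicityPoint]:
    """The three clinical (days per cycle, max daily oral mg) toxicity limits."""
    pts = _load("toxicity_points.json")["points"]
    return [ToxicityPoint(p["days"], p["max_daily_oral_mg"]) for p in pts]


def toxicity_coefficients() -> dict:
    """Published coefficients of the linear and log-scale toxicity curves."""
    return _load("params.json")["toxicity"]


def _schedules(key: str) -> list[Schedule]:
    return [
        Schedule(
            name=s["name"], treatment_days=tuple(s["treatment_days"]),
            oral_mg=s["oral_mg"], serum_peak=s["serum_peak_ng_ml"],
            tumor_peak=s["tumor_peak_nM"],
        )
        for s in _load("schedules.json")[key]
    ]


def mtd_schedules() -> list[Schedule]:
    """Five treatment schedules dosing at the MTD for 5..1 days per cycle."""
    return _schedules("mtd")


def fixed_total_dose_schedules() -> list[Schedule]:
    """Variant schedules delivering (roughly) a fixed total dose per cycle."""
    return _schedules("fixed_total_dose")
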