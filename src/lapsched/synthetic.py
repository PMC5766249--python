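"""Synthetic in vitro cell-count data.

The original SF268 count data behind the pharmacodynamic fits were never
deposited, so this module generates datasets with the same design and
statistical structure: triplicate viable/dead counts over a 5-day window,
150,000 cells seeded per dish, and a panel of lapatinib concentrations
bracketing the growth-arrest concentration (~2,180 nM).  Noiseless
trajectories come from the logistic birth-death model with exponential
dose-response rates; observation noise is multiplicative lognormal with
mean 1 and configurable coefficient of variation (counts are positive and
heteroscedastic), with a Poisson option.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .invitro import COUNT_COLUMNS, DoseResponseParams, GrowthParams, simulate_logistic

__all__ = ["SyntheticConfig", "generate_counts", "write_counts", "read_counts"]

#: Concentration panel (nM) spanning the qualitative range of the assay.
DEFAULT_CONCENTRATIONS = (0.0, 125.0, 250.0, 500.0, 1000.0, 2000.0, 4000.0)
DEFAULT_DAYS = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)


def _default_true_params() -> DoseResponseParams:
    from .datasets import dose_response_params

    return dose_response_params()


@dataclass
class SyntheticConfig:
    """Design and ground truth of a synthetic cell-count experiment."""

    concentrations: tuple = DEFAULT_CONCENTRATIONS
    days: tuple = DEFAULT_DAYS
    replicates: int = 3
    initial_viable: float = 150_000.0
    initial_dead: float = 0.0
    true_params: DoseResponseParams = field(default_factory=_default_true_params)
    carrying_capacity: float = 1e6
    clearance: float = 0.0
    noise_cv: float = 0.1
    noise: str = "lognormal"  # or "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.size == 0:
            raise ValueError("concentration list must not be empty")
        if np.any(conc < 0):
            raise ValueError("concentrations must be non-negative")
        if 0.0 not in conc:
            raise ValueError("concentration panel must include the untreated 0 nM arm")
        if len(self.days) < 2:
            raise ValueError("need at least two measurement days")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.initial_viable <= 0:
            raise ValueError("initial_viable must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.noise not in ("lognormal", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")


def generate_counts(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a tidy replicate-level cell-count table.

    For each concentration the noiseless trajectory is obtained by
    integrating the logistic birth-death model with rates from the
    configured dose-response truth; each observation is then perturbed by
    independent mean-1 lognormal noise with the configured CV (or Poisson
    sampling) and rounded to a non-negative integer.  Fully reproducible
    from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    days = np.asarray(config.days, dtype=float)
    dr = config.true_params
    sigma = float(np.sqrt(np.log1p(config.noise_cv**2)))  # lognormal(mean 1, cv)

    frames = []
    for L in np.asarray(config.concentrations, dtype=float):
        params = GrowthParams(b=float(dr.birth_rate(L)), d=float(dr.death_rate(L)),
                              c=config.clearance, K=config.carrying_capacity)
        _, y1, y2 = simulate_logistic(params, config.initial_viable, config.initial_dead,
                                      horizon=float(days.max()) if days.max() > 0 else 1.0,
                                      t_eval=days)
        for rep in range(1, config.replicates + 1):
            if config.noise == "poisson":
                viable = rng.poisson(y1).astype(float)
                dead = rng.poisson(y2).astype(float)
            elif config.noise_cv == 0:
                viable, dead = y1.copy(), y2.copy()
            else:
                fv = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=days.size)
                fd = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=days.size)
                viable, dead = y1 * fv, y2 * fd
            frames.append(pd.DataFrame({
                "concentration_nM": L, "day": days, "replicate": rep,
                "viable": np.maximum(np.rint(viable), 0.0),
                "dead": np.maximum(np.rint(dead), 0.0),
            }))
    out = pd.concat(frames, ignore_index=True)
    return out[list(COUNT_COLUMNS)]


def load_config(path) -> SyntheticConfig:
    """Build a :class:`SyntheticConfig` from a YAML or JSON mapping.

    The ``true_params`` entry, when present, is a mapping with keys
    ``b0, b1, d0, d1``; otherwise the packaged estimates are used.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("synthetic config must be a mapping")
    if "true_params" in raw:
        raw["true_params"] = DoseResponseParams(**raw["true_params"])
    for key in ("concentrations", "days"):
        if key in raw:
            raw[key] = tuple(raw[key])
    known = {f.name for f in fields(SyntheticConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown synthetic config keys: {sorted(unknown)}")
    return SyntheticConfig(**raw)


def write_counts(data: pd.DataFrame, path) -> None:
    data.to_csv(path, index=False)


def read_counts(path) -> pd.DataFrame:
    data = pd.read_csv(path)
    missing = set(COUNT_COLUMNS) - set(data.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    return data
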