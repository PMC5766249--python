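"""Reaction-diffusion (Fisher-KPP) simulation of in vivo GBM growth.

Tumor cell density c(x, t) (cells/mm^3) on a spherically symmetric radial
grid obeys

    dc/dt = D lap(c) + rho(L(t)) c (1 - c/kappa),

with diffusion coefficient D (mm^2/day), logistic proliferation, no-flux
conditions at the origin and the outer boundary, and the proliferation rate
scaled by the in vitro dose-response during treatment:

    rho(L) = rho0 * (b(L) - d(L)) / (b(0) - d(0)).

Variants cover drug-sensitive/resistant subpopulations sharing one carrying
capacity, blood-brain-barrier attenuation of the drug signal (factor Q),
and hypoxia-driven Go-or-Grow switching between proliferative and migratory
phenotypes coupled to an oxygen field.

Numerics: conservative finite-volume discretization of the radial Laplacian
(mass is conserved exactly under pure diffusion), Crank-Nicolson diffusion
with explicit reaction (first-order splitting), and backward-Euler oxygen
with its consumption sink treated implicitly (the sink is stiff inside the
tumor).  The "tumor radius" is the outermost radius where total cell
density crosses the imaging detection threshold (8,000 cells/mm^3 by
default), linearly interpolated between grid cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import solve_banded

from .invitro import DoseResponseParams
from .pk import ConcentrationSignal

__all__ = [
    "PDEParams", "GoGrowParams", "TumorProfile", "PDERun",
    "build_initial_profile", "radius",
    "simulate_fisher_kpp", "simulate_heterogeneous", "simulate_bbb",
    "simulate_go_or_grow", "front_speed",
]


@dataclass(frozen=True)
class PDEParams:
    """Geometry, growth and detection parameters of the in vivo model."""

    D: float = 0.03                      # mm^2/day
    rho0: float = 0.0387                 # per day (0.387 selectable; see methods note)
    kappa: float = 1e6                   # cells/mm^3
    detection_threshold: float = 8000.0  # cells/mm^3 (MRI detectability)
    fatal_radius: float = 30.0           # mm
    domain_radius: float = 60.0          # mm
    dx: float = 0.25                     # mm
    geometry: str = "spherical"          # or "planar" (validation runs)

    def __post_init__(self) -> None:
        if min(self.D, self.kappa, self.dx, self.domain_radius) <= 0:
            raise ValueError("D, kappa, dx and domain_radius must be positive")
        if self.rho0 < 0:
            raise ValueError("rho0 must be non-negative")
        if not 0 < self.detection_threshold < self.kappa:
            raise ValueError("detection threshold must lie in (0, kappa)")
        if not 0 < self.fatal_radius < self.domain_radius:
            raise ValueError("fatal radius must lie inside the domain")
        if self.geometry not in ("spherical", "planar"):
            raise ValueError("geometry must be 'spherical' or 'planar'")

    @property
    def centers(self) -> np.ndarray:
        n = int(round(self.domain_radius / self.dx))
        return (np.arange(n) + 0.5) * self.dx

    @property
    def cell_volumes(self) -> np.ndarray:
        n = int(round(self.domain_radius / self.dx))
        faces = np.arange(n + 1) * self.dx
        if self.geometry == "spherical":
            return (faces[1:] ** 3 - faces[:-1] ** 3) / 3.0  # 4*pi omitted
        return np.full(n, self.dx)


@dataclass(frozen=True)
class GoGrowParams:
    """Go-or-Grow switching and oxygen-field parameters.

    Oxygen is expressed in nmol/mm^3 throughout.  The proliferative ->
    migratory switch turns on below the oxygen scale ``lambda1`` (twice the
    normal-tissue level); the reverse rate is ``lambda2 * sigma``.
    """

    lambda1: float = 4.134     # nmol/mm^3
    lambda2: float = 1.0       # per day per (nmol/mm^3)
    D_sigma: float = 1.51e2    # mm^2/day
    h1: float = 3.37e-1        # per day (transvascular permeability)
    h2: float = 1e-2           # mm^3 per cell per day (consumption)
    sigma0: float = 2.068      # nmol/mm^3 (normal tissue)
    v: float = 12.0            # vascular density (dimensionless)

    def f_mp(self, sigma):
        """Migratory -> proliferative switching rate (per day)."""
        return self.lambda2 * np.clip(sigma, 0.0, None)

    def f_pm(self, sigma):
        """Proliferative -> migratory switching rate, clipped at 0."""
        return np.clip(self.lambda1 - sigma, 0.0, None)


@dataclass(frozen=True)
class TumorProfile:
    """Radial density field(s) at one time point."""

    x: np.ndarray
    fields: dict
    time: float = 0.0

    CELL_FIELDS_EXCLUDED = ("oxygen",)

    def total(self) -> np.ndarray:
        return sum(v for k, v in self.fields.items() if k not in self.CELL_FIELDS_EXCLUDED)


@dataclass
class PDERun:
    """Time series of tumor radii plus profile snapshots."""

    times: np.ndarray
    radii: np.ndarray
    snapshots: list
    params: PDEParams
    masses: np.ndarray = field(default=None)

    @property
    def final_radius(self) -> float:
        return float(self.radii[-1])

    def time_to_radius(self, r: float):
        """First time the detection radius reaches ``r`` (linear interp), or None."""
        above = self.radii >= r
        if not above.any():
            return None
        i = int(np.argmax(above))
        if i == 0:
            return float(self.times[0])
        t0, t1 = self.times[i - 1], self.times[i]
        r0, r1 = self.radii[i - 1], self.radii[i]
        return float(t0 + (r - r0) / (r1 - r0) * (t1 - t0)) if r1 > r0 else float(t1)


def build_initial_profile(params: PDEParams, solid_radius: float = 15.0,
                          isolated_radius: float = 25.0, solid_density: float = 0.8,
                          isolated_density: float = 0.16,
                          tail: str = "linear") -> TumorProfile:
    """Initial tumor: solid core at 80% of kappa, falling tail of isolated cells.

    The density is ``solid_density * kappa`` out to ``solid_radius`` and
    falls to ``isolated_density * kappa`` at ``isolated_radius``.  With the
    default linear tail the same slope continues outward (floored at 0), so
    the initial detection radius sits between the isolated and fatal radii
    (~27.4 mm with the defaults).  ``tail="exponential"`` uses log-linear
    decay instead; note that continuing that shallow log-slope outward puts
    the detection radius beyond the fatal radius, so the linear tail is the
    default for survival-style analyses.
    """
    if tail not in ("linear", "exponential"):
        raise ValueError("tail must be 'linear' or 'exponential'")
    x = params.centers
    c = np.empty_like(x)
    hi = solid_density * params.kappa
    lo = isolated_density * params.kappa
    if tail == "linear":
        slope = (lo - hi) / (isolated_radius - solid_radius)
        c = hi + slope * (x - solid_radius)
    else:
        lam = np.log(hi / lo) / (isolated_radius - solid_radius)
        c = hi * np.exp(-lam * (x - solid_radius))
    c[x <= solid_radius] = hi
    return TumorProfile(x=x, fields={"total": np.clip(c, 0.0, None)}, time=0.0)


def radius(profile: TumorProfile, threshold: float) -> float:
    """Outermost radius where total density crosses ``threshold`` (mm)."""
    c = profile.total()
    return _radius_from_array(profile.x, c, threshold)


def _radius_from_array(x: np.ndarray, c: np.ndarray, threshold: float) -> float:
    above = c >= threshold
    if not above.any():
        return 0.0
    i = int(len(c) - 1 - np.argmax(above[::-1]))  # outermost cell above threshold
    if i == len(c) - 1:
        return float(x[-1])
    # linear interpolation toward the first cell below the threshold
    return float(x[i] + (x[i + 1] - x[i]) * (c[i] - threshold) / (c[i] - c[i + 1]))


class _Diffusion:
    """Conservative finite-volume Crank-Nicolson diffusion on the radial grid."""

    def __init__(self, params: PDEParams, D: float, dt: float):
        n = params.centers.size
        faces = np.arange(n + 1) * params.dx
        area = faces**2 if params.geometry == "spherical" else np.ones(n + 1)
        w = D * area / params.dx          # face conductances; no-flux at ends
        w[0] = w[-1] = 0.0
        V = params.cell_volumes
        lower = w[1:-1] / V[1:]           # coupling to cell i-1
        upper = w[1:-1] / V[:-1]          # coupling to cell i+1
        diag = -(w[:-1] + w[1:]) / V
        self.n, self.dt = n, dt
        self.lower, self.diag, self.upper = lower, diag, upper
        # banded LHS for (I - dt/2 M)
        ab = np.zeros((3, n))
        ab[0, 1:] = -0.5 * dt * upper
        ab[1, :] = 1.0 - 0.5 * dt * diag
        ab[2, :-1] = -0.5 * dt * lower
        self.lhs = ab

    def apply(self, c: np.ndarray) -> np.ndarray:
        """M @ c for the explicit half step."""
        out = self.diag * c
        out[1:] += self.lower * c[:-1]
        out[:-1] += self.upper * c[1:]
        return out

    def step(self, c: np.ndarray) -> np.ndarray:
        rhs = c + 0.5 * self.dt * self.apply(c)
        return solve_banded((1, 1), self.lhs, rhs)

    def implicit_step(self, c: np.ndarray, sink: np.ndarray, source: np.ndarray) -> np.ndarray:
        """Backward Euler with implicit linear sink: used for the oxygen field."""
        ab = np.zeros((3, self.n))
        ab[0, 1:] = -self.dt * self.upper
        ab[1, :] = 1.0 - self.dt * self.diag + self.dt * sink
        ab[2, :-1] = -self.dt * self.lower
        return solve_banded((1, 1), ab, c + self.dt * source)


def _rho_schedule(params: PDEParams, signal, dose_response, times: np.ndarray) -> np.ndarray:
    """Effective proliferation rate at each step midpoint."""
    if signal is None:
        return np.full(times.size, params.rho0)
    if dose_response is None:
        raise ValueError("dose_response is required when a drug signal is given")
    L = signal(times)
    return params.rho0 * dose_response.net_rate(L) / dose_response.net_rate(0.0)


def _prep(params: PDEParams, horizon: float, dt: float, snapshot_times):
    n_steps = int(np.ceil(horizon / dt - 1e-9))
    t_edges = np.minimum(np.arange(n_steps + 1) * dt, horizon)
    mids = 0.5 * (t_edges[:-1] + t_edges[1:])
    if snapshot_times is None:
        snapshot_times = [0.0, horizon]
    snap_idx = {int(np.argmin(np.abs(t_edges - ts))): float(ts) for ts in snapshot_times}
    return n_steps, t_edges, mids, snap_idx


def _generic_run(params: PDEParams, fields: dict, diffusion_for: dict,
                 reaction, horizon: float, dt: float, snapshot_times,
                 track_mass: bool = False, stop_radius: float | None = None) -> PDERun:
    """Shared stepping loop: explicit reaction, CN diffusion, radius tracking.

    ``reaction(k, fields) -> dict`` returns per-day increments for each
    field at step ``k``; fields without an entry in ``diffusion_for`` skip
    the diffusion solve.  Stops early once the detection radius reaches
    ``stop_radius`` (event extraction for trials).
    """
    n_steps, t_edges, _, snap_idx = _prep(params, horizon, dt, snapshot_times)
    x = params.centers
    V = params.cell_volumes
    thr = params.detection_threshold
    fields = {k: np.array(v, dtype=float, copy=True) for k, v in fields.items()}

    ops = {k: _Diffusion(params, D, dt) for k, D in diffusion_for.items() if D > 0}

    times = np.empty(n_steps + 1)
    radii = np.empty(n_steps + 1)
    masses = np.empty(n_steps + 1) if track_mass else None
    snapshots = []

    def total():
        return sum(v for k, v in fields.items() if k != "oxygen")

    def record(i, t):
        times[i] = t
        radii[i] = _radius_from_array(x, total(), thr)
        if track_mass:
            masses[i] = float(total() @ V)

    record(0, 0.0)
    if 0 in snap_idx:
        snapshots.append(TumorProfile(x=x, fields={k: v.copy() for k, v in fields.items()},
                                      time=0.0))
    last = n_steps
    for k in range(n_steps):
        dt_k = t_edges[k + 1] - t_edges[k]
        incs = reaction(k, fields)
        for name, inc in incs.items():
            fields[name] = fields[name] + dt_k * inc
        for name, op in ops.items():
            fields[name] = op.step(fields[name])
        for name in fields:
            if name != "oxygen":
                np.clip(fields[name], 0.0, None, out=fields[name])
        record(k + 1, t_edges[k + 1])
        if (k + 1) in snap_idx:
            snapshots.append(TumorProfile(x=x, fields={k2: v.copy() for k2, v in fields.items()},
                                          time=t_edges[k + 1]))
        if stop_radius is not None and radii[k + 1] >= stop_radius:
            last = k + 1
            break
    sl = slice(0, last + 1)
    return PDERun(times=times[sl], radii=radii[sl], snapshots=snapshots, params=params,
                  masses=masses[sl] if track_mass else None)


def simulate_fisher_kpp(params: PDEParams, initial: TumorProfile | None = None,
                        signal: ConcentrationSignal | None = None,
                        dose_response: DoseResponseParams | None = None,
                        horizon: float = 100.0, dt: float = 0.01,
                        snapshot_times=None, track_mass: bool = False,
                        stop_radius: float | None = None) -> PDERun:
    """Single-population logistic reaction-diffusion growth under treatment."""
    if initial is None:
        initial = build_initial_profile(params)
    n_steps, t_edges, mids, _ = _prep(params, horizon, dt, snapshot_times)
    rho = _rho_schedule(params, signal, dose_response, mids)
    kappa = params.kappa

    def reaction(k, fields):
        c = fields["total"]
        return {"total": rho[k] * c * (1.0 - c / kappa)}

    return _generic_run(params, {"total": initial.total()}, {"total": params.D},
                        reaction, horizon, dt, snapshot_times, track_mass, stop_radius)


def simulate_heterogeneous(params: PDEParams, resistant_fraction: float,
                           signal: ConcentrationSignal | None,
                           dose_response: DoseResponseParams | None,
                           initial: TumorProfile | None = None,
                           horizon: float = 100.0, dt: float = 0.01,
                           snapshot_times=None, stop_radius: float | None = None) -> PDERun:
    """Sensitive + resistant subpopulations competing for one carrying capacity.

    The resistant fraction proliferates at the untreated rate ``rho0``
    regardless of the drug signal.
    """
    if not 0.0 <= resistant_fraction < 1.0:
        raise ValueError("resistant fraction must lie in [0, 1)")
    if initial is None:
        initial = build_initial_profile(params)
    c0 = initial.total()
    n_steps, t_edges, mids, _ = _prep(params, horizon, dt, snapshot_times)
    rho = _rho_schedule(params, signal, dose_response, mids)
    kappa, rho0 = params.kappa, params.rho0

    def reaction(k, fields):
        cs, cr = fields["sensitive"], fields["resistant"]
        room = 1.0 - (cs + cr) / kappa
        return {"sensitive": rho[k] * cs * room, "resistant": rho0 * cr * room}

    return _generic_run(params,
                        {"sensitive": (1.0 - resistant_fraction) * c0,
                         "resistant": resistant_fraction * c0},
                        {"sensitive": params.D, "resistant": params.D},
                        reaction, horizon, dt, snapshot_times, stop_radius=stop_radius)


def simulate_bbb(params: PDEParams, signal: ConcentrationSignal,
                 dose_response: DoseResponseParams, Q: float,
                 initial: TumorProfile | None = None, horizon: float = 100.0,
                 dt: float = 0.01, snapshot_times=None,
                 stop_radius: float | None = None) -> PDERun:
    """Base model with only a fraction ``Q`` of the drug reaching the tumor."""
    if not 0.0 <= Q <= 1.0:
        raise ValueError("Q must lie in [0, 1]")
    scaled = signal.scaled(Q) if Q > 0 else None
    return simulate_fisher_kpp(params, initial, scaled, dose_response,
                               horizon, dt, snapshot_times, stop_radius=stop_radius)


def simulate_go_or_grow(params: PDEParams, go: GoGrowParams,
                        signal: ConcentrationSignal | None,
                        dose_response: DoseResponseParams | None,
                        initial: TumorProfile | None = None,
                        migratory_fraction: float = 0.0,
                        horizon: float = 100.0, dt: float = 0.005,
                        snapshot_times=None, stop_radius: float | None = None) -> PDERun:
    """Hypoxia-driven switching between proliferative and migratory phenotypes.

    Migratory cells diffuse but do not divide; proliferative cells divide
    (drug-modulated) but do not move.  Oxygen relaxes toward the normal
    level ``sigma0``, is consumed by tumor cells, and controls the switch
    rates.  Oxygen starts at ``sigma0`` everywhere.
    """
    if initial is None:
        initial = build_initial_profile(params)
    c0 = initial.total()
    n_steps, t_edges, mids, _ = _prep(params, horizon, dt, snapshot_times)
    rho = _rho_schedule(params, signal, dose_response, mids)
    kappa = params.kappa
    sigma_op = _Diffusion(params, go.D_sigma, dt)
    h1v = go.h1 * go.v
    source = np.full(params.centers.size, h1v * go.sigma0)

    def reaction(k, fields):
        cm, cp, sigma = fields["migratory"], fields["proliferative"], fields["oxygen"]
        fmp, fpm = go.f_mp(sigma), go.f_pm(sigma)
        inc_m = -fmp * cm + fpm * cp
        inc_p = rho[k] * cp * (1.0 - (cm + cp) / kappa) + fmp * cm - fpm * cp
        # oxygen handled implicitly below; return no explicit increment
        return {"migratory": inc_m, "proliferative": inc_p}

    # wrap the generic loop but advance oxygen inside the reaction callback:
    # the implicit solve needs the *current* cell densities, so do it first.
    def reaction_with_oxygen(k, fields):
        sink = h1v + go.h2 * (fields["migratory"] + fields["proliferative"])
        fields["oxygen"] = np.clip(
            sigma_op.implicit_step(fields["oxygen"], sink, source), 0.0, None)
        return reaction(k, fields)

    return _generic_run(params,
                        {"migratory": migratory_fraction * c0,
                         "proliferative": (1.0 - migratory_fraction) * c0,
                         "oxygen": np.full(params.centers.size, go.sigma0)},
                        {"migratory": params.D},
                        reaction_with_oxygen, horizon, dt, snapshot_times,
                        stop_radius=stop_radius)


def front_speed(run: PDERun, t_start: float, t_end: float) -> float:
    """Front speed (mm/day): least-squares slope of radius vs time on a window."""
    mask = (run.times >= t_start) & (run.times <= t_end)
    if mask.sum() < 2:
        raise ValueError("window contains fewer than 2 samples")
    return float(np.polyfit(run.times[mask], run.radii[mask], 1)[0])
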