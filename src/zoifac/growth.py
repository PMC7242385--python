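"""Growth dynamics: metabolic-scaling growth with ZOI-mediated interactions.

The neighbor-free ("potential") growth law is the ontogenetic growth
equation of metabolic scaling theory with an energy-limitation stress term::

    dm/dt = a * m**(3/4) * [1 - S - (m/M)**(1/4)]

where ``m`` is biomass, ``M`` the theoretical maximum mass, ``a`` a
species-specific constant, and ``S`` in [0, 1] the stress intensity (the
proportional reduction in incoming energy).  Substituting ``x = (m/M)**(1/4)``
makes the law linear, ``dx/dt = (a / (4 M**(1/4))) * (1 - S - x)``, so an
isolated plant relaxes exponentially to the fixed point ``m* = M (1 - S)**4``.

Interactions enter through the zone of influence ``A = C0 * m**(3/4)``: with
competition index ``I_c`` and facilitation index ``I_f`` from
:mod:`zoifac.geometry`, the realized growth rate is::

    dm/dt = r * A * [(1 - S * I_f) * I_c - (m/M)**(1/4)]

with intrinsic growth rate ``r`` (mass area^-1 time^-1).  With ``a = r * C0``
and ``I_c = I_f = 1`` this reduces exactly to the potential law, so the two
equations carry the same units (mass time^-1).  The facilitative-response
term ``S * I_f = S * (1 - A_f / A)`` makes stress relief size-dependent: the
same ameliorated area ``A_f`` helps a small beneficiary more than a large one.

Time stepping is synchronous forward Euler on a toroidal arena.  Masses are
additionally capped at the largest value whose ZOI still fits the torus
(radius at most half the arena span); this arena carrying limit only binds
under weak stress, where the interaction geometry is saturated anyway.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import Arena, InteractionField, SharingMode, ZoiCircle, compute_field

__all__ = [
    "GrowthParams",
    "Plant",
    "SimConfig",
    "SimResult",
    "default_growth_params",
    "potential_growth_rate",
    "realized_growth_rate",
    "lone_growth_rate",
    "integrate_lone",
    "init_population",
    "step",
    "run_simulation",
]

#: Calibrated default scale constants (see docs/methods.md).  ``_M_MAX`` is
#: the theoretical maximum mass; ``_ZOI_RADIUS_AT_M`` the ZOI radius (in
#: cells) of a plant at mass ``_M_MAX``, which together with ``_M_MAX`` fixes
#: the allometric constant C0; ``_RELAX_RATE`` is the per-step relaxation
#: rate of the linearized growth law, which fixes ``a`` (and ``r = a / C0``)
#: so that lone plants equilibrate well within the 50-step protocol.
_M_MAX = 2.0e4
_ZOI_RADIUS_AT_M = 160.0
_RELAX_RATE = 0.017
_M0 = 0.01

#: Fraction of the arena's half-span used as the ZOI radius ceiling when
#: capping masses inside a simulation (kept just under 1 so rasterization
#: never sees an ill-defined self-overlapping circle).
_RADIUS_CAP_FRACTION = 0.98


@dataclass(frozen=True)
class GrowthParams:
    """Growth-law parameters.

    ``a`` (mass^(1/4) time^-1 scale), ``r`` (mass area^-1 time^-1), maximum
    mass ``M``, allometric constant ``C0`` (area mass^(-3/4)), initial mass
    ``m0``, Euler step ``dt`` and death threshold ``m_death``.  By default
    ``a = r * C0``, which makes the realized and potential growth laws agree
    exactly for a plant without neighbors.
    """

    a: float
    r: float
    M: float
    C0: float
    m0: float = _M0
    dt: float = 1.0
    m_death: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a", "r", "M", "C0", "m0", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.m0 >= self.M:
            raise ValueError("m0 must be below the maximum mass M")

    def zoi_area(self, m):
        """Allometric ZOI area A = C0 * m**(3/4)."""
        return self.C0 * np.asarray(m, dtype=float) ** 0.75

    def mass_at_radius(self, radius: float) -> float:
        """Inverse allometry: the mass whose ZOI has the given radius."""
        return (math.pi * radius * radius / self.C0) ** (4.0 / 3.0)

    def equilibrium_mass(self, S: float) -> float:
        """Lone-plant fixed point m* = M * (1 - S)**4."""
        _check_stress(S)
        return self.M * (1.0 - S) ** 4


def default_growth_params(**overrides) -> GrowthParams:
    """The package's calibrated default parameter set.

    The absolute parameter scale is a free calibration (only dimensionless
    combinations matter for the interaction patterns): ``M`` sets the mass
    unit, the ZOI radius at maximum mass sets ``C0``, and the relaxation
    rate of the linearized law sets ``a = 4 * k * M**(1/4)`` with
    ``r = a / C0``.  Defaults were chosen so that, on the default 200 x 200
    arena, ZOIs of stressed populations at the study densities straddle the
    overlap onset — weak contact at the lowest densities, saturated contact
    at the highest — which is the regime in which both competition and
    facilitation are expressed.
    """
    C0 = math.pi * _ZOI_RADIUS_AT_M**2 / _M_MAX**0.75
    a = 4.0 * _RELAX_RATE * _M_MAX**0.25
    params = GrowthParams(a=a, r=a / C0, M=_M_MAX, C0=C0)
    return replace(params, **overrides) if overrides else params


def _check_stress(S) -> None:
    S = np.asarray(S)
    if np.any(S < 0) or np.any(S > 1):
        raise ValueError("stress S must lie in [0, 1]")


def potential_growth_rate(m, params: GrowthParams, S: float):
    """Neighbor-free growth rate a * m**(3/4) * (1 - S - (m/M)**(1/4))."""
    m = np.asarray(m, dtype=float)
    if np.any(m <= 0):
        raise ValueError("mass must be positive")
    _check_stress(S)
    return params.a * m**0.75 * (1.0 - S - (m / params.M) ** 0.25)


def realized_growth_rate(m, I_c, I_f, params: GrowthParams, S: float):
    """Interaction-modified growth rate r * A * ((1 - S*I_f)*I_c - (m/M)**(1/4))."""
    m = np.asarray(m, dtype=float)
    I_c = np.asarray(I_c, dtype=float)
    I_f = np.asarray(I_f, dtype=float)
    if np.any(m <= 0):
        raise ValueError("mass must be positive")
    _check_stress(S)
    eps = 1e-12
    if np.any(I_c < -eps) or np.any(I_c > 1 + eps) or np.any(I_f < -eps) or np.any(I_f > 1 + eps):
        raise ValueError("interaction indices must lie in [0, 1]")
    A = params.zoi_area(m)
    return params.r * A * ((1.0 - S * I_f) * I_c - (m / params.M) ** 0.25)


def lone_growth_rate(m, params: GrowthParams, S: float):
    """Growth rate of a plant without neighbors, r * A * (1 - S - (m/M)**(1/4)).

    Identical to :func:`realized_growth_rate` with ``I_c = I_f = 1``; used to
    integrate the no-neighbor reference trajectory for RII baselines.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m <= 0):
        raise ValueError("mass must be positive")
    _check_stress(S)
    return params.r * params.zoi_area(m) * (1.0 - S - (m / params.M) ** 0.25)


def integrate_lone(
    params: GrowthParams, S: float, n_steps: int, return_trajectory: bool = False
):
    """Euler-integrate the lone-plant law from ``m0`` for ``n_steps`` steps.

    Uses the same discretization as the spatial simulator so the two code
    paths agree step-by-step for an isolated plant.  The trajectory is
    unconstrained by any arena (a reference plant growing alone).
    """
    m = params.m0
    traj = [m]
    for _ in range(n_steps):
        m = m + params.dt * float(lone_growth_rate(m, params, S))
        m = min(m, params.M)
        traj.append(m)
    if return_trajectory:
        return np.array(traj)
    return m


@dataclass
class Plant:
    """One individual: toroidal position, biomass, life status."""

    id: int
    x: float
    y: float
    mass: float
    alive: bool = True
    birth_step: int = 0


@dataclass(frozen=True)
class SimConfig:
    """Everything needed to run one simulation replicate."""

    growth: GrowthParams = field(default_factory=default_growth_params)
    stress: float = 0.0
    mode: SharingMode = field(default_factory=SharingMode)
    arena: Arena = field(default_factory=Arena)
    n_plants: int = 2
    pattern: str = "random"
    n_steps: int = 50
    record_every: int = 10
    seed: int = 0
    agg_cluster_size: int = 4
    agg_sigma: float = 25.0

    def __post_init__(self) -> None:
        _check_stress(self.stress)
        if self.n_plants < 1:
            raise ValueError("need at least one plant")
        if self.n_steps < 1 or self.record_every < 1:
            raise ValueError("n_steps and record_every must be >= 1")
        if self.pattern not in ("random", "regular", "aggregated"):
            raise ValueError(f"unknown spatial pattern {self.pattern!r}")


def _regular_positions(n: int, arena: Arena) -> np.ndarray:
    """Maximally even (near-square, centered) lattice of n points."""
    rows = max(1, round(math.sqrt(n)))
    base, extra = divmod(n, rows)
    counts = [base + (1 if j < extra else 0) for j in range(rows)]
    pts = []
    for j, cnt in enumerate(counts):
        y = (j + 0.5) * arena.height / rows
        for i in range(cnt):
            x = (i + 0.5) * arena.width / cnt
            pts.append((x, y))
    return np.array(pts, dtype=float)


def init_population(config: SimConfig, rng: np.random.Generator | None = None) -> list[Plant]:
    """Place ``n_plants`` individuals of mass ``m0`` under the configured pattern.

    ``random``: i.i.d. uniform positions.  ``regular``: deterministic
    maximally even lattice.  ``aggregated``: uniform cluster centers (one per
    ``agg_cluster_size`` plants, rounded up) with members scattered
    isotropically (Gaussian, sd ``agg_sigma`` cells, default 25 — moderate
    clustering on the 200-cell arena) and wrapped onto the torus.
    Reproducible under the config seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, arena = config.n_plants, config.arena
    if config.pattern == "random":
        xy = np.column_stack(
            [rng.uniform(0, arena.width, n), rng.uniform(0, arena.height, n)]
        )
    elif config.pattern == "regular":
        xy = _regular_positions(n, arena)
    else:  # aggregated
        n_clusters = math.ceil(n / config.agg_cluster_size)
        centers = np.column_stack(
            [rng.uniform(0, arena.width, n_clusters), rng.uniform(0, arena.height, n_clusters)]
        )
        members = np.arange(n) % n_clusters
        xy = centers[members] + rng.normal(0.0, config.agg_sigma, size=(n, 2))
        xy[:, 0] %= arena.width
        xy[:, 1] %= arena.height
    return [
        Plant(id=i, x=float(xy[i, 0]), y=float(xy[i, 1]), mass=config.growth.m0)
        for i in range(n)
    ]


def _mass_cap(config: SimConfig) -> float:
    radius_cap = _RADIUS_CAP_FRACTION * config.arena.max_radius
    return min(config.growth.M, config.growth.mass_at_radius(radius_cap))


class _FieldCache:
    """Fast interaction fields for a *static* set of plant positions.

    Plant centers never move, so each plant's nearby cell centers can be
    enumerated once, sorted by (minimum-image) distance; rasterization at
    any radius is then a binary search.  Observationally equivalent to
    :func:`zoifac.geometry.compute_field` on the same circles (tested), just
    much faster for many small plants over many steps.
    """

    def __init__(self, xy: np.ndarray, arena: Arena) -> None:
        self.xy = xy
        self.arena = arena
        n = len(xy)
        self._flat: list[np.ndarray] = [None] * n  # cell ids sorted by distance
        self._dist: list[np.ndarray] = [None] * n
        self._r_cache = np.zeros(n)

    def _build(self, i: int, r: float) -> None:
        arena = self.arena
        r = min(r, arena.max_radius)
        cx, cy = arena.wrap(self.xy[i, 0], self.xy[i, 1])
        ii = np.arange(math.floor(cx - r - 0.5), math.ceil(cx + r - 0.5) + 1)
        jj = np.arange(math.floor(cy - r - 0.5), math.ceil(cy + r - 0.5) + 1)
        dx = ii + 0.5 - cx
        dy = jj + 0.5 - cy
        d2 = dx[:, None] ** 2 + dy[None, :] ** 2
        inside = d2 < r * r
        gi, gj = np.nonzero(inside)
        flat = (ii[gi] % arena.width) + (jj[gj] % arena.height) * arena.width
        dist = np.sqrt(d2[gi, gj])
        order = np.argsort(dist, kind="stable")
        self._flat[i] = flat[order].astype(np.int64)
        self._dist[i] = dist[order]
        self._r_cache[i] = r

    def cells(self, i: int, radius: float) -> np.ndarray:
        if radius > self._r_cache[i]:
            self._build(i, max(1.5 * radius, 4.0))
        k = int(np.searchsorted(self._dist[i], radius, side="left"))
        return self._flat[i][:k]

    def field(
        self, alive_idx: np.ndarray, radii: np.ndarray, mode: SharingMode
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(I_c, I_f, A) for the live plants, in ``alive_idx`` order."""
        from .geometry import _accumulate_shares

        arena = self.arena
        cell_area = arena.cell_area
        lists = [self.cells(i, r) for i, r in zip(alive_idx, radii)]
        counts = np.array([len(ix) for ix in lists], dtype=float)
        A = counts * cell_area
        n = len(lists)
        nonzero = counts > 0
        A_c = np.zeros(n)
        A_f = np.zeros(n)
        if nonzero.any():
            entry_cell = np.concatenate([lists[j] for j in range(n) if nonzero[j]])
            entry_owner = np.concatenate(
                [np.full(len(lists[j]), j, dtype=np.int64) for j in range(n) if nonzero[j]]
            )
            n_cells = arena.n_cells
            cover = np.bincount(entry_cell, minlength=n_cells)
            A_c = cell_area * _accumulate_shares(
                entry_cell, entry_owner, A, mode.p, n_cells, n
            )
            contested = cover[entry_cell] >= 2
            if contested.any():
                A_f = cell_area * _accumulate_shares(
                    entry_cell[contested], entry_owner[contested], A, mode.q,
                    n_cells, n,
                )
        with np.errstate(invalid="ignore", divide="ignore"):
            I_c = np.where(nonzero, A_c / np.where(nonzero, A, 1.0), 1.0)
            I_f = np.where(nonzero, 1.0 - A_f / np.where(nonzero, A, 1.0), 1.0)
        return I_c, I_f, A


def _field_for(masses: np.ndarray, xy: np.ndarray, config: SimConfig) -> InteractionField:
    circles = [
        ZoiCircle(x=xy[i, 0], y=xy[i, 1], area=float(config.growth.zoi_area(masses[i])))
        for i in range(len(masses))
    ]
    return compute_field(circles, config.arena, config.mode)


def step(population: list[Plant], config: SimConfig) -> list[Plant]:
    """One synchronous update of a plant list (functional: returns new list).

    The interaction field is computed once from the current snapshot of all
    live plants; every plant then grows by ``dt`` times its realized rate.
    Plants whose mass falls to the death threshold are marked dead and no
    longer enter future fields.  Masses are capped at ``M`` and at the arena
    carrying limit.
    """
    alive_idx = [i for i, p in enumerate(population) if p.alive]
    out = [replace(p) for p in population]
    if not alive_idx:
        return out
    masses = np.array([population[i].mass for i in alive_idx])
    xy = np.array([[population[i].x, population[i].y] for i in alive_idx])
    fld = _field_for(masses, xy, config)
    rates = realized_growth_rate(masses, fld.I_c, fld.I_f, config.growth, config.stress)
    new_m = np.minimum(masses + config.growth.dt * rates, _mass_cap(config))
    for j, i in enumerate(alive_idx):
        if new_m[j] <= config.growth.m_death:
            out[i].alive = False
            out[i].mass = 0.0
        else:
            out[i].mass = float(new_m[j])
    return out


@dataclass
class SimResult:
    """Output of one simulation run.

    ``trajectory``: per-plant rows (step, plant_id, x, y, mass, alive) at
    every recording step.  ``summary``: per-step population summary
    (step, n_alive, mean_mass) at *every* step, for time-resolved analyses;
    ``mean_mass`` is over survivors and NaN when none remain.
    """

    config: SimConfig
    trajectory: pd.DataFrame
    summary: pd.DataFrame

    def final_mean_mass(self) -> float:
        return float(self.summary["mean_mass"].iloc[-1])

    def final_n_alive(self) -> int:
        return int(self.summary["n_alive"].iloc[-1])


def run_simulation(config: SimConfig, rng: np.random.Generator | None = None) -> SimResult:
    """Run the full time loop and collect records.

    Per-plant state is recorded at step 0, every ``record_every`` steps and
    at the final step; the population summary is recorded at every step.
    Deterministic given the config seed (the dynamics itself is
    deterministic; randomness only enters through initial positions).
    """
    plants = init_population(config, rng)
    n = config.n_plants
    masses = np.array([p.mass for p in plants])
    xy = np.array([[p.x, p.y] for p in plants])
    alive = np.ones(n, dtype=bool)
    cap = _mass_cap(config)
    g, S = config.growth, config.stress

    record_steps = sorted(
        set(range(0, config.n_steps + 1, config.record_every)) | {config.n_steps}
    )
    traj_rows: list[tuple] = []
    summary_rows: list[tuple] = []

    def record_traj(t: int) -> None:
        for i in range(n):
            traj_rows.append(
                (t, i, xy[i, 0], xy[i, 1], masses[i] if alive[i] else 0.0, bool(alive[i]))
            )

    def record_summary(t: int) -> None:
        mean = float(masses[alive].mean()) if alive.any() else math.nan
        summary_rows.append((t, int(alive.sum()), mean))

    cache = _FieldCache(xy, config.arena)
    record_traj(0)
    record_summary(0)
    for t in range(1, config.n_steps + 1):
        if alive.any():
            alive_idx = np.flatnonzero(alive)
            radii = np.sqrt(g.zoi_area(masses[alive_idx]) / math.pi)
            I_c, I_f, _ = cache.field(alive_idx, radii, config.mode)
            rates = realized_growth_rate(masses[alive], I_c, I_f, g, S)
            new_m = np.minimum(masses[alive] + g.dt * rates, cap)
            dead = new_m <= g.m_death
            idx = np.flatnonzero(alive)
            masses[idx] = np.where(dead, 0.0, new_m)
            alive[idx[dead]] = False
        if t in record_steps:
            record_traj(t)
        record_summary(t)

    trajectory = pd.DataFrame(
        traj_rows, columns=["step", "plant_id", "x", "y", "mass", "alive"]
    )
    summary = pd.DataFrame(summary_rows, columns=["step", "n_alive", "mean_mass"])
    return SimResult(config=config, trajectory=trajectory, summary=summary)
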