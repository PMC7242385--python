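"""Interaction analysis: RII against the lone-plant baseline.

The relative interaction index::

    RII = (P_w - P_s) / (P_w + P_s)

compares performance with neighbors (``P_w``, here the mean biomass of
survivors in a replicate) against performance without neighbors (``P_s``, the
lone-plant growth law integrated to the same measurement step).  RII lies in
[-1, 1]; negative values indicate net competition and positive values net
facilitation.  Density always refers to *initial* density, not surviving
density, and the replicate (the simulated arena, analogous to an
experimental pot) is the unit of analysis.

This module also runs the full factorial stress x density x replicate
protocol and extracts the pattern diagnostics: where the facilitation-density
curve peaks, and whether it is monotonically decreasing or hump-shaped.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .growth import GrowthParams, SimConfig, integrate_lone, run_simulation

__all__ = [
    "FactorialDesign",
    "compute_rii",
    "lone_baseline",
    "run_factorial",
    "summarize_rii",
    "peak_density",
    "classify_shape",
]

logger = logging.getLogger(__name__)

RII_COLUMNS = ["stress", "density", "replicate", "P_w", "P_s", "RII"]


@dataclass(frozen=True)
class FactorialDesign:
    """The default stress x density x replicate protocol.

    Four stress levels — none (0), low (0.45), high (0.75) and extreme
    (0.85) — crossed with seven initial-density levels (2..8, a relative
    scale), five replicates each, measured after 50 steps.

    Density levels are a *scale*, not raw counts: level ``d`` seeds
    ``round(plants_per_density * d ** density_exponent)`` individuals on the
    arena.  The multiplier keeps each replicate in the self-averaging regime
    (each arena holds enough plants that its mean performance is not
    dominated by the contact lottery of a handful of random positions),
    which is what makes five replicates per cell enough for stable mean
    curves.  The super-linear exponent widens the spanned count ratio
    (64-fold between the extreme levels) so the factorial covers
    competition intensities from well below to well above those at
    intermediate levels — at linear spacing the window is too narrow to
    contain the interaction optima of both high-stress levels at once.
    """

    stress_levels: tuple[float, ...] = (0.0, 0.45, 0.75, 0.85)
    density_levels: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    replicates: int = 5
    measurement_step: int = 50
    plants_per_density: float = 2.1
    density_exponent: float = 3.0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if any(s < 0 or s > 1 for s in self.stress_levels):
            raise ValueError("stress levels must lie in [0, 1]")
        if any(d < 1 for d in self.density_levels):
            raise ValueError("density levels must be >= 1")
        if self.plants_per_density <= 0 or self.density_exponent < 0:
            raise ValueError("plants_per_density must be > 0 and exponent >= 0")

    def n_plants(self, density_level: int) -> int:
        """Individuals seeded on the arena for one density level."""
        return max(1, round(self.plants_per_density * density_level**self.density_exponent))

    @property
    def n_runs(self) -> int:
        return len(self.stress_levels) * len(self.density_levels) * self.replicates


def compute_rii(P_w: float, P_s: float) -> float:
    """RII = (P_w - P_s) / (P_w + P_s); NaN (with a warning) if both are 0."""
    if P_w < 0 or P_s < 0:
        raise ValueError("performances must be non-negative")
    if P_w + P_s == 0:
        warnings.warn("both performances are zero (all plants dead); RII undefined")
        return math.nan
    return (P_w - P_s) / (P_w + P_s)


def lone_baseline(S: float, params: GrowthParams, measurement_step: int = 50) -> float:
    """Deterministic no-neighbor biomass P_s at the measurement step.

    Integrates the lone-plant law with the same Euler discretization as the
    simulator, so the baseline is the biomass a simulated plant would reach
    alone after the same number of steps (rather than the analytic
    equilibrium, which later steps would approach).
    """
    return float(integrate_lone(params, S, measurement_step))


def _replicate_seed(master_seed: int, s_idx: int, d_idx: int, rep: int) -> int:
    """Deterministic per-replicate seed so any factorial subset is reproducible."""
    ss = np.random.SeedSequence([int(master_seed), s_idx, d_idx, rep])
    return int(ss.generate_state(1)[0] % (2**31))


def run_factorial(
    design: FactorialDesign | None = None,
    template: SimConfig | None = None,
    master_seed: int = 0,
    time_resolved: bool = False,
) -> pd.DataFrame:
    """Run the full factorial and emit one RII record per replicate.

    ``template`` supplies everything but stress, density and seed (arena,
    growth parameters, sharing mode, spatial pattern).  Each replicate gets a
    seed derived deterministically from (master seed, stress, density,
    replicate).  Returns a tidy table with columns stress, density,
    replicate, P_w, P_s, RII plus n_alive and step; with ``time_resolved``
    the table instead carries one row per step per replicate (the
    measurement-step rows are flagged by ``step``).
    """
    design = design or FactorialDesign()
    template = template or SimConfig()
    rows = []
    for s_idx, S in enumerate(design.stress_levels):
        baseline_traj = integrate_lone(
            template.growth, S, design.measurement_step, return_trajectory=True
        )
        P_s_final = float(baseline_traj[design.measurement_step])
        for d_idx, N in enumerate(design.density_levels):
            for rep in range(design.replicates):
                cfg = replace(
                    template,
                    stress=S,
                    n_plants=design.n_plants(N),
                    n_steps=design.measurement_step,
                    seed=_replicate_seed(master_seed, s_idx, d_idx, rep),
                )
                res = run_simulation(cfg)
                if time_resolved:
                    for t, n_alive, mean_mass in res.summary.itertuples(index=False):
                        P_w = 0.0 if n_alive == 0 else float(mean_mass)
                        P_s = float(baseline_traj[t])
                        rows.append(
                            (S, N, rep, P_w, P_s, compute_rii(P_w, P_s), n_alive, t)
                        )
                else:
                    n_alive = res.final_n_alive()
                    if n_alive == 0:
                        logger.warning(
                            "all plants dead (S=%s, N=%s, rep=%s)", S, N, rep
                        )
                        P_w = 0.0
                    else:
                        P_w = res.final_mean_mass()
                    rows.append(
                        (
                            S, N, rep, P_w, P_s_final,
                            compute_rii(P_w, P_s_final),
                            n_alive, design.measurement_step,
                        )
                    )
    return pd.DataFrame(rows, columns=RII_COLUMNS + ["n_alive", "step"])


def summarize_rii(records: pd.DataFrame) -> pd.DataFrame:
    """Mean RII with SEM per (stress, density) cell."""
    grp = records.groupby(["stress", "density"])["RII"]
    out = grp.agg(
        mean_rii="mean",
        sem=lambda x: float(x.std(ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0,
        n="count",
    ).reset_index()
    return out


def peak_density(mean_rii_by_density: pd.Series) -> float:
    """Density level at which mean RII is maximal (ties -> lower density).

    Expects a Series indexed by density.  The low-density tie-break is
    conservative for detecting rightward peak shifts with stress.
    """
    s = mean_rii_by_density.dropna()
    if len(s) < 2:
        raise ValueError("need at least two density levels")
    s = s.sort_index()
    return float(s.index[np.argmax(s.to_numpy())])


def classify_shape(
    mean_rii_by_density: pd.Series,
    tolerance: float = 0.0,
) -> str:
    """Classify a facilitation-density curve.

    ``hump-shaped`` if the curve has a *significant* interior peak: the
    argmax is interior, it stands more than ``tolerance`` above both
    endpoints, and the curve is monotone within ``tolerance`` on each side
    of it.  Otherwise ``monotone-decreasing`` if every successive difference
    is <= tolerance, else ``other``.  The hump test runs first so that a
    genuine interior peak is not absorbed by a generous tolerance in the
    monotonicity test.  The tolerance should be on the scale of the
    replicate standard error of the mean RII (see :func:`summarize_rii`),
    since the absolute RII scale depends on calibration.
    """
    s = mean_rii_by_density.dropna().sort_index()
    if len(s) < 3:
        raise ValueError("need at least three density levels")
    vals = s.to_numpy()
    diffs = np.diff(vals)
    k = int(np.argmax(vals))
    if (
        0 < k < len(vals) - 1
        and vals[k] - vals[0] > tolerance
        and vals[k] - vals[-1] > tolerance
        and np.all(diffs[:k] >= -tolerance)
        and np.all(diffs[k:] <= tolerance)
    ):
        return "hump-shaped"
    if np.all(diffs <= tolerance):
        return "monotone-decreasing"
    return "other"
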