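"""Seeded synthetic fixtures: toy geometries and synthetic RII tables.

These generators make every stage of the pipeline testable without any
external data.  The toy geometries exercise the interaction-field edge
cases — including the size-dependent facilitative-response scenario in
which two beneficiaries receive the *same* ameliorated overlap area from a
benefactor but respond differently because of their own size.  The
synthetic RII tables exercise the Bayesian model-comparison machinery with
known generating coefficients.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .analysis import FactorialDesign
from .bayes import Standardizer
from .geometry import Arena, ZoiCircle, analytic_pair_overlap

__all__ = ["TOY_CASES", "generate_toy_geometry", "generate_synthetic_rii"]

logger = logging.getLogger(__name__)

TOY_CASES = ("isolated", "coincident-pair", "fig5-triplet", "disjoint", "lattice")


def _facilitation_triplet(arena: Arena) -> list[ZoiCircle]:
    """Benefactor X with a small fully-covered and a large partly-covered
    beneficiary whose overlap areas with X are equal.

    Beneficiary A (small) lies entirely inside X's ZOI, so its overlap is
    its whole area; beneficiary B (large) is placed at the distance where
    the analytic lens area with X equals A's area.  A and B do not overlap
    each other.  Equal stress amelioration, different relative relief: the
    smaller plant's facilitative response is stronger.
    """
    r_x, r_a, r_b = 20.0, 6.0, 15.0
    cx = (arena.width / 2.0, arena.height / 2.0)
    x = ZoiCircle(cx[0], cx[1], np.pi * r_x**2)
    a = ZoiCircle(cx[0] - 10.0, cx[1], np.pi * r_a**2)  # fully inside X
    target = a.area

    def lens_minus_target(d: float) -> float:
        probe = ZoiCircle(cx[0] + d, cx[1], np.pi * r_b**2)
        return analytic_pair_overlap(x, probe) - target

    # overlap shrinks monotonically with distance; bracket it between
    # near-containment and tangency
    d_b = brentq(lens_minus_target, r_x - r_b + 1e-6, r_x + r_b - 1e-6)
    b = ZoiCircle(cx[0] + d_b, cx[1], np.pi * r_b**2)
    return [x, a, b]


def generate_toy_geometry(case: str, arena: Arena | None = None) -> list[ZoiCircle]:
    """Deterministic plant configurations for geometry tests.

    Cases: ``isolated`` (one plant), ``coincident-pair`` (two identical
    fully overlapping circles), ``fig5-triplet`` (see
    :func:`_facilitation_triplet`; plants ordered benefactor, small
    beneficiary, large beneficiary), ``disjoint`` (four well-separated
    circles), ``lattice`` (3 x 3 grid of equal circles with nearest-neighbor
    overlap).
    """
    arena = arena or Arena()
    w, h = arena.width, arena.height
    if case == "isolated":
        return [ZoiCircle(w / 2, h / 2, np.pi * 10.0**2)]
    if case == "coincident-pair":
        c = ZoiCircle(w / 2, h / 2, np.pi * 8.0**2)
        return [c, ZoiCircle(c.x, c.y, c.area)]
    if case == "fig5-triplet":
        return _facilitation_triplet(arena)
    if case == "disjoint":
        r = min(w, h) / 10.0
        return [
            ZoiCircle(w / 4, h / 4, np.pi * r**2 / 4),
            ZoiCircle(3 * w / 4, h / 4, np.pi * r**2 / 4),
            ZoiCircle(w / 4, 3 * h / 4, np.pi * r**2 / 4),
            ZoiCircle(3 * w / 4, 3 * h / 4, np.pi * r**2 / 4),
        ]
    if case == "lattice":
        spacing = min(w, h) / 4.0
        radius = 0.6 * spacing  # neighbors overlap, diagonals do not
        return [
            ZoiCircle((i + 0.5) * spacing + w / 8, (j + 0.5) * spacing + h / 8,
                      np.pi * radius**2)
            for j in range(3)
            for i in range(3)
        ]
    raise ValueError(f"unknown toy geometry case {case!r}; options: {TOY_CASES}")


def generate_synthetic_rii(
    coefficients: dict[str, float],
    design: FactorialDesign | None = None,
    noise_scale: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic replicate-level RII table from a known linear model.

    ``RII = b0 + bS * S' + bD * D' + bSD * S' D' + eps`` with standardized
    predictors (as in the fitting code), Gaussian noise and clipping to the
    admissible [-1, 1] range (clip events are logged).  Coefficient keys:
    ``intercept``, ``S``, ``D``, ``SxD`` (missing keys default to 0).
    Deterministic under the seed; schema matches the factorial RII table.
    """
    if noise_scale <= 0:
        raise ValueError("noise scale must be positive")
    design = design or FactorialDesign()
    rng = np.random.default_rng(seed)
    rows = []
    for S in design.stress_levels:
        for D in design.density_levels:
            for rep in range(design.replicates):
                rows.append((S, D, rep))
    base = pd.DataFrame(rows, columns=["stress", "density", "replicate"])
    scaler = Standardizer.from_data(base["stress"], base["density"])
    s, d = scaler.transform(base["stress"], base["density"])
    mu = (
        coefficients.get("intercept", 0.0)
        + coefficients.get("S", 0.0) * s
        + coefficients.get("D", 0.0) * d
        + coefficients.get("SxD", 0.0) * s * d
    )
    rii = mu + rng.normal(0.0, noise_scale, size=len(base))
    clipped = np.clip(rii, -1.0, 1.0)
    n_clip = int((clipped != rii).sum())
    if n_clip:
        logger.info("clipped %d synthetic RII values to [-1, 1]", n_clip)
    base["P_w"] = np.nan
    base["P_s"] = np.nan
    base["RII"] = clipped
    return base
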