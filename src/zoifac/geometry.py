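"""Zone-of-influence geometry on a wrap-around patch grid.

Each plant is represented by a circular zone of influence (ZOI) whose area
``A`` scales allometrically with biomass.  The arena is a grid of square
patches with toroidal topology, so circles are rasterized into patch sets and
all interaction bookkeeping is done in exact cell counts.  Where ZOIs overlap,
each contested cell carries one unit of resource (divided among the coverers
according to the competition exponent ``p``) and one unit of stress
amelioration (divided according to the facilitation exponent ``q``).  The
resulting per-plant quantities are

* ``A_c`` — resources actually obtained (non-overlapping cells plus the
  plant's share of contested cells), with competition index ``I_c = A_c / A``;
* ``A_f`` — stress reduction received from neighbors (its share of contested
  cells), with facilitation index ``I_f = 1 - A_f / A``.

Both indices lie in [0, 1] identically because areas are measured in the same
rasterized cell counts.  A solitary plant has ``I_c = 1`` (all resources) and
``I_f = 1`` (no amelioration: it bears the full ambient stress).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Arena",
    "ZoiCircle",
    "SharingMode",
    "InteractionField",
    "rasterize",
    "share_weights",
    "compute_field",
    "analytic_pair_overlap",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Arena:
    """Toroidal grid of homogeneous square patches.

    Parameters
    ----------
    width, height:
        Patch counts along x and y.
    cell_area:
        Area of one patch, in the model's area units.
    torus:
        Whether opposite edges are identified (wrap-around).  The torus is
        the default and the only topology exercised by the simulator; it
        removes edge effects.
    """

    width: int = 200
    height: int = 200
    cell_area: float = 1.0
    torus: bool = True

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("arena dimensions must be >= 1 patch")
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")

    @property
    def n_cells(self) -> int:
        return self.width * self.height

    @property
    def total_area(self) -> float:
        return self.n_cells * self.cell_area

    @property
    def max_radius(self) -> float:
        """Largest circle radius representable without self-overlap.

        On a torus a circle whose radius exceeds half the smaller span would
        wrap onto itself, which makes coverage ill-defined; rasterization
        rejects such circles.
        """
        return 0.5 * min(self.width, self.height)

    def wrap(self, x: float, y: float) -> tuple[float, float]:
        return x % self.width, y % self.height


@dataclass(frozen=True)
class ZoiCircle:
    """A plant's circular zone of influence in arena coordinates."""

    x: float
    y: float
    area: float

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("ZOI area must be non-negative")

    @property
    def radius(self) -> float:
        return math.sqrt(self.area / math.pi)


@dataclass(frozen=True)
class SharingMode:
    """Division rules for contested cells.

    ``p`` is the mode of competition and ``q`` the mode of facilitation.
    Both run from 0 (complete symmetry: equal shares regardless of size)
    through 1 (shares proportional to ZOI area) to ``math.inf`` (complete
    asymmetry: the largest coverer takes the whole cell, ties split equally).
    """

    p: float = 1.0
    q: float = 1.0

    def __post_init__(self) -> None:
        if not (self.p >= 0 and self.q >= 0):
            raise ValueError("sharing exponents must be >= 0 (inf allowed)")


@dataclass
class InteractionField:
    """Per-plant contested-area bookkeeping for one time step.

    All areas are rasterized cell-count areas, so the index invariants
    ``I_c = A_c / A in [0, 1]`` and ``I_f = 1 - A_f / A in [0, 1]`` hold
    exactly.  Plants whose circle rasterizes to zero cells get the
    no-interaction convention ``I_c = I_f = 1``.
    """

    A: np.ndarray
    A_c: np.ndarray
    A_f: np.ndarray
    I_c: np.ndarray
    I_f: np.ndarray
    covered_cells: int = 0
    cell_indices: list[np.ndarray] = field(default_factory=list, repr=False)


def rasterize(circle: ZoiCircle, arena: Arena) -> np.ndarray:
    """Flat indices of arena cells covered by ``circle``.

    A cell is covered iff its *center* lies inside the circle (strictly
    within the radius).  The covered cell area then approximates the analytic
    area with an error bounded by the cell size times the perimeter, and the
    count is invariant under integer translations on the torus.

    Returns a 1-D int64 array of flat indices (``ix + iy * width``), without
    duplicates.  Raises ``ValueError`` for radii exceeding half the arena
    span, where toroidal coverage would self-overlap.
    """
    r = circle.radius
    if r > arena.max_radius:
        raise ValueError(
            f"ZOI radius {r:.2f} exceeds half the arena span "
            f"({arena.max_radius:.2f}); coverage on the torus is ill-defined"
        )
    if circle.area == 0.0:
        return np.empty(0, dtype=np.int64)
    cx, cy = arena.wrap(circle.x, circle.y)
    # bounding box of candidate cell centers (i + 0.5, j + 0.5)
    i_lo = math.floor(cx - r - 0.5)
    i_hi = math.ceil(cx + r - 0.5)
    j_lo = math.floor(cy - r - 0.5)
    j_hi = math.ceil(cy + r - 0.5)
    ii = np.arange(i_lo, i_hi + 1)
    jj = np.arange(j_lo, j_hi + 1)
    dx = ii + 0.5 - cx
    dy = jj + 0.5 - cy
    inside = (dx[:, None] ** 2 + dy[None, :] ** 2) < r * r
    gi, gj = np.nonzero(inside)
    flat = (ii[gi] % arena.width) + (jj[gj] % arena.height) * arena.width
    return flat.astype(np.int64)


def share_weights(sizes, exponent: float) -> np.ndarray:
    """Fractional shares of a contested cell among its coverers.

    ``weight_i = size_i**exponent / sum_j size_j**exponent``.  Exponent 0
    gives equal shares; ``math.inf`` gives the whole cell to the largest
    coverer, split equally among tied maxima.
    """
    s = np.asarray(sizes, dtype=float)
    if s.size == 0:
        raise ValueError("share_weights requires at least one size")
    if np.any(s <= 0):
        raise ValueError("all sizes must be positive")
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    if math.isinf(exponent):
        winners = s == s.max()
        return winners / winners.sum()
    w = s**exponent
    return w / w.sum()


def _accumulate_shares(
    entry_cell: np.ndarray,
    entry_owner: np.ndarray,
    sizes: np.ndarray,
    exponent: float,
    n_cells: int,
    n_plants: int,
) -> np.ndarray:
    """Per-plant summed cell shares for one exponent, fully vectorized.

    ``entry_cell``/``entry_owner`` list every (cell, plant) coverage pair.
    Returns, for each plant, the sum over its cells of its share weight.
    """
    if math.isinf(exponent):
        cell_max = np.zeros(n_cells)
        np.maximum.at(cell_max, entry_cell, sizes[entry_owner])
        is_winner = sizes[entry_owner] == cell_max[entry_cell]
        n_win = np.bincount(entry_cell, weights=is_winner, minlength=n_cells)
        share = np.where(is_winner, 1.0 / n_win[entry_cell], 0.0)
    else:
        w = sizes**exponent
        denom = np.bincount(entry_cell, weights=w[entry_owner], minlength=n_cells)
        share = w[entry_owner] / denom[entry_cell]
    return np.bincount(entry_owner, weights=share, minlength=n_plants)


def compute_field(
    circles: list[ZoiCircle],
    arena: Arena,
    mode: SharingMode | None = None,
) -> InteractionField:
    """Compute A, A_c, A_f, I_c, I_f for every plant in one pass.

    The computation is cell-wise: every covered cell contributes its full
    ``cell_area`` of resource, divided among coverers by ``p``-weights
    (a solitary coverer keeps it all); every *contested* cell (two or more
    coverers) additionally contributes ``cell_area`` of stress-amelioration
    budget, divided by ``q``-weights.  Resources are conserved: the A_c sum
    equals the rasterized area of the union of all ZOIs.  The size measure
    entering the weights is the rasterized ZOI area, a monotone proxy for
    biomass under the allometry ``A = C0 * m**(3/4)``.
    """
    if mode is None:
        mode = SharingMode()
    n = len(circles)
    cell_lists = [rasterize(c, arena) for c in circles]
    counts = np.array([len(ix) for ix in cell_lists], dtype=float)
    A = counts * arena.cell_area

    A_c = np.zeros(n)
    A_f = np.zeros(n)
    nonzero = counts > 0
    if np.any(counts == 0):
        logger.info(
            "%d plant(s) with zero rasterized ZOI; using I_c = I_f = 1",
            int((counts == 0).sum()),
        )

    covered = 0
    if nonzero.any():
        entry_cell = np.concatenate([cell_lists[i] for i in range(n) if nonzero[i]])
        entry_owner = np.concatenate(
            [np.full(len(cell_lists[i]), i, dtype=np.int64) for i in range(n) if nonzero[i]]
        )
        n_cells = arena.n_cells
        cover_count = np.bincount(entry_cell, minlength=n_cells)
        covered = int((cover_count > 0).sum())

        sizes = A.copy()
        A_c = arena.cell_area * _accumulate_shares(
            entry_cell, entry_owner, sizes, mode.p, n_cells, n
        )
        contested = cover_count[entry_cell] >= 2
        if contested.any():
            A_f = arena.cell_area * _accumulate_shares(
                entry_cell[contested],
                entry_owner[contested],
                sizes,
                mode.q,
                n_cells,
                n,
            )

    with np.errstate(invalid="ignore", divide="ignore"):
        I_c = np.where(nonzero, A_c / np.where(nonzero, A, 1.0), 1.0)
        I_f = np.where(nonzero, 1.0 - A_f / np.where(nonzero, A, 1.0), 1.0)
    return InteractionField(
        A=A, A_c=A_c, A_f=A_f, I_c=I_c, I_f=I_f,
        covered_cells=covered, cell_indices=cell_lists,
    )


def analytic_pair_overlap(circle1: ZoiCircle, circle2: ZoiCircle) -> float:
    """Exact lens area of two circles on the plane (no wrapping).

    Closed-form circular-segment formula; used as the discretization oracle
    for rasterized overlaps.  Disjoint circles give 0; full containment gives
    the smaller circle's area.
    """
    r1, r2 = circle1.radius, circle2.radius
    d = math.hypot(circle1.x - circle2.x, circle1.y - circle2.y)
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return math.pi * min(r1, r2) ** 2
    # lens = sum of the two circular segments cut by the radical chord
    a1 = r1 * r1 * math.acos((d * d + r1 * r1 - r2 * r2) / (2 * d * r1))
    a2 = r2 * r2 * math.acos((d * d + r2 * r2 - r1 * r1) / (2 * d * r2))
    a3 = 0.5 * math.sqrt(
        (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2)
    )
    return a1 + a2 - a3


def coverage_table(circles: list[ZoiCircle], arena: Arena):
    """Debug dump: one row per covered cell with the ids covering it.

    Returns a pandas DataFrame with columns (cell_x, cell_y, plant_ids),
    plant_ids being a comma-joined id list sorted ascending.
    """
    import pandas as pd

    cell_map: dict[int, list[int]] = {}
    for pid, c in enumerate(circles):
        for flat in rasterize(c, arena):
            cell_map.setdefault(int(flat), []).append(pid)
    rows = [
        {
            "cell_x": flat % arena.width,
            "cell_y": flat // arena.width,
            "plant_ids": ",".join(str(i) for i in ids),
        }
        for flat, ids in sorted(cell_map.items())
    ]
    return pd.DataFrame(rows, columns=["cell_x", "cell_y", "plant_ids"])
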