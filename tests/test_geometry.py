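"""Geometry: rasterization, cell sharing and the interaction field."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from zoifac import (
    Arena,
    SharingMode,
    ZoiCircle,
    analytic_pair_overlap,
    compute_field,
    rasterize,
    share_weights,
)


def reference_field(circles, arena, p, q):
    """Independent cell-by-cell enumeration oracle (pure Python).

    Walks every cell of the arena, finds its coverers by the minimum-image
    center-in-circle criterion, and divides resource and amelioration
    budgets with inline power weights.
    """
    n = len(circles)
    areas = np.zeros(n)
    a_c = np.zeros(n)
    a_f = np.zeros(n)
    cover = {}
    for ix in range(arena.width):
        for iy in range(arena.height):
            cx, cy = ix + 0.5, iy + 0.5
            ids = []
            for i, c in enumerate(circles):
                dx = min(abs(cx - c.x % arena.width), arena.width - abs(cx - c.x % arena.width))
                dy = min(abs(cy - c.y % arena.height), arena.height - abs(cy - c.y % arena.height))
                if dx * dx + dy * dy < c.radius**2:
                    ids.append(i)
            if ids:
                cover[(ix, iy)] = ids
    for ids in cover.values():
        for i in ids:
            areas[i] += arena.cell_area
    for ids in cover.values():
        sizes = np.array([areas[i] for i in ids])
        if math.isinf(p):
            w = (sizes == sizes.max()) / (sizes == sizes.max()).sum()
        else:
            w = sizes**p / (sizes**p).sum()
        for i, wi in zip(ids, w):
            a_c[i] += arena.cell_area * wi
        if len(ids) >= 2:
            if math.isinf(q):
                wq = (sizes == sizes.max()) / (sizes == sizes.max()).sum()
            else:
                wq = sizes**q / (sizes**q).sum()
            for i, wi in zip(ids, wq):
                a_f[i] += arena.cell_area * wi
    return areas, a_c, a_f


class TestRasterize:
    def test_zero_area_covers_nothing(self):
        assert rasterize(ZoiCircle(5, 5, 0.0), Arena()).size == 0

    def test_translation_invariance_on_torus(self):
        arena = Arena()
        a = rasterize(ZoiCircle(0, 0, math.pi * 9), arena)
        b = rasterize(ZoiCircle(100, 100, math.pi * 9), arena)
        assert a.size == b.size

    def test_covered_count_approximates_area(self):
        # A = 100*pi with unit cells: count within 10% of the analytic area
        arena = Arena()
        area = 100 * math.pi
        count = rasterize(ZoiCircle(57.3, 41.8, area), arena).size
        assert abs(count - area) / area < 0.10

    def test_discretization_error_shrinks_with_resolution(self):
        # same circle at growing radius: relative error is bounded by
        # perimeter/area ~ 2/r, so it shrinks as cells get relatively smaller
        errors = []
        for r in (5.0, 20.0, 80.0):
            count = rasterize(ZoiCircle(100.3, 99.2, math.pi * r * r), Arena()).size
            errors.append(abs(count - math.pi * r * r) / (math.pi * r * r))
        assert errors[2] < errors[0]
        assert errors[2] < 0.01

    def test_oversized_radius_rejected(self):
        with pytest.raises(ValueError, match="half the arena span"):
            rasterize(ZoiCircle(0, 0, math.pi * 101**2), Arena())

    def test_no_duplicate_cells(self):
        flat = rasterize(ZoiCircle(1.2, 198.7, math.pi * 36), Arena())
        assert len(np.unique(flat)) == len(flat)


class TestShareWeights:
    def test_symmetric_equal_shares(self):
        np.testing.assert_allclose(share_weights([1.0, 3.0], 0.0), [0.5, 0.5])

    def test_fully_asymmetric_winner_takes_all(self):
        np.testing.assert_allclose(share_weights([1.0, 3.0], math.inf), [0.0, 1.0])

    def test_proportional_sharing(self):
        np.testing.assert_allclose(share_weights([1.0, 3.0], 1.0), [0.25, 0.75])

    def test_asymmetric_ties_split(self):
        np.testing.assert_allclose(
            share_weights([2.0, 2.0, 1.0], math.inf), [0.5, 0.5, 0.0]
        )

    @pytest.mark.parametrize("bad", [[], [0.0, 1.0], [-1.0, 2.0]])
    def test_invalid_sizes_rejected(self, bad):
        with pytest.raises(ValueError):
            share_weights(bad, 1.0)

    @given(
        sizes=st.lists(st.floats(0.1, 1e4), min_size=1, max_size=6),
        exponent=st.floats(0.0, 8.0),
    )
    def test_weights_are_a_distribution(self, sizes, exponent):
        w = share_weights(sizes, exponent)
        assert np.all(w >= 0)
        assert math.isclose(w.sum(), 1.0, rel_tol=1e-9)

    @given(exponent=st.floats(0.0, 6.0))
    def test_larger_plant_share_nondecreasing_in_exponent(self, exponent):
        lo = share_weights([2.0, 5.0], exponent)[1]
        hi = share_weights([2.0, 5.0], exponent + 0.5)[1]
        assert hi >= lo - 1e-12


class TestAnalyticOverlap:
    def test_containment(self):
        a = ZoiCircle(0, 0, math.pi * 4)
        b = ZoiCircle(0, 0, math.pi * 25)
        assert analytic_pair_overlap(a, b) == pytest.approx(4 * math.pi)

    def test_disjoint(self):
        a = ZoiCircle(0, 0, math.pi * 9)
        b = ZoiCircle(10, 0, math.pi * 9)
        assert analytic_pair_overlap(a, b) == 0.0

    def test_lens_formula(self):
        # equal radii r=3 at distance 3: 2 r^2 cos^-1(d/2r) - (d/2) sqrt(4r^2 - d^2)
        r, d = 3.0, 3.0
        expected = 2 * r * r * math.acos(d / (2 * r)) - (d / 2) * math.sqrt(
            4 * r * r - d * d
        )
        a = ZoiCircle(0, 0, math.pi * r * r)
        b = ZoiCircle(d, 0, math.pi * r * r)
        assert analytic_pair_overlap(a, b) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("r1,r2,d", [(6.0, 9.0, 7.5), (12.0, 5.0, 10.4)])
    def test_rasterized_overlap_converges_to_lens(self, r1, r2, d):
        # overlap measured in unit cells at three geometric scales; the
        # relative error must shrink within a perimeter/area envelope
        errors = []
        for scale in (1.0, 2.0, 4.0):
            arena = Arena(width=200, height=200)
            c1 = ZoiCircle(80.0, 100.0, math.pi * (r1 * scale) ** 2)
            c2 = ZoiCircle(80.0 + d * scale, 100.0, math.pi * (r2 * scale) ** 2)
            cells1 = set(rasterize(c1, arena).tolist())
            cells2 = set(rasterize(c2, arena).tolist())
            overlap = len(cells1 & cells2)
            exact = analytic_pair_overlap(c1, c2)
            errors.append(abs(overlap - exact) / exact)
        assert errors[2] <= errors[0] + 1e-3
        assert errors[2] < 0.02


class TestComputeField:
    def test_single_plant_full_resources_no_relief(self):
        fld = compute_field([ZoiCircle(20, 20, math.pi * 25)], Arena(width=60, height=60))
        assert fld.I_c[0] == pytest.approx(1.0)
        assert fld.I_f[0] == pytest.approx(1.0)
        assert fld.A_f[0] == 0.0

    def test_coincident_pair_splits_evenly(self):
        c = ZoiCircle(30, 30, math.pi * 64)
        fld = compute_field([c, ZoiCircle(c.x, c.y, c.area)], Arena(width=80, height=80))
        np.testing.assert_allclose(fld.I_c, [0.5, 0.5])
        np.testing.assert_allclose(fld.I_f, [0.5, 0.5])

    def test_zero_area_plant_convention(self):
        fld = compute_field(
            [ZoiCircle(10, 10, 0.0), ZoiCircle(20, 20, math.pi * 9)],
            Arena(width=40, height=40),
        )
        assert fld.I_c[0] == 1.0 and fld.I_f[0] == 1.0

    @pytest.mark.parametrize("p,q", [(0.0, 0.0), (1.0, 1.0), (2.5, 0.5), (math.inf, 1.0)])
    def test_matches_cellwise_reference(self, p, q, rng, small_arena):
        circles = [
            ZoiCircle(rng.uniform(0, 40), rng.uniform(0, 40), math.pi * rng.uniform(2, 8) ** 2)
            for _ in range(5)
        ]
        fld = compute_field(circles, small_arena, SharingMode(p=p, q=q))
        areas, a_c, a_f = reference_field(circles, small_arena, p, q)
        np.testing.assert_allclose(fld.A, areas)
        np.testing.assert_allclose(fld.A_c, a_c, atol=1e-9)
        np.testing.assert_allclose(fld.A_f, a_f, atol=1e-9)

    def test_resource_conservation_and_bounds(self, rng):
        # sum of A_c equals the rasterized union area; indices stay in [0, 1]
        arena = Arena(width=100, height=100)
        for trial in range(20):
            circles = [
                ZoiCircle(
                    rng.uniform(0, 100), rng.uniform(0, 100),
                    math.pi * rng.uniform(0.5, 15) ** 2,
                )
                for _ in range(rng.integers(2, 9))
            ]
            fld = compute_field(circles, arena, SharingMode(p=1.0, q=1.0))
            union = len(set(np.concatenate([rasterize(c, arena) for c in circles]).tolist()))
            assert fld.A_c.sum() == pytest.approx(union * arena.cell_area, rel=1e-9)
            assert np.all(fld.I_c >= 0) and np.all(fld.I_c <= 1)
            assert np.all(fld.I_f >= 0) and np.all(fld.I_f <= 1)

    def test_permutation_symmetry(self, rng, small_arena):
        circles = [
            ZoiCircle(rng.uniform(0, 40), rng.uniform(0, 40), math.pi * rng.uniform(2, 7) ** 2)
            for _ in range(4)
        ]
        fld = compute_field(circles, small_arena)
        perm = [2, 0, 3, 1]
        fld_p = compute_field([circles[i] for i in perm], small_arena)
        np.testing.assert_allclose(fld_p.I_c, fld.I_c[perm])
        np.testing.assert_allclose(fld_p.I_f, fld.I_f[perm])

    def test_larger_plant_gains_with_asymmetry(self):
        # the larger of two overlapping plants takes a non-decreasing share
        # of contested cells as the competition exponent grows
        arena = Arena(width=80, height=80)
        pair = [
            ZoiCircle(35, 40, math.pi * 100),
            ZoiCircle(47, 40, math.pi * 49),
        ]
        shares = []
        for p in (0.0, 1.0, 3.0, math.inf):
            fld = compute_field(pair, arena, SharingMode(p=p, q=1.0))
            contested_gain = fld.A_c[0] - (fld.A[0] - fld.A_f[0] / fld.A_f.sum() * 0)
            shares.append(fld.A_c[0])
        assert all(b >= a - 1e-9 for a, b in zip(shares, shares[1:]))

    def test_facilitation_requires_neighbors(self, rng, small_arena):
        circles = [
            ZoiCircle(rng.uniform(0, 40), rng.uniform(0, 40), math.pi * rng.uniform(1, 6) ** 2)
            for _ in range(6)
        ]
        fld = compute_field(circles, small_arena)
        cell_sets = [set(ix.tolist()) for ix in fld.cell_indices]
        for i in range(len(circles)):
            overlaps = any(
                i != j and cell_sets[i] & cell_sets[j] for j in range(len(circles))
            )
            assert (fld.A_f[i] > 0) == overlaps
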