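import math

import numpy as np
import pytest

from symsurf import (
    AxisBounds,
    BuildSpec,
    ResidueGeometry,
    SymmetryAxis,
    axis_bounds,
    compute_ndp_records,
    detect_point_group,
    make_cyclic,
    make_dihedral,
    ndp_2fold,
    ndp_all,
    ndp_nfold,
    ndp_per_axis,
    residue_geometries,
    transform_assembly,
)
from symsurf.errors import ContractViolationError, InputError, NotApplicableError
from symsurf.symmetry import SymmetrySolution
from symsurf.synthetic import random_rigid_transform


def _geoms(points):
    return [ResidueGeometry(("A", str(i + 1)), p) for i, p in enumerate(points)]


def _axis(v, fold=2):
    v = np.asarray(v, dtype=float)
    return SymmetryAxis(v / np.linalg.norm(v), fold)


def brute_force_ndp(axes, residues):
    """Independent oracle: explicit double loop, no vectorization."""
    out = {}
    for res in residues:
        best = math.inf
        for axis in axes:
            projections = [float(np.dot(axis.direction, g.r)) for g in residues]
            d_max, d_min = max(projections), min(projections)
            p = float(np.dot(axis.direction, res.r))
            best = min(best, min(d_max - p, p - d_min))
        out[res.residue_key] = best
    return out


class TestAxisBounds:
    def test_extreme_projections(self):
        geoms = _geoms([[0, 0, 0], [1, 1, 2], [3, -2, 10]])
        b = axis_bounds(_axis([0, 0, 1]), geoms)
        assert b.d_max == 10.0 and b.d_min == 0.0

    def test_single_residue_degenerate(self):
        b = axis_bounds(_axis([0, 0, 1]), _geoms([[5, 5, 7]]))
        assert b.d_max == b.d_min == 7.0

    def test_axis_sign_flip_swaps_bounds_but_not_ndp(self):
        rng = np.random.default_rng(4)
        geoms = _geoms(rng.normal(scale=8, size=(30, 3)))
        up, down = _axis([0, 0, 1]), SymmetryAxis(np.array([0.0, 0.0, -1.0]), 2)
        b_up, b_down = axis_bounds(up, geoms), axis_bounds(down, geoms)
        assert b_down.d_max == pytest.approx(-b_up.d_min)
        assert b_down.d_min == pytest.approx(-b_up.d_max)
        for g in geoms:
            assert ndp_per_axis(b_up, g) == pytest.approx(ndp_per_axis(b_down, g), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            axis_bounds(_axis([0, 0, 1]), [])


class TestNdpPerAxis:
    def test_formula_and_boundary_cases(self):
        b = AxisBounds(_axis([0, 0, 1]), d_max=10.0, d_min=0.0)
        assert ndp_per_axis(b, ResidueGeometry(("A", "1"), [0, 0, 2])) == 2.0
        assert ndp_per_axis(b, ResidueGeometry(("A", "2"), [0, 0, 10])) == 0.0
        # midpoint attains the per-axis maximum (d_max - d_min) / 2
        assert ndp_per_axis(b, ResidueGeometry(("A", "3"), [0, 0, 5])) == 5.0

    def test_out_of_bounds_residue_rejected(self):
        b = AxisBounds(_axis([0, 0, 1]), d_max=10.0, d_min=0.0)
        with pytest.raises(ContractViolationError):
            ndp_per_axis(b, ResidueGeometry(("A", "1"), [0, 0, 12]))


class TestNdpAll:
    def test_single_axis_equals_per_axis(self):
        rng = np.random.default_rng(5)
        geoms = _geoms(rng.normal(scale=10, size=(25, 3)))
        axis = _axis([1, 2, 3], fold=3)
        b = axis_bounds(axis, geoms)
        result = ndp_all([axis], geoms)
        for g in geoms:
            assert result[g.residue_key][0] == pytest.approx(ndp_per_axis(b, g), abs=1e-12)

    def test_apex_residue_takes_value_from_its_axis(self):
        # residue at the apex along z but mid-height along x
        geoms = _geoms([[0, 0, 10], [0, 0, -10], [10, 0, 0], [-10, 0, 0]])
        result = ndp_all([_axis([0, 0, 1], 4), _axis([1, 0, 0], 2)], geoms)
        assert result[("A", "1")][0] == 0.0  # apex along z
        assert result[("A", "1")][1] == 4

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        geoms = _geoms(rng.normal(scale=12, size=(100, 3)))
        axes = [_axis(rng.normal(size=3), fold) for fold in (2, 3, 4)]
        vectorized = ndp_all(axes, geoms)
        oracle = brute_force_ndp(axes, geoms)
        for key, expected in oracle.items():
            assert vectorized[key][0] == pytest.approx(expected, abs=1e-9)

    def test_empty_axes_rejected(self):
        with pytest.raises(InputError):
            ndp_all([], _geoms([[0, 0, 0]]))


class TestFoldVariants:
    def test_subset_min_ordering_on_d3(self, random_d3_axes_and_geoms):
        axes, geoms = random_d3_axes_and_geoms
        base = ndp_all(axes, geoms)
        two = ndp_2fold(axes, geoms)
        high = ndp_nfold(axes, geoms)
        for g in geoms:
            key = g.residue_key
            assert base[key][0] <= two[key] + 1e-12
            assert base[key][0] <= high[key] + 1e-12

    def test_not_applicable_on_cyclic_and_d2(self):
        geoms = _geoms(np.random.default_rng(7).normal(size=(10, 3)))
        with pytest.raises(NotApplicableError):
            ndp_2fold([_axis([0, 0, 1], fold=4)], geoms)
        d2_axes = [_axis([0, 0, 1], 2), _axis([1, 0, 0], 2), _axis([0, 1, 0], 2)]
        with pytest.raises(NotApplicableError):
            ndp_2fold(d2_axes, geoms)
        with pytest.raises(NotApplicableError):
            ndp_nfold(d2_axes, geoms)

    def test_residue_on_twofold_bounding_plane_scores_zero(self):
        axes = [_axis([0, 0, 1], 4), _axis([1, 0, 0], 2), _axis([0, 1, 0], 2)]
        geoms = _geoms([[12, 0, 0], [-12, 0, 0], [0, 3, 5], [0, -3, -5]])
        two = ndp_2fold(axes, geoms)
        assert two[("A", "1")] == 0.0


@pytest.fixture(scope="module")
def random_d3_axes_and_geoms():
    rng = np.random.default_rng(8)
    axes = [
        _axis([0, 0, 1], 3),
        _axis([1, 0, 0], 2),
        _axis([math.cos(math.pi / 3), math.sin(math.pi / 3), 0], 2),
        _axis([math.cos(2 * math.pi / 3), math.sin(2 * math.pi / 3), 0], 2),
    ]
    geoms = _geoms(rng.normal(scale=15, size=(60, 3)))
    return axes, geoms


class TestDispatch:
    def test_cyclic_gets_base_variant_only(self, c3):
        asm, _ = c3
        recs = compute_ndp_records(asm, detect_point_group(asm))
        assert all(r.ndp_2fold is None and r.ndp_nfold is None for r in recs)
        assert all(r.closest_axis_fold == 3 for r in recs)

    def test_d2_gets_base_variant_only(self, d2):
        asm, _ = d2
        recs = compute_ndp_records(asm, detect_point_group(asm))
        assert all(r.ndp_2fold is None and r.ndp_nfold is None for r in recs)

    def test_d4_gets_all_variants_and_recombination(self, d4, d4_solution):
        asm, _ = d4
        recs = compute_ndp_records(asm, d4_solution)
        for r in recs:
            assert r.ndp_2fold is not None and r.ndp_nfold is not None
            assert r.ndp == pytest.approx(min(r.ndp_2fold, r.ndp_nfold), abs=1e-9)

    def test_c1_without_axes_rejected(self, monomer):
        asm, _ = monomer
        sol = SymmetrySolution("C1", [], asm.ca_centroid(), 0.0)
        with pytest.raises(InputError):
            compute_ndp_records(asm, sol)

    def test_monomer_control_yields_full_column(self, monomer):
        asm, axis = monomer
        sol = SymmetrySolution("C1", [axis], asm.ca_centroid(), 0.0)
        recs = compute_ndp_records(asm, sol)
        assert len(recs) == len(asm.eligible_residues())
        assert all(r.ndp >= 0 for r in recs)


class TestInvariants:
    def test_non_negative_with_zero_extremes_both_sides(self, d4, d4_solution):
        asm, _ = d4
        geoms = residue_geometries(asm, d4_solution.center)
        for axis in d4_solution.axes:
            b = axis_bounds(axis, geoms)
            values_max = [b.d_max - float(np.dot(axis.direction, g.r)) for g in geoms]
            values_min = [float(np.dot(axis.direction, g.r)) - b.d_min for g in geoms]
            assert min(values_max) == pytest.approx(0.0, abs=1e-9)
            assert min(values_min) == pytest.approx(0.0, abs=1e-9)

    def test_origin_independence(self, d4, d4_solution):
        asm, _ = d4
        rng = np.random.default_rng(9)
        base = {
            r.residue_key: r.ndp for r in compute_ndp_records(asm, d4_solution)
        }
        for _ in range(5):
            shifted = SymmetrySolution(
                d4_solution.group_label,
                d4_solution.axes,
                d4_solution.center + rng.uniform(-40, 40, size=3),
                d4_solution.rmsd,
            )
            for r in compute_ndp_records(asm, shifted):
                assert r.ndp == pytest.approx(base[r.residue_key], abs=1e-9)

    def test_rigid_motion_equivariance(self, d4, d4_solution):
        asm, _ = d4
        base = {r.residue_key: r.ndp for r in compute_ndp_records(asm, d4_solution)}
        R, t = random_rigid_transform(10)
        moved = transform_assembly(asm, R, t)
        moved_axes = [
            SymmetryAxis(R @ a.direction, a.fold, R @ a.origin + t)
            for a in d4_solution.axes
        ]
        moved_sol = SymmetrySolution(
            d4_solution.group_label, moved_axes, R @ d4_solution.center + t
        )
        for r in compute_ndp_records(moved, moved_sol):
            assert r.ndp == pytest.approx(base[r.residue_key], abs=1e-8)

    def test_per_axis_upper_bound(self, random_d3_axes_and_geoms):
        axes, geoms = random_d3_axes_and_geoms
        for axis in axes:
            b = axis_bounds(axis, geoms)
            half_span = (b.d_max - b.d_min) / 2.0
            for g in geoms:
                assert ndp_per_axis(b, g) <= half_span + 1e-12

    def test_plane_count_accounting(self, c3, d2, d4):
        for (asm, _), expected_axes in [(c3, 1), (d2, 3), (d4, 5)]:
            sol = detect_point_group(asm)
            assert 2 * len(sol.axes) == 2 * expected_axes
        # Cn → 2 planes, D2 → 6, Dn (n>2) → 2(n+1)
        assert 2 * len(detect_point_group(c3[0]).axes) == 2
        assert 2 * len(detect_point_group(d2[0]).axes) == 6
        assert 2 * len(detect_point_group(d4[0]).axes) == 2 * (4 + 1)
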