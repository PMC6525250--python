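"""Normal distance to the closest bounding plane (nDp).

For each symmetry axis *a* (unit vector **s** through the assembly center),
two bounding planes orthogonal to the axis pass through the extreme Cα
projections d_max = max_i s·r_i and d_min = min_i s·r_i over all residues of
the quaternary structure. A residue's nDp with respect to that axis is its
distance to the nearer plane:

    nDp(a, i) = min(d_max − s·r_i, s·r_i − d_min)

Low nDp marks residues near an apex of the assembly along a symmetry axis —
the geometric hot spots where point mutations can seed open, high-order
self-assembly.

Three variants are produced depending on the symmetry class:

* ``ndp``        — minimum over all axes (always computed; the only variant
                   for cyclic assemblies, D2 and the monomer control);
* ``ndp_2fold``  — minimum over the 2-fold axes only (Dn, n > 2);
* ``ndp_nfold``  — against the unique highest-fold axis (Dn, n > 2).

D2 has three indistinguishable 2-fold axes, so fold-restricted variants are
undefined there. All values are origin-independent: nDp is a difference of
projections, so the choice of center cancels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractViolationError, InputError, NotApplicableError
from .structure_io import Assembly
from .symmetry import SymmetryAxis, SymmetrySolution

__all__ = [
    "ResidueGeometry",
    "AxisBounds",
    "NdpRecord",
    "residue_geometries",
    "axis_bounds",
    "ndp_per_axis",
    "ndp_all",
    "ndp_2fold",
    "ndp_nfold",
    "compute_ndp_records",
]

_TIE_TOL = 1e-9


@dataclass
class ResidueGeometry:
    """Residue key and its Cα position vector r (Å) from the assembly center."""

    residue_key: tuple[str, str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.shape != (3,) or not np.all(np.isfinite(self.r)):
            raise InputError(f"residue {self.residue_key}: r must be 3 finite components")


@dataclass
class AxisBounds:
    """The two bounding planes of one axis: extreme projections d_max ≥ d_min."""

    axis: SymmetryAxis
    d_max: float
    d_min: float


@dataclass
class NdpRecord:
    """Per-residue nDp variants and the closest-plane assignment."""

    residue_key: tuple[str, str]
    ndp: float
    closest_axis_fold: int
    closest_plane: tuple[int, str]  # (axis index, "max" | "min")
    ndp_2fold: float | None = None
    ndp_nfold: float | None = None


def residue_geometries(assembly: Assembly, center: np.ndarray | None = None) -> list[ResidueGeometry]:
    """Position vectors for every descriptor-eligible (Cα-bearing, non-hetero) residue."""
    if center is None:
        center = assembly.ca_centroid()
    center = np.asarray(center, dtype=float)
    return [
        ResidueGeometry(res.key, res.ca.coord - center)
        for res in assembly.eligible_residues()
    ]


def _projections(axis: SymmetryAxis, residues: list[ResidueGeometry]) -> np.ndarray:
    rs = np.array([g.r for g in residues], dtype=float)
    return rs @ axis.direction


def axis_bounds(axis: SymmetryAxis, residues: list[ResidueGeometry]) -> AxisBounds:
    """Bounding-plane positions: extreme Cα projections onto the axis."""
    if not residues:
        raise InputError("axis_bounds requires at least one residue")
    proj = _projections(axis, residues)
    return AxisBounds(axis=axis, d_max=float(proj.max()), d_min=float(proj.min()))


def ndp_per_axis(bounds: AxisBounds, residue: ResidueGeometry) -> float:
    """nDp of one residue against one axis: min(d_max − s·r, s·r − d_min)."""
    p = float(np.dot(bounds.axis.direction, residue.r))
    value = min(bounds.d_max - p, p - bounds.d_min)
    if value < -1e-9:
        raise ContractViolationError(
            f"residue {residue.residue_key} lies outside the bounding planes "
            f"(nDp {value:.3g} < 0); it was not part of the bounds computation"
        )
    return max(value, 0.0)


def _ndp_table(axes: list[SymmetryAxis], residues: list[ResidueGeometry]) -> np.ndarray:
    """(n_axes, n_residues) matrix of per-axis nDp values."""
    rs = np.array([g.r for g in residues], dtype=float)
    out = np.empty((len(axes), len(residues)))
    for i, axis in enumerate(axes):
        proj = rs @ axis.direction
        out[i] = np.minimum(proj.max() - proj, proj - proj.min())
    return np.maximum(out, 0.0)


def ndp_all(
    axes: list[SymmetryAxis], residues: list[ResidueGeometry]
) -> dict[tuple[str, str], tuple[float, int, tuple[int, str]]]:
    """Per-residue minimum nDp over all axes.

    Returns residue_key → (ndp, fold of the realizing axis, (axis index,
    side)). Ties between axes within 1e-9 Å resolve to the lowest fold, then
    to input order.
    """
    if not axes:
        raise InputError("ndp_all requires at least one axis")
    table = _ndp_table(axes, residues)
    rs = np.array([g.r for g in residues], dtype=float)
    bounds_list = [axis_bounds(a, residues) for a in axes]
    result: dict[tuple[str, str], tuple[float, int, tuple[int, str]]] = {}
    for j, geom in enumerate(residues):
        best_i = 0
        for i in range(1, len(axes)):
            if table[i, j] < table[best_i, j] - _TIE_TOL:
                best_i = i
            elif abs(table[i, j] - table[best_i, j]) <= _TIE_TOL and (
                axes[i].fold < axes[best_i].fold
            ):
                best_i = i
        axis = axes[best_i]
        proj = float(rs[j] @ axis.direction)
        bounds = bounds_list[best_i]
        side = "max" if (bounds.d_max - proj) <= (proj - bounds.d_min) else "min"
        result[geom.residue_key] = (float(table[best_i, j]), axis.fold, (best_i, side))
    return result


def ndp_2fold(
    axes: list[SymmetryAxis], residues: list[ResidueGeometry]
) -> dict[tuple[str, str], float]:
    """Per-residue minimum nDp over the 2-fold axes (Dn, n > 2 only)."""
    folds = [a.fold for a in axes]
    twofold = [a for a in axes if a.fold == 2]
    if not twofold:
        raise NotApplicableError("no 2-fold axes present")
    if max(folds) == 2:
        raise NotApplicableError(
            "all axes are 2-fold (C2 or D2): axis folds cannot be distinguished, "
            "only the unrestricted nDp is defined"
        )
    table = _ndp_table(twofold, residues)
    mins = table.min(axis=0)
    return {g.residue_key: float(v) for g, v in zip(residues, mins)}


def ndp_nfold(
    axes: list[SymmetryAxis], residues: list[ResidueGeometry]
) -> dict[tuple[str, str], float]:
    """Per-residue nDp against the unique highest-fold axis (Dn, n > 2 only)."""
    if not axes:
        raise InputError("ndp_nfold requires at least one axis")
    top = max(a.fold for a in axes)
    candidates = [a for a in axes if a.fold == top]
    if top == 2 or len(candidates) != 1:
        raise NotApplicableError(
            "no unique highest-fold axis (C2/D2 or ambiguous folds)"
        )
    table = _ndp_table(candidates, residues)
    return {g.residue_key: float(v) for g, v in zip(residues, table[0])}


def compute_ndp_records(assembly: Assembly, solution: SymmetrySolution) -> list[NdpRecord]:
    """All nDp variants appropriate for the assembly's symmetry class.

    Cyclic assemblies, D2 and the fold-1 monomer control get the unrestricted
    ``ndp`` only; high-order dihedral assemblies (Dn, n > 2) additionally get
    ``ndp_2fold`` and ``ndp_nfold``. C1 without a control axis has no bounding
    planes and raises.
    """
    if not solution.axes:
        raise InputError(
            "assembly has no symmetry axes: nDp is undefined for an asymmetric "
            "structure unless a random control axis is supplied"
        )
    residues = residue_geometries(assembly, solution.center)
    base = ndp_all(solution.axes, residues)
    two: dict | None = None
    high: dict | None = None
    if solution.is_high_order_dihedral:
        two = ndp_2fold(solution.axes, residues)
        high = ndp_nfold(solution.axes, residues)
    records = []
    for geom in residues:
        value, fold, plane = base[geom.residue_key]
        records.append(
            NdpRecord(
                residue_key=geom.residue_key,
                ndp=value,
                closest_axis_fold=fold,
                closest_plane=plane,
                ndp_2fold=None if two is None else two[geom.residue_key],
                ndp_nfold=None if high is None else high[geom.residue_key],
            )
        )
    return records
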