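"""Point-group detection for homomeric assemblies.

A homomer with cyclic symmetry Cn is related by n rotations about a single
axis; a dihedral homomer Dn additionally carries n 2-fold axes perpendicular
to the main axis. The detector superposes the first chain onto every other
chain (Kabsch, Cα only), decomposes each superposition into an axis and an
angle, clusters the axes, infers the fold of each axis from the observed
angles (multiples of 2π/n) and verifies group closure by applying each
generator to the whole assembly.

Axes may instead be loaded from a tabulated file (columns pdb_long, fold,
x, y, z), e.g. output of an external symmetry-analysis tool. A seeded random
unit axis provides the monomer negative control used to compute hypothetical
bounding-plane descriptors on asymmetric structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import (
    AsymmetricStructureError,
    DegenerateGeometryError,
    FormatError,
    HeteromerError,
    InputError,
)
from .structure_io import Assembly, Chain

__all__ = [
    "SymmetryAxis",
    "SymmetrySolution",
    "kabsch_superpose",
    "rotation_axis_angle",
    "detect_point_group",
    "read_axes_file",
    "random_unit_axis",
    "solution_from_axes",
]

#: default angular tolerance for clustering axis directions (radians); ~2°
ANGLE_TOL = math.radians(2.0)
#: default closure RMSD tolerance (Å) — crystallographic homomers are only
#: approximately symmetric
RMSD_TOL = 3.0


@dataclass
class SymmetryAxis:
    """A symmetry axis: unit direction vector, integer fold, origin point (Å).

    Fold 1 marks the monomer-control pseudo-axis.
    """

    direction: np.ndarray
    fold: int
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        norm = float(np.linalg.norm(self.direction))
        if abs(norm - 1.0) > 1e-9:
            raise InputError(f"axis direction must be a unit vector (norm {norm:.6g})")
        if self.fold < 1:
            raise InputError(f"axis fold must be ≥ 1, got {self.fold}")


@dataclass
class SymmetrySolution:
    """Detected point group: label (C1/Cn/Dn), axes, assembly center, fit RMSD (Å)."""

    group_label: str
    axes: list[SymmetryAxis]
    center: np.ndarray
    rmsd: float = 0.0

    @property
    def max_fold(self) -> int:
        return max((a.fold for a in self.axes), default=1)

    @property
    def is_high_order_dihedral(self) -> bool:
        """Dn with n > 2 — the only class where fold-restricted variants are defined."""
        return self.group_label.startswith("D") and self.max_fold > 2


def kabsch_superpose(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-RMSD proper rigid transform (R, t, rmsd) mapping ``coords_a`` onto ``coords_b``.

    Reflections are rejected: the returned rotation always has determinant +1,
    so a mirror-image pair yields a strictly positive RMSD.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise InputError(f"coordinate sets must be equal-shaped N×3, got {a.shape} vs {b.shape}")
    if a.shape[0] < 3:
        raise InputError("need at least 3 points to superpose")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    # collinear (rank < 2) point sets leave the rotation underdetermined
    if np.linalg.matrix_rank(a0, tol=1e-8 * max(1.0, np.abs(a0).max())) < 2:
        raise DegenerateGeometryError("points are collinear; rotation is underdetermined")
    rot, _ = Rotation.align_vectors(b0, a0)
    R = rot.as_matrix()
    t = cb - R @ ca
    rmsd = float(np.sqrt(np.mean(np.sum((a @ R.T + t - b) ** 2, axis=1))))
    return R, t, rmsd


def rotation_axis_angle(rotation: np.ndarray, tol: float = 1e-8) -> tuple[np.ndarray, float]:
    """Decompose a proper rotation into (unit axis, angle ∈ (0, π]).

    The axis sign is canonicalized so its first nonzero component is positive,
    which maps a rotation and its inverse to the same axis representative —
    exactly what axis clustering needs.
    """
    rot = Rotation.from_matrix(np.asarray(rotation, dtype=float))
    rotvec = rot.as_rotvec()
    angle = float(np.linalg.norm(rotvec))
    if angle <= tol:
        raise DegenerateGeometryError("rotation is (near-)identity; no axis defined")
    axis = rotvec / angle
    for comp in axis:
        if abs(comp) > 1e-12:
            if comp < 0:
                axis = -axis
            break
    return axis, angle


def random_unit_axis(seed: int, center: np.ndarray) -> SymmetryAxis:
    """Seeded uniformly-distributed random unit axis through ``center`` (fold 1).

    Sampling: normalized 3-variate standard Gaussian draw, which is exactly
    uniform on the sphere.
    """
    rng = np.random.default_rng(seed)
    v = rng.normal(size=3)
    while np.linalg.norm(v) < 1e-12:  # pragma: no cover - probability ~0
        v = rng.normal(size=3)
    v = v / np.linalg.norm(v)
    return SymmetryAxis(direction=v, fold=1, origin=np.asarray(center, dtype=float))


def read_axes_file(path: str | Path) -> list[SymmetryAxis]:
    """Read symmetry axes from a tabulated file with header pdb_long, fold, x, y, z.

    Comma- or whitespace-separated. Direction vectors must be unit length
    within 1e-3 (they are renormalized); larger deviations are rejected.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python", skipinitialspace=True)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot read axes file {path}: {exc}") from exc
    required = {"pdb_long", "fold", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"axes file {path} lacks columns: {sorted(missing)}")
    axes = []
    for _, row in df.iterrows():
        v = np.array([row["x"], row["y"], row["z"]], dtype=float)
        norm = float(np.linalg.norm(v))
        if abs(norm - 1.0) >= 1e-3:
            raise FormatError(f"axes file {path}: vector {v.tolist()} is not unit length")
        fold = int(row["fold"])
        if fold < 1:
            raise FormatError(f"axes file {path}: fold {fold} < 1")
        axes.append(SymmetryAxis(direction=v / norm, fold=fold))
    return axes


def solution_from_axes(axes: list[SymmetryAxis], assembly: Assembly) -> SymmetrySolution:
    """Wrap externally supplied axes into a SymmetrySolution for the assembly.

    The group label is inferred from the axis folds: a single axis gives Cn
    (or C1 for a fold-1 control axis); multiple axes give Dn with n the
    highest fold.
    """
    if not axes:
        raise InputError("no axes supplied")
    center = assembly.ca_centroid()
    axes = [SymmetryAxis(a.direction, a.fold, center) for a in axes]
    if len(axes) == 1:
        fold = axes[0].fold
        label = "C1" if fold == 1 else f"C{fold}"
    else:
        n = max(a.fold for a in axes)
        label = f"D{n}"
    return SymmetrySolution(group_label=label, axes=axes, center=center, rmsd=float("nan"))


# ---------------------------------------------------------------------------
# detection


def _chain_ca(chain: Chain) -> tuple[list[str], dict[str, np.ndarray], list[str]]:
    keys, coords, letters = [], {}, []
    for res in chain:
        if res.eligible:
            k = f"{res.number}{res.icode}"
            keys.append(k)
            coords[k] = res.ca.coord
            letters.append(res.letter)
    return keys, coords, letters


def _paired_coords(chain_a: Chain, chain_b: Chain) -> tuple[np.ndarray, np.ndarray]:
    """Cα coordinate pairing between two homomer chains by residue number."""
    keys_a, coords_a, _ = _chain_ca(chain_a)
    keys_b, coords_b, _ = _chain_ca(chain_b)
    if len(keys_a) == len(keys_b):
        shared = keys_a if keys_a == keys_b else [k for k in keys_a if k in coords_b]
    else:
        shared = [k for k in keys_a if k in coords_b]
    if len(shared) < 3:
        raise HeteromerError(
            f"chains {chain_a.chain_id} and {chain_b.chain_id} share fewer than 3 residues"
        )
    a = np.array([coords_a[k] for k in shared])
    b = np.array([coords_b[k] for k in shared])
    return a, b


def _check_homomer(assembly: Assembly) -> None:
    ref = None
    for chain in assembly.chains:
        _, coords, letters = _chain_ca(chain)
        seq = "".join(letters)
        if ref is None:
            ref = seq
        elif seq != ref and not (seq in ref or ref in seq):
            raise HeteromerError(
                f"chain {chain.chain_id} sequence differs from the first chain; "
                "point-group detection requires a homomer"
            )


def _cluster_axes(
    entries: list[tuple[np.ndarray, float, float]], angle_tol: float
) -> list[dict]:
    """Greedy clustering of canonical axis directions within ``angle_tol``."""
    clusters: list[dict] = []
    for axis, angle, rmsd in entries:
        for cl in clusters:
            if float(np.dot(axis, cl["direction"])) >= math.cos(angle_tol):
                cl["members"].append((axis, angle, rmsd))
                stack = np.array([m[0] for m in cl["members"]])
                mean = stack.mean(axis=0)
                cl["direction"] = mean / np.linalg.norm(mean)
                break
        else:
            clusters.append({"direction": axis.copy(), "members": [(axis, angle, rmsd)]})
    return clusters


def _angles_match_fold(angles: list[float], n: int, tol: float) -> bool:
    """Observed rotation magnitudes must be multiples of 2π/n (folded into (0, π])."""
    expected = sorted(
        min(2 * math.pi * k / n, 2 * math.pi - 2 * math.pi * k / n) for k in range(1, n)
    )
    if len(angles) != len(expected):
        return False
    return all(abs(a - e) <= tol for a, e in zip(sorted(angles), expected))


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    return Rotation.from_rotvec(axis * angle).as_matrix()


def _closure_rmsd(assembly: Assembly, axes: list[SymmetryAxis], center: np.ndarray) -> float:
    """Worst per-chain RMSD when mapping each rotated chain onto its best match."""
    chain_data = []
    for chain in assembly.chains:
        keys, coords, _ = _chain_ca(chain)
        chain_data.append((set(keys), keys, coords))
    worst = 0.0
    for axis in axes:
        R = _rotation_about(axis.direction, 2 * math.pi / axis.fold)
        for keyset, keys, coords in chain_data:
            pts = np.array([coords[k] for k in keys])
            moved = (pts - center) @ R.T + center
            best = math.inf
            for other_set, other_keys, other_coords in chain_data:
                shared = [k for k in keys if k in other_coords]
                if len(shared) < 3 or len(shared) < 0.5 * len(keys):
                    continue
                idx = {k: i for i, k in enumerate(keys)}
                m = moved[[idx[k] for k in shared]]
                o = np.array([other_coords[k] for k in shared])
                best = min(best, float(np.sqrt(np.mean(np.sum((m - o) ** 2, axis=1)))))
            worst = max(worst, best)
    return worst


def detect_point_group(
    assembly: Assembly,
    rmsd_tol: float = RMSD_TOL,
    angle_tol: float = ANGLE_TOL,
) -> SymmetrySolution:
    """Determine the Cn/Dn point group and symmetry axes of a homomer.

    Parameters
    ----------
    assembly : parsed biological assembly whose chains are sequence-identical.
    rmsd_tol : maximum per-chain RMSD (Å) allowed when verifying group closure.
    angle_tol : angular tolerance (radians) for clustering axis directions and
        matching rotation angles to multiples of 2π/n.

    Returns
    -------
    SymmetrySolution with the group label (C1, Cn or Dn), one axis per group
    generator direction (Cn: one fold-n axis; Dn, n>2: one fold-n axis plus n
    fold-2 axes; D2: three orthogonal fold-2 axes), the Cα centroid as center,
    and the worst closure RMSD as fit quality.
    """
    m = len(assembly.chains)
    center = assembly.ca_centroid()
    if m == 1:
        return SymmetrySolution("C1", [], center, 0.0)
    _check_homomer(assembly)

    entries = []
    ref = assembly.chains[0]
    for chain in assembly.chains[1:]:
        a, b = _paired_coords(ref, chain)
        R, _, rmsd = kabsch_superpose(a, b)
        try:
            axis, angle = rotation_axis_angle(R)
        except DegenerateGeometryError as exc:
            raise AsymmetricStructureError(
                f"chains {ref.chain_id} and {chain.chain_id} superpose without rotation "
                "(superposed chains?)"
            ) from exc
        entries.append((axis, angle, rmsd))

    clusters = _cluster_axes(entries, angle_tol)

    if len(clusters) == 1:
        # cyclic: a single axis must explain all chains with angles 2πk/m
        cl = clusters[0]
        angles = [mem[1] for mem in cl["members"]]
        if not _angles_match_fold(angles, m, angle_tol):
            raise AsymmetricStructureError(
                f"single rotation axis but angles {np.round(angles, 3).tolist()} "
                f"do not match a {m}-fold cyclic group"
            )
        axes = [SymmetryAxis(cl["direction"], m, center)]
        label = f"C{m}"
    else:
        if m % 2 != 0:
            raise AsymmetricStructureError(
                f"{len(clusters)} axis directions for {m} chains: no consistent group"
            )
        n = m // 2
        if n == 2:
            axes, label = _resolve_d2(clusters, center, angle_tol)
        else:
            axes, label = _resolve_dn(clusters, n, center, angle_tol)

    closure = _closure_rmsd(assembly, axes, center)
    if closure > rmsd_tol:
        raise AsymmetricStructureError(
            f"group {label} fails closure: worst chain RMSD {closure:.2f} Å > {rmsd_tol} Å"
        )
    return SymmetrySolution(label, axes, center, closure)


def _resolve_d2(clusters: list[dict], center: np.ndarray, angle_tol: float):
    if len(clusters) != 3:
        raise AsymmetricStructureError(
            f"expected 3 two-fold axes for D2, found {len(clusters)} axis directions"
        )
    dirs = [cl["direction"] for cl in clusters]
    for cl in clusters:
        for _, angle, _ in cl["members"]:
            if abs(angle - math.pi) > angle_tol:
                raise AsymmetricStructureError("D2 candidate has a non-180° rotation")
    for i in range(3):
        for j in range(i + 1, 3):
            if abs(np.dot(dirs[i], dirs[j])) > math.sin(angle_tol):
                raise AsymmetricStructureError("D2 two-fold axes are not mutually orthogonal")
    return [SymmetryAxis(d, 2, center) for d in dirs], "D2"


def _resolve_dn(clusters: list[dict], n: int, center: np.ndarray, angle_tol: float):
    main = None
    for cl in clusters:
        if len(cl["members"]) == n - 1:
            angles = [mem[1] for mem in cl["members"]]
            if _angles_match_fold(angles, n, angle_tol):
                main = cl
                break
    if main is None:
        raise AsymmetricStructureError(f"no candidate {n}-fold main axis found")
    twofolds = [cl for cl in clusters if cl is not main]
    if len(twofolds) != n:
        raise AsymmetricStructureError(
            f"expected {n} two-fold axes perpendicular to the {n}-fold axis, "
            f"found {len(twofolds)}"
        )
    for cl in twofolds:
        for _, angle, _ in cl["members"]:
            if abs(angle - math.pi) > angle_tol:
                raise AsymmetricStructureError("candidate two-fold axis with a non-180° rotation")
        if abs(float(np.dot(cl["direction"], main["direction"]))) > math.sin(angle_tol):
            raise AsymmetricStructureError("two-fold axis not perpendicular to the main axis")
    axes = [SymmetryAxis(main["direction"], n, center)]
    axes += [SymmetryAxis(cl["direction"], 2, center) for cl in twofolds]
    return axes, f"D{n}"
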