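"""Solvent-accessible surface area (Shrake–Rupley) and relative ASA.

Per-atom ASA is estimated by quadrature: each atom is expanded by the probe
radius, a deterministic golden-spiral lattice of points is placed on the
expanded sphere, and the accessible fraction is the share of points not
buried inside any neighboring expanded sphere.

The quadrature lattice is oriented in a local frame derived from the chain's
own atoms, so the point set rotates rigidly with the molecule. Consequences:

* ASA values are exactly invariant under rigid motion of the structure;
* computing a chain alone and within the assembly uses the same oriented
  point set, so adding context can only remove accessible points — per-atom
  ASA is exactly monotone under added chains.

Relative ASA (rASA, percent) divides a residue's summed atom ASA by a
residue-type reference maximum (theoretical Gly-X-Gly values) and clamps the
result into [0, 100]: raw values above 100, which occur for distorted or
terminal residues, are corrected to 100.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import InputError
from .structure_io import Assembly, Atom, Residue

__all__ = [
    "SasaConfig",
    "SasaRecord",
    "golden_spiral_points",
    "shrake_rupley",
    "relative_asa",
    "complexed_and_unbound",
]

_HYDROGENS = {"H", "D"}


def _load_defaults() -> dict:
    with resources.files("symsurf.data").joinpath("sasa_defaults.json").open() as fh:
        return json.load(fh)


@dataclass
class SasaConfig:
    """Quadrature and normalization parameters for SASA.

    probe_radius : solvent probe radius, Å (water: 1.4).
    sphere_points : quadrature points per atom (≥ 100; error ~1/n).
    radius_set : element symbol → van-der-Waals radius (Å).
    max_asa_table : 3-letter residue code → reference maximal ASA (Ų).
    """

    probe_radius: float = 1.4
    sphere_points: int = 960
    radius_set: dict[str, float] = field(default_factory=dict)
    max_asa_table: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        defaults = _load_defaults()
        if not self.radius_set:
            self.radius_set = dict(defaults["radius_set"])
        if not self.max_asa_table:
            self.max_asa_table = dict(defaults["max_asa_table"])
        if self.probe_radius <= 0:
            raise InputError("probe_radius must be > 0")
        if self.sphere_points < 100:
            raise InputError("sphere_points must be ≥ 100")
        if any(r <= 0 for r in self.radius_set.values()):
            raise InputError("all van-der-Waals radii must be > 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "SasaConfig":
        """Load a JSON config with any of probe_radius, sphere_points, radius_set, max_asa_table."""
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            probe_radius=data.get("probe_radius", 1.4),
            sphere_points=data.get("sphere_points", 960),
            radius_set=dict(data.get("radius_set", {})),
            max_asa_table=dict(data.get("max_asa_table", {})),
        )

    def radius(self, element: str) -> float:
        key = element.upper()
        if key not in self.radius_set:
            raise InputError(f"no van-der-Waals radius for element {element!r}")
        return self.radius_set[key]


@dataclass
class SasaRecord:
    """Per-residue relative ASA in the complexed (rASAc) and unbound (rASAu) states, percent."""

    residue_key: tuple[str, str]
    rASA_in_BU: float | None
    rASA_alone: float | None

    @property
    def delta(self) -> float | None:
        """ΔrASA = rASAu − rASAc; surface area buried on complexation (≥ 0)."""
        if self.rASA_in_BU is None or self.rASA_alone is None:
            return None
        return self.rASA_alone - self.rASA_in_BU


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic near-uniform lattice of n unit vectors (golden-angle spiral)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = i * math.pi * (3.0 - math.sqrt(5.0))
    rho = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def local_frame(coords: np.ndarray) -> np.ndarray:
    """Orthonormal frame built from the first non-collinear atom triple.

    Rotating the coordinates rotates the frame identically, which is what
    makes the quadrature rigid-motion invariant. Degenerate inputs (< 3
    atoms, collinear) fall back to the identity frame.
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        return np.eye(3)
    v1 = None
    for p in coords[1:]:
        d = p - coords[0]
        if np.linalg.norm(d) > 1e-6:
            v1 = d / np.linalg.norm(d)
            break
    if v1 is None:
        return np.eye(3)
    for p in coords[1:]:
        d = p - coords[0]
        perp = d - np.dot(d, v1) * v1
        if np.linalg.norm(perp) > 1e-6:
            e2 = perp / np.linalg.norm(perp)
            return np.column_stack([v1, e2, np.cross(v1, e2)])
    return np.eye(3)


def _heavy(atoms: list[Atom]) -> list[Atom]:
    return [a for a in atoms if a.element.upper() not in _HYDROGENS]


def _per_atom_asa(
    coords: np.ndarray,
    radii: np.ndarray,
    config: SasaConfig,
    point_sets: list[np.ndarray],
) -> np.ndarray:
    """Core quadrature: accessible area per atom given pre-oriented unit point sets."""
    n = len(coords)
    probe = config.probe_radius
    expanded = radii + probe
    tree = cKDTree(coords)
    out = np.empty(n)
    max_exp = float(expanded.max())
    for i in range(n):
        pts = coords[i] + expanded[i] * point_sets[i]
        neigh = [j for j in tree.query_ball_point(coords[i], expanded[i] + max_exp) if j != i]
        if neigh:
            nc = coords[neigh]
            nr = expanded[neigh]
            d2 = np.sum((pts[:, None, :] - nc[None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < (nr**2)[None, :] - 1e-12, axis=1)
            acc = int(np.count_nonzero(~buried))
        else:
            acc = len(pts)
        out[i] = 4.0 * math.pi * expanded[i] ** 2 * acc / config.sphere_points
    return out


def shrake_rupley(
    atoms: list[Atom],
    config: SasaConfig | None = None,
    frame: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Ų), aligned with the input list.

    Hydrogens are ignored: they receive 0 Ų and do not occlude neighbors.
    ``frame`` optionally fixes the quadrature orientation; by default it is
    derived from the heavy-atom coordinates themselves.
    """
    config = config or SasaConfig()
    if not atoms:
        raise InputError("shrake_rupley requires at least one atom")
    heavy_idx = [i for i, a in enumerate(atoms) if a.element.upper() not in _HYDROGENS]
    if not heavy_idx:
        return np.zeros(len(atoms))
    coords = np.array([atoms[i].coord for i in heavy_idx], dtype=float)
    radii = np.array([config.radius(atoms[i].element) for i in heavy_idx], dtype=float)
    if frame is None:
        frame = local_frame(coords)
    unit = golden_spiral_points(config.sphere_points) @ frame.T
    asa = _per_atom_asa(coords, radii, config, [unit] * len(coords))
    out = np.zeros(len(atoms))
    out[heavy_idx] = asa
    return out


def relative_asa(
    atom_asa: np.ndarray, residue: Residue, max_asa_table: dict[str, float]
) -> float | None:
    """Residue rASA percent: 100 × (summed atom ASA) / reference max, clamped to [0, 100].

    Returns None when the residue type has no reference value (nonstandard
    residues carry no rASA).
    """
    ref = max_asa_table.get(residue.name3)
    if ref is None or ref <= 0:
        return None
    value = 100.0 * float(np.sum(atom_asa)) / ref
    return min(max(value, 0.0), 100.0)


def complexed_and_unbound(assembly: Assembly, config: SasaConfig | None = None) -> list[SasaRecord]:
    """Per-residue rASA in the complexed (whole assembly) and unbound (isolated chain) states.

    The same chain-local quadrature orientation is used in both states, so
    rASA_alone ≥ rASA_in_BU holds exactly per residue (before clamping both
    are computed from the identical point sets).
    """
    config = config or SasaConfig()
    # flatten heavy atoms, remembering chain and residue of each
    chain_frames: dict[str, np.ndarray] = {}
    entries: list[tuple[str, Residue, Atom]] = []
    for chain in assembly.chains:
        heavy_coords = np.array(
            [a.coord for r in chain for a in _heavy(r.atoms)], dtype=float
        )
        if heavy_coords.size == 0:
            continue
        chain_frames[chain.chain_id] = local_frame(heavy_coords)
        for res in chain:
            for atom in _heavy(res.atoms):
                entries.append((chain.chain_id, res, atom))
    if not entries:
        raise InputError("assembly has no heavy atoms")

    coords = np.array([e[2].coord for e in entries], dtype=float)
    radii = np.array([config.radius(e[2].element) for e in entries], dtype=float)
    unit = golden_spiral_points(config.sphere_points)
    point_sets = [unit @ chain_frames[e[0]].T for e in entries]

    asa_complex = _per_atom_asa(coords, radii, config, point_sets)

    asa_alone = np.empty_like(asa_complex)
    chain_ids = np.array([e[0] for e in entries])
    for cid in chain_frames:
        mask = chain_ids == cid
        idx = np.nonzero(mask)[0]
        asa_alone[idx] = _per_atom_asa(
            coords[idx], radii[idx], config, [point_sets[i] for i in idx]
        )

    records = []
    seen: dict[tuple[str, str], list[int]] = {}
    order: list[tuple[tuple[str, str], Residue]] = []
    for i, (_, res, _) in enumerate(entries):
        if res.key not in seen:
            seen[res.key] = []
            order.append((res.key, res))
        seen[res.key].append(i)
    for key, res in order:
        idx = seen[key]
        records.append(
            SasaRecord(
                residue_key=key,
                rASA_in_BU=relative_asa(asa_complex[idx], res, config.max_asa_table),
                rASA_alone=relative_asa(asa_alone[idx], res, config.max_asa_table),
            )
        )
    return records
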