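"""Seeded synthetic homomers with known symmetry ground truth.

Real biological assemblies require downloads and carry approximate symmetry;
these builders construct exact Cn and Dn homomers (plus monomer controls) by
rigid-body symmetry operations on a deterministic pseudo-random backbone
chain, so every descriptor module can be exercised against construction
ground truth: the axes, folds and group label are known by design.

Chains are Cα + N + C + O backbone traces with consecutive Cα–Cα distances
of 3.8 ± 0.1 Å and mild self-avoidance — enough geometry for SASA, patch and
bounding-plane computations without pretending to be physically folded
proteins. Residue types are drawn uniformly from the 20 standard amino
acids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import InputError
from .structure_io import AA1TO3, Assembly, Atom, Chain, Residue
from .symmetry import SymmetryAxis, SymmetrySolution, random_unit_axis

__all__ = [
    "BuildSpec",
    "make_chain",
    "make_cyclic",
    "make_dihedral",
    "make_monomer_control",
    "transform_assembly",
    "random_rigid_transform",
]

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_LETTERS = sorted(AA1TO3)


@dataclass
class BuildSpec:
    """Construction parameters for a synthetic homomer.

    group_label : "C1", "Cn" or "Dn" (informational; the make_* entry point
        chooses the topology).
    n : fold of the main axis (number of chains = n for cyclic, 2n for
        dihedral).
    chain_size : residues per chain.
    radial_offset : distance (Å) of each chain centroid from the main axis;
        must be positive for n ≥ 2 so chains are not superposed.
    axial_spread : separation (Å) between the two rings of a dihedral
        assembly along the main axis.
    seed : seed for the chain builder and any random placement.
    """

    group_label: str = "Cn"
    n: int = 3
    chain_size: int = 40
    radial_offset: float = 18.0
    axial_spread: float = 14.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InputError("fold n must be ≥ 1")
        if self.n >= 2 and self.radial_offset <= 0:
            raise InputError(
                "radial_offset must be > 0 for oligomers: chains must not be superposed"
            )


def make_chain(spec: BuildSpec, chain_id: str = "A") -> Chain:
    """Deterministic pseudo-random compact backbone chain (Cα + N + C + O)."""
    if spec.chain_size < 3:
        raise InputError("chain_size must be ≥ 3")
    rng = np.random.default_rng(spec.seed)
    step = 3.8
    ca = [np.zeros(3)]
    direction = _random_unit(rng)
    for _ in range(spec.chain_size - 1):
        for _attempt in range(40):
            # bounded turning keeps the trace compact but locally chain-like
            perturb = _random_unit(rng)
            new_dir = direction + 0.9 * perturb
            new_dir /= np.linalg.norm(new_dir)
            length = step + rng.uniform(-0.1, 0.1)
            candidate = ca[-1] + length * new_dir
            clashes = [
                p for p in ca[:-1] if np.linalg.norm(candidate - p) < 3.5
            ]
            if not clashes:
                break
        ca.append(candidate)
        direction = new_dir

    chain = Chain(chain_id=chain_id)
    letters = rng.choice(_LETTERS, size=spec.chain_size)
    for i, pos in enumerate(ca):
        prev_dir = _unit(ca[1] - ca[0]) if i == 0 else _unit(pos - ca[i - 1])
        perp = _any_perpendicular(prev_dir)
        name3 = AA1TO3[str(letters[i])]
        res = Residue(chain_id=chain_id, number=i + 1, icode="", name3=name3)
        res.atoms = [
            Atom("N", "N", pos - 1.46 * prev_dir + 0.4 * perp),
            Atom("CA", "C", pos.copy()),
            Atom("C", "C", pos + 1.52 * prev_dir + 0.4 * perp),
            Atom("O", "O", pos + 1.52 * prev_dir + 1.6 * perp),
        ]
        chain.residues.append(res)
    return chain


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(v, ref)
    return p / np.linalg.norm(p)


def _centered_copy(chain: Chain) -> Chain:
    centroid = np.mean([r.ca.coord for r in chain if r.ca is not None], axis=0)
    return _transform_chain(chain, np.eye(3), -centroid, chain.chain_id)


def _transform_chain(chain: Chain, R: np.ndarray, t: np.ndarray, new_id: str) -> Chain:
    out = Chain(chain_id=new_id)
    for res in chain:
        new_res = Residue(
            chain_id=new_id, number=res.number, icode=res.icode, name3=res.name3,
            hetero=res.hetero,
        )
        new_res.atoms = [
            Atom(a.name, a.element, R @ a.coord + t, a.occupancy, a.altloc, a.bfactor)
            for a in res.atoms
        ]
        out.residues.append(new_res)
    return out


def _rot_z(angle: float) -> np.ndarray:
    return Rotation.from_rotvec([0.0, 0.0, angle]).as_matrix()


def make_cyclic(spec: BuildSpec) -> tuple[Assembly, SymmetrySolution]:
    """Cn homomer: n chain copies rotated by 2πk/n about z, centroids off-axis.

    Returns the assembly and the construction ground truth (group Cn, one
    fold-n axis along z through the origin).
    """
    if spec.n < 2:
        raise InputError("make_cyclic requires n ≥ 2")
    base = _centered_copy(make_chain(spec))
    base = _transform_chain(base, np.eye(3), np.array([spec.radial_offset, 0.0, 0.0]), "A")
    chains = []
    for k in range(spec.n):
        R = _rot_z(2.0 * math.pi * k / spec.n)
        chains.append(_transform_chain(base, R, np.zeros(3), _CHAIN_IDS[k]))
    assembly = Assembly(pdb_long=f"synthC{spec.n}_{spec.seed}", chains=chains)
    truth = SymmetrySolution(
        group_label=f"C{spec.n}",
        axes=[SymmetryAxis(np.array([0.0, 0.0, 1.0]), spec.n, np.zeros(3))],
        center=assembly.ca_centroid(),
    )
    return assembly, truth


def make_dihedral(spec: BuildSpec) -> tuple[Assembly, SymmetrySolution]:
    """Dn homomer: a Cn ring plus its image under a 180° rotation about x.

    The two rings sit at ±axial_spread/2 along z. Ground truth: for n > 2,
    one fold-n axis along z and n fold-2 axes in the xy-plane at angles
    πk/n; for n = 2, three mutually orthogonal fold-2 axes (z, x, y).
    """
    if spec.n < 2:
        raise InputError("make_dihedral requires n ≥ 2")
    base = _centered_copy(make_chain(spec))
    shift = np.array([spec.radial_offset, 0.0, spec.axial_spread / 2.0])
    base = _transform_chain(base, np.eye(3), shift, "A")
    chains = []
    for k in range(spec.n):
        R = _rot_z(2.0 * math.pi * k / spec.n)
        chains.append(_transform_chain(base, R, np.zeros(3), _CHAIN_IDS[k]))
    flip = Rotation.from_rotvec([math.pi, 0.0, 0.0]).as_matrix()
    for k in range(spec.n):
        chains.append(
            _transform_chain(chains[k], flip, np.zeros(3), _CHAIN_IDS[spec.n + k])
        )
    assembly = Assembly(pdb_long=f"synthD{spec.n}_{spec.seed}", chains=chains)
    z = np.array([0.0, 0.0, 1.0])
    if spec.n == 2:
        axes = [
            SymmetryAxis(z, 2, np.zeros(3)),
            SymmetryAxis(np.array([1.0, 0.0, 0.0]), 2, np.zeros(3)),
            SymmetryAxis(np.array([0.0, 1.0, 0.0]), 2, np.zeros(3)),
        ]
    else:
        axes = [SymmetryAxis(z, spec.n, np.zeros(3))]
        for k in range(spec.n):
            angle = math.pi * k / spec.n
            axes.append(
                SymmetryAxis(np.array([math.cos(angle), math.sin(angle), 0.0]), 2, np.zeros(3))
            )
    truth = SymmetrySolution(
        group_label=f"D{spec.n}", axes=axes, center=assembly.ca_centroid()
    )
    return assembly, truth


def make_monomer_control(spec: BuildSpec) -> tuple[Assembly, SymmetryAxis]:
    """Monomer plus a seeded random fold-1 axis through its Cα centroid.

    This is the negative control: hypothetical bounding-plane descriptors
    computed on an asymmetric structure along a single random axis.
    """
    chain = make_chain(spec)
    assembly = Assembly(pdb_long=f"synthC1_{spec.seed}", chains=[chain])
    axis = random_unit_axis(spec.seed, assembly.ca_centroid())
    return assembly, axis


def transform_assembly(assembly: Assembly, R: np.ndarray, t: np.ndarray) -> Assembly:
    """Rigidly transformed copy of an assembly (same chain ids and numbering)."""
    chains = [_transform_chain(ch, R, t, ch.chain_id) for ch in assembly.chains]
    return Assembly(pdb_long=assembly.pdb_long, chains=chains)


def random_rigid_transform(seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded uniformly random rotation and a translation in [-50, 50]³ Å."""
    rng = np.random.default_rng(seed)
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-50.0, 50.0, size=3)
    return R, t
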