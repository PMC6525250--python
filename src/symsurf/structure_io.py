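"""Read and write PDB-format biological assemblies.

The internal model is a light chain → residue → atom hierarchy carrying the
coordinates, occupancies and B-factors needed by the descriptor modules.
Parsing and serialization are delegated to gemmi; this module fixes the
conventions the descriptors rely on: first model only (with model-expanded
symmetry copies promoted to chains), waters dropped, highest-occupancy
alternate conformers kept, and author residue numbering preserved verbatim.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .errors import EmptyStructureError, FormatError, InputError

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Assembly",
    "read_assembly",
    "write_assembly",
    "write_value_projection",
    "AA3TO1",
    "AA1TO3",
]

#: 3-letter → 1-letter codes for the 20 standard amino acids.
AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1TO3 = {v: k for k, v in AA3TO1.items()}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass
class Atom:
    """One atom: name, element symbol, coordinates (Å), occupancy, altloc, B-factor."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise InputError(f"atom {self.name!r}: coordinates must be 3 finite values")


@dataclass
class Residue:
    """One residue with author numbering preserved (number + insertion code)."""

    chain_id: str
    number: int
    icode: str
    name3: str
    atoms: list[Atom] = field(default_factory=list)
    hetero: bool = False

    @property
    def letter(self) -> str:
        """1-letter code; 'X' for nonstandard residues."""
        return AA3TO1.get(self.name3, "X")

    @property
    def ca(self) -> Atom | None:
        for atom in self.atoms:
            # name CA with element CA is a calcium ion, not an alpha carbon
            if atom.name == "CA" and atom.element.upper() != "CA":
                return atom
        return None

    @property
    def key(self) -> tuple[str, str]:
        """(chain id, author number + insertion code) — the residue identifier used everywhere."""
        return (self.chain_id, f"{self.number}{self.icode}".strip())

    @property
    def eligible(self) -> bool:
        """True if the residue enters geometric descriptors (has a Cα, not a hetero group)."""
        return self.ca is not None and not self.hetero


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self):
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Assembly:
    """A biological assembly: ordered chains of ordered residues."""

    pdb_long: str
    chains: list[Chain] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.chains:
            raise EmptyStructureError(f"{self.pdb_long}: assembly has no chains")

    def residues(self):
        for chain in self.chains:
            yield from chain.residues

    def eligible_residues(self) -> list[Residue]:
        return [r for r in self.residues() if r.eligible]

    def ca_coords(self) -> np.ndarray:
        """(N, 3) Cα coordinates over eligible residues."""
        return np.array([r.ca.coord for r in self.eligible_residues()], dtype=float)

    def ca_centroid(self) -> np.ndarray:
        coords = self.ca_coords()
        if coords.size == 0:
            raise InputError(f"{self.pdb_long}: no Cα atoms")
        return coords.mean(axis=0)


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties resolve to the first conformer in the file
    best = atoms[0]
    for a in atoms[1:]:
        if a.occ > best.occ:
            best = a
    return best


def _convert_residue(chain_id: str, res: gemmi.Residue) -> Residue:
    by_name: dict[str, list[gemmi.Atom]] = {}
    for atom in res:
        by_name.setdefault(atom.name, []).append(atom)
    out = Residue(
        chain_id=chain_id,
        number=res.seqid.num,
        icode=(res.seqid.icode or "").strip(),
        name3=res.name.strip(),
        hetero=(res.het_flag == "H"),
    )
    for name, group in by_name.items():
        a = _pick_altloc(group)
        out.atoms.append(
            Atom(
                name=name,
                element=a.element.name,
                coord=np.array([a.pos.x, a.pos.y, a.pos.z]),
                occupancy=a.occ,
                altloc=(a.altloc or "").strip(),
                bfactor=a.b_iso,
            )
        )
    return out


def _next_chain_ids():
    for c in string.ascii_uppercase + string.ascii_lowercase + string.digits:
        yield c
    i = 0
    while True:
        yield f"x{i}"
        i += 1


def read_assembly(path: str | Path, keep_hetero: bool = False) -> Assembly:
    """Read a PDB-format biological assembly.

    Waters are always dropped; other HETATM groups are dropped unless
    ``keep_hetero``. For alternate locations the highest-occupancy conformer is
    kept (ties → first in file). When a multi-model file repeats chain
    identifiers across models — the PDB's way of encoding symmetry copies —
    every model is kept and chains are reassigned fresh identifiers; otherwise
    only the first model is read.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (OSError, RuntimeError, ValueError) as exc:
        raise InputError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models / no ATOM records")

    models = [st[0]]
    if len(st) > 1:
        first_ids = {ch.name for ch in st[0]}
        if any(ch.name in first_ids for m in list(st)[1:] for ch in m):
            models = list(st)

    reassign = len(models) > 1
    id_gen = _next_chain_ids()
    chains: list[Chain] = []
    for model in models:
        for gchain in model:
            cid = next(id_gen) if reassign else gchain.name
            chain = Chain(chain_id=cid)
            for gres in gchain:
                name = gres.name.strip()
                if name in _WATER_NAMES:
                    continue
                if gres.het_flag == "H" and not keep_hetero:
                    continue
                chain.residues.append(_convert_residue(cid, gres))
            if chain.residues:
                chains.append(chain)

    if not chains or not any(res.atoms for ch in chains for res in ch):
        raise EmptyStructureError(f"{path}: no ATOM records after filtering")

    assembly = Assembly(pdb_long=path.stem, chains=chains)
    _warn_if_ca_only(assembly)
    return assembly


def _warn_if_ca_only(assembly: Assembly) -> None:
    for chain in assembly.chains:
        atom_names = {a.name for r in chain for a in r.atoms}
        if atom_names == {"CA"}:
            warnings.warn(
                f"chain {chain.chain_id} of {assembly.pdb_long} contains only Cα atoms "
                "(backbone trace); SASA-based descriptors will be unreliable",
                stacklevel=3,
            )


def _to_gemmi(assembly: Assembly, bvalues: dict[tuple[str, str], float] | None = None,
              missing_sentinel: float = 0.0) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = assembly.pdb_long
    model = gemmi.Model(1)
    for chain in assembly.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name3
            gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
            gres.het_flag = "H" if res.hetero else "A"
            if bvalues is None:
                bset = None
            else:
                bset = bvalues.get(res.key, missing_sentinel)
                formatted = f"{bset:6.2f}"
                if len(formatted) > 6:
                    raise FormatError(
                        f"value {bset!r} for residue {res.key} does not fit the "
                        "fixed-width B-factor column"
                    )
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coord)
                ga.occ = atom.occupancy
                ga.b_iso = atom.bfactor if bset is None else bset
                if atom.altloc:
                    ga.altloc = atom.altloc
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_assembly(assembly: Assembly, path: str | Path) -> None:
    """Write the assembly as a PDB file, preserving stored B-factors."""
    _to_gemmi(assembly).write_pdb(str(path))


def write_value_projection(
    assembly: Assembly,
    values: dict[tuple[str, str], float],
    path: str | Path,
    missing_sentinel: float = -99.0,
) -> None:
    """Write a PDB file with per-residue values stored in the B-factor column.

    ``values`` is keyed by residue key (chain id, number + insertion code);
    residues absent from the mapping get ``missing_sentinel``. The written
    file can be loaded in a molecular viewer and colored by B-factor to
    visualize any per-residue descriptor on the structure.
    """
    _to_gemmi(assembly, bvalues=values, missing_sentinel=missing_sentinel).write_pdb(str(path))
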