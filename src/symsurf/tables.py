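"""Descriptor table schemas, CSV writers and the chain-connectivity filter.

Three tables mirror the dataset layout the descriptors feed:

* residue table  — one row per Cα-bearing standard residue: coordinates,
  rASA in both states, stickiness values, patch size and the nDp variants;
* axes table     — one row per symmetry axis: pdb_long, fold, x, y, z;
* assembly table — one row per assembly: identifiers, symmetry label,
  subunit count, molecular weight and passthrough curation fields.

Missing values are encoded as "NA". The connectivity filter rejects
assemblies that fall apart into disconnected components once weak
chain–chain contacts (fewer than 5 contacting residue pairs) are ignored.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import FormatError
from .ndp import NdpRecord
from .sasa import SasaRecord
from .stickiness import EnvironmentStickinessRecord, StickinessScale
from .structure_io import Assembly
from .symmetry import SymmetryAxis, SymmetrySolution

__all__ = [
    "RESIDUE_COLUMNS",
    "AXES_COLUMNS",
    "ASSEMBLY_COLUMNS",
    "NA",
    "build_residue_rows",
    "build_assembly_row",
    "write_residue_table",
    "write_axes_table",
    "write_assembly_table",
    "read_table",
    "connectivity_filter",
]

NA = "NA"

RESIDUE_COLUMNS = [
    "pdb_long", "chain", "num", "name", "letter", "x", "y", "z",
    "rASA_in_BU", "rASA_alone", "sticky_scale", "sticky_patch", "patch_size",
    "nDp", "fold", "nDp_n_fold", "nDp_2_fold",
]
AXES_COLUMNS = ["pdb_long", "fold", "x", "y", "z"]
ASSEMBLY_COLUMNS = [
    "pdb_long", "pdb_short", "uniprot", "resol", "sym", "nsub", "mw",
    "PiQSi", "QSalign", "QSbio", "tv_discard", "h_80", "h_90",
]

# average residue masses (Da): amino acid minus one water
_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
_WATER_MASS = 18.0153

# fixed output precision per column family
_FORMATS = {
    "x": "{:.3f}", "y": "{:.3f}", "z": "{:.3f}",
    "rASA_in_BU": "{:.1f}", "rASA_alone": "{:.1f}",
    "sticky_scale": "{:.4f}", "sticky_patch": "{:.4f}",
    "nDp": "{:.3f}", "nDp_n_fold": "{:.3f}", "nDp_2_fold": "{:.3f}",
    "patch_size": "{:d}", "fold": "{:d}", "num": "{}",
}


def build_residue_rows(
    assembly: Assembly,
    solution: SymmetrySolution,
    ndp_records: list[NdpRecord],
    sasa_records: list[SasaRecord],
    env_records: list[EnvironmentStickinessRecord] | None = None,
    scale: StickinessScale | None = None,
) -> pd.DataFrame:
    """Assemble the per-residue descriptor table (one row per Cα-bearing standard residue).

    The fold-restricted nDp columns are populated only for high-order
    dihedral assemblies (Dn, n > 2); everywhere else they hold the missing
    marker, as does any descriptor that could not be computed for a residue.
    """
    ndp_by_key = {r.residue_key: r for r in ndp_records}
    sasa_by_key = {r.residue_key: r for r in sasa_records}
    env_by_key = {r.residue_key: r for r in env_records or []}
    dihedral = solution.is_high_order_dihedral

    rows = []
    for res in assembly.eligible_residues():
        if res.letter == "X":
            continue
        key = res.key
        ndp = ndp_by_key.get(key)
        sasa = sasa_by_key.get(key)
        env = env_by_key.get(key)
        rows.append(
            {
                "pdb_long": assembly.pdb_long,
                "chain": res.chain_id,
                "num": f"{res.number}{res.icode}",
                "name": res.name3,
                "letter": res.letter,
                "x": res.ca.coord[0],
                "y": res.ca.coord[1],
                "z": res.ca.coord[2],
                "rASA_in_BU": None if sasa is None else sasa.rASA_in_BU,
                "rASA_alone": None if sasa is None else sasa.rASA_alone,
                "sticky_scale": None if scale is None else scale[res.letter],
                "sticky_patch": None if env is None else env.sticky_patch,
                "patch_size": None if env is None else env.patch_size,
                "nDp": None if ndp is None else ndp.ndp,
                "fold": ndp.closest_axis_fold if (dihedral and ndp) else None,
                "nDp_n_fold": ndp.ndp_nfold if (dihedral and ndp) else None,
                "nDp_2_fold": ndp.ndp_2fold if (dihedral and ndp) else None,
            }
        )
    return pd.DataFrame(rows, columns=RESIDUE_COLUMNS)


def build_assembly_row(assembly: Assembly, solution: SymmetrySolution) -> dict:
    """One assembly-descriptor row; curation fields are passthrough and left missing."""
    mass = sum(
        _RESIDUE_MASS.get(res.letter, 0.0)
        for res in assembly.residues()
        if not res.hetero
    ) + _WATER_MASS * len(assembly.chains)
    return {
        "pdb_long": assembly.pdb_long,
        "pdb_short": assembly.pdb_long.split("_")[0][:4],
        "uniprot": None,
        "resol": None,
        "sym": solution.group_label,
        "nsub": len(assembly.chains),
        "mw": round(mass, 1),
        "PiQSi": None,
        "QSalign": None,
        "QSbio": None,
        "tv_discard": None,
        "h_80": None,
        "h_90": None,
    }


def _format_value(column: str, value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return NA
    fmt = _FORMATS.get(column)
    if fmt is None:
        return str(value)
    if fmt == "{:d}":
        return fmt.format(int(value))
    return fmt.format(value)


def _write(df: pd.DataFrame, columns: list[str], path: str | Path) -> None:
    extra = [c for c in df.columns if c not in columns]
    missing = [c for c in columns if c not in df.columns]
    if extra or missing:
        bad = (extra + missing)[0]
        raise FormatError(f"table does not match schema: column {bad!r}")
    out = pd.DataFrame(
        {c: [_format_value(c, v) for v in df[c]] for c in columns}, columns=columns
    )
    out.to_csv(path, index=False)


def write_residue_table(df: pd.DataFrame, path: str | Path) -> None:
    _write(df, RESIDUE_COLUMNS, path)


def write_axes_table(
    axes: list[SymmetryAxis], pdb_long: str, path: str | Path
) -> None:
    df = pd.DataFrame(
        [
            {
                "pdb_long": pdb_long,
                "fold": a.fold,
                "x": f"{a.direction[0]:.6f}",
                "y": f"{a.direction[1]:.6f}",
                "z": f"{a.direction[2]:.6f}",
            }
            for a in axes
        ],
        columns=AXES_COLUMNS,
    )
    df.to_csv(path, index=False)


def write_assembly_table(rows: list[dict], path: str | Path) -> None:
    df = pd.DataFrame(rows, columns=ASSEMBLY_COLUMNS) if rows else pd.DataFrame(
        columns=ASSEMBLY_COLUMNS
    )
    _write(df, ASSEMBLY_COLUMNS, path)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a written table with "NA" as the missing marker."""
    return pd.read_csv(path, na_values=[NA], keep_default_na=False)


def connectivity_filter(
    assembly: Assembly,
    min_mean_contacts: int = 5,
    contact_distance: float = 5.0,
) -> tuple[bool, list[list[str]]]:
    """Accept the assembly iff its chain-contact graph is connected.

    Two chains are linked when at least ``min_mean_contacts`` residue pairs
    are in contact (any heavy-atom pair closer than ``contact_distance`` Å).
    Returns (accepted, connected components as lists of chain ids) so callers
    can report how a rejected assembly splits apart.
    """
    graph = nx.Graph()
    atom_chain, atom_res, coords = [], [], []
    for chain in assembly.chains:
        graph.add_node(chain.chain_id)
        for res in chain:
            for atom in res.atoms:
                if atom.element.upper() in ("H", "D"):
                    continue
                atom_chain.append(chain.chain_id)
                atom_res.append(res.key)
                coords.append(atom.coord)
    if len(assembly.chains) == 1:
        return True, [[assembly.chains[0].chain_id]]
    tree = cKDTree(np.asarray(coords))
    contacts: dict[tuple[str, str], set] = {}
    for i, j in tree.query_pairs(contact_distance):
        ci, cj = atom_chain[i], atom_chain[j]
        if ci == cj:
            continue
        pair = (ci, cj) if ci < cj else (cj, ci)
        rpair = (atom_res[i], atom_res[j]) if ci < cj else (atom_res[j], atom_res[i])
        contacts.setdefault(pair, set()).add(rpair)
    for (ci, cj), respairs in contacts.items():
        if len(respairs) >= min_mean_contacts:
            graph.add_edge(ci, cj)
    components = [sorted(c) for c in nx.connected_components(graph)]
    return len(components) == 1, sorted(components)
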