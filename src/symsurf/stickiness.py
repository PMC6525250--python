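"""Residue region classification, stickiness scales, environment stickiness.

Stickiness quantifies an amino acid's interaction propensity as the log-ratio
of its frequency at protein–protein interfaces relative to solvent-exposed
surfaces. The two regions are defined from relative ASA in the complexed and
unbound states (rASAc, rASAu; ΔrASA = rASAu − rASAc):

* surface:        ΔrASA = 0 and rASAc > 25%
* interface core: ΔrASA > 0 and rASAc < 25% and rASAu > 25%

The *environment stickiness* of a residue averages the scale values of the
surface residues (rASAc > 25%, no Δ condition) whose Cα lies within a 400 Ų
circular patch centered on the residue's own Cα — a maximum Cα–Cα distance
of sqrt(400/π) ≈ 11.28 Å. The central residue is excluded from the average;
buried residues (rASAc < 25%) receive no value. A low environment stickiness
marks surface regions protected against accidental self-assembly by
low-propensity neighborhoods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import FormatError, InputError
from .sasa import SasaRecord
from .structure_io import AA1TO3, Assembly

__all__ = [
    "SURFACE",
    "INTERFACE_CORE",
    "BURIED",
    "OTHER",
    "StickinessScale",
    "PatchConfig",
    "EnvironmentStickinessRecord",
    "classify_region",
    "derive_scale",
    "environment_stickiness",
]

SURFACE = "surface"
INTERFACE_CORE = "interface_core"
BURIED = "buried"
OTHER = "other"

_DELTA_TOL = 1e-6
STANDARD_LETTERS = sorted(AA1TO3)


def classify_region(rASAc: float, rASAu: float, threshold: float = 25.0) -> str:
    """Assign one of surface / interface_core / buried / other from (rASAc, rASAu).

    Comparisons against the threshold are strict, so a residue at exactly the
    threshold is neither surface nor buried; "other" collects everything
    outside the two defined classes (e.g. the interface rim).
    """
    if not (0.0 <= rASAc <= 100.0 and 0.0 <= rASAu <= 100.0):
        raise InputError(f"rASA values must lie in [0, 100], got ({rASAc}, {rASAu})")
    delta = rASAu - rASAc
    if abs(delta) <= _DELTA_TOL and rASAc > threshold:
        return SURFACE
    if delta > _DELTA_TOL and rASAc < threshold and rASAu > threshold:
        return INTERFACE_CORE
    if rASAc < threshold:
        return BURIED
    return OTHER


@dataclass
class StickinessScale:
    """Amino-acid letter → stickiness value (log frequency ratio, dimensionless)."""

    values: dict[str, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = set(STANDARD_LETTERS) - set(self.values)
        extra = set(self.values) - set(STANDARD_LETTERS)
        if missing or extra:
            raise InputError(
                f"scale must cover exactly the 20 standard amino acids "
                f"(missing {sorted(missing)}, extra {sorted(extra)})"
            )
        if not all(math.isfinite(v) for v in self.values.values()):
            raise InputError("scale values must be finite")

    def __getitem__(self, letter: str) -> float:
        return self.values[letter]

    @classmethod
    def from_file(cls, path: str | Path) -> "StickinessScale":
        """Read a two-column text file: amino-acid letter, value (one row per residue type)."""
        values: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.replace(",", " ").split()
                if len(parts) != 2:
                    raise FormatError(f"scale file {path}: bad line {line!r}")
                values[parts[0].upper()] = float(parts[1])
        return cls(values=values, provenance=str(path))

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for letter in STANDARD_LETTERS:
                fh.write(f"{letter} {self.values[letter]:.6f}\n")


def derive_scale(
    surface_counts: dict[str, float],
    interface_counts: dict[str, float],
    log_base: float = math.e,
) -> StickinessScale:
    """Stickiness scale from amino-acid counts at surfaces and interface cores.

    value(aa) = log( f_interface(aa) / f_surface(aa) ) with frequencies
    normalized within each region. When any raw count is zero, an additive
    pseudocount of 1 is applied to every raw count before normalizing.
    """
    if not surface_counts or not interface_counts:
        raise InputError("both count tables must be non-empty")
    surf = np.array([float(surface_counts.get(a, 0.0)) for a in STANDARD_LETTERS])
    intf = np.array([float(interface_counts.get(a, 0.0)) for a in STANDARD_LETTERS])
    if surf.sum() <= 0 or intf.sum() <= 0:
        raise InputError("count tables must have positive totals")
    if (surf == 0).any() or (intf == 0).any():
        surf = surf + 1.0
        intf = intf + 1.0
    f_surf = surf / surf.sum()
    f_intf = intf / intf.sum()
    values = np.log(f_intf / f_surf) / math.log(log_base)
    return StickinessScale(
        values=dict(zip(STANDARD_LETTERS, values.tolist())),
        provenance=f"derived from counts (log base {log_base:g})",
    )


@dataclass
class PatchConfig:
    """Surface-patch geometry: circular patch area (Ų) and the rASA surface threshold (%)."""

    patch_area: float = 400.0
    surface_threshold: float = 25.0

    def __post_init__(self) -> None:
        if self.patch_area <= 0:
            raise InputError("patch_area must be > 0")

    @property
    def max_distance(self) -> float:
        """Maximum Cα–Cα distance (Å) implied by the circular patch area: sqrt(area/π)."""
        return math.sqrt(self.patch_area / math.pi)


@dataclass
class EnvironmentStickinessRecord:
    """Mean neighbor stickiness in the patch around one residue, and the neighbor count."""

    residue_key: tuple[str, str]
    sticky_patch: float | None
    patch_size: int


def environment_stickiness(
    assembly: Assembly,
    sasa: list[SasaRecord],
    scale: StickinessScale,
    patch: PatchConfig | None = None,
) -> list[EnvironmentStickinessRecord]:
    """Environment stickiness for every non-buried residue of the assembly.

    For each center residue with rASAc above the surface threshold, neighbors
    are the *surface* residues of the whole assembly (all chains, rASAc above
    threshold, standard amino acids) whose Cα lies within the patch radius of
    the center's Cα, the center itself excluded. The record value is the
    arithmetic mean of the neighbors' scale values; a surface residue with no
    neighbor in range gets patch_size 0 and no value. Buried residues get no
    record at all.
    """
    patch = patch or PatchConfig()
    rasac = {rec.residue_key: rec.rASA_in_BU for rec in sasa}
    eligible = [
        r
        for r in assembly.eligible_residues()
        if rasac.get(r.key) is not None and rasac[r.key] > patch.surface_threshold
    ]
    if not eligible:
        return []
    # neighbors must carry a scale value: standard residues only
    neighbors = [r for r in eligible if r.letter != "X"]
    centers = eligible
    records = []
    if neighbors:
        ncoords = np.array([r.ca.coord for r in neighbors], dtype=float)
        nvalues = np.array([scale[r.letter] for r in neighbors], dtype=float)
        nkeys = [r.key for r in neighbors]
        tree = cKDTree(ncoords)
        for res in centers:
            idx = tree.query_ball_point(res.ca.coord, patch.max_distance)
            idx = [i for i in idx if nkeys[i] != res.key]
            if idx:
                records.append(
                    EnvironmentStickinessRecord(res.key, float(nvalues[idx].mean()), len(idx))
                )
            else:
                records.append(EnvironmentStickinessRecord(res.key, None, 0))
    else:
        records = [EnvironmentStickinessRecord(r.key, None, 0) for r in centers]
    return records
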