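"""End-to-end descriptor pipeline: PDB file in, descriptor tables out.

Stages: read assembly → obtain symmetry axes (detection, axes file, or a
seeded random control axis for monomers) → bounding-plane descriptors →
complexed/unbound SASA → environment stickiness → CSV tables and a
projection PDB with nDp in the B-factor column for visual inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import AsymmetricStructureError
from .ndp import compute_ndp_records
from .sasa import SasaConfig, complexed_and_unbound
from .stickiness import PatchConfig, StickinessScale, environment_stickiness
from .structure_io import read_assembly, write_value_projection
from .symmetry import (
    SymmetrySolution,
    detect_point_group,
    random_unit_axis,
    read_axes_file,
    solution_from_axes,
)
from .tables import build_residue_rows, write_axes_table, write_residue_table

logger = logging.getLogger("symsurf")

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    solution: SymmetrySolution
    residue_table: pd.DataFrame
    residue_table_path: Path
    axes_table_path: Path
    projection_path: Path


def run_pipeline(
    pdb_path: str | Path,
    out_prefix: str | Path,
    axes_path: str | Path | None = None,
    scale_path: str | Path | None = None,
    control_axis: bool = False,
    seed: int = 0,
    patch_area: float = 400.0,
    rasa_threshold: float = 25.0,
    probe_radius: float = 1.4,
    sphere_points: int = 960,
    keep_hetero: bool = False,
) -> PipelineResult:
    """Compute every descriptor for one assembly and write the output files.

    Monomers (or structures failing symmetry detection) require either an
    axes file or ``control_axis=True``, which draws a seeded random fold-1
    axis through the Cα centroid — the negative-control mode.

    Writes ``<out_prefix>_residues.csv``, ``<out_prefix>_axes.csv`` and
    ``<out_prefix>_ndp_projection.pdb``. When a stickiness scale is given
    and environment stickiness is computed, ``<out_prefix>_sticky_projection.pdb``
    is written as well.
    """
    out_prefix = Path(out_prefix)
    assembly = read_assembly(pdb_path, keep_hetero=keep_hetero)
    logger.info(
        "read %s: %d chains, %d residues",
        assembly.pdb_long, len(assembly.chains), sum(len(c) for c in assembly.chains),
    )

    if axes_path is not None:
        axes = read_axes_file(axes_path)
        solution = solution_from_axes(axes, assembly)
        logger.info("loaded %d axes from %s (group %s)", len(axes), axes_path, solution.group_label)
    elif len(assembly.chains) == 1:
        if not control_axis:
            raise AsymmetricStructureError(
                "monomer has no symmetry axes; pass an axes file or enable the "
                "random control axis"
            )
        center = assembly.ca_centroid()
        axis = random_unit_axis(seed, center)
        solution = SymmetrySolution("C1", [axis], center, 0.0)
        logger.info("monomer control: random axis %s (seed %d)", axis.direction.round(4), seed)
    else:
        solution = detect_point_group(assembly)
        logger.info(
            "detected group %s with %d axes (closure RMSD %.3f Å)",
            solution.group_label, len(solution.axes), solution.rmsd,
        )

    ndp_records = compute_ndp_records(assembly, solution)
    logger.info("nDp computed for %d residues", len(ndp_records))

    config = SasaConfig(probe_radius=probe_radius, sphere_points=sphere_points)
    sasa_records = complexed_and_unbound(assembly, config)
    logger.info("rASA computed for %d residues", len(sasa_records))

    scale = None
    env_records = None
    if scale_path is not None:
        scale = StickinessScale.from_file(scale_path)
        patch = PatchConfig(patch_area=patch_area, surface_threshold=rasa_threshold)
        env_records = environment_stickiness(assembly, sasa_records, scale, patch)
        logger.info("environment stickiness computed for %d surface residues", len(env_records))
    else:
        logger.info("no stickiness scale supplied; stickiness columns left missing")

    df = build_residue_rows(assembly, solution, ndp_records, sasa_records, env_records, scale)

    residue_path = out_prefix.with_name(out_prefix.name + "_residues.csv")
    axes_table_path = out_prefix.with_name(out_prefix.name + "_axes.csv")
    projection_path = out_prefix.with_name(out_prefix.name + "_ndp_projection.pdb")
    write_residue_table(df, residue_path)
    write_axes_table(solution.axes, assembly.pdb_long, axes_table_path)
    write_value_projection(
        assembly, {r.residue_key: r.ndp for r in ndp_records}, projection_path
    )
    if env_records is not None:
        sticky_path = out_prefix.with_name(out_prefix.name + "_sticky_projection.pdb")
        write_value_projection(
            assembly,
            {r.residue_key: r.sticky_patch for r in env_records if r.sticky_patch is not None},
            sticky_path,
        )
    logger.info("wrote %s (%d rows)", residue_path, len(df))
    return PipelineResult(solution, df, residue_path, axes_table_path, projection_path)
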