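# Methods

This note records how symsurf computes its descriptors, which choices were
genuinely open and how they were fixed, and what the synthetic test bed
does and does not establish about real structures.

## Structure model

A PDB file is reduced to chains → residues → atoms. Only the first model
is used, except when a multi-model file repeats chain identifiers across
models — the convention some biological-assembly files use for symmetry
copies — in which case every model is kept and its chains get fresh
identifiers. Waters are always discarded; other HETATM groups are kept only
on request and are never descriptor-eligible. Alternate conformers resolve
to the highest occupancy (ties → first in file). Author residue numbering,
including insertion codes, is preserved verbatim in every output; a residue
is identified throughout by (chain id, number + insertion code).
Nonstandard residues map to letter `X`: they keep coordinates and rASA but
carry no stickiness value and are dropped from the residue table.
Geometric descriptors use only residues that have a Cα.

## Symmetry detection

Cn/Dn point groups are inferred from pairwise chain superpositions rather
than taken from an external symmetry engine, so the whole pipeline runs
self-contained:

1. chain 1 is superposed onto every other chain (Kabsch on paired Cα;
   pairing by residue order, or by shared residue numbers when lengths
   differ, tolerating missing loops);
2. each rotation is decomposed into axis and angle; axis signs are
   canonicalized (first nonzero component positive) so a rotation and its
   inverse share one representative;
3. axes are clustered greedily within an angular tolerance (default 2°, a
   value loose enough for the near-symmetry of crystallographic homomers);
4. one cluster ⇒ cyclic with fold = chain count, checked against the
   expected angle multiset {2πk/n}; several clusters ⇒ dihedral with
   n = chains/2, requiring either three mutually orthogonal 2-fold axes
   (D2) or one n-fold axis plus n perpendicular 2-folds;
5. closure is verified by applying each generator to all Cα and matching
   every rotated chain to some chain within an RMSD tolerance (default
   3 Å). The worst closure RMSD is reported so callers can filter dubious
   assignments.

The assembly center is the unweighted Cα centroid. "Center of mass"
without masses is ambiguous, but the choice is immaterial for nDp (see
below); it only shifts reported axis origins.

Axes may instead be read from a tabulated file (`pdb_long, fold, x, y, z`);
vectors off unit length by more than 1e-3 are rejected rather than silently
renormalized. The monomer control draws a single fold-1 axis uniformly on
the sphere (normalized 3-variate Gaussian), seeded for reproducibility.

Cubic (T/O/I) and helical symmetries are out of scope; heteromers are
rejected.

## nDp

For axis *a* with unit vector **s** and residue Cα vectors **r**ᵢ taken
from the assembly center, the bounding planes sit at the extreme
projections over *all* residues of the quaternary structure, and
nDp(a,i) = min(d_max − **s**·**r**ᵢ, **s**·**r**ᵢ − d_min).

Properties the implementation relies on (and the tests assert):

* nDp is a difference of projections, so it is exactly independent of the
  chosen center and equivariant under rigid motion of assembly plus axes;
* per axis, at least one residue attains 0 on each side, and no value
  exceeds (d_max − d_min)/2;
* the all-axes variant is the pointwise minimum over per-axis values, so
  `nDp ≤ nDp_2_fold` and `nDp ≤ nDp_n_fold` wherever those exist.

Dispatch by symmetry class: cyclic and the monomer control have one axis,
so only `nDp` is defined. D2's three 2-fold axes cannot be told apart, so
again only `nDp` is reported. Dn with n > 2 gets all three variants. Each
residue also records the fold of the axis realizing its minimum and which
plane (axis, max/min side) is closest; ties between axes within 1e-9 Å
resolve to the lowest fold, then input order — a deterministic rule chosen
for reproducible tables, not a claim about any original convention.

## SASA and rASA

Per-atom solvent accessibility uses the Shrake–Rupley construction: each
atom's van-der-Waals sphere is inflated by the probe radius (default
1.4 Å), covered with a deterministic golden-spiral lattice (default 960
points, quadrature error well under 1 % for an isolated sphere), and the
accessible fraction is the share of points outside every neighboring
inflated sphere. Neighbor search uses a k-d tree. Hydrogens are ignored
entirely — crystal structures mostly lack them, and mixed treatment would
bias rASA between structures.

The lattice is oriented by a frame built from each chain's first
non-collinear atom triple, so the point set rotates rigidly with the
molecule. This makes ASA exactly invariant under rigid motion and — because
the complexed and unbound computations reuse the same oriented points —
makes burial exactly monotone: a residue's ASA in the assembly can never
exceed its ASA in the isolated chain.

Relative ASA divides the residue's summed atom ASA by a residue-type
reference maximum (theoretical Gly-X-Gly values; Tien et al. 2013) and is
clamped into [0, 100] %: raw values above 100, common for distorted or
terminal residues, are corrected to 100. Radii and the normalization table
ship as an explicit JSON config and are swappable; no parity with any
particular legacy ASA program is promised, and absolute rASA may differ
from other tools by a few percent depending on their normalization.

## Regions, scales, environment stickiness

Region classification is a pure function of (rASAc, rASAu) with strict
threshold comparisons (default 25 %): surface requires ΔrASA = 0 (within
1e-6, absorbing quadrature noise) and rASAc > 25 %; interface core requires
ΔrASA > 0, rASAc < 25 % and rASAu > 25 %; anything else below the threshold
is buried, the remainder (e.g. the interface rim) is "other". A residue at
exactly 25 % falls in neither surface nor buried — the operators are strict
as written.

A stickiness scale is log(f_interface / f_surface) with frequencies
normalized within each region. The natural logarithm is the default (the
base is configurable); an additive pseudocount of 1 on every raw count is
applied whenever any count is zero. Swapping the two count tables negates
the scale exactly. The package ships no published scale: scales are
pluggable files, and all tests run on synthetic scales.

Environment stickiness of a non-buried residue (rASAc > 25 %) averages the
scale values of surface residues (rASAc > 25 %, no Δ condition) within a
patch of area 400 Ų centered on its Cα. The radius uses the full-precision
√(400/π) ≈ 11.2838 Å with an inclusive boundary — 11.28 is a rounding of
the analytic value. Neighbors are drawn from the entire assembly, all
chains, because patches live on the quaternary-structure surface. The
center is always excluded, so perturbing a residue's own scale value never
changes its own patch value. A surface residue with an empty patch reports
patch size 0 and no value; buried residues report nothing. Whether the
original convention used an inclusive boundary or crossed chain boundaries
is unknown; these are documented choices of this implementation.

## Tables, filter, pipeline

The residue table has exactly the columns
`pdb_long, chain, num, name, letter, x, y, z, rASA_in_BU, rASA_alone,
sticky_scale, sticky_patch, patch_size, nDp, fold, nDp_n_fold, nDp_2_fold`,
one row per Cα-bearing standard residue; coordinates print at 3 decimals,
rASA at 1, stickiness at 4, nDp at 3, and `NA` marks missing values
(including the fold-restricted columns outside Dn, n > 2). The assembly
table computes subunit count and molecular weight (average residue masses
plus one water per chain); curation fields (PiQSi/QSalign/QSbio/h80/h90)
are passthrough only.

The connectivity filter builds a chain-contact graph — an edge where two
chains share at least 5 contacting residue pairs, a contact being any
heavy-atom pair within 5 Å — and accepts an assembly iff the graph is
connected. The 5 Å heavy-atom cutoff is a documented stand-in: the cutoff
used by the reference database is not published.

The `symsurf` CLI wraps the pipeline (read → axes → nDp → rASA →
environment stickiness → tables + B-factor projections) and distinguishes
input errors (exit 2) from asymmetric structures (exit 3). Without a scale
file the stickiness columns are left `NA` and the run still succeeds.

## Synthetic assemblies

The generator builds exact Cn/Dn homomers by applying rigid symmetry
operations to one seeded pseudo-random chain: a self-avoiding Cα walk with
3.8 ± 0.1 Å steps and bounded turning, decorated with N/C/O backbone atoms
and uniform random residue types. Cyclic assemblies place the chain
centroid `radial_offset` (default 18 Å) from the z-axis and rotate n
copies; dihedral assemblies add the image of the ring under a 180° rotation
about x, the rings separated by `axial_spread` (default 14 Å). Defaults
(40 residues/chain) keep assemblies in the size range where every
descriptor is non-trivial while whole-matrix symmetry-recovery tests stay
fast; tests use 12–25 residues per chain for the same reason.

What the generator emulates: exact point-group geometry, chain–chain
interfaces (small radial offsets), disconnected assemblies (large offsets),
monomer controls with seeded random axes. What it does not: real folds,
side chains, sequence composition bias, crystallographic noise, or
near-symmetry. Passing tests therefore establish the correctness of the
geometric and statistical machinery, not the biological distributions of
the descriptors on real structures; detection tolerances (2°, 3 Å) are
exercised only in their trivially-satisfied regime.

## Known limitations

* Symmetry detection assumes co-numbered homomer chains; heavy
  insertion-code divergence between chains degrades pairing.
* ASA is quadrature-based; absolute values carry ~1/√n_points noise and a
  normalization-table dependence.
* D2 assemblies report no fold-restricted nDp by construction, and the
  `fold` column is populated only for Dn (n > 2), mirroring the dataset
  schema the tables follow.
* The connectivity filter's 5 Å / 5-residue rule is a stand-in (see above).
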