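# Methods

## Overview

voxscreen implements a structure-based virtual-screening pipeline of the
kind used to screen large commercial libraries against a GPCR homology
model: a binding site is delineated by flood-filling from a seed point,
protein–ligand poses are sampled rigidly inside it, each pose is
rasterized into a fixed-size multi-channel occupancy grid, a 3D
convolutional network regresses the grid onto binding affinity (pK), the
per-pose scores are combined by Boltzmann-weighted averaging, and the
ranked library passes through a triage cascade (top-K cut, property and
substructure filters, ECFP4/Butina diversity clustering, drug-likeness
rules). A synthetic-data module generates pockets, ligands and libraries
with known ground truth so every stage is testable offline, and a
structure-QC module covers superposition RMSD, steric-clash detection and
pLDDT confidence banding.

## Binding-site flooding

The published description names only "a flooding algorithm based on an
initial seed"; the occupancy rule is this package's own definition,
chosen so that open solvent cannot flood. The site is grown by
breadth-first traversal over a cubic lattice anchored at the seed (the
seed sits exactly on a lattice point; default spacing 1 Å). A lattice
point is accepted when it is

* **open** — no protein heavy atom within `occlusion_radius` (2 Å,
  strict) of the voxel center,
* **buried** — at least `burial_min_neighbors` (8) protein heavy atoms
  within `burial_radius` (8 Å), and
* within `max_radius` (12 Å) of the seed.

Connectivity is 6-neighbor by default (26 available). If more than half
of the rejected expansion steps fail only on the radius bound the flood
is effectively escaping into solvent and an `OpenSolventWarning` is
emitted. The site center is the unweighted mean of voxel centers — the
site is a spatial region, not a molecule, so no mass weighting is used.
Whether the original system flooded a plain occupancy lattice or a
solvent-accessible surface is unstated; every parameter of the rule is
therefore exposed in `FloodParams`.

## Pose sampling and augmentation

Poses are random rigid placements: the ligand is centered at the site
center, rotated uniformly (uniform-quaternion construction via
`scipy.spatial.transform.Rotation`), and translated uniformly within a
ball of radius `t_max` (default 4 Å). A placement is rejected when any
ligand–protein heavy-atom distance falls below `clash_factor` (0.75)
times the sum of the pair's Bondi van der Waals radii; sampling continues
until the requested count or an attempt budget (200 per pose) is
exhausted. How the original pipeline generated poses (docking vs
sampling) is unpublished; the scorer consumes any pose source. Data
augmentation applies one uniform rotation plus a small translation
(default 2 Å ball) jointly to protein and ligand about the site center,
so the network cannot memorize a preferred absolute orientation.

Hydrogens are ignored throughout (grids, clashes, flooding): the source
description never mentions protonation, and heavy-atom-only is the
simplest defensible convention.

## Rasterization

Grids are cubic, default 30 voxels per edge at 1 Å spacing, origin at the
site center minus half the box edge. An atom at `x` occupies voxel
`floor((x − origin)/spacing)` in its atom-type channel; atoms outside the
box are ignored. Occupancy is binary — the grid encodes the *presence* of
atom types, analogous to the three color channels of a pixel; a Gaussian
density option is deliberately out of scope. The default channel scheme
is {C, N, O, S, P, halogen, other} × {protein, ligand} = 14 channels;
finer typing (aromatic vs aliphatic carbon, charged nitrogen) is
unpublished for the original, so the scheme is pluggable.

## Scoring network

The default architecture follows the published layer list: five
convolutions of 32×3³, 64×3³, 64×3³, 64×3³, 64×2³ filters, a 256-unit
ReLU dense layer, and a scalar linear output. Strides and pooling are
unstated in the original; the default uses stride-1 valid convolutions
with two 2³ max-pools (after the second and fourth convolutions), which
gives a 1728-feature flatten on a 30³ input; the layer list is fully
configurable so other readings are expressible. Training minimizes MSE
against pK labels (pKd/pKi/pIC50 treated as one scale) with Adam,
mini-batches of 64, default learning rate 1e-3.

The network is implemented directly in NumPy (im2col convolution via
`sliding_window_view` + BLAS matmul, explicit reverse-mode gradients,
Adam) in float32 on the CPU. Gradient correctness is enforced by
finite-difference tests rather than assumed. Initialization (He-normal)
and shuffling are deterministic functions of explicit seeds, which makes
whole-pipeline runs bit-reproducible on a fixed platform.

## Boltzmann pose averaging

Pose scores are combined as

    S = Σᵢ sᵢ·exp(β·sᵢ) / Σⱼ exp(β·sⱼ)

computed with a max-shift for overflow safety. β (pK⁻¹ units, default 1)
interpolates between the arithmetic mean (β = 0) and the maximum
(β → ∞). One property worth stating precisely: this softmax-weighted
mean is *not* monotone in every individual input — raising a score that
sits far below the current average (specifically when β(sᵢ − S) < −1)
can lower the average, because the term's weight grows faster than its
contribution. It is monotone in the maximal score, bounded by the input
range, and shift-equivariant; the tests assert exactly these.

## Screening and ranking

Per compound: sample poses, rasterize, score, Boltzmann-average. Ranking
is descending by score (higher pK = stronger predicted binding), ties
broken lexicographically by compound id. Compounds with no placeable pose
are ranked last and flagged, never dropped. Each compound's pose stream
is seeded from a hash of its content and the run seed, so identical
compounds receive identical scores and results are independent of
library order.

## Triage cascade

Stage order is fixed: (1) top-K by rank (default 30,000); (2) MW > 200 Da
(strict); (3) exclusion-SMARTS substructure filter; (4) ECFP4 (Morgan
radius 2, 2048 bits) + Butina clustering at Tanimoto ≥ 0.35, keeping one
representative per cluster; (5) MW < 500 Da, cLogP < 5, PAINS pass.
Inequality strictness follows the printed symbols verbatim. A cutoff
value above 1 disables clustering (every compound a singleton), which the
permissive no-op configuration uses.

The Butina procedure is implemented here with explicit determinism:
neighbor counts at the cutoff, descending order with lexicographic id
tie-break, greedy sphere exclusion. A brute-force reference sweep (naive
loops) lives in `voxscreen.reference` and the tests require exact
partition agreement on randomized inputs.

Descriptors (MW, Crippen cLogP, Lipinski N+O / NH+OH counts, rotatable
bonds, Ertl TPSA), fingerprints, SMARTS matching and the public PAINS
A/B/C catalog come from RDKit. The original workflow's proprietary
SMARTS exclusion set and the ICM PAINS/toxicology scores are replaced by
an editable shipped exclusion list (reactive/undesirable moieties), PAINS
substructure matching with pass = 0 matches, and an optional external
toxicity-score column hook. The Lipinski engine follows the printed
strict inequalities; note the published descriptor table contains one row
(cLogP = 5.05) that the prose calls compliant but the strict "< 5"
flags — the engine follows the symbol and the divergence is asserted in
the tests rather than resolved.

## Structure QC

`kabsch_superpose` is a standard SVD Kabsch with the proper-rotation
correction; degenerate (collinear) inputs raise. `backbone_rmsd` pairs
residues by index (the backbone atom set is configurable, default
{N, CA, C}; CA-only offered) — sequence alignment is out of scope.
Clash detection reports ligand–protein pairs closer than 0.75× summed
Bondi radii, attributed to residues. pLDDT banding follows the AlphaFold
DB convention (≥90 very high, 70–90 confident, 50–70 low, <50 very low;
lower edges inclusive) since the source names the category but not the
edges.

## Synthetic data: what it emulates and what it does not

* **Pockets** are hollow cuboid shells of pseudo-atoms (mixed C/N/O on a
  lattice) with the innermost wall at sup-norm distance
  `cavity_edge/2 + 1.7 Å` from the center — placed so that, at the
  default flood parameters, interior lattice points are open and the
  first exterior layer is occluded, making flooded voxel counts exactly
  predictable (a closed 3 Å cavity floods to 27 voxels). An optional
  aperture opens a solvent leak for testing the open-solvent warning.
* **Ligands** are random tree-connected heavy-atom clusters (4–20 atoms
  from {C,N,O,S}, 1.5 Å bonds, 1.2 Å minimum separation, valence-capped).
  They have sensible geometry but no conformer physics or realistic
  torsional preferences.
* **Ground-truth affinity** is a transparent contact-count model:
  +0.1 pK per ligand-heavy-atom/protein-N-or-O pair within 4 Å,
  −1 pK per steric clash, plus Gaussian label noise (default sd 0.2 pK).
  The gain is set so labels land in a physical pK range (roughly 0–9 for
  the default pocket). The model is deliberately learnable by a 3D
  occupancy CNN, so ranking-recovery tests probe the featurizer and
  network, not chemistry.
* **Screening libraries** are built from scaffold families (carbazole,
  xanthine, N-phenylindole, an aliphatic sulfonamide, a bromotetralin, a
  catechol-adamantane PAINS family, a trityl-acetylsugar heavy family, a
  polychlorobiphenyl high-logP family, and sub-200 Da benzene
  derivatives) decorated with small polar fragments through
  family-specific linkers. Scaffolds and decorations were chosen so that
  ECFP4 similarity is ≥ 0.35 within every family and < 0.35 across
  families, making the Butina stage's outcome exactly one cluster per
  surviving family. Property classes (MW band, cLogP class, PAINS) are
  family-uniform so stage-5 outcomes do not depend on which member
  becomes the cluster representative. The generator validates all of
  this at build time with its own descriptor/fingerprint computation and
  raises a `PlanError` on any violation — the planted truth is assigned
  from the plan, never measured from the triage pipeline under test.

Passing tests on these fixtures demonstrate algorithmic correctness and
end-to-end reproducibility; they do not demonstrate chemical accuracy on
real protein–ligand data, which would require experimental affinities
and a trained model far beyond desk scale.

## Problem sizes and numerical choices

Benchmark runs use desk-scale sizes chosen so a full run takes minutes on
one CPU core: ranking recovery trains on 500 complexes in a 9 Å pocket at
a 16-voxel grid with a reduced-width network (8/16-filter convolutions;
the printed default stack needs ≥ 20 voxels per edge to be shape-valid)
for 15 epochs at learning rate 3e-3, then screens 50 held-out compounds
with 8 poses each. The
memorization capacity check runs the full printed layer stack on 20³
grids (builds are additionally verified at 30³), 8 examples, learning
rate 1e-2, 120 epochs. Ties in ranking are broken by id; max-pool crops
odd trailing voxels; ensemble averaging max-shifts exponents; training
aborts with a diagnostic on non-finite loss.

## Known limitations

* Pose sampling is rigid-body with clash rejection — no docking, no
  flexible ligands, no learned pose ranking.
* Binary occupancy only; no Gaussian smoothing or finer atom typing.
* A single global model; no per-target fine-tuning API.
* The published hit ranks, IC50s and homology-model RMSDs depend on
  proprietary weights, a commercial library, or unpublished coordinates
  and are recorded as context only; nothing here attempts to reproduce
  them.
* mmCIF, protonation/tautomer enumeration, and bond-order perception
  from 3D coordinates are out of scope.
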