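"""Synthetic pockets, ligands, labeled complexes, and screening libraries.

Everything the pipeline consumes can be generated here with known ground
truth, so every stage is testable without downloads:

* :func:`make_pocket` — a hollow cuboid shell of pseudo-atoms enclosing an
  empty cavity; closed pockets guarantee flood termination.
* :func:`make_ligand_set` — random small heavy-atom clusters with valid
  geometry and tree connectivity.
* :func:`true_affinity` — a transparent contact-count affinity: each
  ligand-heavy-atom/protein-polar-atom pair within the contact radius
  adds ``contact_gain`` pK, each steric clash subtracts ``clash_penalty``,
  plus Gaussian label noise. Simple enough that a 3D occupancy network
  can in principle learn it, so ranking recovery tests the featurizer and
  network rather than chemistry.
* :func:`make_training_set` — composes pocket, ligands, pose sampling,
  affinity and rasterization into (grid, pK) pairs with a seed manifest.
* :func:`make_screen_library` — a SMILES library with planted scaffold
  families and property classes, plus the exact expected survivor counts
  of each triage stage.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

import itertools
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chemio import AtomRecord, MolGraph, Structure
from .constants import vdw_radius
from .posegrid import (GridSpec, NoPlaceablePoseError, Pose, VoxelGrid,
                       rasterize, sample_poses)
from .sitefinder import BindingSite, FloodParams, flood_site
from .triage import TriageConfig, descriptors, ecfp4

__all__ = [
    "PocketParams",
    "AffinityWeights",
    "PlanError",
    "FamilySpec",
    "LibraryTruth",
    "make_pocket",
    "make_ligand_set",
    "true_affinity",
    "make_training_set",
    "make_screen_library",
    "default_library_plan",
]

_RES_NAMES = ["ALA", "GLY", "SER", "THR", "VAL", "LEU", "ILE", "PHE"]


class PlanError(ValueError):
    """A planted library plan is infeasible or violated by its chemistry."""


@dataclass(frozen=True)
class PocketParams:
    """Geometry of a synthetic hollow pocket. Lengths in Angstrom."""

    cavity_edge: float = 3.0
    wall_thickness: float = 2.0
    wall_atom_spacing: float = 1.0
    aperture: float | None = None  # diameter of a hole in the +x face
    atoms_per_residue: int = 24
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.cavity_edge < 3.0:
            raise ValueError("cavity_edge must be >= 3 A")


@dataclass(frozen=True)
class AffinityWeights:
    """Parameters of the synthetic contact-count affinity (pK units)."""

    contact_gain: float = 0.1    # pK per ligand/polar-protein contact
    clash_penalty: float = 1.0   # pK per clashing pair
    contact_radius: float = 4.0  # A
    clash_factor: float = 0.75   # fraction of summed vdW radii
    noise_sd: float = 0.2        # Gaussian label noise, pK

    def __post_init__(self) -> None:
        if self.contact_gain <= 0:
            raise ValueError("contact_gain must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_pocket(p: PocketParams = PocketParams()) -> tuple[Structure, np.ndarray]:
    """Build a hollow cuboid shell of pseudo-atoms around an empty cavity.

    Returns the wall structure and the cavity center (the flood seed).
    The innermost wall layer sits at sup-norm distance ``cavity_edge/2 +
    1.7`` from the center, placed so that, at the default flood
    parameters, lattice points inside the cavity are open and the first
    layer beyond it is occluded. With ``aperture`` set, a circular hole
    in the +x wall opens a leak path to solvent.
    """
    rng = np.random.default_rng(p.rng_seed)
    r0 = p.cavity_edge / 2.0 + 1.7
    n_layers = int(np.floor(p.wall_thickness / p.wall_atom_spacing)) + 1
    positions: list[np.ndarray] = []
    seen: set[tuple[float, float, float]] = set()
    for m in range(n_layers):
        r = r0 + m * p.wall_atom_spacing
        ext = int(np.floor(r / p.wall_atom_spacing))
        grid = np.arange(-ext, ext + 1) * p.wall_atom_spacing
        for axis in range(3):
            for sign in (-1.0, 1.0):
                for u, v in itertools.product(grid, grid):
                    pos = [0.0, 0.0, 0.0]
                    pos[axis] = sign * r
                    pos[(axis + 1) % 3] = u
                    pos[(axis + 2) % 3] = v
                    key = tuple(np.round(pos, 6))
                    if key in seen:
                        continue
                    seen.add(key)
                    positions.append(np.array(pos))
    if p.aperture is not None:
        half = p.aperture / 2.0
        positions = [pos for pos in positions
                     if not (pos[0] > 0 and
                             np.hypot(pos[1], pos[2]) < half and
                             abs(pos[0]) >= r0 - 1e-9)]
    elements = rng.choice(["C", "N", "O"], size=len(positions),
                          p=[0.7, 0.15, 0.15])
    atoms = []
    for k, (pos, el) in enumerate(zip(positions, elements)):
        res_index = k // p.atoms_per_residue + 1
        atoms.append(AtomRecord(
            element=str(el), xyz=pos, res_index=res_index,
            res_name=_RES_NAMES[(res_index - 1) % len(_RES_NAMES)],
            chain="A", role="protein", name=f"{el}{k % p.atoms_per_residue + 1}"))
    return Structure(atoms, id="synthetic-pocket"), np.zeros(3)


def make_ligand_set(n: int, size_range: tuple[int, int] = (4, 20),
                    rng_seed: int = 0) -> list[MolGraph]:
    """Random tree-connected heavy-atom clusters with valid geometry.

    Atoms are drawn from {C, N, O, S}, grown one bond (1.5 A) at a time
    from a random parent, with all interatomic distances kept >= 1.2 A.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError(f"bad size range {size_range}")
    rng = np.random.default_rng(rng_seed)
    max_degree = {"C": 4, "N": 3, "O": 2, "S": 2}
    mols = []
    for k in range(n):
        n_atoms = int(rng.integers(lo, hi + 1))
        elements = list(rng.choice(["C", "N", "O", "S"], size=n_atoms,
                                   p=[0.55, 0.15, 0.2, 0.1]))
        coords = np.zeros((n_atoms, 3))
        degree = np.zeros(n_atoms, dtype=int)
        bonds: list[tuple[int, int, float]] = []
        for i in range(1, n_atoms):
            open_sites = [j for j in range(i)
                          if degree[j] < max_degree[elements[j]]]
            if not open_sites:
                elements[i - 1] = "C"  # reopen the chain end
                open_sites = [i - 1]
            for _ in range(200):
                parent = int(rng.choice(open_sites))
                d = rng.normal(size=3)
                d /= np.linalg.norm(d)
                cand = coords[parent] + 1.5 * d
                if i == 1 or \
                        np.min(np.linalg.norm(coords[:i] - cand, axis=1)) >= 1.2:
                    coords[i] = cand
                    bonds.append((parent, i, 1.0))
                    degree[parent] += 1
                    degree[i] += 1
                    break
            else:  # pragma: no cover - extremely unlikely at these sizes
                raise RuntimeError("could not grow ligand without overlap")
        mols.append(MolGraph(id=f"LIG{k:04d}", smiles="", atoms=elements,
                             bonds=bonds, coords=coords))
    return mols


def true_affinity(s: Structure, pose: Pose,
                  w: AffinityWeights = AffinityWeights(),
                  rng_seed: int = 0) -> float:
    """Ground-truth pK of a placed pose under the contact-count model.

    ``contact_gain`` per (ligand heavy atom, protein N/O atom) pair within
    ``contact_radius``, minus ``clash_penalty`` per pair closer than
    ``clash_factor`` x summed vdW radii, plus Gaussian noise.
    """
    prot = s.protein_atoms()
    prot_xyz = np.array([a.xyz for a in prot])
    polar = np.array([a.element in ("N", "O") for a in prot])
    prot_r = np.array([vdw_radius(a.element) for a in prot])
    n_contacts = 0
    n_clashes = 0
    for xyz, el in zip(pose.ligand_coords, pose.elements):
        d = np.linalg.norm(prot_xyz - xyz, axis=1)
        n_contacts += int(np.count_nonzero(polar & (d < w.contact_radius)))
        thr = w.clash_factor * (vdw_radius(el) + prot_r)
        n_clashes += int(np.count_nonzero(d < thr))
    noise = 0.0
    if w.noise_sd > 0:
        noise = float(np.random.default_rng(rng_seed).normal(0.0, w.noise_sd))
    return w.contact_gain * n_contacts - w.clash_penalty * n_clashes + noise


def make_training_set(n_complexes: int,
                      pocket: PocketParams = PocketParams(cavity_edge=9.0),
                      size_range: tuple[int, int] = (4, 16),
                      weights: AffinityWeights = AffinityWeights(),
                      grid_spec: GridSpec = GridSpec(),
                      flood: FloodParams = FloodParams(),
                      t_max: float = 2.0,
                      rng_seed: int = 0
                      ) -> tuple[list[tuple[VoxelGrid, float]], dict]:
    """Generate (grid, pK) training pairs inside one synthetic pocket.

    Pipeline per complex: pocket -> ligand -> pose sampling -> ground-truth
    affinity -> rasterization. The returned manifest records every seed
    and parameter block; re-running with the same arguments reproduces
    the data bit-exactly.
    """
    struct, seed_pt = make_pocket(pocket)
    site = flood_site(struct, seed_pt, flood)
    ligands = make_ligand_set(n_complexes, size_range, rng_seed=rng_seed + 1)
    seq = np.random.default_rng(rng_seed)
    data: list[tuple[VoxelGrid, float]] = []
    for k, lig in enumerate(ligands):
        pose_seed = int(seq.integers(0, 2 ** 31 - 1))
        noise_seed = int(seq.integers(0, 2 ** 31 - 1))
        # an occasional ligand shape cannot be placed in the cavity; swap
        # in a deterministic replacement so the set size stays fixed
        for retry in range(20):
            try:
                poses = sample_poses(struct, lig, site, n_poses=1,
                                     t_max=t_max, rng_seed=pose_seed)
                break
            except NoPlaceablePoseError:
                lig = make_ligand_set(
                    1, size_range,
                    rng_seed=(rng_seed + 1000003 * (k + 1) + retry)
                    % (2 ** 31 - 1))[0]
        else:
            raise NoPlaceablePoseError(
                f"complex {k}: no placeable ligand after 20 replacements")
        label = true_affinity(struct, poses[0], weights, rng_seed=noise_seed)
        grid = rasterize(struct, poses[0], site, grid_spec)
        data.append((grid, label))
    manifest = {
        "n_complexes": n_complexes,
        "pocket": asdict(pocket),
        "size_range": list(size_range),
        "weights": asdict(weights),
        "grid": {"n": grid_spec.n, "spacing": grid_spec.spacing},
        "flood": asdict(flood),
        "t_max": t_max,
        "rng_seed": rng_seed,
    }
    return data, manifest


# ---------------------------------------------------------------------------
# Planted screening libraries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilySpec:
    """One scaffold family of a planted library.

    ``scaffold`` is a SMILES with a single ``[*:1]`` attachment point.
    Property classes are family-uniform so that stage-5 outcomes do not
    depend on which member Butina picks as representative:

    * ``mw_class``: 'small' (< 200 Da, fails the MW > 200 gate), 'mid'
      (200-500 Da), or 'heavy' (> 500 Da, fails the MW < 500 gate);
    * ``pains`` / ``high_logp``: the whole family carries (or not) a
      PAINS motif / cLogP >= 5.

    ``n_excluded`` members receive a decoration bearing the exclusion
    motif (a nitro group) and are removed at the SMARTS stage.
    """

    name: str
    scaffold: str
    n_members: int
    mw_class: str = "mid"
    n_excluded: int = 0
    pains: bool = False
    high_logp: bool = False
    linker: str = ""  # family-specific spacer between scaffold and decoration

    def __post_init__(self) -> None:
        if self.mw_class not in ("small", "mid", "heavy"):
            raise ValueError(f"unknown mw_class {self.mw_class!r}")
        if not (0 <= self.n_excluded <= self.n_members):
            raise ValueError("n_excluded out of range")


@dataclass
class LibraryTruth:
    """Exact expected outcome of each triage stage, by construction."""

    stage_counts: dict[str, int]
    stage_members: dict[str, list[str]]  # stages input..smarts (id lists)
    n_clusters: int                      # expected stage-4 survivor count
    final_families: list[str]            # families whose rep passes stage 5


# polar decoration fragments, all starting with a heteroatom so that
# carbon-prefixed variants can never collide with another base fragment;
# each contributes <= +0.3 cLogP on an aromatic carbon so decorated 'mid'
# families stay below the logP filter for every member
_POLAR_DECOS = [
    "O", "OC", "OCCO", "OCCN", "OCCOC", "OC(=O)C", "OCCCO", "N", "NC",
    "N(C)C", "NCCO", "NC(=O)C", "NCCN", "NS(C)(=O)=O", "N(C)C(=O)C",
    "OCC#N", "S(=O)(=O)C", "S(=O)(=O)N", "S(=O)(=O)NC", "S(=O)C",
    "N1CCOCC1", "OCCNC", "NCCOC", "OC(C)CO", "NC(=O)N", "NC(=O)NC",
    "N(C)C(N)=O", "OCC(N)=O", "NCC(N)=O", "NCC(=O)O", "OCC(=O)O",
    "S(=O)(=O)NCC", "NS(=O)(=O)CC", "N1CCOC1", "OCCS(C)(=O)=O",
    "NC(=O)COC", "OCC(=O)N(C)C", "NCCS(C)(=O)=O", "OCCCN", "NC(=O)OC",
    "OC(=O)NC", "NCC#N",
]

# small-class members must stay under the 200 Da gate: restrict to the
# lighter fragments (<= ~85 Da added)
_SMALL_DECOS = [b for b in _POLAR_DECOS
                if b not in ("NS(C)(=O)=O", "S(=O)(=O)NC", "S(=O)(=O)NCC",
                             "NS(=O)(=O)CC", "OCCS(C)(=O)=O", "NC(=O)COC",
                             "OCC(=O)N(C)C", "NCCS(C)(=O)=O")]


def _decoration(index: int, fam: "FamilySpec") -> str:
    """Deterministic distinct decoration fragment for a member index."""
    if fam.high_logp:
        # plain alkyl chains keep every member's cLogP above the cutoff
        return "C" * (index + 1)
    decos = _SMALL_DECOS if fam.mw_class == "small" else _POLAR_DECOS
    base = decos[index % len(decos)]
    prefix = "C" * (index // len(decos))
    return fam.linker + prefix + base


def _attach(scaffold: str, fragment: str | None) -> str:
    scaf = Chem.MolFromSmiles(scaffold)
    if scaf is None:
        raise PlanError(f"unparsable scaffold SMILES {scaffold!r}")
    if fragment is None:
        # cap the attachment point with a hydrogen
        capped = Chem.RWMol(scaf)
        for atom in list(capped.GetAtoms()):
            if atom.GetAtomicNum() == 0:
                nbr = atom.GetNeighbors()[0]
                capped.RemoveAtom(atom.GetIdx())
        mol = capped.GetMol()
        Chem.SanitizeMol(mol)
        return Chem.MolToSmiles(mol)
    frag = Chem.MolFromSmiles(f"[*:1]{fragment}")
    if frag is None:
        raise PlanError(f"unparsable decoration fragment {fragment!r}")
    combined = Chem.molzip(Chem.CombineMols(scaf, frag))
    Chem.SanitizeMol(combined)
    return Chem.MolToSmiles(combined)


_MW_BOUNDS = {"small": (0.0, 195.0), "mid": (205.0, 495.0), "heavy": (505.0, 1e9)}
# high-logP families fail the final filter on cLogP alone, so only the
# MW > 200 gate constrains them from below
_MW_BOUNDS_HIGH_LOGP = (205.0, 1e9)


def make_screen_library(plan: Sequence[FamilySpec],
                        cfg: TriageConfig = TriageConfig(),
                        rng_seed: int = 0,
                        validate: bool = True
                        ) -> tuple[list[tuple[str, str]], list[str], LibraryTruth]:
    """Emit a planted SMILES library plus exact per-stage triage truth.

    Returns ``(library, ranked_ids, truth)`` where ``library`` is a list
    of (id, SMILES) and ``ranked_ids`` is the planted screen ranking
    (seeded shuffle of all ids). Validation recomputes descriptors and
    fingerprints and raises :class:`PlanError` when the chemistry
    violates a planted class (MW band, logP class, PAINS flag) or when
    family fingerprints do not separate at the Butina cutoff.
    """
    if not plan:
        return [], [], LibraryTruth({s: 0 for s in (
            "input", "top_k", "mw_min", "smarts", "cluster_reps",
            "final_filters")}, {}, 0, [])
    library: list[tuple[str, str]] = []
    fam_of: dict[str, FamilySpec] = {}
    excluded_ids: set[str] = set()
    for fam in plan:
        for k in range(fam.n_members):
            cid = f"{fam.name}-{k:03d}"
            if k < fam.n_excluded:
                # dedicated nitro-bearing decoration; distinct via chain length
                smi = _attach(fam.scaffold,
                              fam.linker + "C" * k + "C[N+](=O)[O-]")
                excluded_ids.add(cid)
            else:
                smi = _attach(fam.scaffold, _decoration(k, fam))
            library.append((cid, smi))
            fam_of[cid] = fam

    rng = np.random.default_rng(rng_seed)
    ranked = [cid for cid, _ in library]
    rng.shuffle(ranked)

    stage1 = ranked[:cfg.top_k]
    stage2 = [c for c in stage1 if fam_of[c].mw_class != "small"]
    stage3 = [c for c in stage2 if c not in excluded_ids]
    surviving_families = sorted({fam_of[c].name for c in stage3})
    final_families = [f.name for f in plan if f.name in surviving_families
                      and f.mw_class == "mid" and not f.pains
                      and not f.high_logp]
    truth = LibraryTruth(
        stage_counts={
            "input": len(ranked),
            "top_k": len(stage1),
            "mw_min": len(stage2),
            "smarts": len(stage3),
            "cluster_reps": len(surviving_families),
            "final_filters": len(final_families),
        },
        stage_members={"input": ranked, "top_k": stage1,
                       "mw_min": sorted(stage2), "smarts": sorted(stage3)},
        n_clusters=len(surviving_families),
        final_families=final_families,
    )
    if validate:
        _validate_plan(library, fam_of, excluded_ids, cfg)
    return library, ranked, truth


def _validate_plan(library: list[tuple[str, str]], fam_of: dict[str, FamilySpec],
                   excluded_ids: set[str], cfg: TriageConfig) -> None:
    from .triage import pains_matches

    fps = {}
    fam_name: dict[str, str] = {}
    for cid, smi in library:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise PlanError(f"generated SMILES for {cid} does not parse: {smi}")
        fam = fam_of[cid]
        d = descriptors(mol)
        if cid in excluded_ids:
            # removed at the SMARTS stage by construction: only the MW > 200
            # gate upstream of it constrains them
            if d.mw <= 205.0:
                raise PlanError(f"{cid}: excluded-motif member too light "
                                f"({d.mw:.1f} Da) to pass the MW gate")
            continue
        lo, hi = _MW_BOUNDS_HIGH_LOGP if fam.high_logp else \
            _MW_BOUNDS[fam.mw_class]
        if not lo <= d.mw <= hi:
            raise PlanError(
                f"{cid}: MW {d.mw:.1f} outside its planted class "
                f"{fam.mw_class!r} band [{lo}, {hi}]")
        if fam.high_logp and d.clogp < cfg.logp_max:
            raise PlanError(f"{cid}: cLogP {d.clogp:.2f} below planted "
                            f"high-logP class threshold {cfg.logp_max}")
        if not fam.high_logp and fam.mw_class == "mid" and \
                d.clogp >= cfg.logp_max:
            raise PlanError(f"{cid}: cLogP {d.clogp:.2f} violates planted "
                            "pass class")
        n_pains = pains_matches(mol)
        if fam.pains and n_pains == 0:
            raise PlanError(f"{cid}: planted PAINS family but no match")
        # a PAINS hit only matters for families planted to pass the final
        # filters; heavy/high-logP families fail stage 5 regardless
        if not fam.pains and fam.mw_class == "mid" and not fam.high_logp \
                and n_pains > 0:
            raise PlanError(f"{cid}: unplanned PAINS match")
        # separation only matters for compounds that can reach the
        # clustering stage: small-class and excluded-motif members are
        # removed by earlier stages by construction
        if cid not in excluded_ids and fam.mw_class != "small":
            fps[cid] = ecfp4(mol)
            fam_name[cid] = fam.name

    # fingerprint separation: within-family pairs at/above the cutoff,
    # cross-family pairs below it
    ids = sorted(fps)
    mat = np.stack([fps[i].bits for i in ids]).astype(np.float32)
    inter = mat @ mat.T
    pops = mat.sum(axis=1)
    union = pops[:, None] + pops[None, :] - inter
    sim = inter / np.maximum(union, 1e-12)
    names = np.array([fam_name[i] for i in ids])
    same = names[:, None] == names[None, :]
    off_diag = ~np.eye(len(ids), dtype=bool)
    within = sim[same & off_diag]
    cross = sim[~same]
    if within.size and within.min() < cfg.butina_cutoff:
        k = np.argwhere((sim < cfg.butina_cutoff) & same & off_diag)[0]
        raise PlanError(
            f"within-family similarity {within.min():.3f} below cutoff "
            f"{cfg.butina_cutoff} (e.g. {ids[k[0]]} vs {ids[k[1]]})")
    if cross.size and cross.max() >= cfg.butina_cutoff:
        k = np.argwhere((sim >= cfg.butina_cutoff) & ~same)[0]
        raise PlanError(
            f"cross-family similarity {cross.max():.3f} reaches cutoff "
            f"{cfg.butina_cutoff} (e.g. {ids[k[0]]} vs {ids[k[1]]})")


def default_library_plan(n_compounds: int = 1000) -> list[FamilySpec]:
    """A balanced plan mixing every planted outcome class.

    Scaffolds are chosen to be mutually dissimilar under ECFP4 so that
    each family collapses to exactly one Butina cluster at cutoff 0.35.
    """
    scaffolds_mid = [
        ("carbazole", "COc1ccc2c(c1)[nH]c1ccc([*:1])cc12", "C"),
        ("xanthine", "Cn1c(=O)c2c(nc([*:1])n2C)n(C)c1=O", "CCC"),
        ("phenylindole", "c1ccc(cc1)n1cc([*:1])c2ccccc21", "CC(C)"),
        ("morphsulf", "O=S(=O)(N1CCOCC1)C1CCC([*:1])CC1", ""),
        ("tetralin", "Brc1ccc2c(c1)CCCC2([*:1])", "C(C)C"),
    ]
    pains_scaffold = ("catechol",
                      "Oc1ccc(cc1O)C12CC3CC(CC([*:1])(C3)C1)C2")
    heavy_scaffold = ("heavy",
                      "c1ccc(cc1)C(c1ccccc1)(c1ccccc1)OCC1OC(Oc2ccc([*:1])"
                      "cc2)C(OC(C)=O)C(OC(C)=O)C1OC(C)=O")
    logp_scaffold = ("chloro", "Clc1cc(Cl)c(cc1Cl)-c1cc(Cl)c(cc1Cl)[*:1]")
    small_scaffold = ("benzene", "c1ccc([*:1])cc1")

    n_families = len(scaffolds_mid) + 4
    base = n_compounds // n_families
    if base < 1:
        raise PlanError(f"n_compounds={n_compounds} too small for the plan")
    extra = n_compounds - base * n_families
    plan = [FamilySpec(name, scaf, n_members=base + (extra if k == 0 else 0),
                       n_excluded=max(1, base // 6) if k % 2 == 0 else 0,
                       linker=link)
            for k, (name, scaf, link) in enumerate(scaffolds_mid)]
    plan.append(FamilySpec(*pains_scaffold, n_members=base, pains=True))
    plan.append(FamilySpec(*heavy_scaffold, n_members=base, mw_class="heavy"))
    plan.append(FamilySpec(*logp_scaffold, n_members=base, high_logp=True))
    plan.append(FamilySpec(*small_scaffold, n_members=base, mw_class="small"))
    return plan
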