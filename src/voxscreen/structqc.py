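"""Structure-model quality checks.

Superposition RMSD (Kabsch), backbone RMSD between paired structures,
ligand steric-clash detection against van der Waals radii, and
per-residue confidence (pLDDT) banding. These are the checks one runs
before trusting a homology or predicted model for screening: does the
model superpose well on its template, does a transplanted ligand fit the
pocket without clashes, and is the pocket region predicted confidently.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .chemio import AA_3TO1, ResidueRef, Structure
from .constants import vdw_radius
from .posegrid import RigidTransform

__all__ = [
    "Superposition",
    "ClashReport",
    "ConfidenceBands",
    "PairingError",
    "kabsch_superpose",
    "backbone_rmsd",
    "detect_clashes",
    "band_confidence",
    "read_plddt_pdb",
    "read_plddt_csv",
]


class PairingError(ValueError):
    """Residues could not be paired for RMSD computation."""


@dataclass
class Superposition:
    transform: RigidTransform
    rmsd: float
    n_atoms: int


def kabsch_superpose(A: np.ndarray, B: np.ndarray) -> Superposition:
    """Least-squares optimal superposition of B onto A (Kabsch).

    ``A`` and ``B`` are (N, 3) with correspondence by row index, N >= 3.
    Returns the proper rigid transform minimizing ||A - (R B + t)|| and
    the residual RMSD. Degenerate (collinear) inputs raise.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("A and B must both be (N, 3)")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 paired atoms")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    if np.linalg.matrix_rank(A0, tol=1e-9) < 2 or \
            np.linalg.matrix_rank(B0, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) point set")
    H = B0.T @ A0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    moved = B @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - A) ** 2, axis=1))))
    return Superposition(RigidTransform(R, t), rmsd, n)


def backbone_rmsd(a: Structure, b: Structure,
                  atom_names: frozenset[str] | set[str] = frozenset({"N", "CA", "C"}),
                  pairing: dict[int, int] | None = None) -> float:
    """Backbone RMSD between two structures after optimal superposition.

    Residues are paired by identical residue index (or an explicit
    index map ``pairing`` from a-residues to b-residues); each paired
    residue must contain every requested backbone atom in both
    structures, otherwise a :class:`PairingError` lists the offenders.
    """
    def collect(s: Structure) -> dict[int, dict[str, np.ndarray]]:
        out: dict[int, dict[str, np.ndarray]] = {}
        for at in s.protein_atoms():
            if at.name in atom_names:
                out.setdefault(at.res_index, {})[at.name] = at.xyz
        return out

    res_a, res_b = collect(a), collect(b)
    if pairing is None:
        pairing = {i: i for i in sorted(set(res_a) & set(res_b))}
    if not pairing:
        raise PairingError("no residues could be paired")

    pa, pb, offenders = [], [], []
    for ia, ib in sorted(pairing.items()):
        da, db = res_a.get(ia, {}), res_b.get(ib, {})
        if set(atom_names) - set(da) or set(atom_names) - set(db):
            offenders.append((ia, ib))
            continue
        for name in sorted(atom_names):
            pa.append(da[name])
            pb.append(db[name])
    if offenders:
        raise PairingError(
            f"residue pairs missing backbone atoms {sorted(atom_names)}: "
            f"{offenders}")
    return kabsch_superpose(np.array(pa), np.array(pb)).rmsd


@dataclass
class ClashReport:
    """Ligand-protein contacts closer than the vdW-scaled threshold."""

    pairs: list[tuple[int, ResidueRef, float, float]]  # (lig idx, res, d, thresh)

    @property
    def n_clashes(self) -> int:
        return len(self.pairs)

    def by_residue(self) -> dict[ResidueRef, list[tuple[int, float, float]]]:
        out: dict[ResidueRef, list[tuple[int, float, float]]] = {}
        for i, ref, d, thr in self.pairs:
            out.setdefault(ref, []).append((i, d, thr))
        return out


def detect_clashes(lig_coords: np.ndarray, lig_elements: list[str],
                   s: Structure, factor: float = 0.75) -> ClashReport:
    """Report every ligand-protein heavy-atom pair with distance below
    ``factor`` times the sum of the pair's Bondi vdW radii."""
    lig_coords = np.asarray(lig_coords, dtype=float)
    prot = s.protein_atoms()
    if not prot:
        return ClashReport(pairs=[])
    coords = np.array([a.xyz for a in prot])
    radii = np.array([vdw_radius(a.element) for a in prot])
    tree = cKDTree(coords)
    max_reach = factor * (max(vdw_radius(e) for e in lig_elements) + radii.max())
    pairs = []
    for i, (xyz, el) in enumerate(zip(lig_coords, lig_elements)):
        r_lig = vdw_radius(el)
        for j in tree.query_ball_point(xyz, max_reach):
            thr = factor * (r_lig + radii[j])
            d = float(np.linalg.norm(xyz - coords[j]))
            if d < thr:
                at = prot[j]
                ref = ResidueRef(AA_3TO1.get(at.res_name, "X"), at.res_index)
                pairs.append((i, ref, d, float(thr)))
    return ClashReport(pairs=pairs)


@dataclass(frozen=True)
class ConfidenceBands:
    """Ordered (lower-edge, label) bands over a 0-100 confidence score.

    The default follows the AlphaFold DB convention: >=90 very_high,
    70-90 confident, 50-70 low, <50 very_low. Lower edges are inclusive.
    """

    edges: tuple[tuple[float, str], ...] = (
        (90.0, "very_high"), (70.0, "confident"), (50.0, "low"), (0.0, "very_low"))

    def __post_init__(self) -> None:
        vals = [e for e, _ in self.edges]
        if vals != sorted(vals, reverse=True):
            raise ValueError("band edges must be strictly decreasing")

    def label(self, score: float) -> str:
        for edge, name in self.edges:
            if score >= edge:
                return name
        return self.edges[-1][1]


def band_confidence(plddt: dict[int, float],
                    bands: ConfidenceBands = ConfidenceBands(),
                    regions: dict[str, list[int]] | None = None
                    ) -> tuple[dict[int, str], dict[str, str]]:
    """Label each residue's pLDDT and summarize named regions.

    A region's summary label is the band of its mean score. Scores must
    lie in [0, 100].
    """
    for res, score in plddt.items():
        if not 0.0 <= score <= 100.0:
            raise ValueError(f"pLDDT of residue {res} out of [0, 100]: {score}")
    labels = {res: bands.label(score) for res, score in plddt.items()}
    summaries: dict[str, str] = {}
    for name, members in (regions or {}).items():
        missing = [r for r in members if r not in plddt]
        if missing:
            raise ValueError(f"region {name!r} references unscored residues "
                             f"{missing}")
        mean = float(np.mean([plddt[r] for r in members]))
        summaries[name] = bands.label(mean)
    return labels, summaries


def read_plddt_pdb(s: Structure | str | Path) -> dict[int, float]:
    """Per-residue pLDDT from the B-factor column (AlphaFold convention).

    All atoms of a residue carry the same value; the CA atom's value is
    used where present, else the residue's first atom.
    """
    import gemmi
    if isinstance(s, (str, Path)):
        st = gemmi.read_structure(str(s))
        out: dict[int, float] = {}
        for chain in st[0]:
            for res in chain:
                chosen = None
                for atom in res:
                    if atom.name == "CA":
                        chosen = atom.b_iso
                        break
                    if chosen is None:
                        chosen = atom.b_iso
                if chosen is not None:
                    out[res.seqid.num] = float(chosen)
        return out
    raise TypeError("read_plddt_pdb expects a PDB file path")


def read_plddt_csv(path: str | Path) -> dict[int, float]:
    """Two-column CSV: residue index, score (header optional)."""
    out: dict[int, float] = {}
    with open(path) as fh:
        for row in csv.reader(fh):
            if not row or not row[0].strip().lstrip("-").isdigit():
                continue
            out[int(row[0])] = float(row[1])
    return out
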