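"""Molecular input/output and atom-typing for grid featurization.

Reads protein structures from PDB files (via gemmi), ligand libraries from
SMILES or SDF (via RDKit), parses pocket-residue specifications such as
``"S91, R94"``, and maps atoms onto the occupancy channels used by the
rasterizer.

Conventions used throughout the package:

* hydrogens are ignored everywhere (grids, clash checks, flooding);
* coordinates are in Angstrom and copied verbatim from the source file —
  centering happens later, in :mod:`voxscreen.posegrid`;
* for alternate locations only the highest-occupancy conformer is kept;
* residue numbering follows the source file verbatim.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "AtomRecord",
    "Structure",
    "MolGraph",
    "ResidueRef",
    "ChannelScheme",
    "DEFAULT_SCHEME",
    "EmptyStructureError",
    "ResidueSpecError",
    "read_pdb",
    "write_pdb",
    "read_ligands",
    "write_rejects_csv",
    "parse_residue_spec",
    "format_residue_spec",
    "atom_channel",
]

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}
_HALOGENS = {"F", "CL", "BR", "I", "AT"}

#: three-letter -> one-letter amino-acid codes (standard 20 + common variants)
AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items() if k not in ("MSE", "SEC")}


class EmptyStructureError(ValueError):
    """Raised when a structure file yields no heavy atoms."""


class ResidueSpecError(ValueError):
    """Raised for malformed or duplicated residue-spec tokens."""


@dataclass(frozen=True)
class ResidueRef:
    """A pocket residue named by one-letter code and residue index."""

    res_name_1letter: str
    res_index: int

    def __post_init__(self) -> None:
        if self.res_index < 1:
            raise ValueError(f"residue index must be >= 1, got {self.res_index}")

    def __str__(self) -> str:  # e.g. "S91"
        return f"{self.res_name_1letter}{self.res_index}"


@dataclass
class AtomRecord:
    """One heavy atom of a protein or ligand.

    ``role`` is either ``"protein"`` or ``"ligand"``; ``name`` is the PDB
    atom name (needed to pick backbone atoms), falling back to the element
    symbol where no PDB name exists.
    """

    element: str
    xyz: np.ndarray  # shape (3,), Angstrom
    res_index: int
    res_name: str
    chain: str
    role: str
    name: str = ""

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError("xyz must be a finite 3-vector")
        if self.role not in ("protein", "ligand"):
            raise ValueError(f"role must be protein|ligand, got {self.role!r}")
        self.element = self.element.capitalize()
        if not self.name:
            self.name = self.element


@dataclass
class Structure:
    """An ordered collection of heavy-atom records with a text id."""

    atoms: list[AtomRecord]
    id: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyStructureError(f"structure {self.id!r} has no heavy atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self, role: str | None = None) -> np.ndarray:
        """Coordinates as an (N, 3) array, optionally restricted to a role."""
        sel = self.atoms if role is None else [a for a in self.atoms if a.role == role]
        if not sel:
            return np.zeros((0, 3))
        return np.array([a.xyz for a in sel], dtype=float)

    def protein_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.role == "protein"]

    def ligand_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.role == "ligand"]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    about: np.ndarray | None = None) -> "Structure":
        """Return a rigidly moved copy: ``x -> R (x - about) + about + t``."""
        about = np.zeros(3) if about is None else np.asarray(about, dtype=float)
        out = []
        for a in self.atoms:
            xyz = rotation @ (a.xyz - about) + about + np.asarray(translation, float)
            out.append(AtomRecord(a.element, xyz, a.res_index, a.res_name,
                                  a.chain, a.role, a.name))
        return Structure(out, id=self.id)


@dataclass
class MolGraph:
    """A small molecule: elements, bonds, optional 3D coordinates.

    ``coords`` is an (N, 3) array over the heavy atoms (one row per atom).
    ``smiles`` is kept when the molecule came from a SMILES/SDF source so
    descriptor and fingerprint code can rebuild an RDKit molecule.
    """

    id: str
    smiles: str
    atoms: list[str]
    bonds: list[tuple[int, int, float]]
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) endpoint out of range for {n} atoms")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n, 3):
                raise ValueError(
                    f"coords shape {self.coords.shape} does not match {n} atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def to_rdkit(self) -> Chem.Mol:
        """Rebuild an RDKit molecule.

        Uses the stored SMILES when no coordinates are present; with
        coordinates the graph is rebuilt atom by atom so the atom order
        matches the coordinate rows.
        """
        if self.smiles and self.coords is None:
            mol = Chem.MolFromSmiles(self.smiles)
            if mol is not None:
                return mol
        rw = Chem.RWMol()
        for el in self.atoms:
            rw.AddAtom(Chem.Atom(el))
        order_map = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
                     3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}
        for i, j, order in self.bonds:
            rw.AddBond(int(i), int(j), order_map.get(float(order), Chem.BondType.SINGLE))
            if float(order) == 1.5:
                rw.GetAtomWithIdx(int(i)).SetIsAromatic(True)
                rw.GetAtomWithIdx(int(j)).SetIsAromatic(True)
        mol = rw.GetMol()
        Chem.SanitizeMol(mol, catchErrors=True)
        return mol


@dataclass(frozen=True)
class ChannelScheme:
    """Ordered atom-type channels: element groups crossed with roles.

    The default is seven element groups {C, N, O, S, P, halogen, other}
    for each of the two roles, protein channels first — 14 channels total.
    Unknown elements fall into ``other``; the mapping is total.
    """

    element_groups: tuple[str, ...] = ("C", "N", "O", "S", "P", "halogen", "other")
    roles: tuple[str, ...] = ("protein", "ligand")

    @property
    def n_channels(self) -> int:
        return len(self.element_groups) * len(self.roles)

    def group_index(self, element: str) -> int:
        el = element.upper()
        for k, g in enumerate(self.element_groups):
            if g == "halogen":
                if el in _HALOGENS:
                    return k
            elif g.upper() == el:
                return k
        return self.element_groups.index("other")


DEFAULT_SCHEME = ChannelScheme()


def atom_channel(atom: AtomRecord, scheme: ChannelScheme = DEFAULT_SCHEME) -> int:
    """Channel index for an atom under a channel scheme (total, deterministic)."""
    role_idx = scheme.roles.index(atom.role)
    return role_idx * len(scheme.element_groups) + scheme.group_index(atom.element)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path, *, structure_id: str | None = None) -> Structure:
    """Read a PDB file into a :class:`Structure` of heavy atoms.

    Hydrogens and waters are skipped; non-water HETATM records become
    ligand atoms; for alternate locations only the highest-occupancy
    conformer of each atom is kept. Coordinates are copied verbatim.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError, OSError) as exc:
        raise IOError(f"cannot read PDB file {path}: {exc}") from exc

    atoms: list[AtomRecord] = []
    if len(st) == 0:
        raise EmptyStructureError(f"{path} contains no models")
    model = st[0]
    for chain in model:
        for res in chain:
            resname = res.name.strip().upper()
            if resname in _WATER_NAMES:
                continue
            role = "ligand" if res.het_flag == "H" else "protein"
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in best.values():
                atoms.append(AtomRecord(
                    element=atom.element.name,
                    xyz=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    res_index=res.seqid.num,
                    res_name=resname,
                    chain=chain.name or "A",
                    role=role,
                    name=atom.name,
                ))
    if not atoms:
        raise EmptyStructureError(f"{path} contains no heavy atoms")
    return Structure(atoms, id=structure_id or path.stem)


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` back to PDB (ATOM/HETATM heavy atoms only)."""
    st = gemmi.Structure()
    st.name = s.id or "voxscreen"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for a in s.atoms:
        ch = chains.get(a.chain)
        if ch is None:
            ch = gemmi.Chain(a.chain)
            chains[a.chain] = ch
            model.add_chain(ch)
            ch = model[-1]
            chains[a.chain] = ch
        res = None
        if len(ch) > 0:
            last = ch[-1]
            if last.seqid.num == a.res_index and last.name == a.res_name:
                res = last
        if res is None:
            res = gemmi.Residue()
            res.name = a.res_name
            res.seqid = gemmi.SeqId(a.res_index, " ")
            res.het_flag = "H" if a.role == "ligand" else "A"
            ch.add_residue(res)
            res = ch[-1]
        atom = gemmi.Atom()
        atom.name = a.name
        atom.element = gemmi.Element(a.element)
        atom.pos = gemmi.Position(*a.xyz)
        atom.occ = 1.0
        res.add_atom(atom)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Ligand reading
# ---------------------------------------------------------------------------

def _mol_to_graph(mol: Chem.Mol, mol_id: str, keep_coords: bool) -> MolGraph:
    mol = Chem.RemoveHs(mol)
    atoms = [a.GetSymbol() for a in mol.GetAtoms()]
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
             for b in mol.GetBonds()]
    coords = None
    if keep_coords and mol.GetNumConformers() > 0:
        coords = np.array(mol.GetConformer().GetPositions(), dtype=float)
    return MolGraph(id=mol_id, smiles=Chem.MolToSmiles(mol), atoms=atoms,
                    bonds=bonds, coords=coords)


def read_ligands(path: str | Path, fmt: str = "smiles"
                 ) -> tuple[list[MolGraph], list[tuple[str, str]]]:
    """Read a ligand library from a SMILES file or an SDF.

    SMILES files are one molecule per line with an optional whitespace- or
    tab-separated id. Invalid records are collected into a rejects list of
    ``(id, reason)`` pairs and do not abort the run.

    Returns ``(molecules, rejects)``.
    """
    path = Path(path)
    mols: list[MolGraph] = []
    rejects: list[tuple[str, str]] = []
    if fmt == "smiles":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                smi = parts[0]
                mol_id = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
                mol = Chem.MolFromSmiles(smi)
                if mol is None:
                    rejects.append((mol_id, f"unparsable SMILES: {smi}"))
                    continue
                mols.append(_mol_to_graph(mol, mol_id, keep_coords=False))
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=True)
        for k, mol in enumerate(supplier):
            if mol is None:
                rejects.append((f"record{k + 1}", "unparsable SDF record"))
                continue
            mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and \
                mol.GetProp("_Name").strip() else f"record{k + 1}"
            mols.append(_mol_to_graph(mol, mol_id, keep_coords=True))
    else:
        raise ValueError(f"unknown ligand format {fmt!r} (use 'smiles' or 'sdf')")
    return mols, rejects


def write_sdf(mols: Sequence[MolGraph], path: str | Path,
              coords_override: dict[str, np.ndarray] | None = None) -> None:
    """Write molecules (with 3D coordinates) to an SDF V2000 file."""
    from rdkit.Chem import AllChem  # noqa: F401  (registers writers)
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for mg in mols:
            mol = Chem.RWMol(mg.to_rdkit())
            coords = mg.coords
            if coords_override and mg.id in coords_override:
                coords = coords_override[mg.id]
            if coords is None:
                raise ValueError(f"molecule {mg.id!r} has no 3D coordinates")
            conf = Chem.Conformer(mol.GetNumAtoms())
            for i in range(mol.GetNumAtoms()):
                conf.SetAtomPosition(i, [float(v) for v in coords[i]])
            mol.RemoveAllConformers()
            mol.AddConformer(conf)
            mol.SetProp("_Name", mg.id)
            writer.write(mol)
    finally:
        writer.close()


def write_rejects_csv(rejects: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "reason"])
        w.writerows(rejects)


# ---------------------------------------------------------------------------
# Residue specifications
# ---------------------------------------------------------------------------

_RES_TOKEN = re.compile(r"^([A-Za-z])(\d+)$")


def parse_residue_spec(text: str) -> list[ResidueRef]:
    """Parse a comma-separated residue list like ``"S91, R94"``.

    Order is preserved; duplicate tokens are an error; malformed tokens
    raise naming the offender.
    """
    refs: list[ResidueRef] = []
    seen: set[tuple[str, int]] = set()
    for raw in text.split(","):
        token = raw.strip()
        if not token:
            continue
        m = _RES_TOKEN.match(token)
        if not m:
            raise ResidueSpecError(f"malformed residue token {token!r}")
        ref = ResidueRef(m.group(1).upper(), int(m.group(2)))
        key = (ref.res_name_1letter, ref.res_index)
        if key in seen:
            raise ResidueSpecError(f"duplicate residue token {token!r}")
        seen.add(key)
        refs.append(ref)
    if not refs:
        raise ResidueSpecError("empty residue specification")
    return refs


def format_residue_spec(refs: Sequence[ResidueRef]) -> str:
    """Inverse of :func:`parse_residue_spec`."""
    return ", ".join(str(r) for r in refs)
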