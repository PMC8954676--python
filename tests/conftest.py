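"""Shared fixtures: synthetic pockets, ligands, and a literal PDB file."""

from __future__ import annotations

import numpy as np
import pytest

from voxscreen.chemio import AtomRecord, Structure
from voxscreen.posegrid import GridSpec
from voxscreen.sitefinder import FloodParams, flood_site
from voxscreen.synthdata import PocketParams, make_ligand_set, make_pocket


def pdb_line(serial: int, name: str, resname: str, chain: str, resnum: int,
             x: float, y: float, z: float, element: str,
             record: str = "ATOM", occ: float = 1.0, altloc: str = " ") -> str:
    """Format one fixed-width PDB ATOM/HETATM line (wwPDB v3.3 columns)."""
    return (f"{record:<6s}{serial:>5d} {name:<4s}{altloc}{resname:<3s} "
            f"{chain}{resnum:>4d}    {x:>8.3f}{y:>8.3f}{z:>8.3f}"
            f"{occ:>6.2f}{0.0:>6.2f}          {element:>2s}")


@pytest.fixture(scope="session")
def cavity_pocket():
    """Closed 3 A cavity: flood yields exactly 27 voxels at 1 A spacing."""
    struct, seed = make_pocket(PocketParams(cavity_edge=3.0, rng_seed=7))
    return struct, seed


@pytest.fixture(scope="session")
def cavity_site(cavity_pocket):
    struct, seed = cavity_pocket
    return flood_site(struct, seed, FloodParams())


@pytest.fixture(scope="session")
def big_pocket():
    """9 A cavity able to host multi-atom ligands."""
    struct, seed = make_pocket(PocketParams(cavity_edge=9.0, rng_seed=3))
    return struct, seed


@pytest.fixture(scope="session")
def big_site(big_pocket):
    struct, seed = big_pocket
    return flood_site(struct, seed, FloodParams())


@pytest.fixture(scope="session")
def small_ligands():
    return make_ligand_set(6, (4, 8), rng_seed=11)


@pytest.fixture()
def tiny_grid_spec():
    return GridSpec(n=8)


def single_atom_structure(element="C", xyz=(0.0, 0.0, 0.0), res_index=1,
                          res_name="ALA", chain="A", role="protein",
                          name=None) -> Structure:
    atom = AtomRecord(element, np.array(xyz, dtype=float), res_index,
                      res_name, chain, role, name or element)
    return Structure([atom], id="single")


def backbone_structure(offsets, struct_id="s") -> Structure:
    """n residues with N/CA/C backbone atoms, rigidly shifted per residue."""
    atoms = []
    base = {"N": np.array([0.0, 0, 0]), "CA": np.array([1.46, 0, 0]),
            "C": np.array([2.0, 1.4, 0.3])}
    for k, off in enumerate(offsets):
        for name, pos in base.items():
            atoms.append(AtomRecord("C" if name != "N" else "N",
                                    pos + np.array([0, 0, 3.0 * k]) + off,
                                    k + 1, "ALA", "A", "protein", name))
    return Structure(atoms, id=struct_id)


@pytest.fixture()
def literal_pdb(tmp_path):
    """A hand-written PDB exercising waters, hydrogens, HETATM, altlocs."""
    lines = [
        pdb_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, "N"),
        pdb_line(2, "CA", "ALA", "A", 1, 1.458, 0.0, 0.0, "C"),
        pdb_line(3, "C", "ALA", "A", 1, 2.0, 1.4, 0.0, "C"),
        pdb_line(4, "HA", "ALA", "A", 1, 1.6, -0.9, 0.0, "H"),  # skipped
        pdb_line(5, "CB", "SER", "A", 2, 4.0, 0.0, 0.0, "C", altloc="A",
                 occ=0.4),
        pdb_line(6, "CB", "SER", "A", 2, 4.5, 0.0, 0.0, "C", altloc="B",
                 occ=0.6),
        pdb_line(7, "C1", "LIG", "A", 100, 8.0, 8.0, 8.0, "C",
                 record="HETATM"),
        pdb_line(8, "O", "HOH", "A", 200, 9.0, 9.0, 9.0, "O",
                 record="HETATM"),  # water: skipped
        "END",
    ]
    path = tmp_path / "fixture.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
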