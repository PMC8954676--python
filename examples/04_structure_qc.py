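"""Structure-model QC: superposition RMSD, clash check, pLDDT bands.

Compares a backbone model with a perturbed copy, places a ligand into a
pocket that has an inward-pointing residue, and bands per-residue
confidence scores the way one would vet a predicted structure before
screening against it.
"""

import numpy as np

from voxscreen.chemio import AtomRecord, Structure
from voxscreen.structqc import (backbone_rmsd, band_confidence,
                                detect_clashes, kabsch_superpose)

# two 6-residue backbones, the second with a displaced loop residue
base = {"N": np.array([0.0, 0, 0]), "CA": np.array([1.46, 0, 0]),
        "C": np.array([2.0, 1.4, 0.3])}
bend = [np.zeros(3), [1, 0, 0], [0, 1.5, 0], [1, 1, 0.5], [0, 0.5, 1],
        [0.5, 0, 0]]


def chain(displace_last=False):
    atoms = []
    for k, off in enumerate(bend):
        for name, pos in base.items():
            xyz = pos + np.array([0, 0, 3.0 * k]) + off
            if displace_last and k == len(bend) - 1:
                xyz = xyz + np.array([1.2, -0.8, 0.3])
            atoms.append(AtomRecord("N" if name == "N" else "C", xyz,
                                    k + 1, "ALA", "A", "protein", name))
    return Structure(atoms, id="model")


rmsd = backbone_rmsd(chain(), chain(displace_last=True))
print(f"backbone RMSD (N, CA, C) after displacing one residue: {rmsd:.3f} A")

pocket = Structure([AtomRecord("C", [1.1, 0, 0], 194, "LEU", "A", "protein",
                               "CD1"),
                    AtomRecord("C", [6.0, 0, 0], 91, "SER", "A", "protein",
                               "OG")], id="pocket")
clashes = detect_clashes(np.zeros((1, 3)), ["C"], pocket)
for i, ref, d, thr in clashes.pairs:
    print(f"ligand atom {i} clashes with {ref}: {d:.2f} A < {thr:.2f} A")

labels, regions = band_confidence({194: 48.0, 195: 55.0, 196: 62.0},
                                  regions={"ECL2": [194, 195, 196]})
print(f"per-residue bands: {labels}")
print(f"region summary: {regions}")
# A clash attributed to an inward-facing pocket residue and a low-confidence
# loop band are the two red flags this QC is designed to surface.
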