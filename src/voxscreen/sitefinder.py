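"""Binding-site definition by lattice flooding.

The screening site is grown from a seed point by breadth-first traversal
over a cubic lattice anchored at the seed. A lattice point joins the site
when it is

* *open* — no protein heavy atom lies within ``occlusion_radius`` of the
  voxel center (strict inequality),
* *buried* — at least ``burial_min_neighbors`` protein heavy atoms lie
  within ``burial_radius``, and
* within ``max_radius`` of the seed.

The burial requirement stops the flood from leaking into open solvent;
if more than half of the rejected expansion steps fail only on the radius
bound, the pocket is effectively open to solvent and an
``OpenSolventWarning`` is emitted.

The site's center is the unweighted arithmetic mean of the flooded voxel
centers — the site is a spatial region, not a molecule, so no mass
weighting is applied.
"""

from __future__ import annotations

import json
import warnings
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .chemio import AA_3TO1, ResidueRef, Structure, format_residue_spec

__all__ = [
    "FloodParams",
    "BindingSite",
    "SeedingError",
    "ResidueLookupError",
    "OpenSolventWarning",
    "flood_site",
    "seed_from_residues",
    "pocket_residues",
]

_OFFSETS_6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
_OFFSETS_26 = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
               if (i, j, k) != (0, 0, 0)]


class SeedingError(ValueError):
    """The seed point is occluded by a protein atom."""


class ResidueLookupError(KeyError):
    """A residue reference did not resolve to any protein atom."""


class OpenSolventWarning(UserWarning):
    """The flood reached the max-radius shell on most directions."""


@dataclass(frozen=True)
class FloodParams:
    """Parameters of the flooding rule. All lengths in Angstrom."""

    spacing: float = 1.0
    occlusion_radius: float = 2.0
    max_radius: float = 12.0
    burial_min_neighbors: int = 8
    burial_radius: float = 8.0
    connectivity: int = 6

    def __post_init__(self) -> None:
        if min(self.spacing, self.occlusion_radius,
               self.max_radius, self.burial_radius) <= 0:
            raise ValueError("all lengths must be > 0")
        if self.max_radius < self.spacing:
            raise ValueError("max_radius must be >= spacing")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")


@dataclass
class BindingSite:
    """A flooded pocket: voxel set on a seed-anchored lattice."""

    seed: np.ndarray
    voxels: set[tuple[int, int, int]]
    origin: np.ndarray  # lattice origin == seed (seed sits on a lattice point)
    spacing: float
    center: np.ndarray
    pocket_residues: list[ResidueRef] = field(default_factory=list)

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    def voxel_centers(self) -> np.ndarray:
        """(n_voxels, 3) Cartesian centers of the flooded voxels."""
        idx = np.array(sorted(self.voxels), dtype=float)
        return self.origin[None, :] + self.spacing * idx

    def to_json(self, path: str | Path, params: FloodParams | None = None) -> None:
        payload = {
            "seed": list(map(float, self.seed)),
            "spacing": self.spacing,
            "center": list(map(float, self.center)),
            "voxels": sorted(map(list, self.voxels)),
            "pocket_residues": format_residue_spec(self.pocket_residues)
            if self.pocket_residues else "",
        }
        if params is not None:
            payload["params"] = {
                "spacing": params.spacing,
                "occlusion_radius": params.occlusion_radius,
                "max_radius": params.max_radius,
                "burial_min_neighbors": params.burial_min_neighbors,
                "burial_radius": params.burial_radius,
                "connectivity": params.connectivity,
            }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "BindingSite":
        from .chemio import parse_residue_spec
        d = json.loads(Path(path).read_text())
        voxels = {tuple(v) for v in d["voxels"]}
        refs = parse_residue_spec(d["pocket_residues"]) if d["pocket_residues"] else []
        return cls(seed=np.array(d["seed"]), voxels=voxels,
                   origin=np.array(d["seed"]), spacing=d["spacing"],
                   center=np.array(d["center"]), pocket_residues=refs)


def flood_site(s: Structure, seed: np.ndarray,
               p: FloodParams = FloodParams()) -> BindingSite:
    """Grow a binding site from ``seed`` by breadth-first lattice flooding.

    Raises :class:`SeedingError` if the seed voxel itself is occluded.
    """
    seed = np.asarray(seed, dtype=float)
    prot = s.coords(role="protein")
    if prot.shape[0] == 0:
        raise ValueError("structure has no protein atoms to flood against")
    tree = cKDTree(prot)

    offsets = _OFFSETS_6 if p.connectivity == 6 else _OFFSETS_26

    def center_of(ijk: tuple[int, int, int]) -> np.ndarray:
        return seed + p.spacing * np.asarray(ijk, dtype=float)

    def is_open(pt: np.ndarray) -> bool:
        d, _ = tree.query(pt)
        return bool(d >= p.occlusion_radius)

    def is_buried(pt: np.ndarray) -> bool:
        n = len(tree.query_ball_point(pt, p.burial_radius))
        return n >= p.burial_min_neighbors

    if not is_open(seed):
        raise SeedingError(
            "seed point is occluded: a protein heavy atom lies within "
            f"{p.occlusion_radius} A of it")

    accepted: set[tuple[int, int, int]] = {(0, 0, 0)}
    queue: deque[tuple[int, int, int]] = deque([(0, 0, 0)])
    rejected_radius = 0
    rejected_closed = 0
    visited_bad: set[tuple[int, int, int]] = set()

    while queue:
        cur = queue.popleft()
        for off in offsets:
            nxt = (cur[0] + off[0], cur[1] + off[1], cur[2] + off[2])
            if nxt in accepted or nxt in visited_bad:
                continue
            pt = center_of(nxt)
            if np.linalg.norm(pt - seed) > p.max_radius:
                visited_bad.add(nxt)
                rejected_radius += 1
                continue
            if not (is_open(pt) and is_buried(pt)):
                visited_bad.add(nxt)
                rejected_closed += 1
                continue
            accepted.add(nxt)
            queue.append(nxt)

    total_rejected = rejected_radius + rejected_closed
    if total_rejected > 0 and rejected_radius / total_rejected > 0.5:
        warnings.warn(
            "flood reached the max-radius shell on most directions; the "
            "pocket is likely open to solvent", OpenSolventWarning)

    idx = np.array(sorted(accepted), dtype=float)
    center = seed + p.spacing * idx.mean(axis=0)
    return BindingSite(seed=seed, voxels=accepted, origin=seed.copy(),
                       spacing=p.spacing, center=center)


def seed_from_residues(s: Structure, refs: list[ResidueRef]) -> np.ndarray:
    """Seed point = centroid of all heavy atoms of the named residues."""
    coords: list[np.ndarray] = []
    for ref in refs:
        matched = [a for a in s.protein_atoms()
                   if a.res_index == ref.res_index
                   and AA_3TO1.get(a.res_name, "X") == ref.res_name_1letter]
        if not matched:
            raise ResidueLookupError(
                f"residue {ref} not found among protein atoms of {s.id!r}")
        coords.extend(a.xyz for a in matched)
    return np.mean(np.array(coords), axis=0)


def pocket_residues(s: Structure, site: BindingSite,
                    cutoff: float = 4.5) -> list[ResidueRef]:
    """Protein residues with a heavy atom within ``cutoff`` of a voxel center.

    Sorted by residue index, deduplicated.
    """
    if site.n_voxels == 0:
        raise ValueError("binding site has no voxels")
    centers = site.voxel_centers()
    tree = cKDTree(centers)
    found: dict[tuple[str, int], ResidueRef] = {}
    for a in s.protein_atoms():
        if tree.query_ball_point(a.xyz, cutoff):
            one = AA_3TO1.get(a.res_name, "X")
            found.setdefault((one, a.res_index), ResidueRef(one, a.res_index))
    return sorted(found.values(), key=lambda r: r.res_index)
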