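"""Pose sampling, rigid-body augmentation, and voxel-grid rasterization.

A pose is a rigid placement of a ligand inside the binding site: the
ligand is centered at the site center, given a uniformly random rotation,
then translated uniformly within a ball of radius ``t_max``. Placements
that bring a ligand heavy atom closer to a protein heavy atom than
``clash_factor`` times the sum of their Bondi van der Waals radii are
rejected and resampled.

Each accepted complex is rasterized into a fixed-size cubic occupancy
grid (default 30 voxels per edge at 1 Angstrom spacing) whose origin sits
at the site center minus half the box edge. Occupancy is binary per
channel: a voxel records the *presence* of an atom type, like the three
color channels of a pixel record the presence of red, green and blue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .chemio import ChannelScheme, DEFAULT_SCHEME, MolGraph, Structure, atom_channel
from .constants import vdw_radius
from .sitefinder import BindingSite

__all__ = [
    "RigidTransform",
    "Pose",
    "GridSpec",
    "VoxelGrid",
    "NoPlaceablePoseError",
    "sample_poses",
    "augment",
    "rasterize",
    "random_rotation",
    "random_in_ball",
]


class NoPlaceablePoseError(RuntimeError):
    """No clash-free placement was found within the attempt budget."""


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion: ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation",
                           np.asarray(self.translation, dtype=float))
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if abs(np.linalg.det(R) - 1.0) > 1e-8 or \
                not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be proper orthonormal")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class Pose:
    """A placed ligand: transformed coordinates plus provenance.

    ``elements`` carries the ligand's element symbols so the rasterizer and
    the synthetic affinity function can type the atoms without reaching
    back to the molecule object.
    """

    ligand_coords: np.ndarray  # (N, 3)
    transform: RigidTransform
    clash_free: bool
    elements: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ligand_coords = np.asarray(self.ligand_coords, dtype=float)
        if self.ligand_coords.ndim != 2 or self.ligand_coords.shape[1] != 3:
            raise ValueError("ligand_coords must be (N, 3)")


@dataclass(frozen=True)
class GridSpec:
    """Geometry and channels of the rasterization grid."""

    n: int = 30
    spacing: float = 1.0
    scheme: ChannelScheme = DEFAULT_SCHEME

    def __post_init__(self) -> None:
        if self.n < 8:
            raise ValueError("grid edge must be >= 8 voxels")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")

    @property
    def n_channels(self) -> int:
        return self.scheme.n_channels

    def origin_for(self, site_center: np.ndarray) -> np.ndarray:
        return np.asarray(site_center, float) - self.n * self.spacing / 2.0


@dataclass
class VoxelGrid:
    """Binary multi-channel occupancy tensor with placement metadata."""

    values: np.ndarray  # (channels, n, n, n) of {0, 1}
    spec: GridSpec
    origin: np.ndarray

    @property
    def occupancy(self) -> int:
        return int(self.values.sum())


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (uniform-quaternion construction)."""
    return Rotation.random(random_state=rng).as_matrix()


def random_in_ball(rng: np.random.Generator, radius: float) -> np.ndarray:
    """Uniform random point in a ball of the given radius."""
    if radius == 0:
        return np.zeros(3)
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    r = radius * rng.random() ** (1.0 / 3.0)
    return r * v


def _clash_free(lig_xyz: np.ndarray, lig_elements: list[str],
                tree: cKDTree, prot_elements: list[str],
                clash_factor: float) -> bool:
    lig_r = np.array([vdw_radius(e) for e in lig_elements])
    max_thresh = clash_factor * (lig_r.max() + max(vdw_radius(e)
                                                   for e in prot_elements))
    prot_r = np.array([vdw_radius(e) for e in prot_elements])
    for xyz, r in zip(lig_xyz, lig_r):
        for j in tree.query_ball_point(xyz, max_thresh):
            thresh = clash_factor * (r + prot_r[j])
            if np.linalg.norm(xyz - tree.data[j]) < thresh:
                return False
    return True


def sample_poses(s: Structure, lig: MolGraph, site: BindingSite,
                 n_poses: int = 16, t_max: float = 4.0,
                 clash_factor: float = 0.75, rng_seed: int = 0,
                 max_attempts: int | None = None) -> list[Pose]:
    """Sample clash-free rigid placements of a ligand in the site.

    Fully reproducible from ``rng_seed``. Raises
    :class:`NoPlaceablePoseError` when the attempt budget is exhausted with
    zero accepted poses; returns fewer than ``n_poses`` with a warning when
    some but not all were placed.
    """
    if lig.coords is None:
        raise ValueError(f"ligand {lig.id!r} has no 3D coordinates")
    if n_poses < 1:
        raise ValueError("n_poses must be >= 1")
    if max_attempts is None:
        max_attempts = 200 * n_poses

    rng = np.random.default_rng(rng_seed)
    centered = lig.coords - lig.coords.mean(axis=0)
    prot = s.coords(role="protein")
    prot_elements = [a.element for a in s.protein_atoms()]
    tree = cKDTree(prot) if prot.shape[0] else None

    poses: list[Pose] = []
    attempts = 0
    while len(poses) < n_poses and attempts < max_attempts:
        attempts += 1
        R = random_rotation(rng)
        t = site.center + random_in_ball(rng, t_max)
        xyz = centered @ R.T + t
        ok = True
        if tree is not None:
            ok = _clash_free(xyz, lig.atoms, tree, prot_elements, clash_factor)
        if ok:
            poses.append(Pose(xyz, RigidTransform(R, t), clash_free=True,
                              elements=list(lig.atoms)))
    if not poses:
        raise NoPlaceablePoseError(
            f"no clash-free placement of {lig.id!r} in {max_attempts} attempts")
    if len(poses) < n_poses:
        warnings.warn(
            f"only {len(poses)}/{n_poses} poses placed for {lig.id!r} "
            f"within {max_attempts} attempts")
    return poses


def augment(s: Structure, pose: Pose, site: BindingSite,
            rng_seed: int = 0, t_max: float = 2.0) -> tuple[Structure, Pose]:
    """Jointly rotate and translate protein and ligand about the site center.

    One uniform random rotation about ``site.center`` plus a translation
    uniform in a ball of radius ``t_max`` is applied to the whole complex,
    preserving all internal geometry. This stops the network from
    memorizing a preferred absolute orientation of the protein.
    """
    rng = np.random.default_rng(rng_seed)
    R = random_rotation(rng)
    t = random_in_ball(rng, t_max)
    new_s = s.transformed(R, t, about=site.center)
    new_xyz = (pose.ligand_coords - site.center) @ R.T + site.center + t
    new_transform = RigidTransform(R @ pose.transform.rotation,
                                   R @ (pose.transform.translation - site.center)
                                   + site.center + t)
    return new_s, Pose(new_xyz, new_transform, pose.clash_free,
                       elements=list(pose.elements))


def rasterize(s: Structure, pose: Pose | None, site: BindingSite,
              spec: GridSpec = GridSpec()) -> VoxelGrid:
    """Rasterize a protein (and optionally a posed ligand) into a grid.

    Atom at position x occupies voxel index floor((x - origin) / spacing)
    in its atom-type channel; atoms falling outside the box are ignored;
    occupancy is binary.
    """
    origin = spec.origin_for(site.center)
    values = np.zeros((spec.n_channels, spec.n, spec.n, spec.n), dtype=np.uint8)

    def put(xyz: np.ndarray, channel: int) -> None:
        idx = np.floor((xyz - origin) / spec.spacing).astype(int)
        if np.all((idx >= 0) & (idx < spec.n)):
            values[channel, idx[0], idx[1], idx[2]] = 1

    n_roles = len(spec.scheme.element_groups)
    for a in s.protein_atoms():
        put(a.xyz, atom_channel(a, spec.scheme))
    if pose is not None:
        lig_role_offset = spec.scheme.roles.index("ligand") * n_roles
        for xyz, el in zip(pose.ligand_coords, pose.elements):
            put(xyz, lig_role_offset + spec.scheme.group_index(el))
    return VoxelGrid(values=values, spec=spec, origin=origin)
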