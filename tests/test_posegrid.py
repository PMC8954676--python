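"""Pose sampling, rigid augmentation, and rasterization."""

import itertools

import numpy as np
import pytest

from voxscreen.chemio import AtomRecord, MolGraph, Structure
from voxscreen.posegrid import (
    GridSpec, NoPlaceablePoseError, Pose, RigidTransform, augment, rasterize,
    sample_poses,
)
from voxscreen.sitefinder import BindingSite


def point_ligand(element="C"):
    return MolGraph("pt", "", [element], [], coords=np.zeros((1, 3)))


def free_site(center=(0.0, 0.0, 0.0)):
    c = np.array(center, dtype=float)
    return BindingSite(seed=c, voxels={(0, 0, 0)}, origin=c.copy(),
                       spacing=1.0, center=c)


class TestRigidTransform:
    def test_rejects_improper_rotation(self):
        R = np.diag([1.0, 1.0, -1.0])  # reflection
        with pytest.raises(ValueError):
            RigidTransform(R, np.zeros(3))

    def test_apply(self):
        Rz = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]])
        t = RigidTransform(Rz, np.array([1.0, 0, 0]))
        np.testing.assert_allclose(t.apply(np.array([[1.0, 0, 0]])),
                                   [[1.0, 1.0, 0.0]], atol=1e-12)


class TestSamplePoses:
    def test_point_ligand_lands_at_center(self, big_pocket, big_site):
        struct, _ = big_pocket
        poses = sample_poses(struct, point_ligand(), big_site, n_poses=1,
                             t_max=0.0, rng_seed=0)
        assert len(poses) == 1
        assert poses[0].clash_free
        np.testing.assert_allclose(poses[0].ligand_coords[0], big_site.center,
                                   atol=1e-9)

    def test_dense_slab_unplaceable(self):
        # solid block of atoms around the site center: everything clashes
        pts = [(x, y, z) for x in range(-3, 4) for y in range(-3, 4)
               for z in range(-3, 4)]
        atoms = [AtomRecord("C", np.array(p, float), 1, "ALA", "A", "protein")
                 for p in pts]
        slab = Structure(atoms, id="slab")
        lig = MolGraph("l", "", ["C", "C"], [(0, 1, 1.0)],
                       coords=np.array([[0.0, 0, 0], [1.5, 0, 0]]))
        with pytest.raises(NoPlaceablePoseError):
            sample_poses(slab, lig, free_site(), n_poses=1, t_max=1.0,
                         rng_seed=0, max_attempts=50)

    def test_determinism(self, big_pocket, big_site, small_ligands):
        struct, _ = big_pocket
        a = sample_poses(struct, small_ligands[0], big_site, n_poses=4,
                         rng_seed=123)
        b = sample_poses(struct, small_ligands[0], big_site, n_poses=4,
                         rng_seed=123)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.ligand_coords, pb.ligand_coords)

    def test_acceptance_invariant_to_atom_order(self, big_pocket, big_site,
                                                small_ligands):
        struct, _ = big_pocket
        lig = small_ligands[1]
        perm = np.arange(lig.n_atoms)[::-1]
        inv = np.argsort(perm)
        permuted = MolGraph(lig.id, "", [lig.atoms[i] for i in perm],
                            [(int(inv[i]), int(inv[j]), o)
                             for i, j, o in lig.bonds],
                            coords=lig.coords[perm])
        a = sample_poses(struct, lig, big_site, n_poses=3, rng_seed=7)
        b = sample_poses(struct, permuted, big_site, n_poses=3, rng_seed=7)
        for pa, pb in zip(a, b):
            np.testing.assert_allclose(pa.ligand_coords,
                                       pb.ligand_coords[inv], atol=1e-12)


class TestAugment:
    def test_rigid_motion_preserves_internal_geometry(self, big_pocket,
                                                      big_site,
                                                      small_ligands):
        struct, _ = big_pocket
        pose = sample_poses(struct, small_ligands[0], big_site, n_poses=1,
                            rng_seed=1)[0]
        new_s, new_pose = augment(struct, pose, big_site, rng_seed=5)
        # all pairwise distances within the complex are preserved
        old = np.vstack([struct.coords(), pose.ligand_coords])
        new = np.vstack([new_s.coords(), new_pose.ligand_coords])
        k = np.random.default_rng(0).integers(0, len(old), size=(50, 2))
        d_old = np.linalg.norm(old[k[:, 0]] - old[k[:, 1]], axis=1)
        d_new = np.linalg.norm(new[k[:, 0]] - new[k[:, 1]], axis=1)
        np.testing.assert_allclose(d_new, d_old, atol=1e-9)

    def test_centroid_distance_to_center_shifts_by_translation_only(
            self, big_pocket, big_site, small_ligands):
        struct, _ = big_pocket
        pose = sample_poses(struct, small_ligands[0], big_site, n_poses=1,
                            rng_seed=1)[0]
        d0 = np.linalg.norm(pose.ligand_coords.mean(0) - big_site.center)
        for seed in range(20):
            new_s, new_pose = augment(struct, pose, big_site, rng_seed=seed)
            t = (np.vstack([new_s.coords()]).mean(0)
                 - struct.coords().mean(0))  # pure translation component
            d1 = np.linalg.norm(new_pose.ligand_coords.mean(0)
                                - (big_site.center + t))
            assert d1 == pytest.approx(d0, abs=1e-9)

    def test_zero_translation_budget(self, big_pocket, big_site,
                                     small_ligands):
        struct, _ = big_pocket
        pose = sample_poses(struct, small_ligands[0], big_site, n_poses=1,
                            rng_seed=1)[0]
        _, new_pose = augment(struct, pose, big_site, rng_seed=2, t_max=0.0)
        d0 = np.linalg.norm(pose.ligand_coords.mean(0) - big_site.center)
        d1 = np.linalg.norm(new_pose.ligand_coords.mean(0) - big_site.center)
        assert d1 == pytest.approx(d0, abs=1e-9)


class TestRasterize:
    def test_single_carbon_at_center(self, tiny_grid_spec):
        site = free_site((10.0, 10.0, 10.0))
        spec = GridSpec(n=30)
        pose = Pose(np.array([[10.0, 10.0, 10.0]]), RigidTransform.identity(),
                    True, elements=["C"])
        s = Structure([AtomRecord("C", [999.0, 999, 999], 1, "ALA", "A",
                                  "protein")], id="far")
        grid = rasterize(s, pose, site, spec)
        occupied = np.argwhere(grid.values)
        assert occupied.shape == (1, 4)
        channel, i, j, k = occupied[0]
        assert (i, j, k) == (15, 15, 15)
        assert channel == 7  # ligand-carbon channel

    def test_out_of_box_atoms_ignored(self):
        site = free_site()
        spec = GridSpec(n=8)
        rng = np.random.default_rng(3)
        inside = rng.uniform(-3.5, 3.5, size=(8, 3))
        outside = np.array([[50.0, 0, 0], [0, -50.0, 0]])
        coords = np.vstack([inside, outside])
        pose = Pose(coords, RigidTransform.identity(), True,
                    elements=["C"] * 10)
        s = Structure([AtomRecord("C", [999.0, 999, 999], 1, "ALA", "A",
                                  "protein")], id="far")
        grid = rasterize(s, pose, site, spec)
        assert grid.occupancy == 8

    def test_empty_region_all_zero(self):
        s = Structure([AtomRecord("C", [999.0, 999, 999], 1, "ALA", "A",
                                  "protein")], id="far")
        grid = rasterize(s, None, free_site(), GridSpec(n=8))
        assert grid.occupancy == 0

    def test_occupancy_conservation(self, big_pocket, big_site,
                                    small_ligands):
        struct, _ = big_pocket
        pose = sample_poses(struct, small_ligands[2], big_site, n_poses=1,
                            rng_seed=9)[0]
        spec = GridSpec(n=40)  # big enough to hold the whole complex
        grid = rasterize(struct, pose, big_site, spec)
        # wall atoms sit on a 1 A lattice: several share voxels, so the
        # occupancy cannot exceed the atom count, and the ligand channels
        # (generic positions) conserve counts exactly
        lig_channels = grid.values[7:]
        assert lig_channels.sum() == pose.ligand_coords.shape[0]
        assert grid.occupancy <= len(struct) + pose.ligand_coords.shape[0]

    def test_cube_rotations_permute_grid(self, big_site):
        rng = np.random.default_rng(0)
        # generic (off-lattice) positions: atoms exactly on voxel boundaries
        # would be assigned to different half-open cells after reflection
        prot_xyz = big_site.center + rng.uniform(-6, 6, size=(40, 3)) + 0.137
        struct = Structure(
            [AtomRecord(el, p, k + 1, "ALA", "A", "protein")
             for k, (p, el) in enumerate(zip(
                 prot_xyz, rng.choice(["C", "N", "O"], size=40)))],
            id="generic")
        coords = big_site.center + rng.uniform(-3, 3, size=(5, 3)) + 0.091
        pose = Pose(coords, RigidTransform.identity(), True,
                    elements=["C", "N", "O", "S", "C"])
        spec = GridSpec(n=16)
        base = rasterize(struct, pose, big_site, spec)

        rotations = []
        for perm in itertools.permutations(range(3)):
            for signs in itertools.product([1, -1], repeat=3):
                R = np.zeros((3, 3))
                for row, (col, sg) in enumerate(zip(perm, signs)):
                    R[row, col] = sg
                if np.linalg.det(R) > 0:
                    rotations.append(R)
        assert len(rotations) == 24

        c = big_site.center
        half = (spec.n - 1) / 2.0
        for R in rotations:
            moved_struct = struct.transformed(R, np.zeros(3), about=c)
            moved_pose = Pose((coords - c) @ R.T + c,
                              RigidTransform.identity(), True,
                              elements=pose.elements)
            rotated = rasterize(moved_struct, moved_pose, big_site, spec)
            # voxel permutation: index i -> R (i - half) + half
            idx = np.argwhere(base.values)
            expected = np.zeros_like(base.values)
            for ch, i, j, k in idx:
                v = R @ (np.array([i, j, k]) - half) + half
                vi = np.round(v).astype(int)
                expected[ch, vi[0], vi[1], vi[2]] = 1
            np.testing.assert_array_equal(rotated.values, expected)
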